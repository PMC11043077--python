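"""Synthetic paired bulk multi-omics cohorts with known cellular composition.

The generator emulates the statistical structure the deconvolution model
assumes: a shared per-sample cell-count fraction vector p (Dirichlet),
modality-specific lognormal cell size factors s1/s2, individualized
reference panels (a base panel perturbed by per-sample lognormal effects),
and bulk profiles formed as panel @ (p * s) plus additive Gaussian noise on
the log2 scale. Two coupling scenarios control how correlated the protein
and RNA molecule-level fractions are: scenario A draws the size factors of
the two modalities independently (low cross-modality correlation), scenario
B derives both from one shared draw with a small modality-specific
perturbation (high correlation).

Pseudo signature matrices for initialization are made by multiplicative
lognormal corruption of the true RNA base panel ('small' sd 0.1 / 'large'
sd 0.5), and marker genes are ranked by their coefficient of variation
across cell types. A genotype generator plants cell-type-specific
protein-panel shifts so the QTL screen has a known causal cell type.

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BulkMatrix, GeneAnnotation, GenotypeTable, PairedBulk, SignatureMatrix
from .jnmf import normalize_fractions

SIGNATURE_NOISE_SD = {"small": 0.1, "large": 0.5}


@dataclass
class NoiseSpec:
    """Noise configuration for the generator.

    panel_cv : sd of the per-sample lognormal panel heterogeneity.
    bulk_sd : sd of the additive Gaussian noise applied on the log2 scale.
    signature_noise : 'small' or 'large', the multiplicative lognormal sd
        used when corrupting the true signature into a pseudo signature.
    """

    panel_cv: float = 0.2
    bulk_sd: float = 0.05
    signature_noise: str = "small"

    def __post_init__(self) -> None:
        if self.panel_cv < 0 or self.bulk_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.signature_noise not in SIGNATURE_NOISE_SD:
            raise ValueError(f"signature_noise must be one of {sorted(SIGNATURE_NOISE_SD)}")


@dataclass
class FractionDraw:
    p: np.ndarray  # (n, K) cell-count fractions, rows on the simplex
    s1: np.ndarray  # (n, K) protein size factors
    s2: np.ndarray  # (n, K) RNA size factors
    theta1: np.ndarray  # (n, K) normalized protein fractions
    theta2: np.ndarray  # (n, K) normalized RNA fractions


@dataclass
class TruthSet:
    """Full ground truth of one synthetic cohort."""

    p_true: np.ndarray
    s1_true: np.ndarray
    s2_true: np.ndarray
    X1_base: np.ndarray  # (G, K)
    X2_base: np.ndarray  # (M, K)
    panels1: np.ndarray  # (n, G, K) individualized protein panels
    panels2: np.ndarray  # (n, M, K)
    theta1_true: np.ndarray
    theta2_true: np.ndarray
    scenario: str
    seed: int
    protein_ids: list[str]
    gene_ids: list[str]
    cell_types: list[str]
    sample_ids: list[str]
    protein_to_gene: dict[str, str]
    params: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.p_true.shape[0]

    @property
    def K(self) -> int:
        return self.p_true.shape[1]

    def signature(self) -> SignatureMatrix:
        """The true RNA signature (base panel) used to seed pseudo signatures."""
        return SignatureMatrix(self.X2_base.copy(), list(self.gene_ids), list(self.cell_types))


def simulate_fractions(
    n: int,
    K: int,
    scenario: str = "A",
    concentration: float = 2.0,
    coupling: float = 0.5,
    s_sd: float = 0.4,
    seed: int | None = None,
) -> FractionDraw:
    """Draw shared cell counts and modality-specific size factors.

    p rows ~ Dirichlet(concentration * 1_K); size factors are lognormal with
    sd ``s_sd``. Under scenario B, s1 and s2 share one base draw and differ
    only by a lognormal perturbation of sd ``(1 - coupling) * s_sd``, so the
    cross-modality correlation of the normalized fractions increases
    monotonically with ``coupling``.
    """
    if n < 2 or K < 1:
        raise ValueError("need n >= 2 samples and K >= 1 cell types")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if scenario not in ("A", "B"):
        raise ValueError("scenario must be 'A' or 'B'")
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.full(K, concentration), size=n)
    if scenario == "A":
        s1 = rng.lognormal(0.0, s_sd, size=(n, K))
        s2 = rng.lognormal(0.0, s_sd, size=(n, K))
    else:
        base = rng.lognormal(0.0, s_sd, size=(n, K))
        perturb_sd = max(1.0 - coupling, 0.0) * s_sd
        s1 = base * rng.lognormal(0.0, perturb_sd, size=(n, K))
        s2 = base * rng.lognormal(0.0, perturb_sd, size=(n, K))
    theta1 = np.vstack([normalize_fractions(p[i], s1[i]) for i in range(n)])
    theta2 = np.vstack([normalize_fractions(p[i], s2[i]) for i in range(n)])
    return FractionDraw(p=p, s1=s1, s2=s2, theta1=theta1, theta2=theta2)


def simulate_reference_panels(
    X1_base: np.ndarray,
    X2_base: np.ndarray,
    n: int,
    panel_cv: float,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Individualized panels: base panel times elementwise lognormal(0, cv)
    per sample. ``panel_cv=0`` gives identical panels for every sample."""
    X1_base = np.asarray(X1_base, dtype=float)
    X2_base = np.asarray(X2_base, dtype=float)
    if np.any(X1_base < 0) or np.any(X2_base < 0):
        raise ValueError("base panels must be non-negative")
    rng = np.random.default_rng(seed)
    panels1 = X1_base[None] * rng.lognormal(0.0, panel_cv, size=(n,) + X1_base.shape)
    panels2 = X2_base[None] * rng.lognormal(0.0, panel_cv, size=(n,) + X2_base.shape)
    return panels1, panels2


def _base_panels(
    G: int,
    K: int,
    M: int,
    rng: np.random.Generator,
    marker_frac: float = 0.3,
    marker_fold: float = 8.0,
    base_sd: float = 0.5,
    protein_shift_sd: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Marker-structured base panels: a fraction of genes is boosted
    ``marker_fold``-fold in one assigned cell type; the protein panel is the
    RNA panel of the coding gene times a lognormal translation-efficiency
    factor."""
    if G > M:
        raise ValueError("G <= M required (each protein maps to one gene)")
    X2 = rng.lognormal(0.0, base_sd, size=(M, K))
    n_marker = int(round(marker_frac * M))
    marker_rows = rng.choice(M, size=n_marker, replace=False)
    marker_ct = rng.integers(0, K, size=n_marker)
    X2[marker_rows, marker_ct] *= marker_fold
    X1 = X2[:G] * rng.lognormal(0.0, protein_shift_sd, size=(G, K))
    return X1, X2


def make_truth(
    n: int = 50,
    K: int = 4,
    G: int = 500,
    M: int = 500,
    scenario: str = "A",
    concentration: float = 2.0,
    coupling: float = 0.5,
    s_sd: float = 0.4,
    panel_cv: float = 0.2,
    marker_frac: float = 0.3,
    marker_fold: float = 8.0,
    protein_shift_sd: float = 0.3,
    seed: int = 0,
) -> TruthSet:
    """Assemble a complete ground-truth cohort (fractions, base panels,
    individualized panels, derived thetas) under one scenario and seed.

    ``s_sd=0, panel_cv=0, protein_shift_sd=0`` gives a fully degenerate
    cohort (unit size factors, shared panels, protein panel equal to the RNA
    panel of the coding gene) whose generating parameters coincide with the
    standard initialization — useful for exact-recovery checks.
    """
    rng = np.random.default_rng(seed)
    frac = simulate_fractions(
        n, K, scenario, concentration, coupling, s_sd,
        seed=int(rng.integers(2**31)),
    )
    X1_base, X2_base = _base_panels(
        G, K, M, rng, marker_frac, marker_fold, protein_shift_sd=protein_shift_sd
    )
    panels1, panels2 = simulate_reference_panels(
        X1_base, X2_base, n, panel_cv, seed=int(rng.integers(2**31))
    )
    gene_ids = [f"gene_{j:05d}" for j in range(M)]
    protein_ids = [f"prot_{j:05d}" for j in range(G)]
    return TruthSet(
        p_true=frac.p,
        s1_true=frac.s1,
        s2_true=frac.s2,
        X1_base=X1_base,
        X2_base=X2_base,
        panels1=panels1,
        panels2=panels2,
        theta1_true=frac.theta1,
        theta2_true=frac.theta2,
        scenario=scenario,
        seed=seed,
        protein_ids=protein_ids,
        gene_ids=gene_ids,
        cell_types=[f"ct{k}" for k in range(K)],
        sample_ids=[f"S{i:04d}" for i in range(n)],
        protein_to_gene={p: g for p, g in zip(protein_ids, gene_ids)},
        params=dict(
            n=n, K=K, G=G, M=M, scenario=scenario, concentration=concentration,
            coupling=coupling, s_sd=s_sd, panel_cv=panel_cv,
            marker_frac=marker_frac, marker_fold=marker_fold,
            protein_shift_sd=protein_shift_sd, seed=seed,
        ),
    )


def synthesize_bulk(truth: TruthSet, noise: NoiseSpec | None = None, seed: int | None = None) -> PairedBulk:
    """Mix the individualized panels into paired bulk profiles.

    Per sample i and modality j: y = panels_j[i] @ (p_i * s_i^(j)); with
    ``bulk_sd > 0`` additive Gaussian noise is applied on the log2(y+1)
    scale, back-transformed, and clamped at zero.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    n = truth.n
    w1 = truth.p_true * truth.s1_true  # (n, K)
    w2 = truth.p_true * truth.s2_true
    Y1 = np.einsum("ngk,nk->gn", truth.panels1, w1)
    Y2 = np.einsum("nmk,nk->mn", truth.panels2, w2)
    if noise.bulk_sd > 0:
        Y1 = np.maximum(
            np.exp2(np.log2(Y1 + 1.0) + rng.normal(0.0, noise.bulk_sd, size=Y1.shape)) - 1.0, 0.0
        )
        Y2 = np.maximum(
            np.exp2(np.log2(Y2 + 1.0) + rng.normal(0.0, noise.bulk_sd, size=Y2.shape)) - 1.0, 0.0
        )
    protein = BulkMatrix(Y1, truth.protein_ids, truth.sample_ids, "protein")
    rna = BulkMatrix(Y2, truth.gene_ids, truth.sample_ids, "rna")
    return PairedBulk(protein=protein, rna=rna, protein_to_gene=dict(truth.protein_to_gene))


def perturb_signature(
    signature: SignatureMatrix,
    level: str | float = "small",
    seed: int | None = None,
) -> SignatureMatrix:
    """Pseudo signature: elementwise multiplicative lognormal noise with sd
    0.1 ('small') or 0.5 ('large'); a float gives the sd directly."""
    sd = SIGNATURE_NOISE_SD[level] if isinstance(level, str) else float(level)
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    vals = signature.values * rng.lognormal(0.0, sd, size=signature.values.shape)
    return SignatureMatrix(vals, list(signature.feature_ids), list(signature.cell_types))


def rank_markers_by_cv(signature: SignatureMatrix, top_frac: float = 0.5) -> list[str]:
    """Rank signature genes by coefficient of variation across cell types
    (descending; ties by input order) and keep the top fraction."""
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    vals = signature.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    order = np.argsort(-cv, kind="stable")
    n_keep = max(1, int(round(top_frac * len(order))))
    return [signature.feature_ids[i] for i in order[:n_keep]]


def make_planted_selection_cohort(
    n: int = 40,
    G: int = 500,
    n_planted: int = 50,
    M: int = 100,
    K: int = 4,
    signal_sd: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[PairedBulk, list[str]]:
    """Cohort for validating signature-protein selection.

    ``n_planted`` proteins carry the shared cell-composition signal (random
    loadings on the centered cell-count fractions plus measurement noise of
    sd ``noise_sd``); the remaining proteins are independent noise whose
    total variance matches the planted rows, so selection must identify the
    shared structure, not just row variance. All ``M`` RNA marker genes load
    the same composition factor. Values are on the log scale (may be
    negative). Returns the paired cohort and the planted protein ids.
    """
    if not 0 < n_planted <= G:
        raise ValueError("need 0 < n_planted <= G")
    rng = np.random.default_rng(seed)
    frac = simulate_fractions(n, K, "B", seed=int(rng.integers(2**31)))
    Zc = frac.p - frac.p.mean(axis=0)  # (n, K) centered shared composition
    Y1 = np.empty((G, n))
    bg_sd = float(np.sqrt(signal_sd**2 * Zc.var() * K + noise_sd**2))
    planted_idx = rng.choice(G, size=n_planted, replace=False)
    planted_mask = np.zeros(G, dtype=bool)
    planted_mask[planted_idx] = True
    load1 = rng.normal(0.0, signal_sd, size=(n_planted, K))
    Y1[planted_mask] = load1 @ Zc.T + rng.normal(0.0, noise_sd, size=(n_planted, n))
    Y1[~planted_mask] = rng.normal(0.0, bg_sd, size=(G - n_planted, n))
    load2 = rng.normal(0.0, signal_sd, size=(M, K))
    Y2 = load2 @ Zc.T + rng.normal(0.0, noise_sd, size=(M, n))
    protein_ids = [f"prot_{j:05d}" for j in range(G)]
    gene_ids = [f"gene_{j:05d}" for j in range(M)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    paired = PairedBulk(
        protein=BulkMatrix(Y1, protein_ids, sample_ids, "protein", scale="log"),
        rna=BulkMatrix(Y2, gene_ids, sample_ids, "rna", scale="log"),
    )
    return paired, [protein_ids[j] for j in sorted(planted_idx)]


@dataclass(frozen=True)
class PlantedEffect:
    """A cell-type-specific genotype effect on the protein panel.

    For every carrier sample, ``beta * dosage`` is added to the panel rows
    of ``protein_indices`` in cell type ``cell_type`` before mixing.
    """

    snp_index: int
    cell_type: int
    protein_indices: tuple[int, ...]
    beta: float


def simulate_genotypes(
    truth: TruthSet,
    n_snps: int,
    maf: float = 0.3,
    effects: Sequence[PlantedEffect] = (),
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    bulk_seed: int | None = None,
    chromosome: str = "1",
    first_position: int = 1_000_000,
    spacing: int = 5_000,
) -> tuple[GenotypeTable, BulkMatrix]:
    """Draw SNP dosages ~ Binomial(2, maf) and re-mix the protein bulk with
    planted cell-type-specific panel shifts.

    With no effects the returned protein matrix is identical to the one
    :func:`synthesize_bulk` produces for the same ``bulk_seed``.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf, size=(n_snps, truth.n)).astype(float)
    snp_ids = [f"snp_{j:05d}" for j in range(n_snps)]
    positions = [(chromosome, first_position + j * spacing) for j in range(n_snps)]
    table = GenotypeTable(dosages, snp_ids, truth.sample_ids, positions)

    panels1 = truth.panels1.copy()
    for eff in effects:
        shift = eff.beta * dosages[eff.snp_index]  # (n,)
        idx = list(eff.protein_indices)
        panels1[:, idx, eff.cell_type] = np.maximum(
            panels1[:, idx, eff.cell_type] + shift[:, None], 0.0
        )
    modified = TruthSet(**{**asdict_shallow(truth), "panels1": panels1})
    bulk = synthesize_bulk(modified, noise, seed=bulk_seed)
    return table, bulk.protein


def asdict_shallow(truth: TruthSet) -> dict:
    """Field dict without deep-copying the arrays (dataclasses.asdict would)."""
    return {f: getattr(truth, f) for f in truth.__dataclass_fields__}


def make_gene_annotations(
    truth: TruthSet,
    chromosome: str = "1",
    first_start: int = 1_000_000,
    gene_length: int = 2_000,
    spacing: int = 5_000,
) -> list[GeneAnnotation]:
    """Evenly spaced 1-based gene intervals for the cohort's genes, so the
    planted-QTL screen has coordinates to pair against."""
    return [
        GeneAnnotation(g, chromosome, first_start + j * spacing,
                       first_start + j * spacing + gene_length - 1)
        for j, g in enumerate(truth.gene_ids)
    ]


def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    """Write the ground-truth matrices and the generator parameterization
    (metadata.yaml sidecar) to ``outdir``."""
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ct, sid = truth.cell_types, truth.sample_ids
    pd.DataFrame(truth.p_true, index=sid, columns=ct).to_csv(outdir / "p_true.tsv", sep="\t")
    pd.DataFrame(truth.s1_true, index=sid, columns=ct).to_csv(outdir / "s1_true.tsv", sep="\t")
    pd.DataFrame(truth.s2_true, index=sid, columns=ct).to_csv(outdir / "s2_true.tsv", sep="\t")
    pd.DataFrame(truth.theta1_true, index=sid, columns=ct).to_csv(outdir / "theta1_true.tsv", sep="\t")
    pd.DataFrame(truth.theta2_true, index=sid, columns=ct).to_csv(outdir / "theta2_true.tsv", sep="\t")
    pd.DataFrame(truth.X1_base, index=truth.protein_ids, columns=ct).to_csv(outdir / "X1_base.tsv", sep="\t")
    pd.DataFrame(truth.X2_base, index=truth.gene_ids, columns=ct).to_csv(outdir / "X2_base.tsv", sep="\t")
    with open(outdir / "metadata.yaml", "w") as fh:
        yaml.safe_dump({"generator": "omixdeconv.synth.make_truth", **truth.params}, fh)
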