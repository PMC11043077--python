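"""Cell-type-specific protein QTL screening.

Given bulk protein abundance, pre-estimated cell-type fractions theta
(samples x K) and SNP dosages, each candidate (protein, SNP) pair in cis is
tested with an interaction linear model,

    E[y_i] = sum_k theta_ik * beta_k
           + sum_k sum_{a in {1,2}} theta_ik * gamma_ka * 1[g_i = a],

i.e. genotype enters categorically and every effect is scaled by the
fraction of the cell type it acts in. There is no global intercept: when
theta rows sum to one the intercept direction lies in the span of the theta
columns, which also makes the test invariant to constant shifts of y. The
cell-type-k hypothesis H0: gamma_k1 = gamma_k2 = 0 is assessed by a nested
F-test on residual sums of squares, and p-values are Benjamini-Hochberg
adjusted per cell type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BulkMatrix, GeneAnnotation, GenotypeTable

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000


def cis_pairs(
    gene_annotations: list[GeneAnnotation],
    snps: GenotypeTable,
    window: int = DEFAULT_CIS_WINDOW,
) -> list[tuple[str, str]]:
    """All (gene_id, snp_id) pairs on the same chromosome with distance
    between the SNP position and the gene interval at most ``window`` bases
    (distance 0 when the SNP lies inside the gene)."""
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for sid, (chrom, pos) in zip(snps.snp_ids, snps.snp_positions):
        by_chrom.setdefault(str(chrom), []).append((int(pos), sid))
    pairs = []
    for gene in gene_annotations:
        for pos, sid in by_chrom.get(str(gene.chromosome), []):
            if gene.start <= pos <= gene.end:
                dist = 0
            else:
                dist = min(abs(pos - gene.start), abs(pos - gene.end))
            if dist <= window:
                pairs.append((gene.gene_id, sid))
    return pairs


@dataclass
class CellTypeTest:
    cell_type: str
    F: float
    df1: int
    df2: int
    p: float
    n_used: int
    skipped: str | None = None  # reason, when the test could not be run


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Least-squares residual sum of squares and design rank (pseudo-inverse
    fit, so rank-deficient designs are handled without error)."""
    coef, residuals, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), int(rank)


def csqtl_ftest(
    y: np.ndarray,
    theta: np.ndarray,
    genotype: np.ndarray,
    cell_types: list[str] | None = None,
    covariates: np.ndarray | None = None,
    genotype_mode: str = "categorical",
) -> list[CellTypeTest]:
    """Per-cell-type interaction F-test of genotype effect on bulk abundance.

    Missing genotypes or y values drop the sample (complete case). With
    ``genotype_mode='additive'`` the dosage enters as a single linear term
    per cell type (df1 = 1). Zero residual variance in the full model (e.g.
    constant y) yields F = 0, p = 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    theta = np.asarray(theta, dtype=float)
    g = np.asarray(genotype, dtype=float).ravel()
    n, K = theta.shape
    if y.size != n or g.size != n:
        raise ValueError("y, theta and genotype must share the sample dimension")
    names = cell_types if cell_types is not None else [f"ct{k}" for k in range(K)]

    keep = np.isfinite(y) & np.isfinite(g)
    y, theta, g = y[keep], theta[keep], g[keep]
    n_used = int(keep.sum())

    groups = np.unique(g)
    if groups.size < 2:
        return [
            CellTypeTest(names[k], np.nan, 0, 0, np.nan, n_used,
                         skipped="fewer than two genotype groups observed")
            for k in range(K)
        ]

    if genotype_mode == "categorical":
        # baseline = smallest observed genotype; one indicator per other group
        contrasts = [(g == a).astype(float) for a in groups[1:]]
    elif genotype_mode == "additive":
        contrasts = [g]
    else:
        raise ValueError("genotype_mode must be 'categorical' or 'additive'")
    q = len(contrasts)

    inter_cols = [theta[:, k] * c for k in range(K) for c in contrasts]
    X_parts = [theta] + [np.column_stack(inter_cols)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cov = cov[keep] if cov.shape[0] == keep.size else cov
        X_parts.append(cov.reshape(len(y), -1))
    X_full = np.column_stack(X_parts)

    rss1, rank_full = _ols_rss(X_full, y)
    if rank_full < X_full.shape[1]:
        logger.warning("csqtl_ftest: singular full design (rank %d < %d); pseudo-inverse fit",
                       rank_full, X_full.shape[1])
    df2 = len(y) - rank_full
    if df2 <= 0:
        return [
            CellTypeTest(names[k], np.nan, q, df2, np.nan, n_used,
                         skipped="not enough samples for the full design")
            for k in range(K)
        ]

    out = []
    for k in range(K):
        drop = {K + k * q + j for j in range(q)}  # this cell type's interaction columns
        keep_cols = [c for c in range(X_full.shape[1]) if c not in drop]
        rss0, _ = _ols_rss(X_full[:, keep_cols], y)
        num = max(rss0 - rss1, 0.0) / q
        scale = float(y @ y) + 1.0
        if rss1 <= 1e-12 * scale:
            if num <= 1e-12 * scale:
                out.append(CellTypeTest(names[k], 0.0, q, df2, 1.0, n_used))
            else:
                out.append(CellTypeTest(names[k], np.inf, q, df2, 0.0, n_used))
            continue
        F = num / (rss1 / df2)
        p = float(stats.f.sf(F, q, df2))
        out.append(CellTypeTest(names[k], float(F), q, df2, p, n_used))
    return out


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_csqtl(
    protein: BulkMatrix,
    theta: pd.DataFrame,
    genotypes: GenotypeTable,
    gene_annotations: list[GeneAnnotation],
    protein_to_gene: dict[str, str] | None = None,
    window: int = DEFAULT_CIS_WINDOW,
    covariates: np.ndarray | None = None,
    genotype_mode: str = "categorical",
    fdr_scope: str = "per_cell_type",
) -> pd.DataFrame:
    """Screen every cis (protein, SNP) pair and return a tidy result table.

    ``theta`` is a samples x cell-types DataFrame aligned to
    ``protein.sample_ids``. Proteins are located through their coding gene's
    annotation (identity mapping when ``protein_to_gene`` is None); proteins
    without an annotation are skipped and counted. BH adjustment is applied
    per cell type across all tested pairs (``fdr_scope='pooled'`` pools all
    rows instead).
    """
    theta = theta.loc[protein.sample_ids]
    mapping = protein_to_gene or {p: p for p in protein.feature_ids}
    annot_by_gene = {a.gene_id: a for a in gene_annotations}

    shared = [s for s in protein.sample_ids if s in set(genotypes.sample_ids)]
    if not shared:
        raise ValueError("no shared samples between protein matrix and genotypes")
    prot = protein.subset_samples(shared)
    th = theta.loc[shared].to_numpy(dtype=float)
    geno_idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
    geno_cols = [geno_idx[s] for s in shared]

    gene_to_proteins: dict[str, list[str]] = {}
    n_unannotated = 0
    for p_id in prot.feature_ids:
        gene = mapping.get(p_id)
        if gene is None or gene not in annot_by_gene:
            n_unannotated += 1
            continue
        gene_to_proteins.setdefault(gene, []).append(p_id)
    if n_unannotated:
        logger.warning("run_csqtl: skipped %d proteins without gene annotation", n_unannotated)

    genes = [annot_by_gene[g] for g in gene_to_proteins]
    pairs = cis_pairs(genes, genotypes, window=window)

    feat_idx = {f: i for i, f in enumerate(prot.feature_ids)}
    snp_idx = {s: i for i, s in enumerate(genotypes.snp_ids)}
    rows = []
    for gene_id, snp_id in pairs:
        dosage = genotypes.dosages[snp_idx[snp_id], geno_cols]
        for p_id in gene_to_proteins[gene_id]:
            yvec = prot.values[feat_idx[p_id], :]
            tests = csqtl_ftest(
                yvec, th, dosage, cell_types=list(theta.columns),
                covariates=covariates, genotype_mode=genotype_mode,
            )
            for t in tests:
                rows.append(
                    dict(protein_id=p_id, snp_id=snp_id, cell_type=t.cell_type,
                         F_stat=t.F, df1=t.df1, df2=t.df2, p_value=t.p,
                         n_used=t.n_used, skipped=t.skipped)
                )
    result = pd.DataFrame(
        rows,
        columns=["protein_id", "snp_id", "cell_type", "F_stat", "df1", "df2",
                 "p_value", "n_used", "skipped"],
    )
    result["q_value"] = np.nan
    tested = result["p_value"].notna()
    if tested.any():
        if fdr_scope == "per_cell_type":
            for ct, idx in result[tested].groupby("cell_type").groups.items():
                result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"].to_numpy())
        elif fdr_scope == "pooled":
            result.loc[tested, "q_value"] = bh_adjust(result.loc[tested, "p_value"].to_numpy())
        else:
            raise ValueError("fdr_scope must be 'per_cell_type' or 'pooled'")
    return result
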