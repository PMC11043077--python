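"""Joint non-negative matrix factorization of paired bulk profiles.

For each tissue sample i the observed bulk protein vector y1 (length G) and
bulk RNA vector y2 (length M) are modeled as mixtures over K cell types,

    E[y1] = X1 diag(p) s1,      E[y2] = X2 diag(p) s2,

where X1 (G x K) and X2 (M x K) are individualized purified expression
panels, p (length K) the tissue cell-count fractions shared across the two
molecular sources, and s1, s2 (length K) modality-specific cell size factors
(per-cell molecular yield). The molecule-level fraction of cell type k in
modality j is theta_k = p_k * s_k^(j), normalized to the simplex at the end.

All parameters eta = {X1, X2, p, s1, s2} are estimated per sample by
minimizing the summed squared-error loss

    l(eta) = ||y1 - X1 diag(p) s1||^2 + ||y2 - X2 diag(p) s2||^2

with projected gradient descent: a gradient step followed by projection onto
the non-negative orthant, with rejection-and-halving of the step size so the
loss trace is non-increasing. Initialization uses an external RNA signature
matrix (copied into both panels via a protein->gene map), unit size factors,
and user-supplied or NNLS cell-count fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .core import BulkMatrix, PairedBulk, SignatureMatrix, rescale

logger = logging.getLogger(__name__)


@dataclass
class ParamSet:
    """Per-sample JNMF parameters (all non-negative)."""

    X1: np.ndarray  # (G, K) purified protein panel
    X2: np.ndarray  # (M, K) purified RNA panel
    p: np.ndarray  # (K,) cell-count fractions
    s1: np.ndarray  # (K,) protein size factors
    s2: np.ndarray  # (K,) RNA size factors

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        self.p = np.asarray(self.p, dtype=float).ravel()
        self.s1 = np.asarray(self.s1, dtype=float).ravel()
        self.s2 = np.asarray(self.s2, dtype=float).ravel()
        K = self.p.size
        if self.X1.ndim != 2 or self.X2.ndim != 2:
            raise ValueError("X1/X2 must be 2-dimensional")
        if self.X1.shape[1] != K or self.X2.shape[1] != K:
            raise ValueError("X1/X2 column count must equal len(p)")
        if self.s1.size != K or self.s2.size != K:
            raise ValueError("s1/s2 must have length K")

    @property
    def K(self) -> int:
        return self.p.size

    def copy(self) -> "ParamSet":
        return ParamSet(self.X1.copy(), self.X2.copy(), self.p.copy(), self.s1.copy(), self.s2.copy())

    def blocks(self) -> dict[str, np.ndarray]:
        return {"X1": self.X1, "X2": self.X2, "p": self.p, "s1": self.s1, "s2": self.s2}

    def max_abs_diff(self, other: "ParamSet") -> float:
        return max(
            float(np.max(np.abs(a - b))) if a.size else 0.0
            for a, b in zip(self.blocks().values(), other.blocks().values())
        )


@dataclass
class FitOptions:
    """Optimizer settings for per-sample projected gradient descent.

    step is the PGD step size Delta; tol the convergence threshold epsilon on
    the max absolute parameter change; rescale_method optionally transforms
    the bulk (and signature) values before fitting ('log', 'minmax', None).
    """

    step: float = 1e-3
    tol: float = 1e-5
    max_iter: int = 1000
    max_halvings: int = 30
    rescale_method: str | None = None

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


@dataclass
class DeconvResult:
    """Output of :func:`deconvolve`.

    theta1/theta2 rows (samples x K) are the normalized modality-specific
    fractions; rows of failed samples are NaN and listed in ``failures``.
    """

    theta1: np.ndarray
    theta2: np.ndarray
    cell_types: list[str]
    sample_ids: list[str]
    panels: list[ParamSet]
    loss_trace: list[np.ndarray]
    converged: np.ndarray
    iterations: np.ndarray
    init_props: np.ndarray
    failures: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# NNLS initial proportions
# ---------------------------------------------------------------------------

def nnls_proportions(bulk_markers: np.ndarray, signature: SignatureMatrix) -> np.ndarray:
    """Per-sample non-negative least squares of bulk marker expression on the
    signature columns, renormalized to the simplex.

    ``bulk_markers`` is (marker features x samples) with rows aligned to
    ``signature.feature_ids``. All-zero NNLS solutions map to uniform 1/K
    with a warning; a rank-deficient signature warns but still returns.
    """
    S = signature.values
    Y = np.asarray(bulk_markers, dtype=float)
    if Y.shape[0] != S.shape[0]:
        raise ValueError("bulk marker rows must align with signature features")
    K = S.shape[1]
    if np.linalg.matrix_rank(S) < K:
        warnings.warn("signature matrix is rank deficient; NNLS solution not unique")
    out = np.empty((Y.shape[1], K))
    for i in range(Y.shape[1]):
        w, _ = _scipy_nnls(S, Y[:, i])
        tot = w.sum()
        if tot <= 0:
            warnings.warn(f"NNLS returned all zeros for sample {i}; using uniform fractions")
            out[i] = 1.0 / K
        else:
            out[i] = w / tot
    return out


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

@dataclass
class Initialization:
    """Initial parameters plus the feature-filtered views of the data they
    correspond to (proteins without a mapped signature gene are dropped)."""

    param_sets: list[ParamSet]
    protein_ids: list[str]
    rna_ids: list[str]
    y1: np.ndarray  # (G, n)
    y2: np.ndarray  # (M, n)
    init_props: np.ndarray  # (n, K)
    cell_types: list[str]
    sample_ids: list[str]
    n_dropped_proteins: int
    n_dropped_genes: int


def initialize_parameters(
    paired: PairedBulk,
    signature: SignatureMatrix,
    init_props: np.ndarray | None = None,
) -> Initialization:
    """Build identical initial parameter sets for every sample.

    X2 rows are the signature rows of the retained RNA features; X1 rows are
    the signature rows of each protein's mapped gene; size factors start at
    one. Cell-count fractions come from ``init_props`` (renormalized with a
    warning if rows do not sum to 1) or NNLS on the RNA features shared with
    the signature.
    """
    sig_index = {f: i for i, f in enumerate(signature.feature_ids)}

    rna_keep = [g for g in paired.rna.feature_ids if g in sig_index]
    n_dropped_genes = paired.rna.n_features - len(rna_keep)
    if not rna_keep:
        raise ValueError("no RNA feature overlaps the signature matrix")
    if n_dropped_genes:
        logger.info("initialize_parameters: dropped %d RNA features absent from signature", n_dropped_genes)

    prot_keep, prot_sig_rows = [], []
    for prot in paired.protein.feature_ids:
        gene = paired.protein_to_gene.get(prot)
        if gene is not None and gene in sig_index:
            prot_keep.append(prot)
            prot_sig_rows.append(sig_index[gene])
    n_dropped_prot = paired.protein.n_features - len(prot_keep)
    if not prot_keep:
        raise ValueError("no protein maps to a signature gene; check protein_to_gene")
    if n_dropped_prot:
        logger.info("initialize_parameters: dropped %d proteins without a mapped signature gene", n_dropped_prot)

    y1 = paired.protein.subset_features(prot_keep).values
    y2 = paired.rna.subset_features(rna_keep).values
    X1_0 = signature.values[prot_sig_rows, :]
    X2_0 = signature.values[[sig_index[g] for g in rna_keep], :]
    K = signature.n_cell_types
    n = paired.n_samples

    if init_props is None:
        props = nnls_proportions(y2, signature.subset_features(rna_keep))
    else:
        props = np.asarray(init_props, dtype=float)
        if props.shape != (n, K):
            raise ValueError(f"init_props must be (n_samples={n}, K={K}), got {props.shape}")
        if np.any(props < 0):
            raise ValueError("init_props must be non-negative")
        sums = props.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("init_props rows must have positive sum")
        if not np.allclose(sums, 1.0, atol=1e-8):
            warnings.warn("init_props rows do not sum to 1; renormalizing")
            props = props / sums[:, None]

    params = [
        ParamSet(X1_0.copy(), X2_0.copy(), props[i].copy(), np.ones(K), np.ones(K))
        for i in range(n)
    ]
    return Initialization(
        param_sets=params,
        protein_ids=prot_keep,
        rna_ids=rna_keep,
        y1=y1,
        y2=y2,
        init_props=props,
        cell_types=list(signature.cell_types),
        sample_ids=list(paired.sample_ids),
        n_dropped_proteins=n_dropped_prot,
        n_dropped_genes=n_dropped_genes,
    )


# ---------------------------------------------------------------------------
# Loss, gradient, projection
# ---------------------------------------------------------------------------

def jnmf_loss(param: ParamSet, y1: np.ndarray, y2: np.ndarray) -> float:
    """Summed squared-error loss of the two modality fits."""
    w1 = param.p * param.s1
    w2 = param.p * param.s2
    with np.errstate(over="ignore"):  # overflow -> inf, caught by the fit loop
        r1 = np.asarray(y1, float).ravel() - param.X1 @ w1
        r2 = np.asarray(y2, float).ravel() - param.X2 @ w2
        return float(r1 @ r1 + r2 @ r2)


def jnmf_gradient(param: ParamSet, y1: np.ndarray, y2: np.ndarray) -> ParamSet:
    """Analytic gradient of :func:`jnmf_loss` w.r.t. every parameter block.

    The cell-count fractions p appear in both modality terms, so their
    gradient sums contributions from protein and RNA residuals.
    """
    y1 = np.asarray(y1, float).ravel()
    y2 = np.asarray(y2, float).ravel()
    w1 = param.p * param.s1
    w2 = param.p * param.s2
    r1 = y1 - param.X1 @ w1
    r2 = y2 - param.X2 @ w2
    Xtr1 = param.X1.T @ r1  # (K,)
    Xtr2 = param.X2.T @ r2
    return ParamSet(
        X1=-2.0 * np.outer(r1, w1),
        X2=-2.0 * np.outer(r2, w2),
        p=-2.0 * (Xtr1 * param.s1 + Xtr2 * param.s2),
        s1=-2.0 * Xtr1 * param.p,
        s2=-2.0 * Xtr2 * param.p,
    )


def project_nonneg(param: ParamSet) -> ParamSet:
    """Project every block onto the non-negative orthant (elementwise clamp)."""
    return ParamSet(
        np.maximum(param.X1, 0.0),
        np.maximum(param.X2, 0.0),
        np.maximum(param.p, 0.0),
        np.maximum(param.s1, 0.0),
        np.maximum(param.s2, 0.0),
    )


# ---------------------------------------------------------------------------
# Per-sample optimization
# ---------------------------------------------------------------------------

def fit_sample(
    y1: np.ndarray,
    y2: np.ndarray,
    init: ParamSet,
    opts: FitOptions | None = None,
) -> tuple[ParamSet, np.ndarray, bool, int]:
    """Fit one sample by projected gradient descent.

    Iterates eta <- [eta - step * grad l(eta)]_+ . A step that would increase
    the loss is rejected and the step size halved (up to ``max_halvings``),
    so the returned loss trace is non-increasing. Convergence is declared
    when the max absolute parameter change falls below ``tol``.

    Returns (final parameters, loss trace incl. the initial loss, converged
    flag, number of iterations taken).
    """
    opts = opts or FitOptions()
    eta = project_nonneg(init)
    loss = jnmf_loss(eta, y1, y2)
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss at iteration 0")
    trace = [loss]
    step = opts.step
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        grad = jnmf_gradient(eta, y1, y2)
        cand = None
        for _ in range(opts.max_halvings + 1):
            trial = ParamSet(
                np.maximum(eta.X1 - step * grad.X1, 0.0),
                np.maximum(eta.X2 - step * grad.X2, 0.0),
                np.maximum(eta.p - step * grad.p, 0.0),
                np.maximum(eta.s1 - step * grad.s1, 0.0),
                np.maximum(eta.s2 - step * grad.s2, 0.0),
            )
            trial_loss = jnmf_loss(trial, y1, y2)
            if not np.isfinite(trial_loss):
                raise FloatingPointError(f"non-finite loss at iteration {it}")
            if trial_loss <= loss:
                cand = (trial, trial_loss)
                break
            step *= 0.5
        if cand is None:
            # even the smallest step increases the loss: stalled at a
            # (numerical) stationary point
            converged = True
            it -= 1
            break
        trial, trial_loss = cand
        delta = trial.max_abs_diff(eta)
        eta, loss = trial, trial_loss
        trace.append(loss)
        if delta < opts.tol:
            converged = True
            break
    return eta, np.asarray(trace), converged, it


def normalize_fractions(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """theta_k = p_k s_k / sum_j p_j s_j (molecule-level fractions)."""
    p = np.asarray(p, float).ravel()
    s = np.asarray(s, float).ravel()
    if np.any(p < 0) or np.any(s < 0):
        raise ValueError("p and s must be non-negative")
    prod = p * s
    tot = prod.sum()
    if tot <= 0:
        raise ValueError("sum of p*s is zero: uninformative sample")
    return prod / tot


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------

def deconvolve(
    paired: PairedBulk,
    signature: SignatureMatrix,
    init_props: np.ndarray | None = None,
    opts: FitOptions | None = None,
) -> DeconvResult:
    """Run per-sample JNMF over a paired cohort.

    Samples are fit independently; a failure in one sample is recorded and
    does not affect the others. theta1 comes from (p, s1) and theta2 from
    (p, s2) via :func:`normalize_fractions`. When ``opts.rescale_method`` is
    set, bulk matrices and the signature are rescaled consistently before
    initialization.
    """
    opts = opts or FitOptions()
    if opts.rescale_method:
        paired = PairedBulk(
            protein=rescale(paired.protein, opts.rescale_method),
            rna=rescale(paired.rna, opts.rescale_method),
            protein_to_gene=paired.protein_to_gene,
        )
        sig_bulk = BulkMatrix(
            signature.values, signature.feature_ids, signature.cell_types, "rna"
        )
        sig_scaled = rescale(sig_bulk, opts.rescale_method)
        signature = SignatureMatrix(
            sig_scaled.values, signature.feature_ids, signature.cell_types
        )
    ini = initialize_parameters(paired, signature, init_props)
    n, K = len(ini.sample_ids), len(ini.cell_types)

    theta1 = np.full((n, K), np.nan)
    theta2 = np.full((n, K), np.nan)
    panels: list[ParamSet] = []
    traces: list[np.ndarray] = []
    converged = np.zeros(n, dtype=bool)
    iters = np.zeros(n, dtype=int)
    failures: dict[str, str] = {}

    for i, sid in enumerate(ini.sample_ids):
        try:
            fitted, trace, conv, it = fit_sample(ini.y1[:, i], ini.y2[:, i], ini.param_sets[i], opts)
            theta1[i] = normalize_fractions(fitted.p, fitted.s1)
            theta2[i] = normalize_fractions(fitted.p, fitted.s2)
            panels.append(fitted)
            traces.append(trace)
            converged[i] = conv
            iters[i] = it
        except (ValueError, FloatingPointError) as exc:
            failures[sid] = str(exc)
            panels.append(ini.param_sets[i])
            traces.append(np.asarray([np.nan]))
            logger.warning("deconvolve: sample %s failed: %s", sid, exc)

    return DeconvResult(
        theta1=theta1,
        theta2=theta2,
        cell_types=ini.cell_types,
        sample_ids=ini.sample_ids,
        panels=panels,
        loss_trace=traces,
        converged=converged,
        iterations=iters,
        init_props=ini.init_props,
        failures=failures,
    )
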