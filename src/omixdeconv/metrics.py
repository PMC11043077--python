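"""Evaluation metrics and the simulation benchmark harness.

The benchmark mirrors the recovery experiment the deconvolution model is
designed for: generate a cohort with known modality-specific fractions,
corrupt the true RNA signature into a pseudo signature, estimate initial
fractions by NNLS, refine them with joint factorization, and compare both
estimates to the protein-fraction truth with MAE and Lin's concordance
correlation coefficient, summarized by a paired t-test over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .jnmf import FitOptions, deconvolve
from .synth import NoiseSpec, make_truth, perturb_signature, rank_markers_by_cv, synthesize_bulk


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation. Constant input is undefined and raises."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must share a length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population (1/n)
    moments: 2 cov(x,y) / (var x + var y + (mean x - mean y)^2).

    Penalizes both decorrelation and location/scale shifts. When both inputs
    are constant: 1 if equal, 0 otherwise.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must share a length >= 2")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0  # both constant and equal
    return float(2.0 * cov / denom)


def mae(est: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute error over all entries."""
    est = np.asarray(est, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.shape}")
    return float(np.mean(np.abs(est - truth)))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-sample t-test on the paired differences a - b; two-sided p from
    the t distribution with n-1 degrees of freedom. All-zero differences
    return (0, 1)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("inputs must share a length >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return (np.inf if d.mean() > 0 else -np.inf), 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return float(t), p


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkReport:
    """Per-replicate metrics and the paired-test summary of JNMF vs the
    NNLS initial protein-fraction estimates."""

    table: pd.DataFrame  # replicate, mae_jnmf, mae_init, ccc_jnmf, ccc_init, r_jnmf, r_init
    scenario: str
    t_mae: float
    p_mae: float
    t_ccc: float
    p_ccc: float
    frac_improved: float  # share of replicates with mae_jnmf < mae_init

    def summary(self) -> dict:
        tab = self.table
        return dict(
            scenario=self.scenario,
            n_replicates=int(len(tab)),
            mean_mae_jnmf=float(tab.mae_jnmf.mean()),
            mean_mae_init=float(tab.mae_init.mean()),
            mean_ccc_jnmf=float(tab.ccc_jnmf.mean()),
            mean_ccc_init=float(tab.ccc_init.mean()),
            t_mae=self.t_mae,
            p_mae=self.p_mae,
            t_ccc=self.t_ccc,
            p_ccc=self.p_ccc,
            frac_improved=self.frac_improved,
        )


def benchmark_replicate(
    scenario: str,
    seed: int,
    n: int = 50,
    K: int = 4,
    G: int = 300,
    M: int = 300,
    signature_noise: str = "small",
    marker_frac: float = 0.5,
    opts: FitOptions | None = None,
) -> dict:
    """One recovery replicate: simulate, NNLS-initialize, JNMF-refine, score
    the protein fractions against truth."""
    rng = np.random.default_rng(seed)
    truth = make_truth(n=n, K=K, G=G, M=M, scenario=scenario, seed=int(rng.integers(2**31)))
    noise = NoiseSpec(signature_noise=signature_noise)
    paired = synthesize_bulk(truth, noise, seed=int(rng.integers(2**31)))
    pseudo = perturb_signature(truth.signature(), signature_noise, seed=int(rng.integers(2**31)))
    markers = rank_markers_by_cv(pseudo, top_frac=marker_frac)
    sig = pseudo.subset_features(markers)
    res = deconvolve(paired, sig, opts=opts or FitOptions(max_iter=300))
    ok = ~np.isnan(res.theta1).any(axis=1)
    th_true = truth.theta1_true[ok]
    th_jnmf = res.theta1[ok]
    th_init = res.init_props[ok]
    return dict(
        mae_jnmf=mae(th_jnmf, th_true),
        mae_init=mae(th_init, th_true),
        ccc_jnmf=lin_ccc(th_jnmf, th_true),
        ccc_init=lin_ccc(th_init, th_true),
        r_jnmf=pearson_r(th_jnmf, th_true),
        r_init=pearson_r(th_init, th_true),
        n_failed=int((~ok).sum()),
    )


def benchmark(
    scenario: str,
    n_replicates: int = 20,
    seed: int = 0,
    **kwargs,
) -> BenchmarkReport:
    """Run replicates and summarize JNMF-vs-initial with paired t-tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        row = benchmark_replicate(scenario, seed=int(rng.integers(2**31)), **kwargs)
        row["replicate"] = rep
        rows.append(row)
    tab = pd.DataFrame(rows)
    t_mae, p_mae = paired_t(tab.mae_jnmf.to_numpy(), tab.mae_init.to_numpy())
    t_ccc, p_ccc = paired_t(tab.ccc_jnmf.to_numpy(), tab.ccc_init.to_numpy())
    return BenchmarkReport(
        table=tab,
        scenario=scenario,
        t_mae=t_mae,
        p_mae=p_mae,
        t_ccc=t_ccc,
        p_ccc=p_ccc,
        frac_improved=float((tab.mae_jnmf < tab.mae_init).mean()),
    )
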