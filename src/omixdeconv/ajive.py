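"""Angle-based joint and individual variation decomposition (AJIVE) of
sample-matched expression blocks, and cross-modal signature protein selection.

Each block Y_j (features x samples, shared samples) is split into

    Y_j = C_j + I_j + E_j

where C_j is the variation common to all blocks, I_j block-specific
structured variation, and E_j residual noise. The joint space is found by
(1) a rank-r_j SVD of each block, (2) an SVD of the stacked sample-score
bases, whose squared singular values measure agreement between the block row
spaces, and (3) keeping components whose squared singular value exceeds both
a Wedin perturbation bound (estimated by resampling the block residuals) and
a random-direction bound for chance correlation. The right singular vectors
of the stacked matrix restricted to those components are the common
normalized scores (CNS), one orthonormal column per joint component.

Signature proteins are then chosen by projecting the observed proteome onto
the joint space through the loadings V of the SVD of its common matrix and
ranking proteins by the Euclidean distance between each observed row and its
projection: small distance = strong participation in the shared variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import PairedBulk

logger = logging.getLogger(__name__)


@dataclass
class BlockDecomposition:
    """Common / individual / residual split of one block."""

    C: np.ndarray
    I: np.ndarray
    E: np.ndarray
    V: np.ndarray  # feature loadings of C (features x joint_rank), orthonormal
    row_means: np.ndarray  # per-feature means removed before decomposition
    initial_rank: int


@dataclass
class AjiveResult:
    blocks: list[BlockDecomposition]
    joint_rank: int
    cns: np.ndarray  # (n_samples, joint_rank), orthonormal columns
    stacked_sq_svals: np.ndarray  # squared singular values of the stacked score matrix
    wedin_threshold: float
    random_threshold: float


def _orthonormal(rng: np.random.Generator, n: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return q[:, :r]


def _scree_rank(svals: np.ndarray, min_var_share: float = 0.05) -> int:
    tot = float(np.sum(svals**2))
    if tot <= 0:
        return 1
    return max(1, int(np.sum(svals**2 / tot >= min_var_share)))


def default_initial_ranks(blocks: list[np.ndarray], min_var_share: float = 0.05) -> list[int]:
    """Scree rule: per block, count components explaining at least
    ``min_var_share`` of the (row-centered) block variance."""
    ranks = []
    for Y in blocks:
        Yc = Y - Y.mean(axis=1, keepdims=True)
        svals = np.linalg.svd(Yc, compute_uv=False)
        ranks.append(_scree_rank(svals, min_var_share))
    return ranks


def ajive_decompose(
    blocks: list[np.ndarray],
    initial_ranks: list[int],
    n_resample: int = 100,
    seed: int | None = None,
    center: bool = True,
    percentile: float = 95.0,
) -> AjiveResult:
    """Joint/individual/residual decomposition of >= 2 sample-matched blocks.

    Parameters
    ----------
    blocks : list of (features_j x n_samples) arrays with a common sample axis.
    initial_ranks : per-block signal rank for the first-stage SVD; clipped
        (with a warning) to the block's numerical rank.
    n_resample : resamples for the Wedin and random-direction bounds.
    seed : RNG seed controlling the resampling (fully deterministic given it).
    center : remove per-feature means before decomposing. The means are left
        in the residual E so that C + I + E always reconstructs the input.

    The joint rank may legitimately be 0 (no distinguishable shared space).
    """
    if len(blocks) < 2:
        raise ValueError("AJIVE needs at least two blocks")
    blocks = [np.asarray(Y, dtype=float) for Y in blocks]
    n = blocks[0].shape[1]
    if any(Y.shape[1] != n for Y in blocks):
        raise ValueError("all blocks must share the sample (column) dimension")
    if len(initial_ranks) != len(blocks):
        raise ValueError("initial_ranks must have one entry per block")
    rng = np.random.default_rng(seed)
    J = len(blocks)

    row_means = []
    centered = []
    for Y in blocks:
        mu = Y.mean(axis=1, keepdims=True) if center else np.zeros((Y.shape[0], 1))
        row_means.append(mu)
        centered.append(Y - mu)

    # Stage 1: per-block truncated SVD
    svds = []
    ranks = []
    for j, Yc in enumerate(centered):
        U, S, Vt = np.linalg.svd(Yc, full_matrices=False)
        num_rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
        r_j = int(initial_ranks[j])
        if r_j < 1:
            raise ValueError("initial ranks must be >= 1")
        if r_j > num_rank:
            warnings.warn(
                f"block {j}: initial rank {r_j} exceeds numerical rank {num_rank}; clipping"
            )
            r_j = max(num_rank, 1)
        svds.append((U[:, :r_j], S[:r_j], Vt[:r_j]))
        ranks.append(r_j)

    # Stage 2: SVD of the stacked sample-score bases. Squared singular values
    # lie in [0, J]; values near J indicate directions present in every block.
    stacked = np.vstack([Vt for (_, _, Vt) in svds])  # (sum r_j, n)
    Us, Ss, Vst = np.linalg.svd(stacked, full_matrices=False)
    sq_svals = Ss**2

    # Wedin bound per block: how far can the estimated row space be rotated by
    # the residual? sin(theta) <= max(||E'U||, ||EV||) / sigma_min, with the
    # operator norms estimated by resampled random orthonormal directions.
    wedin_sin2 = []
    for j, (U, S, Vt) in enumerate(svds):
        E_j = centered[j] - U @ (S[:, None] * Vt)
        sigma_min = S[-1]
        samples = np.empty(n_resample)
        d_j = centered[j].shape[0]
        for b in range(n_resample):
            Ov = _orthonormal(rng, n, ranks[j])
            Ou = _orthonormal(rng, d_j, ranks[j])
            term = max(
                np.linalg.norm(E_j @ Ov, ord=2),
                np.linalg.norm(E_j.T @ Ou, ord=2),
            )
            samples[b] = min(1.0, (term / sigma_min) ** 2) if sigma_min > 0 else 1.0
        wedin_sin2.append(np.percentile(samples, percentile))
    wedin_threshold = J - float(np.sum(wedin_sin2))

    # Random-direction (null) bound: largest squared singular value of stacked
    # independent random score bases of the same per-block ranks.
    null_sq = np.empty(n_resample)
    for b in range(n_resample):
        rand_stack = np.vstack([_orthonormal(rng, n, r_j).T for r_j in ranks])
        null_sq[b] = np.linalg.svd(rand_stack, compute_uv=False)[0] ** 2
    random_threshold = float(np.percentile(null_sq, percentile))

    threshold = max(wedin_threshold, random_threshold)
    joint_rank = int(np.sum(sq_svals > threshold))
    joint_rank = min(joint_rank, n)
    cns = Vst[:joint_rank].T  # (n, r), orthonormal columns

    out_blocks = []
    proj = cns @ cns.T  # (n, n) projection onto the joint score space
    for j, Y in enumerate(blocks):
        Yc = centered[j]
        C = Yc @ proj if joint_rank > 0 else np.zeros_like(Yc)
        R = Yc - C
        ind_rank = max(ranks[j] - joint_rank, 0)
        if ind_rank > 0:
            Ur, Sr, Vtr = np.linalg.svd(R, full_matrices=False)
            I_mat = Ur[:, :ind_rank] @ (Sr[:ind_rank, None] * Vtr[:ind_rank])
        else:
            I_mat = np.zeros_like(Yc)
        E = Y - C - I_mat  # residual keeps the removed row means
        if joint_rank > 0:
            Vc, _, _ = np.linalg.svd(C, full_matrices=False)
            V = Vc[:, :joint_rank]
        else:
            V = np.zeros((Y.shape[0], 0))
        out_blocks.append(
            BlockDecomposition(C=C, I=I_mat, E=E, V=V, row_means=row_means[j], initial_rank=ranks[j])
        )

    return AjiveResult(
        blocks=out_blocks,
        joint_rank=joint_rank,
        cns=cns,
        stacked_sq_svals=sq_svals,
        wedin_threshold=wedin_threshold,
        random_threshold=random_threshold,
    )


def project_proteome(Y1: np.ndarray, V1: np.ndarray) -> np.ndarray:
    """Rank-r approximation Ytilde = V1 V1' Y1 of the proteome through the
    common-variation loadings. ``V1`` must have orthonormal columns."""
    Y1 = np.asarray(Y1, dtype=float)
    V1 = np.asarray(V1, dtype=float)
    if V1.ndim != 2 or V1.shape[0] != Y1.shape[0]:
        raise ValueError("V1 must be (n_features x r)")
    if V1.shape[1] == 0:
        return np.zeros_like(Y1)
    gram = V1.T @ V1
    if not np.allclose(gram, np.eye(V1.shape[1]), atol=1e-8):
        raise ValueError("V1 columns must be orthonormal (pass SVD loadings)")
    return V1 @ (V1.T @ Y1)


def feature_distances(Y1: np.ndarray, Ytilde: np.ndarray) -> np.ndarray:
    """Per-feature Euclidean distance d_g = ||y_g. - ytilde_g.||_2."""
    Y1 = np.asarray(Y1, dtype=float)
    Ytilde = np.asarray(Ytilde, dtype=float)
    if Y1.shape != Ytilde.shape:
        raise ValueError("shape mismatch between observed and projected matrices")
    return np.linalg.norm(Y1 - Ytilde, axis=1)


@dataclass
class SelectionResult:
    """Signature-protein selection: distances and the n smallest."""

    distances: np.ndarray
    protein_ids: list[str]
    selected_ids: list[str]
    n_select: int
    ajive: AjiveResult = field(repr=False, default=None)  # type: ignore[assignment]


def ajrf_select(
    paired: PairedBulk,
    marker_gene_ids: list[str],
    n_select: int,
    initial_ranks: list[int] | None = None,
    n_resample: int = 100,
    seed: int | None = None,
) -> SelectionResult:
    """Select signature proteins by distance to the AJIVE common space.

    The whole proteome and the RNA block restricted to ``marker_gene_ids``
    are decomposed jointly; the proteome is projected through the loadings of
    its common matrix, the row means (removed for the decomposition) are
    added back, and the ``n_select`` proteins with the smallest distances to
    their projection are returned. Ties break by input protein order.
    """
    missing = [g for g in marker_gene_ids if g not in set(paired.rna.feature_ids)]
    if missing:
        raise ValueError(f"marker genes absent from RNA features: {missing[:5]}")
    G = paired.protein.n_features
    if not 1 <= n_select <= G:
        raise ValueError(f"n_select must be in [1, {G}]")

    Y1 = paired.protein.values
    Y2 = paired.rna.subset_features(marker_gene_ids).values
    if initial_ranks is None:
        initial_ranks = default_initial_ranks([Y1, Y2])
    res = ajive_decompose([Y1, Y2], initial_ranks, n_resample=n_resample, seed=seed)
    if res.joint_rank == 0:
        raise ValueError(
            "AJIVE joint rank is 0: no shared space to project onto; "
            "try larger initial ranks"
        )
    block1 = res.blocks[0]
    Yc = Y1 - block1.row_means
    Ytilde = project_proteome(Yc, block1.V) + block1.row_means
    d = feature_distances(Y1, Ytilde)
    order = np.argsort(d, kind="stable")
    selected = [paired.protein.feature_ids[i] for i in order[:n_select]]
    return SelectionResult(
        distances=d,
        protein_ids=list(paired.protein.feature_ids),
        selected_ids=selected,
        n_select=n_select,
        ajive=res,
    )
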