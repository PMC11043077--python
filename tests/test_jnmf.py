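"""Joint factorization: NNLS initialization, loss/gradient correctness
against independent oracles, projected-gradient optimization, and the
cohort-level driver."""

import itertools

import numpy as np
import pytest

from omixdeconv import (
    BulkMatrix,
    FitOptions,
    NoiseSpec,
    PairedBulk,
    ParamSet,
    SignatureMatrix,
    deconvolve,
    fit_sample,
    initialize_parameters,
    jnmf_gradient,
    jnmf_loss,
    nnls_proportions,
    normalize_fractions,
    project_nonneg,
    synthesize_bulk,
)
from conftest import exact_bulk, random_paramset


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def loss_by_double_loop(param, y1, y2):
    """Term-by-term summation of the two squared-residual sums."""
    total = 0.0
    for g in range(len(y1)):
        pred = sum(param.X1[g, k] * param.p[k] * param.s1[k] for k in range(param.K))
        total += (y1[g] - pred) ** 2
    for m in range(len(y2)):
        pred = sum(param.X2[m, k] * param.p[k] * param.s2[k] for k in range(param.K))
        total += (y2[m] - pred) ** 2
    return total


def finite_difference_gradient(param, y1, y2, h=1e-6):
    """Central finite differences over every scalar parameter."""
    grads = {}
    for name, arr in param.blocks().items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up = jnmf_loss(param, y1, y2)
            arr[idx] = orig - h
            down = jnmf_loss(param, y1, y2)
            arr[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads[name] = g
    return grads


def direction_grid_search(S, y, step=0.001):
    """Best simplex direction w (K=2) with free non-negative scale: the
    oracle for NNLS-then-renormalize."""
    best, best_loss = None, np.inf
    for t in np.arange(0.0, 1.0 + step / 2, step):
        w = np.array([t, 1.0 - t])
        Sw = S @ w
        denom = Sw @ Sw
        c = max(Sw @ y / denom, 0.0) if denom > 0 else 0.0
        r = y - c * Sw
        loss = r @ r
        if loss < best_loss:
            best, best_loss = w, loss
    return best


def p_grid_search(param_truth, y1, y2, step=0.001):
    """Exhaustive search for the best cell-count fractions on the K=2
    simplex with panels and size factors held at truth."""
    best_p, best_loss = None, np.inf
    for t in np.arange(0.0, 1.0 + step / 2, step):
        p = np.array([t, 1.0 - t])
        cand = ParamSet(param_truth.X1, param_truth.X2, p, param_truth.s1, param_truth.s2)
        loss = jnmf_loss(cand, y1, y2)
        if loss < best_loss:
            best_p, best_loss = p, loss
    return best_p, best_loss


# ---------------------------------------------------------------------------
# NNLS proportions
# ---------------------------------------------------------------------------

class TestNnlsProportions:
    def test_identity_design_passthrough(self, identity_signature):
        bulk = np.array([[0.3], [0.7]])
        np.testing.assert_allclose(
            nnls_proportions(bulk, identity_signature), [[0.3, 0.7]], atol=1e-12
        )

    def test_exact_model_recovered(self, rng):
        S = rng.uniform(0.5, 3.0, size=(6, 3))
        w = np.array([0.2, 0.5, 0.3])
        sig = SignatureMatrix(S, [f"f{i}" for i in range(6)], ["a", "b", "c"])
        est = nnls_proportions((S @ w)[:, None], sig)
        np.testing.assert_allclose(est[0], w, atol=1e-8)

    def test_active_constraint_matches_grid_oracle(self):
        # design chosen so the unconstrained LS solution has a negative entry
        S = np.array([[1.0, 0.9], [0.9, 1.0], [0.1, 0.8]])
        y = np.array([1.0, 0.5, 0.0])
        assert np.any(np.linalg.lstsq(S, y, rcond=None)[0] < 0)
        sig = SignatureMatrix(S, ["f1", "f2", "f3"], ["a", "b"])
        est = nnls_proportions(y[:, None], sig)[0]
        oracle = direction_grid_search(S, y)
        np.testing.assert_allclose(est, oracle, atol=0.005)

    def test_rank_deficient_signature_warns(self, rng):
        col = rng.uniform(0.5, 1.0, size=4)
        sig = SignatureMatrix(np.column_stack([col, col]), [f"f{i}" for i in range(4)], ["a", "b"])
        with pytest.warns(UserWarning, match="rank deficient"):
            nnls_proportions(col[:, None], sig)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

class TestInitialize:
    @pytest.fixture
    def setup(self, rng):
        sig = SignatureMatrix(rng.uniform(0.5, 2.0, (3, 2)), ["g0", "g1", "g2"], ["a", "b"])
        prot = BulkMatrix(rng.uniform(0, 2, (2, 4)), ["p0", "pX"], list("wxyz"), "protein")
        rna = BulkMatrix(rng.uniform(0, 2, (3, 4)), ["g0", "g1", "g2"], list("wxyz"), "rna")
        paired = PairedBulk(protein=prot, rna=rna, protein_to_gene={"p0": "g1"})
        return paired, sig

    def test_supplied_props_pass_through_and_unit_size_factors(self, setup):
        paired, sig = setup
        props = np.tile([0.25, 0.75], (4, 1))
        ini = initialize_parameters(paired, sig, props)
        for ps in ini.param_sets:
            np.testing.assert_array_equal(ps.s1, 1.0)
            np.testing.assert_array_equal(ps.s2, 1.0)
        np.testing.assert_array_equal(ini.param_sets[2].p, [0.25, 0.75])

    def test_panel_copy_semantics_and_dropping(self, setup):
        paired, sig = setup
        ini = initialize_parameters(paired, sig, np.tile([0.5, 0.5], (4, 1)))
        # protein p0 maps to g1 -> X1 row copies signature row for g1; pX dropped
        assert ini.protein_ids == ["p0"]
        assert ini.n_dropped_proteins == 1
        np.testing.assert_array_equal(ini.param_sets[0].X1[0], sig.values[1])
        np.testing.assert_array_equal(ini.param_sets[0].X2, sig.values)

    def test_unnormalized_props_renormalized_with_warning(self, setup):
        paired, sig = setup
        with pytest.warns(UserWarning, match="renormaliz"):
            ini = initialize_parameters(paired, sig, np.tile([1.0, 3.0], (4, 1)))
        np.testing.assert_allclose(ini.init_props.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# loss / gradient / projection
# ---------------------------------------------------------------------------

class TestLossAndGradient:
    def test_zero_residual_loss_and_gradient(self, rng):
        param = random_paramset(rng)
        y1, y2 = exact_bulk(param)
        assert jnmf_loss(param, y1, y2) == pytest.approx(0.0, abs=1e-24)
        grad = jnmf_gradient(param, y1, y2)
        for block in grad.blocks().values():
            np.testing.assert_allclose(block, 0.0, atol=1e-12)

    def test_scalar_instance(self):
        param = ParamSet(np.ones((1, 1)), np.ones((1, 1)), [1.0], [1.0], [1.0])
        assert jnmf_loss(param, np.array([2.0]), np.array([3.0])) == pytest.approx(5.0)

    def test_loss_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            param = random_paramset(rng, G=4, M=3, K=2)
            y1 = rng.uniform(0, 3, 4)
            y2 = rng.uniform(0, 3, 3)
            assert jnmf_loss(param, y1, y2) == pytest.approx(
                loss_by_double_loop(param, y1, y2), abs=1e-12, rel=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        param = random_paramset(rng, G=3, M=4, K=2)
        y1 = rng.uniform(0, 3, 3)
        y2 = rng.uniform(0, 3, 4)
        analytic = jnmf_gradient(param, y1, y2).blocks()
        fd = finite_difference_gradient(param, y1, y2)
        for name in analytic:
            num = np.linalg.norm(analytic[name] - fd[name])
            den = np.linalg.norm(fd[name]) + 1e-12
            assert num / den < 1e-4, name

    def test_zero_size_factors_zero_panel_gradient(self, rng):
        param = random_paramset(rng)
        param.s1[:] = 0.0
        param.s2[:] = 0.0
        grad = jnmf_gradient(param, rng.uniform(0, 1, 3), rng.uniform(0, 1, 4))
        np.testing.assert_array_equal(grad.X1, 0.0)
        np.testing.assert_array_equal(grad.X2, 0.0)


class TestProjection:
    def test_clamp_and_idempotency(self):
        param = ParamSet(
            np.array([[-1.0], [0.5]]), np.array([[0.0]]), [-0.2], [0.5], [-3.0]
        )
        proj = project_nonneg(param)
        np.testing.assert_array_equal(proj.X1, [[0.0], [0.5]])
        assert proj.p[0] == 0.0 and proj.s2[0] == 0.0
        twice = project_nonneg(proj)
        for a, b in zip(proj.blocks().values(), twice.blocks().values()):
            np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# per-sample optimization
# ---------------------------------------------------------------------------

class TestFitSample:
    def test_truth_init_converges_immediately(self, rng):
        param = random_paramset(rng)
        y1, y2 = exact_bulk(param)
        fitted, trace, converged, iters = fit_sample(y1, y2, param)
        assert converged and iters <= 2
        assert fitted.max_abs_diff(param) < 1e-5
        assert trace[-1] == pytest.approx(0.0, abs=1e-20)

    def test_zero_iteration_budget(self, rng):
        param = random_paramset(rng)
        y1, y2 = exact_bulk(param)
        fitted, trace, converged, iters = fit_sample(y1, y2, param, FitOptions(max_iter=0))
        assert not converged and iters == 0 and len(trace) == 1
        assert fitted.max_abs_diff(param) == 0.0

    def test_loss_trace_non_increasing(self, rng):
        param = random_paramset(rng, G=5, M=5, K=3)
        y1 = rng.uniform(0, 3, 5)
        y2 = rng.uniform(0, 3, 5)
        init = random_paramset(rng, G=5, M=5, K=3)
        _, trace, _, _ = fit_sample(y1, y2, init, FitOptions(max_iter=200, step=1e-2))
        assert np.all(np.diff(trace) <= 1e-12)

    def test_perturbed_p_recovery_vs_grid_oracle(self, rng):
        """From a +10% perturbation of p on a noiseless K=2 instance, PGD
        must reach near-zero loss, match the restricted simplex grid oracle
        to within its resolution, and not exceed the oracle minimum by more
        than 1% of the initial loss."""
        truth = random_paramset(rng, G=3, M=3, K=2)
        truth.p = np.array([0.3572, 0.6428])  # off-grid on purpose
        y1, y2 = exact_bulk(truth)
        init = truth.copy()
        init.p = truth.p * np.array([1.1, 1.0])
        loss0 = jnmf_loss(init, y1, y2)
        fitted, trace, _, _ = fit_sample(y1, y2, init, FitOptions(max_iter=2000, tol=1e-8))
        p_grid, grid_min = p_grid_search(truth, y1, y2)
        assert trace[-1] <= 0.01 * loss0
        assert trace[-1] <= grid_min + 0.01 * loss0
        theta_pgd = normalize_fractions(fitted.p, fitted.s1)
        theta_grid = normalize_fractions(p_grid, truth.s1)
        np.testing.assert_allclose(theta_pgd, theta_grid, atol=0.02)

    def test_non_finite_loss_reports_iteration(self):
        param = ParamSet(np.array([[1e200]]), np.array([[1e200]]), [1e200], [1.0], [1.0])
        with pytest.raises(FloatingPointError, match="iteration"):
            fit_sample(np.array([1.0]), np.array([1.0]), param)


class TestNormalizeFractions:
    def test_direct_formula(self):
        np.testing.assert_allclose(
            normalize_fractions([0.5, 0.5], [1.0, 3.0]), [0.25, 0.75]
        )

    def test_unit_size_factors_identity(self, rng):
        p = rng.uniform(0.1, 1.0, 4)
        np.testing.assert_allclose(normalize_fractions(p, np.ones(4)), p / p.sum())

    def test_single_cell_type(self):
        np.testing.assert_array_equal(normalize_fractions([2.0], [0.5]), [1.0])

    def test_zero_product_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            normalize_fractions([1.0, 0.0], [0.0, 1.0])


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

class TestDeconvolve:
    def test_noiseless_truth_init_recovers_truth(self):
        """On a degenerate cohort (shared panels, unit size factors, no
        noise) the standard initialization sits at the zero-residual global
        optimum and must reproduce the true fractions to 1e-6."""
        from omixdeconv import make_truth

        truth = make_truth(n=5, K=3, G=25, M=25, s_sd=0.0, panel_cv=0.0,
                           protein_shift_sd=0.0, seed=4)
        paired = synthesize_bulk(truth, NoiseSpec(bulk_sd=0.0), seed=1)
        res = deconvolve(paired, truth.signature(), init_props=truth.p_true)
        assert not res.failures
        np.testing.assert_allclose(res.theta1, truth.theta1_true, atol=1e-6)
        np.testing.assert_allclose(res.theta2, truth.theta2_true, atol=1e-6)
        for tr in res.loss_trace:
            assert tr[-1] < 1e-10 and np.all(np.diff(tr) <= 1e-12)

    def test_cell_type_permutation_equivariance(self, tiny_truth, tiny_noiseless_paired):
        sig = tiny_truth.signature()
        perm = [2, 0, 1]
        sig_perm = SignatureMatrix(
            sig.values[:, perm], sig.feature_ids, [sig.cell_types[j] for j in perm]
        )
        init = tiny_truth.p_true / tiny_truth.p_true.sum(axis=1, keepdims=True)
        opts = FitOptions(max_iter=50)
        res = deconvolve(tiny_noiseless_paired, sig, init_props=init, opts=opts)
        res_perm = deconvolve(
            tiny_noiseless_paired, sig_perm, init_props=init[:, perm], opts=opts
        )
        np.testing.assert_allclose(res_perm.theta1, res.theta1[:, perm], atol=1e-10)

    def test_scale_indeterminacy_of_theta(self, rng):
        """Scaling initial p by c and both size factors by 1/c leaves the
        normalized fractions unchanged at a zero-residual optimum."""
        param = random_paramset(rng, G=4, M=4, K=3)
        y1, y2 = exact_bulk(param)
        c = 2.5
        scaled = ParamSet(param.X1, param.X2, param.p * c, param.s1 / c, param.s2 / c)
        f1, *_ = fit_sample(y1, y2, param)
        f2, *_ = fit_sample(y1, y2, scaled)
        np.testing.assert_allclose(
            normalize_fractions(f1.p, f1.s1), normalize_fractions(f2.p, f2.s1), atol=1e-9
        )

    def test_theta_on_simplex_with_noise(self, tiny_truth):
        paired = synthesize_bulk(tiny_truth, NoiseSpec(bulk_sd=0.1), seed=3)
        res = deconvolve(paired, tiny_truth.signature(), opts=FitOptions(max_iter=100))
        ok = ~np.isnan(res.theta1).any(axis=1)
        assert ok.all()
        np.testing.assert_allclose(res.theta1.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.theta1 >= 0)
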