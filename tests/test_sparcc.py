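import numpy as np
import pytest

from mebnet import sparcc
from mebnet.synthetic import SyntheticSpec, generate_community
from mebnet.tables import OtuTable


def naive_log_ratio_variances(frac: np.ndarray) -> np.ndarray:
    """Oracle: explicit per-pair variance loop."""
    p = frac.shape[0]
    t = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i != j:
                t[i, j] = np.var(np.log(frac[i] / frac[j]), ddof=1)
    return t


class TestLogRatioVariances:
    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        frac = rng.dirichlet(np.ones(3), size=10).T
        t = sparcc.log_ratio_variances(frac)
        assert np.allclose(t, naive_log_ratio_variances(frac))

    def test_identical_rows_zero(self):
        x = np.tile(np.random.default_rng(1).random(6), (2, 1))
        t = sparcc.log_ratio_variances(x)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariant_pair(self):
        rng = np.random.default_rng(2)
        x1 = rng.random(8)
        frac = np.vstack([x1, 3.0 * x1, rng.random(8)])
        t = sparcc.log_ratio_variances(frac)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sparcc.log_ratio_variances(np.ones((3, 2)))


class TestBasisVariances:
    def test_all_equal_t_gives_unit_omega(self):
        t = np.full((6, 6), 2.0)
        np.fill_diagonal(t, 0.0)
        assert np.allclose(sparcc.estimate_basis_variances(t), 1.0)

    def test_three_otu_closed_form(self):
        t12, t13, t23 = 0.5, 1.2, 0.9
        t = np.array([[0, t12, t13], [t12, 0, t23], [t13, t23, 0.0]])
        w2 = sparcc.estimate_basis_variances(t)
        assert w2[0] == pytest.approx((t12 + t13 - t23) / 2)
        assert w2[1] == pytest.approx((t12 + t23 - t13) / 2)
        assert w2[2] == pytest.approx((t13 + t23 - t12) / 2)

    def test_zero_t_floored(self):
        t = np.zeros((4, 4))
        w2 = sparcc.estimate_basis_variances(t)
        assert (w2 > 0).all() and (w2 <= 1e-9).all()

    def test_closed_form_matches_general_solve_random(self):
        """3-variable exact solution vs the general lstsq path on random t."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c = rng.uniform(0.5, 2.0, 3)
            # ensure a valid (positive-variance) triple
            t = np.array([[0, a + b, a + c], [a + b, 0, b + c], [a + c, b + c, 0.0]])
            w2 = sparcc.estimate_basis_variances(t)
            assert np.allclose(w2, [a, b, c], atol=1e-8)


class TestEstimateCorrelations:
    def test_all_equal_t_zero_rho(self):
        rng = np.random.default_rng(4)
        # rows scaled copies of a base: all log-ratio variances equal pattern
        frac = rng.dirichlet(np.ones(5), size=30).T
        est = sparcc.estimate_correlations(frac)
        assert np.allclose(est.rho, est.rho.T)
        assert np.allclose(np.diag(est.rho), 1.0)
        assert (np.abs(est.rho) <= 1.0).all()

    def test_planted_pair_recovered(self):
        spec = SyntheticSpec(
            n_samples=200, n_bacteria=10, n_eukaryotes=5,
            planted_edges=[(0, 0, 1, 0.9)],
            depth_bacteria=5000, depth_eukaryotes=5000, seed=11,
        )
        euk, bact, _ = generate_community(spec)
        counts = np.vstack([euk.counts, bact.counts])
        frac = sparcc.to_fractions(counts)
        est = sparcc.estimate_correlations(frac)
        assert est.rho[0, 5] == pytest.approx(0.9, abs=0.15)

    def test_exclusion_bounded_by_max_rounds(self):
        rng = np.random.default_rng(5)
        frac = rng.dirichlet(np.ones(8), size=25).T
        est = sparcc.estimate_correlations(frac, exclusion_threshold=0.0,
                                           max_exclusion_rounds=3)
        assert len(est.excluded_pairs) <= 3


class TestDirichletAverage:
    @pytest.fixture
    def counts(self):
        rng = np.random.default_rng(6)
        return rng.integers(0, 200, size=(6, 20))

    def test_single_draw_is_one_estimate(self, counts):
        a = sparcc.dirichlet_average(counts, n_draws=1, seed=9)
        rng = np.random.default_rng(9)
        g = rng.standard_gamma(counts.astype(float) + 1.0)
        frac = g / g.sum(axis=0, keepdims=True)
        b = sparcc.estimate_correlations(frac)
        assert np.allclose(a.rho, b.rho)

    def test_deterministic_under_seed(self, counts):
        a = sparcc.dirichlet_average(counts, n_draws=5, seed=1)
        b = sparcc.dirichlet_average(counts, n_draws=5, seed=1)
        assert np.array_equal(a.rho, b.rho)

    def test_median_within_envelope(self, counts):
        # median of draws must lie within the element-wise min/max of draws
        rhos = []
        rng_seeds = np.random.SeedSequence(1).spawn(1)
        rng = np.random.default_rng(1)
        alpha = counts.astype(float) + 1.0
        for _ in range(5):
            g = rng.standard_gamma(alpha)
            frac = g / g.sum(axis=0, keepdims=True)
            rhos.append(sparcc.estimate_correlations(frac).rho)
        med = sparcc.dirichlet_average(counts, n_draws=5, seed=1).rho
        lo = np.min(rhos, axis=0) - 1e-9
        hi = np.max(rhos, axis=0) + 1e-9
        off = ~np.eye(6, dtype=bool)
        assert ((med >= lo) & (med <= hi))[off].all()


class TestBootstrapPvalues:
    def test_extreme_rho_small_p_and_null_rho_large_p(self):
        spec = SyntheticSpec(
            n_samples=60, n_bacteria=6, n_eukaryotes=3,
            planted_edges=[(0, 0, 1, 0.95)],
            depth_bacteria=5000, depth_eukaryotes=5000, seed=2,
        )
        euk, bact, _ = generate_community(spec)
        counts = np.vstack([euk.counts, bact.counts])
        est = sparcc.dirichlet_average(counts, n_draws=5, seed=0)
        sig = sparcc.bootstrap_pvalues(counts, est, n_boot=40, seed=0)
        assert sig.p[0, 3] < 0.05  # planted pair
        # weakest observed correlations should not look significant
        off = np.triu_indices(9, k=1)
        weakest = np.argmin(np.abs(est.rho[off]))
        assert sig.p[off[0][weakest], off[1][weakest]] > 0.2

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 100, size=(5, 15))
        est = sparcc.dirichlet_average(counts, n_draws=2, seed=0)
        a = sparcc.bootstrap_pvalues(counts, est, n_boot=20, seed=5)
        b = sparcc.bootstrap_pvalues(counts, est, n_boot=20, seed=5)
        off = ~np.eye(5, dtype=bool)
        assert np.array_equal(a.p[off], b.p[off])
        assert np.isnan(np.diag(a.p)).all()


class TestSignificantEdges:
    @pytest.mark.parametrize(
        "rho, p, kept",
        [
            (0.61, 0.01, True),   # above both thresholds
            (0.60, 0.01, False),  # boundary rho: strict inequality
            (0.90, 0.06, False),  # boundary p
            (-0.7, 0.04, True),   # negative correlations count by magnitude
        ],
    )
    def test_thresholds(self, rho, p, kept):
        r = np.array([[1.0, rho], [rho, 1.0]])
        pm = np.array([[np.nan, p], [p, np.nan]])
        edges = sparcc.significant_edges(r, pm, ["A", "B"])
        assert (len(edges) == 1) == kept
        if kept:
            assert edges.iloc[0]["sign"] == ("positive" if rho > 0 else "negative")
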