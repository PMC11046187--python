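"""Bonferroni, Storey pi0/q-values, and the lattice-aware Q-Q expectation."""

import numpy as np
import pytest
from scipy.stats import binom

from penmate.mcnemar_core import Scenario, mcnemar_exact_p, mcnemar_mid_p, run_genome_scan
from penmate.multiplicity import (
    DiscreteNull,
    bonferroni_threshold,
    estimate_pi0,
    q_values,
    qq_expected,
)
from penmate.synthetic_data import SimConfig, generate


class TestBonferroni:
    def test_study_scale(self):
        thr, neglog = bonferroni_threshold(0.05, 561_683)
        assert neglog == pytest.approx(7.05, abs=0.005)

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.01, 100, 1e-4)])
    def test_simple(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m)[0] == pytest.approx(expected)


class TestPi0:
    def test_uniform_null_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 10_000)
        for method in ("bootstrap", "polynomial"):
            pi0, _ = estimate_pi0(p, method=method, seed=2)
            assert pi0 == pytest.approx(1.0, abs=0.05)

    def test_half_alternative_mixture(self):
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(0, 1, 5000), rng.uniform(0, 1e-4, 5000)])
        pi0, _ = estimate_pi0(p, method="bootstrap", seed=4)
        assert pi0 == pytest.approx(0.5, abs=0.07)

    def test_all_identical_clamps_to_one(self):
        with pytest.warns(UserWarning):
            pi0, _ = estimate_pi0(np.ones(200), method="bootstrap")
        assert pi0 == 1.0

    def test_bootstrap_below_polynomial_on_heavy_lattice_mass(self):
        """With discrete p-values piling up at 1, the polynomial fit chases
        the rising tail of pi0(lambda) while the bootstrap favors smaller
        lambda; the bootstrap estimate comes out lower."""
        rng = np.random.default_rng(5)
        # discrete McNemar p-values with small supports: heavy mass at p = 1
        t = rng.integers(1, 8, 4000)
        b = rng.binomial(t, 0.5)
        p = np.array([mcnemar_mid_p(int(x), int(tt - x)) for x, tt in zip(b, t)])
        pi0_b, _ = estimate_pi0(p, method="bootstrap", seed=6)
        pi0_p, _ = estimate_pi0(p, method="polynomial", seed=6)
        assert pi0_b < pi0_p


class TestQValues:
    def test_single_p(self):
        assert q_values(np.array([0.05]), pi0=1.0)[0] == pytest.approx(0.05)

    def test_hand_computed_two_group(self):
        p = np.array([0.001] * 10 + [0.9] * 90)
        q = q_values(p, pi0=1.0)
        assert np.allclose(q[:10], 100 * 0.001 / 10)
        assert np.allclose(q[10:], 0.9)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 500)
        q = q_values(p, pi0=0.8)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_one_equals_bh(self):
        """With pi0 = 1, Storey q-values coincide with Benjamini-Hochberg
        adjusted p-values (independent statsmodels implementation)."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(0, 0.01, 30), rng.uniform(0, 1, 470)])
        q = q_values(p, pi0=1.0)
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, bh, atol=1e-12)

    def test_scaling_in_pi0(self):
        p = np.array([0.01, 0.2, 0.6])
        assert np.allclose(q_values(p, 0.5), 0.5 * q_values(p, 1.0))


class TestDiscreteNull:
    def test_support_one_lattice(self):
        # t = 1: both splits (0,1) and (1,0) give exact p = 1 after capping,
        # and mid-p = 2*(0.5 - 0.25) = 0.5.
        p, w = DiscreteNull(np.array([1, 1, 1]), variant="exact").pooled_pvalues()
        assert np.allclose(p, 1.0)
        assert w.sum() == pytest.approx(3.0)
        p, w = DiscreteNull(np.array([1, 1, 1]), variant="mid_p").pooled_pvalues()
        assert np.allclose(p, 0.5)

    def test_single_support_matches_enumeration(self):
        t = 4
        p, w = DiscreteNull(np.array([t])).pooled_pvalues()
        expect = {}
        for k in range(t + 1):
            pv = mcnemar_mid_p(k, t - k)
            expect[pv] = expect.get(pv, 0.0) + binom.pmf(k, t, 0.5)
        got = {}
        for pv, ww in zip(p, w):
            got[pv] = got.get(pv, 0.0) + ww
        assert set(np.round(list(got), 12)) == set(np.round(list(expect), 12))
        for pv, mass in expect.items():
            assert got[pv] == pytest.approx(mass, abs=1e-12)

    def test_exact_p_is_valid_on_lattice(self):
        """P(exact p <= alpha) <= alpha at every achievable alpha, t <= 60."""
        for t in range(1, 61):
            k = np.arange(t + 1)
            pmf = binom.pmf(k, t, 0.5)
            pvals = np.array([mcnemar_exact_p(int(b), int(t - b)) for b in k])
            for alpha in np.unique(pvals):
                assert pmf[pvals <= alpha].sum() <= alpha + 1e-12

    def test_null_scan_qq_slope_near_one(self):
        mat = generate(SimConfig(n_pairs=102, n_null_snps=4000, missing_rate=0.0,
                                 within_pair_corr=0.0, seed=31))
        res = run_genome_scan(mat, scenarios=(Scenario("a1", "two_copy"),))
        res = res.dropna(subset=["mid_p"])
        null = DiscreteNull((res["b"] + res["c"]).to_numpy())
        n_points = 500
        expected = np.sort(qq_expected(null, n_points))  # descending -log10 sorted asc
        ps = np.sort(res["mid_p"].to_numpy())
        pick = np.minimum(
            (((np.arange(1, n_points + 1) - 0.5) / n_points) * ps.size).astype(int),
            ps.size - 1,
        )
        observed = np.sort(-np.log10(ps[pick]))
        # regress observed on expected through the origin
        slope = np.sum(expected * observed) / np.sum(expected**2)
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_empty_scan_errors(self):
        with pytest.raises(ValueError):
            DiscreteNull(np.array([])).pooled_pvalues()
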