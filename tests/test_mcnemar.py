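"""McNemar statistics against enumeration oracles and printed reference rows."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from penmate.mcnemar_core import (
    ALL_SCENARIOS,
    Scenario,
    best_per_snp,
    cohens_g,
    mcnemar_chi2,
    mcnemar_exact_p,
    mcnemar_mid_p,
    odds_ratio_ci,
    prs_value,
    run_genome_scan,
    tabulate_pairs,
)
from penmate.plink_io import SnpMeta
from penmate.qc_filters import apply_post_filters
from penmate.synthetic_data import SimConfig, fixture_from_quadrants, generate


def binom_pmf_exact(k: int, n: int) -> float:
    return comb(n, k) / 2**n


def midp_oracle(b: int, c: int) -> float:
    """Direct PMF summation: 2 (sum_{i<k} f(i) + f(k)/2), k = min(b,c)."""
    t, k = b + c, min(b, c)
    s = sum(binom_pmf_exact(i, t) for i in range(k)) + 0.5 * binom_pmf_exact(k, t)
    return min(1.0, 2.0 * s)


def exactp_oracle(b: int, c: int) -> float:
    t, k = b + c, min(b, c)
    return min(1.0, 2.0 * sum(binom_pmf_exact(i, t) for i in range(k + 1)))


class TestPValues:
    @settings(max_examples=200, deadline=None)
    @given(b=st.integers(0, 200), c=st.integers(0, 200))
    def test_against_enumeration_oracle(self, b, c):
        if b + c == 0 or b + c > 200:
            return
        assert mcnemar_mid_p(b, c) == pytest.approx(midp_oracle(b, c), abs=1e-12)
        assert mcnemar_exact_p(b, c) == pytest.approx(exactp_oracle(b, c), abs=1e-12)

    def test_published_rows(self):
        """Frozen values for the two strongest association signals: the
        homozygous-major two-copy quadrants (42, 5) and (37, 5)."""
        assert -np.log10(mcnemar_mid_p(42, 5)) == pytest.approx(7.86, abs=0.005)
        assert -np.log10(mcnemar_mid_p(37, 5)) == pytest.approx(6.60, abs=0.005)
        assert mcnemar_exact_p(28, 1) == pytest.approx(1.1e-7, rel=0.05)

    def test_symmetric_counts_give_one(self):
        assert mcnemar_mid_p(5, 5) == 1.0
        assert mcnemar_exact_p(1, 1) == 1.0

    def test_one_sided_extreme_closed_form(self):
        assert mcnemar_exact_p(10, 0) == pytest.approx(2 * 0.5**10, abs=1e-15)

    @settings(max_examples=100, deadline=None)
    @given(b=st.integers(0, 100), c=st.integers(0, 100))
    def test_midp_below_exact_when_asymmetric(self, b, c):
        if b + c == 0 or b == c:
            return
        assert mcnemar_mid_p(b, c) <= mcnemar_exact_p(b, c)


class TestDerivedStatistics:
    def test_chi2_continuity_corrected_rows(self):
        assert mcnemar_chi2(42, 5, continuity=True) == pytest.approx(27.6, abs=0.05)
        assert mcnemar_chi2(37, 5, continuity=True) == pytest.approx(22.9, abs=0.05)

    def test_chi2_no_correction_symmetric_zero(self):
        assert mcnemar_chi2(6, 6, continuity=False) == 0.0

    def test_chi2_cc_floors_at_zero(self):
        assert mcnemar_chi2(6, 6, continuity=True) == 0.0

    def test_odds_ratio_wald_ci_rows(self):
        or_, lo, hi = odds_ratio_ci(42, 5)
        assert (or_, lo, hi) == (pytest.approx(8.4), pytest.approx(3.3, abs=0.05),
                                 pytest.approx(21, abs=0.5))
        or_, lo, hi = odds_ratio_ci(28, 1)
        assert or_ == 28
        assert hi == pytest.approx(206, abs=1)

    def test_odds_ratio_zero_cell_flagged(self):
        or_, lo, hi = odds_ratio_ci(10, 0)
        assert np.isinf(or_) and np.isnan(lo) and np.isnan(hi)

    def test_or_symmetric_inverse(self):
        a, _, _ = odds_ratio_ci(13, 4)
        b, _, _ = odds_ratio_ci(4, 13)
        assert a * b == pytest.approx(1.0)

    def test_cohens_g_rows_and_bounds(self):
        assert cohens_g(42, 5) == pytest.approx(0.394, abs=0.0005)
        assert cohens_g(44, 11) == pytest.approx(0.300, abs=0.0005)
        assert cohens_g(7, 7) == 0.0

    def test_prs_value_rows(self):
        g = cohens_g(42, 5)
        assert prs_value(g, 42, 5, 102) == pytest.approx(0.18, abs=0.005)
        g = cohens_g(44, 11)
        assert prs_value(g, 44, 11, 101) == pytest.approx(0.163, abs=0.001)


class TestTabulation:
    def test_discordant_pair_lands_in_b(self, snp_ag):
        mat = fixture_from_quadrants(0, 1, 0, 0, Scenario("a1", "two_copy"), snp_ag)
        assert tabulate_pairs(mat, 0, Scenario("a1", "two_copy")) == (0, 1, 0, 0, 1)

    def test_het_pair_concordant_under_one_copy(self, snp_ag):
        mat = fixture_from_quadrants(1, 0, 0, 0, Scenario("a1", "one_copy"), snp_ag)
        assert tabulate_pairs(mat, 0, Scenario("a1", "one_copy"))[0] == 1

    def test_missing_member_drops_whole_pair(self, snp_ag):
        mat = fixture_from_quadrants(2, 1, 0, 1, Scenario("a1", "two_copy"), snp_ag)
        mat.calls[0, 0] = "0"  # control of the first (concordant-exposed) pair
        a, b, c, d, n = tabulate_pairs(mat, 0, Scenario("a1", "two_copy"))
        assert n == 3 and (a, b, c, d) == (1, 1, 0, 1)

    def test_quadrants_realized_exactly(self, snp_ag):
        mat = fixture_from_quadrants(55, 42, 5, 0, Scenario("a1", "two_copy"), snp_ag)
        assert tabulate_pairs(mat, 0, Scenario("a1", "two_copy")) == (55, 42, 5, 0, 102)


class TestGenomeScan:
    def test_six_rows_per_snp(self, small_matrix):
        res = run_genome_scan(small_matrix)
        assert len(res) == 6 * small_matrix.n_snps
        per_snp = res.groupby("snp_id").size()
        assert (per_snp == 6).all()

    def test_complement_identity_dominant_vs_recessive(self, small_matrix):
        """(a1, one_or_two) is the complement relabeling of (a2, two_copy):
        quadrants b and c swap, p-values coincide."""
        res = run_genome_scan(small_matrix)
        dom = res[(res["model"] == "one_or_two")].set_index(["snp_id", "risk_allele"])
        rec = res[(res["model"] == "two_copy")].set_index(["snp_id", "risk_allele"])
        for snp in small_matrix.snps:
            r1 = dom.loc[(snp.snp_id, snp.a1)]
            r2 = rec.loc[(snp.snp_id, snp.a2)]
            assert (r1["b"], r1["c"]) == (r2["c"], r2["b"])
            if not np.isnan(r1["mid_p"]):
                assert r1["mid_p"] == pytest.approx(r2["mid_p"], abs=1e-12)

    def test_case_control_swap_inverts_or(self, spiked_matrix):
        """Relabeling every pair's case/control swaps b and c, inverts the OR
        and leaves mid-p, chi2 and g unchanged."""
        import copy

        flipped = copy.deepcopy(spiked_matrix)
        n = flipped.n_pairs
        order = np.arange(2 * n).reshape(n, 2)[:, ::-1].ravel()
        flipped.calls = flipped.calls[order]
        res = run_genome_scan(spiked_matrix)
        res_f = run_genome_scan(flipped)
        key = ["snp_id", "risk_allele", "model"]
        merged = res.merge(res_f, on=key, suffixes=("", "_f"))
        assert (merged["b"] == merged["c_f"]).all()
        pd.testing.assert_series_equal(
            merged["mid_p"], merged["mid_p_f"], check_names=False
        )
        both = merged[(merged["b"] > 0) & (merged["c"] > 0)]
        assert np.allclose(both["OR"] * both["OR_f"], 1.0)

    def test_protective_orientation(self, spiked_matrix):
        """A risk allele (b > c) in one orientation shows OR < 1 in the
        complementary orientation."""
        res = run_genome_scan(spiked_matrix)
        spike = res[(res["snp_id"] == "spikeA") & (res["model"] == "two_copy")]
        risk_row = spike[spike["b"] > spike["c"]].iloc[0]
        other = res[
            (res["snp_id"] == "spikeA")
            & (res["model"] == "one_or_two")
            & (res["risk_allele"] != risk_row["risk_allele"])
        ].iloc[0]
        assert risk_row["OR"] > 1 and other["OR"] < 1

    def test_null_midp_close_to_uniform_on_lattice(self):
        """Null SNPs' mid-p values are near-uniform once lattice discreteness
        is accounted for: the fraction with p <= 0.05 stays near 0.05."""
        mat = generate(SimConfig(n_pairs=102, n_null_snps=2000, missing_rate=0.0,
                                 within_pair_corr=0.0, seed=23))
        res = run_genome_scan(mat, scenarios=(Scenario("a1", "two_copy"),))
        p = res["mid_p"].dropna()
        frac = (p <= 0.05).mean()
        assert 0.02 <= frac <= 0.08


class TestPostFilter:
    def test_no_informative_and_bad_chrom_removed(self, snp_ag):
        rows = []
        for snp_id, chrom, b, c in [
            ("ok", 7, 10, 2), ("noinfo", 7, 0, 0), ("unmapped", 0, 5, 5),
            ("ychrom", 31, 5, 5), ("mito", 32, 1, 1), ("xchrom", 30, 3, 3),
        ]:
            rows.append({"snp_id": snp_id, "chrom": chrom, "b": b, "c": c})
        df = pd.DataFrame(rows)
        kept, report = apply_post_filters(df)
        assert set(kept["snp_id"]) == {"ok", "xchrom"}
        assert report.n_removed_no_informative == 1
        assert report.n_removed_unplaced_y_mt == 3
        report.check_conservation()
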