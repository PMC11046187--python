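"""Per-SNP McNemar tests over matched case-control pairs.

Each biallelic SNP is scored under six scenarios: either allele (a1 or a2)
hypothesized as the risk allele, under three inheritance models:

* ``one_copy``   — exposed iff heterozygous;
* ``one_or_two`` — exposed iff carrying at least one copy (dominant);
* ``two_copy``   — exposed iff homozygous for the risk allele (recessive).

Pairs where either member is untyped at the SNP are dropped from that SNP's
table. The 2x2 quadrants count pairs by (case exposure, control exposure):
a = (+,+), b = (+,-), c = (-,+), d = (-,-); only the discordant quadrants
b and c are informative. The test treats b as Binomial(b+c, 1/2) under the
null and reports:

* mid-p   = 2 (F(k; t, 1/2) - f(k; t, 1/2) / 2), k = min(b,c), t = b + c,
  capped at 1 — the primary statistic;
* exact p = min(1, 2 F(k; t, 1/2));
* chi-squared (b-c)^2/t and its continuity-corrected form (|b-c|-1)^2/t;
* odds ratio b/c with 95% Wald interval exp(ln OR ± 1.96 sqrt(1/b + 1/c));
* Cohen's g = max(b,c)/t - 1/2, an effect size in [0, 1/2];
* a per-marker polygenic-risk-factor value, g x (b+c)/n_pairs_used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import binom

from .plink_io import MISSING, PairedGenotypeMatrix, SnpMeta

Model = Literal["one_copy", "one_or_two", "two_copy"]
MODELS: tuple[Model, ...] = ("one_copy", "one_or_two", "two_copy")


@dataclass(frozen=True)
class Scenario:
    """One of the six (risk allele, inheritance model) combinations."""

    allele: Literal["a1", "a2"]
    model: Model

    def risk_letter(self, snp: SnpMeta) -> str:
        return snp.a1 if self.allele == "a1" else snp.a2

    def exposed_codes(self, snp: SnpMeta) -> set[str]:
        """Call codes that count as exposed at ``snp`` under this scenario."""
        risk = self.risk_letter(snp)
        het = snp.het_code
        if self.model == "one_copy":
            return {het}
        if self.model == "two_copy":
            return {risk}
        return {risk, het}


ALL_SCENARIOS: tuple[Scenario, ...] = tuple(
    Scenario(allele, model) for allele, model in product(("a1", "a2"), MODELS)
)


@dataclass
class McNemarResult:
    snp_id: str
    scenario: Scenario
    a: int
    b: int
    c: int
    d: int
    n_pairs_used: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    chi2_cc: float
    mid_p: float
    exact_p: float
    cohens_g: float
    prop_informative: float
    prs_value: float


def mcnemar_mid_p(b: int, c: int) -> float:
    """Two-sided binomial mid-p for discordant counts (b, c); b + c >= 1."""
    t = b + c
    if t < 1:
        raise ValueError("no informative pairs (b + c = 0)")
    k = min(b, c)
    p = 2.0 * (binom.cdf(k, t, 0.5) - 0.5 * binom.pmf(k, t, 0.5))
    return float(min(1.0, p))


def mcnemar_exact_p(b: int, c: int) -> float:
    """Two-sided exact conditional p, min(1, 2 F(min(b,c); b+c, 1/2))."""
    t = b + c
    if t < 1:
        raise ValueError("no informative pairs (b + c = 0)")
    return float(min(1.0, 2.0 * binom.cdf(min(b, c), t, 0.5)))


def mcnemar_chi2(b: int, c: int, continuity: bool = True) -> float:
    """McNemar chi-squared; the continuity-corrected form floors at 0."""
    t = b + c
    if t < 1:
        raise ValueError("no informative pairs (b + c = 0)")
    if continuity:
        return max(0.0, (abs(b - c) - 1.0)) ** 2 / t
    return (b - c) ** 2 / t


def odds_ratio_ci(
    b: int, c: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Discordant-pair odds ratio b/c with a Wald interval on the log scale.

    No continuity (Haldane) correction is applied: a zero in either quadrant
    yields an infinite or zero OR with NaN bounds, which callers must treat
    as undefined.
    """
    from scipy.stats import norm

    if b < 0 or c < 0 or b + c < 1:
        raise ValueError("need b, c >= 0 with b + c >= 1")
    if c == 0:
        return float("inf"), float("nan"), float("nan")
    if b == 0:
        return 0.0, float("nan"), float("nan")
    z = norm.ppf(0.5 + level / 2.0)
    or_ = b / c
    se = np.sqrt(1.0 / b + 1.0 / c)
    return or_, float(np.exp(np.log(or_) - z * se)), float(np.exp(np.log(or_) + z * se))


def cohens_g(b: int, c: int) -> float:
    """Effect size for paired binary data: max(b,c)/(b+c) - 1/2."""
    t = b + c
    if t < 1:
        raise ValueError("no informative pairs (b + c = 0)")
    return max(b, c) / t - 0.5


def prs_value(g: float, b: int, c: int, n_pairs_used: int) -> float:
    """Polygenic-risk-factor value: effect size x proportion informative."""
    return g * (b + c) / n_pairs_used


def tabulate_pairs(
    matrix: PairedGenotypeMatrix, snp_index: int, scenario: Scenario
) -> tuple[int, int, int, int, int]:
    """2x2 quadrants (a, b, c, d) and pair count for one SNP and scenario.

    A pair contributes only if both members are typed at the SNP.
    """
    snp = matrix.snps[snp_index]
    col = matrix.calls[:, snp_index]
    ctrl = col[matrix.control_rows()]
    case = col[matrix.case_rows()]
    called = (ctrl != MISSING) & (case != MISSING)
    codes = scenario.exposed_codes(snp)
    e_case = np.isin(case, list(codes)) & called
    e_ctrl = np.isin(ctrl, list(codes)) & called
    a = int(np.sum(e_case & e_ctrl))
    b = int(np.sum(e_case & ~e_ctrl & called))
    c = int(np.sum(~e_case & e_ctrl & called))
    n_used = int(called.sum())
    d = n_used - a - b - c
    return a, b, c, d, n_used


def result_from_quadrants(
    snp_id: str, scenario: Scenario, a: int, b: int, c: int, d: int, n_pairs_used: int
) -> McNemarResult:
    """Assemble every derived statistic from one SNP's quadrant counts."""
    if b + c >= 1:
        or_, lo, hi = odds_ratio_ci(b, c)
        g = cohens_g(b, c)
        res = McNemarResult(
            snp_id=snp_id,
            scenario=scenario,
            a=a,
            b=b,
            c=c,
            d=d,
            n_pairs_used=n_pairs_used,
            odds_ratio=or_,
            ci_low=lo,
            ci_high=hi,
            chi2=mcnemar_chi2(b, c, continuity=False),
            chi2_cc=mcnemar_chi2(b, c, continuity=True),
            mid_p=mcnemar_mid_p(b, c),
            exact_p=mcnemar_exact_p(b, c),
            cohens_g=g,
            prop_informative=(b + c) / n_pairs_used,
            prs_value=prs_value(g, b, c, n_pairs_used),
        )
    else:
        nan = float("nan")
        res = McNemarResult(
            snp_id, scenario, a, b, c, d, n_pairs_used,
            nan, nan, nan, nan, nan, nan, nan, nan,
            0.0 if n_pairs_used else nan, nan,
        )
    return res


SCAN_COLUMNS = [
    "chrom", "pos_bp", "snp_id", "risk_allele", "model",
    "a", "b", "c", "d", "n_pairs",
    "OR", "CI_low", "CI_high", "chi2", "chi2_cc",
    "mid_p", "exact_p", "neglog10_mid_p",
    "cohens_g", "prop_informative", "prs_value",
]


def _vector_stats(b: np.ndarray, c: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized statistics over arrays of quadrant counts (NaN where t=0)."""
    b = b.astype(float)
    c = c.astype(float)
    t = b + c
    k = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        valid = t >= 1
        ts = np.where(valid, t, 1.0)
        mid = 2.0 * (binom.cdf(k, ts, 0.5) - 0.5 * binom.pmf(k, ts, 0.5))
        exact = 2.0 * binom.cdf(k, ts, 0.5)
        mid = np.where(valid, np.minimum(1.0, mid), np.nan)
        exact = np.where(valid, np.minimum(1.0, exact), np.nan)
        chi2 = np.where(valid, (b - c) ** 2 / ts, np.nan)
        chi2_cc = np.where(valid, np.maximum(np.abs(b - c) - 1.0, 0.0) ** 2 / ts, np.nan)
        or_ = np.where(c > 0, b / np.where(c > 0, c, 1.0), np.where(b > 0, np.inf, np.nan))
        se = np.sqrt(1.0 / np.where(b > 0, b, np.nan) + 1.0 / np.where(c > 0, c, np.nan))
        log_or = np.log(np.where((b > 0) & (c > 0), or_, np.nan))
        lo = np.exp(log_or - 1.959963984540054 * se)
        hi = np.exp(log_or + 1.959963984540054 * se)
        g = np.where(valid, np.maximum(b, c) / ts - 0.5, np.nan)
    return {
        "mid_p": mid, "exact_p": exact, "chi2": chi2, "chi2_cc": chi2_cc,
        "OR": or_, "CI_low": lo, "CI_high": hi, "cohens_g": g,
    }


def run_genome_scan(
    matrix: PairedGenotypeMatrix, scenarios: tuple[Scenario, ...] = ALL_SCENARIOS
) -> pd.DataFrame:
    """Score every SNP under every scenario; six rows per SNP by default.

    Returns a table with :data:`SCAN_COLUMNS`, sorted by (chrom, pos) within
    the input SNP order. Statistics are NaN for scenarios with no informative
    pairs; such SNPs are later dropped by the post-association filter.
    """
    n_snps = matrix.n_snps
    ctrl = matrix.calls[matrix.control_rows(), :]
    case = matrix.calls[matrix.case_rows(), :]
    called = (ctrl != MISSING) & (case != MISSING)  # pairs x snps
    n_used = called.sum(axis=0)

    a1 = np.array([s.a1 for s in matrix.snps])
    a2 = np.array([s.a2 for s in matrix.snps])
    het = np.array([s.het_code for s in matrix.snps])

    frames = []
    for scen in scenarios:
        risk = a1 if scen.allele == "a1" else a2
        if scen.model == "one_copy":
            e_case = case == het
            e_ctrl = ctrl == het
        elif scen.model == "two_copy":
            e_case = case == risk
            e_ctrl = ctrl == risk
        else:
            e_case = (case == risk) | (case == het)
            e_ctrl = (ctrl == risk) | (ctrl == het)
        e_case &= called
        e_ctrl &= called
        a = (e_case & e_ctrl).sum(axis=0)
        b = (e_case & ~e_ctrl & called).sum(axis=0)
        c = (~e_case & e_ctrl & called).sum(axis=0)
        d = n_used - a - b - c
        stats = _vector_stats(b, c)
        df = pd.DataFrame(
            {
                "chrom": [s.chrom for s in matrix.snps],
                "pos_bp": [s.pos_bp for s in matrix.snps],
                "snp_id": [s.snp_id for s in matrix.snps],
                "risk_allele": risk,
                "model": scen.model,
                "a": a, "b": b, "c": c, "d": d, "n_pairs": n_used,
                "OR": stats["OR"], "CI_low": stats["CI_low"], "CI_high": stats["CI_high"],
                "chi2": stats["chi2"], "chi2_cc": stats["chi2_cc"],
                "mid_p": stats["mid_p"], "exact_p": stats["exact_p"],
                "neglog10_mid_p": -np.log10(stats["mid_p"]),
                "cohens_g": stats["cohens_g"],
                "prop_informative": np.where(n_used > 0, (b + c) / np.maximum(n_used, 1), np.nan),
                "prs_value": stats["cohens_g"] * (b + c) / np.maximum(n_used, 1),
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    # stable sort: ties in p resolved by genome coordinates
    out = out.sort_values(["chrom", "pos_bp", "snp_id"], kind="stable").reset_index(drop=True)
    return out[SCAN_COLUMNS]


def best_per_snp(results: pd.DataFrame, model: Model) -> pd.DataFrame:
    """One row per SNP for a given model: the allele orientation with the
    smaller mid-p (ties broken toward the a-priori first orientation)."""
    sub = results[results["model"] == model]
    idx = sub.groupby("snp_id", sort=False)["mid_p"].idxmin()
    return sub.loc[idx.dropna()].reset_index(drop=True)
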