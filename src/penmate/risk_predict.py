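"""Two-locus homozygous-risk classification and predictive values.

The two-SNP test scores an animal by its risk-allele copy counts at two
loci (here modeled after the ARRDC3 and NFIA markers). Disease-risk tiers
follow the combined genotype configuration:

====================  ==========  =====  =============  =====
(copies L1, L2)       total       tier   transmission%  rank
====================  ==========  =====  =============  =====
(2, 2)                4           28x    100            5
one locus with 2      2 or 3      8x     50/75          3/4
all others            0-2         1x     0/25/50        1-3
====================  ==========  =====  =============  =====

Transmission probability is 25% per risk allele carried (the chance a
gamete carries a risk allele at a given locus, averaged over both loci).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcnemar_core import McNemarResult, Scenario, result_from_quadrants
from .plink_io import IUPAC_HET, MISSING, PairedGenotypeMatrix, SnpMeta


@dataclass(frozen=True)
class RiskConfiguration:
    copies_locus1: int
    copies_locus2: int
    total_risk_alleles: int
    tier_label: str  # "1x" | "8x" | "28x"
    breeding_rank: int  # 1-5
    transmission_prob: float  # percent


def _tier(c1: int, c2: int) -> tuple[str, int]:
    if c1 == 2 and c2 == 2:
        return "28x", 5
    total = c1 + c2
    if c1 == 2 or c2 == 2:
        return "8x", 3 if total == 2 else 4
    # ranks for the 1x tier track total copies: 0 -> 1, 1 -> 2, 2 -> 3
    return "1x", total + 1


def risk_configuration(copies_locus1: int, copies_locus2: int) -> RiskConfiguration:
    """Tier, breeding rank and transmission probability for a copy-count pair."""
    for c in (copies_locus1, copies_locus2):
        if c not in (0, 1, 2):
            raise ValueError(f"copy count must be 0, 1 or 2; got {c}")
    tier, rank = _tier(copies_locus1, copies_locus2)
    total = copies_locus1 + copies_locus2
    return RiskConfiguration(
        copies_locus1=copies_locus1,
        copies_locus2=copies_locus2,
        total_risk_alleles=total,
        tier_label=tier,
        breeding_rank=rank,
        transmission_prob=25.0 * total,
    )


def _copies(call: str, snp: SnpMeta, risk_allele: str) -> int | None:
    """Risk-allele copies in a one-letter call; None when missing."""
    if risk_allele not in (snp.a1, snp.a2):
        raise ValueError(f"{snp.snp_id}: risk allele {risk_allele} not among {snp.a1}/{snp.a2}")
    if frozenset((snp.a1, snp.a2)) not in IUPAC_HET:
        raise ValueError(f"{snp.snp_id}: allele pair has no unique IUPAC het code")
    if call == MISSING:
        return None
    if call == snp.het_code:
        return 1
    if call == risk_allele:
        return 2
    other = snp.a2 if risk_allele == snp.a1 else snp.a1
    if call == other:
        return 0
    raise ValueError(f"{snp.snp_id}: unexpected call {call!r}")


def classify_animal(
    genotype_locus1: str,
    genotype_locus2: str,
    locus1: SnpMeta,
    locus2: SnpMeta,
    risk_allele1: str,
    risk_allele2: str,
) -> RiskConfiguration | None:
    """Risk configuration for one animal; None if either locus is untyped."""
    c1 = _copies(genotype_locus1, locus1, risk_allele1)
    c2 = _copies(genotype_locus2, locus2, risk_allele2)
    if c1 is None or c2 is None:
        return None
    return risk_configuration(c1, c2)


def combined_exposure_mcnemar(
    matrix: PairedGenotypeMatrix,
    locus1_index: int,
    locus2_index: int,
    risk_allele1: str,
    risk_allele2: str,
) -> McNemarResult:
    """McNemar test with exposure = homozygous risk at BOTH loci.

    Pairs with any missing call at either locus are dropped.
    """
    snp1, snp2 = matrix.snps[locus1_index], matrix.snps[locus2_index]
    col1 = matrix.calls[:, locus1_index]
    col2 = matrix.calls[:, locus2_index]
    called = (col1 != MISSING) & (col2 != MISSING)
    exposed = (col1 == risk_allele1) & (col2 == risk_allele2)
    if risk_allele1 not in (snp1.a1, snp1.a2) or risk_allele2 not in (snp2.a1, snp2.a2):
        raise ValueError("risk allele not among the locus alleles")
    ctrl_rows, case_rows = matrix.control_rows(), matrix.case_rows()
    ok = called[ctrl_rows] & called[case_rows]
    e_case = exposed[case_rows] & ok
    e_ctrl = exposed[ctrl_rows] & ok
    a = int(np.sum(e_case & e_ctrl))
    b = int(np.sum(e_case & ~e_ctrl & ok))
    c = int(np.sum(~e_case & e_ctrl & ok))
    n_used = int(ok.sum())
    d = n_used - a - b - c
    scen = Scenario("a1" if risk_allele1 == snp1.a1 else "a2", "two_copy")
    return result_from_quadrants(
        f"{snp1.snp_id}+{snp2.snp_id}", scen, a, b, c, d, n_used
    )


@dataclass
class ClassifierMetrics:
    sensitivity: float
    specificity: float
    prevalence: float
    ppv: float
    npv: float


def predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> ClassifierMetrics:
    """Prevalence-adjusted PPV and NPV by Bayes' rule."""
    for name, v in [("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)]:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    se, sp, pi = sensitivity, specificity, prevalence
    denom_p = se * pi + (1 - sp) * (1 - pi)
    denom_n = sp * (1 - pi) + (1 - se) * pi
    ppv = se * pi / denom_p if denom_p > 0 else float("nan")
    npv = sp * (1 - pi) / denom_n if denom_n > 0 else float("nan")
    return ClassifierMetrics(se, sp, pi, ppv, npv)


def cohort_risk_summary(
    genotypes: pd.DataFrame,
    locus1: SnpMeta,
    locus2: SnpMeta,
    risk_allele1: str,
    risk_allele2: str,
    cohort_col: str = "cohort",
    locus1_col: str = "locus1",
    locus2_col: str = "locus2",
) -> pd.DataFrame:
    """Per-cohort tier counts and fraction homozygous at both loci.

    ``genotypes`` holds one row per animal with one-letter calls at the two
    loci. Animals untyped at either locus are excluded from the denominator
    and counted in ``n_unclassified``.
    """
    records = []
    for cohort, sub in genotypes.groupby(cohort_col, sort=False):
        tiers = {"1x": 0, "8x": 0, "28x": 0}
        n_unclassified = 0
        for _, row in sub.iterrows():
            cfg = classify_animal(
                row[locus1_col], row[locus2_col], locus1, locus2,
                risk_allele1, risk_allele2,
            )
            if cfg is None:
                n_unclassified += 1
            else:
                tiers[cfg.tier_label] += 1
        n_classified = sum(tiers.values())
        records.append(
            {
                cohort_col: cohort,
                "n": len(sub),
                "n_unclassified": n_unclassified,
                "n_1x": tiers["1x"],
                "n_8x": tiers["8x"],
                "n_28x": tiers["28x"],
                "frac_both_homozygous": tiers["28x"] / n_classified
                if n_classified
                else float("nan"),
            }
        )
    return pd.DataFrame.from_records(records)
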