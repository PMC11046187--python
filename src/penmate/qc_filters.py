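"""Pre- and post-association SNP filters.

Pre-association filters mirror the PLINK options used for array QC:
minor-allele frequency (``--maf``), per-SNP missing-call rate (``--geno``)
and the Hardy-Weinberg exact test with mid-p adjustment (``--hwe midp``).
A marker is kept iff it passes all three; for reporting, each removed marker
is attributed to the first filter it fails in the order maf -> missing -> hwe.

Post-association removals drop markers on unmapped/Y/MT chromosome codes
(0, 31, 32) and markers with no informative pairs (b + c = 0 in every
scenario).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import lgamma, exp

import numpy as np
import pandas as pd

from .plink_io import MISSING, PairedGenotypeMatrix, SnpMeta


@dataclass
class FilterReport:
    """Accounting of SNP removals; each SNP counts toward exactly one reason."""

    n_input: int = 0
    n_removed_maf: int = 0
    n_removed_missing: int = 0
    n_removed_hwe: int = 0
    n_removed_no_informative: int = 0
    n_removed_unplaced_y_mt: int = 0
    kept_ids: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)

    def check_conservation(self) -> None:
        total = (
            self.n_kept
            + self.n_removed_maf
            + self.n_removed_missing
            + self.n_removed_hwe
            + self.n_removed_no_informative
            + self.n_removed_unplaced_y_mt
        )
        if total != self.n_input:
            raise AssertionError(f"filter accounting broken: {total} != {self.n_input}")

    def to_json(self) -> str:
        d = asdict(self)
        d["n_kept"] = self.n_kept
        d.pop("kept_ids")
        return json.dumps(d, indent=2)


def genotype_counts(
    column: np.ndarray, snp: SnpMeta
) -> tuple[int, int, int, int]:
    """Count (a1-homozygote, heterozygote, a2-homozygote, missing) calls."""
    col = np.asarray(column)
    n11 = int(np.sum(col == snp.a1))
    n12 = int(np.sum(col == snp.het_code))
    n22 = int(np.sum(col == snp.a2))
    nmiss = int(np.sum(col == MISSING))
    if n11 + n12 + n22 + nmiss != col.size:
        foreign = set(col) - {snp.a1, snp.a2, snp.het_code, MISSING}
        raise ValueError(f"{snp.snp_id}: foreign call codes {sorted(foreign)}")
    return n11, n12, n22, nmiss


def maf(counts: tuple[int, int, int, int]) -> float:
    """Minor allele frequency from genotype counts; NaN if all calls missing."""
    n11, n12, n22, _ = counts
    n_called = n11 + n12 + n22
    if n_called == 0:
        return float("nan")
    p = (2 * n11 + n12) / (2 * n_called)
    return min(p, 1.0 - p)


def hwe_exact_midp(n11: int, n12: int, n22: int) -> float:
    """Exact conditional Hardy-Weinberg test with the mid-p adjustment.

    Conditions on the observed allele counts and enumerates every heterozygote
    count of matching parity; mid-p sums the probability of configurations
    strictly less probable than the observed one plus half the probability of
    those equally probable (the observed configuration included). Degenerate
    tables with a single achievable configuration return 1.0.
    """
    if min(n11, n12, n22) < 0:
        raise ValueError("negative genotype count")
    n = n11 + n12 + n22
    if n == 0:
        raise ValueError("no genotyped animals")
    na = 2 * n11 + n12  # copies of a1
    nb = 2 * n22 + n12
    rare = min(na, nb)
    # achievable het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    if hets.size <= 1:
        return 1.0
    # P(n12=h | na, nb) = C(n, (na-h)/2, h, (nb-h)/2) 2^h / C(2n, na)
    logc = lgamma(n + 1) + lgamma(na + 1) + lgamma(nb + 1) - lgamma(2 * n + 1)
    logp = np.array(
        [
            logc
            + h * np.log(2)
            - lgamma((na - h) // 2 + 1)
            - lgamma(h + 1)
            - lgamma((nb - h) // 2 + 1)
            for h in hets
        ]
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.nonzero(hets == n12)[0][0]]
    # tolerance guards against float noise in the equal-probability class
    tol = 1e-12 * p_obs
    less = probs < p_obs - tol
    equal = np.abs(probs - p_obs) <= tol
    midp = probs[less].sum() + 0.5 * probs[equal].sum()
    return float(min(1.0, midp))


def apply_pre_filters(
    matrix: PairedGenotypeMatrix,
    maf_min: float = 0.05,
    geno_max: float = 0.05,
    hwe_min: float = 1e-4,
) -> tuple[PairedGenotypeMatrix, FilterReport]:
    """MAF / missingness / HWE filters over the pooled sample.

    Keeps a SNP iff maf >= maf_min, missing fraction <= geno_max and HWE
    mid-p >= hwe_min. All-missing SNPs fall under the missingness reason.
    """
    report = FilterReport(n_input=matrix.n_snps)
    n_animals = 2 * matrix.n_pairs
    keep: list[int] = []
    for j, snp in enumerate(matrix.snps):
        counts = genotype_counts(matrix.calls[:, j], snp)
        f = maf(counts)
        if not np.isnan(f) and f < maf_min:
            report.n_removed_maf += 1
            continue
        if counts[3] / n_animals > geno_max or np.isnan(f):
            report.n_removed_missing += 1
            continue
        if hwe_exact_midp(*counts[:3]) < hwe_min:
            report.n_removed_hwe += 1
            continue
        keep.append(j)
        report.kept_ids.append(snp.snp_id)
    report.check_conservation()
    return matrix.subset_snps(keep), report


def apply_post_filters(results: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Drop scan rows for SNPs on chromosome codes 0/31/32 or with no
    informative pairs (b + c = 0) in every scenario.

    ``results`` is a genome-scan table with columns snp_id, chrom, b, c.
    """
    report = FilterReport(n_input=results["snp_id"].nunique())
    informative = results.groupby("snp_id")[["b", "c"]].sum().sum(axis=1)
    chrom = results.groupby("snp_id")["chrom"].first()
    bad_chrom = chrom.isin([0, 31, 32])
    no_info = (informative == 0) & ~bad_chrom
    report.n_removed_unplaced_y_mt = int(bad_chrom.sum())
    report.n_removed_no_informative = int(no_info.sum())
    keep_ids = chrom.index[~bad_chrom & (informative > 0)]
    report.kept_ids = list(keep_ids)
    report.check_conservation()
    out = results[results["snp_id"].isin(set(keep_ids))].reset_index(drop=True)
    return out, report
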