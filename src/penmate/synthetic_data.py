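"""Seeded generator of matched-pair genotype datasets.

The generator emulates the structure of a feedlot matched case-control
study: N case-control pairs sharing a pair identifier, biallelic SNPs
spread over 29 autosomes plus X, per-SNP minor-allele frequencies, per-call
missingness, a within-pair genotype correlation standing in for shared
ranch origin, and a small set of risk loci where the homozygous-major
genotype is enriched in cases with a specified discordant-pair odds ratio.

Null SNPs use a shared latent pair frequency: each pair draws an allele
frequency q from a Beta distribution with mean p and variance rho p (1-p)
(so any two allele draws within the pair have correlation rho), then both
members sample genotypes from Hardy-Weinberg proportions at q.

Risk loci are simulated exposure-first: the pair's (case exposure, control
exposure) cell is drawn from the 2x2 distribution implied by the control
exposure prevalence under the inheritance model and the target odds ratio
theta (case exposure odds = theta x control exposure odds, members
independent given the effect); genotypes are then sampled from the HWE
distribution conditioned on the drawn exposure status, which keeps the
marginal allele frequency near its target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mcnemar_core import Model, Scenario
from .plink_io import (
    IUPAC_HET,
    MISSING,
    Animal,
    PairedGenotypeMatrix,
    SnpMeta,
    _assign_alleles,
    write_ped_map,
)

_LETTER_PAIRS = [tuple(sorted(fs)) for fs in sorted(IUPAC_HET, key=lambda f: "".join(sorted(f)))]


@dataclass(frozen=True)
class RiskLocus:
    chrom: int
    pos_bp: int
    maf: float
    model: Model  # exposure definition for the risk effect
    theta: float  # target discordant-pair odds ratio
    snp_id: str = ""


@dataclass
class SimConfig:
    """Full parameterization of one synthetic dataset; seeded and reproducible."""

    n_pairs: int = 102
    n_null_snps: int = 1000
    risk_loci: list[RiskLocus] = field(default_factory=list)
    maf_range: tuple[float, float] = (0.05, 0.5)
    maf_values: np.ndarray | None = None  # explicit per-SNP MAFs, overrides range
    within_pair_corr: float = 0.1
    missing_rate: float = 0.01
    n_chromosomes: int = 29  # autosomes; X (code 30) is appended in rotation
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.within_pair_corr < 1:
            raise ValueError("within_pair_corr must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 <= lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        for locus in self.risk_loci:
            if locus.theta <= 0:
                raise ValueError(f"{locus.snp_id or locus.pos_bp}: theta must be > 0")
            if not 0 < locus.maf <= 0.5:
                raise ValueError("risk locus maf must be in (0, 0.5]")
            _risk_cells(locus)  # raises on infeasible combinations


def _exposure_prevalence(p_major: float, model: Model) -> float:
    """HWE prevalence of the exposed genotype class for the major allele."""
    q = 1.0 - p_major
    if model == "two_copy":
        return p_major**2
    if model == "one_copy":
        return 2.0 * p_major * q
    return p_major**2 + 2.0 * p_major * q


def _risk_cells(locus: RiskLocus) -> tuple[float, float, float, float]:
    """(a, b, c, d) cell probabilities for one pair at a risk locus."""
    e0 = _exposure_prevalence(1.0 - locus.maf, locus.model)
    if not 1e-9 < e0 < 1 - 1e-9:
        raise ValueError(
            f"risk locus at {locus.chrom}:{locus.pos_bp}: exposure prevalence "
            f"{e0:.3f} leaves no discordant pairs"
        )
    odds1 = locus.theta * e0 / (1.0 - e0)
    e1 = odds1 / (1.0 + odds1)
    cells = (e1 * e0, e1 * (1 - e0), (1 - e1) * e0, (1 - e1) * (1 - e0))
    if any(not 0 <= x <= 1 for x in cells):
        raise ValueError("infeasible (theta, maf): cell probability outside [0, 1]")
    return cells


def _null_dosages(
    rng: np.random.Generator, n_pairs: int, p_major: np.ndarray, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """Major-allele dosage (0/1/2) for both pair members at null SNPs."""
    p = np.broadcast_to(p_major, (n_pairs, p_major.size))
    if rho == 0:
        q = p
    else:
        conc = (1.0 - rho) / rho
        q = rng.beta(np.maximum(p * conc, 1e-9), np.maximum((1.0 - p) * conc, 1e-9))
    return rng.binomial(2, q), rng.binomial(2, q)


def _conditional_dosage(
    rng: np.random.Generator, exposed: np.ndarray, p_major: float, model: Model
) -> np.ndarray:
    """Sample major-allele dosage given exposure status, from conditional HWE."""
    q = 1.0 - p_major
    hwe = np.array([q**2, 2 * p_major * q, p_major**2])  # dosage 0,1,2
    if model == "two_copy":
        exp_mask = np.array([False, False, True])
    elif model == "one_copy":
        exp_mask = np.array([False, True, False])
    else:
        exp_mask = np.array([False, True, True])
    out = np.empty(exposed.size, dtype=np.int8)
    for flag in (True, False):
        probs = np.where(exp_mask == flag, hwe, 0.0)
        total = probs.sum()
        if total == 0:
            raise ValueError("exposure class has zero HWE probability")
        probs = probs / total
        idx = np.nonzero(exposed == flag)[0]
        out[idx] = rng.choice(3, size=idx.size, p=probs)
    return out


def _dosage_to_calls(dosage: np.ndarray, hi: str, lo: str) -> np.ndarray:
    het = IUPAC_HET[frozenset((hi, lo))]
    lookup = np.array([lo, het, hi], dtype="<U1")
    return lookup[dosage]


def generate(config: SimConfig) -> PairedGenotypeMatrix:
    """Simulate one matched-pair dataset; identical config + seed reproduce
    the matrix bit-identically."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_pairs = config.n_pairs
    m_null = config.n_null_snps

    # --- null SNPs ---
    if config.maf_values is not None:
        mafs = np.asarray(config.maf_values, float)
        if mafs.size != m_null:
            raise ValueError("maf_values length must equal n_null_snps")
    else:
        lo, hi = config.maf_range
        mafs = rng.uniform(lo, hi, m_null)
    p_major = 1.0 - mafs
    dos_ctrl, dos_case = _null_dosages(rng, n_pairs, p_major, config.within_pair_corr)
    pair_idx = rng.integers(0, len(_LETTER_PAIRS), m_null)

    chroms = np.concatenate([np.arange(1, config.n_chromosomes + 1), [30]])
    calls = np.empty((2 * n_pairs, m_null + len(config.risk_loci)), dtype="<U1")
    snps: list[SnpMeta] = []
    pos_counter: dict[int, int] = {}
    for j in range(m_null):
        hi_l, lo_l = _LETTER_PAIRS[pair_idx[j]]
        calls[0::2, j] = _dosage_to_calls(dos_ctrl[:, j], hi_l, lo_l)
        calls[1::2, j] = _dosage_to_calls(dos_case[:, j], hi_l, lo_l)
        chrom = int(chroms[j % chroms.size])
        pos_counter[chrom] = pos_counter.get(chrom, 0) + 10_000
        snps.append(
            SnpMeta(chrom=chrom, pos_bp=pos_counter[chrom], snp_id=f"null{j:06d}")
        )

    # --- risk loci ---
    for r, locus in enumerate(config.risk_loci):
        j = m_null + r
        cells = _risk_cells(locus)
        cat = rng.choice(4, size=n_pairs, p=cells)  # 0=a,1=b,2=c,3=d
        case_exposed = np.isin(cat, [0, 1])
        ctrl_exposed = np.isin(cat, [0, 2])
        p_maj = 1.0 - locus.maf
        dos_case_r = _conditional_dosage(rng, case_exposed, p_maj, locus.model)
        dos_ctrl_r = _conditional_dosage(rng, ctrl_exposed, p_maj, locus.model)
        calls[0::2, j] = _dosage_to_calls(dos_ctrl_r, "A", "G")
        calls[1::2, j] = _dosage_to_calls(dos_case_r, "A", "G")
        snps.append(
            SnpMeta(
                chrom=locus.chrom,
                pos_bp=locus.pos_bp,
                snp_id=locus.snp_id or f"risk{r:03d}",
            )
        )

    # --- missingness ---
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    for j, snp in enumerate(snps):
        _assign_alleles(snp, calls[:, j])

    pairs = [str(i + 1) for i in range(n_pairs)]
    animals: list[Animal] = []
    for pid in pairs:
        animals.append(Animal(pair_id=pid, iid=f"ctrl{pid}", sex=0, phenotype=1))
        animals.append(Animal(pair_id=pid, iid=f"case{pid}", sex=0, phenotype=2))
    matrix = PairedGenotypeMatrix(pairs=pairs, animals=animals, snps=snps, calls=calls)
    matrix.validate()
    return matrix


def write_dataset(config: SimConfig, prefix: str | Path) -> PairedGenotypeMatrix:
    """Generate and write ped/map plus a manifest JSON of realized summaries."""
    matrix = generate(config)
    ped, map_ = write_ped_map(matrix, prefix)
    n_missing = int(np.sum(matrix.calls == MISSING))
    manifest = {
        "seed": config.seed,
        "n_pairs": config.n_pairs,
        "n_snps": matrix.n_snps,
        "n_risk_loci": len(config.risk_loci),
        "missing_fraction": n_missing / matrix.calls.size,
        "files": {"ped": str(ped), "map": str(map_)},
    }
    Path(prefix).with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    return matrix


def fixture_from_quadrants(
    a: int,
    b: int,
    c: int,
    d: int,
    scenario: Scenario,
    snp: SnpMeta,
) -> PairedGenotypeMatrix:
    """Deterministic single-SNP matrix realizing exactly the quadrants
    (a, b, c, d) under ``scenario``. Useful for reproducing printed rows."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("quadrant counts must be nonnegative")
    snp.validate()
    risk = scenario.risk_letter(snp)
    other = snp.a2 if risk == snp.a1 else snp.a1
    het = snp.het_code
    if scenario.model == "one_copy":
        exposed_call, unexposed_call = het, risk
    else:  # one_or_two and two_copy: homozygous risk is exposed either way
        exposed_call, unexposed_call = risk, other
    n_pairs = a + b + c + d
    pairs = [str(i + 1) for i in range(n_pairs)]
    animals: list[Animal] = []
    calls = np.empty((2 * n_pairs, 1), dtype="<U1")
    # pair order: a then b then c then d
    flags = [(True, True)] * a + [(True, False)] * b + [(False, True)] * c + [(False, False)] * d
    for i, (pid, (case_exp, ctrl_exp)) in enumerate(zip(pairs, flags)):
        animals.append(Animal(pair_id=pid, iid=f"ctrl{pid}", sex=0, phenotype=1))
        animals.append(Animal(pair_id=pid, iid=f"case{pid}", sex=0, phenotype=2))
        calls[2 * i, 0] = exposed_call if ctrl_exp else unexposed_call
        calls[2 * i + 1, 0] = exposed_call if case_exp else unexposed_call
    return PairedGenotypeMatrix(pairs=pairs, animals=animals, snps=[snp], calls=calls)


def fixture_two_locus(
    a: int,
    b: int,
    c: int,
    d: int,
    snp1: SnpMeta,
    snp2: SnpMeta,
    risk1: str,
    risk2: str,
) -> PairedGenotypeMatrix:
    """Two-SNP matrix where exposure = homozygous risk at BOTH loci realizes
    the quadrants (a, b, c, d)."""
    for snp in (snp1, snp2):
        snp.validate()
    other1 = snp1.a2 if risk1 == snp1.a1 else snp1.a1
    other2 = snp2.a2 if risk2 == snp2.a1 else snp2.a1
    n_pairs = a + b + c + d
    pairs = [str(i + 1) for i in range(n_pairs)]
    animals: list[Animal] = []
    calls = np.empty((2 * n_pairs, 2), dtype="<U1")
    flags = [(True, True)] * a + [(True, False)] * b + [(False, True)] * c + [(False, False)] * d
    for i, (pid, (case_exp, ctrl_exp)) in enumerate(zip(pairs, flags)):
        animals.append(Animal(pair_id=pid, iid=f"ctrl{pid}", sex=0, phenotype=1))
        animals.append(Animal(pair_id=pid, iid=f"case{pid}", sex=0, phenotype=2))
        calls[2 * i, 0] = risk1 if ctrl_exp else other1
        calls[2 * i, 1] = risk2 if ctrl_exp else risk2  # locus2 homozygous risk for all
        calls[2 * i + 1, 0] = risk1 if case_exp else other1
        calls[2 * i + 1, 1] = risk2
    return PairedGenotypeMatrix(pairs=pairs, animals=animals, snps=[snp1, snp2], calls=calls)
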