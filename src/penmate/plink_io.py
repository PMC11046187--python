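"""Reading and writing PLINK-dialect ped/map text files for matched-pair studies.

The dialect differs from stock PLINK in two ways that matter downstream:

* the ped family ID column carries the *pair* identifier, so a case and its
  matched pen-mate control share an FID;
* two-letter genotypes are collapsed to one-letter codes, with heterozygotes
  written as the IUPAC ambiguity letter for the allele pair (R=A/G, Y=C/T,
  M=A/C, K=G/T, S=C/G, W=A/T) and missing calls as ``0``.

Chromosomes are stored as integer codes 0-32: 0 unmapped, 1-29 autosomes,
30 = X, 31 = Y, 32 = MT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = "0"

#: IUPAC ambiguity letter for each unordered nucleotide pair.
IUPAC_HET = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
}
#: Inverse map: ambiguity letter -> alphabetically ordered allele pair.
IUPAC_EXPAND = {v: tuple(sorted(k)) for k, v in IUPAC_HET.items()}

NUCLEOTIDES = frozenset("ACGT")

_CHROM_ALIASES = {"X": 30, "Y": 31, "MT": 32, "M": 32, "XY": 30}

CONTROL_PHENO = 1
CASE_PHENO = 2


class PedMapError(ValueError):
    """Structural or parse error in a ped/map file."""


def normalize_chrom(label: str | int) -> int:
    """Map a chromosome label to the internal integer code 0-32."""
    s = str(label).strip().upper()
    if s in _CHROM_ALIASES:
        return _CHROM_ALIASES[s]
    try:
        code = int(s)
    except ValueError:
        raise PedMapError(f"unrecognized chromosome label {label!r}") from None
    if not 0 <= code <= 32:
        raise PedMapError(f"chromosome code {code} outside 0-32")
    return code


def chrom_label(code: int) -> str:
    """Human-readable label for an internal chromosome code."""
    return {30: "X", 31: "Y", 32: "MT"}.get(code, str(code))


@dataclass
class SnpMeta:
    """Marker metadata. ``a1`` is the most frequent allele across all typed
    animals at assignment time; ties break alphabetically."""

    chrom: int
    pos_bp: int
    snp_id: str
    a1: str = "?"
    a2: str = "?"

    @property
    def het_code(self) -> str:
        """IUPAC letter for the heterozygous genotype at this marker."""
        return IUPAC_HET[frozenset((self.a1, self.a2))]

    def validate(self) -> None:
        if self.pos_bp < 0:
            raise PedMapError(f"{self.snp_id}: negative position")
        if self.a1 == self.a2 or self.a1 not in NUCLEOTIDES or self.a2 not in NUCLEOTIDES:
            raise PedMapError(f"{self.snp_id}: invalid allele pair {self.a1}/{self.a2}")


@dataclass
class Animal:
    pair_id: str
    iid: str
    sex: int
    phenotype: int  # 1 = control, 2 = case

    @property
    def is_case(self) -> bool:
        return self.phenotype == CASE_PHENO


@dataclass
class PairedGenotypeMatrix:
    """Genotypes for N case-control pairs at M markers.

    ``calls`` is a (2N, M) array of one-letter codes; animal rows are grouped
    by pair with the control first, matching ``animals``.
    """

    pairs: list[str]
    animals: list[Animal]
    snps: list[SnpMeta]
    calls: np.ndarray  # dtype '<U1'

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def control_rows(self) -> np.ndarray:
        return np.arange(0, 2 * self.n_pairs, 2)

    def case_rows(self) -> np.ndarray:
        return np.arange(1, 2 * self.n_pairs, 2)

    def validate(self) -> None:
        if self.calls.shape != (2 * self.n_pairs, self.n_snps):
            raise PedMapError("calls shape inconsistent with pairs/snps")
        for i, pid in enumerate(self.pairs):
            ctrl, case = self.animals[2 * i], self.animals[2 * i + 1]
            if ctrl.pair_id != pid or case.pair_id != pid:
                raise PedMapError(f"pair {pid}: animal ordering broken")
            if ctrl.phenotype != CONTROL_PHENO or case.phenotype != CASE_PHENO:
                raise PedMapError(f"pair {pid}: phenotypes not (control, case)")
        for j, snp in enumerate(self.snps):
            snp.validate()
            legal = {snp.a1, snp.a2, snp.het_code, MISSING}
            bad = set(np.unique(self.calls[:, j])) - legal
            if bad:
                raise PedMapError(f"{snp.snp_id}: illegal call codes {sorted(bad)}")

    def subset_snps(self, keep: np.ndarray | list[int]) -> "PairedGenotypeMatrix":
        """New matrix restricted to the SNP indices in ``keep`` (order kept)."""
        idx = np.asarray(keep, dtype=int)
        return PairedGenotypeMatrix(
            pairs=list(self.pairs),
            animals=list(self.animals),
            snps=[self.snps[j] for j in idx],
            calls=self.calls[:, idx].copy(),
        )


def read_map(path: str | Path) -> list[SnpMeta]:
    """Read a 4-column map file (chrom, snp_id, cM, pos_bp); order preserved.

    Allele columns are filled in later by :func:`read_ped`.
    """
    snps: list[SnpMeta] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise PedMapError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom_s, snp_id, _cm, pos_s = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise PedMapError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            if snp_id in seen:
                warnings.warn(f"duplicate snp_id {snp_id!r} in {path}; keeping both")
            seen.add(snp_id)
            snps.append(SnpMeta(chrom=normalize_chrom(chrom_s), pos_bp=pos, snp_id=snp_id))
    return snps


def _collapse(al1: str, al2: str, lineno: int, snp_id: str) -> str:
    """Two allele letters -> one-letter code. Half-missing is fully missing."""
    if al1 == "0" or al2 == "0":
        return MISSING
    for a in (al1, al2):
        if a not in NUCLEOTIDES:
            raise PedMapError(f"line {lineno}, {snp_id}: allele {a!r} not in A/C/G/T/0")
    if al1 == al2:
        return al1
    return IUPAC_HET[frozenset((al1, al2))]


def _assign_alleles(snp: SnpMeta, column: np.ndarray) -> None:
    """Set a1/a2 from observed calls: a1 is the more frequent allele, ties
    broken alphabetically. Monomorphic columns get an arbitrary partner so the
    invariant a1 != a2 holds (the marker is later removed by the MAF filter)."""
    counts: dict[str, int] = {}
    for code in column:
        if code == MISSING:
            continue
        if code in NUCLEOTIDES:
            counts[code] = counts.get(code, 0) + 2
        else:
            for a in IUPAC_EXPAND[code]:
                counts[a] = counts.get(a, 0) + 1
    alleles = sorted(counts, key=lambda a: (-counts[a], a))
    if len(alleles) > 2:
        raise PedMapError(f"{snp.snp_id}: more than two alleles observed")
    if len(alleles) == 2:
        snp.a1, snp.a2 = alleles
    elif len(alleles) == 1:
        snp.a1 = alleles[0]
        snp.a2 = next(a for a in "ACGT" if a != snp.a1)
    else:  # all missing; placeholder pair, removed by filters
        snp.a1, snp.a2 = "A", "C"


def read_ped(path: str | Path, snps: list[SnpMeta]) -> PairedGenotypeMatrix:
    """Read a ped file whose FID column is the pair identifier.

    Each pair must have exactly one control (PHENO=1) and one case (PHENO=2);
    within a pair the control is ordered first. Genotypes are collapsed to
    one-letter codes and each SNP's a1/a2 assigned from overall frequency.
    """
    m = len(snps)
    rows: list[tuple[Animal, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise PedMapError(
                    f"{path}:{lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
                )
            fid, iid, _pat, _mat, sex_s, pheno_s = fields[:6]
            try:
                sex, pheno = int(sex_s), int(pheno_s)
            except ValueError:
                raise PedMapError(f"{path}:{lineno}: bad sex/phenotype") from None
            if pheno not in (CONTROL_PHENO, CASE_PHENO):
                raise PedMapError(f"{path}:{lineno}: phenotype must be 1 or 2")
            geno = [
                _collapse(fields[6 + 2 * j], fields[7 + 2 * j], lineno, snps[j].snp_id)
                for j in range(m)
            ]
            rows.append((Animal(pair_id=fid, iid=iid, sex=sex, phenotype=pheno), geno))

    by_pair: dict[str, list[tuple[Animal, list[str]]]] = {}
    order: list[str] = []
    for animal, geno in rows:
        if animal.pair_id not in by_pair:
            order.append(animal.pair_id)
        by_pair.setdefault(animal.pair_id, []).append((animal, geno))

    bad = [
        pid
        for pid, members in by_pair.items()
        if len(members) != 2
        or {members[0][0].phenotype, members[1][0].phenotype} != {1, 2}
    ]
    if bad:
        raise PedMapError(
            "pairs must have exactly one control and one case; offending FIDs: "
            + ", ".join(sorted(bad))
        )

    animals: list[Animal] = []
    call_rows: list[list[str]] = []
    for pid in order:
        members = sorted(by_pair[pid], key=lambda ag: ag[0].phenotype)
        for animal, geno in members:
            animals.append(animal)
            call_rows.append(geno)

    calls = np.array(call_rows, dtype="<U1").reshape(len(animals), m)
    for j, snp in enumerate(snps):
        _assign_alleles(snp, calls[:, j])
    mat = PairedGenotypeMatrix(pairs=order, animals=animals, snps=list(snps), calls=calls)
    mat.validate()
    return mat


def _expand(code: str) -> tuple[str, str]:
    if code == MISSING:
        return "0", "0"
    if code in NUCLEOTIDES:
        return code, code
    return IUPAC_EXPAND[code]


def write_ped_map(matrix: PairedGenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``prefix``.ped and ``prefix``.map; round-trips through
    :func:`read_ped` bit-identically on calls, phenotypes and pair structure."""
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for snp in matrix.snps:
            fh.write(f"{snp.chrom} {snp.snp_id} 0 {snp.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(matrix.animals):
            lead = [animal.pair_id, animal.iid, "0", "0", str(animal.sex), str(animal.phenotype)]
            alleles: list[str] = []
            for code in matrix.calls[i]:
                alleles.extend(_expand(code))
            fh.write(" ".join(lead + alleles) + "\n")
    return ped_path, map_path
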