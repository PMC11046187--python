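"""Population-substructure screening: IBS distances and classical MDS.

A matched pen-mate design tolerates substructure better than an unmatched
case-control design, but a gross split (e.g. two breeds) would still
invalidate pooled allele-frequency assumptions. The screen mirrors the
standard array-QC recipe: pairwise identity-by-state (IBS) distance over
autosomal SNPs, then classical (metric) multidimensional scaling of the
distance matrix; matched pairs should scatter together rather than by
case status.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .plink_io import MISSING, PairedGenotypeMatrix


@dataclass
class IbsMatrix:
    sample_ids: list[str]
    distances: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]


def _dosage(matrix: PairedGenotypeMatrix) -> np.ndarray:
    """a1 allele count per call: 0/1/2, with -1 for missing."""
    n, m = matrix.calls.shape
    out = np.full((n, m), -1, dtype=np.int8)
    for j, snp in enumerate(matrix.snps):
        col = matrix.calls[:, j]
        out[col == snp.a1, j] = 2
        out[col == snp.het_code, j] = 1
        out[col == snp.a2, j] = 0
    return out


def ibs_distance(matrix: PairedGenotypeMatrix, autosomes_only: bool = True) -> IbsMatrix:
    """1 - (shared alleles)/(2 x co-called SNPs) for every sample pair.

    Shared alleles per SNP are 2 - |dosage difference|, i.e. 2 for identical
    genotypes, 1 when the genotypes share one allele, 0 for opposite
    homozygotes. Only SNPs called in both samples contribute. Non-autosomal
    markers (chromosome codes 0 and >= 30) are excluded by default.
    """
    keep = [
        j
        for j, s in enumerate(matrix.snps)
        if not autosomes_only or 1 <= s.chrom <= 29
    ]
    dos = _dosage(matrix)[:, keep].astype(np.int16)
    n = dos.shape[0]
    dist = np.zeros((n, n))
    called = dos >= 0
    for i in range(n):
        both = called[i] & called  # (n, m)
        n_co = both.sum(axis=1)
        if np.any(n_co == 0):
            bad = np.nonzero(n_co == 0)[0]
            bad = bad[bad != i]
            if bad.size:
                raise ValueError(
                    f"sample pair with zero co-called SNPs: ({i}, {bad[0]})"
                )
        diff = np.abs(dos[i] - dos) * both
        dist[i] = diff.sum(axis=1) / (2.0 * np.maximum(n_co, 1))
    np.fill_diagonal(dist, 0.0)
    ids = [a.iid for a in matrix.animals]
    return IbsMatrix(sample_ids=ids, distances=dist)


def classical_mds(distances: IbsMatrix | np.ndarray, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double-center the squared distances,
    eigendecompose, and return the top-k coordinates scaled by sqrt of the
    eigenvalues. Requesting more dimensions than there are positive
    eigenvalues truncates with a warning. The sign of each axis is fixed so
    its largest-magnitude loading is positive.
    """
    d = distances.distances if isinstance(distances, IbsMatrix) else np.asarray(distances)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-9 * abs(vals[0]))
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k}")
        k = n_pos
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    for axis in range(k):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords
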