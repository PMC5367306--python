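"""Diploid genotype containers and per-locus diversity summaries.

Genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer array of
allele codes with ``-1`` marking a missing call. Missingness is
all-or-nothing per genotype: either both allele slots are observed or both
are ``-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["MISSING", "Locus", "GenotypeTable", "CallSet", "summary_stats"]


@dataclass(frozen=True)
class Locus:
    """A genotyped locus: ``kind`` is ``'microsat'`` or ``'snp'``."""

    id: str
    kind: str = "snp"

    def __post_init__(self) -> None:
        if self.kind not in ("microsat", "snp"):
            raise ValueError(f"unknown locus kind: {self.kind!r}")


@dataclass
class GenotypeTable:
    """Individuals x loci diploid allele calls with population labels."""

    individual_ids: list[str]
    pop_labels: list[str]
    loci: list[Locus]
    calls: np.ndarray  # (n_ind, n_loci, 2) int, MISSING = -1

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, m = len(self.individual_ids), len(self.loci)
        if len(self.pop_labels) != n:
            raise ValueError("pop_labels must match individual_ids in length")
        if self.calls.shape != (n, m, 2):
            raise ValueError(f"calls must have shape ({n}, {m}, 2), got {self.calls.shape}")
        half = (self.calls == MISSING).sum(axis=2)
        if np.any(half == 1):
            raise ValueError("half-missing genotypes are not allowed")
        if np.any(self.calls < MISSING):
            raise ValueError("allele codes must be non-negative (or the missing sentinel)")

    # -- basic views ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_ind, n_loci) array; True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING

    def pop_indices(self, pop: str) -> np.ndarray:
        idx = np.array([i for i, p in enumerate(self.pop_labels) if p == pop], dtype=int)
        if idx.size == 0:
            raise KeyError(f"unknown population: {pop!r}")
        return idx

    def subset(self, individuals=None, loci=None) -> "GenotypeTable":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals, dtype=int)
        loc = np.arange(self.n_loci) if loci is None else np.asarray(loci, dtype=int)
        return GenotypeTable(
            [self.individual_ids[i] for i in ind],
            [self.pop_labels[i] for i in ind],
            [self.loci[j] for j in loc],
            self.calls[np.ix_(ind, loc)],
        )

    def alleles_at(self, locus_index: int) -> np.ndarray:
        """Sorted distinct observed allele codes at a locus (missing excluded)."""
        a = self.calls[:, locus_index, :].ravel()
        return np.unique(a[a != MISSING])

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.pop_labels == other.pop_labels
            and [(l.id, l.kind) for l in self.loci] == [(l.id, l.kind) for l in other.loci]
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class CallSet:
    """A SNP call set carrying per-genotype stack depths and tag grouping.

    ``tag_ids[j]`` names the RAD tag that SNP ``j`` came from; several SNPs may
    share a tag. ``depths`` is 0 where the genotype is missing, >= 1 otherwise.
    """

    table: GenotypeTable
    depths: np.ndarray  # (n_ind, n_loci) int
    tag_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.shape != (self.table.n_individuals, self.table.n_loci):
            raise ValueError("depths shape must be (n_individuals, n_loci)")
        if len(self.tag_ids) != self.table.n_loci:
            raise ValueError("tag_ids must have one entry per SNP")
        miss = self.table.missing_mask()
        if np.any(self.depths[~miss] < 1):
            raise ValueError("called genotypes must have depth >= 1")
        if np.any(self.depths[miss] != 0):
            raise ValueError("missing genotypes must have depth 0")


def summary_stats(gt: GenotypeTable) -> pd.DataFrame:
    """Per-locus, per-population allele count, Ho and unbiased He.

    He uses the small-sample correction ``2n/(2n-1) * (1 - sum p_hat^2)`` on
    the ``n`` non-missing genotypes; Ho is the heterozygous fraction of those
    genotypes. Locus-population cells with no data are reported with n=0 and
    NaN statistics.
    """
    rows = []
    miss = gt.missing_mask()
    for j, locus in enumerate(gt.loci):
        for pop in gt.populations:
            idx = gt.pop_indices(pop)
            ok = idx[~miss[idx, j]]
            n = ok.size
            if n == 0:
                rows.append((locus.id, pop, 0, 0, np.nan, np.nan))
                continue
            pair = gt.calls[ok, j, :]
            alleles, counts = np.unique(pair.ravel(), return_counts=True)
            p_hat = counts / (2 * n)
            ho = float(np.mean(pair[:, 0] != pair[:, 1]))
            if alleles.size < 2:
                he = 0.0
                ho = 0.0
            else:
                he = (2 * n) / (2 * n - 1) * (1.0 - float(np.sum(p_hat**2)))
            rows.append((locus.id, pop, n, alleles.size, ho, he))
    return pd.DataFrame(rows, columns=["locus", "pop", "n", "n_alleles", "Ho", "He"])
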