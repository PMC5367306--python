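"""Locus-level population-genetic tests and the marker filtering rules.

Contents: the Markov-chain exact test of Hardy-Weinberg proportions
(Guo-Thompson switch chain, probability-test version), a genotypic G-test of
linkage disequilibrium with permutation significance, Storey's q-value FDR
correction, the microsatellite HWE-exclusion rule, and the RAD SNP call
filters (call-count whitelist, one SNP per tag, minimum stack depth).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_rng
from .genotypes import MISSING, CallSet, GenotypeTable
from .results import TestResult

__all__ = [
    "genotype_counts",
    "hwe_exact_mc",
    "ld_perm_test",
    "storey_q",
    "filter_microsat_loci",
    "FilterResult",
    "filter_snp_calls",
]


def genotype_counts(gt: GenotypeTable, locus_index: int, pop: str) -> dict[tuple[int, int], int]:
    """Observed genotype counts ``{(a, b): count}`` (a <= b) for one
    locus-population cell, missing genotypes excluded."""
    idx = gt.pop_indices(pop)
    pair = gt.calls[idx, locus_index, :]
    pair = pair[pair[:, 0] != MISSING]
    out: dict[tuple[int, int], int] = {}
    for a, b in np.sort(pair, axis=1):
        out[(int(a), int(b))] = out.get((int(a), int(b)), 0) + 1
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test, Markov-chain Monte Carlo


def _table_logprob(counts: dict[tuple[int, int], int]) -> float:
    """Log of the conditional table probability, up to a constant:
    H*ln2 - sum(lgamma(n_ij + 1))."""
    h = sum(c for (a, b), c in counts.items() if a != b)
    return h * math.log(2.0) - sum(math.lgamma(c + 1) for c in counts.values())


def hwe_exact_mc(
    counts: dict[tuple[int, int], int] | np.ndarray,
    dememorization: int = 10_000,
    batches: int = 1_000,
    iterations_per_batch: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Markov-chain estimate of the exact HWE probability-test p-value.

    The p-value is the probability, conditional on the allele counts, of
    genotype tables no more probable than the observed one. The chain swaps
    uniformly chosen gene copies between two individuals: the uniform
    distribution over gene-copy pairings induces exactly the conditional
    table probability ``n! prod(a_k!) 2^H / ((2n)! prod(n_ij!))``, so every
    swap is accepted and the visited tables follow the exact null law. The
    Monte-Carlo standard error comes from the between-batch variance of the
    per-batch indicator fractions.
    """
    if isinstance(counts, np.ndarray):
        arr = np.asarray(counts)
        counts = {
            (i, j): int(arr[i, j])
            for i in range(arr.shape[0])
            for j in range(i, arr.shape[1])
            if arr[i, j] > 0
        }
    counts = {tuple(sorted(k)): v for k, v in counts.items() if v > 0}
    if batches < 2 or iterations_per_batch < 1 or dememorization < 0:
        raise ValueError("invalid chain settings")
    n = sum(counts.values())
    if n < 1:
        raise ValueError("empty genotype table")
    meta = {
        "dememorization": dememorization,
        "batches": batches,
        "iterations_per_batch": iterations_per_batch,
    }
    alleles = sorted({a for pair in counts for a in pair})
    if len(alleles) < 2 or n < 2:
        # monomorphic locus or a single individual: one attainable table
        return TestResult(statistic=0.0, df=0, p=1.0, mc_se=0.0, meta=meta)

    # genotype list as two parallel allele arrays
    g = np.array([pair for pair, c in counts.items() for _ in range(c)], dtype=np.int64)
    cur = {k: v for k, v in counts.items()}
    log2 = math.log(2.0)
    l_obs = _table_logprob(cur)
    l_cur = l_obs
    rng = child_rng(seed, "hwe_mc")

    total_steps = dememorization + batches * iterations_per_batch
    ind1 = rng.integers(0, n, size=total_steps)
    ind2 = rng.integers(0, n - 1, size=total_steps)
    ind2 = np.where(ind2 >= ind1, ind2 + 1, ind2)  # distinct individuals
    slots = rng.integers(0, 2, size=(total_steps, 2))

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    batch_means = np.empty(batches)
    acc = 0.0
    count_in_batch = 0
    batch_idx = -1  # dememorization phase
    tol = 1e-9
    for step in range(total_steps):
        i1, i2 = int(ind1[step]), int(ind2[step])
        s1, s2 = int(slots[step, 0]), int(slots[step, 1])
        a, b = int(g[i1, s1]), int(g[i2, s2])
        if a != b:
            o1, o2 = int(g[i1, 1 - s1]), int(g[i2, 1 - s2])
            c1, c2 = key(a, o1), key(b, o2)
            c1n, c2n = key(b, o1), key(a, o2)
            dl = math.log(cur[c1])
            cur[c1] -= 1
            dl += math.log(cur[c2])
            cur[c2] -= 1
            cur[c1n] = cur.get(c1n, 0) + 1
            dl -= math.log(cur[c1n])
            cur[c2n] = cur.get(c2n, 0) + 1
            dl -= math.log(cur[c2n])
            dh = (c1n[0] != c1n[1]) + (c2n[0] != c2n[1]) - (c1[0] != c1[1]) - (c2[0] != c2[1])
            dl += dh * log2
            g[i1, s1], g[i2, s2] = b, a
            l_cur += dl
        if step >= dememorization:
            k = step - dememorization
            if k % iterations_per_batch == 0:
                if batch_idx >= 0:
                    batch_means[batch_idx] = acc / count_in_batch
                batch_idx += 1
                acc, count_in_batch = 0.0, 0
            acc += 1.0 if l_cur <= l_obs + tol else 0.0
            count_in_batch += 1
    batch_means[batch_idx] = acc / count_in_batch

    p = float(np.mean(batch_means))
    mc_se = float(np.std(batch_means, ddof=1) / math.sqrt(batches))
    return TestResult(statistic=l_obs, df=None, p=min(p, 1.0), mc_se=mc_se, meta=meta)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _genotype_codes(gt: GenotypeTable, locus: int, idx: np.ndarray) -> np.ndarray:
    """Canonical genotype labels (sorted allele pairs) for given individuals;
    -1 for missing."""
    pair = np.sort(gt.calls[idx, locus, :], axis=1)
    codes = pair[:, 0] * 10_000 + pair[:, 1]
    codes[pair[:, 0] == MISSING] = -1
    return codes


def _g_statistic(xcode: np.ndarray, ycode: np.ndarray, nx: int, ny: int) -> float:
    """G for factorized class codes (0..nx-1, 0..ny-1)."""
    tab = np.bincount(xcode * ny + ycode, minlength=nx * ny).reshape(nx, ny).astype(float)
    n = tab.sum()
    e = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    nz = tab > 0
    return 2.0 * float(np.sum(tab[nz] * np.log(tab[nz] / e[nz])))


def ld_perm_test(
    gt: GenotypeTable,
    locus_a: int,
    locus_b: int,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Genotypic G-test of linkage disequilibrium per population, with a
    Fisher-combined p-value across testable populations under ``"combined"``.

    The statistic is the log-likelihood ratio G of the genotype-by-genotype
    contingency table; significance comes from permuting one locus's
    genotypes across individuals within the population (add-one estimator).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = child_rng(seed, "ld_perm")
    results: dict[str, TestResult] = {}
    for pop in gt.populations:
        idx = gt.pop_indices(pop)
        xa = _genotype_codes(gt, locus_a, idx)
        xb = _genotype_codes(gt, locus_b, idx)
        ok = (xa >= 0) & (xb >= 0)
        ca, na = np.unique(xa[ok], return_inverse=True)[1], len(np.unique(xa[ok]))
        cb, nb = np.unique(xb[ok], return_inverse=True)[1], len(np.unique(xb[ok]))
        if na < 2 or nb < 2:
            results[pop] = TestResult(statistic=np.nan, p=np.nan, testable=False)
            continue
        g_obs = _g_statistic(ca, cb, na, nb)
        hits = 0
        for _ in range(n_perm):
            if _g_statistic(ca, rng.permutation(cb), na, nb) >= g_obs - 1e-12:
                hits += 1
        p = (1.0 + hits) / (n_perm + 1.0)
        results[pop] = TestResult(statistic=g_obs, p=p, meta={"n_perm": n_perm})

    ps = [r.p for r in results.values() if r.testable]
    if ps:
        chi2 = -2.0 * float(np.sum(np.log(ps)))
        df = 2 * len(ps)
        results["combined"] = TestResult(statistic=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))
    else:
        results["combined"] = TestResult(statistic=np.nan, p=np.nan, testable=False)
    return results


# ---------------------------------------------------------------------------
# Storey q-values


def storey_q(pvals, lam: float = 0.5, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    ``pi0 = min(1, mean(p > lam) / (1 - lam))``; on the sorted p-values
    ``q(i) = min_{j >= i} pi0 * m * p(j) / j``. Forcing ``pi0=1`` reduces the
    procedure exactly to Benjamini-Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 <= lam < 1.0):
        raise ValueError("lambda must lie in [0, 1)")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, float(np.mean(p > lam)) / (1.0 - lam))
        if pi0 <= 0.0:  # all p below lambda; fall back to the BH limit
            pi0 = 1.0 / m
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# filtering rules


def filter_microsat_loci(
    hwe_significant: pd.DataFrame, max_deviating_pops: int = 4
) -> tuple[list[str], pd.DataFrame]:
    """Exclude loci significant (post-FDR) in more than ``max_deviating_pops``
    populations.

    ``hwe_significant`` is a locus x population boolean table; untestable
    cells should be filled with False (they count as non-significant).
    Returns the kept locus list and a per-locus report with deviation counts.
    """
    sig = hwe_significant.fillna(False).astype(bool)
    n_dev = sig.sum(axis=1)
    excluded = n_dev > max_deviating_pops
    report = pd.DataFrame(
        {"n_deviating_pops": n_dev, "excluded": excluded}, index=sig.index
    )
    kept = [str(locus) for locus in sig.index[~excluded]]
    return kept, report


@dataclass
class FilterResult:
    """Outcome of the SNP call filters, with per-step survivor counts."""

    callset: CallSet
    report: dict = field(default_factory=dict)

    @property
    def table(self) -> GenotypeTable:
        return self.callset.table


def filter_snp_calls(
    callset: CallSet,
    min_individuals: int = 40,
    min_depth: int = 5,
    biallelic_only: bool = True,
) -> FilterResult:
    """Apply the RAD call filters and report survivors per step.

    Genotypes with stack depth below ``min_depth`` are set to missing; SNPs
    must then be biallelic and called in at least ``min_individuals``
    individuals; finally only the SNP called in the largest number of
    individuals is retained per tag (ties break to the first SNP). Applying
    the filter to its own output is a no-op.
    """
    gt = callset.table
    calls = gt.calls.copy()
    depths = callset.depths.copy()
    low = (depths > 0) & (depths < min_depth)
    calls[low] = MISSING
    depths[low] = 0
    n_masked = int(low.sum())

    called = calls[:, :, 0] != MISSING
    call_counts = called.sum(axis=0)
    keep = call_counts >= min_individuals
    if biallelic_only:
        for j in range(gt.n_loci):
            if not keep[j]:
                continue
            a = calls[:, j, :][called[:, j]]
            if np.unique(a).size != 2:
                keep[j] = False
    n_whitelist = int(keep.sum())

    best_per_tag: dict[str, int] = {}
    for j in np.nonzero(keep)[0]:
        tag = callset.tag_ids[j]
        if tag not in best_per_tag or call_counts[j] > call_counts[best_per_tag[tag]]:
            best_per_tag[tag] = int(j)
    chosen = sorted(best_per_tag.values())

    sub = gt.subset(loci=chosen)
    out = CallSet(
        GenotypeTable(sub.individual_ids, sub.pop_labels, sub.loci, calls[:, chosen]),
        depths[:, chosen],
        [callset.tag_ids[j] for j in chosen],
    )
    report = {
        "n_input_snps": gt.n_loci,
        "n_genotypes_depth_masked": n_masked,
        "n_after_whitelist": n_whitelist,
        "n_after_one_per_tag": len(chosen),
        "min_individuals": min_individuals,
        "min_depth": min_depth,
    }
    if gt.n_loci == 0:
        warnings.warn("empty call set: nothing to filter")
    return FilterResult(out, report)
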