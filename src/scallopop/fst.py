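"""Population differentiation: Weir-Cockerham theta, permutation tests,
distance-matrix association and genotype PCA.

The F_ST estimator is the Weir & Cockerham (1984) variance-components theta:
per locus and allele, the variance is split into among-population (a),
among-individuals-within-population (b) and within-individual (c) components,
and the multilocus estimate is the ratio of sums sum(a) / sum(a + b + c)
over loci and alleles. Missing genotypes are excluded pairwise per locus, so
per-locus sample sizes differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seeds import child_rng
from .genotypes import MISSING, GenotypeTable
from .popgen import storey_q
from .results import TestResult

__all__ = [
    "DistanceMatrix",
    "FstMatrix",
    "wc_theta",
    "pairwise_fst",
    "mantel_test",
    "GeneticPCA",
    "genetic_pca",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistanceMatrix:
    """A symmetric non-negative distance matrix with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.labels)
        if self.d.shape != (k, k):
            raise ValueError("matrix shape must match the label count")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < -1e-9):
            raise ValueError("distances must be non-negative")


@dataclass
class FstMatrix:
    """Pairwise theta with permutation p-values and table-wide q-values.

    ``testable`` marks pairs where both populations had at least two
    individuals; untestable entries carry NaN p and q.
    """

    labels: list[str]
    theta: np.ndarray
    p: np.ndarray
    q: np.ndarray
    testable: np.ndarray

    def to_distance(self) -> DistanceMatrix:
        """Theta as a genetic distance (negative estimates clipped to 0)."""
        d = np.clip(self.theta, 0.0, None)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(self.labels), (d + d.T) / 2.0)


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components


def _encode(gt: GenotypeTable, loci_subset=None):
    """Per-individual allele dosages and heterozygote indicators.

    Returns ``dosage`` (n, L, K), ``het`` (n, L, K), ``valid`` (n, L) where K
    is the maximum allele count over the included loci; unused allele slots
    stay zero and contribute nothing to the components.
    """
    loc = np.arange(gt.n_loci) if loci_subset is None else np.asarray(loci_subset)
    n = gt.n_individuals
    allele_maps = []
    for j in loc:
        allele_maps.append({int(a): i for i, a in enumerate(gt.alleles_at(int(j)))})
    K = max((len(m) for m in allele_maps), default=0)
    if K == 0:
        raise ValueError("no observed alleles")
    dosage = np.zeros((n, len(loc), K))
    het = np.zeros((n, len(loc), K))
    valid = np.zeros((n, len(loc)), dtype=bool)
    for jj, j in enumerate(loc):
        pair = gt.calls[:, int(j), :]
        ok = pair[:, 0] != MISSING
        valid[:, jj] = ok
        amap = allele_maps[jj]
        for i in np.nonzero(ok)[0]:
            a, b = int(pair[i, 0]), int(pair[i, 1])
            ia, ib = amap[a], amap[b]
            dosage[i, jj, ia] += 1
            dosage[i, jj, ib] += 1
            if ia != ib:
                het[i, jj, ia] = 1
                het[i, jj, ib] = 1
    return dosage, het, valid


def _wc_components(sum_d, sum_h, n_i):
    """Variance components from per-group sums.

    ``sum_d``/``sum_h``: (..., r, L, K) summed dosages and heterozygote
    indicators; ``n_i``: (..., r, L) genotyped individuals per group.
    Returns a, b, c of shape (..., L, K) plus a per-locus usability mask;
    loci with fewer than two genotyped individuals in any group are masked.
    """
    r = sum_d.shape[-3]
    usable = (n_i >= 2).all(axis=-2)  # (..., L)
    n_safe = np.maximum(n_i, 1e-12)
    nbar = n_i.mean(axis=-2)  # (..., L)
    nbar_safe = np.maximum(nbar, 1.0 + 1e-12)
    nc = (r * nbar - (n_i**2).sum(axis=-2) / np.maximum(r * nbar, 1e-12)) / (r - 1)
    nc_safe = np.maximum(nc, 1e-12)

    p_i = sum_d / (2.0 * n_safe[..., None])  # (..., r, L, K)
    pbar = sum_d.sum(axis=-3) / (2.0 * r * np.maximum(nbar, 1e-12))[..., None]
    s2 = (n_safe[..., None] * (p_i - pbar[..., None, :, :]) ** 2).sum(axis=-3) / (
        (r - 1) * np.maximum(nbar, 1e-12)[..., None]
    )
    hbar = sum_h.sum(axis=-3) / (r * np.maximum(nbar, 1e-12))[..., None]

    nbar_b = nbar_safe[..., None]
    inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
    a = nbar[..., None] / nc_safe[..., None] * (
        s2 - (inner - hbar / 4.0) / (nbar_b - 1.0)
    )
    b = nbar_b / (nbar_b - 1.0) * (inner - (2.0 * nbar[..., None] - 1.0) / (4.0 * nbar[..., None]) * hbar)
    c = hbar / 2.0
    mask = usable[..., None]
    return a * mask, b * mask, c * mask, usable


@dataclass
class ThetaResult:
    theta: float
    per_locus: np.ndarray
    loci_used: np.ndarray  # bool per included locus


def wc_theta(gt: GenotypeTable, populations_subset=None, loci_subset=None) -> ThetaResult:
    """Multilocus and per-locus Weir-Cockerham theta.

    Monomorphic loci contribute zero to every component and are reported as
    NaN per locus; the multilocus ratio of sums skips them automatically.
    """
    pops = populations_subset or gt.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    keep = [i for i, p in enumerate(gt.pop_labels) if p in set(pops)]
    sub = gt.subset(individuals=keep)
    dosage, het, valid = _encode(sub, loci_subset)
    onehot = np.array([[1.0 if lbl == p else 0.0 for lbl in sub.pop_labels] for p in pops])
    n_i = onehot @ valid  # (r, L)
    sum_d = np.einsum("rn,nlk->rlk", onehot, dosage * valid[:, :, None])
    sum_h = np.einsum("rn,nlk->rlk", onehot, het * valid[:, :, None])
    a, b, c, usable = _wc_components(sum_d, sum_h, n_i)
    denom_locus = (a + b + c).sum(axis=-1)
    num_locus = a.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(np.abs(denom_locus) > 1e-300, num_locus / denom_locus, np.nan)
    per_locus = np.where(usable, per_locus, np.nan)
    denom = denom_locus[usable].sum()
    theta = float(num_locus[usable].sum() / denom) if abs(denom) > 0 else float("nan")
    return ThetaResult(theta, per_locus, usable)


# ---------------------------------------------------------------------------
# pairwise F_ST with permutation significance


def _pair_theta_batch(dosage, het, valid, assign):
    """Theta for a batch of two-group assignments.

    ``assign``: (P, n) boolean, True = group A. Returns (P,) thetas.
    """
    n, L, K = dosage.shape
    X = np.concatenate(
        [
            (dosage * valid[:, :, None]).reshape(n, L * K),
            (het * valid[:, :, None]).reshape(n, L * K),
            valid.astype(float),
        ],
        axis=1,
    )
    totals = X.sum(axis=0)
    SA = assign.astype(float) @ X  # (P, D)
    SB = totals[None, :] - SA
    S = np.stack([SA, SB], axis=1)  # (P, 2, D)
    sum_d = S[:, :, : L * K].reshape(-1, 2, L, K)
    sum_h = S[:, :, L * K : 2 * L * K].reshape(-1, 2, L, K)
    n_i = S[:, :, 2 * L * K :].reshape(-1, 2, L)
    a, b, c, usable = _wc_components(sum_d, sum_h, n_i)
    m = usable[:, :, None]
    num = (a * m).sum(axis=(1, 2))
    den = ((a + b + c) * m).sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(np.abs(den) > 0, num / den, np.nan)


def pairwise_fst(gt: GenotypeTable, n_perm: int = 1000, seed: int = 0) -> FstMatrix:
    """Pairwise theta for every population pair with permutation p-values.

    Significance permutes whole individuals (both alleles together) between
    the two populations of the pair; ``p = (1 + #{theta_perm >= theta_obs})
    / (n_perm + 1)``, one-sided. q-values apply Storey FDR table-wide over
    all testable pairs.
    """
    pops = gt.populations
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    rng = child_rng(seed, "pairwise_fst")
    theta = np.zeros((r, r))
    p = np.full((r, r), np.nan)
    testable = np.zeros((r, r), dtype=bool)
    dosage_all, het_all, valid_all = _encode(gt)
    idx_by_pop = {pop: gt.pop_indices(pop) for pop in pops}

    pairs = [(i, j) for i in range(r) for j in range(i + 1, r)]
    for i, j in pairs:
        ia, ib = idx_by_pop[pops[i]], idx_by_pop[pops[j]]
        sel = np.concatenate([ia, ib])
        nA = ia.size
        dosage = dosage_all[sel]
        het = het_all[sel]
        valid = valid_all[sel]
        obs_assign = np.zeros((1, sel.size), dtype=bool)
        obs_assign[0, :nA] = True
        th = float(_pair_theta_batch(dosage, het, valid, obs_assign)[0])
        theta[i, j] = theta[j, i] = th
        if nA < 2 or ib.size < 2:
            continue
        u = rng.random((n_perm, sel.size))
        ranks = np.argsort(u, axis=1)
        assign = np.zeros((n_perm, sel.size), dtype=bool)
        np.put_along_axis(assign, ranks[:, :nA], True, axis=1)
        th_perm = _pair_theta_batch(dosage, het, valid, assign)
        th_perm = th_perm[np.isfinite(th_perm)]
        hits = int(np.sum(th_perm >= th - 1e-12))
        p[i, j] = p[j, i] = (1.0 + hits) / (len(th_perm) + 1.0)
        testable[i, j] = testable[j, i] = True

    q = np.full((r, r), np.nan)
    test_pairs = [(i, j) for i, j in pairs if testable[i, j]]
    if test_pairs:
        qvals = storey_q(np.array([p[i, j] for i, j in test_pairs]))
        for (i, j), qv in zip(test_pairs, qvals):
            q[i, j] = q[j, i] = qv
    return FstMatrix(pops, theta, p, q, testable)


# ---------------------------------------------------------------------------
# Mantel test


def mantel_test(
    d_gen: DistanceMatrix, d_geo: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> TestResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over the upper-triangle entries; the
    one-sided (greater) p-value permutes rows and columns of one matrix
    simultaneously, with the add-one estimator.
    """
    if d_gen.labels != d_geo.labels:
        raise ValueError("distance matrices must share labels and order")
    k = len(d_gen.labels)
    if k < 3:
        return TestResult(statistic=np.nan, p=np.nan, testable=False)
    iu = np.triu_indices(k, 1)
    x = d_gen.d[iu]
    y = d_geo.d[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return TestResult(statistic=np.nan, p=np.nan, testable=False)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = child_rng(seed, "mantel")
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(k)
        xp = d_gen.d[np.ix_(perm, perm)][iu]
        if np.corrcoef(xp, y)[0, 1] >= r_obs - 1e-12:
            hits += 1
    p = (1.0 + hits) / (n_perm + 1.0)
    return TestResult(statistic=r_obs, p=p, meta={"n_perm": n_perm})


# ---------------------------------------------------------------------------
# genotype PCA


@dataclass
class GeneticPCA:
    scores: np.ndarray  # (n, r)
    loadings: np.ndarray  # (p, r)
    variance_fractions: np.ndarray
    columns: list[str]


def genetic_pca(gt: GenotypeTable, missing: str = "mean_impute") -> GeneticPCA:
    """PCA of per-allele dosage vectors (0/1/2 counts per allele).

    Columns are mean-imputed over missing genotypes, then centered (not
    scaled); the decomposition uses singular values, retaining
    ``min(n - 1, p)`` components. Component signs follow the convention that
    the largest-magnitude loading is positive.
    """
    if gt.n_individuals < 2:
        raise ValueError("need at least two individuals")
    if missing != "mean_impute":
        raise ValueError("only mean_impute is supported for missing data")
    dosage, _, valid = _encode(gt)
    n = gt.n_individuals
    cols, names = [], []
    for j, locus in enumerate(gt.loci):
        alleles = gt.alleles_at(j)
        for ai, allele in enumerate(alleles):
            v = dosage[:, j, ai].copy()
            ok = valid[:, j]
            if not ok.any():
                warnings.warn(f"dropping all-missing column {locus.id}:{allele}")
                continue
            v[~ok] = v[ok].mean()
            cols.append(v)
            names.append(f"{locus.id}:{allele}")
    X = np.column_stack(cols)
    X = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    rank = min(n - 1, X.shape[1])
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    flip = np.sign(vt[np.arange(rank), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    loadings = (vt * flip[:, None]).T
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else np.zeros_like(var)
    return GeneticPCA(scores, loadings, fractions, names)
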