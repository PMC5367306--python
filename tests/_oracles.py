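"""Independent oracles used by the test suite.

Each function recomputes a quantity by a route different from the package
implementation it checks: complete enumeration, textbook mean-square ANOVA
formulas, closed forms, or a dense eigensolver.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def hwe_enum_biallelic(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE probability-test p by enumerating heterozygote counts of
    matching parity (Levene's conditional distribution)."""
    n = n_aa + n_ab + n_bb
    a = 2 * n_aa + n_ab
    states = []
    for h in range(a % 2, min(a, 2 * n - a) + 1, 2):
        aa = (a - h) // 2
        bb = n - aa - h
        if aa < 0 or bb < 0:
            continue
        lp = h * math.log(2.0) - math.lgamma(aa + 1) - math.lgamma(h + 1) - math.lgamma(bb + 1)
        states.append((h, lp))
    mx = max(lp for _, lp in states)
    total = sum(math.exp(lp - mx) for _, lp in states)
    obs = dict(states)[n_ab]
    return sum(math.exp(lp - mx) for h, lp in states if lp <= obs + 1e-12) / total


def hwe_enum_general(counts: dict[tuple[int, int], int]) -> float:
    """Exact HWE p for any allele number by enumerating all genotype tables
    with the observed allele counts (feasible only for tiny samples)."""
    alleles = sorted({a for pair in counts for a in pair})
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}
    allele_counts = np.zeros(k, dtype=int)
    n = 0
    for (a, b), c in counts.items():
        allele_counts[idx[a]] += c
        allele_counts[idx[b]] += c
        n += c
    cells = [(i, j) for i in range(k) for j in range(i, k)]

    def logprob(tab):
        h = sum(c for (i, j), c in zip(cells, tab) if i != j)
        return h * math.log(2.0) - sum(math.lgamma(c + 1) for c in tab)

    states = []

    def rec(pos, remaining_n, acount, tab):
        if pos == len(cells):
            if remaining_n == 0 and all(c == 0 for c in acount):
                states.append(logprob(tab))
            return
        i, j = cells[pos]
        need = 2 if i == j else 1
        cmax = remaining_n
        cmax = min(cmax, acount[i] // need if i == j else min(acount[i], acount[j]))
        for c in range(cmax + 1):
            ac = list(acount)
            ac[i] -= c * (2 if i == j else 1)
            if i != j:
                ac[j] -= c
            if min(ac) < 0:
                continue
            rec(pos + 1, remaining_n - c, ac, tab + [c])

    rec(0, n, list(allele_counts), [])
    obs_tab = [counts.get((alleles[i], alleles[j]), 0) for i, j in cells]
    obs_lp = logprob(obs_tab)
    mx = max(states)
    total = sum(math.exp(lp - mx) for lp in states)
    return sum(math.exp(lp - mx) for lp in states if lp <= obs_lp + 1e-12) / total


def wc_theta_anova(pops: list[np.ndarray]) -> float:
    """Weir-Cockerham theta via the three-level ANOVA mean squares.

    ``pops``: per population an (n_i, 2) array of allele codes. For each
    allele, MSP/MSI/MSG are formed from the 0/1 indicators of gene copies
    (individuals nested in populations, copies nested in individuals), and
    a = (MSP - MSI) / (2 nc), b = (MSI - MSG) / 2, c = MSG.
    """
    r = len(pops)
    n_i = np.array([len(p) for p in pops], dtype=float)
    n = n_i.sum()
    nc = (n - (n_i**2).sum() / n) / (r - 1)
    alleles = sorted({int(a) for p in pops for a in np.asarray(p).ravel()})
    num = den = 0.0
    for al in alleles:
        y = [np.asarray(p) == al for p in pops]  # (n_i, 2) booleans
        ybar_i = [yi.mean() for yi in y]
        ybar = sum(yi.sum() for yi in y) / (2 * n)
        msp = sum(2 * ni * (m - ybar) ** 2 for ni, m in zip(n_i, ybar_i)) / (r - 1)
        msi = sum(
            2 * ((yi.mean(axis=1) - m) ** 2).sum() for yi, m in zip(y, ybar_i)
        ) / (n - r)
        msg = sum(((yi - yi.mean(axis=1, keepdims=True)) ** 2).sum() for yi in y) / n
        a = (msp - msi) / (2 * nc)
        b = (msi - msg) / 2.0
        c = msg
        num += a
        den += a + b + c
    return num / den


def procrustes_two_shape_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Classical full ordinary Procrustes distance between two centered
    unit-size configurations (closed form via the singular values of B'A,
    rotation only)."""

    def norm(P):
        Q = P - P.mean(axis=0)
        return Q / np.sqrt((Q**2).sum())

    A, B = norm(A), norm(B)
    M = B.T @ A
    u, s, vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(u @ vt))
    trace = s[0] + d * s[1]
    return float(np.sqrt(max(0.0, 2.0 - 2.0 * trace)))


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values, written independently of storey_q."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def pca_eig_oracle(X: np.ndarray):
    """Eigen-decomposition of the sample covariance: returns eigenvalues
    (descending) and the scores' squared column norms for comparison with an
    SVD route."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc
    w, v = np.linalg.eigh(C)
    w = w[::-1]
    v = v[:, ::-1]
    scores = Xc @ v
    return w, scores


def tps_direct_solve(ref: np.ndarray, target: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Thin-plate spline mapping by an independently assembled linear system."""
    k = len(ref)

    def U(r2):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = r2 * np.log(r2)
        return np.where(r2 > 0, out, 0.0)

    d2 = ((ref[:, None] - ref[None, :]) ** 2).sum(-1)
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = U(d2)
    L[:k, k] = 1.0
    L[:k, k + 1 :] = ref
    L[k, :k] = 1.0
    L[k + 1 :, :k] = ref.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    sol = np.linalg.solve(L, rhs)
    q2 = ((query[:, None] - ref[None, :]) ** 2).sum(-1)
    return U(q2) @ sol[:k] + np.column_stack([np.ones(len(query)), query]) @ sol[k:]


def all_biallelic_tables(max_n: int):
    """All genotype count triples (nAA, nAB, nBB) with 1 <= n <= max_n,
    deduplicated under the allele-swap symmetry."""
    seen = set()
    out = []
    for n in range(1, max_n + 1):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                key = (min(n_aa, n_bb), n_ab, max(n_aa, n_bb))
                if key not in seen:
                    seen.add(key)
                    out.append((n_aa, n_ab, n_bb))
    return out
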