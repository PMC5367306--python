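"""Drift-divergence power analysis for marker panels.

Following the POWSIM design: subpopulations drift independently from common
base allele frequencies for t generations at effective size Ne (expected
divergence ``F_ST = 1 - (1 - 1/(2*Ne))**t``), samples of diploids are drawn
from each, and allele-frequency homogeneity across subpopulations is tested
per locus. The default test is the Pearson chi-square on the subpopulation x
allele count table, with statistics and degrees of freedom summed across
loci; a Monte-Carlo Fisher exact variant is available. Power is the fraction
of simulation replicates in which the panel-wide test rejects at level
alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_rng
from .simulate import BaseFrequencies, DriftScenario

__all__ = ["expected_fst", "PowerResult", "powsim_power", "power_table", "simulated_drift_fst"]


def expected_fst(Ne: int, t: int) -> float:
    """Analytic drift expectation ``1 - (1 - 1/(2*Ne))**t``."""
    if Ne < 1:
        raise ValueError("Ne must be at least 1")
    if t < 0:
        raise ValueError("t must be non-negative")
    return 1.0 - (1.0 - 1.0 / (2.0 * Ne)) ** t


@dataclass
class PowerResult:
    """Fraction of significant replicates plus its Monte-Carlo error."""

    power: float
    n_reps: int
    alpha: float
    mc_se: float
    expected_fst: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.power <= 1.0):
            raise ValueError("power must lie in [0, 1]")
        if self.mc_se < 0:
            raise ValueError("mc_se must be non-negative")


def _collapse_rare(table: np.ndarray) -> np.ndarray:
    """Merge allele classes whose pooled expected count falls below 1 into the
    adjacent class, protecting the chi-square approximation. Rows are
    subpopulations, columns allele classes (assumed size-ordered)."""
    tab = table.copy()
    while tab.shape[1] > 2:
        colsum = tab.sum(axis=0)
        rowsum = tab.sum(axis=1)
        n = tab.sum()
        expected_min = rowsum.min() * colsum / n
        j = int(np.argmin(expected_min))
        if expected_min[j] >= 1.0:
            break
        k = j - 1 if j > 0 else j + 1
        tab[:, k] += tab[:, j]
        tab = np.delete(tab, j, axis=1)
    return tab


def _chi2_one_table(tab: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square and df for one subpopulation x allele table; returns
    (0, 0) when the locus is monomorphic after collapsing."""
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        return 0.0, 0
    tab = _collapse_rare(tab)
    if tab.shape[1] < 2:
        return 0.0, 0
    n = tab.sum()
    e = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    stat = float(np.sum((tab - e) ** 2 / e))
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return stat, df


def _fisher_mc_p(tab: np.ndarray, rng, n_mc: int = 200) -> float:
    """Monte-Carlo Fisher exact p for an r x c table with fixed margins."""
    from scipy.special import gammaln

    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        return 1.0
    logp_obs = -gammaln(tab + 1).sum()
    sampler = stats.random_table(tab.sum(axis=1), tab.sum(axis=0))
    draws = sampler.rvs(n_mc, random_state=rng)
    logp = -gammaln(draws + 1).sum(axis=(1, 2))
    return (1.0 + np.sum(logp <= logp_obs + 1e-9)) / (n_mc + 1.0)


def powsim_power(
    base: BaseFrequencies,
    scen: DriftScenario,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    test: str = "chi2",
    fisher_mc: int = 200,
) -> PowerResult:
    """Estimate the power of a marker panel to detect drift divergence.

    Per replicate, every subpopulation drifts independently (Wright-Fisher
    multinomial resampling of 2*Ne gene copies per generation), 2*n diploid
    gene copies are sampled per subpopulation under HWE, and per-locus
    homogeneity statistics are combined across the panel (chi-square: summed
    statistics and df; fisher: Fisher's method over per-locus Monte-Carlo
    exact p-values). Loci fixed across all subpopulations in a replicate drop
    out of that replicate's combination.
    """
    if base.n_loci < 1:
        raise ValueError("base panel has no loci")
    if test not in ("chi2", "fisher"):
        raise ValueError("test must be 'chi2' or 'fisher'")
    rng = child_rng(seed, f"powsim-{scen.Ne}-{scen.t}")
    s, n_per = scen.n_subpops, scen.n_per_subpop

    stat_sum = np.zeros(n_reps)
    df_sum = np.zeros(n_reps, dtype=int)
    fisher_logs = np.zeros(n_reps)
    fisher_k = np.zeros(n_reps, dtype=int)
    theta_num = np.zeros(n_reps)
    theta_den = np.zeros(n_reps)

    snp_like = all(p.size == 2 for p in base.freqs)
    if snp_like and test == "chi2":
        # fully vectorized biallelic path: (n_reps, s, L) allele-1 frequencies
        p0 = np.array([p[1] for p in base.freqs])
        freqs = np.broadcast_to(p0, (n_reps, s, base.n_loci)).copy()
        for _ in range(scen.t):
            freqs = rng.binomial(2 * scen.Ne, freqs) / (2.0 * scen.Ne)
        c1 = rng.binomial(2 * n_per, freqs)  # sampled allele-1 counts
        tot = 2 * n_per
        col1 = c1.sum(axis=1)  # (n_reps, L)
        col0 = s * tot - col1
        # same guard as the multiallelic collapse rule: a biallelic locus whose
        # rarer allele has pooled expected count < 1 per subpopulation cannot
        # be collapsed further and drops out of the replicate's sum
        poly = (np.minimum(col1, col0) >= s)
        p_pool = col1 / (s * tot)
        e1 = tot * p_pool[:, None, :]
        e0 = tot - e1
        with np.errstate(invalid="ignore", divide="ignore"):
            cell = (c1 - e1) ** 2 / e1 + ((tot - c1) - e0) ** 2 / e0
        stat_l = np.where(poly[:, None, :], cell, 0.0).sum(axis=1)
        stat_sum = np.where(poly, stat_l, 0.0).sum(axis=1)
        df_sum = (poly * (s - 1)).sum(axis=1)
        # drift-level divergence bookkeeping (frequency variance ratio)
        pbar = freqs.mean(axis=1)
        var = freqs.var(axis=1, ddof=1)
        theta_num = var.sum(axis=1)
        theta_den = (pbar * (1 - pbar) + var / s).sum(axis=1)
    else:
        for p in base.freqs:
            k = p.size
            freqs = np.broadcast_to(p, (n_reps, s, k)).copy()
            for _ in range(scen.t):
                freqs = rng.multinomial(2 * scen.Ne, freqs) / (2.0 * scen.Ne)
            counts = rng.multinomial(2 * n_per, freqs)  # (n_reps, s, k)
            for r_i in range(n_reps):
                tab = counts[r_i]
                if test == "chi2":
                    st, df = _chi2_one_table(tab)
                    stat_sum[r_i] += st
                    df_sum[r_i] += df
                else:
                    if (tab.sum(axis=0) > 0).sum() >= 2:
                        fisher_logs[r_i] += np.log(_fisher_mc_p(tab, rng, fisher_mc))
                        fisher_k[r_i] += 1
            pbar = freqs.mean(axis=1)
            var = freqs.var(axis=1, ddof=1)
            theta_num += (var).sum(axis=1)
            theta_den += (pbar * (1 - pbar) + var / s).sum(axis=1)

    if test == "chi2":
        with np.errstate(invalid="ignore"):
            pvals = stats.chi2.sf(stat_sum, np.maximum(df_sum, 1))
        pvals = np.where(df_sum > 0, pvals, 1.0)
    else:
        stat = -2.0 * fisher_logs
        pvals = np.where(fisher_k > 0, stats.chi2.sf(stat, 2 * fisher_k), 1.0)

    power = float(np.mean(pvals <= alpha))
    mc_se = float(np.sqrt(power * (1.0 - power) / n_reps))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_reps = np.where(theta_den > 0, theta_num / theta_den, np.nan)
    return PowerResult(
        power,
        n_reps,
        alpha,
        mc_se,
        expected_fst(scen.Ne, scen.t),
        meta={
            "test": test,
            "mean_theta": float(np.nanmean(theta_reps)),
            "n_subpops": s,
            "n_per_subpop": n_per,
            # POWSIM's Fisher-exact chain settings, accepted for compatibility
            "burn_ins": 1000,
            "mc_batches": 100,
            "mc_iterations": 1000,
        },
    )


def power_table(
    panels: dict[str, BaseFrequencies],
    Ne_list,
    t_list,
    n_subpops: int = 9,
    n_per_subpop: dict[str, int] | int = 20,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Power over a (panel, t, Ne) grid as a tidy table."""
    rows = []
    for name, base in panels.items():
        n_per = n_per_subpop[name] if isinstance(n_per_subpop, dict) else n_per_subpop
        for t in t_list:
            for Ne in Ne_list:
                scen = DriftScenario(Ne=Ne, t=t, n_subpops=n_subpops, n_per_subpop=n_per, seed=seed)
                res = powsim_power(base, scen, n_reps=n_reps, alpha=alpha, seed=seed)
                rows.append((name, t, Ne, res.power, res.mc_se, res.expected_fst))
    return pd.DataFrame(rows, columns=["panel", "t", "Ne", "power", "mc_se", "expected_fst"])


def simulated_drift_fst(
    p0: float | np.ndarray,
    Ne: int,
    t: int,
    n_loci: int = 10_000,
    n_subpops: int = 9,
    seed: int = 0,
) -> float:
    """Mean standardized allele-frequency variance across replicate loci.

    Each locus drifts in ``n_subpops`` independent subpopulations; the
    statistic per locus is the unbiased across-subpopulation variance of the
    drifted frequency divided by ``p0 * (1 - p0)``. Its mean estimates the
    drift expectation ``1 - (1 - 1/(2*Ne))**t``.
    """
    rng = child_rng(seed, "drift_fst")
    p0 = np.broadcast_to(np.asarray(p0, dtype=float), (n_loci,))
    freqs = np.broadcast_to(p0, (n_subpops, n_loci)).copy()
    for _ in range(t):
        freqs = rng.binomial(2 * Ne, freqs) / (2.0 * Ne)
    var = freqs.var(axis=0, ddof=1)
    return float(np.mean(var / (p0 * (1.0 - p0))))
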