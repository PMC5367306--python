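"""End-to-end orchestration and the reference "plasticity scenario".

The plasticity scenario mirrors the study design this package is built
around: nine sampled populations of which eight are genetically
indistinguishable (identical base allele frequencies, no drift) while one
outlier population has diverged strongly by drift, yet shell shape and
pigmentation differ among all populations. Genetics should therefore flag
only the outlier, while morphometrics and colour analysis recover
population effects — the signature of phenotypically plastic traits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .assoc import run_association
from .colour import colour_index, oneway_anova
from .fst import DistanceMatrix, genetic_pca, mantel_test, pairwise_fst
from .genotypes import GenotypeTable, summary_stats
from .outlines import efa_coefficients, gpa_align, resample_equal
from .popgen import filter_snp_calls, hwe_exact_mc, genotype_counts, storey_q
from .power import power_table
from .shapestats import manova_wilks, retain_components, shape_pca
from .simulate import (
    BaseFrequencies,
    DriftScenario,
    PigmentModel,
    ShellShapeModel,
    default_shell_coeffs,
    drift_frequencies,
    make_colour_image,
    make_snp_callset,
    make_shell_population,
    microsat_panel,
    sample_genotypes,
    snp_panel,
)
from .outlines import EFACoefficients

__all__ = [
    "PipelineConfig",
    "read_accounting",
    "scenario_genotypes",
    "scenario_shells",
    "scenario_colours",
    "run_pipeline",
]


def read_accounting(
    total_reads: int, retained_reads: int, removed_reads: int, duplicate_reads: int
) -> dict[str, float]:
    """Read-retention arithmetic of a sequencing run.

    Returns the percentage of raw reads surviving quality/length filtering,
    the percentages of the retained reads removed overall and flagged as PCR
    duplicates, and the read count remaining for assembly.
    """
    if not (0 < retained_reads <= total_reads):
        raise ValueError("retained_reads must be positive and at most total_reads")
    if not (0 <= duplicate_reads <= removed_reads <= retained_reads):
        raise ValueError("need 0 <= duplicates <= removed <= retained")
    return {
        "pct_retained": 100.0 * retained_reads / total_reads,
        "pct_removed_of_retained": 100.0 * removed_reads / retained_reads,
        "pct_duplicates_of_retained": 100.0 * duplicate_reads / retained_reads,
        "reads_remaining": float(retained_reads - removed_reads),
    }


# ---------------------------------------------------------------------------
# plasticity scenario generators


def scenario_genotypes(
    seed: int = 0,
    n_pops: int = 9,
    n_per_pop: int = 20,
    n_loci: int = 500,
    outlier_index: int = 0,
    outlier_Ne: int = 100,
    outlier_t: int = 200,
) -> GenotypeTable:
    """SNP genotypes: no divergence except one drift-diverged outlier
    population (default expected F_ST against the others is about 0.63)."""
    base = snp_panel(n_loci, seed=child_seed(seed, "scenario_base"))
    drifted = drift_frequencies(
        base,
        DriftScenario(
            Ne=outlier_Ne, t=outlier_t, n_subpops=2, n_per_subpop=n_per_pop,
            seed=child_seed(seed, "scenario_outlier"),
        ),
    )
    subpop_freqs = []
    for p, d in zip(base.freqs, drifted):
        rows = np.tile(p, (n_pops, 1))
        rows[outlier_index] = d[0]
        subpop_freqs.append(rows)
    return sample_genotypes(
        subpop_freqs,
        n_per_pop,
        seed=child_seed(seed, "scenario_sample"),
        kinds=["snp"] * n_loci,
        pop_names=[f"pop{i + 1}" for i in range(n_pops)],
    )


def scenario_shell_model(
    n_pops: int = 9, n_harmonics: int = 15, coeff_sd: float = 0.01, effect: float = 1.0
) -> ShellShapeModel:
    """Population mean shapes differing in hinge-related low harmonics.

    The between-population spread is about twice the within-population
    coefficient noise at ``effect=1``, echoing the strong shape separation
    the scenario is meant to display."""
    means = {}
    for i in range(n_pops):
        h = default_shell_coeffs(n_harmonics).harmonics.copy()
        h[1, 3] += effect * 0.020 * (i - (n_pops - 1) / 2) / max(n_pops // 2, 1)
        h[2, 0] += effect * 0.015 * ((i % 3) - 1)
        means[f"pop{i + 1}"] = EFACoefficients(h)
    return ShellShapeModel(means, coeff_sd=coeff_sd, n_harmonics=n_harmonics)


def scenario_shells(seed: int = 0, n_pops: int = 9, n_per_pop: int = 20, **model_kw):
    model = scenario_shell_model(n_pops, **model_kw)
    return make_shell_population(model, n_per_pop, seed=child_seed(seed, "scenario_shells"))


def scenario_colours(
    seed: int = 0,
    n_pops: int = 9,
    n_per_pop: int = 20,
    image_size: tuple[int, int] = (48, 64),
) -> pd.DataFrame:
    """Per-shell colour indices with population-specific pigmentation.

    Pigment extent rises across populations (0.15 to 0.55) with the mean
    pigment grey drifting from 70 to 95; individuals jitter around their
    population's targets."""
    rng = np.random.default_rng(child_seed(seed, "scenario_colours"))
    rows = []
    for i in range(n_pops):
        extent0 = 0.15 + 0.40 * i / max(n_pops - 1, 1)
        grey0 = 70.0 + 25.0 * i / max(n_pops - 1, 1)
        for k in range(n_per_pop):
            extent = float(np.clip(extent0 + rng.normal(0, 0.04), 0.02, 0.95))
            grey = float(np.clip(grey0 + rng.normal(0, 4.0), 5.0, 105.0))
            model = PigmentModel(grey, extent, image_size)
            img, mask = make_colour_image(model, seed=int(rng.integers(2**31)))
            res = colour_index(img, mask)
            rows.append((f"pop{i + 1}", f"pop{i + 1}_{k + 1:03d}", res.mean_pigment_grey,
                         res.pigment_fraction, res.colour_index))
    return pd.DataFrame(
        rows, columns=["pop", "individual", "mean_pigment_grey", "pigment_fraction", "colour_index"]
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """All stage parameters with defaults matching the reference analysis
    (1000 permutations, 15 harmonics at the 0.98 power threshold, the 0-110
    colour window, call-count/depth filters of 40/5, 500 power replicates at
    alpha 0.05). The HWE chain settings are pipeline-scale defaults; the
    ``hwe_exact_mc`` function itself defaults to the full-length chain."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    # scenario sizes
    n_pops: int = 9
    n_snp_loci: int = 500
    n_per_pop_snp: int = 5
    n_shells_per_pop: int = 20
    # stage parameters
    missing_rate: float = 0.08
    snps_per_tag: int = 2
    min_individuals: int = 40
    min_depth: int = 5
    n_perm: int = 1000
    n_landmarks: int = 200
    n_harmonics: int = 15
    harmonic_threshold: float = 0.98
    pca_threshold: float = 0.95
    colour_threshold: int = 110
    power_reps: int = 500
    alpha: float = 0.05
    hwe_loci: int = 12
    hwe_dememorization: int = 1000
    hwe_batches: int = 50
    hwe_iterations: int = 200
    # stage toggles
    run_power: bool = True
    run_morpho: bool = True
    run_colour: bool = True
    run_assoc: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineReport:
    config: PipelineConfig
    results: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _write(df: pd.DataFrame, out: Path, name: str, outputs: dict) -> None:
    path = out / name
    df.to_csv(path, index=False)
    outputs[name] = str(path)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the plasticity scenario end to end, writing CSV outputs, the
    resolved configuration and a seed log beside them."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(cfg)
    results, outputs = report.results, report.outputs
    log: list[str] = [f"master seed: {cfg.seed}"]

    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=2, sort_keys=True)
    outputs["config.json"] = str(out / "config.json")

    # --- genotypes, filtering -----------------------------------------
    gt_raw = scenario_genotypes(
        cfg.seed, cfg.n_pops, cfg.n_per_pop_snp, cfg.n_snp_loci
    )
    log.append(f"scenario_genotypes child seed: {child_seed(cfg.seed, 'scenario_sample')}")
    callset = make_snp_callset(
        gt_raw, missing_rate=cfg.missing_rate, snps_per_tag=cfg.snps_per_tag,
        seed=child_seed(cfg.seed, "callset"),
    )
    filt = filter_snp_calls(callset, cfg.min_individuals, cfg.min_depth)
    gt = filt.table
    results["filter_report"] = filt.report
    log.append(f"filters: {filt.report}")

    # --- summary statistics and HWE -----------------------------------
    summ = summary_stats(gt)
    _write(summ, out, "summary_stats.csv", outputs)
    hwe_rows = []
    for j in range(min(cfg.hwe_loci, gt.n_loci)):
        for pop in gt.populations:
            counts = genotype_counts(gt, j, pop)
            if not counts:
                continue
            res = hwe_exact_mc(
                counts, cfg.hwe_dememorization, cfg.hwe_batches, cfg.hwe_iterations,
                seed=child_seed(cfg.seed, f"hwe-{j}-{pop}"),
            )
            hwe_rows.append((gt.loci[j].id, pop, res.p, res.mc_se))
    hwe = pd.DataFrame(hwe_rows, columns=["locus", "pop", "p", "mc_se"])
    if len(hwe):
        hwe["q"] = storey_q(hwe["p"].to_numpy())
    _write(hwe, out, "hwe.csv", outputs)

    # --- population structure -----------------------------------------
    fst = pairwise_fst(gt, n_perm=cfg.n_perm, seed=child_seed(cfg.seed, "fst"))
    results["fst"] = fst
    fst_df = pd.DataFrame(fst.theta, index=fst.labels, columns=fst.labels)
    fst_df.to_csv(out / "fst_theta.csv")
    outputs["fst_theta.csv"] = str(out / "fst_theta.csv")
    pq = pd.DataFrame(
        [
            (fst.labels[i], fst.labels[j], fst.theta[i, j], fst.p[i, j], fst.q[i, j])
            for i in range(len(fst.labels))
            for j in range(i + 1, len(fst.labels))
        ],
        columns=["pop_a", "pop_b", "theta", "p", "q"],
    )
    _write(pq, out, "fst_pairs.csv", outputs)

    pca = genetic_pca(gt)
    results["genetic_pca"] = pca
    scores = pd.DataFrame(
        pca.scores[:, :5], columns=[f"PC{i + 1}" for i in range(min(5, pca.scores.shape[1]))]
    )
    scores.insert(0, "individual", gt.individual_ids)
    scores.insert(1, "pop", gt.pop_labels)
    _write(scores, out, "genetic_pca_scores.csv", outputs)

    # isolation by distance against a linear-coastline geography
    pops = gt.populations
    coast = np.abs(np.subtract.outer(np.arange(len(pops)), np.arange(len(pops)))) * 10.0
    mant = mantel_test(
        fst.to_distance(), DistanceMatrix(pops, coast), n_perm=999,
        seed=child_seed(cfg.seed, "mantel"),
    )
    results["mantel"] = mant

    # --- power grid ----------------------------------------------------
    if cfg.run_power:
        panels = {
            "microsat": microsat_panel(13, seed=child_seed(cfg.seed, "panel_ms")),
            "snp": snp_panel(min(cfg.n_snp_loci, 2000), seed=child_seed(cfg.seed, "panel_snp")),
        }
        tab = power_table(
            panels, Ne_list=[1000, 2000, 3000], t_list=[10, 20], n_subpops=cfg.n_pops,
            n_per_subpop={"microsat": 20, "snp": 5}, n_reps=cfg.power_reps,
            alpha=cfg.alpha, seed=child_seed(cfg.seed, "power"),
        )
        results["power_table"] = tab
        _write(tab, out, "power_table.csv", outputs)

    # --- morphometrics --------------------------------------------------
    if cfg.run_morpho:
        shells = scenario_shells(cfg.seed, cfg.n_pops, cfg.n_shells_per_pop)
        configs, pops_of = [], []
        for pop, outlines in shells.outlines.items():
            for o in outlines:
                configs.append(resample_equal(o, cfg.n_landmarks))
                pops_of.append(pop)
        aligned, _mean = gpa_align(configs)
        coeff_rows = [
            efa_coefficients(c, cfg.n_harmonics).harmonics.ravel() for c in aligned
        ]
        coeff_mat = np.array(coeff_rows)
        spca = shape_pca(coeff_mat)
        k_keep = retain_components(spca.variance_fractions, cfg.pca_threshold)
        man = manova_wilks(spca.scores[:, :k_keep], pops_of)
        results["shape_manova"] = man
        results["shape_pca"] = spca
        results["shape_groups"] = pops_of
        shape_scores = pd.DataFrame(
            spca.scores[:, : min(5, spca.scores.shape[1])],
            columns=[f"shapePC{i + 1}" for i in range(min(5, spca.scores.shape[1]))],
        )
        shape_scores.insert(0, "pop", pops_of)
        _write(shape_scores, out, "shape_pca_scores.csv", outputs)
        log.append(
            f"morpho: kept {k_keep} PCs, Wilks lambda {man.statistic:.4f}, p {man.p:.2e}"
        )

    # --- colour ----------------------------------------------------------
    if cfg.run_colour:
        col = scenario_colours(cfg.seed, cfg.n_pops, cfg.n_shells_per_pop)
        anova = oneway_anova(col["colour_index"], col["pop"])
        results["colour_anova"] = anova
        results["colour_table"] = col
        _write(col, out, "colour_index.csv", outputs)
        by_pop = col.groupby("pop")["colour_index"].agg(["mean", "sem"]).reset_index()
        _write(by_pop, out, "colour_by_pop.csv", outputs)

    # --- association -----------------------------------------------------
    if cfg.run_assoc and cfg.run_colour:
        # phenotype per genotyped individual: population-level colour means
        # plus individual noise stand in when shells and genotypes are from
        # different sampled individuals
        col = results["colour_table"]
        pop_means = col.groupby("pop")["colour_index"].mean()
        rng = np.random.default_rng(child_seed(cfg.seed, "assoc_pheno"))
        pheno = np.array(
            [pop_means[p] + rng.normal(0, col["colour_index"].std() * 0.5) for p in gt.pop_labels]
        )
        assoc = run_association(
            pheno, pca.scores[:, :2], gt.pop_labels, exclude=[pops[0]]
        )
        results["association"] = assoc

    with open(out / "pipeline.log", "w") as fh:
        fh.write("\n".join(log) + "\n")
    outputs["pipeline.log"] = str(out / "pipeline.log")
    return report
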