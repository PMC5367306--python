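"""Synthetic data generators.

Everything downstream of field sampling — genotype panels diverged by drift,
RAD-style SNP call sets with stack depths, shell outlines and pigmentation
images — can be generated here with known statistical structure, so the whole
analysis is testable without any external data.

The drift model is Wright-Fisher: per generation, the allele counts of each
subpopulation are resampled multinomially from 2*Ne gene copies. After t
generations the expected standardized allele-frequency variance (F_ST) is
``1 - (1 - 1/(2*Ne))**t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon as _fill_polygon

from ._seeds import child_rng
from .genotypes import MISSING, CallSet, GenotypeTable, Locus
from .outlines import EFACoefficients, OutlineShape, inverse_efa

__all__ = [
    "BaseFrequencies",
    "DriftScenario",
    "ShellShapeModel",
    "PigmentModel",
    "ShellPopulationSample",
    "microsat_panel",
    "snp_panel",
    "drift_frequencies",
    "sample_genotypes",
    "make_snp_callset",
    "make_shell_population",
    "rasterize_outline",
    "make_colour_image",
]


# ---------------------------------------------------------------------------
# base allele frequencies


@dataclass
class BaseFrequencies:
    """Base (ancestral) allele frequencies of a marker panel.

    ``freqs`` holds one probability vector per locus; SNP loci are biallelic,
    microsatellite loci have two or more alleles.
    """

    freqs: list[np.ndarray]
    kinds: list[str]

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.kinds):
            raise ValueError("freqs and kinds must have equal length")
        clean = []
        for p, kind in zip(self.freqs, self.kinds):
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError("each frequency vector must be non-negative and sum to 1")
            if kind == "snp" and p.size != 2:
                raise ValueError("snp loci must have exactly 2 alleles")
            if kind == "microsat" and p.size < 2:
                raise ValueError("microsat loci need at least 2 alleles")
            if kind not in ("snp", "microsat"):
                raise ValueError(f"unknown locus kind {kind!r}")
            clean.append(p)
        self.freqs = clean

    @property
    def n_loci(self) -> int:
        return len(self.freqs)

    def loci(self) -> list[Locus]:
        return [Locus(f"L{i:04d}", k) for i, k in enumerate(self.kinds)]


def microsat_panel(n_loci: int = 13, seed: int = 0, mean_alleles: int = 11) -> BaseFrequencies:
    """A microsatellite-like panel: symmetric Dirichlet(1) frequencies over k
    alleles, k uniform on a range centred so the panel averages ``mean_alleles``
    alleles per locus (matching a typically polymorphic marker set)."""
    rng = child_rng(seed, "microsat_panel")
    ks = rng.integers(mean_alleles - 3, mean_alleles + 4, size=n_loci)
    freqs = [rng.dirichlet(np.ones(k)) for k in ks]
    return BaseFrequencies(freqs, ["microsat"] * n_loci)


def snp_panel(n_loci: int = 2000, seed: int = 0, maf_range=(0.05, 0.5)) -> BaseFrequencies:
    """A SNP panel with minor-allele frequencies uniform on ``maf_range``."""
    rng = child_rng(seed, "snp_panel")
    maf = rng.uniform(*maf_range, size=n_loci)
    freqs = [np.array([1.0 - m, m]) for m in maf]
    return BaseFrequencies(freqs, ["snp"] * n_loci)


# ---------------------------------------------------------------------------
# drift and genotype sampling


@dataclass
class DriftScenario:
    """Divergence-by-drift design: ``n_subpops`` subpopulations of effective
    size ``Ne`` drift independently for ``t`` generations from common base
    frequencies; ``n_per_subpop`` diploids are then sampled from each."""

    Ne: int
    t: int
    n_subpops: int = 9
    n_per_subpop: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError("Ne must be at least 1")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if self.n_subpops < 2:
            raise ValueError("need at least 2 subpopulations")
        if self.n_per_subpop < 1:
            raise ValueError("need at least 1 sampled individual per subpopulation")


def _drift_one_locus(p: np.ndarray, Ne: int, t: int, n_subpops: int, rng) -> np.ndarray:
    """Wright-Fisher drift of one locus; returns (n_subpops, k) frequencies."""
    freqs = np.tile(p, (n_subpops, 1))
    for _ in range(t):
        counts = rng.multinomial(2 * Ne, freqs)
        freqs = counts / (2.0 * Ne)
    return freqs


def drift_frequencies(base: BaseFrequencies, scen: DriftScenario) -> list[np.ndarray]:
    """Per-locus (n_subpops, k) allele frequencies after ``t`` generations."""
    rng = child_rng(scen.seed, "drift")
    return [
        _drift_one_locus(p, scen.Ne, scen.t, scen.n_subpops, rng) for p in base.freqs
    ]


def sample_genotypes(
    subpop_freqs: list[np.ndarray],
    n_per_subpop: int,
    seed: int = 0,
    kinds: list[str] | None = None,
    pop_names: list[str] | None = None,
) -> GenotypeTable:
    """Sample diploid genotypes under within-subpopulation HWE.

    ``subpop_freqs`` is one (n_subpops, k) frequency array per locus, as
    returned by :func:`drift_frequencies`. Each genotype is two independent
    allele draws; there is no missing data.
    """
    if not subpop_freqs:
        raise ValueError("no loci supplied")
    if n_per_subpop < 1:
        raise ValueError("n_per_subpop must be at least 1")
    rng = child_rng(seed, "sample_genotypes")
    n_subpops = subpop_freqs[0].shape[0]
    n_loci = len(subpop_freqs)
    kinds = kinds or ["snp" if f.shape[1] == 2 else "microsat" for f in subpop_freqs]
    pop_names = pop_names or [f"pop{i + 1}" for i in range(n_subpops)]

    calls = np.empty((n_subpops * n_per_subpop, n_loci, 2), dtype=np.int64)
    for j, freqs in enumerate(subpop_freqs):
        if freqs.shape[0] != n_subpops:
            raise ValueError("inconsistent subpopulation count across loci")
        k = freqs.shape[1]
        for s in range(n_subpops):
            draw = rng.choice(k, size=(n_per_subpop, 2), p=freqs[s])
            calls[s * n_per_subpop : (s + 1) * n_per_subpop, j, :] = draw

    ids = [f"{pop_names[s]}_{i + 1:03d}" for s in range(n_subpops) for i in range(n_per_subpop)]
    labels = [pop_names[s] for s in range(n_subpops) for _ in range(n_per_subpop)]
    loci = [Locus(f"L{j:04d}", kinds[j]) for j in range(n_loci)]
    return GenotypeTable(ids, labels, loci, calls)


# ---------------------------------------------------------------------------
# RAD-style call sets


def make_snp_callset(
    gt: GenotypeTable,
    missing_rate: float = 0.0,
    depth_sampler=None,
    snps_per_tag: int = 1,
    seed: int = 0,
) -> CallSet:
    """Attach stack depths, missingness and tag grouping to a genotype table.

    ``depth_sampler`` maps ``(rng, size)`` to integer depths >= 1; the default
    is 1 + Poisson(19) (mean stack depth 20). Consecutive SNPs are grouped
    into tags of ``snps_per_tag``.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    if snps_per_tag < 1:
        raise ValueError("snps_per_tag must be at least 1")
    rng = child_rng(seed, "callset")
    n, m = gt.n_individuals, gt.n_loci
    if depth_sampler is None:
        depth_sampler = lambda r, size: 1 + r.poisson(19, size=size)
    depths = np.asarray(depth_sampler(rng, (n, m)), dtype=np.int64)
    if np.any(depths < 1):
        raise ValueError("depth sampler produced depths below 1")
    calls = gt.calls.copy()
    miss = rng.random((n, m)) < missing_rate
    calls[miss] = MISSING
    depths[miss] = 0
    tag_ids = [f"tag{j // snps_per_tag:05d}" for j in range(m)]
    table = GenotypeTable(list(gt.individual_ids), list(gt.pop_labels), list(gt.loci), calls)
    return CallSet(table, depths, tag_ids)


# ---------------------------------------------------------------------------
# shell shapes


def default_shell_coeffs(n_harmonics: int = 15) -> EFACoefficients:
    """A scallop-like base outline: a slightly squashed ellipse with a
    flattened hinge edge supplied by small higher harmonics."""
    h = np.zeros((n_harmonics, 4))
    h[0] = (1.0, 0.0, 0.0, 0.85)  # main ellipse
    if n_harmonics >= 2:
        h[1] = (0.02, 0.0, 0.0, 0.06)
    if n_harmonics >= 3:
        h[2] = (-0.05, 0.01, 0.0, 0.02)
    if n_harmonics >= 4:
        h[3] = (0.0, 0.0, 0.01, -0.01)
    return EFACoefficients(h)


@dataclass
class ShellShapeModel:
    """Population-specific elliptic-Fourier mean shapes plus Gaussian
    per-coefficient individual noise of scale ``coeff_sd``."""

    pop_mean_coeffs: dict[str, EFACoefficients]
    coeff_sd: float = 0.0
    n_harmonics: int = 15

    def __post_init__(self) -> None:
        if self.coeff_sd < 0:
            raise ValueError("coeff_sd must be non-negative")
        for pop, c in self.pop_mean_coeffs.items():
            if c.n_harmonics != self.n_harmonics:
                raise ValueError(f"population {pop!r} has a mismatched harmonic count")


@dataclass
class ShellPopulationSample:
    outlines: dict[str, list[OutlineShape]]
    coeffs: dict[str, np.ndarray]  # pop -> (n, n_harmonics, 4)
    model: ShellShapeModel = field(repr=False, default=None)


def make_shell_population(
    model: ShellShapeModel, n_per_pop: int, seed: int = 0, n_points: int = 300
) -> ShellPopulationSample:
    """Draw per-individual coefficient sets and reconstruct their outlines."""
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be at least 1")
    rng = child_rng(seed, "shells")
    outlines: dict[str, list[OutlineShape]] = {}
    coeffs: dict[str, np.ndarray] = {}
    for pop, mean in model.pop_mean_coeffs.items():
        draws = mean.harmonics[None, :, :] + model.coeff_sd * rng.standard_normal(
            (n_per_pop, model.n_harmonics, 4)
        )
        coeffs[pop] = draws
        outlines[pop] = [
            inverse_efa(EFACoefficients(d, mean.a0, mean.c0), n_points) for d in draws
        ]
    return ShellPopulationSample(outlines, coeffs, model)


def rasterize_outline(
    outline: OutlineShape, image_size: tuple[int, int] = (512, 512), margin: int = 8
) -> np.ndarray:
    """Rasterize an outline to a binary mask (even-odd polygon fill, no
    anti-aliasing), scaled to fit the image with the given pixel margin."""
    h, w = image_size
    pts = outline.points
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    scale = min((w - 1 - 2 * margin) / max(span[0], 1e-12), (h - 1 - 2 * margin) / max(span[1], 1e-12))
    xy = (pts - lo) * scale + margin
    rr, cc = _fill_polygon(xy[:, 1], xy[:, 0], shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# pigmentation images


@dataclass
class PigmentModel:
    """Target pigmentation of a synthetic shell image: mean grey of pigmented
    pixels (on the 0-110 pigment window) and the pigmented fraction of the
    shell area."""

    mean_pigment_grey: float = 80.0
    extent: float = 0.3
    image_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_pigment_grey <= 110.0):
            raise ValueError("mean_pigment_grey must lie in [0, 110]")
        if not (0.0 <= self.extent <= 1.0):
            raise ValueError("extent must lie in [0, 1]")


def make_colour_image(model: PigmentModel, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """A grey image (0-255) plus boolean shell mask with the model's targets.

    The shell is an inscribed ellipse. A spatially coherent pigment patch
    (grown from a random focal point) covers ``round(extent * shell_area)``
    pixels; pigment greys are drawn symmetrically around the target mean
    within the 0-110 window, unpigmented shell is light (150-230) and the
    background is white.
    """
    rng = child_rng(seed, "colour_image")
    h, w = model.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = h * 0.42, w * 0.42
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    n_shell = int(mask.sum())
    if n_shell == 0:
        raise ValueError("image too small to contain a shell")

    grey = np.full((h, w), 255, dtype=np.int64)
    light = rng.integers(150, 231, size=n_shell)
    grey[mask] = light

    m_pig = int(round(model.extent * n_shell))
    if m_pig > 0:
        sy, sx = np.nonzero(mask)
        focal = rng.integers(0, n_shell)
        dist = np.hypot(sy - sy[focal], sx - sx[focal]) + rng.normal(0, 0.8, size=n_shell)
        order = np.argsort(dist)[:m_pig]
        half = min(model.mean_pigment_grey, 110.0 - model.mean_pigment_grey, 18.0)
        vals = np.rint(
            rng.uniform(model.mean_pigment_grey - half, model.mean_pigment_grey + half, size=m_pig)
        ).astype(np.int64)
        grey[sy[order], sx[order]] = np.clip(vals, 0, 110)
    return grey, mask
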