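"""Shell pigmentation quantification.

Inner-shell brown pigmentation is summarized by a scalar colour index:
``sqrt(mean pigment grey x pigmented fraction of the shell area)``, where
pigmented pixels are those with grey value in the 0-110 window. The raw mean
grey enters the formula as printed (darker pigment therefore lowers the
intensity term); an inverted mode (110 - mean grey) is available for users
who want high values to track visually darker pigment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .results import TestResult

__all__ = ["ColourResult", "rgb_to_grey", "colour_index", "oneway_anova"]


@dataclass
class ColourResult:
    mean_pigment_grey: float | None  # None when no pixel is pigmented
    pigment_fraction: float
    colour_index: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pigment_fraction <= 1.0):
            raise ValueError("pigment_fraction must lie in [0, 1]")
        if self.colour_index < 0:
            raise ValueError("colour_index must be non-negative")


def rgb_to_grey(rgb: np.ndarray) -> np.ndarray:
    """Grey conversion by the per-pixel channel mean (R + G + B) / 3,
    rounded half-up to an integer in 0-255."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    mean = rgb.astype(float).sum(axis=2) / 3.0
    return np.floor(mean + 0.5).astype(np.int64)


def colour_index(
    grey: np.ndarray,
    mask: np.ndarray,
    threshold: int = 110,
    inclusive: bool = True,
    inverted: bool = False,
) -> ColourResult:
    """Colour index of a masked grey image.

    Pigmented pixels are shell pixels with grey <= ``threshold`` (strict
    inequality when ``inclusive`` is False). An empty pigmented set yields
    index 0 with an undefined mean grey.
    """
    grey = np.asarray(grey)
    mask = np.asarray(mask, dtype=bool)
    if grey.shape != mask.shape:
        raise ValueError("grey image and mask dimensions must match")
    n_shell = int(mask.sum())
    if n_shell == 0:
        raise ValueError("mask selects no shell pixels")
    vals = grey[mask]
    pig = vals <= threshold if inclusive else vals < threshold
    frac = float(pig.sum()) / n_shell
    if not pig.any():
        return ColourResult(None, 0.0, 0.0)
    mean_grey = float(vals[pig].mean())
    intensity = (threshold - mean_grey) if inverted else mean_grey
    return ColourResult(mean_grey, frac, float(np.sqrt(intensity * frac)))


def oneway_anova(values, groups) -> TestResult:
    """Classical one-way fixed-effects ANOVA with (k-1, n-k) df."""
    y = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every group needs at least two values")
    n = y.size
    grand = y.mean()
    means = np.array([y[inv == i].mean() for i in range(k)])
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((y - means[inv]) ** 2))
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        warnings.warn("zero within-group variance: F is unbounded")
        return TestResult(statistic=float("inf"), df=(df1, df2), p=0.0)
    F = (ssb / df1) / (ssw / df2)
    from scipy import stats

    return TestResult(statistic=float(F), df=(df1, df2), p=float(stats.f.sf(F, df1, df2)))
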