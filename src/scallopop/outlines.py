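"""Outline geometric morphometrics.

Closed 2-D outlines (shell silhouettes) are carried through the classic
outline pipeline: boundary tracing of a binary mask, iterative smoothing,
equal-arc-length pseudo-landmark resampling, generalized Procrustes
superimposition (translation + scale + rotation), and elliptic Fourier
decomposition into per-harmonic coefficient quadruples (a_n, b_n, c_n, d_n).

Coordinate convention: pixel coordinates with x rightward and y downward
(image row). "Counterclockwise" refers to the mathematical sense in an
x-right / y-up frame, i.e. negative shoelace sum on the stored (x, y=row)
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

__all__ = [
    "OutlineShape",
    "LandmarkConfig",
    "EFACoefficients",
    "trace_outline",
    "smooth_outline",
    "normalize_start",
    "resample_equal",
    "gpa_align",
    "efa_coefficients",
    "inverse_efa",
    "harmonic_power",
    "harmonic_power_calibration",
]


# ---------------------------------------------------------------------------
# containers


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class OutlineShape:
    """An ordered closed coordinate chain; the first point is not repeated."""

    points: np.ndarray  # (N, 2) float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if len(self.points) < 3:
            raise ValueError("an outline needs at least 3 points")
        d = self.points - np.roll(self.points, 1, axis=0)
        if np.any(np.all(d == 0, axis=1)):
            raise ValueError("consecutive duplicate points are not allowed")

    @property
    def orientation(self) -> str:
        # y points down, so a negative shoelace sum is mathematically CCW
        return "counterclockwise" if _signed_area(self.points) < 0 else "clockwise"

    def reversed(self) -> "OutlineShape":
        return OutlineShape(self.points[::-1].copy())

    def perimeter(self) -> float:
        d = np.roll(self.points, -1, axis=0) - self.points
        return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


@dataclass
class LandmarkConfig:
    """A fixed-length pseudo-landmark configuration.

    ``centroid_size`` records the size of the configuration in its original
    units (the square root of the summed squared distances to the centroid),
    even after the coordinates have been normalized by alignment.
    """

    points: np.ndarray  # (k, 2) float
    centroid_size: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (k, 2) array")
        if not self.centroid_size > 0:
            raise ValueError("centroid_size must be positive")


@dataclass
class EFACoefficients:
    """Elliptic Fourier coefficients: ``harmonics[n-1] = (a_n, b_n, c_n, d_n)``."""

    harmonics: np.ndarray  # (n_harmonics, 4)
    a0: float = 0.0
    c0: float = 0.0

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4:
            raise ValueError("harmonics must be an (n, 4) array")
        if len(self.harmonics) < 1:
            raise ValueError("at least one harmonic is required")
        if not np.all(np.isfinite(self.harmonics)):
            raise ValueError("coefficients must be finite")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def power(self) -> np.ndarray:
        """Per-harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2."""
        return 0.5 * np.sum(self.harmonics**2, axis=1)


def harmonic_power(coeffs: EFACoefficients) -> np.ndarray:
    return coeffs.power()


# ---------------------------------------------------------------------------
# boundary tracing

# Moore neighborhood in clockwise order (visually, with y downward)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_outline(mask: np.ndarray) -> OutlineShape:
    """Trace the boundary pixel chain of a single connected component.

    Moore-neighbor (8-connected) tracing with Jacob's stopping criterion.
    Returns the chain as (x=column, y=row) coordinates, oriented
    counterclockwise.
    """
    mask = np.asarray(mask).astype(bool)
    lab, n_comp = label(mask, connectivity=2, return_num=True)
    if n_comp != 1:
        raise ValueError(f"mask must contain exactly one component, found {n_comp}")
    if int(mask.sum()) < 3:
        raise ValueError("component area must be at least 3 pixels")

    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    backtrack = (start[0], start[1] - 1)  # entered scanning from the west

    chain: list[tuple[int, int]] = []
    cur, back = start, backtrack
    first_state = None
    for _ in range(8 * int(padded.sum()) + 64):
        chain.append(cur)
        # rotate clockwise around cur starting just after the backtrack pixel
        offset = (back[0] - cur[0], back[1] - cur[1])
        k0 = _MOORE.index(offset)
        nxt, nxt_back = None, None
        for step in range(1, 9):
            dr, dc = _MOORE[(k0 + step) % 8]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                nxt = cand
                pr, pc = _MOORE[(k0 + step - 1) % 8]
                nxt_back = (cur[0] + pr, cur[1] + pc)
                break
        if nxt is None:  # isolated pixel cluster smaller than tracing needs
            break
        if first_state is None:
            first_state = (cur, nxt)
        elif (cur, nxt) == first_state:
            chain.pop()  # cur == start already recorded at position 0
            break
        cur, back = nxt, nxt_back
    else:  # pragma: no cover - safety net
        raise RuntimeError("boundary tracing failed to terminate")

    # drop a possible duplicated closing pixel and de-pad; (x, y) = (col, row)
    pts = np.array([(c - 1, r - 1) for r, c in chain], dtype=float)
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    pts = pts[keep]
    out = OutlineShape(pts)
    if out.orientation != "counterclockwise":
        out = out.reversed()
    return out


def normalize_start(outline: OutlineShape) -> OutlineShape:
    """Rotate the chain so it starts at the point of maximal x after centering.

    Ties are broken by the smallest y, then by original order, which makes the
    starting point reproducible across similar outlines.
    """
    pts = outline.points
    centered = pts - pts.mean(axis=0)
    order = np.lexsort((np.arange(len(pts)), centered[:, 1], -centered[:, 0]))
    i0 = int(order[0])
    return OutlineShape(np.roll(pts, -i0, axis=0))


# ---------------------------------------------------------------------------
# smoothing and resampling


def smooth_outline(outline: OutlineShape, n_iters: int = 10) -> OutlineShape:
    """Cyclic three-point moving-average smoothing, applied ``n_iters`` times."""
    if n_iters < 0:
        raise ValueError("n_iters must be non-negative")
    pts = outline.points.copy()
    for _ in range(int(n_iters)):
        pts = (np.roll(pts, 1, axis=0) + pts + np.roll(pts, -1, axis=0)) / 3.0
    return OutlineShape(pts)


def resample_equal(outline: OutlineShape, k: int = 1000) -> LandmarkConfig:
    """Resample ``k`` points at equal arc length along the closed polyline.

    The first output point is the outline's first point; subsequent points sit
    at arc positions ``j * perimeter / k``.
    """
    if k < 3:
        raise ValueError("k must be at least 3")
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    if not total > 0:
        raise ValueError("outline perimeter must be positive")
    target = np.arange(k) * total / k
    x = np.interp(target, cum, closed[:, 0])
    y = np.interp(target, cum, closed[:, 1])
    new = np.column_stack([x, y])
    centered = new - new.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if not size > 0:
        raise ValueError("degenerate outline (zero centroid size)")
    return LandmarkConfig(new, size)


# ---------------------------------------------------------------------------
# generalized Procrustes superimposition


def _normalize(points: np.ndarray) -> tuple[np.ndarray, float]:
    centered = points - points.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if not size > 0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return centered / size, size


def _rotate_to(z: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Optimal rotation (no reflection) of complex shape z onto m."""
    s = np.vdot(m, z)  # sum conj(m) * z
    mag = abs(s)
    if mag == 0:
        return z
    return z * np.conj(s) / mag


def gpa_align(
    configs: list[LandmarkConfig], tol: float = 1e-11, max_iter: int = 200
) -> tuple[list[LandmarkConfig], np.ndarray]:
    """Full generalized Procrustes alignment of same-length configurations.

    Every configuration is translated to zero centroid, scaled to unit
    centroid size and rotated to the iteratively re-estimated mean shape.
    Returns the aligned configurations (centroid sizes keep the original
    values) and the mean shape as a (k, 2) array of unit centroid size.

    The overall rotation of a Procrustes solution is arbitrary; to make the
    result deterministic and idempotent the final frame is canonicalized by
    rotating the mean shape's principal axis onto the x axis (sign fixed by
    the third moment), unless the mean is nearly isotropic.
    """
    if not configs:
        raise ValueError("no configurations supplied")
    k = configs[0].points.shape[0]
    if any(c.points.shape[0] != k for c in configs):
        raise ValueError("all configurations must share the landmark count")

    zs, sizes = [], []
    for c in configs:
        norm, _ = _normalize(c.points)
        zs.append(norm[:, 0] + 1j * norm[:, 1])
        sizes.append(c.centroid_size)

    mean = zs[0].copy()
    mean /= np.sqrt(np.sum(np.abs(mean) ** 2))
    for _ in range(max_iter):
        aligned = [_rotate_to(z, mean) for z in zs]
        new_mean = np.mean(aligned, axis=0)
        norm = np.sqrt(np.sum(np.abs(new_mean) ** 2))
        if norm == 0:
            raise ValueError("degenerate mean shape")
        new_mean = new_mean / norm
        # compare in a rotation-fixed frame to measure real change
        delta = np.linalg.norm(_rotate_to(new_mean, mean) - mean)
        mean = new_mean
        if delta < tol:
            break
    mean = mean * _canonical_rotation(mean)
    aligned = [_rotate_to(z, mean) for z in zs]
    out = [
        LandmarkConfig(np.column_stack([z.real, z.imag]), s)
        for z, s in zip(aligned, sizes)
    ]
    return out, np.column_stack([mean.real, mean.imag])


def _canonical_rotation(mean: np.ndarray) -> complex:
    """Unit complex number rotating the mean's principal axis onto x."""
    P = np.column_stack([mean.real, mean.imag])
    C = P.T @ P
    w, v = np.linalg.eigh(C)
    if w[1] - w[0] < 1e-9 * max(w[1], 1e-300):
        return 1.0 + 0.0j  # nearly isotropic: keep the converged frame
    axis = v[:, 1]
    rot = np.exp(-1j * np.arctan2(axis[1], axis[0]))
    x = (mean * rot).real
    skew = float(np.sum(x**3))
    if abs(skew) < 1e-12:
        skew = float(np.sum((mean * rot).imag ** 3))
    if skew < 0:
        rot = -rot
    return rot


# ---------------------------------------------------------------------------
# elliptic Fourier analysis (Kuhl-Giardina)


def _as_points(shape) -> np.ndarray:
    if isinstance(shape, (OutlineShape, LandmarkConfig)):
        return shape.points
    return np.asarray(shape, dtype=float)


def _parameterize(pts: np.ndarray, parameterization: str):
    d = np.roll(pts, -1, axis=0) - pts
    if parameterization == "chord":
        dt = np.hypot(d[:, 0], d[:, 1])
    elif parameterization == "uniform":
        dt = np.ones(len(pts))
    else:
        raise ValueError(f"unknown parameterization: {parameterization!r}")
    if np.any(dt <= 0):
        raise ValueError("zero-length segment in outline")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    return d, dt, t, t[-1]


def efa_coefficients(
    shape, n_harmonics: int = 15, parameterization: str = "chord"
) -> EFACoefficients:
    """Elliptic Fourier coefficients of a closed configuration.

    No first-ellipse normalization is applied: when the configurations have
    already been brought to a common position, scale and rotation by
    Procrustes alignment, normalizing against the first harmonic would
    discard real shape differences.

    ``parameterization`` is ``"chord"`` (constant speed along the polygon,
    the default) or ``"uniform"`` (equal parameter increment per vertex).
    The two coincide on equal-arc-length resampled configurations.
    """
    pts = _as_points(shape)
    k = len(pts)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be at least 1")
    if n_harmonics >= k / 2:
        raise ValueError("n_harmonics must be below half the point count")
    d, dt, t, T = _parameterize(pts, parameterization)
    if not T > 0:
        raise ValueError("zero-perimeter input")

    n = np.arange(1, n_harmonics + 1)
    phi = np.outer(n, 2.0 * np.pi * t / T)  # (n_h, k+1)
    dcos = np.diff(np.cos(phi), axis=1)
    dsin = np.diff(np.sin(phi), axis=1)
    const = T / (2.0 * np.pi**2 * n**2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = const * (dcos @ dx_dt)
    b = const * (dsin @ dx_dt)
    c = const * (dcos @ dy_dt)
    dd = const * (dsin @ dy_dt)

    # center offsets (piecewise-linear integral of x(t), y(t) over one period)
    xi = np.cumsum(d[:, 0]) - dx_dt * t[1:]
    a0 = pts[0, 0] + (np.sum(dx_dt / 2.0 * np.diff(t**2)) + np.sum(xi * dt)) / T
    delta = np.cumsum(d[:, 1]) - dy_dt * t[1:]
    c0 = pts[0, 1] + (np.sum(dy_dt / 2.0 * np.diff(t**2)) + np.sum(delta * dt)) / T

    return EFACoefficients(np.column_stack([a, b, c, dd]), float(a0), float(c0))


def inverse_efa(coeffs: EFACoefficients, n_points: int = 300) -> OutlineShape:
    """Evaluate the truncated Fourier series at equally spaced parameters."""
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    t = np.arange(n_points) / n_points
    n = np.arange(1, coeffs.n_harmonics + 1)
    ang = 2.0 * np.pi * np.outer(t, n)  # (n_points, n_h)
    cos, sin = np.cos(ang), np.sin(ang)
    h = coeffs.harmonics
    x = coeffs.a0 + cos @ h[:, 0] + sin @ h[:, 1]
    y = coeffs.c0 + cos @ h[:, 2] + sin @ h[:, 3]
    return OutlineShape(np.column_stack([x, y]))


def harmonic_power_calibration(
    coeff_set: list[EFACoefficients],
    threshold: float = 0.98,
    exclude_first: bool = True,
) -> tuple[int, np.ndarray]:
    """Smallest harmonic count whose mean cumulative power reaches ``threshold``.

    For each specimen the cumulative fraction of total harmonic power is
    computed; fractions are averaged across specimens and the first harmonic
    number at which the mean curve reaches the threshold is returned together
    with the curve itself.

    With ``exclude_first`` the baseline (and the cumulative sum) starts at
    harmonic 2: Procrustes-aligned, ellipse-like outlines hold nearly all raw
    power in harmonic 1, so calibration is only informative on the residual
    spectrum. The returned count still refers to the harmonic number (a result
    of ``N`` means "harmonics 1..N").
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if not coeff_set:
        raise ValueError("empty coefficient set")
    m = coeff_set[0].n_harmonics
    if any(c.n_harmonics != m for c in coeff_set):
        raise ValueError("all coefficient sets must share the harmonic count")
    powers = np.array([c.power() for c in coeff_set])  # (S, m)
    start = 1 if exclude_first else 0
    tail = powers[:, start:]
    totals = tail.sum(axis=1)
    frac = np.where(
        totals[:, None] > 0, np.cumsum(tail, axis=1) / np.maximum(totals, 1e-300)[:, None], 1.0
    )
    curve = frac.mean(axis=0)
    hit = np.nonzero(curve >= threshold - 1e-12)[0]
    n_sel = (int(hit[0]) if hit.size else len(curve) - 1) + 1 + start
    return n_sel, curve
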