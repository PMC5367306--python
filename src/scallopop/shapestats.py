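"""Statistics on shape descriptors.

PCA of elliptic Fourier coefficient matrices, component retention by
explained variance, one-way MANOVA with Wilks' lambda (Rao's F
approximation), and thin-plate-spline deformation grids between mean shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .outlines import LandmarkConfig
from .results import TestResult

__all__ = [
    "ShapePCA",
    "shape_pca",
    "retain_components",
    "manova_wilks",
    "DeformationGrid",
    "tps_deformation",
    "group_mean_shapes",
]


# ---------------------------------------------------------------------------
# PCA of descriptors


@dataclass
class ShapePCA:
    scores: np.ndarray
    loadings: np.ndarray
    variance_fractions: np.ndarray


def shape_pca(coeff_matrix: np.ndarray) -> ShapePCA:
    """PCA by singular value decomposition of the centered (not scaled)
    specimen x descriptor matrix. Signs follow the largest-magnitude-loading
    convention so results are deterministic."""
    X = np.asarray(coeff_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need at least 2 specimens and 1 descriptor")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    rank = min(X.shape[0] - 1, X.shape[1])
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    if not np.any(s > 1e-12 * max(1.0, s.max(initial=0.0))):
        warnings.warn("constant matrix: no variance to decompose")
        return ShapePCA(np.zeros((X.shape[0], 0)), np.zeros((X.shape[1], 0)), np.zeros(0))
    flip = np.sign(vt[np.arange(rank), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = u * s * flip
    loadings = (vt * flip[:, None]).T
    var = s**2
    return ShapePCA(scores, loadings, var / var.sum())


def retain_components(variance_fractions, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative variance fraction reaches ``threshold``."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    f = np.asarray(variance_fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("variance fractions must be non-negative")
    cum = np.cumsum(f)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else len(f)


# ---------------------------------------------------------------------------
# one-way MANOVA, Wilks' lambda


def manova_wilks(scores: np.ndarray, groups) -> TestResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    ``Lambda = det(E) / det(E + H)`` with E and H the within- and
    between-group cross-product matrices. The F approximation and its
    degrees of freedom follow Rao's standard layout; for a single response
    it reduces exactly to the one-way ANOVA F.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups)
    n, p = Y.shape
    labels, inv = np.unique(groups, return_inverse=True)
    g = len(labels)
    if g < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every group needs at least two specimens")
    if p >= n - g:
        raise ValueError("too many response variables for the residual df")

    grand = Y.mean(axis=0)
    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for k in range(g):
        Yk = Y[inv == k]
        mk = Yk.mean(axis=0)
        D = Yk - mk
        E += D.T @ D
        dm = (mk - grand)[:, None]
        H += counts[k] * (dm @ dm.T)

    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    if sign_e <= 0:
        raise ValueError("singular within-group matrix; retain fewer components")
    lam = float(np.exp(logdet_e - logdet_t))

    nu_h, nu_e = g - 1, n - g
    denom = p**2 + nu_h**2 - 5
    s = np.sqrt((p**2 * nu_h**2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * nu_h
    m = nu_e + nu_h - (p + nu_h + 1) / 2.0
    df2 = m * s - df1 / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    F = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return TestResult(
        statistic=lam, df=(df1, df2), p=pval, meta={"F": float(F), "n_groups": g, "n_vars": p}
    )


# ---------------------------------------------------------------------------
# thin-plate splines


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 * ln(r^2), with U(0) = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = r2 * np.log(r2)
    return np.where(r2 > 0, u, 0.0)


class _TPSpline:
    """Interpolating thin-plate spline between two landmark sets."""

    def __init__(self, ref: np.ndarray, target: np.ndarray):
        ref = np.asarray(ref, dtype=float)
        target = np.asarray(target, dtype=float)
        if ref.shape != target.shape or ref.ndim != 2 or ref.shape[1] != 2:
            raise ValueError("ref and target must be matching (k, 2) arrays")
        k = ref.shape[0]
        if k < 3:
            raise ValueError("need at least 3 landmarks")
        d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=2)
        K = _tps_kernel(d2)
        P = np.column_stack([np.ones(k), ref])
        L = np.zeros((k + 3, k + 3))
        L[:k, :k] = K
        L[:k, k:] = P
        L[k:, :k] = P.T
        rhs = np.zeros((k + 3, 2))
        rhs[:k] = target
        try:
            sol = linalg.solve(L, rhs)
        except linalg.LinAlgError as exc:
            raise ValueError("singular TPS system (collinear reference landmarks)") from exc
        if not np.all(np.isfinite(sol)):
            raise ValueError("singular TPS system (collinear reference landmarks)")
        self.ref = ref
        self.w = sol[:k]
        self.affine = sol[k:]
        self.K = K

    def transform(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        d2 = np.sum((pts[:, None, :] - self.ref[None, :, :]) ** 2, axis=2)
        U = _tps_kernel(d2)
        P = np.column_stack([np.ones(len(pts)), pts])
        return U @ self.w + P @ self.affine

    def bending_energy(self) -> float:
        return float(np.trace(self.w.T @ self.K @ self.w))


@dataclass
class DeformationGrid:
    """A reference grid and its image under the interpolating spline."""

    source_grid: np.ndarray  # (g, g, 2)
    mapped_grid: np.ndarray  # (g, g, 2)
    bending_energy: float


def tps_deformation(
    ref_landmarks: np.ndarray,
    target_landmarks: np.ndarray,
    grid_n: int = 20,
    landmark_step: int | None = None,
) -> DeformationGrid:
    """Deformation grid carrying the reference mean shape onto the target.

    Dense pseudo-landmark sets are subsampled (default: to about 40
    landmarks) to keep the interpolation system well-conditioned; the grid
    spans the reference bounding box with a small margin.
    """
    ref = np.asarray(ref_landmarks, dtype=float)
    target = np.asarray(target_landmarks, dtype=float)
    if landmark_step is None:
        landmark_step = max(1, len(ref) // 40)
    ref_s = ref[::landmark_step]
    tgt_s = target[::landmark_step]
    spline = _TPSpline(ref_s, tgt_s)

    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    pad = 0.05 * (hi - lo)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_n)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_n)
    xx, yy = np.meshgrid(gx, gy)
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    mapped = spline.transform(nodes)
    return DeformationGrid(
        nodes.reshape(grid_n, grid_n, 2),
        mapped.reshape(grid_n, grid_n, 2),
        max(spline.bending_energy(), 0.0),
    )


def group_mean_shapes(configs: list[LandmarkConfig], groups) -> dict[str, np.ndarray]:
    """Per-group mean of aligned pseudo-landmark configurations."""
    groups = list(groups)
    if len(groups) != len(configs):
        raise ValueError("one group label per configuration is required")
    out: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(groups):
        pts = [c.points for c, grp in zip(configs, groups) if grp == label]
        out[str(label)] = np.mean(pts, axis=0)
    return out
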