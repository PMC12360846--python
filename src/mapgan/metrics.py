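"""Map-pair similarity metrics: SSIM, correlation, correlation about mean, PCC.

``correlation`` is the plain normalized dot product; ``correlation about
mean`` and ``PCC`` are both mean-centered and therefore algebraically
identical over the same voxel support — they are kept as separate code
paths so each can be validated independently, and an optional threshold
mask lets callers restrict the correlation family to high-density voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter

from mapgan.errors import UndefinedMetricError
from mapgan.volume_io import DensityMap

DEFAULT_SSIM_WINDOW = 7
DEFAULT_DATA_RANGE = 1.0


@dataclass(frozen=True)
class MetricsReport:
    ssim: float
    correlation: float
    correlation_about_mean: float
    pcc: float
    n_voxels: int

    def to_dict(self) -> dict:
        return {
            "ssim": self.ssim,
            "correlation": self.correlation,
            "correlation_about_mean": self.correlation_about_mean,
            "pcc": self.pcc,
            "n_voxels": self.n_voxels,
        }


def align_grids(a: DensityMap, b: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    """Resample ``b`` onto ``a``'s grid (trilinear, outside -> 0).

    Identical grids are returned unchanged.
    """
    same = (
        a.shape == b.shape
        and np.allclose(a.voxel_size, b.voxel_size)
        and np.allclose(a.origin, b.origin)
    )
    if same:
        return a.data, b.data

    # overlap check on world extents (voxel centers)
    a_lo, a_hi = _world_bounds(a)
    b_lo, b_hi = _world_bounds(b)
    if np.any(a_hi < b_lo) or np.any(b_hi < a_lo):
        raise ValueError("maps do not overlap in world space")

    nz, ny, nx = a.shape
    xs = (a.origin[0] + np.arange(nx) * a.voxel_size[0] - b.origin[0]) / b.voxel_size[0]
    ys = (a.origin[1] + np.arange(ny) * a.voxel_size[1] - b.origin[1]) / b.voxel_size[1]
    zs = (a.origin[2] + np.arange(nz) * a.voxel_size[2] - b.origin[2]) / b.voxel_size[2]
    coords = np.stack(np.meshgrid(zs, ys, xs, indexing="ij"))
    resampled = map_coordinates(
        b.data.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    return a.data, resampled.astype(np.float32)


def _world_bounds(m: DensityMap) -> tuple[np.ndarray, np.ndarray]:
    nz, ny, nx = m.shape
    span = (np.array([nx, ny, nz]) - 1) * m.voxel_size
    return m.origin, m.origin + span


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    window: int = DEFAULT_SSIM_WINDOW,
    data_range: float = DEFAULT_DATA_RANGE,
) -> float:
    """Mean local SSIM over all fully contained 3D windows.

    Uniform window, sample (ddof=1) variances/covariance, and
    ``c1 = (0.01 * data_range)²``, ``c2 = (0.03 * data_range)²`` — the
    standard image-library convention for volumetric data.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if min(x.shape) < window:
        raise ValueError(
            f"window {window} exceeds smallest volume dimension {min(x.shape)}"
        )

    np_win = window**3
    cov_norm = np_win / (np_win - 1)  # sample statistics
    ux = uniform_filter(x, window)
    uy = uniform_filter(y, window)
    uxx = uniform_filter(x * x, window)
    uyy = uniform_filter(y * y, window)
    uxy = uniform_filter(x * y, window)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    r = window // 2
    core = s[r:-r, r:-r, r:-r] if r else s
    return float(core.mean())


def correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized dot product <X, Y> / (||X|| ||Y||), no mean centering."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx_ = np.linalg.norm(x)
    ny_ = np.linalg.norm(y)
    if nx_ == 0.0 or ny_ == 0.0:
        raise UndefinedMetricError("correlation undefined for an all-zero map")
    return float(np.dot(x, y) / (nx_ * ny_))


def correlation_about_mean(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized dot product of mean-centered maps."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = np.linalg.norm(xc)
    ny_ = np.linalg.norm(yc)
    if nx_ == 0.0 or ny_ == 0.0:
        raise UndefinedMetricError(
            "correlation about mean undefined for a constant map"
        )
    return float(np.dot(xc, yc) / (nx_ * ny_))


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient via the explicit summation form."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    dx = x - x.mean()
    dy = y - y.mean()
    num = np.sum(dx * dy)
    den = np.sqrt(np.sum(dx * dx)) * np.sqrt(np.sum(dy * dy))
    if den == 0.0:
        raise UndefinedMetricError("PCC undefined for a constant map")
    return float(num / den)


def evaluate_pair(
    generated: DensityMap,
    experimental: DensityMap,
    window: int = DEFAULT_SSIM_WINDOW,
    data_range: float = DEFAULT_DATA_RANGE,
    threshold: float | None = None,
) -> MetricsReport:
    """Align grids then compute all four scores.

    ``threshold``, when given, restricts the correlation family (but not
    SSIM, which is window-based) to voxels where either map exceeds the
    level — useful for emulating tools that score only high-density regions.
    """
    x, y = align_grids(generated, experimental)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)

    s = ssim(x, y, window=window, data_range=data_range)

    if threshold is not None:
        mask = (x > threshold) | (y > threshold)
        if not mask.any():
            raise UndefinedMetricError(
                f"threshold {threshold} excludes every voxel"
            )
        xs_, ys_ = x[mask], y[mask]
        n_vox = int(mask.sum())
    else:
        xs_, ys_ = x.ravel(), y.ravel()
        n_vox = x.size

    return MetricsReport(
        ssim=s,
        correlation=correlation(xs_, ys_),
        correlation_about_mean=correlation_about_mean(xs_, ys_),
        pcc=pcc(xs_, ys_),
        n_voxels=n_vox,
    )
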