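"""Curation of raw experimental maps and stochastic augmentation of inputs.

Curation boxes the raw map around the aligned atomic model, resamples to a
1 Å grid and min-max normalizes, producing the training target.  Augmentation
perturbs normalized simulated maps with random Gaussian noise, random blur,
and random single-axis anisotropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from mapgan.errors import EmptyModelError
from mapgan.volume_io import AtomicModel, DensityMap, minmax_normalize, resample

DEFAULT_BOX_MARGIN = 5.0  # Å; "slightly larger" than the structure


@dataclass(frozen=True)
class BoxSpec:
    """An axis-aligned world-space box, corners in (x, y, z) Å."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=np.float64).reshape(3))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=np.float64).reshape(3))
        if not np.all(self.upper > self.lower):
            raise ValueError(f"box upper {self.upper} must exceed lower {self.lower}")


@dataclass(frozen=True)
class AugmentConfig:
    noise_std_range: tuple[float, float] = (0.0, 0.05)
    blur_sigma_range: tuple[float, float] = (0.0, 1.0)  # voxels
    anisotropy_factor_range: tuple[float, float] = (1.5, 2.0)
    per_transform_probability: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_std_range", "blur_sigma_range", "anisotropy_factor_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi, got ({lo}, {hi})")
        if not 0.0 <= self.per_transform_probability <= 1.0:
            raise ValueError(
                f"per_transform_probability must be in [0, 1], "
                f"got {self.per_transform_probability}"
            )


def compute_bounding_box(model: AtomicModel, margin: float) -> BoxSpec:
    """Per-axis min/max of atom coordinates expanded by ``margin``."""
    if model.M == 0:
        raise EmptyModelError("cannot box an empty model")
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    pos = model.positions
    return BoxSpec(pos.min(axis=0) - margin, pos.max(axis=0) + margin)


def extract_box(density_map: DensityMap, box: BoxSpec) -> DensityMap:
    """Cut out the voxels whose centers lie inside the box.

    Parts of the box outside the map are zero-filled; the origin is updated
    to the first retained voxel center.
    """
    voxel = density_map.voxel_size
    origin = density_map.origin
    nz, ny, nx = density_map.shape
    n_xyz = np.array([nx, ny, nz])

    lo_idx = np.ceil((box.lower - origin) / voxel - 1e-9).astype(int)  # (x, y, z)
    hi_idx = np.floor((box.upper - origin) / voxel + 1e-9).astype(int)
    if np.any(hi_idx < lo_idx):
        raise ValueError("box selects no voxel centers along some axis")
    if np.any(hi_idx < 0) or np.any(lo_idx >= n_xyz):
        raise ValueError("box does not overlap the map extent")

    out_shape_xyz = hi_idx - lo_idx + 1
    out = np.zeros(out_shape_xyz[::-1], dtype=np.float32)  # (z, y, x)

    src_lo = np.maximum(lo_idx, 0)
    src_hi = np.minimum(hi_idx, n_xyz - 1)
    dst_lo = src_lo - lo_idx
    dst_hi = dst_lo + (src_hi - src_lo)
    out[
        dst_lo[2] : dst_hi[2] + 1,
        dst_lo[1] : dst_hi[1] + 1,
        dst_lo[0] : dst_hi[0] + 1,
    ] = density_map.data[
        src_lo[2] : src_hi[2] + 1,
        src_lo[1] : src_hi[1] + 1,
        src_lo[0] : src_hi[0] + 1,
    ]
    new_origin = origin + lo_idx * voxel
    return DensityMap(out, voxel.copy(), new_origin, density_map.label)


def curate_expmap(
    raw: DensityMap, model: AtomicModel, margin: float = DEFAULT_BOX_MARGIN
) -> DensityMap:
    """Box the raw map around the model, resample to 1 Å, normalize to [0, 1]."""
    box = compute_bounding_box(model, margin)
    boxed = extract_box(raw, box)
    iso = resample(boxed, (1.0, 1.0, 1.0))
    return minmax_normalize(iso)


def augment(density_map: DensityMap, config: AugmentConfig) -> DensityMap:
    """Stochastically perturb a normalized map; deterministic per seed.

    Independently with ``per_transform_probability`` applies additive
    Gaussian noise, Gaussian blur, and single-axis anisotropy (downsample one
    random axis, trilinear-upsample back).  The result is clipped to [0, 1].
    Shape, voxel size and origin are never changed.
    """
    data = density_map.data
    if float(data.min()) < -1e-6 or float(data.max()) > 1.0 + 1e-6:
        raise ValueError(
            "augment expects a map normalized to [0, 1]; "
            f"got range [{data.min():.4g}, {data.max():.4g}]"
        )
    rng = np.random.default_rng(config.seed)
    out = data.astype(np.float64)
    p = config.per_transform_probability

    # draw all gate/parameter variates unconditionally so that the random
    # stream (and hence determinism) does not depend on which gates fire
    gate_noise, gate_blur, gate_aniso = rng.random(3) < p
    noise_std = rng.uniform(*config.noise_std_range)
    blur_sigma = rng.uniform(*config.blur_sigma_range)
    aniso_factor = rng.uniform(*config.anisotropy_factor_range)
    aniso_axis = int(rng.integers(0, 3))
    noise = rng.standard_normal(out.shape)

    if gate_noise:
        out = out + noise_std * noise
    if gate_blur and blur_sigma > 0:
        out = gaussian_filter(out, sigma=blur_sigma, mode="nearest")
    if gate_aniso and aniso_factor > 1.0:
        n = out.shape[aniso_axis]
        n_small = max(2, int(math.floor(n / aniso_factor)))
        down = [1.0, 1.0, 1.0]
        down[aniso_axis] = n_small / n
        small = zoom(out, down, order=1, mode="nearest", grid_mode=False)
        up = [o / s for o, s in zip(out.shape, small.shape)]
        out = zoom(small, up, order=1, mode="nearest", grid_mode=False)
        if out.shape != data.shape:  # zoom rounding guard
            out = np.resize(out, data.shape)

    out = np.clip(out, 0.0, 1.0)
    return DensityMap(
        out.astype(np.float32),
        density_map.voxel_size.copy(),
        density_map.origin.copy(),
        density_map.label,
    )
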