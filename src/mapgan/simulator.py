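"""Gaussian point-spread simulation of density maps from atomic models.

Each heavy atom contributes an isotropic Gaussian scaled by its atomic
number::

    rho(x) = sum_i theta * Z_i * exp(-k * |x - r_i|^2)

with ``k = 1 / (2 * sigma^2)`` and ``sigma = resolution * sigma_factor``.
The default ``sigma_factor`` of ``1 / (pi * sqrt(2))`` follows the ChimeraX
molmap resolution convention; other packages use different conventions, so
it is a parameter rather than a constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from mapgan.errors import EmptyModelError
from mapgan.volume_io import AtomicModel, DensityMap, minmax_normalize

#: ChimeraX molmap convention: sigma = resolution / (pi * sqrt(2))
MOLMAP_SIGMA_FACTOR = 1.0 / (math.pi * math.sqrt(2.0))

#: Default simulation resolution in Å.
DEFAULT_RESOLUTION = 2.0


def resolution_to_k(resolution: float, sigma_factor: float) -> float:
    """Convert a resolution (Å) to the Gaussian decay constant k (Å^-2)."""
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if sigma_factor <= 0:
        raise ValueError(f"sigma_factor must be positive, got {sigma_factor}")
    sigma = resolution * sigma_factor
    return 1.0 / (2.0 * sigma * sigma)


@dataclass(frozen=True)
class SimulationParams:
    """Kernel parameters for the Gaussian simulator.

    ``cutoff_sigmas`` truncates each atom's contribution beyond that many
    standard deviations (``None`` disables truncation; used by exactness
    tests).  ``use_occupancy`` optionally weights each atom by its occupancy.
    """

    resolution: float = DEFAULT_RESOLUTION
    theta: float = 1.0
    sigma_factor: float = MOLMAP_SIGMA_FACTOR
    cutoff_sigmas: float | None = 5.0
    use_occupancy: bool = False

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.sigma_factor <= 0:
            raise ValueError(f"sigma_factor must be positive, got {self.sigma_factor}")
        if self.cutoff_sigmas is not None and self.cutoff_sigmas < 3:
            raise ValueError(
                f"cutoff_sigmas must be >= 3 for acceptable accuracy, "
                f"got {self.cutoff_sigmas}"
            )

    @property
    def sigma(self) -> float:
        return self.resolution * self.sigma_factor

    @property
    def k(self) -> float:
        return resolution_to_k(self.resolution, self.sigma_factor)


def grid_from_model(model: AtomicModel, voxel: float, margin: float) -> DensityMap:
    """Build a zero-filled axis-aligned grid covering the model plus margin."""
    if model.M == 0:
        raise EmptyModelError("cannot build a grid around an empty model")
    if voxel <= 0:
        raise ValueError(f"voxel must be positive, got {voxel}")
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    pos = model.positions
    lower = pos.min(axis=0) - margin  # (x, y, z)
    upper = pos.max(axis=0) + margin
    n = np.floor((upper - lower) / voxel + 1e-9).astype(int) + 1  # (x, y, z)
    data = np.zeros((n[2], n[1], n[0]), dtype=np.float32)
    return DensityMap(data, np.full(3, float(voxel)), lower)


def evaluate_gaussian_sum(
    model: AtomicModel, grid: DensityMap, params: SimulationParams
) -> np.ndarray:
    """Evaluate the Gaussian point-spread sum in float64 on every grid point.

    Vectorized per atom over the sub-box within ``cutoff_sigmas * sigma`` of
    its center; the no-cutoff path evaluates every atom on the full grid.
    Returns the double-precision accumulation; :func:`simulate_map` wraps it
    into a (32-bit) :class:`DensityMap`.
    """
    if model.M == 0:
        raise EmptyModelError("cannot simulate an empty model")
    k = params.k
    theta = params.theta
    nz, ny, nx = grid.shape
    out = np.zeros((nz, ny, nx), dtype=np.float64)

    # per-axis voxel-center world coordinates
    xs = grid.origin[0] + np.arange(nx) * grid.voxel_size[0]
    ys = grid.origin[1] + np.arange(ny) * grid.voxel_size[1]
    zs = grid.origin[2] + np.arange(nz) * grid.voxel_size[2]

    weights = model.atomic_numbers.astype(np.float64) * theta
    if params.use_occupancy:
        weights = weights * model.occupancies

    if params.cutoff_sigmas is None:
        radius = None
    else:
        radius = params.cutoff_sigmas * params.sigma

    for pos, w in zip(model.positions, weights):
        if radius is None:
            ix0, ix1, iy0, iy1, iz0, iz1 = 0, nx, 0, ny, 0, nz
        else:
            ix0 = max(0, math.ceil((pos[0] - radius - grid.origin[0]) / grid.voxel_size[0]))
            ix1 = min(nx, math.floor((pos[0] + radius - grid.origin[0]) / grid.voxel_size[0]) + 1)
            iy0 = max(0, math.ceil((pos[1] - radius - grid.origin[1]) / grid.voxel_size[1]))
            iy1 = min(ny, math.floor((pos[1] + radius - grid.origin[1]) / grid.voxel_size[1]) + 1)
            iz0 = max(0, math.ceil((pos[2] - radius - grid.origin[2]) / grid.voxel_size[2]))
            iz1 = min(nz, math.floor((pos[2] + radius - grid.origin[2]) / grid.voxel_size[2]) + 1)
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
        dx2 = (xs[ix0:ix1] - pos[0]) ** 2
        dy2 = (ys[iy0:iy1] - pos[1]) ** 2
        dz2 = (zs[iz0:iz1] - pos[2]) ** 2
        r2 = dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]
        contrib = w * np.exp(-k * r2)
        if radius is not None:
            contrib[r2 > radius * radius] = 0.0
        out[iz0:iz1, iy0:iy1, ix0:ix1] += contrib

    return out


def simulate_map(
    model: AtomicModel, grid: DensityMap, params: SimulationParams
) -> DensityMap:
    """Simulate a density map from an atomic model on the given grid."""
    out = evaluate_gaussian_sum(model, grid, params)
    return DensityMap(
        out.astype(np.float32), grid.voxel_size.copy(), grid.origin.copy(), grid.label
    )


def simulate_on_reference(
    model: AtomicModel, reference: DensityMap, params: SimulationParams
) -> DensityMap:
    """Simulate on the reference map's exact grid and min-max normalize."""
    grid = DensityMap(
        np.zeros(reference.shape, dtype=np.float32),
        reference.voxel_size.copy(),
        reference.origin.copy(),
        reference.label,
    )
    sim = simulate_map(model, grid, params)
    if float(sim.data.max()) == 0.0:
        warnings.warn(
            "model lies entirely outside the reference grid; returning an "
            "all-zero map",
            stacklevel=2,
        )
    return minmax_normalize(sim)
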