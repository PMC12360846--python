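"""Deterministic 32-cubed tiling with exact center-crop reassembly.

A map of shape ``d`` per axis is placed at offset 32 inside a zero canvas of
shape ``d + 64``.  Tiles of shape 32³ start at ``26 + 20*j`` per axis for
``j = 0 .. ceil(d/20) - 1``, so each tile's central 20³ block lands at
``[32 + 20*j, 32 + 20*(j+1))`` — the cores partition the region covering
the original volume with no gaps and no double counting.  Reassembly pastes
each processed tile's core and crops back to the original shape, restoring
voxel size and origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mapgan.volume_io import DensityMap

TILE_SIZE = 32
CORE_SIZE = 20
CORE_LO = (TILE_SIZE - CORE_SIZE) // 2  # 6
PAD = TILE_SIZE  # padding added on every side


@dataclass
class TilePack:
    """Ordered 32³ tiles plus the geometry to reassemble them exactly."""

    tiles: np.ndarray  # (n_tiles, 32, 32, 32) float32
    starts: np.ndarray  # (n_tiles, 3) voxel offsets (z, y, x) into the padded canvas
    original_shape: tuple[int, int, int]  # (z, y, x)
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label: str = ""

    tile_size: int = TILE_SIZE
    core_size: int = CORE_SIZE
    stride: int = CORE_SIZE
    pad_offset: tuple[int, int, int] = (PAD, PAD, PAD)

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        return tuple(d + 2 * PAD for d in self.original_shape)


def _axis_starts(d: int) -> np.ndarray:
    n = -(-d // CORE_SIZE)  # ceil(d / 20)
    return PAD - CORE_LO + CORE_SIZE * np.arange(n)  # 26 + 20*j


def pad_and_tile(density_map: DensityMap) -> TilePack:
    """Decompose a map into 32³ tiles on the zero-padded canvas.

    Tiles are enumerated in lexicographic (z, y, x) order of their start
    offsets.
    """
    shape = density_map.shape
    if min(shape) == 0:
        raise ValueError(f"cannot tile a map with an empty axis, shape={shape}")

    canvas = np.zeros([d + 2 * PAD for d in shape], dtype=np.float32)
    canvas[PAD : PAD + shape[0], PAD : PAD + shape[1], PAD : PAD + shape[2]] = (
        density_map.data
    )

    sz, sy, sx = (_axis_starts(d) for d in shape)
    starts = np.array(
        [(z, y, x) for z in sz for y in sy for x in sx], dtype=np.int64
    )
    tiles = np.empty((len(starts), TILE_SIZE, TILE_SIZE, TILE_SIZE), dtype=np.float32)
    for t, (z, y, x) in enumerate(starts):
        tiles[t] = canvas[z : z + TILE_SIZE, y : y + TILE_SIZE, x : x + TILE_SIZE]

    return TilePack(
        tiles=tiles,
        starts=starts,
        original_shape=tuple(shape),
        voxel_size=density_map.voxel_size.copy(),
        origin=density_map.origin.copy(),
        label=density_map.label,
    )


def reassemble(pack: TilePack, processed_tiles: np.ndarray | list) -> DensityMap:
    """Rebuild a map from processed tiles using only each tile's central 20³.

    ``processed_tiles`` must match the pack's tile count and shape; order is
    irrelevant as long as tiles stay aligned with ``pack.starts``.
    """
    tiles = np.asarray(processed_tiles, dtype=np.float32)
    expected = (pack.n_tiles, TILE_SIZE, TILE_SIZE, TILE_SIZE)
    if tiles.shape != expected:
        raise ValueError(
            f"processed tiles have shape {tiles.shape}, expected {expected}"
        )

    canvas = np.zeros(pack.padded_shape, dtype=np.float32)
    lo, hi = CORE_LO, CORE_LO + CORE_SIZE
    for tile, (z, y, x) in zip(tiles, pack.starts):
        canvas[
            z + lo : z + hi, y + lo : y + hi, x + lo : x + hi
        ] = tile[lo:hi, lo:hi, lo:hi]

    d0, d1, d2 = pack.original_shape
    data = canvas[PAD : PAD + d0, PAD : PAD + d1, PAD : PAD + d2]
    return DensityMap(data, pack.voxel_size.copy(), pack.origin.copy(), pack.label)


def core_coverage(pack: TilePack) -> np.ndarray:
    """Count, per padded-canvas voxel, how many tile cores cover it.

    Diagnostic used by the partition invariant: within the region covering
    the original volume every count must be exactly one.
    """
    cov = np.zeros(pack.padded_shape, dtype=np.int32)
    lo, hi = CORE_LO, CORE_LO + CORE_SIZE
    for z, y, x in pack.starts:
        cov[z + lo : z + hi, y + lo : y + hi, x + lo : x + hi] += 1
    return cov


def save_tilepack(pack: TilePack, path: str | Path) -> None:
    """Serialize a tile pack to an .npz container."""
    np.savez_compressed(
        path,
        tiles=pack.tiles,
        starts=pack.starts,
        original_shape=np.array(pack.original_shape, dtype=np.int64),
        voxel_size=pack.voxel_size,
        origin=pack.origin,
        label=np.array(pack.label),
    )


def load_tilepack(path: str | Path) -> TilePack:
    with np.load(path, allow_pickle=False) as npz:
        return TilePack(
            tiles=npz["tiles"].astype(np.float32),
            starts=npz["starts"].astype(np.int64),
            original_shape=tuple(int(v) for v in npz["original_shape"]),
            voxel_size=npz["voxel_size"].astype(np.float64),
            origin=npz["origin"].astype(np.float64),
            label=str(npz["label"]),
        )
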