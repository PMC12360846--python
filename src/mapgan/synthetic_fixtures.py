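"""Desk-scale synthetic inputs with known ground-truth transforms.

Random atom clouds (optionally arranged on helical curves to mimic
secondary-structure-like density) are simulated into maps; the paired
"pseudo-experimental" target is a blurred, noised copy of the simulated map
normalized back to [0, 1].  Because the target transform is known and
low-capacity, toy GAN training outcomes are attributable: a generator that
learns anything useful must beat the raw simulated map against the target.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from mapgan.simulator import SimulationParams, grid_from_model, simulate_map
from mapgan.tiling import pad_and_tile
from mapgan.volume_io import Atom, AtomicModel, ATOMIC_NUMBERS, DensityMap, minmax_normalize, write_map

_HELIX_RISE = 1.5  # Å per point along the helix axis
_HELIX_RADIUS = 2.3  # Å
_HELIX_TURN = math.radians(100.0)  # rotation per point

_GRID_MARGIN = 4.0  # Å around the atom cloud when building fixture grids


@dataclass(frozen=True)
class FixtureSpec:
    n_atoms: int = 50
    extent: float = 32.0  # Å; atoms live in [0, extent]^3
    element_mix: dict[str, float] = field(
        default_factory=lambda: {"C": 0.55, "N": 0.2, "O": 0.2, "S": 0.05}
    )
    helix_fraction: float = 0.5
    blur_sigma: float = 2.0  # voxels, ground-truth target transform
    noise_std: float = 0.05  # normalized-density units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atoms < 1:
            raise ValueError(f"n_atoms must be >= 1, got {self.n_atoms}")
        if self.extent <= 0:
            raise ValueError(f"extent must be positive, got {self.extent}")
        total = sum(self.element_mix.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ValueError(f"element_mix weights must sum to 1, got {total}")
        if not 0.0 <= self.helix_fraction <= 1.0:
            raise ValueError(
                f"helix_fraction must be in [0, 1], got {self.helix_fraction}"
            )


def random_atom_cloud(spec: FixtureSpec) -> AtomicModel:
    """Deterministic random atom cloud; a fraction lies on helical curves."""
    rng = np.random.default_rng(spec.seed)
    n_helix = int(round(spec.helix_fraction * spec.n_atoms))
    n_uniform = spec.n_atoms - n_helix

    positions: list[np.ndarray] = []
    while len(positions) < n_helix:
        seg = min(n_helix - len(positions), int(rng.integers(5, 15)))
        start = rng.uniform(0.2 * spec.extent, 0.8 * spec.extent, size=3)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        # orthonormal frame around the helix axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(axis @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(axis, ref)
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        phase = rng.uniform(0, 2 * math.pi)
        for t in range(seg):
            ang = phase + t * _HELIX_TURN
            p = (
                start
                + axis * (t * _HELIX_RISE)
                + u * (_HELIX_RADIUS * math.cos(ang))
                + v * (_HELIX_RADIUS * math.sin(ang))
            )
            positions.append(np.clip(p, 0.0, spec.extent))
    positions.extend(rng.uniform(0.0, spec.extent, size=(n_uniform, 3)))

    symbols = list(spec.element_mix.keys())
    weights = np.array([spec.element_mix[s] for s in symbols])
    choices = rng.choice(len(symbols), size=spec.n_atoms, p=weights / weights.sum())

    atoms = [
        Atom(
            element=symbols[c],
            atomic_number=ATOMIC_NUMBERS[symbols[c].upper()],
            position=np.asarray(pos, dtype=np.float64),
        )
        for pos, c in zip(positions, choices)
    ]
    return AtomicModel(atoms)


def make_training_pair(
    model: AtomicModel,
    spec: FixtureSpec,
    sim_params: SimulationParams | None = None,
) -> tuple[DensityMap, DensityMap]:
    """(simulated map, pseudo-experimental map) on a shared 1 Å grid.

    The pseudo-experimental target is
    ``minmax_normalize(blur(sim, blur_sigma) + noise(noise_std))`` with noise
    drawn from the spec's seed, so the transform the generator must learn is
    known exactly.
    """
    sim_params = sim_params or SimulationParams()
    grid = grid_from_model(model, voxel=1.0, margin=_GRID_MARGIN)
    sim = minmax_normalize(simulate_map(model, grid, sim_params))

    rng = np.random.default_rng(spec.seed + 1)
    target = sim.data.astype(np.float64)
    if spec.blur_sigma > 0:
        target = gaussian_filter(target, sigma=spec.blur_sigma, mode="nearest")
    if spec.noise_std > 0:
        target = target + spec.noise_std * rng.standard_normal(target.shape)
    pseudo_exp = minmax_normalize(
        DensityMap(target.astype(np.float32), sim.voxel_size.copy(), sim.origin.copy())
    )
    return sim, pseudo_exp


def build_toy_dataset(
    n_pairs: int,
    spec: FixtureSpec,
    sim_params: SimulationParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stacks of aligned (sim tile, target tile) pairs from ``n_pairs`` models.

    Each pair is tiled with identical geometry, so tiles at the same index
    share their start offset.  Deterministic per spec seed.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    sim_tiles: list[np.ndarray] = []
    exp_tiles: list[np.ndarray] = []
    for i in range(n_pairs):
        pair_spec = FixtureSpec(
            n_atoms=spec.n_atoms,
            extent=spec.extent,
            element_mix=spec.element_mix,
            helix_fraction=spec.helix_fraction,
            blur_sigma=spec.blur_sigma,
            noise_std=spec.noise_std,
            seed=spec.seed + 1000 * i,
        )
        model = random_atom_cloud(pair_spec)
        sim, exp = make_training_pair(model, pair_spec, sim_params)
        sim_pack = pad_and_tile(sim)
        exp_pack = pad_and_tile(exp)
        assert np.array_equal(sim_pack.starts, exp_pack.starts)
        sim_tiles.append(sim_pack.tiles)
        exp_tiles.append(exp_pack.tiles)
    return np.concatenate(sim_tiles), np.concatenate(exp_tiles)


def write_fixture_set(
    n_pairs: int,
    spec: FixtureSpec,
    out_dir: str | Path,
    sim_params: SimulationParams | None = None,
) -> dict:
    """Write paired MRC files plus a JSON manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_pairs):
        pair_spec = FixtureSpec(
            n_atoms=spec.n_atoms,
            extent=spec.extent,
            element_mix=spec.element_mix,
            helix_fraction=spec.helix_fraction,
            blur_sigma=spec.blur_sigma,
            noise_std=spec.noise_std,
            seed=spec.seed + 1000 * i,
        )
        model = random_atom_cloud(pair_spec)
        sim, exp = make_training_pair(model, pair_spec, sim_params)
        sim_path = out_dir / f"pair{i:03d}_sim.mrc"
        exp_path = out_dir / f"pair{i:03d}_exp.mrc"
        write_map(sim, sim_path)
        write_map(exp, exp_path)
        entries.append(
            {
                "index": i,
                "seed": pair_spec.seed,
                "n_atoms": pair_spec.n_atoms,
                "extent": pair_spec.extent,
                "blur_sigma": pair_spec.blur_sigma,
                "noise_std": pair_spec.noise_std,
                "sim": sim_path.name,
                "exp": exp_path.name,
            }
        )
    manifest = {"n_pairs": n_pairs, "base_seed": spec.seed, "pairs": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
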