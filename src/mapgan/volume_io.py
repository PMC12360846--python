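"""Density-volume and atomic-model I/O with explicit grid conventions.

Conventions used everywhere in this package:

* ``DensityMap.data`` is a 3-D ``float32`` array indexed ``(z, y, x)``.
* ``voxel_size`` and ``origin`` are 3-vectors in **(x, y, z)** order, in Å.
* The world coordinate of voxel ``(k, j, i)`` (i.e. ``data[k, j, i]``) is
  ``origin + (i, j, k) * voxel_size``.
* MRC files are written in MRC2014 mode 2 with axis order
  ``(mapc, mapr, maps) = (1, 2, 3)``; arbitrary axis permutations are
  accepted on read and folded back into the canonical ``(z, y, x)`` layout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from mapgan.errors import (
    EmptyModelError,
    MapFormatError,
    ModelParseError,
    UnsupportedModeError,
)

# ---------------------------------------------------------------------------
# periodic table (symbol -> atomic number), uppercase keys
# ---------------------------------------------------------------------------

_ELEMENTS = (
    "H HE LI BE B C N O F NE NA MG AL SI P S CL AR K CA SC TI V CR MN FE CO NI "
    "CU ZN GA GE AS SE BR KR RB SR Y ZR NB MO TC RU RH PD AG CD IN SN SB TE I "
    "XE CS BA LA CE PR ND PM SM EU GD TB DY HO ER TM YB LU HF TA W RE OS IR PT "
    "AU HG TL PB BI PO AT RN FR RA AC TH PA U NP PU AM CM BK CF ES FM MD NO LR "
    "RF DB SG BH HS MT DS RG CN NH FL MC LV TS OG"
).split()

ATOMIC_NUMBERS: dict[str, int] = {sym: z for z, sym in enumerate(_ELEMENTS, start=1)}


@dataclass(frozen=True)
class Atom:
    element: str
    atomic_number: int
    position: np.ndarray  # (3,) float64, Å, (x, y, z)
    occupancy: float = 1.0
    chain: str = ""
    residue: str = ""


@dataclass
class AtomicModel:
    """Heavy atoms of a molecular structure.

    Hydrogens are excluded on construction via :func:`read_model`; ``M`` is
    the heavy-atom count.
    """

    atoms: list[Atom] = field(default_factory=list)

    @property
    def M(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(M, 3) array of coordinates in (x, y, z) order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.position for a in self.atoms])

    @property
    def atomic_numbers(self) -> np.ndarray:
        return np.array([a.atomic_number for a in self.atoms], dtype=np.int64)

    @property
    def occupancies(self) -> np.ndarray:
        return np.array([a.occupancy for a in self.atoms])

    def translated(self, shift: Sequence[float]) -> "AtomicModel":
        shift = np.asarray(shift, dtype=float)
        return AtomicModel(
            [replace(a, position=a.position + shift) for a in self.atoms]
        )


@dataclass
class DensityMap:
    """A 3-D scalar volume on a regular grid.

    ``data`` is indexed ``(z, y, x)``; ``voxel_size`` and ``origin`` are in
    (x, y, z) order.  ``origin`` is the world position of the *center* of
    voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(self.data, dtype=np.float32)
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3-D, got ndim={self.data.ndim}")
        if not np.all(self.voxel_size > 0):
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # (nz, ny, nx)

    def voxel_to_world(self, kji: np.ndarray) -> np.ndarray:
        """World coordinates of voxel indices given as (k, j, i) rows."""
        kji = np.atleast_2d(kji)
        ijk = kji[:, ::-1]  # -> (i, j, k) = (x, y, z) index order
        return self.origin + ijk * self.voxel_size

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional (k, j, i) indices of world points given as (x, y, z) rows."""
        xyz = np.atleast_2d(xyz)
        ijk = (xyz - self.origin) / self.voxel_size
        return ijk[:, ::-1]

    def copy(self) -> "DensityMap":
        return DensityMap(
            self.data.copy(), self.voxel_size.copy(), self.origin.copy(), self.label
        )


# ---------------------------------------------------------------------------
# MRC2014 reader / writer
# ---------------------------------------------------------------------------

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


def read_map(path: str | Path) -> DensityMap:
    """Read an MRC2014 volume, normalising to the canonical (z, y, x) layout.

    Axis order is folded back from ``(mapc, mapr, maps)``; when the origin
    record is all-zero the origin is derived from the start indices
    (``nstart`` × voxel size).
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MapFormatError(
            f"{path}: file is {len(raw)} bytes, smaller than the 1024-byte header"
        )
    hdr = raw[:_HEADER_SIZE]

    nx, ny, nz, mode = struct.unpack_from("<4i", hdr, 0)
    nxstart, nystart, nzstart = struct.unpack_from("<3i", hdr, 16)
    mx, my, mz = struct.unpack_from("<3i", hdr, 28)
    cella = struct.unpack_from("<3f", hdr, 40)
    mapc, mapr, maps = struct.unpack_from("<3i", hdr, 64)
    nsymbt = struct.unpack_from("<i", hdr, 92)[0]
    origin_rec = np.array(struct.unpack_from("<3f", hdr, 196), dtype=np.float64)

    if min(nx, ny, nz) <= 0:
        raise MapFormatError(f"{path}: non-positive dimensions nx/ny/nz=({nx},{ny},{nz})")
    if mode not in _MODE_DTYPES:
        raise UnsupportedModeError(
            f"{path}: mode {mode} is not a scalar volume mode (supported: 0, 1, 2, 6)"
        )
    if sorted((mapc, mapr, maps)) != [1, 2, 3]:
        raise MapFormatError(
            f"{path}: (mapc, mapr, maps)=({mapc},{mapr},{maps}) is not a "
            "permutation of (1, 2, 3)"
        )
    if min(mx, my, mz) <= 0:
        raise MapFormatError(f"{path}: non-positive sampling mx/my/mz=({mx},{my},{mz})")
    if any(c <= 0 for c in cella):
        raise MapFormatError(f"{path}: non-positive cell dimensions cella={cella}")

    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    n_values = nx * ny * nz
    offset = _HEADER_SIZE + max(nsymbt, 0)
    expected = offset + n_values * dtype.itemsize
    if len(raw) < expected:
        raise MapFormatError(
            f"{path}: truncated data block, expected {expected} bytes, got {len(raw)}"
        )
    flat = np.frombuffer(raw, dtype=dtype, count=n_values, offset=offset)
    stored = flat.reshape(nz, ny, nx)  # (sections, rows, columns)

    # storage dims (sec,row,col) hold world axes (maps, mapr, mapc); build the
    # transpose that yields canonical (z, y, x)
    axis_of_dim = (maps, mapr, mapc)  # world axis id (1=x,2=y,3=z) per stored dim
    perm = tuple(axis_of_dim.index(a) for a in (3, 2, 1))
    data = np.ascontiguousarray(stored.transpose(perm), dtype=np.float32)

    voxel = np.array(cella, dtype=np.float64) / np.array([mx, my, mz], dtype=np.float64)

    if np.any(origin_rec != 0.0):
        origin = origin_rec
    else:
        nstart_world = np.zeros(3)
        for start, axis in zip((nxstart, nystart, nzstart), (mapc, mapr, maps)):
            nstart_world[axis - 1] = start
        origin = nstart_world * voxel

    return DensityMap(data, voxel, origin, label=path.name)


def write_map(density_map: DensityMap, path: str | Path) -> None:
    """Write an MRC2014 mode-2 file with (mapc, mapr, maps) = (1, 2, 3)."""
    m = density_map
    nz, ny, nx = m.shape
    data = np.ascontiguousarray(m.data, dtype="<f4")

    hdr = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", hdr, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", hdr, 16, 0, 0, 0)  # nstart
    struct.pack_into("<3i", hdr, 28, nx, ny, nz)  # mx, my, mz
    cella = (m.voxel_size * np.array([nx, ny, nz])).astype(np.float32)
    struct.pack_into("<3f", hdr, 40, *cella)
    struct.pack_into("<3f", hdr, 52, 90.0, 90.0, 90.0)  # cellb
    struct.pack_into("<3i", hdr, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", hdr, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", hdr, 88, 1)  # ispg: volume
    struct.pack_into("<i", hdr, 92, 0)  # nsymbt
    struct.pack_into("<3f", hdr, 196, *m.origin.astype(np.float32))
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian machine stamp
    struct.pack_into("<f", hdr, 216, float(data.std()))
    struct.pack_into("<i", hdr, 220, 1)
    label = (m.label or "mapgan")[:80].ljust(80).encode("ascii", "replace")
    hdr[224 : 224 + 80] = label

    with open(path, "wb") as fh:
        fh.write(bytes(hdr))
        fh.write(data.tobytes())


# ---------------------------------------------------------------------------
# atomic models
# ---------------------------------------------------------------------------


def read_model(path: str | Path) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Hydrogens are excluded.  Alternate locations keep the highest-occupancy
    conformer (ties: first in file order).  Element symbols are resolved to
    atomic numbers through a built-in periodic table.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            import biotite.structure.io.pdbx as pdbx

            cif = pdbx.CIFFile.read(str(path))
            arr = pdbx.get_structure(
                cif, model=1, extra_fields=["occupancy"], altloc="occupancy"
            )
        else:
            import biotite.structure.io.pdb as pdb

            pdb_file = pdb.PDBFile.read(str(path))
            arr = pdb.get_structure(
                pdb_file, model=1, extra_fields=["occupancy"], altloc="occupancy"
            )
    except Exception as exc:  # biotite raises a mix of exception types
        raise ModelParseError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        symbol = str(arr.element[i]).strip().upper()
        if not symbol:
            raise ModelParseError(f"{path}: atom {i} has an empty element symbol")
        z = ATOMIC_NUMBERS.get(symbol)
        if z is None:
            raise ModelParseError(f"{path}: unknown element symbol '{symbol}'")
        if z == 1:  # hydrogen exclusion
            continue
        coord = np.asarray(arr.coord[i], dtype=np.float64)
        if not np.all(np.isfinite(coord)):
            raise ModelParseError(f"{path}: non-finite coordinates for atom {i}")
        atoms.append(
            Atom(
                element=symbol,
                atomic_number=z,
                position=coord,
                occupancy=float(arr.occupancy[i]),
                chain=str(arr.chain_id[i]),
                residue=f"{arr.res_name[i]}{arr.res_id[i]}",
            )
        )
    if not atoms:
        raise EmptyModelError(f"{path}: no heavy atoms found")
    return AtomicModel(atoms)


# ---------------------------------------------------------------------------
# grid primitives
# ---------------------------------------------------------------------------


def resample(density_map: DensityMap, target_voxel: Sequence[float]) -> DensityMap:
    """Trilinearly resample onto a grid with the given voxel size.

    The output grid starts at the input origin and has
    ``floor(extent / target_voxel) + 1`` samples per axis, where extent is
    the center-to-center span of the input grid.  Samples falling outside the
    input grid evaluate to 0.
    """
    target = np.asarray(target_voxel, dtype=np.float64).reshape(3)
    if not np.all(target > 0):
        raise ValueError(f"target voxel size must be positive, got {target}")

    nz, ny, nx = density_map.shape
    extent = (np.array([nx, ny, nz]) - 1) * density_map.voxel_size  # (x, y, z)
    # tolerance absorbs float fuzz when extent is an exact multiple
    n_out = np.floor(extent / target + 1e-9).astype(int) + 1  # (x, y, z)

    # output index grids in input fractional-index space, per axis
    scale = target / density_map.voxel_size  # output step in input index units
    zi = np.arange(n_out[2]) * scale[2]
    yi = np.arange(n_out[1]) * scale[1]
    xi = np.arange(n_out[0]) * scale[0]
    coords = np.stack(np.meshgrid(zi, yi, xi, indexing="ij"))
    out = map_coordinates(
        density_map.data.astype(np.float64), coords, order=1, mode="constant", cval=0.0
    )
    return DensityMap(
        out.astype(np.float32), target, density_map.origin.copy(), density_map.label
    )


def minmax_normalize(density_map: DensityMap) -> DensityMap:
    """Rescale voxel values to [0, 1]; a constant map becomes all zeros."""
    data = density_map.data
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return DensityMap(
        out, density_map.voxel_size.copy(), density_map.origin.copy(), density_map.label
    )
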