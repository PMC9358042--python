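"""Density maps on regular orthogonal grids, MRC/CCP4 I/O, and fit scores.

A :class:`DensityMap` is a 3D voxel grid of density values with a physical
origin and voxel size, both in Angstroms.  The value array is indexed
``values[ix, iy, iz]`` and a voxel *center* sits at
``origin + index * voxel_size`` (grid-node convention; there is no half-voxel
offset).

Three scores quantify how well a subunit density ``Y`` matches an
experimental (or simulated) complex density ``X`` on a voxel region:

* ``ccc``  -- plain cross-correlation  sum(X*Y)/sqrt(sum(X^2) sum(Y^2)),
* ``pccc`` -- Pearson (mean-centered) cross-correlation,
* ``overlap`` -- |X∩Y| / |Y| between two contour masks, normalized by the
  subunit mask Y.

Map simulation places an isotropic 3D Gaussian kernel on every atom; the
nominal resolution is interpreted as the kernel FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "DensityMap",
    "ContourMask",
    "MapFormatError",
    "UndefinedScoreError",
    "read_map",
    "write_map",
    "simulate_map",
    "contour_mask",
    "ccc",
    "pccc",
    "overlap",
    "resolution_to_sigma",
    "ATOMIC_MASSES",
]

# heavy-atom masses (Da); hydrogens are dropped before simulation
ATOMIC_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
}
_DEFAULT_MASS = 12.011


class MapFormatError(ValueError):
    """Raised for malformed or unsupported map files."""


class UndefinedScoreError(ValueError):
    """Raised when a correlation/overlap score is mathematically undefined."""


@dataclass
class DensityMap:
    """A 3D density grid with physical placement.

    Attributes
    ----------
    origin : (3,) float array, Å — position of voxel (0,0,0).
    voxel_size : (3,) float array, Å per voxel along x, y, z.
    values : float array of shape ``dims`` indexed [ix, iy, iz].
    """

    origin: np.ndarray
    voxel_size: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + np.arange(n) * self.voxel_size[axis]

    def copy(self) -> "DensityMap":
        return DensityMap(self.origin.copy(), self.voxel_size.copy(), self.values.copy())


@dataclass
class ContourMask:
    """Boolean occupancy mask sharing a parent map's geometry."""

    origin: np.ndarray
    voxel_size: np.ndarray
    mask: np.ndarray
    level: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3D array")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


def _check_orthogonal(cell: gemmi.UnitCell, path: str) -> None:
    for name, ang in (("alpha", cell.alpha), ("beta", cell.beta), ("gamma", cell.gamma)):
        if abs(ang - 90.0) > 1e-3:
            raise MapFormatError(
                f"{path}: non-orthogonal unit cell ({name}={ang:g}°) is not supported"
            )


def read_map(path: str) -> DensityMap:
    """Read an MRC/CCP4 map, normalizing axis order to the canonical X-fast layout.

    Honors MAPC/MAPR/MAPS axis permutations, the ORIGIN header record and
    NX/NY/NZSTART offsets.  Raises :class:`MapFormatError` for files that are
    not MRC maps or that use a non-orthogonal cell.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except RuntimeError as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    _check_orthogonal(m.grid.unit_cell, str(path))
    # reorder data so that axis 0 = X (crystallographic a), 1 = Y, 2 = Z
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    mx, my, mz = (m.header_i32(8), m.header_i32(9), m.header_i32(10))
    if mx <= 0 or my <= 0 or mz <= 0:
        raise MapFormatError(f"{path}: non-positive sampling counts MX/MY/MZ")
    voxel = np.array([cell.a / mx, cell.b / my, cell.c / mz])
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    nstart = np.array([m.header_i32(w) for w in (5, 6, 7)], dtype=float)
    origin = origin + nstart * voxel
    if not np.all(np.isfinite(values)):
        raise MapFormatError(f"{path}: non-finite density values")
    return DensityMap(origin=origin, voxel_size=voxel, values=values)


def write_map(dmap: DensityMap, path: str) -> None:
    """Write a DensityMap as a standard MRC2014 file (MAPC/MAPR/MAPS = 1,2,3)."""
    nx, ny, nz = dmap.dims
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(
        nx * dmap.voxel_size[0], ny * dmap.voxel_size[1], nz * dmap.voxel_size[2],
        90.0, 90.0, 90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    try:
        m.write_ccp4_map(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc


def resolution_to_sigma(resolution: float) -> float:
    """Gaussian kernel width for a nominal resolution treated as FWHM."""
    return resolution / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def simulate_map(
    atoms,
    resolution: float = 10.0,
    voxel_size: float = 1.0,
    padding: float | None = None,
    origin: np.ndarray | None = None,
    dims: tuple[int, int, int] | None = None,
) -> DensityMap:
    """Simulate a density map from atoms as a sum of normalized Gaussian kernels.

    Parameters
    ----------
    atoms : iterable of (element, xyz, weight) or an (n, 3) coordinate array.
        When a bare coordinate array is given every atom has unit weight.
    resolution : nominal resolution in Å, interpreted as the kernel FWHM.
    voxel_size : isotropic grid spacing in Å.
    padding : margin added around the atom bounding box on every side, Å.
        Defaults to ``2 * resolution`` which conserves >99% of the kernel mass.
    origin, dims : optional explicit grid placement overriding the automatic
        bounding box (used to rasterize a subunit onto a prescribed grid).

    The kernel for an atom of weight w is
    ``w * (2 pi sigma^2)^{-3/2} exp(-r^2 / (2 sigma^2)) * voxel_volume`` with
    ``sigma = resolution / (2 sqrt(2 ln 2))``, so the discrete density sum
    approximates the total atom weight.
    """
    if resolution <= 0 or voxel_size <= 0:
        raise ValueError("resolution and voxel_size must be positive")
    coords, weights = _atoms_to_arrays(atoms)
    if len(coords) == 0:
        raise ValueError("cannot simulate a map from zero atoms")
    if padding is None:
        padding = 2.0 * resolution
    sigma = resolution_to_sigma(resolution)
    vox = float(voxel_size)

    if origin is None:
        lo = coords.min(axis=0) - padding
        # snap origin to the voxel lattice so integer-voxel atom shifts
        # translate the density array exactly
        origin = np.floor(lo / vox) * vox
    else:
        origin = np.asarray(origin, dtype=float).reshape(3)
    if dims is None:
        hi = coords.max(axis=0) + padding
        dims = tuple(int(np.ceil((h - o) / vox)) + 1 for h, o in zip(hi, origin))

    values = np.zeros(dims, dtype=float)
    # kernel support radius: 4 sigma keeps >99.99% of the mass
    r_vox = int(np.ceil(4.0 * sigma / vox))
    norm = (2.0 * np.pi * sigma * sigma) ** -1.5 * vox**3
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for (x, y, z), w in zip(coords, weights):
        centers = []
        slices = []
        ok = True
        for axis, c in enumerate((x, y, z)):
            ic = (c - origin[axis]) / vox
            i0 = max(int(np.floor(ic)) - r_vox, 0)
            i1 = min(int(np.ceil(ic)) + r_vox + 1, dims[axis])
            if i1 <= i0:
                ok = False
                break
            g = np.arange(i0, i1) * vox + origin[axis]
            centers.append(np.exp(-((g - c) ** 2) * inv2s2))
            slices.append(slice(i0, i1))
        if not ok:
            continue
        gx, gy, gz = centers
        values[tuple(slices)] += (w * norm) * (
            gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return DensityMap(origin=origin, voxel_size=np.full(3, vox), values=values)


def _atoms_to_arrays(atoms) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(atoms, np.ndarray) and atoms.ndim == 2 and atoms.shape[1] == 3:
        return atoms.astype(float), np.ones(len(atoms))
    coords = []
    weights = []
    for entry in atoms:
        element, xyz, *rest = entry
        w = rest[0] if rest else ATOMIC_MASSES.get(str(element).upper(), _DEFAULT_MASS)
        coords.append(np.asarray(xyz, dtype=float))
        weights.append(float(w))
    if not coords:
        return np.zeros((0, 3)), np.zeros(0)
    return np.stack(coords), np.asarray(weights)


def contour_mask(dmap: DensityMap, level: float) -> ContourMask:
    """Threshold a map at ``level``: mask is true where density >= level."""
    if not np.isfinite(level):
        raise ValueError("contour level must be finite")
    return ContourMask(
        origin=dmap.origin,
        voxel_size=dmap.voxel_size,
        mask=dmap.values >= level,
        level=float(level),
    )


def _check_geometry(a, b) -> None:
    if a.dims != b.dims:
        raise ValueError(f"grid dimension mismatch: {a.dims} vs {b.dims}")


def ccc(x: DensityMap, y: DensityMap, region: ContourMask | None = None) -> float:
    """Cross-correlation coefficient sum(XY)/sqrt(sum(X^2) sum(Y^2)) on a region."""
    _check_geometry(x, y)
    sel = slice(None) if region is None else region.mask
    xs = x.values[sel].ravel()
    ys = y.values[sel].ravel()
    nx2 = float(xs @ xs)
    ny2 = float(ys @ ys)
    if nx2 == 0.0 or ny2 == 0.0:
        raise UndefinedScoreError("cross-correlation undefined: zero-norm density on region")
    return float(xs @ ys) / np.sqrt(nx2 * ny2)


def pccc(x: DensityMap, y: DensityMap, region: ContourMask | None = None) -> float:
    """Pearson cross-correlation (mean-centered CCC) on a region."""
    _check_geometry(x, y)
    sel = slice(None) if region is None else region.mask
    xs = x.values[sel].ravel().astype(float)
    ys = y.values[sel].ravel().astype(float)
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    nx2 = float(xs @ xs)
    ny2 = float(ys @ ys)
    if nx2 == 0.0 or ny2 == 0.0:
        raise UndefinedScoreError("Pearson correlation undefined: constant density on region")
    return float(xs @ ys) / np.sqrt(nx2 * ny2)


def overlap(x: ContourMask, y: ContourMask) -> float:
    """Fraction |X∩Y| / |Y| of subunit-mask voxels covered by the map mask."""
    _check_geometry(x, y)
    ny = y.count()
    if ny == 0:
        raise UndefinedScoreError("overlap undefined: empty subunit mask Y")
    return float(np.count_nonzero(x.mask & y.mask)) / ny
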