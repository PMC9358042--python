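"""Per-subunit exhaustive 6D pose search.

For each rotation in an orientation set, the rotated subunit is rasterized to
a density map at the experimental map's voxel size and the best integer-voxel
translation is found by FFT cross-correlation.  The per-shift score is the
unweighted sum of a cross-correlation term (CCC for experimental maps, PCCC
for simulated maps) and the overlap fraction OV.

The summation region for the correlation terms at a shift is the rotated
subunit's own density footprint (voxels above a small fraction of its density
maximum); the experimental density is pre-thresholded at the working contour
level and treated as zero outside its grid.

Retained poses must overlap the map contour by at least 50%, are greedily
clustered so transformed centroids stay >= 8 Å apart, and at most the top 100
poses per subunit are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .rigid_structures import RigidTransform, RotationSet, Subunit, centroid, quat_to_matrix
from .voxel_maps import ContourMask, DensityMap, resolution_to_sigma, simulate_map

__all__ = [
    "Pose",
    "PoseSet",
    "TranslationScanner",
    "EmptyPoseSetError",
    "scan_translations",
    "filter_overlap",
    "cluster_poses",
    "search_subunit",
    "rasterize_subunit",
    "suggest_contour_level",
    "DEFAULT_OVERLAP_CUTOFF",
    "DEFAULT_CLUSTER_RADIUS",
    "DEFAULT_MAX_POSES",
    "DEFAULT_FOOTPRINT_FRACTION",
]

DEFAULT_OVERLAP_CUTOFF = 0.5
DEFAULT_CLUSTER_RADIUS = 8.0
DEFAULT_MAX_POSES = 100
DEFAULT_FOOTPRINT_FRACTION = 0.03


class EmptyPoseSetError(RuntimeError):
    """No pose survived the overlap filter for a subunit."""


@dataclass
class Pose:
    """One candidate rigid placement of a subunit with its fit scores."""

    subunit_id: str
    transform: RigidTransform
    cc: float
    ov: float
    rotation_index: int = -1

    @property
    def fit_score(self) -> float:
        return self.cc + self.ov


@dataclass
class PoseSet:
    """Retained candidate poses of one subunit, sorted by descending fit score."""

    subunit_id: str
    poses: list

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    def __getitem__(self, i):
        return self.poses[i]


def suggest_contour_level(dmap: DensityMap, mass_fraction: float = 0.95) -> float:
    """Density level whose super-level set holds ``mass_fraction`` of the total mass.

    Serves as the "recommended" contour level for simulated maps, where no
    depositor-recommended threshold exists.
    """
    v = np.sort(dmap.values.ravel())[::-1]
    cum = np.cumsum(v)
    total = cum[-1]
    if total <= 0:
        return 0.0
    k = int(np.searchsorted(cum, mass_fraction * total))
    return float(v[min(k, len(v) - 1)])


def rasterize_subunit(
    s: Subunit,
    rotation_q: np.ndarray,
    resolution: float,
    voxel_size: float,
    box_dims: tuple[int, int, int] | None = None,
    padding: float | None = None,
) -> DensityMap:
    """Simulate the density of a subunit rotated about its Cα centroid.

    The grid is a cube centered on the (rotation-invariant) centroid with its
    origin snapped to the voxel lattice, so all rotations of one subunit share
    identical grid dims — a prerequisite for reusing the experimental-map FFTs
    across rotations.
    """
    c0 = centroid(s)
    R = quat_to_matrix(rotation_q)
    rotated = (s.coords - c0) @ R.T + c0
    if padding is None:
        padding = resolution
    if box_dims is None:
        r_max = float(np.max(np.linalg.norm(s.coords - c0, axis=1)))
        half = r_max + padding
        n = int(np.ceil(2 * half / voxel_size)) + 1
        box_dims = (n, n, n)
    half_extent = (np.asarray(box_dims) - 1) * voxel_size / 2.0
    origin = np.floor((c0 - half_extent) / voxel_size) * voxel_size
    masses = [
        ("X", xyz, w)
        for xyz, w in zip(rotated, _atom_weights(s))
    ]
    return simulate_map(masses, resolution=resolution, voxel_size=voxel_size,
                        origin=origin, dims=tuple(box_dims))


def _atom_weights(s: Subunit) -> np.ndarray:
    from .voxel_maps import ATOMIC_MASSES, _DEFAULT_MASS

    return np.array([ATOMIC_MASSES.get(e.upper(), _DEFAULT_MASS) for e in s.elements])


def subunit_box_dims(s: Subunit, voxel_size: float, resolution: float,
                     padding: float | None = None) -> tuple[int, int, int]:
    """Fixed cubic grid dims that hold the subunit under any rotation."""
    if padding is None:
        padding = resolution
    c0 = centroid(s)
    r_max = float(np.max(np.linalg.norm(s.coords - c0, axis=1)))
    n = int(np.ceil(2 * (r_max + padding) / voxel_size)) + 1
    return (n, n, n)


class TranslationScanner:
    """FFT translational scan of a subunit map against an experimental map.

    Precomputes the experimental-side transforms once; each rotation then
    costs two forward and three-to-four inverse FFTs.  Scores are evaluated
    for every integer-voxel shift of the subunit grid relative to the
    experimental grid (full linear correlation range, zero-padded, so there
    is no wrap-around aliasing).
    """

    def __init__(
        self,
        exp_map: DensityMap,
        exp_contour: ContourMask,
        sub_dims: tuple[int, int, int],
        map_kind: str = "experimental",
    ):
        if map_kind not in ("experimental", "simulated"):
            raise ValueError("map_kind must be 'experimental' or 'simulated'")
        self.map_kind = map_kind
        self.exp_map = exp_map
        self.exp_contour = exp_contour
        self.sub_dims = tuple(sub_dims)
        nx = np.asarray(exp_map.dims)
        my = np.asarray(self.sub_dims)
        self.pad = tuple(sfft.next_fast_len(int(n + m - 1), real=True)
                         for n, m in zip(nx, my))
        x = np.where(exp_contour.mask, exp_map.values, 0.0)
        self.x_thresholded = x
        xm = exp_contour.mask.astype(float)
        self.fx = sfft.rfftn(x, s=self.pad)
        self.fx2 = sfft.rfftn(x * x, s=self.pad)
        self.fmask = sfft.rfftn(xm, s=self.pad)
        # index vectors mapping circular-correlation output to linear shifts
        self.shifts = [np.arange(-(m - 1), n) for n, m in zip(nx, my)]
        self.shift_index = [s % p for s, p in zip(self.shifts, self.pad)]

    def _corr(self, f_kernel: np.ndarray, f_signal: np.ndarray) -> np.ndarray:
        full = sfft.irfftn(f_signal * np.conj(f_kernel), s=self.pad)
        ix, iy, iz = self.shift_index
        return full[np.ix_(ix, iy, iz)]

    def score_all(self, sub_map: DensityMap, footprint_fraction: float = DEFAULT_FOOTPRINT_FRACTION):
        """Score every shift; returns (cc, ov, shifts) arrays.

        Shift (i,j,k) of the returned arrays corresponds to displacing the
        subunit grid by ``shifts[0][i], shifts[1][j], shifts[2][k]`` voxels
        relative to the experimental grid.
        """
        if tuple(sub_map.dims) != self.sub_dims:
            raise ValueError("subunit map dims do not match scanner configuration")
        y = sub_map.values
        support = y >= footprint_fraction * y.max()
        n_sup = int(support.sum())
        if n_sup == 0:
            raise ValueError("subunit map has empty density footprint")
        ys = np.where(support, y, 0.0)
        s_float = support.astype(float)
        f_ys = sfft.rfftn(ys, s=self.pad)
        f_s = sfft.rfftn(s_float, s=self.pad)

        num_xy = self._corr(f_ys, self.fx)
        sum_x2 = np.maximum(self._corr(f_s, self.fx2), 0.0)
        n_ov = np.rint(self._corr(f_s, self.fmask))
        ov = np.clip(n_ov / n_sup, 0.0, 1.0)

        sum_y2 = float(ys.ravel() @ ys.ravel())
        # FFT roundoff turns exact zeros into ~1e-12 residue; shifts whose
        # denominator is below a relative floor are undefined, not scored
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.map_kind == "experimental":
                valid = sum_x2 > 1e-9 * max(sum_x2.max(), 1e-300)
                cc = num_xy / np.sqrt(sum_x2 * sum_y2)
            else:
                sum_x = self._corr(f_s, self.fx)
                y_mean = ys.sum() / n_sup
                sum_y2c = sum_y2 - n_sup * y_mean**2
                cov = num_xy - y_mean * sum_x
                var_x = np.maximum(sum_x2 - sum_x**2 / n_sup, 0.0)
                valid = var_x > 1e-9 * max(var_x.max(), 1e-300)
                cc = cov / np.sqrt(var_x * sum_y2c)
        cc = np.where(valid & np.isfinite(cc), cc, -np.inf)
        return cc, ov, self.shifts

    def best_shift(self, sub_map: DensityMap,
                   footprint_fraction: float = DEFAULT_FOOTPRINT_FRACTION):
        """Return (shift_voxels, cc, ov) of the best-scoring translation.

        Ties in the combined score are broken by lexicographic (z, y, x)
        order of the shift indices, which makes the scan deterministic.
        """
        cc, ov, shifts = self.score_all(sub_map, footprint_fraction)
        score = cc + ov
        # first-occurrence argmax in (z, y, x)-major order
        flat = np.argmax(score.transpose(2, 1, 0))
        kz, ky, kx = np.unravel_index(flat, score.transpose(2, 1, 0).shape)
        shift = np.array([shifts[0][kx], shifts[1][ky], shifts[2][kz]])
        return shift, float(cc[kx, ky, kz]), float(ov[kx, ky, kz])


def scan_translations(
    exp_map: DensityMap,
    exp_contour: ContourMask,
    sub_map: DensityMap,
    map_kind: str = "experimental",
    footprint_fraction: float = DEFAULT_FOOTPRINT_FRACTION,
):
    """One-shot FFT translational scan; see :class:`TranslationScanner`."""
    scanner = TranslationScanner(exp_map, exp_contour, sub_map.dims, map_kind)
    return scanner.best_shift(sub_map, footprint_fraction)


def filter_overlap(poses: list, cutoff: float = DEFAULT_OVERLAP_CUTOFF) -> list:
    """Keep exactly the poses with overlap >= cutoff (inclusive), in order."""
    return [p for p in poses if p.ov >= cutoff]


def cluster_poses(poses: list, subunit: Subunit,
                  radius: float = DEFAULT_CLUSTER_RADIUS) -> list:
    """Greedy score-descending clustering of poses by transformed centroid.

    A pose is kept iff its transformed Cα centroid lies at least ``radius``
    Å from every already-kept pose's centroid.  Output is sorted by
    descending fit score; ties preserve input (rotation-index) order.
    """
    if not poses:
        return []
    c0 = centroid(subunit)
    order = sorted(range(len(poses)), key=lambda i: (-poses[i].fit_score, i))
    centers = np.array([poses[i].transform.apply(c0[None, :])[0] for i in order])
    kept_idx: list[int] = []
    kept_centers: list[np.ndarray] = []
    for row, i in enumerate(order):
        c = centers[row]
        if kept_centers:
            d = np.linalg.norm(np.asarray(kept_centers) - c, axis=1)
            if np.any(d < radius):
                continue
        kept_idx.append(i)
        kept_centers.append(c)
    return [poses[i] for i in kept_idx]


def search_subunit(
    exp_map: DensityMap,
    exp_contour: ContourMask,
    s: Subunit,
    rotations: RotationSet,
    map_kind: str = "experimental",
    resolution: float = 10.0,
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF,
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS,
    max_poses: int = DEFAULT_MAX_POSES,
    footprint_fraction: float = DEFAULT_FOOTPRINT_FRACTION,
) -> PoseSet:
    """Exhaustive 6D search of one subunit against the experimental map.

    For every rotation the best translation is found by FFT; poses below the
    overlap cutoff are discarded, the survivors are clustered at
    ``cluster_radius`` and at most ``max_poses`` are retained.
    """
    vox = float(exp_map.voxel_size[0])
    if not np.allclose(exp_map.voxel_size, vox):
        raise ValueError("anisotropic voxel sizes are not supported in the search")
    dims = subunit_box_dims(s, vox, resolution)
    scanner = TranslationScanner(exp_map, exp_contour, dims, map_kind)
    c0 = centroid(s)
    poses: list[Pose] = []
    for ridx, q in enumerate(rotations):
        sub_map = rasterize_subunit(s, q, resolution, vox, box_dims=dims)
        shift, cc, ov = scanner.best_shift(sub_map, footprint_fraction)
        if not np.isfinite(cc):
            continue
        # physical displacement of the rotated subunit grid
        d = (exp_map.origin + shift * exp_map.voxel_size) - sub_map.origin
        R = quat_to_matrix(q)
        t = c0 - R @ c0 + d
        poses.append(Pose(s.id, RigidTransform(q, t), cc, ov, rotation_index=ridx))
    poses = filter_overlap(poses, overlap_cutoff)
    if not poses:
        raise EmptyPoseSetError(
            f"no pose of subunit {s.id!r} overlaps the map contour by >= {overlap_cutoff:.0%}"
        )
    poses = cluster_poses(poses, s, cluster_radius)
    return PoseSet(s.id, poses[:max_poses])
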