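"""Density map I/O, simulation, contouring, and the three fit scores."""

import struct

import numpy as np
import pytest

import mrffit as mf
from mrffit.voxel_maps import MapFormatError, UndefinedScoreError

from conftest import line_map


def random_map(rng, dims=(6, 7, 8)):
    return mf.DensityMap(origin=rng.normal(size=3), voxel_size=[1.5, 2.0, 1.0],
                         values=rng.random(dims))


class TestMapIO:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        m = random_map(rng)
        path = tmp_path / "m.mrc"
        mf.write_map(m, path)
        m2 = mf.read_map(path)
        assert m2.dims == m.dims
        np.testing.assert_allclose(m2.origin, m.origin, atol=1e-5)
        np.testing.assert_allclose(m2.voxel_size, m.voxel_size, rtol=1e-6)
        np.testing.assert_allclose(m2.values, m.values, rtol=1e-6)
        # density sum preserved to relative 1e-6
        assert m2.values.sum() == pytest.approx(m.values.sum(), rel=1e-6)

    def test_declared_dims(self, tmp_path):
        m = mf.DensityMap([0, 0, 0], [1, 1, 1], np.ones((8, 8, 8)))
        path = tmp_path / "c.mrc"
        mf.write_map(m, path)
        assert mf.read_map(path).dims == (8, 8, 8)

    def test_permuted_axis_order_is_canonicalized(self, tmp_path):
        """A file stored with MAPC/MAPR/MAPS = 2,1,3 reads back to the same
        canonical X-fast grid as the standard layout."""
        rng = np.random.default_rng(2)
        arr = rng.random((4, 5, 6)).astype(np.float32)
        vox = (1.5, 2.0, 2.5)
        path = tmp_path / "perm.mrc"
        _write_raw_mrc_permuted(path, arr, vox, origin=(1.0, 2.0, 3.0))
        m = mf.read_map(path)
        assert m.dims == (4, 5, 6)
        np.testing.assert_allclose(m.values, arr, rtol=1e-6)
        np.testing.assert_allclose(m.origin, [1.0, 2.0, 3.0], atol=1e-5)
        np.testing.assert_allclose(m.voxel_size, vox, rtol=1e-5)

    def test_wrong_magic_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.mrc"
        path.write_bytes(b"this is not a density map" * 100)
        with pytest.raises(MapFormatError):
            mf.read_map(path)


def _write_raw_mrc_permuted(path, arr, vox, origin):
    """Independent minimal MRC writer with column axis = Y (MAPC=2)."""
    hdr = bytearray(1024)

    def seti(w, v):
        struct.pack_into("<i", hdr, (w - 1) * 4, v)

    def setf(w, v):
        struct.pack_into("<f", hdr, (w - 1) * 4, float(v))

    nx, ny, nz = arr.shape
    data = np.transpose(arr, (2, 0, 1))  # sections=Z, rows=X, cols=Y
    seti(1, ny), seti(2, nx), seti(3, nz)
    seti(4, 2)
    seti(8, nx), seti(9, ny), seti(10, nz)
    setf(11, nx * vox[0]), setf(12, ny * vox[1]), setf(13, nz * vox[2])
    setf(14, 90), setf(15, 90), setf(16, 90)
    seti(17, 2), seti(18, 1), seti(19, 3)
    setf(20, arr.min()), setf(21, arr.max()), setf(22, arr.mean())
    seti(23, 1)
    setf(50, origin[0]), setf(51, origin[1]), setf(52, origin[2])
    hdr[208:212] = b"MAP "
    hdr[212:216] = bytes([0x44, 0x44, 0, 0])
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(data.tobytes())


class TestSimulateMap:
    def test_single_atom_peak_at_grid_node(self):
        m = mf.simulate_map([("C", (10.0, 12.0, 8.0), 1.0)], resolution=6.0,
                            voxel_size=1.0)
        peak = np.unravel_index(np.argmax(m.values), m.dims)
        coord = m.origin + np.asarray(peak) * m.voxel_size
        np.testing.assert_allclose(coord, [10.0, 12.0, 8.0], atol=1e-9)

    def test_doubling_atoms_doubles_integral(self):
        atoms = [("C", (0.0, 0.0, 0.0), 2.0), ("N", (4.0, 1.0, -2.0), 1.0)]
        m1 = mf.simulate_map(atoms, resolution=8.0, voxel_size=1.0)
        m2 = mf.simulate_map(atoms * 2, resolution=8.0, voxel_size=1.0)
        assert m2.values.sum() == pytest.approx(2 * m1.values.sum(), rel=1e-9)

    def test_mass_conservation_within_one_percent(self):
        rng = np.random.default_rng(3)
        atoms = [("C", xyz, w) for xyz, w in
                 zip(rng.normal(scale=5, size=(30, 3)), rng.uniform(10, 20, 30))]
        total = sum(a[2] for a in atoms)
        m = mf.simulate_map(atoms, resolution=10.0, voxel_size=1.0, padding=20.0)
        assert m.values.sum() == pytest.approx(total, rel=0.01)

    def test_integer_voxel_translation_equivariance(self):
        atoms = [("C", (3.0, 4.0, 5.0), 1.0), ("O", (7.0, 4.0, 2.0), 2.0)]
        shift = np.array([3.0, -2.0, 5.0])  # integer multiples of the voxel
        m1 = mf.simulate_map(atoms, resolution=6.0, voxel_size=1.0, padding=10.0)
        moved = [(e, np.asarray(x) + shift, w) for e, x, w in atoms]
        m2 = mf.simulate_map(moved, resolution=6.0, voxel_size=1.0, padding=10.0)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-12)
        np.testing.assert_allclose(m2.origin - m1.origin, shift)

    def test_default_simulation_convention(self):
        import inspect

        sig = inspect.signature(mf.simulate_map)
        assert sig.parameters["resolution"].default == 10.0
        assert sig.parameters["voxel_size"].default == 1.0

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            mf.simulate_map([], resolution=10.0)


class TestContourMask:
    def test_extreme_levels(self):
        m = line_map([0.1, 0.4, 0.9])
        assert mf.contour_mask(m, -1.0).mask.all()
        assert not mf.contour_mask(m, 2.0).mask.any()

    def test_direct_thresholding(self):
        m = line_map([0.1, 0.4, 0.9])
        np.testing.assert_array_equal(
            mf.contour_mask(m, 0.4).mask.ravel(), [False, True, True]
        )

    def test_count_monotone_in_level(self):
        rng = np.random.default_rng(4)
        m = mf.DensityMap([0, 0, 0], [1, 1, 1], rng.random((5, 5, 5)))
        counts = [mf.contour_mask(m, lv).count() for lv in np.linspace(-0.1, 1.1, 13)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestScores:
    def test_ccc_self_is_one(self):
        rng = np.random.default_rng(5)
        x = random_map(rng)
        assert mf.ccc(x, x) == pytest.approx(1.0)
        # scaling Y by a positive constant keeps CCC at 1
        y = mf.DensityMap(x.origin, x.voxel_size, 3.7 * x.values)
        assert mf.ccc(x, y) == pytest.approx(1.0)

    def test_ccc_disjoint_supports(self):
        x = line_map([1.0, 1.0, 0.0, 0.0])
        y = line_map([0.0, 0.0, 1.0, 1.0])
        assert mf.ccc(x, y) == pytest.approx(0.0)

    def test_ccc_direct_value(self):
        assert mf.ccc(line_map([1, 2]), line_map([2, 1])) == pytest.approx(0.8)

    def test_ccc_symmetric(self):
        rng = np.random.default_rng(6)
        x, y = random_map(rng), random_map(rng)
        assert mf.ccc(x, y) == pytest.approx(mf.ccc(y, x))

    def test_ccc_zero_norm_error(self):
        with pytest.raises(UndefinedScoreError):
            mf.ccc(line_map([0, 0]), line_map([1, 2]))

    def test_pccc_self_and_anticorrelation(self):
        x = line_map([0.0, 1.0, 2.0, 5.0])
        assert mf.pccc(x, x) == pytest.approx(1.0)
        y = line_map([7.0 - v for v in [0.0, 1.0, 2.0, 5.0]])
        assert mf.pccc(x, y) == pytest.approx(-1.0)

    def test_pccc_direct_value(self):
        assert mf.pccc(line_map([0, 1, 2]), line_map([1, 0, 2])) == pytest.approx(0.5)

    def test_pccc_affine_invariance_and_range(self):
        rng = np.random.default_rng(7)
        x, y = random_map(rng), random_map(rng)
        r = mf.pccc(x, y)
        assert -1.0 <= r <= 1.0
        y2 = mf.DensityMap(y.origin, y.voxel_size, 2.5 * y.values + 11.0)
        assert mf.pccc(x, y2) == pytest.approx(r)

    def test_pccc_constant_map_error(self):
        with pytest.raises(UndefinedScoreError):
            mf.pccc(line_map([3, 3, 3]), line_map([1, 2, 3]))

    def test_overlap_examples(self):
        full = np.ones((10, 1, 1), dtype=bool)
        x = mf.ContourMask([0, 0, 0], [1, 1, 1], full.copy())
        assert mf.overlap(x, x) == 1.0
        a = np.zeros((10, 1, 1), bool)
        a[:3] = True
        b = np.zeros((10, 1, 1), bool)
        b[5:] = True
        assert mf.overlap(mf.ContourMask([0, 0, 0], [1, 1, 1], a),
                          mf.ContourMask([0, 0, 0], [1, 1, 1], b)) == 0.0

    def test_overlap_direct_count(self):
        xa = np.zeros((10, 1, 1), bool)
        xa[0:3] = True  # intersection = 3
        ya = np.zeros((10, 1, 1), bool)
        ya[0:6] = True  # |Y| = 6
        x = mf.ContourMask([0, 0, 0], [1, 1, 1], xa)
        y = mf.ContourMask([0, 0, 0], [1, 1, 1], ya)
        assert mf.overlap(x, y) == pytest.approx(0.5)
        # the numerator is a voxel count
        assert (mf.overlap(x, y) * y.count()) == pytest.approx(round(mf.overlap(x, y) * y.count()))

    def test_overlap_empty_y_error(self):
        x = mf.ContourMask([0, 0, 0], [1, 1, 1], np.ones((3, 1, 1), bool))
        y = mf.ContourMask([0, 0, 0], [1, 1, 1], np.zeros((3, 1, 1), bool))
        with pytest.raises(UndefinedScoreError):
            mf.overlap(x, y)
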