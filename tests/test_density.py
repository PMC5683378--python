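import numpy as np
import pytest

from fragfit.density import (
    DensityError,
    DensityMap,
    FilterParams,
    butterworth_lowpass,
    minimal_box,
    normalize_map,
    pearson_ccc,
    read_map,
    simulate_map,
    subtract_context,
    write_map,
)
from fragfit.synthetic_fixtures import (
    all_atom_coords,
    make_experimental_map,
    make_toy_gap,
)
from fragfit.density import default_box


def _random_map(rng, shape=(16, 16, 16), voxel=1.0, origin=(0, 0, 0)):
    return DensityMap(values=rng.normal(size=shape).astype(np.float32),
                      voxel_size=voxel, origin=np.array(origin, float))


class TestMrcIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        dmap = _random_map(rng, origin=(3.0, -2.5, 7.0))
        path = tmp_path / "m.mrc"
        write_map(dmap, path)
        back = read_map(path)
        np.testing.assert_array_equal(back.values, dmap.values)
        assert back.voxel_size == pytest.approx(dmap.voxel_size, abs=1e-6)
        np.testing.assert_allclose(back.origin, dmap.origin, atol=1e-5)

    def test_permuted_axes_normalized(self, tmp_path, rng):
        """A file stored with MAPC/MAPR/MAPS = 3,2,1 reads as its transpose."""
        import struct
        dmap = _random_map(rng, shape=(4, 6, 8))
        path = tmp_path / "a.mrc"
        write_map(dmap, path)
        data = bytearray(path.read_bytes())
        vol = np.frombuffer(bytes(data[1024:]), dtype="<f4").reshape(8, 6, 4)
        permuted = vol.transpose(2, 1, 0)  # storage order now z-fastest
        struct.pack_into("<3i", data, 0, 8, 6, 4)    # NC NR NS
        struct.pack_into("<3i", data, 64, 3, 2, 1)   # MAPC MAPR MAPS
        p2 = tmp_path / "b.mrc"
        p2.write_bytes(bytes(data[:1024]) + permuted.astype("<f4").tobytes())
        back = read_map(p2)
        np.testing.assert_array_equal(back.values, dmap.values)

    def test_truncated_file_rejected(self, tmp_path, rng):
        path = tmp_path / "t.mrc"
        write_map(_random_map(rng), path)
        (tmp_path / "trunc.mrc").write_bytes(path.read_bytes()[:700])
        with pytest.raises(DensityError):
            read_map(tmp_path / "trunc.mrc")

    def test_anisotropic_voxels_rejected(self, tmp_path, rng):
        import gemmi
        g = gemmi.FloatGrid(4, 4, 4)
        g.set_unit_cell(gemmi.UnitCell(4, 8, 4, 90, 90, 90))
        m = gemmi.Ccp4Map(); m.grid = g; m.update_ccp4_header()
        m.write_ccp4_map(str(tmp_path / "aniso.mrc"))
        with pytest.raises(DensityError, match="[Aa]nisotropic"):
            read_map(tmp_path / "aniso.mrc")


class TestSimulateMap:
    def test_single_atom_at_voxel_center(self):
        dmap = simulate_map(np.array([[3.0, 4.0, 5.0]]), 1.0, 4.0,
                            (np.zeros(3), (10, 10, 10)), filtered=False)
        assert dmap.values[3, 4, 5] == pytest.approx(1.0)
        assert dmap.values.sum() == pytest.approx(1.0)

    def test_shift_equivariance(self):
        a = simulate_map(np.array([[4.0, 4.0, 4.0]]), 1.0, 4.0,
                         (np.zeros(3), (16, 16, 16)))
        b = simulate_map(np.array([[4.0, 4.0, 7.0]]), 1.0, 4.0,
                         (np.zeros(3), (16, 16, 16)))
        np.testing.assert_allclose(np.roll(a.values, 3, axis=2), b.values,
                                   atol=1e-9)

    def test_mass_conserved_by_filtering(self, rng):
        coords = rng.uniform(4, 12, size=(30, 3))
        raw = simulate_map(coords, 1.0, 6.0, (np.zeros(3), (16, 16, 16)),
                           filtered=False)
        filt = simulate_map(coords, 1.0, 6.0, (np.zeros(3), (16, 16, 16)))
        assert filt.values.sum() == pytest.approx(raw.values.sum(), rel=1e-6)

    def test_atom_outside_box(self):
        with pytest.raises(DensityError):
            simulate_map(np.array([[50.0, 0.0, 0.0]]), 1.0, 4.0,
                         (np.zeros(3), (8, 8, 8)))
        dmap = simulate_map(np.array([[50.0, 0.0, 0.0], [4.0, 4.0, 4.0]]),
                            1.0, 4.0, (np.zeros(3), (8, 8, 8)), clip=True,
                            filtered=False)
        assert dmap.values.sum() == pytest.approx(1.0)


class TestButterworth:
    def test_constant_map_unchanged(self):
        dmap = DensityMap(np.full((16, 16, 16), 3.7), 1.0, np.zeros(3))
        out = butterworth_lowpass(dmap, FilterParams(4.0, order=8))
        np.testing.assert_allclose(out.values, dmap.values, atol=1e-9)

    @pytest.mark.parametrize("order", [2, 4, 8])
    def test_sinusoid_at_cutoff_scaled_by_sqrt_half(self, order):
        n, voxel, k = 32, 1.0, 4
        cutoff_res = n * voxel / k  # places f_c exactly on lattice frequency k
        x = np.arange(n)
        probe = np.sin(2 * np.pi * k * x / n)[:, None, None] * np.ones((1, n, n))
        dmap = DensityMap(probe, voxel, np.zeros(3))
        out = butterworth_lowpass(dmap, FilterParams(cutoff_res, order=order))
        # project onto the probe to measure the surviving amplitude
        amp = np.vdot(probe, out.values) / np.vdot(probe, probe)
        assert amp == pytest.approx(2 ** -0.5, abs=1e-6)

    def test_linearity(self, rng):
        A = DensityMap(rng.normal(size=(16, 16, 16)), 1.0, np.zeros(3))
        B = DensityMap(rng.normal(size=(16, 16, 16)), 1.0, np.zeros(3))
        params = FilterParams(5.0, order=4)
        lhs = butterworth_lowpass(
            DensityMap(2.0 * A.values + 3.0 * B.values, 1.0, np.zeros(3)), params)
        rhs = (2.0 * butterworth_lowpass(A, params).values
               + 3.0 * butterworth_lowpass(B, params).values)
        np.testing.assert_allclose(lhs.values, rhs, atol=1e-9)

    def test_cutoff_beyond_nyquist_rejected(self, rng):
        with pytest.raises(DensityError):
            butterworth_lowpass(_random_map(rng), FilterParams(1.5, order=8))


class TestMinimalBox:
    @pytest.mark.parametrize("L", [5, 15, 25])
    def test_native_segment_contained(self, L):
        structure, gap = make_toy_gap("loop", L, seed=L)
        exp_map = make_experimental_map(structure, resolution=8.0)
        box = minimal_box(gap, exp_map, pad=8.0)
        native = gap.native_segment()
        lo = box.origin
        hi = box.origin + (np.array(box.shape) - 1) * box.voxel_size
        assert np.all(native.coords >= lo - 1e-9)
        assert np.all(native.coords <= hi + 1e-9)

    def test_box_grows_with_length(self):
        structure, gap5 = make_toy_gap("helix", 5, seed=3)
        exp_map = make_experimental_map(structure, resolution=8.0)
        box5 = minimal_box(gap5, exp_map, pad=4.0)
        _, gap10 = make_toy_gap("helix", 10, seed=3)
        emap10 = make_experimental_map(gap10.structure, resolution=8.0)
        box10 = minimal_box(gap10, emap10, pad=4.0)
        assert np.prod(box10.shape) >= np.prod(box5.shape)

    def test_world_coordinates_preserved(self):
        structure, gap = make_toy_gap("strand", 7, seed=2)
        exp_map = make_experimental_map(structure, resolution=8.0)
        box = minimal_box(gap, exp_map, pad=6.0)
        # landmark: voxel value at a shared world position is identical
        ijk_box = np.array([1, 1, 1])
        world = box.voxel_to_world(ijk_box)
        ijk_map = np.round(exp_map.world_to_voxel(world)).astype(int)
        assert box.values[tuple(ijk_box)] == pytest.approx(
            exp_map.values[tuple(ijk_map)], abs=1e-12)

    def test_stems_outside_map_rejected(self):
        structure, gap = make_toy_gap("helix", 5, seed=1)
        tiny = DensityMap(np.zeros((4, 4, 4)), 1.0, np.array([500.0, 500, 500]))
        with pytest.raises(DensityError):
            minimal_box(gap, tiny, pad=2.0)


class TestNormalize:
    def test_zero_mean_unit_sd(self, rng):
        out = normalize_map(_random_map(rng))
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std() - 1.0) < 1e-9

    def test_idempotent_and_affine_invariant(self, rng):
        m = _random_map(rng)
        n1 = normalize_map(m)
        np.testing.assert_allclose(normalize_map(n1).values, n1.values, atol=1e-9)
        scaled = DensityMap(3.0 * m.values.astype(float) + 7.0, m.voxel_size, m.origin)
        np.testing.assert_allclose(normalize_map(scaled).values, n1.values,
                                   atol=1e-9)

    def test_constant_map_rejected(self):
        with pytest.raises(DensityError):
            normalize_map(DensityMap(np.ones((4, 4, 4)), 1.0, np.zeros(3)))


class TestSubtractContext:
    def test_self_subtraction_cancels(self, rng):
        coords = rng.uniform(6, 18, size=(40, 3))
        box = simulate_map(coords, 1.0, 6.0, (np.zeros(3), (24, 24, 24)))
        residual = subtract_context(box, coords, resolution=6.0)
        assert abs(residual.values.mean()) < 1e-6
        assert residual.values.std() < 1e-6  # exact cancellation

    def test_empty_context_identity(self, rng):
        box = _random_map(rng)
        residual = subtract_context(box, None, resolution=6.0)
        np.testing.assert_allclose(residual.values,
                                   normalize_map(box).values, atol=1e-12)

    def test_subtraction_sharpens_fragment_signal(self, rng):
        context = rng.uniform(5, 19, size=(60, 3))
        fragment = rng.uniform(9, 15, size=(10, 3))
        both = np.vstack([context, fragment])
        box = simulate_map(both, 1.0, 6.0, (np.zeros(3), (24, 24, 24)))
        frag_map = simulate_map(fragment, 1.0, 6.0, box, clip=True)
        ccc_raw = pearson_ccc(frag_map, normalize_map(box))
        residual = subtract_context(box, context, resolution=6.0)
        ccc_residual = pearson_ccc(frag_map, residual)
        assert ccc_residual > ccc_raw


class TestPearson:
    def test_self_and_negation(self, rng):
        m = _random_map(rng)
        assert pearson_ccc(m, m) == pytest.approx(1.0, abs=1e-12)
        neg = DensityMap(-m.values.astype(float), 1.0, np.zeros(3))
        assert pearson_ccc(m, neg) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_hand_formula_2x2x2(self, rng):
        a = rng.normal(size=(2, 2, 2))
        b = rng.normal(size=(2, 2, 2))
        x, y = a.ravel(), b.ravel()
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        want = cov / (x.std() * y.std())
        got = pearson_ccc(DensityMap(a, 1.0, np.zeros(3)),
                          DensityMap(b, 1.0, np.zeros(3)))
        assert got == pytest.approx(want, abs=1e-12)

    def test_affine_invariance(self, rng):
        A, B = _random_map(rng), _random_map(rng)
        base = pearson_ccc(A, B)
        for _ in range(100):
            a, c = rng.uniform(0.1, 5, size=2)
            b, d = rng.uniform(-5, 5, size=2)
            scaled = pearson_ccc(
                DensityMap(a * A.values.astype(float) + b, 1.0, np.zeros(3)),
                DensityMap(c * B.values.astype(float) + d, 1.0, np.zeros(3)))
            assert scaled == pytest.approx(base, abs=1e-9)

    def test_shape_mismatch_and_zero_variance(self, rng):
        with pytest.raises(DensityError):
            pearson_ccc(_random_map(rng), _random_map(rng, shape=(8, 8, 8)))
        with pytest.raises(DensityError):
            pearson_ccc(_random_map(rng),
                        DensityMap(np.zeros((16, 16, 16)), 1.0, np.zeros(3)))
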