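import numpy as np
import pytest

from fragfit.geometry import (
    GeometryError,
    circular_difference_deg,
    compute_fingerprint,
    detect_clashes,
    fingerprint_deviation,
    graft_fragment,
    superpose_fragment,
    superpose_stems,
)
from fragfit.structure_model import CoordinateSet
from fragfit.synthetic_fixtures import (
    native_fragment_record,
    make_toy_gap,
    perturb_fragment,
)
from conftest import random_rigid


def _random_stem(rng):
    base = rng.uniform(-10, 10, size=3)
    return {
        "N": base + rng.normal(0, 1, 3),
        "CA": base,
        "C": base + rng.normal(0, 1, 3),
    }


def _torsion_oracle(p0, p1, p2, p3):
    """Independent torsion via the angle between the two bond planes."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestFingerprint:
    def test_constructed_distance(self):
        ns = {"N": np.array([-1.0, 1, 0]), "CA": np.zeros(3), "C": np.array([1.0, 1, 0])}
        cs = {"N": np.array([9.0, 1, 0]), "CA": np.array([10.0, 0, 0]),
              "C": np.array([11.0, 1, 0])}
        fp = compute_fingerprint(ns, cs)
        assert fp.d == pytest.approx(10.0, abs=1e-12)

    def test_rigid_invariance(self, rng):
        ns, cs = _random_stem(rng), _random_stem(rng)
        fp0 = compute_fingerprint(ns, cs)
        for _ in range(100):
            R, t = random_rigid(rng)
            fp = compute_fingerprint({k: R @ v + t for k, v in ns.items()},
                                     {k: R @ v + t for k, v in cs.items()})
            np.testing.assert_allclose(fp.as_array(), fp0.as_array(), atol=1e-6)

    def test_d_and_phi_match_direct_oracles(self, rng):
        for _ in range(50):
            ns, cs = _random_stem(rng), _random_stem(rng)
            fp = compute_fingerprint(ns, cs)
            assert fp.d == pytest.approx(np.linalg.norm(cs["CA"] - ns["CA"]),
                                         abs=1e-9)
            assert fp.phi == pytest.approx(
                _torsion_oracle(ns["C"], ns["CA"], cs["CA"], cs["N"]), abs=1e-6)

    def test_missing_atom_raises(self):
        with pytest.raises(GeometryError, match="CA"):
            compute_fingerprint({"N": np.zeros(3), "C": np.ones(3)},
                                {"N": np.zeros(3), "CA": np.ones(3), "C": 2 * np.ones(3)})


class TestFingerprintDeviation:
    def test_identical_is_zero(self, rng):
        fp = compute_fingerprint(_random_stem(rng), _random_stem(rng))
        assert fingerprint_deviation(fp, fp) == 0.0

    def test_distance_normalization(self, rng):
        from fragfit.geometry import GeometricFingerprint
        a = GeometricFingerprint(10.0, 90.0, 90.0, 0.0)
        b = GeometricFingerprint(10.75, 90.0, 90.0, 0.0)
        assert fingerprint_deviation(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_phi_difference_is_circular(self):
        from fragfit.geometry import GeometricFingerprint
        a = GeometricFingerprint(10.0, 90.0, 90.0, 179.0)
        b = GeometricFingerprint(10.0, 90.0, 90.0, -179.0)
        assert fingerprint_deviation(a, b) == pytest.approx(2.0 / 30.0, abs=1e-12)
        assert circular_difference_deg(179.0, -179.0) == pytest.approx(2.0)


def _horn_quaternion_superpose(mobile, target):
    """Independent oracle: Horn's closed-form quaternion superposition."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - mc, target - tc
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, v = np.linalg.eigh(K)
    q = v[:, -1]
    q0, q1, q2, q3 = q
    R = np.array([
        [q0*q0+q1*q1-q2*q2-q3*q3, 2*(q1*q2-q0*q3), 2*(q1*q3+q0*q2)],
        [2*(q1*q2+q0*q3), q0*q0-q1*q1+q2*q2-q3*q3, 2*(q2*q3-q0*q1)],
        [2*(q1*q3-q0*q2), 2*(q2*q3+q0*q1), q0*q0-q1*q1-q2*q2+q3*q3]])
    fitted = a @ R.T + tc
    return float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))


class TestSuperpose:
    def test_self_superposition_zero(self, rng):
        pts = rng.normal(size=(8, 3))
        _, rmsd = superpose_stems(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered(self, rng):
        pts = rng.normal(size=(8, 3))
        for _ in range(20):
            R, t = random_rigid(rng)
            rt, rmsd = superpose_stems(pts, pts @ R.T + t)
            assert rmsd < 1e-9
            roundtrip = rt.inverse().apply(rt.apply(pts))
            np.testing.assert_allclose(roundtrip, pts, atol=1e-9)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(300):
            mobile = rng.normal(scale=3.0, size=(8, 3))
            target = mobile + rng.normal(scale=1.0, size=(8, 3))
            _, rmsd = superpose_stems(mobile, target)
            assert rmsd == pytest.approx(
                _horn_quaternion_superpose(mobile, target), abs=1e-9)

    def test_never_worse_than_unfitted(self, rng):
        for _ in range(100):
            mobile = rng.normal(scale=3.0, size=(6, 3))
            target = rng.normal(scale=3.0, size=(6, 3))
            _, rmsd = superpose_stems(mobile, target)
            unfitted = np.sqrt(np.mean(np.sum((mobile - target) ** 2, axis=1)))
            assert rmsd <= unfitted + 1e-12

    def test_degenerate_inputs_raise(self, rng):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(GeometryError):
            superpose_stems(line, line + 1.0)
        with pytest.raises(GeometryError):
            superpose_stems(np.zeros((2, 3)), np.ones((2, 3)))


class TestGraft:
    def test_native_graft_reproduces_native(self):
        _, gap = make_toy_gap("helix", 9, seed=1)
        rec = native_fragment_record(gap)
        placed = graft_fragment(rec, gap)
        native = gap.native_segment(atoms=("N", "CA", "C", "O"))
        np.testing.assert_allclose(placed.coords, native.coords, atol=1e-6)

    def test_graft_deterministic(self):
        _, gap = make_toy_gap("strand", 7, seed=2)
        rec = native_fragment_record(gap)
        a = graft_fragment(rec, gap)
        b = graft_fragment(rec, gap)
        assert np.array_equal(a.coords, b.coords)

    def test_stem_rmsd_zero_for_native(self):
        _, gap = make_toy_gap("loop", 5, seed=4)
        rec = native_fragment_record(gap)
        _, stem_rmsd = superpose_fragment(rec, gap)
        assert stem_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_perturbed_graft_matches_transform_oracle(self, rng):
        _, gap = make_toy_gap("loop", 9, seed=6)
        rec = native_fragment_record(gap)
        frag_cs = rec.backbone_coordinate_set()
        pert = perturb_fragment(frag_cs, sd=0.8, seed=9)
        pert_rec = type(rec)(
            source_id="p", chain_id=rec.chain_id,
            first_residue_number=rec.first_residue_number, length=rec.length,
            sequence=rec.sequence,
            coords=pert.coords.reshape(rec.length, 4, 3), has_o=True)
        placed = graft_fragment(pert_rec, gap)
        # independent oracle: superpose stem atoms directly, transform, measure
        rt, _ = superpose_fragment(pert_rec, gap)
        oracle = rt.apply(pert.coords.reshape(rec.length, 4, 3)[1:-1].reshape(-1, 3))
        np.testing.assert_allclose(placed.coords, oracle, atol=1e-9)
        native = gap.native_segment(atoms=("N", "CA", "C", "O"))
        rmsd_placed = np.sqrt(np.mean(np.sum((placed.coords - native.coords) ** 2, axis=1)))
        assert rmsd_placed > 0.1  # perturbation survives the stem fit


class TestClashes:
    def test_close_context_atom_detected(self, rng):
        placed = rng.normal(size=(5, 3))
        context = placed[:1] + np.array([1.5, 0.0, 0.0])
        assert detect_clashes(placed, context, cutoff=2.0) >= 1

    def test_empty_context_is_clash_free(self, rng):
        assert detect_clashes(rng.normal(size=(5, 3)), None) == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            placed = rng.uniform(0, 12, size=(50, 3))
            context = rng.uniform(0, 12, size=(200, 3))
            brute = int(np.sum(
                np.linalg.norm(placed[:, None] - context[None], axis=-1) < 2.0))
            assert detect_clashes(placed, context, cutoff=2.0) == brute
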