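"""Stem-pair fingerprints, rigid superposition, grafting and clash detection.

The geometric fingerprint condenses the relative pose of the two stem
residues flanking a gap (or terminating a fragment) into four numbers:

* ``d`` — distance between the stem CA atoms (Å);
* ``theta_n`` — angle between the N-stem CA→C bond and the stem-stem axis;
* ``theta_c`` — angle between the C-stem CA→N bond and the reversed axis;
* ``phi`` — torsion C(n)–CA(n)–CA(c)–N(c), in (−180, 180].

All four are invariant under global rotation and translation, so fragments
can be pre-screened against a gap without any superposition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree

from fragfit.structure_model import CoordinateSet

if TYPE_CHECKING:  # pragma: no cover
    from fragfit.fragment_db import FragmentRecord
    from fragfit.structure_model import GapSpec


class GeometryError(ValueError):
    """Raised for degenerate geometric input."""


# normalizers mapping the hard stage-1 distance threshold and a 30° angular
# deviation each onto one unit of fingerprint deviation
D_NORM = 0.75
ANGLE_NORM = 30.0


@dataclass(frozen=True)
class GeometricFingerprint:
    d: float
    theta_n: float
    theta_c: float
    phi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d, self.theta_n, self.theta_c, self.phi])


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise GeometryError("zero-length vector in fingerprint computation")
    return v / n


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(_unit(u), _unit(v)), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees, in (−180, 180], via the atan2 formulation."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = _unit(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def _stem_dict(stem) -> Mapping[str, np.ndarray]:
    if isinstance(stem, CoordinateSet):
        return {n: xyz for n, xyz in zip(stem.atom_names, stem.coords)}
    return stem


def compute_fingerprint(nstem_atoms, cstem_atoms) -> GeometricFingerprint:
    """Fingerprint of a stem pair; each stem must supply named N, CA and C."""
    ns, cs = _stem_dict(nstem_atoms), _stem_dict(cstem_atoms)
    for label, stem in (("N-stem", ns), ("C-stem", cs)):
        for name in ("N", "CA", "C"):
            if name not in stem:
                raise GeometryError(f"{label} is missing atom {name}")
    ca_n, ca_c = np.asarray(ns["CA"], float), np.asarray(cs["CA"], float)
    axis = ca_c - ca_n
    d = float(np.linalg.norm(axis))
    if d < 1e-9:
        raise GeometryError("stem CA atoms coincide")
    theta_n = _angle_deg(np.asarray(ns["C"], float) - ca_n, axis)
    theta_c = _angle_deg(np.asarray(cs["N"], float) - ca_c, -axis)
    phi = dihedral_deg(ns["C"], ca_n, ca_c, cs["N"])
    return GeometricFingerprint(d=d, theta_n=theta_n, theta_c=theta_c, phi=phi)


def circular_difference_deg(a: float, b: float) -> float:
    """Smallest absolute angular difference on the circle, in [0, 180]."""
    diff = abs(a - b) % 360.0
    return min(diff, 360.0 - diff)


def fingerprint_deviation(a: GeometricFingerprint, b: GeometricFingerprint,
                          d_norm: float = D_NORM,
                          angle_norm: float = ANGLE_NORM) -> float:
    """Non-negative deviation between two fingerprints; 0 iff identical.

    Each term is normalized so that the stage-1 hard distance threshold
    (0.75 Å) and a 30° angular deviation contribute one unit each; terms are
    summed with equal weights. The torsion difference is taken on the circle.
    """
    dev = abs(a.d - b.d) / d_norm
    dev += abs(a.theta_n - b.theta_n) / angle_norm
    dev += abs(a.theta_c - b.theta_c) / angle_norm
    dev += circular_difference_deg(a.phi, b.phi) / angle_norm
    return float(dev)


def superpose_stems(mobile, target) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation enforced).

    Returns the transform mapping ``mobile`` onto ``target`` and the
    post-fit RMSD over the fitted points.
    """
    m = mobile.coords if isinstance(mobile, CoordinateSet) else np.asarray(mobile, float)
    t = target.coords if isinstance(target, CoordinateSet) else np.asarray(target, float)
    if m.shape != t.shape or m.ndim != 2 or m.shape[1] != 3:
        raise GeometryError("point sets must be matched (N, 3) arrays")
    n = len(m)
    if n < 3:
        raise GeometryError("at least 3 points are required for superposition")
    mc, tc = m.mean(axis=0), t.mean(axis=0)
    dm, dt = m - mc, t - tc
    # collinearity guard: rank of the covariance of either set must be >= 2
    if min(np.linalg.matrix_rank(dm, tol=1e-8),
           np.linalg.matrix_rank(dt, tol=1e-8)) < 2:
        raise GeometryError("degenerate (collinear) point set")
    H = dm.T @ dt
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    trans = tc - R @ mc
    rt = RigidTransform(R, trans)
    rmsd = float(np.sqrt(np.mean(np.sum((rt.apply(m) - t) ** 2, axis=1))))
    return rt, rmsd


def _matched_stem_points(record: "FragmentRecord", gap: "GapSpec"):
    """Matched (mobile, target) stem-atom arrays for fragment→gap superposition.

    Uses N, CA, C of the first/last fragment residue against the gap stems;
    O is appended on both sides when both the fragment terminals and the gap
    stems have it.
    """
    use_o = record.has_o and gap.stems_have_o()
    names = ("N", "CA", "C", "O") if use_o else ("N", "CA", "C")
    mobile, target = [], []
    for side, res_idx in (("n", 0), ("c", record.length - 1)):
        frag_atoms = record.residue_atoms(res_idx)
        gap_atoms = gap.stem_atoms(side, include_o=use_o)
        for name in names:
            mobile.append(frag_atoms[name])
            target.append(gap_atoms[name])
    return np.asarray(mobile), np.asarray(target)


def superpose_fragment(record: "FragmentRecord", gap: "GapSpec") -> tuple[RigidTransform, float]:
    """Superpose a fragment's terminal residues onto the gap's stem residues."""
    if record.length != gap.fragment_length:
        raise GeometryError(
            f"fragment length {record.length} does not serve a gap of "
            f"{gap.length} residues (needs {gap.fragment_length})")
    mobile, target = _matched_stem_points(record, gap)
    return superpose_stems(mobile, target)


def graft_fragment(record: "FragmentRecord", gap: "GapSpec",
                   transform: RigidTransform | None = None) -> CoordinateSet:
    """Place a fragment into a gap and return the interior residue coordinates.

    The fragment's terminal residues are superposed onto the gap stems; the
    transformed interior (gap.length residues) is returned. Passing a
    pre-computed ``transform`` skips the superposition.
    """
    if transform is None:
        transform, _ = superpose_fragment(record, gap)
    interior = record.interior_coordinate_set()
    return interior.with_coords(transform.apply(interior.coords))


def detect_clashes(placed, context, cutoff: float = 2.0) -> int:
    """Count placed-atom/context-atom pairs closer than ``cutoff`` (strict <)."""
    p = placed.coords if isinstance(placed, CoordinateSet) else np.asarray(placed, float)
    if context is None:
        return 0
    c = context.coords if isinstance(context, CoordinateSet) else np.asarray(context, float)
    if len(p) == 0 or len(c) == 0:
        return 0
    tree = cKDTree(c)
    count = 0
    for point, neighbors in zip(p, tree.query_ball_point(p, r=cutoff)):
        for j in neighbors:
            if np.linalg.norm(point - c[j]) < cutoff:
                count += 1
    return count
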