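"""Cryo-EM volume handling.

A :class:`DensityMap` is a 3-D scalar grid with isotropic voxel size, a world
origin (position of the center of voxel [0,0,0]) and an optional nominal
resolution. Values are indexed ``[ix, iy, iz]``.

Map preprocessing for fragment scoring follows the classical recipe: extract
a minimal sub-box guaranteed to contain any placement of the missing
segment, normalize it, simulate the density of the atoms already modeled
inside the box and subtract it, leaving a residual dominated by the missing
segment. Simulated maps are unit-weight trilinear atom depositions low-pass
filtered to the nominal resolution with a Butterworth filter
H(f) = 1/sqrt(1 + (f/f_c)^(2n)), f_c = 1/resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, TYPE_CHECKING

import gemmi
import numpy as np

from fragfit.structure_model import CoordinateSet

if TYPE_CHECKING:  # pragma: no cover
    from fragfit.structure_model import GapSpec

#: Cα–Cα virtual bond length, the per-residue reach of a polypeptide chain (Å)
CHAIN_REACH_PER_RESIDUE = 3.8


class DensityError(ValueError):
    """Raised for malformed volumes or invalid filter parameters."""


@dataclass
class DensityMap:
    values: np.ndarray              # (nx, ny, nz)
    voxel_size: float               # Å, isotropic
    origin: np.ndarray              # Å, world position of voxel [0,0,0] center
    resolution: float | None = None  # Å, nominal

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DensityError("density values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise DensityError("density values must be finite")
        if self.voxel_size <= 0:
            raise DensityError("voxel size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        return (np.asarray(xyz, float) - self.origin) / self.voxel_size

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk, float) * self.voxel_size + self.origin

    def copy(self) -> "DensityMap":
        return replace(self, values=self.values.copy(), origin=self.origin.copy())


@dataclass(frozen=True)
class FilterParams:
    cutoff_resolution: float  # Å
    order: int = 8

    def validate(self, voxel_size: float) -> None:
        if self.order < 1:
            raise DensityError("filter order must be >= 1")
        if self.cutoff_resolution < 2.0 * voxel_size:
            raise DensityError(
                f"cutoff resolution {self.cutoff_resolution} Å is beyond the "
                f"Nyquist limit {2.0 * voxel_size} Å of this grid")


# ---------------------------------------------------------------------------
# MRC/CCP4 I/O (gemmi handles axis-order normalization and the 2014 header)

def read_map(path, resolution: float | None = None) -> DensityMap:
    """Read an MRC/CCP4-2014 volume; axis order is normalized to x-fastest.

    The origin is taken from the ORIGIN header fields, falling back to the
    NC/NR/NS start offsets. Anisotropic voxels are rejected.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - gemmi raises bare RuntimeError
        raise DensityError(f"cannot read MRC/CCP4 map {path!r}: {exc}") from exc
    starts = [m.header_i32(i) for i in (5, 6, 7)]
    m.setup(0.0)
    spacing = np.array(m.grid.spacing)
    if spacing.min() <= 0:
        raise DensityError("map has zero voxel spacing")
    if (spacing.max() - spacing.min()) > 1e-4 * spacing.mean():
        raise DensityError(
            f"anisotropic voxels {tuple(spacing)} are not supported; "
            "resample the map to an isotropic grid first")
    voxel = float(spacing.mean())
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.allclose(origin, 0.0) and any(starts):
        origin = np.asarray(starts, dtype=float) * voxel
    values = np.array(m.grid, copy=True)
    return DensityMap(values=values, voxel_size=voxel, origin=origin,
                      resolution=resolution)


def write_map(dmap: DensityMap, path) -> None:
    """Write as MRC/CCP4-2014 mode 2 (32-bit float), x-fastest axis order."""
    nx, ny, nz = dmap.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(nx * dmap.voxel_size, ny * dmap.voxel_size,
                                      nz * dmap.voxel_size, 90.0, 90.0, 90.0))
    np.asarray(grid)[:] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Filtering and simulation

def butterworth_lowpass(dmap: DensityMap, params: FilterParams) -> DensityMap:
    """Fourier-space Butterworth low-pass filter; linear, DC gain exactly 1."""
    params.validate(dmap.voxel_size)
    fc = 1.0 / params.cutoff_resolution
    freqs = [np.fft.fftfreq(n, d=dmap.voxel_size) for n in dmap.shape[:2]]
    freqs.append(np.fft.rfftfreq(dmap.shape[2], d=dmap.voxel_size))
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    f2 = fx * fx + fy * fy + fz * fz
    H = 1.0 / np.sqrt(1.0 + (f2 / fc**2) ** params.order)
    spectrum = np.fft.rfftn(dmap.values.astype(float))
    filtered = np.fft.irfftn(spectrum * H, s=dmap.shape, axes=(0, 1, 2))
    return replace(dmap, values=filtered, resolution=params.cutoff_resolution)


def _deposit_trilinear(coords: np.ndarray, shape, origin, voxel_size,
                       clip: bool) -> np.ndarray:
    nx, ny, nz = shape
    frac = (coords - origin) / voxel_size
    inside = np.all((frac >= 0.0) & (frac <= np.array(shape) - 1.0), axis=1)
    if not clip and not inside.all():
        bad = np.flatnonzero(~inside)
        raise DensityError(
            f"{len(bad)} atom(s) fall outside the simulation box "
            f"(first offending atom index {bad[0]})")
    frac = frac[inside]
    vol = np.zeros(shape, dtype=float)
    if len(frac) == 0:
        return vol
    base = np.floor(frac).astype(int)
    base = np.minimum(base, np.array(shape) - 2)  # keep i+1 in range at the top edge
    base = np.maximum(base, 0)
    t = frac - base
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                np.add.at(vol, (base[:, 0] + dx, base[:, 1] + dy, base[:, 2] + dz), w)
    return vol


def simulate_map(coords, voxel_size: float, resolution: float,
                 box, clip: bool = False, order: int = 8,
                 filtered: bool = True) -> DensityMap:
    """Simulate a density map from atomic coordinates.

    Each heavy atom deposits unit weight by trilinear splatting at its world
    position; the volume is then low-pass filtered to ``resolution``.
    ``box`` is either a template :class:`DensityMap` (grid geometry reused)
    or an ``(origin, shape)`` pair. Atoms outside the box raise an error
    unless ``clip=True``, in which case they are dropped.
    """
    xyz = coords.coords if isinstance(coords, CoordinateSet) else np.asarray(coords, float)
    if xyz.size == 0:
        raise DensityError("cannot simulate a map from zero atoms")
    if resolution < 2.0 * voxel_size:
        raise DensityError("resolution must be at least twice the voxel size")
    if isinstance(box, DensityMap):
        origin, shape = box.origin, box.shape
        if abs(box.voxel_size - voxel_size) > 1e-9:
            raise DensityError("template box voxel size disagrees")
    else:
        origin, shape = np.asarray(box[0], float), tuple(box[1])
    vol = _deposit_trilinear(xyz, shape, origin, voxel_size, clip)
    out = DensityMap(values=vol, voxel_size=voxel_size, origin=np.array(origin),
                     resolution=resolution)
    if filtered:
        out = butterworth_lowpass(out, FilterParams(resolution, order))
    return out


def default_box(coords, voxel_size: float, margin: float) -> tuple[np.ndarray, tuple]:
    """Axis-aligned (origin, shape) covering ``coords`` with a world margin."""
    xyz = coords.coords if isinstance(coords, CoordinateSet) else np.asarray(coords, float)
    lo = xyz.min(axis=0) - margin
    hi = xyz.max(axis=0) + margin
    shape = tuple(int(np.ceil((h - l) / voxel_size)) + 1 for l, h in zip(lo, hi))
    return lo, shape


# ---------------------------------------------------------------------------
# Box extraction and scoring

def minimal_box(gap: "GapSpec", dmap: DensityMap, pad: float | None = None) -> DensityMap:
    """Minimal sub-volume that can contain any placement of the gap segment.

    A chain of L residues anchored at both stems reaches at most
    3.8·(L+1) Å of combined distance from the two stem CA atoms, so the
    admissible region is the prolate spheroid with foci at the stem CAs and
    string length R = 3.8·(L+1). The sub-box is the axis-aligned bounding
    box of that spheroid expanded by ``pad`` (default: the map's nominal
    resolution, else 2 voxels) and clipped to the map bounds. The world
    origin is updated so world coordinates are preserved.
    """
    if pad is None:
        pad = dmap.resolution if dmap.resolution else 2.0 * dmap.voxel_size
    a = np.asarray(gap.stem_atoms("n")["CA"], float)
    b = np.asarray(gap.stem_atoms("c")["CA"], float)
    shape = np.array(dmap.shape)
    for point, label in ((a, "N-stem"), (b, "C-stem")):
        frac = dmap.world_to_voxel(point)
        if np.any(frac < -0.5) or np.any(frac > shape - 0.5):
            raise DensityError(f"{label} CA lies outside the density map")
    d = float(np.linalg.norm(b - a))
    R = max(CHAIN_REACH_PER_RESIDUE * (gap.length + 1), d + 1e-6)
    alpha = R / 2.0
    beta = np.sqrt(max(R * R - d * d, 0.0)) / 2.0
    center = (a + b) / 2.0
    u = (b - a) / d if d > 1e-9 else np.array([1.0, 0.0, 0.0])
    # exact AABB half-extent of an ellipsoid of revolution along u
    extent = np.sqrt(alpha**2 * u**2 + beta**2 * (1.0 - u**2))
    lo_w = center - extent - pad
    hi_w = center + extent + pad
    i0 = np.maximum(np.floor(dmap.world_to_voxel(lo_w)).astype(int), 0)
    i1 = np.minimum(np.ceil(dmap.world_to_voxel(hi_w)).astype(int) + 1, shape)
    sub = dmap.values[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    return DensityMap(values=sub.copy(), voxel_size=dmap.voxel_size,
                      origin=dmap.voxel_to_world(i0), resolution=dmap.resolution)


def normalize_map(dmap: DensityMap) -> DensityMap:
    """Shift/scale to mean 0 and standard deviation 1."""
    vals = dmap.values.astype(float)
    sd = float(vals.std())
    if sd < 1e-12:
        raise DensityError("cannot normalize a constant map")
    values = (vals - vals.mean()) / sd
    return replace(dmap, values=values)


def subtract_context(exp_box: DensityMap, context_coords,
                     resolution: float | None = None) -> DensityMap:
    """Remove already-modeled density from the experimental sub-box.

    The atoms of the structural context that fall inside the box are
    converted into a simulated map on the same grid, normalized, and
    subtracted from the normalized experimental box. The residual is
    dominated by the density of the missing segment. An empty context
    returns the normalized box unchanged.
    """
    resolution = resolution or exp_box.resolution
    if resolution is None:
        raise DensityError("a resolution is required for context subtraction")
    box_norm = normalize_map(exp_box)
    if context_coords is None:
        return box_norm
    xyz = (context_coords.coords if isinstance(context_coords, CoordinateSet)
           else np.asarray(context_coords, float))
    lo = exp_box.origin
    hi = exp_box.origin + (np.array(exp_box.shape) - 1) * exp_box.voxel_size
    inside = np.all((xyz >= lo) & (xyz <= hi), axis=1)
    if not inside.any():
        return box_norm
    sim = simulate_map(xyz[inside], exp_box.voxel_size, resolution, exp_box,
                       clip=True)
    if sim.values.std() < 1e-12:
        return box_norm
    residual = box_norm.values - normalize_map(sim).values
    return replace(box_norm, values=residual)


def pearson_ccc(a: DensityMap, b: DensityMap) -> float:
    """Pearson cross-correlation coefficient over all voxels of two volumes."""
    av = a.values if isinstance(a, DensityMap) else np.asarray(a, float)
    bv = b.values if isinstance(b, DensityMap) else np.asarray(b, float)
    if av.shape != bv.shape:
        raise DensityError(f"grid shape mismatch: {av.shape} vs {bv.shape}")
    x = av.ravel().astype(float)
    y = bv.ravel().astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx < 1e-300 or ny < 1e-300:
        raise DensityError("zero-variance volume in correlation")
    return float(np.clip(np.dot(xc, yc) / (nx * ny), -1.0, 1.0))
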