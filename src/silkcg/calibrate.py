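"""Energy-scan calibration of the CG force field.

Each bonded term is calibrated by scanning a single internal coordinate
of a small cluster of residues (bond length, bending angle, torsion
angle) while an energy oracle — an all-atom engine, a precomputed scan
file, or a synthetic potential — reports the total energy at each
sample.  A harmonic potential is then least-squares fitted in a window
around the sampled minimum.  Non-bonded terms are calibrated on pairs
of like residues: the rotating residue is first oriented at its
minimum-energy rotation about each body axis (three scenarios), then
displaced along the center line and fitted with a Lennard-Jones form;
the calibrated (eps, sigma) are arithmetic means over the scenarios.

The scan drivers never evaluate energies themselves: the oracle
callback is the boundary to whatever produced the reference energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

from .forcefield import (
    AngleParam,
    BondParam,
    DihedralParam,
    ExclusionPolicy,
    ForceField,
    PairParam,
    wrap_angle_deg,
)
from .model import build_chain
from .units import KB_KCAL

__all__ = [
    "EnergyScan",
    "HarmonicFit",
    "LJFit",
    "FitWindow",
    "FitError",
    "BoundaryMinimumError",
    "RigidResidue",
    "measure_angle",
    "measure_dihedral",
    "zmatrix_positions",
    "scan_bond",
    "scan_angle",
    "scan_dihedral",
    "fit_harmonic",
    "fit_lj",
    "orientation_scan",
    "calibrate_pair",
    "CalibrationConfig",
    "ChainOracle",
    "calibrate_chain",
]

SCAN_KINDS = ("bond", "angle", "dihedral", "separation", "orientation")


class FitError(RuntimeError):
    """A calibration fit could not be performed."""


class BoundaryMinimumError(FitError):
    """The scan minimum sits on the boundary; extend the scan range."""


@dataclass
class EnergyScan:
    """(coordinate, energy) samples along one controlled coordinate.

    Coordinates are A for bond/separation kinds and degrees for
    angle/dihedral/orientation kinds; energies are kcal/mol.
    """

    coordinates: np.ndarray
    energies: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.kind not in SCAN_KINDS:
            raise ValueError(f"unknown scan kind {self.kind!r}")
        if self.coordinates.ndim != 1 or self.coordinates.size < 5:
            raise ValueError("scan needs at least 5 samples")
        if self.energies.shape != self.coordinates.shape:
            raise ValueError("coordinates and energies must have equal length")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("scan energies must be finite")
        d = np.diff(self.coordinates)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("scan coordinates must be strictly monotone")


@dataclass(frozen=True)
class HarmonicFit:
    stiffness: float  # kcal/mol per A^2 or rad^2
    equilibrium: float  # A or degrees (matching the scan kind)
    offset: float  # energy at the fitted minimum
    window: tuple[float, float]
    residual_rms: float
    n_used: int


@dataclass(frozen=True)
class LJFit:
    epsilon: float
    sigma: float
    offset: float  # fitted baseline energy at large separation
    window: tuple[float, float]
    residual_rms: float
    n_used: int


@dataclass(frozen=True)
class FitWindow:
    """Samples within ``energy_above_min`` of the minimum, at least
    ``min_points`` of them (expanded outward when the thermal window is
    too narrow).  The default window is ~k_B * 300 K per mode."""

    energy_above_min: float = KB_KCAL * 300.0
    min_points: int = 5


@dataclass(frozen=True)
class RigidResidue:
    """A residue treated as a rigid body of (sub-)sites for pair scans."""

    positions: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", np.atleast_2d(np.asarray(self.positions, dtype=float))
        )
        object.__setattr__(
            self, "masses", np.atleast_1d(np.asarray(self.masses, dtype=float))
        )
        if self.positions.shape != (self.masses.size, 3):
            raise ValueError("positions must be (m, 3) matching masses")
        if np.any(self.masses <= 0):
            raise ValueError("site masses must be positive")

    @property
    def com(self) -> np.ndarray:
        return (self.positions * self.masses[:, None]).sum(axis=0) / self.masses.sum()

    def shifted(self, vector: np.ndarray) -> "RigidResidue":
        return RigidResidue(self.positions + vector, self.masses)

    def rotated(self, rotation: Rotation, about: np.ndarray | None = None) -> "RigidResidue":
        pivot = self.com if about is None else np.asarray(about, dtype=float)
        return RigidResidue(rotation.apply(self.positions - pivot) + pivot, self.masses)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def measure_angle(p_i: np.ndarray, p_j: np.ndarray, p_k: np.ndarray) -> float:
    """Bending angle i-j-k in degrees."""
    d1 = np.asarray(p_i, float) - p_j
    d2 = np.asarray(p_k, float) - p_j
    c = np.dot(d1, d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def measure_dihedral(
    p_i: np.ndarray, p_j: np.ndarray, p_k: np.ndarray, p_l: np.ndarray
) -> float:
    """Torsion angle i-j-k-l in degrees, in (-180, 180]."""
    b1 = np.asarray(p_j, float) - p_i
    b2 = np.asarray(p_k, float) - p_j
    b3 = np.asarray(p_l, float) - p_k
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2)
    x = np.dot(n1, n2)
    return wrap_angle_deg(math.degrees(math.atan2(y, x)))


def zmatrix_positions(
    bond_lengths: Sequence[float],
    angles_deg: Sequence[float],
    dihedrals_deg: Sequence[float],
) -> np.ndarray:
    """Cartesian chain coordinates from internal coordinates (NeRF).

    ``bond_lengths`` has n-1 entries, ``angles_deg`` n-2, and
    ``dihedrals_deg`` n-3 for an n-bead chain.  The measured internal
    coordinates of the result match the inputs (dihedral sign follows
    :func:`measure_dihedral`).
    """
    r = np.asarray(bond_lengths, dtype=float)
    th = np.radians(np.asarray(angles_deg, dtype=float))
    ph = np.radians(np.asarray(dihedrals_deg, dtype=float))
    n = r.size + 1
    if th.size != max(n - 2, 0) or ph.size != max(n - 3, 0):
        raise ValueError("inconsistent internal-coordinate counts")
    pos = np.zeros((n, 3))
    if n > 1:
        pos[1] = [r[0], 0.0, 0.0]
    if n > 2:
        pos[2] = pos[1] + r[1] * np.array(
            [-math.cos(th[0]), math.sin(th[0]), 0.0]
        )
    for m in range(3, n):
        a, b, c = pos[m - 3], pos[m - 2], pos[m - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        nrm = np.cross(b - a, bc)
        nrm /= np.linalg.norm(nrm)
        mvec = np.cross(nrm, bc)
        rr, tt, pp = r[m - 1], th[m - 2], ph[m - 3]
        d2 = np.array(
            [
                -rr * math.cos(tt),
                rr * math.sin(tt) * math.cos(pp),
                rr * math.sin(tt) * math.sin(pp),
            ]
        )
        pos[m] = c + d2[0] * bc + d2[1] * mvec + d2[2] * nrm
    return pos


def _coordinate_grid(value_range: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = float(value_range[0]), float(value_range[1])
    if step <= 0:
        raise ValueError("step must be positive")
    if hi <= lo:
        raise ValueError("range must have positive width")
    n = int(round((hi - lo) / step)) + 1
    if n < 2:
        raise ValueError("scan range covers zero steps")
    grid = lo + step * np.arange(n)
    return grid[grid <= hi + 1e-9 * max(1.0, abs(hi))]


# ---------------------------------------------------------------------------
# Scan drivers
# ---------------------------------------------------------------------------

Oracle = Callable[[np.ndarray], float]


def scan_bond(
    cluster: np.ndarray,
    i: int,
    j: int,
    separation_range: tuple[float, float],
    step: float,
    oracle: Oracle,
) -> EnergyScan:
    """Scan the i-j separation: site j moves along the i->j line, i fixed.

    Coordinates recorded are the absolute i-j separations (A).
    """
    pos = np.array(cluster, dtype=float)
    if i == j:
        raise ValueError("i and j must differ")
    grid = _coordinate_grid(separation_range, step)
    if np.any(grid <= 0):
        raise ValueError("separations must be positive")
    d = pos[j] - pos[i]
    r0 = np.linalg.norm(d)
    if r0 == 0:
        raise ValueError("sites i and j coincide; direction undefined")
    unit = d / r0
    energies = np.empty(grid.size)
    for m, target in enumerate(grid):
        trial = pos.copy()
        trial[j] = pos[i] + unit * target
        energies[m] = oracle(trial)
        achieved = np.linalg.norm(trial[j] - trial[i])
        if abs(achieved - target) > 1e-9 * max(1.0, target):
            raise RuntimeError("bond scan failed to hit the target separation")
    return EnergyScan(grid, energies, kind="bond", meta={"sites": (i, j)})


def scan_angle(
    cluster: np.ndarray,
    i: int,
    j: int,
    k: int,
    angle_range: tuple[float, float],
    step: float,
    oracle: Oracle,
) -> EnergyScan:
    """Scan the i-j-k bending angle: k rotates about j in the triple's plane.

    Sites i and j stay fixed; the j-k distance is preserved exactly by
    the rigid rotation (checked to 1e-10).  Coordinates are absolute
    angles in degrees.
    """
    pos = np.array(cluster, dtype=float)
    grid = _coordinate_grid(angle_range, step)
    if np.any(grid <= 0) or np.any(grid >= 180.0):
        raise ValueError("bending angles must lie strictly inside (0, 180)")
    d1 = pos[i] - pos[j]
    d2 = pos[k] - pos[j]
    normal = np.cross(d1, d2)
    nn = np.linalg.norm(normal)
    if nn < 1e-10 * np.linalg.norm(d1) * np.linalg.norm(d2):
        raise ValueError("collinear triple: bending plane undefined")
    normal /= nn
    current = measure_angle(pos[i], pos[j], pos[k])
    r_jk = np.linalg.norm(d2)
    energies = np.empty(grid.size)
    for m, target in enumerate(grid):
        rot = Rotation.from_rotvec(np.radians(target - current) * normal)
        trial = pos.copy()
        trial[k] = rot.apply(pos[k] - pos[j]) + pos[j]
        if abs(np.linalg.norm(trial[k] - trial[j]) - r_jk) > 1e-10 * max(1.0, r_jk):
            raise RuntimeError("angle scan altered the j-k bond length")
        achieved = measure_angle(trial[i], trial[j], trial[k])
        if abs(achieved - target) > 1e-6:
            raise RuntimeError("angle scan failed to hit the target angle")
        energies[m] = oracle(trial)
    return EnergyScan(grid, energies, kind="angle", meta={"sites": (i, j, k)})


def scan_dihedral(
    cluster: np.ndarray,
    i: int,
    j: int,
    k: int,
    l: int,
    angle_range: tuple[float, float],
    step: float,
    oracle: Oracle,
) -> EnergyScan:
    """Scan the i-j-k-l torsion: l rotates rigidly about the j->k axis.

    The rotation center is l's projection onto the axis, so l's distance
    to the axis — and hence every bond and bending angle of the cluster —
    is preserved; only the torsion varies.  Coordinates are recorded on a
    continuous angle axis (degrees, may exceed +-180); the measured
    dihedral equals the coordinate wrapped onto (-180, 180].
    """
    pos = np.array(cluster, dtype=float)
    axis = pos[k] - pos[j]
    an = np.linalg.norm(axis)
    if an == 0:
        raise ValueError("j and k coincide: torsion axis undefined")
    axis /= an
    rel_l = pos[l] - pos[j]
    dist_axis = np.linalg.norm(rel_l - np.dot(rel_l, axis) * axis)
    if dist_axis < 1e-10:
        raise ValueError("site l lies on the j-k axis: torsion undefined")
    grid = _coordinate_grid(angle_range, step)
    current = measure_dihedral(pos[i], pos[j], pos[k], pos[l])
    energies = np.empty(grid.size)
    for m, target in enumerate(grid):
        rot = Rotation.from_rotvec(np.radians(target - current) * axis)
        trial = pos.copy()
        trial[l] = rot.apply(pos[l] - pos[j]) + pos[j]
        rel = trial[l] - trial[j]
        d_ax = np.linalg.norm(rel - np.dot(rel, axis) * axis)
        if abs(d_ax - dist_axis) > 1e-10 * max(1.0, dist_axis):
            raise RuntimeError("torsion scan altered the distance to the axis")
        achieved = measure_dihedral(trial[i], trial[j], trial[k], trial[l])
        if abs(wrap_angle_deg(achieved - target)) > 1e-6:
            raise RuntimeError("torsion scan failed to hit the target dihedral")
        energies[m] = oracle(trial)
    return EnergyScan(grid, energies, kind="dihedral", meta={"sites": (i, j, k, l)})


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------


def _window_indices(scan: EnergyScan, policy: FitWindow) -> np.ndarray:
    e = scan.energies
    imin = int(np.argmin(e))
    if imin in (0, e.size - 1):
        raise BoundaryMinimumError(
            "scan minimum lies on the boundary; extend the scan range"
        )
    lo = hi = imin
    thresh = e[imin] + policy.energy_above_min
    while lo > 0 and e[lo - 1] <= thresh:
        lo -= 1
    while hi < e.size - 1 and e[hi + 1] <= thresh:
        hi += 1
    # widen outward symmetrically if the thermal window is too narrow
    while hi - lo + 1 < policy.min_points and (lo > 0 or hi < e.size - 1):
        if lo > 0:
            lo -= 1
        if hi < e.size - 1 and hi - lo + 1 < policy.min_points:
            hi += 1
    if hi - lo + 1 < 4:
        raise FitError("fit window has fewer than 4 points")
    return np.arange(lo, hi + 1)


def fit_harmonic(scan: EnergyScan, window: FitWindow | None = None) -> HarmonicFit:
    """Least-squares harmonic fit ``c + K (x - x0)^2`` around the minimum.

    The equilibrium ``x0`` is a free parameter, so coarse grids do not
    quantize it.  For angle-like scans the stiffness is returned per
    rad^2 while the equilibrium stays in degrees.
    """
    policy = window or FitWindow()
    idx = _window_indices(scan, policy)
    x = scan.coordinates[idx]
    e = scan.energies[idx]
    angular = scan.kind in ("angle", "dihedral", "orientation")
    xf = np.radians(x) if angular else x
    a, b, c = np.polyfit(xf, e, 2)
    if a <= 0:
        raise FitError("fitted curvature is not positive")
    x0 = -b / (2 * a)
    offset = c - b * b / (4 * a)
    resid = e - (a * xf * xf + b * xf + c)
    rms = float(np.sqrt(np.mean(resid**2)))
    lo, hi = float(x.min()), float(x.max())
    x0_out = math.degrees(x0) if angular else float(x0)
    pad = abs(x[1] - x[0]) if x.size > 1 else 0.0
    if not (lo - pad <= x0_out <= hi + pad):
        raise FitError(
            f"fitted equilibrium {x0_out:.4g} falls outside the fit window "
            f"[{lo:.4g}, {hi:.4g}]"
        )
    return HarmonicFit(
        stiffness=float(a),
        equilibrium=x0_out,
        offset=float(offset),
        window=(lo, hi),
        residual_rms=rms,
        n_used=int(x.size),
    )


def _lj_form(r: np.ndarray, eps: float, sigma: float, u0: float) -> np.ndarray:
    sr6 = (sigma / r) ** 6
    return u0 + 4.0 * eps * (sr6 * sr6 - sr6)


def fit_lj(scan: EnergyScan) -> LJFit:
    """Fit ``U0 + 4 eps [(sigma/r)^12 - (sigma/r)^6]`` around the well.

    Requires an interior minimum with a negative well relative to the
    large-separation tail.  The steep repulsive wall above the tail
    level is excluded from the fit; everything from the well outward is
    used.  Initial guesses: sigma = r_min / 2^(1/6), eps = well depth.
    """
    if scan.kind not in ("separation", "bond"):
        raise ValueError("LJ fits apply to separation scans")
    r = scan.coordinates
    e = scan.energies
    if r[0] > r[-1]:
        r, e = r[::-1], e[::-1]
    imin = int(np.argmin(e))
    if imin in (0, r.size - 1):
        raise BoundaryMinimumError(
            "scan minimum lies on the boundary; extend the scan range"
        )
    tail = e[-1]
    depth = tail - e[imin]
    if depth <= 0:
        raise FitError("purely repulsive scan: no attractive well to fit")
    # fit the region around the minimum: the lower half of the well,
    # widened (up to the whole sub-tail region) if too few samples
    for fraction in (0.5, 1.0, np.inf):
        keep = e <= e[imin] + fraction * depth
        keep &= np.arange(r.size) >= int(np.argmax(e <= tail))
        if keep.sum() >= 4:
            break
    if keep.sum() < 4:
        raise FitError("fit window has fewer than 4 points")
    r_w, e_w = r[keep], e[keep]
    p0 = (max(depth, 1e-6), r[imin] / 2 ** (1 / 6), tail)
    popt, _ = curve_fit(
        _lj_form,
        r_w,
        e_w,
        p0=p0,
        bounds=([0.0, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    eps, sigma, u0 = (float(v) for v in popt)
    resid = e_w - _lj_form(r_w, *popt)
    return LJFit(
        epsilon=eps,
        sigma=sigma,
        offset=u0,
        window=(float(r_w.min()), float(r_w.max())),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_used=int(r_w.size),
    )


# ---------------------------------------------------------------------------
# Non-bonded calibration
# ---------------------------------------------------------------------------

PairOracle = Callable[[np.ndarray, np.ndarray], float]

_AXES = {"X": np.array([1.0, 0, 0]), "Y": np.array([0, 1.0, 0]), "Z": np.array([0, 0, 1.0])}


def orientation_scan(
    residue_i: RigidResidue,
    residue_j: RigidResidue,
    axis: str,
    angle_grid: np.ndarray,
    oracle: PairOracle,
) -> tuple[EnergyScan, float]:
    """Rotate residue J about a lab axis through its own center of mass.

    Both centers of mass stay fixed.  Returns the energy profile over
    the angle grid (degrees) and the minimizing angle; ties are broken
    toward the smallest angle.
    """
    if axis not in _AXES:
        raise ValueError("axis must be 'X', 'Y' or 'Z'")
    grid = np.asarray(angle_grid, dtype=float)
    ax = _AXES[axis]
    com = residue_j.com
    energies = np.empty(grid.size)
    for m, ang in enumerate(grid):
        rot = Rotation.from_rotvec(np.radians(ang) * ax)
        rotated = residue_j.rotated(rot, about=com)
        if np.linalg.norm(rotated.com - com) > 1e-9:
            raise RuntimeError("orientation scan moved the center of mass")
        energies[m] = oracle(residue_i.positions, rotated.positions)
    scan = EnergyScan(grid, energies, kind="orientation", meta={"axis": axis})
    best = float(grid[int(np.argmin(energies))])  # argmin -> first == smallest
    return scan, best


def calibrate_pair(
    residue_i: RigidResidue,
    residue_j: RigidResidue,
    separation_range: tuple[float, float],
    step: float,
    oracle: PairOracle,
    orientation_grid: np.ndarray | None = None,
) -> tuple[PairParam, dict]:
    """Three-scenario LJ calibration for a like-species pair.

    For each lab axis, residue J is rotated to its minimum-energy
    orientation about that axis, then displaced along the center line
    between the residues; each separation scan is fitted with an LJ
    form and the scenario (eps, sigma) are averaged arithmetically.
    """
    grid = (
        np.arange(0.0, 360.0, 5.0) if orientation_grid is None else orientation_grid
    )
    line = residue_j.com - residue_i.com
    ln = np.linalg.norm(line)
    if ln == 0:
        raise ValueError("residue centers coincide: center line undefined")
    unit = line / ln
    scenarios: dict[str, dict] = {}
    fits: list[LJFit] = []
    for axis in ("X", "Y", "Z"):
        _, teta = orientation_scan(residue_i, residue_j, axis, grid, oracle)
        rot = Rotation.from_rotvec(np.radians(teta) * _AXES[axis])
        oriented = residue_j.rotated(rot)
        sep_grid = _coordinate_grid(separation_range, step)
        energies = np.empty(sep_grid.size)
        for m, target in enumerate(sep_grid):
            placed = oriented.shifted(
                residue_i.com + unit * target - oriented.com
            )
            energies[m] = oracle(residue_i.positions, placed.positions)
        scan = EnergyScan(
            sep_grid, energies, kind="separation", meta={"axis": axis, "teta": teta}
        )
        fit = fit_lj(scan)
        fits.append(fit)
        scenarios[axis] = {"teta": teta, "fit": fit, "scan": scan}
    eps = float(np.mean([f.epsilon for f in fits]))
    sigma = float(np.mean([f.sigma for f in fits]))
    return PairParam(epsilon=eps, sigma=sigma), {"scenarios": scenarios}


# ---------------------------------------------------------------------------
# Whole-chain calibration
# ---------------------------------------------------------------------------


class ChainOracle(Protocol):
    """Energy source for whole-chain calibration.

    ``cluster_energy`` receives the template-chain indices of the
    cluster (0-based), trial coordinates for exactly those sites, and
    the scan kind ('bond' | 'angle' | 'dihedral'); bending and torsion
    oracles are expected to drop the non-bonded contributions the
    corresponding calibration excludes.
    """

    def reference_positions(self) -> np.ndarray: ...

    def cluster_energy(
        self, indices: tuple[int, ...], positions: np.ndarray, kind: str
    ) -> float: ...

    def residue_template(self, species: str) -> RigidResidue: ...

    def pair_energy(
        self, species: str, positions_i: np.ndarray, positions_j: np.ndarray
    ) -> float: ...


@dataclass(frozen=True)
class CalibrationConfig:
    bond_halfwidth: float = 0.3  # A
    bond_step: float = 0.02  # A
    angle_halfwidth: float = 15.0  # deg
    angle_step: float = 1.0
    dihedral_halfwidth: float = 20.0  # deg
    dihedral_step: float = 1.0
    pair_separations: tuple[float, float] = (3.6, 11.0)
    pair_step: float = 0.05
    orientation_step: float = 5.0
    initial_pair_separation: float = 7.0
    window: FitWindow = field(default_factory=FitWindow)
    cutoff: float = 12.0
    mixing: str = "geometric"
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)


def calibrate_chain(
    sequence: str,
    oracle: ChainOracle,
    config: CalibrationConfig | None = None,
) -> tuple[ForceField, dict]:
    """Calibrate every bonded term and every like-species pair of a chain.

    Iterates the n-1 bonds, n-2 angles and n-3 dihedrals of the
    template chain (scans centered on the oracle's minimized reference
    geometry) plus one LJ calibration per distinct residue species.
    Terms whose scan lacks an interior minimum are listed in the
    returned report under ``failures`` and left unset in the force
    field.
    """
    cfg = config or CalibrationConfig()
    topo = build_chain(sequence)
    ref = np.asarray(oracle.reference_positions(), dtype=float)
    if ref.shape != (topo.n_beads, 3):
        raise ValueError("reference positions must be (n_beads, 3)")
    ff = ForceField(
        cutoff=cfg.cutoff, mixing=cfg.mixing, exclusions=cfg.exclusions
    )
    report: dict = {"bonds": {}, "angles": {}, "dihedrals": {}, "pairs": {}, "failures": []}

    for bond in topo.bonds:
        ids = (bond.i, bond.j)
        cluster = ref[list(ids)]
        r_c = float(np.linalg.norm(cluster[1] - cluster[0]))
        rng = (max(r_c - cfg.bond_halfwidth, 0.2), r_c + cfg.bond_halfwidth)
        try:
            scan = scan_bond(
                cluster, 0, 1, rng, cfg.bond_step,
                lambda p, ids=ids: oracle.cluster_energy(ids, p, "bond"),
            )
            fit = fit_harmonic(scan, cfg.window)
        except FitError as err:
            report["failures"].append(("bond", bond.type_key, str(err)))
            continue
        ff.bonds[bond.type_key] = BondParam(k=fit.stiffness, r0=fit.equilibrium)
        report["bonds"][bond.type_key] = fit

    for angle in topo.angles:
        ids = (angle.i, angle.j, angle.k)
        cluster = ref[list(ids)]
        t_c = measure_angle(*cluster)
        rng = (
            max(t_c - cfg.angle_halfwidth, 1.0),
            min(t_c + cfg.angle_halfwidth, 179.0),
        )
        try:
            scan = scan_angle(
                cluster, 0, 1, 2, rng, cfg.angle_step,
                lambda p, ids=ids: oracle.cluster_energy(ids, p, "angle"),
            )
            fit = fit_harmonic(scan, cfg.window)
        except (FitError, ValueError) as err:
            report["failures"].append(("angle", angle.type_key, str(err)))
            continue
        ff.angles[angle.type_key] = AngleParam(
            k=fit.stiffness, theta0=min(fit.equilibrium, 180.0)
        )
        report["angles"][angle.type_key] = fit

    for dih in topo.dihedrals:
        ids = (dih.i, dih.j, dih.k, dih.l)
        cluster = ref[list(ids)]
        p_c = measure_dihedral(*cluster)
        rng = (p_c - cfg.dihedral_halfwidth, p_c + cfg.dihedral_halfwidth)
        try:
            scan = scan_dihedral(
                cluster, 0, 1, 2, 3, rng, cfg.dihedral_step,
                lambda p, ids=ids: oracle.cluster_energy(ids, p, "dihedral"),
            )
            fit = fit_harmonic(scan, cfg.window)
        except (FitError, ValueError) as err:
            report["failures"].append(("dihedral", dih.type_key, str(err)))
            continue
        ff.dihedrals[dih.type_key] = DihedralParam(
            k=fit.stiffness, phi0=wrap_angle_deg(fit.equilibrium)
        )
        report["dihedrals"][dih.type_key] = fit

    orientation_grid = np.arange(0.0, 360.0, cfg.orientation_step)
    for species in sorted(set(sequence)):
        template = oracle.residue_template(species)
        res_i = template.shifted(-template.com)
        res_j = template.shifted(
            -template.com + np.array([cfg.initial_pair_separation, 0.0, 0.0])
        )
        try:
            param, pair_report = calibrate_pair(
                res_i,
                res_j,
                cfg.pair_separations,
                cfg.pair_step,
                lambda a, b, s=species: oracle.pair_energy(s, a, b),
                orientation_grid=orientation_grid,
            )
        except FitError as err:
            report["failures"].append(("pair", species, str(err)))
            continue
        ff.pairs[species] = param
        report["pairs"][species] = pair_report

    return ff, report
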