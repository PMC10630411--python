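"""The CG potential: harmonic bonded terms plus Lennard-Jones pairs.

Total energy of a configuration is

    E_total = E_b + E_a + E_d + E_vdW + U_o

with, per interaction,

    E_b   = K_b (r - r_o)^2
    E_a   = K_a (theta - theta_o)^2
    E_d   = K_d (phi - phi_o)^2          (deviation wrapped to (-pi, pi])
    E_vdW = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ]   truncated at the cutoff

Stiffnesses are kcal/mol per A^2 (bonds) or per rad^2 (angles,
dihedrals); equilibrium angles are stored in degrees.  Non-bonded
parameters are per amino-acid species, combined across species with a
geometric mixing rule on both eps and sigma.  The model has no
electrostatic term.  First-neighbour (1-2) pairs are always excluded
from the LJ sum; 1-3 and 1-4 exclusions are configurable (default:
exclude 1-3, include 1-4).

All distances use the minimum-image convention in an orthorhombic
periodic box.  The virial stress tensor is reported tensile-positive,
in GPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import SimState, Topology
from .units import KCAL_A3_TO_GPA, MVV2E

__all__ = [
    "BondParam",
    "AngleParam",
    "DihedralParam",
    "PairParam",
    "ExclusionPolicy",
    "ForceField",
    "NonFiniteEnergyError",
    "EnergyComponents",
    "mix_pair",
    "NeighborList",
    "build_neighbor_list",
    "Evaluator",
    "total_energy",
    "forces",
    "virial_stress",
    "wrap_angle_deg",
]


class NonFiniteEnergyError(RuntimeError):
    """An energy evaluation diverged (e.g. overlapping non-excluded beads)."""


@dataclass(frozen=True)
class BondParam:
    k: float  # kcal/mol/A^2
    r0: float  # A

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("bond stiffness must be non-negative")
        if self.r0 <= 0:
            raise ValueError("equilibrium bond length must be positive")


@dataclass(frozen=True)
class AngleParam:
    k: float  # kcal/mol/rad^2
    theta0: float  # degrees, (0, 180]

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("angle stiffness must be non-negative")
        if not 0.0 < self.theta0 <= 180.0:
            raise ValueError("theta0 must lie in (0, 180] degrees")


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees onto (-180, 180]."""
    wrapped = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


@dataclass(frozen=True)
class DihedralParam:
    k: float  # kcal/mol/rad^2
    phi0: float  # degrees, (-180, 180]

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("dihedral stiffness must be non-negative")
        if not -180.0 < self.phi0 <= 180.0:
            raise ValueError("phi0 must lie in (-180, 180] degrees")


@dataclass(frozen=True)
class PairParam:
    epsilon: float  # kcal/mol
    sigma: float  # A

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def mix_pair(p_i: PairParam, p_j: PairParam, rule: str = "geometric") -> PairParam:
    """Combine like-species LJ parameters into a cross-species pair.

    ``geometric`` takes the geometric mean of both eps and sigma (the
    default throughout this package); ``lorentz`` is the
    Lorentz-Berthelot alternative (arithmetic sigma) kept for
    sensitivity checks.
    """
    if rule == "geometric":
        return PairParam(
            epsilon=math.sqrt(p_i.epsilon * p_j.epsilon),
            sigma=math.sqrt(p_i.sigma * p_j.sigma),
        )
    if rule == "lorentz":
        return PairParam(
            epsilon=math.sqrt(p_i.epsilon * p_j.epsilon),
            sigma=0.5 * (p_i.sigma + p_j.sigma),
        )
    raise ValueError(f"unknown mixing rule {rule!r}")


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which topological neighbours are removed from the LJ sum.

    Directly bonded (1-2) pairs are always excluded.
    """

    exclude_13: bool = True
    exclude_14: bool = False


@dataclass
class ForceField:
    bonds: dict[str, BondParam] = field(default_factory=dict)
    angles: dict[str, AngleParam] = field(default_factory=dict)
    dihedrals: dict[str, DihedralParam] = field(default_factory=dict)
    pairs: dict[str, PairParam] = field(default_factory=dict)
    cutoff: float = 12.0
    mixing: str = "geometric"
    exclusions: ExclusionPolicy = field(default_factory=ExclusionPolicy)
    energy_offset: float = 0.0  # U_o: stored constant, never enters forces
    shift_lj: bool = False  # energy-shifted LJ variant (zero at cutoff)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.pairs:
            max_sigma = max(p.sigma for p in self.pairs.values())
            if self.cutoff <= max_sigma:
                raise ValueError("cutoff must exceed the largest pair sigma")

    def mixed_pair(self, species_i: str, species_j: str) -> PairParam:
        return mix_pair(self.pairs[species_i], self.pairs[species_j], self.mixing)


@dataclass(frozen=True)
class EnergyComponents:
    bond: float
    angle: float
    dihedral: float
    vdw: float
    offset: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.dihedral + self.vdw + self.offset


# ---------------------------------------------------------------------------
# Neighbor list
# ---------------------------------------------------------------------------


class NeighborList:
    """Verlet list over a KD-tree, rebuilt when displacements exceed skin/2.

    Contains every non-excluded pair within ``cutoff`` of each other
    (may contain extras within ``cutoff + skin``).  Each entry carries
    an integer image shift: the separation of entry m is
    ``pos[j] - pos[i] + shifts[m] * box``.  When a periodic box edge is
    shorter than twice the listing radius, a bead interacts with more
    than one image of its neighbours (and with its own images); those
    image pairs are enumerated explicitly, so small boxes such as the
    4x4 bundle lattice evaluate correctly.
    """

    def __init__(self, cutoff: float, skin: float = 2.0):
        if cutoff <= 0 or skin < 0:
            raise ValueError("cutoff must be positive and skin non-negative")
        self.cutoff = cutoff
        self.skin = skin
        self._ref_positions: np.ndarray | None = None
        self._ref_box: np.ndarray | None = None
        self.pairs: np.ndarray = np.empty((0, 2), dtype=np.intp)
        self.shifts: np.ndarray = np.empty((0, 3))

    def _find_pairs(self, state: SimState) -> tuple[np.ndarray, np.ndarray]:
        from scipy.spatial import cKDTree

        r = self.cutoff + self.skin
        pos = state.positions
        box = state.box
        no_pairs = (np.empty((0, 2), dtype=np.intp), np.empty((0, 3)))

        if not np.any(state.periodic):
            tree = cKDTree(pos)
            pairs = tree.query_pairs(r, output_type="ndarray")
            if pairs.size == 0:
                return no_pairs
            return pairs.astype(np.intp), np.zeros((pairs.shape[0], 3))

        if not np.all(state.periodic):
            # mixed periodicity: brute-force minimum image on periodic axes
            n = pos.shape[0]
            iu = np.triu_indices(n, k=1)
            d = pos[iu[1]] - pos[iu[0]]
            shifts = np.zeros_like(d)
            for a in range(3):
                if state.periodic[a]:
                    shifts[:, a] = -np.round(d[:, a] / box[a])
                    d[:, a] += shifts[:, a] * box[a]
            keep = (d * d).sum(axis=1) <= r * r
            if not keep.any():
                return no_pairs
            pairs = np.stack([iu[0][keep], iu[1][keep]], axis=1)
            return pairs.astype(np.intp), shifts[keep]

        wrapped = np.mod(pos, box)
        wrap_shift = np.round((pos - wrapped) / box)  # pos = wrapped + k * box
        # axes longer than twice the listing radius admit a single image per
        # pair and are handled toroidally by the tree; shorter axes need
        # their periodic images enumerated explicitly
        long_axis = box > 2.0 * r
        tree = cKDTree(wrapped, boxsize=np.where(long_axis, box, 0.0))

        def _long_axis_shift(d: np.ndarray) -> np.ndarray:
            s = np.zeros_like(d)
            for a in range(3):
                if long_axis[a]:
                    s[:, a] = -np.round(d[:, a] / box[a])
            return s

        pair_chunks: list[np.ndarray] = []
        shift_chunks: list[np.ndarray] = []
        direct = tree.query_pairs(r, output_type="ndarray")
        if direct.size:
            i, j = direct[:, 0], direct[:, 1]
            d = wrapped[j] - wrapped[i]
            pair_chunks.append(direct)
            shift_chunks.append(
                _long_axis_shift(d) + wrap_shift[i] - wrap_shift[j]
            )
        n_img = np.where(long_axis, 0, (np.floor(r / box) + 1).astype(int))
        # half the nonzero shifts (the other half are the same pairs reversed)
        for sx in range(-n_img[0], n_img[0] + 1):
            for sy in range(-n_img[1], n_img[1] + 1):
                for sz in range(-n_img[2], n_img[2] + 1):
                    s = (sx, sy, sz)
                    if s <= (0, 0, 0):
                        continue
                    svec = np.array(s, dtype=float)
                    hits = tree.query_ball_point(wrapped + svec * box, r)
                    lens = [len(h) for h in hits]
                    if not any(lens):
                        continue
                    jj = np.repeat(np.arange(len(hits)), lens)
                    ii = np.concatenate(
                        [np.asarray(h, dtype=np.intp) for h in hits if h]
                    )
                    # entry: bead ii interacts with the image of bead jj
                    # shifted by s (plus any toroidal-axis correction)
                    d = wrapped[jj] + svec * box - wrapped[ii]
                    pair_chunks.append(np.stack([ii, jj], axis=1))
                    shift_chunks.append(
                        svec
                        + _long_axis_shift(d)
                        + wrap_shift[ii]
                        - wrap_shift[jj]
                    )
        if not pair_chunks:
            return no_pairs
        pairs = np.vstack(pair_chunks).astype(np.intp)
        shifts = np.vstack(shift_chunks)
        return pairs, shifts

    def update(self, state: SimState) -> bool:
        """Rebuild if stale; return True when a rebuild happened."""
        if self._ref_positions is not None and self._ref_positions.shape == (
            state.n,
            3,
        ):
            box_same = np.array_equal(self._ref_box, state.box)
            if box_same:
                disp = state.positions - self._ref_positions
                if np.abs(disp).max(initial=0.0) < self.skin / 2:
                    return False
        self.pairs, self.shifts = self._find_pairs(state)
        self._ref_positions = state.positions.copy()
        self._ref_box = state.box.copy()
        return True


def build_neighbor_list(
    state: SimState, cutoff: float, skin: float = 2.0
) -> NeighborList:
    nl = NeighborList(cutoff=cutoff, skin=skin)
    nl.update(state)
    return nl


# ---------------------------------------------------------------------------
# Evaluator
# ---------------------------------------------------------------------------


def _min_image(d: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    out = d.copy()
    for a in range(3):
        if periodic[a]:
            out[..., a] -= box[a] * np.round(out[..., a] / box[a])
    return out


def _scatter_add(total: np.ndarray, idx: np.ndarray, values: np.ndarray) -> None:
    # np.bincount is much faster than np.ufunc.at for repeated indices
    n = total.shape[0]
    for a in range(3):
        total[:, a] += np.bincount(idx, weights=values[:, a], minlength=n)


class Evaluator:
    """Binds a topology to a force field for fast repeated evaluation.

    Bonded parameters are resolved once into flat arrays; the LJ table
    is mixed into a species-by-species matrix; exclusions are encoded
    as a sorted array of pair codes.  All public energies are kcal/mol,
    forces kcal/mol/A, virial kcal/mol (W = sum r (x) F per interaction).
    """

    def __init__(self, topo: Topology, ff: ForceField):
        self.topo = topo
        self.ff = ff
        n = topo.n_beads

        def _resolve(table: Mapping, key: str, kind: str):
            try:
                return table[key]
            except KeyError:
                raise KeyError(f"no {kind} parameters for type key {key!r}") from None

        if topo.bonds:
            self.bond_idx = np.array([(b.i, b.j) for b in topo.bonds], dtype=np.intp)
            bp = [_resolve(ff.bonds, b.type_key, "bond") for b in topo.bonds]
            self.bond_k = np.array([p.k for p in bp])
            self.bond_r0 = np.array([p.r0 for p in bp])
        else:
            self.bond_idx = np.empty((0, 2), dtype=np.intp)
            self.bond_k = self.bond_r0 = np.empty(0)

        if topo.angles:
            self.angle_idx = np.array(
                [(a.i, a.j, a.k) for a in topo.angles], dtype=np.intp
            )
            ap = [_resolve(ff.angles, a.type_key, "angle") for a in topo.angles]
            self.angle_k = np.array([p.k for p in ap])
            self.angle_t0 = np.radians(np.array([p.theta0 for p in ap]))
        else:
            self.angle_idx = np.empty((0, 3), dtype=np.intp)
            self.angle_k = self.angle_t0 = np.empty(0)

        if topo.dihedrals:
            self.dih_idx = np.array(
                [(d.i, d.j, d.k, d.l) for d in topo.dihedrals], dtype=np.intp
            )
            dp = [_resolve(ff.dihedrals, d.type_key, "dihedral") for d in topo.dihedrals]
            self.dih_k = np.array([p.k for p in dp])
            self.dih_p0 = np.radians(np.array([p.phi0 for p in dp]))
        else:
            self.dih_idx = np.empty((0, 4), dtype=np.intp)
            self.dih_k = self.dih_p0 = np.empty(0)

        # species index per bead + mixed LJ matrices
        species = sorted(set(topo.species))
        self._species = species
        if ff.pairs:
            missing = [s for s in species if s not in ff.pairs]
            if missing:
                raise KeyError(f"no pair parameters for species {missing}")
            ns = len(species)
            eps = np.zeros((ns, ns))
            sig = np.zeros((ns, ns))
            for a, sa in enumerate(species):
                for b, sb in enumerate(species):
                    m = ff.mixed_pair(sa, sb)
                    eps[a, b] = m.epsilon
                    sig[a, b] = m.sigma
            self.eps_matrix = eps
            self.sig_matrix = sig
            self.has_pairs = True
        else:
            self.has_pairs = False
        self.species_index = np.array(
            [species.index(s) for s in topo.species], dtype=np.intp
        )

        # excluded pair codes (i * n + j, i < j), sorted for searchsorted
        excl: set[int] = set()

        def _code(i: int, j: int) -> int:
            a, b = (i, j) if i < j else (j, i)
            return a * n + b

        for b in topo.bonds:
            excl.add(_code(b.i, b.j))
        if ff.exclusions.exclude_13:
            for a in topo.angles:
                excl.add(_code(a.i, a.k))
        if ff.exclusions.exclude_14:
            for d in topo.dihedrals:
                excl.add(_code(d.i, d.l))
        self.excluded_codes = np.array(sorted(excl), dtype=np.int64)
        self.n = n
        self._nlist: NeighborList | None = None
        self._filtered: tuple[np.ndarray, np.ndarray] | None = None

    # -- pair bookkeeping ---------------------------------------------------

    def _filter_excluded(
        self, pairs: np.ndarray, shifts: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        if pairs.size == 0 or self.excluded_codes.size == 0:
            return pairs, shifts
        lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        codes = lo * self.n + hi
        pos = np.searchsorted(self.excluded_codes, codes)
        pos = np.clip(pos, 0, self.excluded_codes.size - 1)
        is_excl = self.excluded_codes[pos] == codes
        return pairs[~is_excl], shifts[~is_excl]

    def _pair_list(
        self, state: SimState, skin: float = 2.0
    ) -> tuple[np.ndarray, np.ndarray]:
        if not self.has_pairs:
            return np.empty((0, 2), dtype=np.intp), np.empty((0, 3))
        if self._nlist is None or self._nlist.cutoff != self.ff.cutoff:
            self._nlist = NeighborList(self.ff.cutoff, skin=skin)
        rebuilt = self._nlist.update(state)
        if rebuilt or self._filtered is None:
            self._filtered = self._filter_excluded(
                self._nlist.pairs, self._nlist.shifts
            )
        return self._filtered

    # -- term evaluators ----------------------------------------------------

    def _bond_terms(self, pos, box, periodic, want_forces, want_virial=True):
        if self.bond_idx.shape[0] == 0:
            return 0.0, None, None
        i, j = self.bond_idx[:, 0], self.bond_idx[:, 1]
        d = _min_image(pos[j] - pos[i], box, periodic)
        r = np.linalg.norm(d, axis=1)
        dr = r - self.bond_r0
        energy = float(np.sum(self.bond_k * dr * dr))
        if not want_forces:
            return energy, None, None
        with np.errstate(divide="ignore", invalid="ignore"):
            fmag = np.where(r > 0, 2.0 * self.bond_k * dr / r, 0.0)
        f_i = fmag[:, None] * d  # pulls i toward j when stretched
        forces = np.zeros_like(pos)
        _scatter_add(forces, i, f_i)
        _scatter_add(forces, j, -f_i)
        virial = (
            -(d[:, :, None] * f_i[:, None, :]).sum(axis=0) if want_virial else None
        )
        return energy, forces, virial

    def _angle_terms(self, pos, box, periodic, want_forces, want_virial=True):
        if self.angle_idx.shape[0] == 0:
            return 0.0, None, None
        i, j, k = (self.angle_idx[:, c] for c in range(3))
        d1 = _min_image(pos[i] - pos[j], box, periodic)
        d2 = _min_image(pos[k] - pos[j], box, periodic)
        r1 = np.linalg.norm(d1, axis=1)
        r2 = np.linalg.norm(d2, axis=1)
        c = np.clip((d1 * d2).sum(axis=1) / (r1 * r2), -1.0, 1.0)
        theta = np.arccos(c)
        dtheta = theta - self.angle_t0
        energy = float(np.sum(self.angle_k * dtheta * dtheta))
        if not want_forces:
            return energy, None, None
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
        coef = 2.0 * self.angle_k * dtheta / s  # = dE/dtheta / sin
        dc_di = d2 / (r1 * r2)[:, None] - (c / (r1 * r1))[:, None] * d1
        dc_dk = d1 / (r1 * r2)[:, None] - (c / (r2 * r2))[:, None] * d2
        f_i = coef[:, None] * dc_di
        f_k = coef[:, None] * dc_dk
        forces = np.zeros_like(pos)
        _scatter_add(forces, i, f_i)
        _scatter_add(forces, k, f_k)
        _scatter_add(forces, j, -(f_i + f_k))
        virial = (
            (d1[:, :, None] * f_i[:, None, :]).sum(axis=0)
            + (d2[:, :, None] * f_k[:, None, :]).sum(axis=0)
            if want_virial
            else None
        )
        return energy, forces, virial

    def _dihedral_terms(self, pos, box, periodic, want_forces, want_virial=True):
        if self.dih_idx.shape[0] == 0:
            return 0.0, None, None
        i, j, k, l = (self.dih_idx[:, c] for c in range(4))
        b1 = _min_image(pos[j] - pos[i], box, periodic)
        b2 = _min_image(pos[k] - pos[j], box, periodic)
        b3 = _min_image(pos[l] - pos[k], box, periodic)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        x = (n1 * n2).sum(axis=1)
        y = (np.cross(n1, n2) * b2).sum(axis=1) / b2n
        phi = np.arctan2(y, x)
        dphi = phi - self.dih_p0
        dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi  # branch nearest zero
        energy = float(np.sum(self.dih_k * dphi * dphi))
        if not want_forces:
            return energy, None, None
        dedphi = 2.0 * self.dih_k * dphi
        n1sq = (n1 * n1).sum(axis=1)
        n2sq = (n2 * n2).sum(axis=1)
        # guard collinear (undefined dihedral): zero force, energy already ~const
        safe1 = np.maximum(n1sq, 1e-16)
        safe2 = np.maximum(n2sq, 1e-16)
        dphi_di = -(b2n / safe1)[:, None] * n1
        dphi_dl = (b2n / safe2)[:, None] * n2
        p = (b1 * b2).sum(axis=1) / (b2n * b2n)
        q = (b3 * b2).sum(axis=1) / (b2n * b2n)
        dphi_dj = -(p + 1.0)[:, None] * dphi_di + q[:, None] * dphi_dl
        dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
        f_i = -dedphi[:, None] * dphi_di
        f_j = -dedphi[:, None] * dphi_dj
        f_k = -dedphi[:, None] * dphi_dk
        f_l = -dedphi[:, None] * dphi_dl
        forces = np.zeros_like(pos)
        _scatter_add(forces, i, f_i)
        _scatter_add(forces, j, f_j)
        _scatter_add(forces, k, f_k)
        _scatter_add(forces, l, f_l)
        # positions relative to j within the (unwrapped) interaction
        r_i = -b1
        r_k = b2
        r_l = b2 + b3
        virial = (
            (r_i[:, :, None] * f_i[:, None, :]).sum(axis=0)
            + (r_k[:, :, None] * f_k[:, None, :]).sum(axis=0)
            + (r_l[:, :, None] * f_l[:, None, :]).sum(axis=0)
            if want_virial
            else None
        )
        return energy, forces, virial

    def _pair_terms(self, pos, box, periodic, want_forces, state, want_virial=True):
        if not self.has_pairs:
            return 0.0, None, None
        pairs, shifts = self._pair_list(state)
        if pairs.shape[0] == 0:
            return 0.0, None, None
        i, j = pairs[:, 0], pairs[:, 1]
        d = pos[j] - pos[i] + shifts * box
        r2 = (d * d).sum(axis=1)
        within = r2 <= self.ff.cutoff**2
        i, j, d, r2 = i[within], j[within], d[within], r2[within]
        if r2.size == 0:
            return 0.0, None, None
        si, sj = self.species_index[i], self.species_index[j]
        eps = self.eps_matrix[si, sj]
        sig = self.sig_matrix[si, sj]
        if np.any(r2 <= 1e-12):
            raise NonFiniteEnergyError(
                "overlapping non-excluded beads (r -> 0): energy diverges"
            )
        inv2 = (sig * sig) / r2
        inv6 = inv2**3
        inv12 = inv6 * inv6
        e_pairs = 4.0 * eps * (inv12 - inv6)
        if self.ff.shift_lj:
            sc = (sig / self.ff.cutoff) ** 6
            e_pairs = e_pairs - 4.0 * eps * (sc * sc - sc)
        energy = float(e_pairs.sum())
        if not np.isfinite(energy):
            raise NonFiniteEnergyError("non-finite LJ energy")
        if not want_forces:
            return energy, None, None
        # dE/dr * (1/r): force on i along +d is dE/dr
        dEdr_over_r = -24.0 * eps * (2.0 * inv12 - inv6) / r2
        f_i = dEdr_over_r[:, None] * d  # F_i = +dE/dr * dhat
        forces = np.zeros_like(pos)
        _scatter_add(forces, i, f_i)
        _scatter_add(forces, j, -f_i)
        virial = (
            -(d[:, :, None] * f_i[:, None, :]).sum(axis=0) if want_virial else None
        )
        return energy, forces, virial

    # -- public evaluation --------------------------------------------------

    def evaluate(
        self, state: SimState, want_forces: bool = True
    ) -> tuple[EnergyComponents, np.ndarray | None, np.ndarray | None]:
        """Energy components, per-bead forces and configurational virial.

        The virial W = sum over interactions of r (x) F (kcal/mol); the
        tensile-positive stress is -(W + kinetic)/V.
        """
        pos, box, periodic = state.positions, state.box, state.periodic
        total_f = np.zeros_like(pos) if want_forces else None
        total_w = np.zeros((3, 3)) if want_forces else None
        comps = []
        for term in (self._bond_terms, self._angle_terms, self._dihedral_terms):
            e, f, w = term(pos, box, periodic, want_forces)
            comps.append(e)
            if want_forces and f is not None:
                total_f += f
                total_w += w
        e, f, w = self._pair_terms(pos, box, periodic, want_forces, state)
        comps.append(e)
        if want_forces and f is not None:
            total_f += f
            total_w += w
        components = EnergyComponents(
            bond=comps[0],
            angle=comps[1],
            dihedral=comps[2],
            vdw=comps[3],
            offset=self.ff.energy_offset,
        )
        if not np.isfinite(components.total):
            raise NonFiniteEnergyError("non-finite total energy")
        return components, total_f, total_w

    def energy(self, state: SimState) -> float:
        return self.evaluate(state, want_forces=False)[0].total

    def bonded_forces(self, state: SimState) -> tuple[float, np.ndarray]:
        """Energy and forces of the bond + angle + dihedral terms only.

        Used by the two-level integrator, which steps the stiff bonded
        forces on a shorter inner timestep.
        """
        pos, box, periodic = state.positions, state.box, state.periodic
        energy = 0.0
        total = np.zeros_like(pos)
        for term in (self._bond_terms, self._angle_terms, self._dihedral_terms):
            e, f, _ = term(pos, box, periodic, True, want_virial=False)
            energy += e
            if f is not None:
                total += f
        return energy, total

    def nonbonded_forces(self, state: SimState) -> tuple[float, np.ndarray]:
        """Energy and forces of the truncated LJ term only."""
        pos, box, periodic = state.positions, state.box, state.periodic
        e, f, _ = self._pair_terms(pos, box, periodic, True, state, want_virial=False)
        if f is None:
            return e, np.zeros_like(pos)
        return e, f

    def stress(self, state: SimState, include_kinetic: bool = False) -> np.ndarray:
        """Virial stress tensor in GPa, tensile positive."""
        if state.volume <= 0:
            raise ValueError("periodic box must have positive volume")
        _, _, w = self.evaluate(state, want_forces=True)
        if include_kinetic and state.velocities is not None:
            v = state.velocities
            m = self.topo.masses
            w = w + MVV2E * np.einsum("n,ni,nj->ij", m, v, v)
        return -w / state.volume * KCAL_A3_TO_GPA


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------


def total_energy(state: SimState, topo: Topology, ff: ForceField) -> EnergyComponents:
    """Energy components (bond, angle, dihedral, vdW, offset) in kcal/mol."""
    return Evaluator(topo, ff).evaluate(state, want_forces=False)[0]


def forces(state: SimState, topo: Topology, ff: ForceField) -> np.ndarray:
    """Analytic per-bead forces, kcal/mol/A."""
    return Evaluator(topo, ff).evaluate(state, want_forces=True)[1]


def virial_stress(
    state: SimState,
    topo: Topology,
    ff: ForceField,
    include_kinetic: bool = False,
) -> np.ndarray:
    """3x3 virial stress tensor in GPa, tensile positive.

    The kinetic contribution is added only when ``include_kinetic`` is
    set and the state carries velocities.
    """
    return Evaluator(topo, ff).stress(state, include_kinetic=include_kinetic)
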