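"""Coarse-grained topology construction for MaSp1 silk assemblies.

One bead per amino-acid residue, placed at the residue center of mass and
carrying the residue mass.  Bonded interactions run along the backbone:
an n-bead chain has n-1 bonds, n-2 angles and n-3 dihedrals.  Bonded type
keys are *position specific* within the template chain (the bond between
residues 9 and 10 is a different type from the one between 10 and 11,
even when the species match) and are shared across replicated chains.
Non-bonded types are per amino-acid species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import AMU_A3_TO_G_CM3

__all__ = [
    "RESIDUE_MASSES",
    "RESIDUE_ATOM_COUNTS",
    "BeadSpec",
    "BondInstance",
    "AngleInstance",
    "DihedralInstance",
    "Topology",
    "SimState",
    "PackingError",
    "masp1_sequence",
    "build_chain",
    "chain_state",
    "dof_reduction",
    "dof_reduction_table",
    "build_lattice",
    "replicate",
    "random_pack",
    "map_to_cg",
]

#: Average residue (amino acid minus water) masses in u.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

#: All-hydrogen atom counts for a *neutral* in-chain residue (formula of the
#: amino acid minus one water).  Used by :func:`dof_reduction`.
RESIDUE_ATOM_COUNTS: dict[str, int] = {
    "G": 7, "A": 10, "S": 11, "P": 14, "V": 16, "T": 14, "C": 11,
    "L": 19, "I": 19, "N": 14, "D": 13, "Q": 17, "K": 21, "E": 16,
    "M": 17, "H": 17, "F": 20, "R": 23, "Y": 21, "W": 24,
}

_MASP1_MOTIF = "GGAGQGGYGGLGSQGAGRGGLGGQGAG"


def masp1_sequence() -> str:
    """Return the 60-residue MaSp1 construct: motif + poly-alanine + motif.

    The glycine-rich 27-residue motif flanks a six-residue poly-alanine
    block (residues 28-33), the crystalline segment of dragline silk.
    """
    return _MASP1_MOTIF + "AAAAAA" + _MASP1_MOTIF


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: a whole residue collapsed to a point mass."""

    residue_code: str
    index: int  # 1-based position within its chain
    mass: float
    pair_type: str
    chain: int = 0

    def __post_init__(self) -> None:
        if self.residue_code not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue code {self.residue_code!r}")
        if self.mass <= 0:
            raise ValueError("bead mass must be positive")
        if self.pair_type != self.residue_code:
            raise ValueError("pair_type must equal residue_code")


@dataclass(frozen=True)
class BondInstance:
    i: int
    j: int
    type_key: str


@dataclass(frozen=True)
class AngleInstance:
    i: int
    j: int
    k: int
    type_key: str


@dataclass(frozen=True)
class DihedralInstance:
    i: int
    j: int
    k: int
    l: int
    type_key: str


@dataclass
class Topology:
    """Connectivity of a CG system: beads plus bonded-term instances.

    ``copy_labels`` optionally tags each bead with the index of the
    rigid copy (bundle) it belongs to, set by :func:`replicate` and
    :func:`random_pack` and used by orientation analysis.
    """

    beads: list[BeadSpec]
    bonds: list[BondInstance] = field(default_factory=list)
    angles: list[AngleInstance] = field(default_factory=list)
    dihedrals: list[DihedralInstance] = field(default_factory=list)
    copy_labels: np.ndarray | None = None

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_chains(self) -> int:
        return len({b.chain for b in self.beads})

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def species(self) -> list[str]:
        return [b.pair_type for b in self.beads]

    def validate(self) -> None:
        n = self.n_beads
        seen: set[tuple[int, ...]] = set()
        for inst in (*self.bonds, *self.angles, *self.dihedrals):
            idx = tuple(
                getattr(inst, a) for a in ("i", "j", "k", "l") if hasattr(inst, a)
            )
            if any(not (0 <= x < n) for x in idx):
                raise ValueError(f"bonded instance {inst} has out-of-range index")
            key = tuple(sorted(idx))
            if key in seen:
                raise ValueError(f"duplicate bonded instance {inst}")
            seen.add(key)


@dataclass
class SimState:
    """Coordinates, orthorhombic periodic box, optional velocities.

    Positions in A; box edge lengths in A; velocities in A/fs.
    """

    positions: np.ndarray
    box: np.ndarray
    periodic: np.ndarray = field(
        default_factory=lambda: np.array([True, True, True])
    )
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.periodic = np.asarray(self.periodic, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def copy(self) -> "SimState":
        return SimState(
            positions=self.positions.copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            velocities=None if self.velocities is None else self.velocities.copy(),
        )


class PackingError(RuntimeError):
    """Raised when random packing cannot place all copies."""

    def __init__(self, message: str, placed: int):
        super().__init__(message)
        self.placed = placed


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, letter in enumerate(sequence, start=1):
        if letter not in RESIDUE_MASSES:
            raise ValueError(
                f"invalid residue letter {letter!r} at position {pos}"
            )


def build_chain(sequence: str, chain: int = 0, offset: int = 0) -> Topology:
    """Build the CG topology of a single chain.

    Type keys are position specific: the bond between residues ``p`` and
    ``p+1`` (1-based) is keyed ``"p-(p+1)"``, e.g. ``"9-10"``; angles and
    dihedrals follow the same convention (``"2-3-4"``, ``"3-4-5-6"``).

    Parameters
    ----------
    sequence : one-letter amino-acid string.
    chain : chain id stored on each bead.
    offset : global index of the chain's first bead (used when the chain
        is embedded in a multi-chain topology).
    """
    _validate_sequence(sequence)
    beads = [
        BeadSpec(
            residue_code=c,
            index=p,
            mass=RESIDUE_MASSES[c],
            pair_type=c,
            chain=chain,
        )
        for p, c in enumerate(sequence, start=1)
    ]
    n = len(sequence)
    bonds = [
        BondInstance(offset + i, offset + i + 1, f"{i + 1}-{i + 2}")
        for i in range(n - 1)
    ]
    angles = [
        AngleInstance(
            offset + i, offset + i + 1, offset + i + 2, f"{i + 1}-{i + 2}-{i + 3}"
        )
        for i in range(n - 2)
    ]
    dihedrals = [
        DihedralInstance(
            offset + i,
            offset + i + 1,
            offset + i + 2,
            offset + i + 3,
            f"{i + 1}-{i + 2}-{i + 3}-{i + 4}",
        )
        for i in range(n - 3)
    ]
    return Topology(beads=beads, bonds=bonds, angles=angles, dihedrals=dihedrals)


_GOLDEN_ANGLE = math.radians(137.50776405003785)


def chain_state(
    topo: Topology,
    bond_lengths: Sequence[float] | float = 3.8,
    box_pad: float = 30.0,
    helical_amplitude: float = 0.4,
) -> SimState:
    """Extended single-chain geometry along Z.

    Pre-equilibration geometry only: per-bond spacings default to 3.8 A
    (or per-position equilibrium lengths when a sequence of ``n-1``
    values is given) and are relaxed later by minimization/annealing.
    A small helical offset (``helical_amplitude``, golden-angle phase
    advance per residue) keeps consecutive triples non-collinear, so
    bending and torsion forces are well defined from the first step;
    set it to zero for a strictly straight chain.
    """
    n = topo.n_beads
    if np.isscalar(bond_lengths):
        lengths = np.full(n - 1, float(bond_lengths)) if n > 1 else np.empty(0)
    else:
        lengths = np.asarray(bond_lengths, dtype=float)
        if lengths.shape != (max(n - 1, 0),):
            raise ValueError("need one bond length per bond")
    z = np.concatenate([[0.0], np.cumsum(lengths)]) if n > 1 else np.zeros(1)
    pos = np.zeros((n, 3))
    pos[:, 2] = z
    if helical_amplitude > 0 and n > 2:
        k = np.arange(n)
        pos[:, 0] = helical_amplitude * np.cos(_GOLDEN_ANGLE * k)
        pos[:, 1] = helical_amplitude * np.sin(_GOLDEN_ANGLE * k)
    length = float(z[-1]) if n > 1 else 0.0
    box = np.array([box_pad, box_pad, length + box_pad])
    return SimState(positions=pos, box=box, periodic=np.array([True] * 3))


# ---------------------------------------------------------------------------
# Degrees-of-freedom bookkeeping
# ---------------------------------------------------------------------------

#: Named all-atom atom-count conventions.  Each maps sequence -> atom count.
DOF_CONVENTIONS = ("charmm27", "neutral")


def _atom_count(sequence: str, convention: str) -> int:
    count = sum(RESIDUE_ATOM_COUNTS[c] for c in sequence)
    if convention == "charmm27":
        # All-hydrogen model, charged termini (NH3+ adds two H, COO- adds
        # one O), protonated Arg/Lys (+1 H each), deprotonated Asp/Glu.
        count += 2 + 1
        count += sequence.count("R") + sequence.count("K")
        count -= sequence.count("D") + sequence.count("E")
    elif convention == "neutral":
        # Neutral termini (NH2 adds one H, COOH adds O and H), neutral
        # side chains as tabulated.
        count += 1 + 2
    else:
        raise ValueError(
            f"unknown convention {convention!r}; choose from {DOF_CONVENTIONS}"
        )
    return count


def dof_reduction(sequence: str, convention: str = "charmm27") -> float:
    """All-atom to CG degrees-of-freedom reduction factor for one chain.

    Ratio of the all-atom atom count (under a named protonation/termini
    convention) to the bead count; both carry 3 translational DOF per
    site, so the atom ratio equals the DOF ratio.
    """
    _validate_sequence(sequence)
    return _atom_count(sequence, convention) / len(sequence)


def dof_reduction_table(sequence: str, convention: str = "charmm27") -> dict:
    """Per-residue atom-count table backing :func:`dof_reduction`."""
    _validate_sequence(sequence)
    per_residue = {
        c: RESIDUE_ATOM_COUNTS[c] for c in sorted(set(sequence))
    }
    return {
        "convention": convention,
        "per_residue_neutral_atoms": per_residue,
        "total_atoms": _atom_count(sequence, convention),
        "n_beads": len(sequence),
        "ratio": dof_reduction(sequence, convention),
    }


# ---------------------------------------------------------------------------
# Multi-chain assemblies
# ---------------------------------------------------------------------------

def _merge_chain_topologies(chains: Iterable[Topology]) -> Topology:
    beads: list[BeadSpec] = []
    bonds: list[BondInstance] = []
    angles: list[AngleInstance] = []
    dihedrals: list[DihedralInstance] = []
    offset = 0
    for cid, chain in enumerate(chains):
        for b in chain.beads:
            beads.append(replace(b, chain=cid))
        for bd in chain.bonds:
            bonds.append(BondInstance(bd.i + offset, bd.j + offset, bd.type_key))
        for an in chain.angles:
            angles.append(
                AngleInstance(an.i + offset, an.j + offset, an.k + offset, an.type_key)
            )
        for dh in chain.dihedrals:
            dihedrals.append(
                DihedralInstance(
                    dh.i + offset, dh.j + offset, dh.k + offset, dh.l + offset,
                    dh.type_key,
                )
            )
        offset += chain.n_beads
    return Topology(beads=beads, bonds=bonds, angles=angles, dihedrals=dihedrals)


def build_lattice(
    chain: Topology,
    nx: int,
    ny: int,
    spacing_x: float = 5.6,
    spacing_y: float = 4.8,
    antiparallel_axis: str = "y",
    bond_lengths: Sequence[float] | float = 3.8,
    spanning_bonds: bool = False,
) -> tuple[Topology, SimState]:
    """Arrange ``nx * ny`` copies of an extended chain on a rectangular grid.

    Chains run along Z.  Along the designated hydrogen-bonding axis the
    chain direction alternates (anti-parallel stacking, default Y with
    4.8 A spacing); along the other lateral axis stacking is parallel
    (side-chain direction, default X with 5.6 A spacing).  The returned
    box is fully periodic, sized ``nx*spacing_x x ny*spacing_y x L`` with
    ``L`` the chain length plus one mean bond spacing, so the chain's own
    periodic image continues the backbone geometry.

    With ``spanning_bonds`` each chain is additionally bonded to its own
    periodic image along Z (type key ``"n-1"`` for an n-residue chain),
    modelling an infinitely continued fiber: useful for verification
    fixtures that need a coherent elastic backbone along the loading
    axis.  The corresponding bond parameters must be added to the force
    field under that key.
    """
    if nx <= 0 or ny <= 0:
        raise ValueError("lattice counts must be positive")
    if spacing_x <= 0 or spacing_y <= 0:
        raise ValueError("lattice spacings must be positive")
    if antiparallel_axis not in ("x", "y"):
        raise ValueError("antiparallel_axis must be 'x' or 'y'")

    single = chain_state(chain, bond_lengths=bond_lengths)
    xy = single.positions[:, :2]
    z = single.positions[:, 2]
    z_max = float(z.max()) if chain.n_beads > 1 else 0.0
    mean_bond = z_max / max(chain.n_beads - 1, 1) if chain.n_beads > 1 else 3.8

    topo = _merge_chain_topologies([chain] * (nx * ny))
    pos = np.empty((nx * ny * chain.n_beads, 3))
    cid = 0
    for ix in range(nx):
        for iy in range(ny):
            row = ix if antiparallel_axis == "x" else iy
            flipped = row % 2 == 1
            zz = (z_max - z) if flipped else z
            sl = slice(cid * chain.n_beads, (cid + 1) * chain.n_beads)
            pos[sl, 0] = (ix + 0.5) * spacing_x + xy[:, 0]
            pos[sl, 1] = (iy + 0.5) * spacing_y + xy[:, 1]
            pos[sl, 2] = zz
            cid += 1
    if spanning_bonds and chain.n_beads > 1:
        n = chain.n_beads
        key = f"{n}-1"
        for cid in range(nx * ny):
            base = cid * n
            topo.bonds.append(BondInstance(base + n - 1, base, key))
    box = np.array([nx * spacing_x, ny * spacing_y, z_max + mean_bond])
    return topo, SimState(positions=pos, box=box)


def replicate(
    topo: Topology, state: SimState, nx: int, ny: int, nz: int
) -> tuple[Topology, SimState]:
    """Tile a periodic system ``nx x ny x nz`` times.

    Bonded instances are duplicated per image with unchanged type keys;
    the box scales by the tiling counts.  Copy labels tag each image.
    """
    if min(nx, ny, nz) <= 0:
        raise ValueError("replication counts must be positive")
    n_img = nx * ny * nz
    merged = _merge_chain_topologies([topo] * n_img)
    # restore per-image chain ids offset by image index
    nch = topo.n_chains
    beads = []
    for img in range(n_img):
        for b in topo.beads:
            beads.append(replace(b, chain=b.chain + img * nch))
    merged.beads = beads
    pos = np.empty((n_img * topo.n_beads, 3))
    labels = np.empty(n_img * topo.n_beads, dtype=int)
    img = 0
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                shift = np.array([ix, iy, iz]) * state.box
                sl = slice(img * topo.n_beads, (img + 1) * topo.n_beads)
                pos[sl] = state.positions + shift
                labels[sl] = img
                img += 1
    merged.copy_labels = labels
    box = state.box * np.array([nx, ny, nz])
    new_state = SimState(positions=pos, box=box, periodic=state.periodic.copy())
    return merged, new_state


def _min_image(disp: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    disp = np.asarray(disp, dtype=float).copy()
    for a in range(3):
        if periodic[a]:
            disp[..., a] -= box[a] * np.round(disp[..., a] / box[a])
    return disp


def random_pack(
    topo: Topology,
    state: SimState,
    n_copies: int,
    box_lengths: Sequence[float],
    min_separation: float = 2.0,
    seed: int = 0,
    max_attempts: int = 2000,
) -> tuple[Topology, SimState]:
    """Place rigid copies of a bundle at random poses inside a periodic box.

    Rejection sampling: each copy gets a uniform random rigid rotation
    about its centroid plus a uniform translation; a pose is accepted
    when no bead comes within ``min_separation`` (minimum image) of any
    bead of an already-placed copy.  Deterministic under a fixed seed.

    Raises
    ------
    PackingError
        if a copy cannot be placed within ``max_attempts`` tries; the
        exception carries the number of copies successfully placed.
    """
    from scipy.spatial import cKDTree
    from scipy.spatial.transform import Rotation

    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    box = np.asarray(box_lengths, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box_lengths must be three positive values")
    base = state.positions - state.positions.mean(axis=0)
    half_span = np.linalg.norm(base, axis=1).max()
    if 2 * half_span > np.linalg.norm(box):
        raise ValueError("bundle does not fit inside the packing box")

    rng = np.random.default_rng(seed)
    placed: list[np.ndarray] = []
    tree: cKDTree | None = None
    occupied: np.ndarray | None = None
    for copy_i in range(n_copies):
        for _ in range(max_attempts):
            rot = Rotation.random(rng=rng)
            cand = rot.apply(base) + rng.uniform(0.0, box)
            cand_wrapped = np.mod(cand, box)
            if tree is not None:
                hits = tree.query_ball_point(
                    cand_wrapped, r=min_separation, return_length=True
                )
                if np.any(hits > 0):
                    continue
            placed.append(cand)
            occupied = (
                cand_wrapped
                if occupied is None
                else np.vstack([occupied, cand_wrapped])
            )
            tree = cKDTree(occupied, boxsize=box)
            break
        else:
            raise PackingError(
                f"failed to place copy {copy_i + 1} of {n_copies} after "
                f"{max_attempts} attempts (placed {copy_i})",
                placed=copy_i,
            )

    merged = _merge_chain_topologies([topo] * n_copies)
    nch = topo.n_chains
    beads = []
    for img in range(n_copies):
        for b in topo.beads:
            beads.append(replace(b, chain=b.chain + img * nch))
    merged.beads = beads
    merged.copy_labels = np.repeat(np.arange(n_copies), topo.n_beads)
    pos = np.vstack(placed)
    return merged, SimState(positions=pos, box=box)


def map_to_cg(
    atom_positions: np.ndarray,
    atom_masses: np.ndarray,
    residue_assignment: np.ndarray,
    box: Sequence[float] | None = None,
) -> SimState:
    """Map all-atom coordinates to CG beads at residue centers of mass.

    ``residue_assignment`` gives, per atom, the index of its residue
    (0-based, need not be contiguous but every atom belongs to exactly
    one residue).  Returns one bead per distinct residue, ordered by
    residue index, at the mass-weighted centroid.
    """
    pos = np.asarray(atom_positions, dtype=float)
    masses = np.asarray(atom_masses, dtype=float)
    assign = np.asarray(residue_assignment)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("atom_positions must be (N, 3)")
    if masses.shape != (pos.shape[0],) or assign.shape != (pos.shape[0],):
        raise ValueError("masses and residue_assignment must match atom count")
    if np.any(masses <= 0):
        raise ValueError("atom masses must be positive")
    residues = np.unique(assign)
    beads = np.empty((residues.size, 3))
    for out, res in enumerate(residues):
        sel = assign == res
        w = masses[sel]
        beads[out] = (pos[sel] * w[:, None]).sum(axis=0) / w.sum()
    if box is None:
        lo, hi = beads.min(axis=0), beads.max(axis=0)
        box_arr = np.maximum(hi - lo, 1.0) + 20.0
    else:
        box_arr = np.asarray(box, dtype=float)
    return SimState(positions=beads, box=box_arr)


def system_mass(topo: Topology) -> float:
    """Total mass in u."""
    return float(topo.masses.sum())


def mass_density(topo: Topology, state: SimState) -> float:
    """Mass density of a periodic system in g/cm^3."""
    if topo.n_beads == 0:
        raise ValueError("empty system has no density")
    return system_mass(topo) / state.volume * AMU_A3_TO_G_CM3
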