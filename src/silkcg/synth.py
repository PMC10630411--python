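"""Synthetic oracles and fixture systems.

The calibration procedures in :mod:`silkcg.calibrate` are defined
against an energy-oracle callback; in production that callback wraps an
external all-atom engine or precomputed scan files.  This module
provides synthetic stand-ins so the whole pipeline is testable offline:

* :class:`OraclePotential` / :func:`make_scan` — closed-form scan
  generators (harmonic, Morse, LJ, angularly-modulated LJ, cosine
  orientation profiles) with optional seeded Gaussian noise;
* :class:`CGOracle` — a coarse-grained force field acting as its own
  reference energy source, which makes calibration round-trips exact;
* :func:`default_forcefield` — a complete synthetic parameter set;
* :func:`make_test_assembly` — the study systems (single chain, 4x4
  bundle, 3x2x3 ordered tiling, random and semi-ordered 20-copy packs)
  at full or reduced scale.

The default force-field magnitudes are plausible placeholders, NOT
calibrated reference values; production parameter tables are
transcribed into the same schema via :mod:`silkcg.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .calibrate import RigidResidue, zmatrix_positions
from .forcefield import (
    AngleParam,
    BondParam,
    DihedralParam,
    ForceField,
    PairParam,
    wrap_angle_deg,
)
from .calibrate import EnergyScan, measure_angle, measure_dihedral
from .model import (
    RESIDUE_MASSES,
    SimState,
    Topology,
    _merge_chain_topologies,
    build_chain,
    build_lattice,
    chain_state,
    masp1_sequence,
    random_pack,
    replicate,
)

__all__ = [
    "OraclePotential",
    "make_scan",
    "CGOracle",
    "default_forcefield",
    "make_test_assembly",
    "ASSEMBLY_KINDS",
]


_FAMILIES = ("harmonic", "morse", "lj", "lj_angular", "cosine")


@dataclass(frozen=True)
class OraclePotential:
    """A closed-form scan oracle with optional additive Gaussian noise.

    Families and their parameters:

    - ``harmonic``: ``k``, ``x0``, ``offset`` -> offset + k (x - x0)^2
    - ``morse``: ``D``, ``a``, ``r_e``, ``offset`` -> offset + D (1 - exp(-a (r - r_e)))^2
    - ``lj``: ``epsilon``, ``sigma``, ``offset``
    - ``lj_angular``: LJ whose well depth is modulated by a fixed
      orientation angle: ``epsilon * (1 + modulation * cos(theta_deg))``
    - ``cosine``: ``amplitude``, ``center_deg``, ``offset`` ->
      offset - amplitude cos(x - center), an orientation profile with
      its minimum at ``center_deg``.
    """

    family: str
    params: dict
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        p = self.params
        if self.family == "morse" and (p["D"] <= 0 or p["a"] <= 0):
            raise ValueError("Morse requires D > 0 and a > 0")
        if self.family in ("lj", "lj_angular") and (
            p["epsilon"] < 0 or p["sigma"] <= 0
        ):
            raise ValueError("LJ requires epsilon >= 0 and sigma > 0")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "harmonic":
            return p.get("offset", 0.0) + p["k"] * (x - p["x0"]) ** 2
        if self.family == "morse":
            return p.get("offset", 0.0) + p["D"] * (
                1.0 - np.exp(-p["a"] * (x - p["r_e"]))
            ) ** 2
        if self.family in ("lj", "lj_angular"):
            eps = p["epsilon"]
            if self.family == "lj_angular":
                eps = eps * (
                    1.0 + p.get("modulation", 0.0)
                    * math.cos(math.radians(p.get("theta_deg", 0.0)))
                )
            sr6 = (p["sigma"] / x) ** 6
            return p.get("offset", 0.0) + 4.0 * eps * (sr6 * sr6 - sr6)
        # cosine orientation profile
        return p.get("offset", 0.0) - p["amplitude"] * np.cos(
            np.radians(x - p["center_deg"])
        )


def make_scan(
    oracle: OraclePotential, grid: np.ndarray, kind: str = "bond"
) -> EnergyScan:
    """Evaluate a synthetic oracle on a coordinate grid.

    Deterministic under the oracle's seed: the same oracle produces the
    same noisy scan every time.
    """
    grid = np.asarray(grid, dtype=float)
    energies = oracle.evaluate(grid)
    if oracle.noise_sigma > 0:
        rng = np.random.default_rng(oracle.seed)
        energies = energies + rng.normal(0.0, oracle.noise_sigma, size=grid.shape)
    return EnergyScan(grid, energies, kind=kind, meta={"family": oracle.family})


# ---------------------------------------------------------------------------
# Synthetic default force field
# ---------------------------------------------------------------------------

# Like-species LJ placeholders, loosely sized with residue bulk.
_PAIR_TABLE: dict[str, PairParam] = {
    "G": PairParam(0.45, 4.40), "A": PairParam(0.55, 4.70),
    "S": PairParam(0.65, 4.90), "P": PairParam(0.70, 5.10),
    "V": PairParam(0.70, 5.20), "T": PairParam(0.70, 5.10),
    "C": PairParam(0.75, 5.00), "L": PairParam(0.85, 5.60),
    "I": PairParam(0.85, 5.60), "N": PairParam(0.85, 5.20),
    "D": PairParam(0.85, 5.10), "Q": PairParam(0.95, 5.50),
    "K": PairParam(0.90, 5.70), "E": PairParam(0.90, 5.30),
    "M": PairParam(0.90, 5.60), "H": PairParam(1.00, 5.60),
    "F": PairParam(1.05, 5.80), "R": PairParam(1.05, 5.90),
    "Y": PairParam(1.10, 5.90), "W": PairParam(1.20, 6.10),
}

_POLY_A_THETA0 = 162.0
_STIFF_TRIPLES = ("G-Y-G", "G-L-G")


def default_forcefield(sequence: str | None = None, seed: int = 1234) -> ForceField:
    """Complete synthetic parameter set for a sequence (default MaSp1).

    Magnitudes are plausible placeholders for a residue-bead silk model,
    deterministic under ``seed``; they are NOT calibrated reference
    values.  Qualitative structure built in: poly-alanine bending
    equilibria are set to 162 degrees, and G-Y-G / G-L-G bending
    stiffnesses sit well above (>= 3x) the median stiffness, mirroring
    the stiff aromatic/aliphatic triples of the silk backbone.
    """
    seq = masp1_sequence() if sequence is None else sequence
    topo = build_chain(seq)
    rng = np.random.default_rng(seed)
    ff = ForceField(cutoff=12.0, mixing="geometric")

    for bond in topo.bonds:
        ff.bonds[bond.type_key] = BondParam(
            k=float(rng.uniform(100.0, 300.0)),
            r0=float(rng.uniform(3.7, 3.9)),
        )

    # poly-alanine block: positions (1-based) of maximal all-A runs >= 4
    poly_a = set()
    run_start = None
    for p, c in enumerate(seq + "#", start=1):
        if c == "A" and run_start is None:
            run_start = p
        elif c != "A" and run_start is not None:
            if p - run_start >= 4:
                poly_a.update(range(run_start, p))
            run_start = None

    base_ks = []
    for angle in topo.angles:
        i1 = int(angle.type_key.split("-")[0])
        triple = "-".join(seq[i1 - 1 + m] for m in range(3))
        in_poly_a = all(pos in poly_a for pos in (i1, i1 + 1, i1 + 2))
        theta0 = _POLY_A_THETA0 if in_poly_a else float(rng.uniform(145.0, 160.0))
        if triple in _STIFF_TRIPLES:
            k = float(rng.uniform(90.0, 110.0))
        else:
            k = float(rng.uniform(18.0, 30.0))
            base_ks.append(k)
        ff.angles[angle.type_key] = AngleParam(k=k, theta0=theta0)

    for dih in topo.dihedrals:
        phi0 = float(rng.uniform(150.0, 175.0)) * (1 if rng.random() < 0.5 else -1)
        ff.dihedrals[dih.type_key] = DihedralParam(
            k=float(rng.uniform(4.0, 8.0)), phi0=wrap_angle_deg(phi0)
        )

    for species in sorted(set(seq)):
        ff.pairs[species] = _PAIR_TABLE[species]
    return ff


# ---------------------------------------------------------------------------
# CG self-oracle (round-trip reference)
# ---------------------------------------------------------------------------


class CGOracle:
    """A CG force field serving as its own calibration energy source.

    ``reference_positions`` returns the chain's exact internal-coordinate
    minimum (built by NeRF from the per-position equilibria), so scans
    are centered on the true minimum and harmonic fits recover the
    parameters to numerical precision.  Bending and torsion cluster
    energies contain no non-bonded contributions, matching the
    calibration procedures' exclusions.
    """

    def __init__(self, ff: ForceField, sequence: str):
        self.ff = ff
        self.sequence = sequence
        self.topo = build_chain(sequence)
        for inst, table, kind in (
            (self.topo.bonds, ff.bonds, "bond"),
            (self.topo.angles, ff.angles, "angle"),
            (self.topo.dihedrals, ff.dihedrals, "dihedral"),
        ):
            for term in inst:
                if term.type_key not in table:
                    raise KeyError(f"{kind} key {term.type_key!r} missing from force field")

    def reference_positions(self) -> np.ndarray:
        n = self.topo.n_beads
        r = [self.ff.bonds[b.type_key].r0 for b in self.topo.bonds]
        th = [self.ff.angles[a.type_key].theta0 for a in self.topo.angles]
        ph = [self.ff.dihedrals[d.type_key].phi0 for d in self.topo.dihedrals]
        pos = zmatrix_positions(r, th, ph)
        assert pos.shape == (n, 3)
        return pos

    # -- term energies ------------------------------------------------------

    def _bond_energy(self, key: str, r: float) -> float:
        p = self.ff.bonds[key]
        return p.k * (r - p.r0) ** 2

    def _angle_energy(self, key: str, theta_deg: float) -> float:
        p = self.ff.angles[key]
        return p.k * math.radians(theta_deg - p.theta0) ** 2

    def _dihedral_energy(self, key: str, phi_deg: float) -> float:
        p = self.ff.dihedrals[key]
        return p.k * math.radians(wrap_angle_deg(phi_deg - p.phi0)) ** 2

    def cluster_energy(
        self, indices: tuple[int, ...], positions: np.ndarray, kind: str
    ) -> float:
        pos = np.asarray(positions, dtype=float)
        i0 = indices[0]

        def bond_key(a: int) -> str:
            return f"{a + 1}-{a + 2}"

        if kind == "bond":
            r = float(np.linalg.norm(pos[1] - pos[0]))
            return self._bond_energy(bond_key(i0), r)
        if kind == "angle":
            e = self._bond_energy(bond_key(i0), float(np.linalg.norm(pos[1] - pos[0])))
            e += self._bond_energy(
                bond_key(i0 + 1), float(np.linalg.norm(pos[2] - pos[1]))
            )
            e += self._angle_energy(
                f"{i0 + 1}-{i0 + 2}-{i0 + 3}", measure_angle(pos[0], pos[1], pos[2])
            )
            return e
        if kind == "dihedral":
            e = 0.0
            for m in range(3):
                e += self._bond_energy(
                    bond_key(i0 + m), float(np.linalg.norm(pos[m + 1] - pos[m]))
                )
            for m in range(2):
                e += self._angle_energy(
                    f"{i0 + m + 1}-{i0 + m + 2}-{i0 + m + 3}",
                    measure_angle(pos[m], pos[m + 1], pos[m + 2]),
                )
            e += self._dihedral_energy(
                f"{i0 + 1}-{i0 + 2}-{i0 + 3}-{i0 + 4}",
                measure_dihedral(pos[0], pos[1], pos[2], pos[3]),
            )
            return e
        raise ValueError(f"unknown cluster kind {kind!r}")

    def residue_template(self, species: str) -> RigidResidue:
        return RigidResidue(
            positions=np.zeros((1, 3)), masses=np.array([RESIDUE_MASSES[species]])
        )

    def pair_energy(
        self, species: str, positions_i: np.ndarray, positions_j: np.ndarray
    ) -> float:
        p = self.ff.pairs[species]
        e = 0.0
        for a in np.atleast_2d(positions_i):
            for b in np.atleast_2d(positions_j):
                r = float(np.linalg.norm(b - a))
                sr6 = (p.sigma / r) ** 6
                e += 4.0 * p.epsilon * (sr6 * sr6 - sr6)
        return e


# ---------------------------------------------------------------------------
# Fixture assemblies
# ---------------------------------------------------------------------------

ASSEMBLY_KINDS = ("single_chain", "bundle16", "ordered_3x2x3", "random20", "semi20")

#: Packing boxes for the disordered assemblies (A).
RANDOM_BOX = np.array([126.5, 126.5, 126.5])
SEMI_BOX = np.array([98.5, 98.5, 197.0])

#: Geometry of the compacted bundle surrogate used for packing fixtures.
#: It stands in for the post-anneal, contracted bundle so a rigid copy
#: fits the packing boxes; synthetic, not an equilibrated structure.
#: Rejection sampling cannot reach the near-space-filling density an
#: optimizing packer achieves, so the surrogate is deliberately slim:
#: copy counts and box dimensions are faithful, the packing density is
#: not.
_COMPACT_BOND = 1.7
_COMPACT_SPACING = (3.2, 2.8)


def _scaled(count: int, scale: float) -> int:
    return max(1, int(round(count * scale)))


def _controlled_pack(
    topo: Topology,
    state: SimState,
    rotations: Sequence[Rotation | None],
    box: np.ndarray,
    min_separation: float,
    seed: int,
    max_attempts: int = 2000,
) -> tuple[Topology, SimState]:
    """Place rigid copies with prescribed rotations and random positions."""
    from dataclasses import replace as _replace

    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    base = state.positions - state.positions.mean(axis=0)
    placed: list[np.ndarray] = []
    occupied: np.ndarray | None = None
    tree = None
    for ci, rot in enumerate(rotations):
        oriented = base if rot is None else rot.apply(base)
        for _ in range(max_attempts):
            cand = oriented + rng.uniform(0.0, box)
            wrapped = np.mod(cand, box)
            if tree is not None:
                hits = tree.query_ball_point(
                    wrapped, r=min_separation, return_length=True
                )
                if np.any(hits > 0):
                    continue
            placed.append(cand)
            occupied = wrapped if occupied is None else np.vstack([occupied, wrapped])
            tree = cKDTree(occupied, boxsize=box)
            break
        else:
            from .model import PackingError

            raise PackingError(
                f"failed to place copy {ci + 1} after {max_attempts} attempts",
                placed=ci,
            )
    merged = _merge_chain_topologies([topo] * len(rotations))
    nch = topo.n_chains
    merged.beads = [
        _replace(b, chain=b.chain + img * nch)
        for img in range(len(rotations))
        for b in topo.beads
    ]
    merged.copy_labels = np.repeat(np.arange(len(rotations)), topo.n_beads)
    return merged, SimState(positions=np.vstack(placed), box=box.copy())


def make_test_assembly(
    kind: str,
    scale_factor: float = 1.0,
    seed: int = 0,
    ff: ForceField | None = None,
) -> tuple[Topology, SimState]:
    """Reproducible fixture systems for simulation and analysis.

    ``scale_factor`` in (0, 1] shrinks copy counts (never box shapes)
    for desk-scale runs; at 1.0 the full constructions are produced:
    a 16-chain 4x4 bundle, its 3x2x3 ordered tiling, a 20-copy random
    pack in a 126.5 A cube, and a 20-copy semi-ordered pack (13 of 20
    copies aligned with Z) in a 98.5 x 98.5 x 197 A box.
    """
    if not 0.0 < scale_factor <= 1.0:
        raise ValueError("scale_factor must lie in (0, 1]")
    if kind not in ASSEMBLY_KINDS:
        raise ValueError(f"unknown assembly kind {kind!r}; choose from {ASSEMBLY_KINDS}")
    seq = masp1_sequence()
    chain = build_chain(seq)
    if ff is not None:
        bond_lengths = [ff.bonds[b.type_key].r0 for b in chain.bonds]
    else:
        bond_lengths = 3.8

    if kind == "single_chain":
        return chain, chain_state(chain, bond_lengths=bond_lengths)

    if kind == "bundle16":
        n = _scaled(4, scale_factor)
        return build_lattice(chain, n, n, bond_lengths=bond_lengths)

    if kind == "ordered_3x2x3":
        n = _scaled(4, scale_factor)
        topo, state = build_lattice(chain, n, n, bond_lengths=bond_lengths)
        return replicate(
            topo,
            state,
            _scaled(3, scale_factor),
            _scaled(2, scale_factor),
            _scaled(3, scale_factor),
        )

    # packing fixtures use a compacted bundle surrogate that fits the box;
    # only the copy count is scaled, the bundle keeps its 16 chains
    bundle_topo, bundle_state = build_lattice(
        chain,
        4,
        4,
        spacing_x=_COMPACT_SPACING[0],
        spacing_y=_COMPACT_SPACING[1],
        bond_lengths=_COMPACT_BOND,
    )
    n_copies = _scaled(20, scale_factor)
    if kind == "random20":
        return random_pack(
            bundle_topo,
            bundle_state,
            n_copies,
            RANDOM_BOX,
            min_separation=2.0,
            seed=seed,
        )
    # semi20: 65% of copies aligned with Z, the rest tilted 45-90 degrees
    n_aligned = int(round(0.65 * n_copies))
    rng = np.random.default_rng(seed)
    rotations: list[Rotation | None] = [None] * n_aligned
    for _ in range(n_copies - n_aligned):
        phi = rng.uniform(0.0, 2 * np.pi)
        axis = np.array([np.cos(phi), np.sin(phi), 0.0])
        angle = np.radians(rng.uniform(45.0, 90.0))
        rotations.append(Rotation.from_rotvec(angle * axis))
    return _controlled_pack(
        bundle_topo,
        bundle_state,
        rotations,
        SEMI_BOX,
        min_separation=2.0,
        seed=seed + 1,
    )
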