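"""File formats: force-field schema, LAMMPS data, XYZ, scans, curves.

The YAML force-field document is the single authoritative parameter
source; the LAMMPS export is derived from it and never read back as
authoritative.  All readers validate strictly and report the offending
section/key; there is no silent coercion.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .calibrate import EnergyScan
from .forcefield import (
    AngleParam,
    BondParam,
    DihedralParam,
    ExclusionPolicy,
    ForceField,
    PairParam,
)
from .mech import StressStrainCurve
from .model import BeadSpec, BondInstance, AngleInstance, DihedralInstance, \
    RESIDUE_MASSES, SimState, Topology

__all__ = [
    "SchemaError",
    "read_forcefield",
    "write_forcefield",
    "read_sequence",
    "write_lammps_data",
    "read_lammps_data",
    "write_lammps_input",
    "write_xyz",
    "write_scan",
    "read_scan",
    "write_curve",
    "read_curve",
    "write_calibration_report",
    "provenance_record",
]

_SCHEMA_TAG = "silkcg-forcefield-1"


class SchemaError(ValueError):
    """A structured document violated its schema."""


# ---------------------------------------------------------------------------
# Force-field schema
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "schema", "cutoff", "mixing", "shift_lj", "energy_offset",
    "exclusions", "bonds", "angles", "dihedrals", "pairs",
}
_REQUIRED_SECTIONS = ("bonds", "angles", "dihedrals", "pairs")


def _check_mapping(obj, allowed: set[str], location: str) -> None:
    if not isinstance(obj, dict):
        raise SchemaError(f"{location}: expected a mapping")
    unknown = set(obj) - allowed
    if unknown:
        raise SchemaError(f"{location}: unknown keys {sorted(unknown)}")


def _position_key_ok(key: str, arity: int) -> bool:
    parts = key.split("-")
    if len(parts) != arity:
        return False
    try:
        nums = [int(p) for p in parts]
    except ValueError:
        return False
    return all(nums[m + 1] == nums[m] + 1 for m in range(arity - 1))


def write_forcefield(ff: ForceField, path) -> None:
    """Serialize a force field to the YAML schema (bit-stable round trip)."""
    doc = {
        "schema": _SCHEMA_TAG,
        "cutoff": float(ff.cutoff),
        "mixing": ff.mixing,
        "shift_lj": bool(ff.shift_lj),
        "energy_offset": float(ff.energy_offset),
        "exclusions": {
            "exclude_13": bool(ff.exclusions.exclude_13),
            "exclude_14": bool(ff.exclusions.exclude_14),
        },
        "bonds": {
            k: {"k": float(p.k), "r0": float(p.r0)} for k, p in ff.bonds.items()
        },
        "angles": {
            k: {"k": float(p.k), "theta0": float(p.theta0)}
            for k, p in ff.angles.items()
        },
        "dihedrals": {
            k: {"k": float(p.k), "phi0": float(p.phi0)}
            for k, p in ff.dihedrals.items()
        },
        "pairs": {
            k: {"epsilon": float(p.epsilon), "sigma": float(p.sigma)}
            for k, p in ff.pairs.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


def read_forcefield(path) -> ForceField:
    """Parse and validate a YAML force-field document.

    Position keys are "9-10" style: the bond between residues 9 and 10
    of the template chain; angles "2-3-4"; dihedrals "3-4-5-6".
    Unknown keys or missing sections raise :class:`SchemaError` naming
    the location.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    _check_mapping(doc, _TOP_KEYS, "top level")
    if doc.get("schema") != _SCHEMA_TAG:
        raise SchemaError(f"top level: schema must be {_SCHEMA_TAG!r}")
    for section in _REQUIRED_SECTIONS:
        if section not in doc:
            raise SchemaError(f"top level: missing required section {section!r}")
    excl = doc.get("exclusions", {})
    _check_mapping(excl, {"exclude_13", "exclude_14"}, "exclusions")

    def _entries(section: str, allowed: set[str], arity: int | None):
        table = doc[section]
        if not isinstance(table, dict):
            raise SchemaError(f"{section}: expected a mapping")
        for key, entry in table.items():
            loc = f"{section}[{key}]"
            if arity is not None and not _position_key_ok(str(key), arity):
                raise SchemaError(
                    f"{loc}: key must be {arity} consecutive 1-based positions"
                )
            _check_mapping(entry, allowed, loc)
            missing = allowed - set(entry)
            if missing:
                raise SchemaError(f"{loc}: missing fields {sorted(missing)}")
            yield str(key), entry, loc

    ff = ForceField(
        cutoff=float(doc.get("cutoff", 12.0)),
        mixing=str(doc.get("mixing", "geometric")),
        shift_lj=bool(doc.get("shift_lj", False)),
        energy_offset=float(doc.get("energy_offset", 0.0)),
        exclusions=ExclusionPolicy(
            exclude_13=bool(excl.get("exclude_13", True)),
            exclude_14=bool(excl.get("exclude_14", False)),
        ),
    )
    try:
        for key, entry, loc in _entries("bonds", {"k", "r0"}, 2):
            ff.bonds[key] = BondParam(k=float(entry["k"]), r0=float(entry["r0"]))
        for key, entry, loc in _entries("angles", {"k", "theta0"}, 3):
            ff.angles[key] = AngleParam(
                k=float(entry["k"]), theta0=float(entry["theta0"])
            )
        for key, entry, loc in _entries("dihedrals", {"k", "phi0"}, 4):
            ff.dihedrals[key] = DihedralParam(
                k=float(entry["k"]), phi0=float(entry["phi0"])
            )
        for key, entry, loc in _entries(
            "pairs", {"epsilon", "sigma"}, None
        ):
            if key not in RESIDUE_MASSES:
                raise SchemaError(f"pairs[{key}]: not a standard residue letter")
            ff.pairs[key] = PairParam(
                epsilon=float(entry["epsilon"]), sigma=float(entry["sigma"])
            )
    except ValueError as err:
        if isinstance(err, SchemaError):
            raise
        raise SchemaError(str(err)) from err
    return ff


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def read_sequence(source) -> str:
    """Sequence from a plain string or a single-record FASTA file."""
    p = Path(source)
    if not p.exists():
        return str(source).strip().upper()
    text = p.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        records = list(SeqIO.parse(str(p), "fasta"))
        if len(records) != 1:
            raise ValueError(
                f"{p}: expected exactly one FASTA record, found {len(records)}"
            )
        return str(records[0].seq).upper()
    return "".join(text.split()).upper()


# ---------------------------------------------------------------------------
# LAMMPS data files
# ---------------------------------------------------------------------------


def write_lammps_data(topo: Topology, state: SimState, ff: ForceField, path) -> None:
    """Standard LAMMPS data file (atom style molecular) with coeff blocks.

    Bond/angle coefficients map onto ``bond_style harmonic`` /
    ``angle_style harmonic`` (both K (x - x0)^2, matching this model);
    dihedrals onto ``dihedral_style quadratic`` (same functional form).
    Type-key comments after each coeff line make the file invertible.
    """
    if topo.n_beads == 0:
        raise ValueError("cannot export an empty topology")
    species = sorted(set(topo.species))
    bond_keys = sorted({b.type_key for b in topo.bonds}, key=lambda k: [int(x) for x in k.split("-")])
    angle_keys = sorted({a.type_key for a in topo.angles}, key=lambda k: [int(x) for x in k.split("-")])
    dih_keys = sorted({d.type_key for d in topo.dihedrals}, key=lambda k: [int(x) for x in k.split("-")])
    sp_id = {s: i + 1 for i, s in enumerate(species)}
    b_id = {k: i + 1 for i, k in enumerate(bond_keys)}
    a_id = {k: i + 1 for i, k in enumerate(angle_keys)}
    d_id = {k: i + 1 for i, k in enumerate(dih_keys)}

    lines: list[str] = ["# silkcg coarse-grained data file", ""]
    lines.append(f"{topo.n_beads} atoms")
    lines.append(f"{len(topo.bonds)} bonds")
    lines.append(f"{len(topo.angles)} angles")
    lines.append(f"{len(topo.dihedrals)} dihedrals")
    lines.append("")
    lines.append(f"{len(species)} atom types")
    if bond_keys:
        lines.append(f"{len(bond_keys)} bond types")
    if angle_keys:
        lines.append(f"{len(angle_keys)} angle types")
    if dih_keys:
        lines.append(f"{len(dih_keys)} dihedral types")
    lines.append("")
    for a, name in enumerate(("x", "y", "z")):
        lines.append(f"0.0 {state.box[a]:.8f} {name}lo {name}hi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    for s in species:
        lines.append(f"{sp_id[s]} {RESIDUE_MASSES[s]:.6f}  # {s}")
    if ff.pairs:
        lines += ["", "Pair Coeffs", ""]
        for s in species:
            p = ff.pairs[s]
            lines.append(f"{sp_id[s]} {p.epsilon:.8f} {p.sigma:.8f}  # {s}")
    if bond_keys:
        lines += ["", "Bond Coeffs", ""]
        for k in bond_keys:
            p = ff.bonds[k]
            lines.append(f"{b_id[k]} {p.k:.8f} {p.r0:.8f}  # {k}")
    if angle_keys:
        lines += ["", "Angle Coeffs", ""]
        for k in angle_keys:
            p = ff.angles[k]
            lines.append(f"{a_id[k]} {p.k:.8f} {p.theta0:.8f}  # {k}")
    if dih_keys:
        lines += ["", "Dihedral Coeffs", ""]
        for k in dih_keys:
            p = ff.dihedrals[k]
            lines.append(f"{d_id[k]} {p.k:.8f} {p.phi0:.8f}  # {k}")
    lines += ["", "Atoms  # molecular", ""]
    for i, bead in enumerate(topo.beads):
        x, y, z = state.positions[i]
        lines.append(
            f"{i + 1} {bead.chain + 1} {sp_id[bead.pair_type]} "
            f"{x:.8f} {y:.8f} {z:.8f}"
        )
    if topo.bonds:
        lines += ["", "Bonds", ""]
        for n, b in enumerate(topo.bonds):
            lines.append(f"{n + 1} {b_id[b.type_key]} {b.i + 1} {b.j + 1}")
    if topo.angles:
        lines += ["", "Angles", ""]
        for n, a in enumerate(topo.angles):
            lines.append(f"{n + 1} {a_id[a.type_key]} {a.i + 1} {a.j + 1} {a.k + 1}")
    if topo.dihedrals:
        lines += ["", "Dihedrals", ""]
        for n, d in enumerate(topo.dihedrals):
            lines.append(
                f"{n + 1} {d_id[d.type_key]} {d.i + 1} {d.j + 1} {d.k + 1} {d.l + 1}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_lammps_data(path) -> tuple[Topology, SimState]:
    """Re-read a data file written by :func:`write_lammps_data`."""
    text = Path(path).read_text().splitlines()
    counts = {"atoms": 0, "bonds": 0, "angles": 0, "dihedrals": 0}
    box = np.zeros(3)
    section = None
    sp_of_type: dict[int, str] = {}
    key_of = {"Bond": {}, "Angle": {}, "Dihedral": {}}
    atoms: dict[int, tuple[int, int, np.ndarray]] = {}
    bonds: list[tuple[int, int, int]] = []
    angles: list[tuple[int, int, int, int]] = []
    dihedrals: list[tuple[int, int, int, int, int]] = []

    for raw in text:
        stripped = raw.split("#")[0].strip()
        comment = raw.split("#", 1)[1].strip() if "#" in raw else ""
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) >= 2 and parts[1] in counts and len(parts) == 2:
            counts[parts[1]] = int(parts[0])
            continue
        if len(parts) == 4 and parts[2].endswith("lo"):
            axis = "xyz".index(parts[2][0])
            box[axis] = float(parts[1]) - float(parts[0])
            continue
        if parts[0] in (
            "Masses", "Atoms", "Bonds", "Angles", "Dihedrals",
        ) or stripped in ("Pair Coeffs", "Bond Coeffs", "Angle Coeffs", "Dihedral Coeffs"):
            section = stripped if "Coeffs" in stripped else parts[0]
            continue
        if "types" in parts:
            continue
        if section == "Masses":
            sp_of_type[int(parts[0])] = comment or "G"
        elif section in ("Bond Coeffs", "Angle Coeffs", "Dihedral Coeffs"):
            key_of[section.split()[0]][int(parts[0])] = comment
        elif section == "Atoms":
            aid, mol, typ = int(parts[0]), int(parts[1]), int(parts[2])
            atoms[aid] = (mol, typ, np.array([float(v) for v in parts[3:6]]))
        elif section == "Bonds":
            bonds.append((int(parts[1]), int(parts[2]), int(parts[3])))
        elif section == "Angles":
            angles.append(
                (int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4]))
            )
        elif section == "Dihedrals":
            dihedrals.append(
                (int(parts[1]), int(parts[2]), int(parts[3]), int(parts[4]), int(parts[5]))
            )

    if len(atoms) != counts["atoms"]:
        raise SchemaError(
            f"{path}: expected {counts['atoms']} atoms, parsed {len(atoms)}"
        )
    order = sorted(atoms)
    chain_pos: dict[int, int] = {}
    beads = []
    positions = np.empty((len(order), 3))
    for row, aid in enumerate(order):
        mol, typ, xyz = atoms[aid]
        chain_pos[mol] = chain_pos.get(mol, 0) + 1
        code = sp_of_type[typ]
        beads.append(
            BeadSpec(
                residue_code=code,
                index=chain_pos[mol],
                mass=RESIDUE_MASSES[code],
                pair_type=code,
                chain=mol - 1,
            )
        )
        positions[row] = xyz
    row_of = {aid: r for r, aid in enumerate(order)}
    topo = Topology(
        beads=beads,
        bonds=[
            BondInstance(row_of[i], row_of[j], key_of["Bond"].get(t, str(t)))
            for t, i, j in bonds
        ],
        angles=[
            AngleInstance(
                row_of[i], row_of[j], row_of[k], key_of["Angle"].get(t, str(t))
            )
            for t, i, j, k in angles
        ],
        dihedrals=[
            DihedralInstance(
                row_of[i], row_of[j], row_of[k], row_of[l],
                key_of["Dihedral"].get(t, str(t)),
            )
            for t, i, j, k, l in dihedrals
        ],
    )
    return topo, SimState(positions=positions, box=box)


def write_lammps_input(path, data_path, ff: ForceField) -> None:
    """Companion input script for cross-validation runs."""
    excl = ff.exclusions
    special = (
        f"special_bonds lj 0.0 {0.0 if excl.exclude_13 else 1.0} "
        f"{0.0 if excl.exclude_14 else 1.0}"
    )
    lines = [
        "units real",
        "atom_style molecular",
        "boundary p p p",
        f"pair_style lj/cut {ff.cutoff}",
        "bond_style harmonic",
        "angle_style harmonic",
        "dihedral_style quadratic",
        special,
        f"read_data {data_path}",
        "pair_modify mix geometric",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(path, state: SimState, topo: Topology, comment: str = "", append: bool = False) -> None:
    """Plain XYZ frame with one-letter species as element placeholders."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{topo.n_beads}\n{comment}\n")
        for bead, (x, y, z) in zip(topo.beads, state.positions):
            fh.write(f"{bead.pair_type} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Scan and curve files
# ---------------------------------------------------------------------------


def write_scan(scan: EnergyScan, path) -> None:
    """Two-column delimited scan with a kind/unit header."""
    units = "degrees" if scan.kind in ("angle", "dihedral", "orientation") else "angstrom"
    with open(path, "w") as fh:
        fh.write(f"# coordinate_kind: {scan.kind}\n")
        fh.write(f"# units: {units}, kcal/mol\n")
        for c, e in zip(scan.coordinates, scan.energies):
            fh.write(f"{c:.10g} {e:.10g}\n")


def read_scan(path) -> EnergyScan:
    """Read a two-column (coordinate, energy) file; comments tolerated."""
    kind = None
    coords: list[float] = []
    energies: list[float] = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "coordinate_kind:" in line:
                kind = line.split("coordinate_kind:")[1].split(",")[0].strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SchemaError(f"{path}:{ln}: expected two columns")
        try:
            coords.append(float(parts[0]))
            energies.append(float(parts[1]))
        except ValueError as err:
            raise SchemaError(f"{path}:{ln}: {err}") from None
    if kind is None:
        raise SchemaError(f"{path}: missing '# coordinate_kind:' header")
    return EnergyScan(np.array(coords), np.array(energies), kind=kind)


def write_curve(curve: StressStrainCurve, path) -> None:
    """Stress-strain curve as CSV with a JSON metadata header line."""
    meta = dict(curve.meta)
    meta["truncated"] = curve.truncated
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(meta, sort_keys=True)}\n")
        fh.write("strain_true,strain_eng,stress_zz_gpa,potential_kcal_mol\n")
        for row in zip(
            curve.strain_true, curve.strain_eng, curve.stress_zz, curve.energy
        ):
            fh.write(",".join(f"{v:.12g}" for v in row) + "\n")


def read_curve(path) -> StressStrainCurve:
    lines = Path(path).read_text().splitlines()
    meta: dict = {}
    if lines and lines[0].startswith("#"):
        meta = json.loads(lines[0][1:].strip())
        lines = lines[1:]
    if not lines or lines[0].split(",")[0] != "strain_true":
        raise SchemaError(f"{path}: missing curve header row")
    data = np.array(
        [[float(v) for v in ln.split(",")] for ln in lines[1:] if ln.strip()]
    )
    truncated = bool(meta.pop("truncated", False))
    return StressStrainCurve(
        strain_true=data[:, 0],
        strain_eng=data[:, 1],
        stress_zz=data[:, 2],
        energy=data[:, 3],
        truncated=truncated,
        meta=meta,
    )


def write_calibration_report(report: dict, prefix) -> None:
    """Per-term calibration table as TSV + JSON next to each other."""
    import pandas as pd

    rows = []
    for section in ("bonds", "angles", "dihedrals"):
        for key, fit in report.get(section, {}).items():
            rows.append(
                {
                    "term": section[:-1],
                    "type_key": key,
                    "stiffness": fit.stiffness,
                    "equilibrium": fit.equilibrium,
                    "residual_rms": fit.residual_rms,
                    "window_lo": fit.window[0],
                    "window_hi": fit.window[1],
                    "n_used": fit.n_used,
                }
            )
    for species, info in report.get("pairs", {}).items():
        fits = [sc["fit"] for sc in info["scenarios"].values()]
        rows.append(
            {
                "term": "pair",
                "type_key": species,
                "stiffness": float(np.mean([f.epsilon for f in fits])),
                "equilibrium": float(np.mean([f.sigma for f in fits])),
                "residual_rms": float(np.mean([f.residual_rms for f in fits])),
                "window_lo": min(f.window[0] for f in fits),
                "window_hi": max(f.window[1] for f in fits),
                "n_used": sum(f.n_used for f in fits),
            }
        )
    frame = pd.DataFrame(rows)
    prefix = Path(prefix)
    frame.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    payload = {
        "terms": rows,
        "failures": [list(f) for f in report.get("failures", [])],
    }
    prefix.with_suffix(".json").write_text(json.dumps(payload, indent=2))


def provenance_record(config: dict, seed: int | None) -> dict:
    """Seed + configuration hash attached to every CLI output."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "seed": seed,
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "config": config,
        "package": "silkcg",
        "version": _pkg_version,
    }
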