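"""Mechanics analysis of stress-strain curves and snapshots.

Extracts the tensile metrics of a silk assembly from a simulated
uniaxial-stretch curve: the initial Young's modulus (linear fit over
the elastic regime), the yield point (offset construction against the
elastic line), the failure point (global stress maximum followed by a
collapse), and the modulus of toughness (area under the curve up to
failure, in MJ/m^3).  Also provides mass density, per-bundle
orientation statistics, and curve-to-curve agreement metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import numpy as np

from .model import SimState, Topology, mass_density

__all__ = [
    "StressStrainCurve",
    "MechSummary",
    "ElasticWindowPolicy",
    "young_modulus",
    "yield_point",
    "failure_point",
    "toughness",
    "density",
    "orientation_fraction",
    "compare_energy_curves",
    "summarize",
]


@dataclass
class StressStrainCurve:
    """Per-increment record of a uniaxial stretch.

    ``strain_true`` = ln(L/L0), ``strain_eng`` = L/L0 - 1; both start
    at zero.  ``stress_zz`` is the longitudinal tensile stress in GPa;
    ``energy`` the potential energy in kcal/mol.  ``truncated`` marks a
    curve cut short by a non-finite energy after an increment.
    """

    strain_true: np.ndarray
    strain_eng: np.ndarray
    stress_zz: np.ndarray
    energy: np.ndarray
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.strain_true = np.asarray(self.strain_true, dtype=float)
        self.strain_eng = np.asarray(self.strain_eng, dtype=float)
        self.stress_zz = np.asarray(self.stress_zz, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        n = self.strain_true.size
        if not (
            self.strain_eng.size == self.stress_zz.size == self.energy.size == n
        ):
            raise ValueError("curve arrays must have equal length")
        if n == 0:
            raise ValueError("curve must contain at least the unstrained sample")
        if abs(self.strain_true[0]) > 1e-12 or abs(self.strain_eng[0]) > 1e-12:
            raise ValueError("first sample must be at zero strain")
        if n > 1 and not np.all(np.diff(self.strain_true) > 0):
            raise ValueError("strain must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.strain_true.size

    def strain(self, definition: str = "true") -> np.ndarray:
        if definition == "true":
            return self.strain_true
        if definition == "engineering":
            return self.strain_eng
        raise ValueError("strain definition must be 'true' or 'engineering'")


@dataclass(frozen=True)
class ElasticWindowPolicy:
    """Longest initial window whose linear fit keeps R^2 >= ``r2_min``.

    When no window of at least ``min_points`` samples reaches the R^2
    threshold (e.g. a flat noisy curve), the full curve is used and the
    fit is flagged in the diagnostics.
    """

    r2_min: float = 0.995
    min_points: int = 3
    definition: str = "true"


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def young_modulus(
    curve: StressStrainCurve, policy: ElasticWindowPolicy | None = None
) -> tuple[float, dict]:
    """Initial Young's modulus (GPa) from the elastic regime.

    Returns the least-squares slope of stress vs strain over the chosen
    window plus diagnostics (window bounds, R^2, sample count).
    """
    pol = policy or ElasticWindowPolicy()
    x = curve.strain(pol.definition)
    y = curve.stress_zz
    if pol.min_points < 3:
        raise ValueError("elastic window needs at least 3 points")
    if x.size < pol.min_points:
        raise ValueError(
            f"curve has {x.size} samples; elastic fit needs >= {pol.min_points}"
        )
    best: tuple[float, float, float] | None = None
    best_n = 0
    for n in range(pol.min_points, x.size + 1):
        slope, intercept, r2 = _linfit(x[:n], y[:n])
        if r2 >= pol.r2_min:
            best = (slope, intercept, r2)
            best_n = n
    fallback = best is None
    if fallback:
        best = _linfit(x, y)
        best_n = x.size
    slope, intercept, r2 = best
    diag = {
        "window": (float(x[0]), float(x[best_n - 1])),
        "n_used": best_n,
        "r2": r2,
        "intercept": intercept,
        "fallback_full_range": fallback,
        "definition": pol.definition,
    }
    return slope, diag


def young_modulus_value(curve: StressStrainCurve, **kw) -> float:
    return young_modulus(curve, **kw)[0]


def yield_point(
    curve: StressStrainCurve,
    offset: float = 0.002,
    modulus: float | None = None,
    policy: ElasticWindowPolicy | None = None,
) -> tuple[float, float] | None:
    """Yield strain/stress by the offset construction (default 0.2%).

    The elastic line ``sigma = E (eps - offset)`` is intersected with
    the measured curve; the first crossing where the measured stress
    falls below the line is returned, linearly interpolated between
    the bracketing samples.  Returns None when the curve never departs
    from the elastic line (no yield).
    """
    pol = policy or ElasticWindowPolicy()
    if modulus is None:
        modulus, _ = young_modulus(curve, pol)
    x = curve.strain(pol.definition)
    y = curve.stress_zz
    line = modulus * (x - offset)
    diff = y - line
    # only look beyond the strain where the offset line starts
    for m in range(1, x.size):
        if x[m] <= offset:
            continue
        if diff[m] < 0 <= diff[m - 1]:
            frac = diff[m - 1] / (diff[m - 1] - diff[m])
            eps = x[m - 1] + frac * (x[m] - x[m - 1])
            sig = y[m - 1] + frac * (y[m] - y[m - 1])
            return float(eps), float(sig)
    return None


def failure_point(
    curve: StressStrainCurve, drop_fraction: float = 0.2
) -> tuple[float, float] | None:
    """Failure strain/stress at the global stress maximum.

    The maximum counts as failure only if a later sample drops by at
    least ``drop_fraction`` of the peak stress, or the curve was
    truncated by a non-finite energy; otherwise the material has not
    failed within the simulated range and None is returned.
    """
    if curve.n_samples < 2:
        raise ValueError("failure detection needs at least 2 samples")
    y = curve.stress_zz
    m = int(np.argmax(y))
    peak = y[m]
    collapsed = np.any(y[m + 1 :] <= (1.0 - drop_fraction) * peak)
    if collapsed or curve.truncated:
        return float(curve.strain_true[m]), float(peak)
    return None


def toughness(curve: StressStrainCurve, up_to_strain: float) -> float:
    """Modulus of toughness in MJ/m^3: area under stress vs true strain.

    Trapezoidal integration from zero to ``up_to_strain`` (interpolating
    the endpoint), converted from GPa * strain (1 GPa = 1000 MJ/m^3).
    """
    x = curve.strain_true
    y = curve.stress_zz
    if not x[0] <= up_to_strain <= x[-1]:
        raise ValueError("up_to_strain outside the curve range")
    keep = x <= up_to_strain
    xs = x[keep]
    ys = y[keep]
    if xs[-1] < up_to_strain:
        y_end = float(np.interp(up_to_strain, x, y))
        xs = np.append(xs, up_to_strain)
        ys = np.append(ys, y_end)
    return float(np.trapezoid(ys, xs)) * 1000.0


def density(state: SimState, topo: Topology) -> float:
    """Mass density of a periodic system in g/cm^3."""
    return mass_density(topo, state)


def orientation_fraction(
    state: SimState,
    copy_labels: np.ndarray,
    axis: str = "z",
    tolerance_deg: float = 10.0,
) -> tuple[float, np.ndarray]:
    """Fraction of bundles whose principal axis lies along a lab axis.

    For each bundle (copy label) the principal axis is the direction of
    largest coordinate spread (leading eigenvector of the position
    covariance); its angle to the loading axis is folded onto [0, 90]
    degrees.  Returns the fraction within ``tolerance_deg`` plus the
    per-bundle angles in label order.
    """
    if copy_labels is None:
        raise ValueError("assembly carries no copy labels")
    ax = {"x": 0, "y": 1, "z": 2}[axis.lower()]
    unit = np.zeros(3)
    unit[ax] = 1.0
    labels = np.asarray(copy_labels)
    uniq = np.unique(labels)
    angles = np.empty(uniq.size)
    for m, lab in enumerate(uniq):
        pos = state.positions[labels == lab]
        centered = pos - pos.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        principal = vt[0]
        c = abs(float(np.dot(principal, unit)))
        angles[m] = np.degrees(np.arccos(min(1.0, c)))
    fraction = float(np.mean(angles <= tolerance_deg))
    return fraction, angles


def compare_energy_curves(
    strain_a: np.ndarray,
    value_a: np.ndarray,
    strain_b: np.ndarray,
    value_b: np.ndarray,
) -> dict:
    """Agreement metrics between two per-strain curves.

    Both curves are interpolated onto the overlapping strain range;
    reports RMS difference, Pearson correlation and maximum absolute
    deviation.
    """
    sa, va = np.asarray(strain_a, float), np.asarray(value_a, float)
    sb, vb = np.asarray(strain_b, float), np.asarray(value_b, float)
    lo = max(sa.min(), sb.min())
    hi = min(sa.max(), sb.max())
    if hi <= lo:
        raise ValueError("curves do not overlap in strain")
    grid = np.linspace(lo, hi, max(sa.size, sb.size, 16))
    ia = np.interp(grid, sa, va)
    ib = np.interp(grid, sb, vb)
    diff = ia - ib
    rms = float(np.sqrt(np.mean(diff**2)))
    if np.std(ia) == 0 or np.std(ib) == 0:
        corr = 1.0 if np.allclose(ia - ia.mean(), ib - ib.mean()) else 0.0
    else:
        corr = float(np.corrcoef(ia, ib)[0, 1])
    return {
        "rms": rms,
        "correlation": corr,
        "max_abs_deviation": float(np.max(np.abs(diff))),
        "overlap": (float(lo), float(hi)),
    }


@dataclass
class MechSummary:
    """Headline tensile metrics extracted from one stress-strain curve."""

    youngs_modulus: float  # GPa
    yield_strain: float | None
    yield_stress: float | None
    failure_strain: float | None
    failure_stress: float | None
    toughness: float | None  # MJ/m^3, up to failure strain
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.yield_strain is not None
            and self.failure_strain is not None
            and self.yield_strain > self.failure_strain + 1e-12
        ):
            raise ValueError("yield strain must not exceed failure strain")
        if self.toughness is not None and self.toughness < -1e-12:
            raise ValueError("toughness must be non-negative")

    def to_dict(self) -> dict:
        return {
            "youngs_modulus_gpa": self.youngs_modulus,
            "yield_strain": self.yield_strain,
            "yield_stress_gpa": self.yield_stress,
            "failure_strain": self.failure_strain,
            "failure_stress_gpa": self.failure_stress,
            "toughness_mj_m3": self.toughness,
            "diagnostics": self.diagnostics,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def summarize(
    curve: StressStrainCurve,
    policy: ElasticWindowPolicy | None = None,
    offset: float = 0.002,
    drop_fraction: float = 0.2,
) -> MechSummary:
    """Full mechanics extraction: modulus, yield, failure, toughness."""
    pol = policy or ElasticWindowPolicy()
    modulus, diag = young_modulus(curve, pol)
    yp = yield_point(curve, offset=offset, modulus=modulus, policy=pol)
    fp = failure_point(curve, drop_fraction=drop_fraction) if curve.n_samples > 1 else None
    tough = toughness(curve, fp[0]) if fp is not None else None
    diag = dict(diag)
    diag.update({"yield_offset": offset, "failure_drop_fraction": drop_fraction})
    if tough is not None and tough < 0:
        # noise-level curve: the integral of near-zero stress can come
        # out marginally negative; report zero absorbed energy instead
        diag["toughness_clamped_from"] = tough
        tough = 0.0
    return MechSummary(
        youngs_modulus=modulus,
        yield_strain=None if yp is None else yp[0],
        yield_stress=None if yp is None else yp[1],
        failure_strain=None if fp is None else fp[0],
        failure_stress=None if fp is None else fp[1],
        toughness=tough,
        diagnostics=diag,
    )
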