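"""Minimization, thermostatted dynamics, and uniaxial stretch protocols.

The deformation protocol is quasi-static: the longitudinal box edge is
grown by a small fractional increment, bead coordinates are scaled
affinely along the loading axis, and the system is relaxed — either by
plain energy minimization at fixed lateral dimensions ("constant-strain
minimization") or by a short spell of thermostatted dynamics with the
lateral pressure components barostatted to 1 atm followed by
minimization.  Strain, virial stress and potential energy are recorded
per increment.

Dynamics uses velocity Verlet with a two-level force splitting: the
stiff bonded terms are integrated on an inner timestep (default 0.2 fs,
five substeps per 1 fs outer step) while the LJ term advances on the
outer step.  Temperature is controlled by a stochastic velocity-
rescaling thermostat and lateral pressure by a Berendsen-style barostat;
the contracts are stated on time averages, not on fluctuation spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .forcefield import Evaluator, ForceField, NonFiniteEnergyError
from .mech import StressStrainCurve
from .model import SimState, Topology, mass_density
from .units import FTM2A, GPA_TO_ATM, KB_KCAL, KCAL_A3_TO_GPA, MVV2E

__all__ = [
    "MinimizeReport",
    "minimize",
    "run_dynamics",
    "Stage",
    "anneal_equilibrate",
    "default_anneal_schedule",
    "ProtocolConfig",
    "PRESETS",
    "protocol_preset",
    "stretch",
]


# ---------------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------------


@dataclass
class MinimizeReport:
    converged: bool
    n_iterations: int
    energy_initial: float
    energy_final: float
    max_force: float
    method: str
    message: str = ""


def _max_force(f: np.ndarray) -> float:
    return float(np.abs(f).max(initial=0.0))


def _minimize_lbfgs(
    ev: Evaluator, state: SimState, force_tol: float, max_iter: int
) -> tuple[SimState, MinimizeReport]:
    from scipy.optimize import minimize as sp_minimize

    shape = state.positions.shape
    work = state.copy()

    def objective(x: np.ndarray):
        work.positions = x.reshape(shape)
        comps, f, _ = ev.evaluate(work, want_forces=True)
        return comps.total, -f.ravel()

    e0, g0 = objective(state.positions.ravel())
    if _max_force(g0) <= force_tol:
        return state.copy(), MinimizeReport(
            True, 0, e0, e0, _max_force(g0), "lbfgs", "already converged"
        )
    x = state.positions.ravel().copy()
    n_total = 0
    e_final = e0
    # a few restarts help L-BFGS push the force norm below tight tolerances
    for _ in range(5):
        res = sp_minimize(
            objective,
            x,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": force_tol * 1e-2, "ftol": 1e-14},
        )
        x = res.x
        n_total += int(res.nit)
        e_final = float(res.fun)
        if _max_force(res.jac) <= force_tol or n_total >= max_iter:
            break
    final = state.copy()
    final.positions = x.reshape(shape)
    _, f, _ = ev.evaluate(final, want_forces=True)
    mf = _max_force(f)
    return final, MinimizeReport(
        mf <= force_tol, n_total, e0, e_final, mf, "lbfgs",
        "" if mf <= force_tol else "max_iter reached before force tolerance",
    )


def _minimize_fire(
    ev: Evaluator, state: SimState, force_tol: float, max_iter: int
) -> tuple[SimState, MinimizeReport]:
    """FIRE (fast inertial relaxation engine) with standard parameters."""
    dt, dt_max = 0.5, 2.5
    alpha0, f_alpha, f_inc, f_dec, n_min = 0.1, 0.99, 1.1, 0.5, 5
    work = state.copy()
    comps, f, _ = ev.evaluate(work, want_forces=True)
    e0 = comps.total
    if _max_force(f) <= force_tol:
        return state.copy(), MinimizeReport(
            True, 0, e0, e0, _max_force(f), "fire", "already converged"
        )
    v = np.zeros_like(work.positions)
    alpha = alpha0
    n_pos = 0
    e = e0
    it = 0
    for it in range(1, max_iter + 1):
        power = float((f * v).sum())
        if power > 0:
            n_pos += 1
            fn = np.linalg.norm(f)
            vn = np.linalg.norm(v)
            if fn > 0:
                v = (1 - alpha) * v + alpha * vn * f / fn
            if n_pos > n_min:
                dt = min(dt * f_inc, dt_max)
                alpha *= f_alpha
        else:
            v[:] = 0.0
            dt *= f_dec
            alpha = alpha0
            n_pos = 0
        v = v + dt * f
        step = dt * v
        max_step = 0.2  # A, guards against LJ blow-ups
        norm = np.abs(step).max(initial=0.0)
        if norm > max_step:
            step *= max_step / norm
        work.positions = work.positions + step
        comps, f, _ = ev.evaluate(work, want_forces=True)
        e = comps.total
        if _max_force(f) <= force_tol:
            break
    mf = _max_force(f)
    return work, MinimizeReport(
        mf <= force_tol, it, e0, e, mf, "fire",
        "" if mf <= force_tol else "max_iter reached before force tolerance",
    )


def minimize(
    state: SimState,
    topo: Topology,
    ff: ForceField,
    method: str = "lbfgs",
    force_tol: float = 1e-4,
    max_iter: int = 5000,
    evaluator: Evaluator | None = None,
) -> tuple[SimState, MinimizeReport]:
    """Relax coordinates at fixed box until max |F| <= ``force_tol``.

    ``force_tol`` is in kcal/mol/A per force component.  When the
    iteration cap is reached first, the best state found is returned
    with ``converged=False``.  A non-finite energy aborts with
    :class:`~silkcg.forcefield.NonFiniteEnergyError`.
    """
    ev = evaluator or Evaluator(topo, ff)
    e_start = ev.energy(state)
    if not np.isfinite(e_start):
        raise NonFiniteEnergyError("starting energy is non-finite")
    if method == "lbfgs":
        return _minimize_lbfgs(ev, state, force_tol, max_iter)
    if method == "fire":
        return _minimize_fire(ev, state, force_tol, max_iter)
    raise ValueError(f"unknown minimizer {method!r} (choose 'lbfgs' or 'fire')")


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------


def _kinetic_energy(v: np.ndarray, m: np.ndarray) -> float:
    return 0.5 * MVV2E * float((m[:, None] * v * v).sum())


def _temperature(v: np.ndarray, m: np.ndarray) -> float:
    n_dof = 3 * v.shape[0] - 3
    return 2.0 * _kinetic_energy(v, m) / (n_dof * KB_KCAL)


def maxwell_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann draw with zero total momentum, rescaled to T."""
    std = np.sqrt(KB_KCAL * temperature / (masses * MVV2E))
    v = rng.normal(size=(masses.size, 3)) * std[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    t_now = _temperature(v, masses)
    if t_now > 0:
        v *= math.sqrt(temperature / t_now)
    return v


def _bussi_rescale(
    v: np.ndarray,
    m: np.ndarray,
    t_target: float,
    dt: float,
    tau: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic velocity-rescaling thermostat (canonical sampling)."""
    n_dof = 3 * v.shape[0] - 3
    kin = _kinetic_energy(v, m)
    if kin <= 0:
        return v
    kin_bar = 0.5 * n_dof * KB_KCAL * t_target
    c = math.exp(-dt / tau)
    r1 = rng.standard_normal()
    r2 = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    ratio = kin_bar / (n_dof * kin)
    alpha2 = (
        c
        + (1.0 - c) * ratio * (r1 * r1 + r2)
        + 2.0 * r1 * math.sqrt(c * (1.0 - c) * ratio)
    )
    return v * math.sqrt(max(alpha2, 0.0))


def _pressure_tensor_atm(
    ev: Evaluator, state: SimState, w: np.ndarray
) -> np.ndarray:
    """Instantaneous pressure tensor (atm): kinetic + configurational."""
    kin = np.zeros((3, 3))
    if state.velocities is not None:
        v = state.velocities
        kin = MVV2E * np.einsum("n,ni,nj->ij", ev.topo.masses, v, v)
    return (kin + w) / state.volume * KCAL_A3_TO_GPA * GPA_TO_ATM


_ENSEMBLES = ("NVE", "NVT", "NPT-lateral")


def run_dynamics(
    state: SimState,
    topo: Topology,
    ff: ForceField,
    ensemble: str = "NVT",
    duration_fs: float = 1000.0,
    timestep: float = 1.0,
    bonded_substeps: int = 5,
    seed: int | None = 0,
    temperature: float | tuple[float, float] = 300.0,
    lateral_pressure: float = 1.0,
    tau_thermostat: float = 100.0,
    tau_barostat: float = 2000.0,
    compressibility: float = 4.6e-5,
    loading_axis: int = 2,
    sample_interval: int = 50,
    evaluator: Evaluator | None = None,
) -> tuple[SimState, pd.DataFrame]:
    """Velocity-Verlet dynamics with two-level bonded/non-bonded splitting.

    ``temperature`` may be a scalar target or a ``(start, end)`` pair
    ramped linearly over the run.  In the NPT-lateral ensemble the two
    axes other than ``loading_axis`` are barostatted towards
    ``lateral_pressure`` (atm) while the loading-axis box length stays
    fixed.  Observables are sampled every ``sample_interval`` outer
    steps into the returned DataFrame.  A zero-duration run returns the
    state unchanged.
    """
    if ensemble not in _ENSEMBLES:
        raise ValueError(f"unknown ensemble {ensemble!r}; choose from {_ENSEMBLES}")
    if timestep <= 0 or bonded_substeps < 1:
        raise ValueError("timestep must be positive, bonded_substeps >= 1")
    n_steps = int(round(duration_fs / timestep))
    work = state.copy()
    if n_steps == 0:
        return work, pd.DataFrame()

    ev = evaluator or Evaluator(topo, ff)
    rng = np.random.default_rng(seed)
    m = topo.masses
    if isinstance(temperature, (tuple, list)):
        t_start, t_end = float(temperature[0]), float(temperature[1])
    else:
        t_start = t_end = float(temperature)
    if work.velocities is None:
        work.velocities = maxwell_velocities(m, t_start, rng)

    dt = timestep
    h = dt / bonded_substeps
    pos = work.positions
    vel = work.velocities
    inv_m = (FTM2A / m)[:, None]

    e_nb, f_nb = ev.nonbonded_forces(work)
    e_b, f_b = ev.bonded_forces(work)
    records: list[dict] = []
    lateral_axes = [a for a in range(3) if a != loading_axis]

    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * f_nb * inv_m
        for _ in range(bonded_substeps):
            vel += 0.5 * h * f_b * inv_m
            pos += h * vel
            e_b, f_b = ev.bonded_forces(work)
            vel += 0.5 * h * f_b * inv_m
        e_nb, f_nb = ev.nonbonded_forces(work)
        vel += 0.5 * dt * f_nb * inv_m

        t_target = t_start + (t_end - t_start) * step / n_steps
        if ensemble in ("NVT", "NPT-lateral"):
            vel[:] = _bussi_rescale(vel, m, t_target, dt, tau_thermostat, rng)
        if ensemble == "NPT-lateral":
            comps, _, w = ev.evaluate(work, want_forces=True)
            p_tensor = _pressure_tensor_atm(ev, work, w)
            for a in lateral_axes:
                mu = (
                    1.0
                    - dt / tau_barostat
                    * compressibility
                    * (lateral_pressure - p_tensor[a, a])
                ) ** (1.0 / 3.0)
                mu = min(max(mu, 0.995), 1.005)
                work.box[a] *= mu
                pos[:, a] *= mu

        if step % sample_interval == 0 or step == n_steps:
            comps, _, w = ev.evaluate(work, want_forces=True)
            p_tensor = _pressure_tensor_atm(ev, work, w)
            records.append(
                {
                    "step": step,
                    "time_fs": step * dt,
                    "temperature": _temperature(vel, m),
                    "target_temperature": t_target,
                    "pxx_atm": p_tensor[0, 0],
                    "pyy_atm": p_tensor[1, 1],
                    "pzz_atm": p_tensor[2, 2],
                    "potential": comps.total,
                    "kinetic": _kinetic_energy(vel, m),
                    "box_x": work.box[0],
                    "box_y": work.box[1],
                    "box_z": work.box[2],
                    "density": mass_density(topo, work),
                }
            )
    return work, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Staged annealing / equilibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stage:
    """One leg of an equilibration schedule."""

    ensemble: str
    t_start: float
    t_end: float
    duration_fs: float
    lateral_pressure: float = 1.0


def default_anneal_schedule(scale: float = 1.0) -> list[Stage]:
    """Heat-soak / cool / ambient-NPT schedule, scalable for desk tests.

    At scale 1 the spans mirror the production recipe (10 ns at 800 K,
    10 ns cooling to 300 K, 30 ns at 300 K and 1 atm laterally); the
    scale factor multiplies every span.
    """
    return [
        Stage("NVT", 800.0, 800.0, 10_000_000.0 * scale),
        Stage("NVT", 800.0, 300.0, 10_000_000.0 * scale),
        Stage("NPT-lateral", 300.0, 300.0, 30_000_000.0 * scale),
    ]


def anneal_equilibrate(
    state: SimState,
    topo: Topology,
    ff: ForceField,
    schedule: Sequence[Stage],
    seed: int = 0,
    trailing_fraction: float = 0.25,
    **dynamics_kw,
) -> tuple[SimState, dict]:
    """Run a staged anneal and report trailing-window observables.

    Returns the final state plus a report holding the concatenated
    time series and the trailing-window (last ``trailing_fraction`` of
    the final stage) mean and standard deviation of density and box
    lengths — the stationarity diagnostics of the equilibration.
    """
    work = state.copy()
    ev = Evaluator(topo, ff)
    frames: list[pd.DataFrame] = []
    for si, stage in enumerate(schedule):
        work, frame = run_dynamics(
            work,
            topo,
            ff,
            ensemble=stage.ensemble,
            duration_fs=stage.duration_fs,
            temperature=(stage.t_start, stage.t_end),
            lateral_pressure=stage.lateral_pressure,
            seed=None if seed is None else seed + si,
            evaluator=ev,
            **dynamics_kw,
        )
        if not frame.empty:
            frame = frame.assign(stage=si)
            frames.append(frame)
    series = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    report: dict = {"series": series}
    if not series.empty:
        last_stage = series[series["stage"] == series["stage"].max()]
        n_tail = max(1, int(round(trailing_fraction * len(last_stage))))
        tail = last_stage.tail(n_tail)
        report["trailing"] = {
            "density_mean": float(tail["density"].mean()),
            "density_std": float(tail["density"].std(ddof=0)),
            "box_mean": [float(tail[c].mean()) for c in ("box_x", "box_y", "box_z")],
            "temperature_mean": float(tail["temperature"].mean()),
            "n_samples": int(len(tail)),
        }
    else:
        report["trailing"] = None
    return work, report


# ---------------------------------------------------------------------------
# Uniaxial stretch protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    """Incremental uniaxial stretch protocol.

    ``increment`` is the per-step fractional growth of the loading-axis
    box length (multiplicative on the current length, so the true
    strain after n increments is n*ln(1+increment)).  In
    ``static_minimize`` mode each increment is followed by energy
    minimization at fixed lateral dimensions; in
    ``equilibrate_then_minimize`` a spell of thermostatted dynamics
    with barostatted lateral axes precedes the minimization.
    """

    increment: float = 0.0005
    n_increments: int = 100
    mode: str = "static_minimize"
    equilibration_fs: float = 200_000.0
    force_tol: float = 1e-4
    max_iter: int = 3000
    minimizer: str = "lbfgs"
    axis: int = 2
    temperature: float = 300.0
    lateral_pressure: float = 1.0
    timestep: float = 1.0
    bonded_substeps: int = 5
    seed: int = 0
    relax_initial: bool = True

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise ValueError("strain increment must be positive")
        if self.n_increments < 0:
            raise ValueError("n_increments must be non-negative")
        if self.mode not in ("static_minimize", "equilibrate_then_minimize"):
            raise ValueError(f"unknown stretch mode {self.mode!r}")
        if self.equilibration_fs < 0:
            raise ValueError("equilibration span must be non-negative")


PRESETS: dict[str, dict] = {
    # constant-strain minimization, 0.005% increments (model verification)
    "verify_0.005pct_static": {"increment": 5e-5, "mode": "static_minimize"},
    # production stretching: 0.05% increments, 200 ps relaxation + minimization
    "production_0.05pct_equil": {
        "increment": 5e-4,
        "mode": "equilibrate_then_minimize",
        "equilibration_fs": 200_000.0,
    },
}


def protocol_preset(name: str, **overrides) -> ProtocolConfig:
    """Named stretch protocol; overrides replace preset fields."""
    if name not in PRESETS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    merged = {**PRESETS[name], **overrides}
    return ProtocolConfig(**merged)


def stretch(
    state: SimState,
    topo: Topology,
    ff: ForceField,
    protocol: ProtocolConfig,
) -> StressStrainCurve:
    """Incremental uniaxial stretch along the loading axis.

    Records ``n_increments + 1`` samples including the unstrained
    point.  Stress is the static virial (no kinetic term) evaluated on
    the post-minimization configuration of each increment; a non-finite
    energy truncates the curve and flags it as failed at that strain.
    """
    ax = protocol.axis
    ev = Evaluator(topo, ff)
    work = state.copy()
    work.velocities = None

    def relax(w: SimState, stage_seed: int) -> SimState:
        if protocol.mode == "equilibrate_then_minimize" and protocol.equilibration_fs > 0:
            w, _ = run_dynamics(
                w,
                topo,
                ff,
                ensemble="NPT-lateral",
                duration_fs=protocol.equilibration_fs,
                timestep=protocol.timestep,
                bonded_substeps=protocol.bonded_substeps,
                temperature=protocol.temperature,
                lateral_pressure=protocol.lateral_pressure,
                loading_axis=ax,
                seed=stage_seed,
                evaluator=ev,
            )
            w.velocities = None
        w, _ = minimize(
            w,
            topo,
            ff,
            method=protocol.minimizer,
            force_tol=protocol.force_tol,
            max_iter=protocol.max_iter,
            evaluator=ev,
        )
        return w

    if protocol.relax_initial:
        work = relax(work, protocol.seed)

    strains_t = [0.0]
    strains_e = [0.0]
    stresses = [float(ev.stress(work)[ax, ax])]
    energies = [ev.energy(work)]
    truncated = False
    log1p = math.log1p(protocol.increment)

    for n in range(1, protocol.n_increments + 1):
        frac_before = work.positions[:, ax] / work.box[ax]
        work.box[ax] *= 1.0 + protocol.increment
        work.positions[:, ax] = frac_before * work.box[ax]
        try:
            work = relax(work, protocol.seed + n)
            stress = float(ev.stress(work)[ax, ax])
            energy = ev.energy(work)
        except NonFiniteEnergyError:
            truncated = True
            break
        strains_t.append(n * log1p)
        strains_e.append((1.0 + protocol.increment) ** n - 1.0)
        stresses.append(stress)
        energies.append(energy)

    return StressStrainCurve(
        strain_true=np.array(strains_t),
        strain_eng=np.array(strains_e),
        stress_zz=np.array(stresses),
        energy=np.array(energies),
        truncated=truncated,
        meta={
            "increment": protocol.increment,
            "mode": protocol.mode,
            "axis": ax,
            "seed": protocol.seed,
        },
    )
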