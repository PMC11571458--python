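"""Elastoplastic foam drop-test simulator.

Synthetic stand-in for the laboratory rig: a rigid mass hits a stack of
closed-cell polyethylene foam layers and the simulated load cell / laser
sensors record force and penetration over time.

Material model (strain-based, strain = compression / effective thickness):

* loading:  ``F = mult * a_f * (exp(b_f*eps) - 1) * D(eps)`` with the
  densification factor ``D(eps) = 1 + c_d * max(0, eps - eps_d)^2 / (1 - eps)``
  which blows up as the cell structure compacts towards full compression;
* unloading: the loading curve scaled by a power-law window,
  ``F = F_load(eps) * ((eps - eps_p)/(eps_pk - eps_p))^(n_u - 1)`` on
  ``[eps_p, eps_pk]`` and zero below the plastic set ``eps_p``.  The set is
  tied to the unloading shape, ``eps_p = (1 - 1/n_u) * eps_pk``, so that
  ``n_u -> 1`` recovers a fully elastic retrace while larger ``n_u`` leaves
  both a fatter hysteresis loop and a larger permanent deformation.  This
  construction keeps the unloading curve below the loading curve for every
  admissible parameter set, hence elastic energy never exceeds absorbed
  energy.

Damage under repeated loading has two channels, both fed by the cycle just
completed:

* *stiffening*: ``stiffness_multiplier = 1 + kappa * cumulative_plastic_energy``
  scales the whole loading curve;
* *permanent set*: crushing is remembered through the deepest point ever
  reached; ``permanent_set = (1 - 1/n_u) * max_crush_depth`` thins the
  effective stack, which moves the densification wall closer and is the
  dominant reason a struck-again mat shows a higher force at the same
  absorbed energy.

Viscous (rate-dependent) effects are deliberately absent; the material is
purely elastoplastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .design import StudyConfig, TestCondition, impact_velocity

__all__ = [
    "FoamParams",
    "FoamState",
    "TraceTruth",
    "ImpactTrace",
    "foam_force",
    "simulate_drop",
    "degrade",
    "generate_dataset",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the integration leaves the supported physical regime."""


@dataclass(frozen=True)
class FoamParams:
    """Material, degradation and sensor-noise parameters.

    Material defaults are the factory calibration against the published
    force-at-30-J table (see :mod:`foamimpact.calibration`); noise defaults
    reflect a load cell with ~1% force error and sub-0.1 mm laser channels.
    """

    a_f: float = 382.6333  # stress scale of the loading law, N
    b_f: float = 3.525141  # exponential strain coefficient, dimensionless
    eps_d: float = 0.75  # densification onset strain
    c_d: float = 13.21335  # densification stiffening coefficient
    n_u: float = 1.265371  # unloading shape exponent (> 1)
    kappa: float = 4.132752e-3  # stiffening rate per J of plastic energy
    specimen_cv: float = 0.03  # CV of a_f across specimens
    noise_force_sd: float = 25.0  # N
    noise_disp_sd: float = 5e-5  # m
    sample_rate: float = 10000.0  # Hz

    def __post_init__(self) -> None:
        if self.a_f <= 0 or self.b_f <= 0:
            raise ValueError("a_f and b_f must be > 0")
        if not (0 < self.eps_d < 1):
            raise ValueError("eps_d must be in (0, 1)")
        if self.c_d < 0:
            raise ValueError("c_d must be >= 0")
        if self.n_u <= 1:
            raise ValueError("n_u must be > 1")
        if self.kappa < 0 or self.specimen_cv < 0:
            raise ValueError("kappa and specimen_cv must be >= 0")
        if self.noise_force_sd < 0 or self.noise_disp_sd < 0:
            raise ValueError("noise levels must be >= 0")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class FoamState:
    """Damage state of one specimen, persisting across repetitions."""

    cumulative_plastic_energy: float = 0.0  # J
    permanent_set: float = 0.0  # m, loss of effective thickness
    stiffness_multiplier: float = 1.0  # = 1 + kappa * cumulative_plastic_energy
    max_crush_depth: float = 0.0  # m, deepest compression from pristine surface

    def __post_init__(self) -> None:
        if self.cumulative_plastic_energy < 0 or self.permanent_set < 0:
            raise ValueError("state quantities must be >= 0")
        if self.stiffness_multiplier < 1.0:
            raise ValueError("stiffness_multiplier must be >= 1")


@dataclass(frozen=True)
class TraceTruth:
    """Noise-free record of one simulated cycle plus its energy bookkeeping."""

    displacement: np.ndarray  # m, compression from contact surface
    force: np.ndarray  # N
    peak_force: float
    peak_displacement: float
    absorbed_energy: float  # J, work done on the foam during loading
    elastic_energy: float  # J, returned during unloading
    plastic_energy: float  # J
    separation_velocity: float  # m/s, negative = moving upward


@dataclass(frozen=True)
class ImpactTrace:
    """Simulated sensor record of one drop.

    ``disp_a`` / ``disp_b`` are the two laser channels: the same true
    penetration signal with independent noise, so averaging them is
    meaningful.  Negative displacement = impactor still above the specimen.
    """

    time: np.ndarray
    disp_a: np.ndarray
    disp_b: np.ndarray
    force: np.ndarray
    condition: TestCondition
    truth: Optional[TraceTruth] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        if n < 2:
            raise ValueError("trace needs at least 2 samples")
        if not (len(self.disp_a) == len(self.disp_b) == len(self.force) == n):
            raise ValueError("channel lengths differ")


def _loading_force(eps: float, params: FoamParams, multiplier: float) -> float:
    if eps <= 0.0:
        return 0.0
    if eps >= 1.0:
        raise SimulationError(f"strain {eps:.3f} >= 1: full compaction")
    f = multiplier * params.a_f * (math.expm1(params.b_f * eps))
    if eps > params.eps_d and params.c_d > 0.0:
        over = eps - params.eps_d
        f *= 1.0 + params.c_d * over * over / (1.0 - eps)
    return f


def foam_force(
    strain: float,
    params: FoamParams,
    state: FoamState,
    phase: str = "loading",
    peak_context: Optional[tuple[float, float]] = None,
) -> float:
    """Foam reaction force (N) at a given strain.

    ``phase`` is ``"loading"`` or ``"unloading"``; unloading requires
    ``peak_context = (strain_peak, strain_plastic_set)``.
    """
    if strain < 0:
        raise ValueError("strain must be >= 0")
    if strain >= 1.0:
        raise SimulationError(f"strain {strain:.3f} >= 1: full compaction")
    mult = state.stiffness_multiplier
    if phase == "loading":
        return _loading_force(strain, params, mult)
    if phase != "unloading":
        raise ValueError(f"unknown phase {phase!r}")
    if peak_context is None:
        raise ValueError("unloading requires peak_context=(strain_peak, strain_p)")
    eps_pk, eps_p = peak_context
    if strain <= eps_p:
        return 0.0
    if strain >= eps_pk:
        return _loading_force(eps_pk, params, mult)
    w = (strain - eps_p) / (eps_pk - eps_p)
    return _loading_force(strain, params, mult) * w ** (params.n_u - 1.0)


def plastic_set_strain(peak_strain: float, params: FoamParams) -> float:
    """Residual strain left behind after unloading from ``peak_strain``."""
    return (1.0 - 1.0 / params.n_u) * peak_strain


SET_APPROACH_RATE = 0.65
"""Per-cycle fraction by which the permanent set closes in on its asymptote.

The set saturates at ``(1 - 1/n_u) * max_crush_depth`` — full residual
deformation of the deepest crush ever — but closed-cell polyethylene
recovers partially between strikes, so each cycle only realises a fixed
fraction of the remaining distance.  This produces the observed pattern of
a large first increase followed by geometrically decaying ones.
"""


def degrade(
    state: FoamState,
    plastic_energy_increment: float,
    params: FoamParams,
    crush_depth: Optional[float] = None,
) -> FoamState:
    """Advance the damage state after one completed cycle.

    ``crush_depth`` is the deepest absolute compression of the cycle measured
    from the pristine surface; when given, the permanent set relaxes toward
    its asymptote ``(1 - 1/n_u) * max_crush_depth`` at ``SET_APPROACH_RATE``
    per cycle.  The permanent set never shrinks.
    """
    if plastic_energy_increment < 0:
        raise ValueError("plastic energy increment must be >= 0")
    e_cum = state.cumulative_plastic_energy + plastic_energy_increment
    max_crush = state.max_crush_depth
    set_new = state.permanent_set
    if crush_depth is not None:
        max_crush = max(max_crush, crush_depth)
        target = (1.0 - 1.0 / params.n_u) * max_crush
        if target > set_new:
            set_new = set_new + SET_APPROACH_RATE * (target - set_new)
    return FoamState(
        cumulative_plastic_energy=e_cum,
        permanent_set=set_new,
        stiffness_multiplier=1.0 + params.kappa * e_cum,
        max_crush_depth=max_crush,
    )


_OVERSAMPLE = 10  # internal integration runs at oversample * sample_rate
_PAD_S = 0.003  # ballistic padding before contact / after separation
_MAX_T = 0.5  # s, hard cap on contact duration


def _integrate_contact(
    v0: float,
    h_eff: float,
    params: FoamParams,
    state: FoamState,
    mass: float,
    gravity: float,
):
    """Fixed-step RK4 of m x'' = m g - F(x/h_eff) from contact to separation.

    Returns internal-rate arrays (x, F) plus the peak point, phase-switch
    bookkeeping and separation velocity.
    """
    dt = 1.0 / (_OVERSAMPLE * params.sample_rate)
    mult = state.stiffness_multiplier
    n_u = params.n_u

    phase_ctx: dict = {"loading": True, "eps_pk": 0.0, "eps_p": 0.0}

    def force_of(eps: float) -> float:
        if eps <= 0.0:
            return 0.0
        if phase_ctx["loading"] or eps >= phase_ctx["eps_pk"]:
            return _loading_force(eps, params, mult)
        eps_pk, eps_p = phase_ctx["eps_pk"], phase_ctx["eps_p"]
        if eps <= eps_p:
            return 0.0
        w = (eps - eps_p) / (eps_pk - eps_p)
        return _loading_force(eps, params, mult) * w ** (n_u - 1.0)

    def accel(x: float, v: float) -> float:
        return gravity - force_of(x / h_eff) / mass

    x, v = 0.0, v0
    xs = [0.0]
    fs = [0.0]
    n_max = int(_MAX_T / dt)
    for _ in range(n_max):
        if x / h_eff >= 0.99:
            raise SimulationError(
                "strain >= 0.99: parameterization outside the supported regime"
            )
        # RK4 step
        k1x = v
        k1v = accel(x, v)
        k2x = v + 0.5 * dt * k1v
        k2v = accel(x + 0.5 * dt * k1x, k2x)
        k3x = v + 0.5 * dt * k2v
        k3v = accel(x + 0.5 * dt * k2x, k3x)
        k4x = v + dt * k3v
        k4v = accel(x + dt * k3x, k4x)
        x_new = x + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        v_new = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if phase_ctx["loading"] and v_new <= 0.0:
            # force maximum coincides with deepest compression; switch law
            eps_pk = x_new / h_eff
            phase_ctx["loading"] = False
            phase_ctx["eps_pk"] = eps_pk
            phase_ctx["eps_p"] = (1.0 - 1.0 / n_u) * eps_pk
        x, v = x_new, v_new
        xs.append(x)
        fs.append(force_of(x / h_eff))
        if not phase_ctx["loading"]:
            if x / h_eff <= phase_ctx["eps_p"] + 1e-12 or fs[-1] <= 0.0:
                break  # separation: foam force back to zero
            if v >= 0.0:
                break  # rebound too weak to reach separation; settles
    else:
        raise SimulationError("contact did not terminate within time cap")

    return (
        np.asarray(xs),
        np.asarray(fs),
        phase_ctx["eps_pk"] * h_eff,
        v,
    )


def _static_settle(
    h_eff: float, params: FoamParams, state: FoamState, mass: float, gravity: float
):
    """Quasi-static placement (zero drop height): solve F(eps) = m g."""
    from scipy.optimize import brentq

    target = mass * gravity
    mult = state.stiffness_multiplier
    eps_eq = brentq(
        lambda e: _loading_force(e, params, mult) - target, 1e-12, 0.989
    )
    return eps_eq * h_eff


def simulate_drop(
    condition: TestCondition,
    params: FoamParams,
    state: FoamState,
    config: StudyConfig,
    seed: Optional[int] = None,
) -> tuple[ImpactTrace, FoamState]:
    """Simulate one drop and return the sensor trace plus the updated state.

    The free fall itself is not integrated: the impactor enters at the
    free-fall contact speed.  A few milliseconds of ballistic approach and
    rebound are prepended/appended so that contact detection downstream
    operates on a realistic record.  Gaussian noise (per ``params``) is added
    independently to the force channel and to each displacement channel; the
    noise-free signal is kept in ``trace.truth``.
    """
    mass = config.impactor_mass
    g = config.gravity
    h_nom = config.specimen_thickness(condition.n_layers)
    h_eff = h_nom - state.permanent_set
    if h_eff <= 0:
        raise SimulationError("specimen fully consumed by permanent set")
    v0 = impact_velocity(condition.drop_height, g)

    if v0 == 0.0:
        x_eq = _static_settle(h_eff, params, state, mass, g)
        n = max(int(0.02 * params.sample_rate), 4)
        x_int = np.full(n * _OVERSAMPLE, x_eq)
        # ramp the first internal samples so the loading integral is defined
        ramp = np.linspace(0.0, x_eq, _OVERSAMPLE)
        x_int[: _OVERSAMPLE] = ramp
        f_int = np.array(
            [_loading_force(xx / h_eff, params, state.stiffness_multiplier) for xx in x_int]
        )
        x_pk = x_eq
        v_sep = 0.0
        new_state = state  # no completed cycle, no damage update
        e_load = float(np.trapezoid(f_int[:_OVERSAMPLE], ramp))
        e_unload = 0.0
    else:
        x_int, f_int, x_pk, v_sep = _integrate_contact(
            v0, h_eff, params, state, mass, g
        )
        i_pk = int(np.argmax(x_int))
        e_load = float(np.trapezoid(f_int[: i_pk + 1], x_int[: i_pk + 1]))
        e_unload = float(abs(np.trapezoid(f_int[i_pk:], x_int[i_pk:])))
        e_plastic = max(e_load - e_unload, 0.0)
        new_state = degrade(
            state, e_plastic, params, crush_depth=state.permanent_set + x_pk
        )

    e_plastic = max(e_load - e_unload, 0.0)

    # decimate internal record to the sensor sample rate
    x_out = x_int[::_OVERSAMPLE]
    f_out = f_int[::_OVERSAMPLE]

    # ballistic padding: approach before contact, rebound after separation
    dt_s = 1.0 / params.sample_rate
    n_pad = int(round(_PAD_S * params.sample_rate))
    t_pre = -dt_s * np.arange(n_pad, 0, -1)
    x_pre = v0 * t_pre + 0.5 * g * t_pre**2
    t_post = dt_s * np.arange(1, n_pad + 1)
    x_sep = x_out[-1]
    x_post = x_sep + v_sep * t_post + 0.5 * g * t_post**2
    # rebound: impactor leaves the surface; do not let padding re-enter deeper
    x_post = np.minimum(x_post, x_sep)

    disp = np.concatenate([x_pre, x_out, x_post])
    force = np.concatenate([np.zeros(n_pad), f_out, np.zeros(n_pad)])
    time = dt_s * np.arange(len(disp))

    truth = TraceTruth(
        displacement=disp.copy(),
        force=force.copy(),
        peak_force=float(np.max(f_int)),
        peak_displacement=float(x_pk),
        absorbed_energy=e_load,
        elastic_energy=e_unload,
        plastic_energy=e_plastic,
        separation_velocity=float(v_sep),
    )

    rng = np.random.default_rng(seed)
    disp_a = disp + rng.normal(0.0, params.noise_disp_sd, size=disp.shape)
    disp_b = disp + rng.normal(0.0, params.noise_disp_sd, size=disp.shape)
    force_n = force + rng.normal(0.0, params.noise_force_sd, size=force.shape)

    trace = ImpactTrace(
        time=time,
        disp_a=disp_a,
        disp_b=disp_b,
        force=force_n,
        condition=condition,
        truth=truth,
    )
    return trace, new_state


def generate_dataset(
    config: StudyConfig,
    params: FoamParams,
    seed: int,
    out_dir=None,
):
    """Simulate every test of the enumerated design.

    Per-specimen stiffness scale ``a_f`` is drawn lognormally with
    coefficient of variation ``params.specimen_cv`` (unit mean).  The damage
    state persists across a specimen's repetitions and resets between
    specimens.  Fully reproducible from ``seed``.

    Returns ``(traces, manifest)``; when ``out_dir`` is given the traces and
    the manifest are also written as CSV files (see :mod:`foamimpact.io`).
    """
    import pandas as pd

    from .design import enumerate_design
    from .io import trace_filename, write_trace_csv

    design = enumerate_design(config)
    by_specimen: dict[str, list[TestCondition]] = {}
    for cond in design.conditions:
        by_specimen.setdefault(cond.specimen_id, []).append(cond)

    master = np.random.SeedSequence(seed)
    traces: list[ImpactTrace] = []
    rows = []
    specimen_ids = sorted(by_specimen)
    children = master.spawn(len(specimen_ids))
    for sid, ss in zip(specimen_ids, children):
        conds = sorted(by_specimen[sid], key=lambda c: c.repetition)
        rng = np.random.default_rng(ss)
        if params.specimen_cv > 0:
            sigma = math.sqrt(math.log1p(params.specimen_cv**2))
            factor = math.exp(rng.normal(0.0, sigma) - 0.5 * sigma**2)
        else:
            factor = 1.0
        p_spec = replace(params, a_f=params.a_f * factor)
        state = FoamState()
        for cond in conds:
            trace_seed = int(rng.integers(0, 2**31 - 1))
            trace, state = simulate_drop(cond, p_spec, state, config, seed=trace_seed)
            traces.append(trace)
            rows.append(
                {
                    "file": trace_filename(cond),
                    "drop_height_m": cond.drop_height,
                    "n_layers": cond.n_layers,
                    "specimen_id": cond.specimen_id,
                    "repetition": cond.repetition,
                    "trace_seed": trace_seed,
                }
            )
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for trace, row in zip(traces, rows):
            write_trace_csv(trace, out / row["file"])
        manifest.to_csv(out / "manifest.csv", index=False)

    return traces, manifest
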