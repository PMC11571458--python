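"""Calibration of the foam material parameters.

The generator is anchored to the published summary of the laboratory study:
the force reached at 30 J of absorbed energy at the 0.50-m drop height, per
layer count and repetition (mean +/- SD over three specimens).  A bounded
least-squares search over ``(a_f, b_f, c_d, kappa, n_u)`` matches the
noise-free simulated force-at-30-J of the 1- and 2-layer first strikes and
the repetition-2 relative increases of all three layers; the 3-layer first
strike force is deliberately held out as validation.  The result of this
factory calibration is frozen as the :class:`~foamimpact.simulator.FoamParams`
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .design import StudyConfig, TestCondition
from .metrics import force_at_energy
from .simulator import FoamParams, FoamState, simulate_drop

__all__ = [
    "CalibrationTarget",
    "REFERENCE_FORCE_AT_30J",
    "REFERENCE_FORCE_STD",
    "REFERENCE_ENERGY_J",
    "default_targets",
    "calibrate_defaults",
    "CalibrationError",
]

# Published repeated-loading reference: force (N) at 30 J absorbed energy,
# 0.50-m drop, by layer count, repetitions 1..5 (means over 3 specimens).
REFERENCE_FORCE_AT_30J = {
    1: (10017.0, 12867.0, 13642.0, 13967.0, 14250.0),
    2: (3858.0, 4525.0, 4683.0, 4767.0, 4833.0),
    3: (2342.0, 2558.0, 2608.0, 2600.0, 2617.0),
}
REFERENCE_FORCE_STD = {
    1: (739.0, 781.0, 946.0, 775.0, 786.0),
    2: (124.0, 121.0, 133.0, 104.0, 161.0),
    3: (20.0, 38.0, 38.0, 0.0, 29.0),
}
REFERENCE_ENERGY_J = 30.0


class CalibrationError(RuntimeError):
    """The optimizer could not reach the required tolerance."""


@dataclass(frozen=True)
class CalibrationTarget:
    n_layers: int
    force_at_30j: float  # N, repetition 1
    rel_increase_rep2: float  # fractional, e.g. 0.28


def default_targets() -> list[CalibrationTarget]:
    """Calibration targets from the published force-at-30-J table."""
    out = []
    for n_layers, forces in REFERENCE_FORCE_AT_30J.items():
        out.append(
            CalibrationTarget(
                n_layers=n_layers,
                force_at_30j=forces[0],
                rel_increase_rep2=forces[1] / forces[0] - 1.0,
            )
        )
    return out


def _noise_free(params: FoamParams) -> FoamParams:
    return replace(params, noise_force_sd=0.0, noise_disp_sd=0.0, specimen_cv=0.0)


def simulate_force_at_energy(
    params: FoamParams,
    n_layers: int,
    config: StudyConfig,
    repetitions: int = 1,
    drop_height: Optional[float] = None,
    target_energy: float = REFERENCE_ENERGY_J,
) -> list[float]:
    """Noise-free force at ``target_energy`` for consecutive strikes.

    Simulates ``repetitions`` successive drops of one specimen and reads the
    force at the target absorbed energy off each truth loading curve.
    """
    if drop_height is None:
        drop_height = config.extra_drop_height
    p = _noise_free(params)
    state = FoamState()
    forces = []
    for rep in range(1, repetitions + 1):
        cond = TestCondition(drop_height, n_layers, "calib", rep)
        trace, state = simulate_drop(cond, p, state, config, seed=0)
        truth = trace.truth
        i_pk = int(np.argmax(truth.displacement))
        forces.append(
            force_at_energy(
                truth.displacement[: i_pk + 1],
                truth.force[: i_pk + 1],
                target_energy,
            )
        )
    return forces


_FIT_FORCE_LAYERS = (1, 2)  # 3-layer first-strike force is held-out validation

# Published observation anchoring the loading-curve shape: single-layer
# compaction sets in around 75% deformation at forces exceeding ~5 kN.
# Without this anchor the split between the exponential backbone (b_f) and
# the densification term (c_d) is not identifiable from two force targets.
_DENSIFICATION_ANCHOR_STRAIN = 0.75
_DENSIFICATION_ANCHOR_FORCE = 5000.0  # N


def _strain_at_force(params: FoamParams, force: float) -> float:
    """Strain at which the fresh loading curve reaches ``force`` (N)."""
    from scipy.optimize import brentq

    from .simulator import _loading_force

    return brentq(lambda e: _loading_force(e, params, 1.0) - force, 1e-9, 0.989)


def _static_force_at_energy(
    params: FoamParams, h: float, target_energy: float
) -> tuple[float, float]:
    """Force and strain at ``target_energy`` on the fresh loading curve.

    First-strike loading follows the static material law, so this pure
    quadrature is equivalent to (and far cheaper than) integrating the drop.
    """
    from .simulator import _loading_force

    eps = np.linspace(1e-6, 0.988, 4000)
    F = np.array([_loading_force(e, params, 1.0) for e in eps])
    x = eps * h
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (F[1:] + F[:-1]) * np.diff(x))])
    if cum[-1] < target_energy:
        raise CalibrationError("loading curve cannot absorb the target energy")
    x_star = float(np.interp(target_energy, cum, x))
    return float(np.interp(x_star, x, F)), x_star / h


def calibrate_defaults(
    targets: Optional[Sequence[CalibrationTarget]] = None,
    config: Optional[StudyConfig] = None,
    tolerance: float = 0.05,
    full_output: bool = False,
):
    """Fit the foam material parameters to the reference force table.

    The least-squares search over ``(a_f, b_f, c_d, kappa, n_u)`` is staged:

    1. the loading-curve parameters ``(a_f, b_f, c_d)`` are fitted by static
       quadrature to the 1- and 2-layer first-strike forces plus the
       densification anchor (first strikes never leave the static curve);
    2. the degradation parameters ``(n_u, kappa)`` are fitted with full drop
       dynamics to the repetition-2 relative increases, with a penalty on
       any non-monotone force-at-energy sequence over five strikes.

    Returns a :class:`FoamParams` whose noise-free simulation reproduces the
    1- and 2-layer first-strike forces at 30 J within ``tolerance`` (5% by
    default); raises :class:`CalibrationError` otherwise.  With
    ``full_output=True`` also returns a diagnostics dict including the
    held-out 3-layer validation error.
    """
    if targets is None:
        targets = default_targets()
    targets = list(targets)
    if not targets:
        raise ValueError("empty calibration target table")
    layers_present = {t.n_layers for t in targets}
    if not {1, 2} <= layers_present:
        raise ValueError("targets must include the 1- and 2-layer first-strike forces")
    if config is None:
        config = StudyConfig()

    h1 = config.layer_thickness

    # --- stage 1: loading curve ---------------------------------------
    force_targets = [t for t in targets if t.n_layers in _FIT_FORCE_LAYERS]

    def shape_residuals(z):
        a, b, c = (math.exp(v) for v in z)
        p = FoamParams(a_f=a, b_f=b, c_d=c, n_u=2.0)
        try:
            res = []
            for t in force_targets:
                f, _ = _static_force_at_energy(
                    p, t.n_layers * h1, REFERENCE_ENERGY_J
                )
                res.append(f / t.force_at_30j - 1.0)
            res.append(
                _strain_at_force(p, _DENSIFICATION_ANCHOR_FORCE)
                - _DENSIFICATION_ANCHOR_STRAIN
            )
            return res
        except Exception:
            return [10.0] * (len(force_targets) + 1)

    sol1 = least_squares(
        shape_residuals,
        [math.log(300.0), math.log(3.5), math.log(15.0)],
        bounds=(
            [math.log(10.0), math.log(1.0), math.log(1e-3)],
            [math.log(3000.0), math.log(12.0), math.log(500.0)],
        ),
        xtol=1e-12,
        ftol=1e-12,
    )
    a_f, b_f, c_d = (math.exp(v) for v in sol1.x)

    # --- stage 2: degradation -----------------------------------------
    n_reps = 5  # probe enough strikes to keep degradation monotone

    def unpack(z) -> FoamParams:
        return FoamParams(
            a_f=a_f, b_f=b_f, c_d=c_d, n_u=1.0 + math.exp(z[0]), kappa=math.exp(z[1])
        )

    def degradation_residuals(z):
        p = unpack(z)
        res = []
        try:
            for t in targets:
                forces = simulate_force_at_energy(
                    p, t.n_layers, config, repetitions=n_reps
                )
                res.append((forces[1] / forces[0] - 1.0) - t.rel_increase_rep2)
                drops = [
                    max(0.0, (forces[r - 1] - forces[r]) / forces[r - 1])
                    for r in range(1, len(forces))
                ]
                res.append(10.0 * sum(drops))
        except Exception:
            return [10.0] * (2 * len(targets))
        return res

    sol2 = least_squares(
        degradation_residuals,
        [math.log(0.25), math.log(2e-3)],
        bounds=(
            [math.log(0.01), math.log(1e-6)],
            [math.log(5.0), math.log(0.05)],
        ),
        xtol=1e-10,
        ftol=1e-10,
        diff_step=0.05,
    )
    fitted = unpack(sol2.x)

    # validation pass
    errors = {}
    increases = {}
    for t in targets:
        f1, f2 = simulate_force_at_energy(fitted, t.n_layers, config, repetitions=2)
        errors[t.n_layers] = abs(f1 - t.force_at_30j) / t.force_at_30j
        increases[t.n_layers] = f2 / f1 - 1.0
    bad = {
        n: e
        for n, e in errors.items()
        if n in _FIT_FORCE_LAYERS and e > tolerance
    }
    if bad:
        raise CalibrationError(
            f"first-strike force errors exceed {tolerance:.0%}: {bad}; "
            "the optimizer bounds likely need widening"
        )
    if full_output:
        return fitted, {
            "force_errors": errors,
            "rel_increase_rep2": increases,
            "cost": float(sol1.cost + sol2.cost),
            "nfev": int(sol1.nfev + sol2.nfev),
        }
    return fitted
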