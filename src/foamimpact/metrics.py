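"""Energy accounting on segmented displacement-force curves.

Absorbed energy E is the area under the loading curve, elastic energy E_E
the area under the unloading curve (returned to the impactor as rebound),
and plastic energy E_P = E - E_E is dissipated in permanent deformation.
All integrals use the trapezoidal rule on the sampled curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .design import StudyConfig, TestCondition
from .traces import SegmentedCurve

__all__ = [
    "EnergyProfile",
    "absorbed_energy",
    "elastic_energy",
    "plastic_energy",
    "energy_at_force_threshold",
    "force_at_energy",
    "energy_profile",
    "ThresholdNotReached",
    "EnergyNotReached",
]

_EP_TOL = 1e-6  # J; |negative| plastic energy beyond this flags a fault


class ThresholdNotReached(ValueError):
    """The loading curve never reaches the requested force threshold."""


class EnergyNotReached(ValueError):
    """The loading curve never absorbs the requested energy."""


def _monotone_loading(
    displacement: np.ndarray, force: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce the loading curve to a strictly increasing displacement path.

    Sensor noise can produce ties and small backtracks in the compression
    signal; samples not advancing beyond the running maximum are dropped
    (keep-first) so that the cumulative-energy function is invertible.
    """
    displacement = np.asarray(displacement, dtype=float)
    force = np.asarray(force, dtype=float)
    if len(displacement) < 2:
        raise ValueError("loading curve needs at least 2 points")
    keep = np.empty(len(displacement), dtype=bool)
    keep[0] = True
    running = displacement[0]
    for i in range(1, len(displacement)):
        if displacement[i] > running:
            keep[i] = True
            running = displacement[i]
        else:
            keep[i] = False
    d, f = displacement[keep], force[keep]
    if len(d) < 2:
        raise ValueError("degenerate loading curve: displacement never advances")
    return d, f


def absorbed_energy(
    displacement: np.ndarray, force: np.ndarray
) -> tuple[float, Callable[[np.ndarray], np.ndarray]]:
    """Total absorbed energy E (J) and the cumulative-energy function.

    Returns ``(E, cumulative)`` where ``cumulative(x)`` evaluates the energy
    absorbed up to compression ``x`` by linear interpolation along the
    loading path.
    """
    d, f = _monotone_loading(displacement, force)
    cum = np.concatenate([[0.0], cumulative_trapezoid(f, d)])

    def cumulative(x):
        return np.interp(x, d, cum)

    return float(cum[-1]), cumulative


def elastic_energy(displacement: np.ndarray, force: np.ndarray) -> float:
    """Energy returned during unloading (J); empty unloading yields 0."""
    displacement = np.asarray(displacement, dtype=float)
    force = np.asarray(force, dtype=float)
    if len(displacement) < 2:
        return 0.0
    return float(abs(np.trapezoid(force, displacement)))


def plastic_energy(E: float, E_E: float, tol: float = _EP_TOL) -> float:
    """E_P = E - E_E, clipping integration slivers within ``tol`` to zero."""
    if E < 0 or E_E < 0:
        raise ValueError("energies must be >= 0")
    ep = E - E_E
    if ep < -tol:
        raise ValueError(
            f"elastic energy exceeds absorbed energy by {-ep:.3g} J: "
            "segmentation or integration fault"
        )
    return max(ep, 0.0)


def energy_at_force_threshold(
    displacement: np.ndarray, force: np.ndarray, threshold: float
) -> float:
    """Energy absorbed when the loading force first reaches ``threshold``."""
    d, f = _monotone_loading(displacement, force)
    cum = np.concatenate([[0.0], cumulative_trapezoid(f, d)])
    idx = np.nonzero(f >= threshold)[0]
    if len(idx) == 0:
        raise ThresholdNotReached(
            f"loading peaks at {f.max():.1f} N, below threshold {threshold:.1f} N"
        )
    i = int(idx[0])
    if i == 0:
        return 0.0
    # linear interpolation of the crossing between samples i-1 and i
    frac = (threshold - f[i - 1]) / (f[i] - f[i - 1])
    x_star = d[i - 1] + frac * (d[i] - d[i - 1])
    return float(cum[i - 1] + 0.5 * (f[i - 1] + threshold) * (x_star - d[i - 1]))


def force_at_energy(
    displacement: np.ndarray, force: np.ndarray, target_energy: float
) -> float:
    """Loading force (N) at the compression where ``target_energy`` J is absorbed."""
    if target_energy < 0:
        raise ValueError("target_energy must be >= 0")
    d, f = _monotone_loading(displacement, force)
    cum = np.concatenate([[0.0], cumulative_trapezoid(f, d)])
    if target_energy > cum[-1] * (1.0 + 1e-9) + 1e-12:
        raise EnergyNotReached(
            f"curve absorbs {cum[-1]:.2f} J, below target {target_energy:.2f} J"
        )
    target_energy = min(target_energy, cum[-1])
    # cumulative energy is non-decreasing in displacement: invert, then read force
    x_star = np.interp(target_energy, cum, d)
    return float(np.interp(x_star, d, f))


@dataclass(frozen=True)
class EnergyProfile:
    """Energy decomposition of one test."""

    total_energy: float  # E, J
    elastic_energy: float  # E_E, J
    plastic_energy: float  # E_P, J
    cumulative_energy: Callable[[np.ndarray], np.ndarray]
    condition: Optional[TestCondition] = None


def energy_profile(curve: SegmentedCurve) -> EnergyProfile:
    """Full energy decomposition of a segmented curve."""
    E, cumulative = absorbed_energy(curve.loading_displacement, curve.loading_force)
    E_E = elastic_energy(curve.unloading_displacement, curve.unloading_force)
    E_P = plastic_energy(E, E_E, tol=max(_EP_TOL, 0.005 * E))
    return EnergyProfile(
        total_energy=E,
        elastic_energy=E_E,
        plastic_energy=E_P,
        cumulative_energy=cumulative,
        condition=curve.peak.condition,
    )


def reference_energy(energies: np.ndarray | list[float]) -> int:
    """Reference energy E_ref: mean over the reference tests, rounded to 1 J.

    The reference tests are the first strikes on fresh single-layer
    specimens from the highest drop height; ``energies`` are their absorbed
    energies at the force-threshold crossing.
    """
    energies = np.asarray(energies, dtype=float)
    if len(energies) == 0:
        raise ValueError("no reference tests supplied")
    return int(round(float(energies.mean())))
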