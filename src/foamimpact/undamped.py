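"""Undamped-force estimation and per-layer transfer functions.

For each impact condition (drop height, repetition) the peak forces of all
layer stacks are plotted against their peak compressions and fitted with
``F(x) = a * exp(b*x)``.  Extrapolating to zero compression, ``F(0) = a``,
estimates the force the load cell would have registered with no protective
specimen at all — the *undamped force*.  Pairing each measured peak with its
condition's undamped force and regressing through the origin, one slope per
layer count, gives the transfer function ``undamped = k * measured``: the
factor by which a force measured through k layers of foam must be multiplied
to recover the bare-impact force.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .traces import PeakPoint

log = logging.getLogger(__name__)

__all__ = [
    "ExponentialFit",
    "TransferFunction",
    "fit_exponential",
    "undamped_force_table",
    "fit_transfer_function",
    "transfer_functions",
    "predict_undamped",
    "attenuation_ratio",
]


@dataclass(frozen=True)
class ExponentialFit:
    """Parameters of F(x) = a*exp(b*x) fitted to peak (x, F) points."""

    a: float  # N; the undamped force F(0)
    b: float  # 1/m; expected negative (thicker stacks compress further, measure less)
    n_points: int
    rss: float  # N^2
    group: Optional[tuple] = None

    def __call__(self, x):
        return self.a * np.exp(self.b * np.asarray(x))


@dataclass(frozen=True)
class TransferFunction:
    """Zero-intercept linear relation undamped = slope * measured."""

    slope: float
    r_squared: float
    ci95: tuple[float, float]
    n_points: int
    n_layers: Optional[int] = None


def _exp_model(x, a, b):
    return a * np.exp(b * x)


def fit_exponential(
    displacements: Sequence[float] | Sequence[PeakPoint],
    forces: Optional[Sequence[float]] = None,
    group: Optional[tuple] = None,
) -> ExponentialFit:
    """Nonlinear least squares of F = a*exp(b*x) on peak points.

    Accepts either two arrays ``(displacements, forces)`` or a single
    sequence of :class:`PeakPoint`.  Starting values come from the
    log-linear regression of ln F on x; ``b`` is unconstrained in sign.
    """
    if forces is None:
        pts = list(displacements)
        x = np.array([p.peak_displacement for p in pts], dtype=float)
        f = np.array([p.peak_force for p in pts], dtype=float)
    else:
        x = np.asarray(displacements, dtype=float)
        f = np.asarray(forces, dtype=float)
    if len(x) != len(f):
        raise ValueError("displacements and forces lengths differ")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    if np.any(f <= 0):
        raise ValueError("forces must be strictly positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all displacements identical")

    if np.ptp(f) == 0:  # constant-force limit: b = 0 exactly
        return ExponentialFit(a=float(f[0]), b=0.0, n_points=len(x), rss=0.0, group=group)

    slope, intercept = np.polyfit(x, np.log(f), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    with warnings.catch_warnings():
        # exact interpolation (n == 2) leaves the covariance undefined
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(_exp_model, x, f, p0=p0, maxfev=20000)
    a, b = float(popt[0]), float(popt[1])
    rss = float(np.sum((f - _exp_model(x, a, b)) ** 2))
    if a <= 0:
        raise ValueError("fit produced non-positive undamped force")
    return ExponentialFit(a=a, b=b, n_points=len(x), rss=rss, group=group)


def undamped_force_table(
    peaks: Iterable[PeakPoint],
    per_layer: bool = False,
) -> pd.DataFrame:
    """One exponential fit per (drop height, repetition) group.

    Peak points of *all* layer counts and specimens at a given height and
    repetition are pooled, so the fit spans the full compression range and
    its zero-compression intercept is one undamped force per impact
    condition.  Groups with fewer than 2 distinct layer counts are skipped
    with a warning.  ``per_layer=True`` instead fits within each
    (height, repetition, layer) cell, where extrapolation rests on
    specimen scatter only; it is provided for sensitivity checks, not as
    the default reading.

    Returns columns: drop_height, repetition[, n_layers], a, b, n_points.
    """
    rows = []
    peaks = list(peaks)
    for p in peaks:
        if p.condition is None:
            raise ValueError("peak points must carry their TestCondition")
    keyfn = (
        (lambda c: (c.drop_height, c.repetition, c.n_layers))
        if per_layer
        else (lambda c: (c.drop_height, c.repetition))
    )
    groups: dict[tuple, list[PeakPoint]] = {}
    for p in peaks:
        groups.setdefault(keyfn(p.condition), []).append(p)
    for key in sorted(groups):
        pts = groups[key]
        n_layer_kinds = len({p.condition.n_layers for p in pts})
        if not per_layer and n_layer_kinds < 2:
            log.warning(
                "group %s has %d layer condition(s); skipping undamped fit",
                key,
                n_layer_kinds,
            )
            continue
        if len(pts) < 2:
            log.warning("group %s has < 2 points; skipping undamped fit", key)
            continue
        fit = fit_exponential(pts, group=key)
        row = {"drop_height": key[0], "repetition": key[1]}
        if per_layer:
            row["n_layers"] = key[2]
        row.update({"a": fit.a, "b": fit.b, "n_points": fit.n_points})
        rows.append(row)
    return pd.DataFrame(rows)


def fit_transfer_function(
    measured: Sequence[float],
    undamped: Sequence[float],
    n_layers: Optional[int] = None,
) -> TransferFunction:
    """Zero-intercept least-squares line undamped = k * measured.

    ``k = sum(m*u)/sum(m^2)``; R^2 uses the uncentered total sum of squares
    (the standard convention for through-origin regression); the 95% CI is
    ``k +/- t(0.975, n-1) * SE(k)``.
    """
    m = np.asarray(measured, dtype=float)
    u = np.asarray(undamped, dtype=float)
    if len(m) != len(u):
        raise ValueError("measured and undamped lengths differ")
    n = len(m)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(m <= 0) or np.any(u <= 0):
        raise ValueError("forces must be strictly positive")
    sxx = float(np.sum(m * m))
    k = float(np.sum(m * u)) / sxx
    resid = u - k * m
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(u**2))
    r2 = 1.0 - ss_res / ss_tot
    se = np.sqrt(ss_res / (n - 1) / sxx)
    tcrit = stats.t.ppf(0.975, n - 1)
    return TransferFunction(
        slope=k,
        r_squared=r2,
        ci95=(k - tcrit * se, k + tcrit * se),
        n_points=n,
        n_layers=n_layers,
    )


def transfer_functions(
    peaks: Iterable[PeakPoint],
    undamped_table: pd.DataFrame,
) -> dict[int, TransferFunction]:
    """Fit the per-layer transfer functions from specimen-level peaks.

    Every measured peak is paired with the undamped force of its
    (drop height, repetition) group; pairs are then split by layer count and
    fitted through the origin.
    """
    lookup = {
        (row.drop_height, row.repetition): row.a
        for row in undamped_table.itertuples()
    }
    pairs: dict[int, list[tuple[float, float]]] = {}
    for p in peaks:
        key = (p.condition.drop_height, p.condition.repetition)
        a = lookup.get(key)
        if a is None:
            continue  # group was skipped upstream
        pairs.setdefault(p.condition.n_layers, []).append((p.peak_force, a))
    out: dict[int, TransferFunction] = {}
    for n_layers in sorted(pairs):
        m, u = zip(*pairs[n_layers])
        out[n_layers] = fit_transfer_function(m, u, n_layers=n_layers)
    return out


def predict_undamped(measured_force: float, tf: TransferFunction | float) -> float:
    """Undamped force for a measured force, in the same unit (N or kN)."""
    if measured_force < 0:
        raise ValueError("measured force must be >= 0")
    slope = tf.slope if isinstance(tf, TransferFunction) else float(tf)
    return slope * measured_force


def attenuation_ratio(
    tf_multi: TransferFunction | float, tf_single: TransferFunction | float
) -> float:
    """How much more a multi-layer stack attenuates than a single layer."""
    k_multi = tf_multi.slope if isinstance(tf_multi, TransferFunction) else float(tf_multi)
    k_single = (
        tf_single.slope if isinstance(tf_single, TransferFunction) else float(tf_single)
    )
    if k_single <= 0 or k_multi <= 0:
        raise ValueError("slopes must be > 0")
    return k_multi / k_single
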