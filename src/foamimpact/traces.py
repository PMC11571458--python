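"""Raw-trace conditioning: channel averaging, contact windowing, segmentation.

The displacement-force record of a drop is reduced to its loading
(ascending, up to the force maximum) and unloading (descending) portions.
Points after the maximum whose compression exceeds the compression at peak
force — creep of the crushed material while the impactor dwells — are
discarded rather than folded into the unloading curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import TestCondition
from .simulator import ImpactTrace

log = logging.getLogger(__name__)

__all__ = [
    "PeakPoint",
    "SegmentedCurve",
    "WindowedTrace",
    "average_displacement",
    "extract_contact_window",
    "segment_curve",
    "process_trace",
    "NoContactError",
]

DEFAULT_FORCE_FLOOR = 20.0  # N, above the noise floor yet far below any signal
SUSTAIN_SAMPLES = 5  # consecutive samples above the floor = real contact


class NoContactError(ValueError):
    """The trace never shows a sustained force excursion above the floor."""


@dataclass(frozen=True)
class PeakPoint:
    """Peak force and the compression at which it occurred."""

    peak_force: float  # N
    peak_displacement: float  # m
    condition: Optional[TestCondition] = None

    def __post_init__(self) -> None:
        if self.peak_force <= 0:
            raise ValueError("peak_force must be > 0")
        if self.peak_displacement <= 0:
            raise ValueError("peak_displacement must be > 0")


@dataclass(frozen=True)
class WindowedTrace:
    """Contact window: baseline-corrected force vs re-zeroed displacement."""

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    baseline: float
    start_index: int
    stop_index: int  # exclusive, in original trace indexing


@dataclass(frozen=True)
class SegmentedCurve:
    loading_displacement: np.ndarray
    loading_force: np.ndarray
    unloading_displacement: np.ndarray
    unloading_force: np.ndarray
    peak: PeakPoint
    discarded_count: int

    @property
    def n_samples(self) -> int:
        return (
            len(self.loading_displacement)
            + len(self.unloading_displacement)
            + self.discarded_count
        )


def average_displacement(trace: ImpactTrace) -> np.ndarray:
    """Mean of the two laser channels, the working displacement signal."""
    a, b = np.asarray(trace.disp_a), np.asarray(trace.disp_b)
    if a.shape != b.shape:
        raise ValueError("displacement channels have different lengths")
    return 0.5 * (a + b)


def _contact_run(force: np.ndarray, floor: float, sustain: int) -> tuple[int, int]:
    """Find the sustained above-floor run containing the global force maximum.

    Returns (start, stop_exclusive).  Short noise bursts before contact are
    rejected because they do not contain the maximum.
    """
    above = force > floor
    if not above.any():
        raise NoContactError("force never exceeds the floor")
    i_max = int(np.argmax(force))
    if not above[i_max]:
        raise NoContactError("force maximum does not exceed the floor")
    # expand from the maximum to the run boundaries
    start = i_max
    while start > 0 and above[start - 1]:
        start -= 1
    stop = i_max + 1
    while stop < len(force) and above[stop]:
        stop += 1
    if stop - start < sustain:
        raise NoContactError(
            f"above-floor excursion shorter than {sustain} samples: noise spike"
        )
    return start, stop


def extract_contact_window(
    trace: ImpactTrace,
    force_floor: float = DEFAULT_FORCE_FLOOR,
    sustain: int = SUSTAIN_SAMPLES,
) -> WindowedTrace:
    """Trim a raw trace to compression-and-release of the specimen.

    The load-cell baseline is estimated as the median force before the
    contact run and subtracted; displacement is re-zeroed at the window
    start.  Samples from the first sustained crossing above ``force_floor``
    up to the last sample before the force falls back below it (after the
    maximum) are kept.
    """
    force = np.asarray(trace.force, dtype=float)
    disp = average_displacement(trace)
    start, stop = _contact_run(force, force_floor, sustain)
    baseline = float(np.median(force[:start])) if start > 0 else 0.0
    f_win = force[start:stop] - baseline
    np.clip(f_win, 0.0, None, out=f_win)
    d_win = disp[start:stop] - disp[start]
    return WindowedTrace(
        time=np.asarray(trace.time)[start:stop],
        displacement=d_win,
        force=f_win,
        baseline=baseline,
        start_index=start,
        stop_index=stop,
    )


def segment_curve(
    displacement: np.ndarray,
    force: np.ndarray,
    condition: Optional[TestCondition] = None,
) -> SegmentedCurve:
    """Split a windowed displacement-force curve at the force maximum.

    Loading runs from the first sample to the global maximum (inclusive).
    Of the remaining samples, those whose compression exceeds the peak
    compression are discarded; the rest form the unloading curve.
    """
    displacement = np.asarray(displacement, dtype=float)
    force = np.asarray(force, dtype=float)
    if len(displacement) != len(force):
        raise ValueError("displacement and force lengths differ")
    if len(force) == 0:
        raise ValueError("empty window")
    i_pk = int(np.argmax(force))
    if np.count_nonzero(force == force[i_pk]) > 1:
        log.warning("multiple samples share the global force maximum; using first")
    x_pk = displacement[i_pk]
    loading_d = displacement[: i_pk + 1]
    loading_f = force[: i_pk + 1]
    rest_d = displacement[i_pk + 1 :]
    rest_f = force[i_pk + 1 :]
    keep = rest_d <= x_pk
    peak = PeakPoint(
        peak_force=float(force[i_pk]),
        peak_displacement=float(x_pk),
        condition=condition,
    )
    return SegmentedCurve(
        loading_displacement=loading_d,
        loading_force=loading_f,
        unloading_displacement=rest_d[keep],
        unloading_force=rest_f[keep],
        peak=peak,
        discarded_count=int(np.count_nonzero(~keep)),
    )


def process_trace(
    trace: ImpactTrace,
    force_floor: float = DEFAULT_FORCE_FLOOR,
    sustain: int = SUSTAIN_SAMPLES,
) -> SegmentedCurve:
    """Window then segment a raw trace in one call."""
    win = extract_contact_window(trace, force_floor=force_floor, sustain=sustain)
    return segment_curve(win.displacement, win.force, condition=trace.condition)
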