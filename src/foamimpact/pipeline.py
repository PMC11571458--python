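"""End-to-end orchestration: simulate -> segment -> energies -> undamped ->
transfer functions -> repeated-loading statistics.

Every stage writes a plain CSV so that any stage can be re-run from its
predecessor's output alone; (config, seed) fully determines all results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .design import StudyConfig
from .metrics import (
    ThresholdNotReached,
    EnergyNotReached,
    absorbed_energy,
    elastic_energy,
    energy_at_force_threshold,
    force_at_energy,
    plastic_energy,
    reference_energy,
)
from .repeated import anova_frame, build_table1, table1_frame
from .simulator import FoamParams, generate_dataset
from .traces import process_trace
from .undamped import transfer_functions, undamped_force_table

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_full_study", "analyze_traces", "report_summary"]


@dataclass
class RunManifest:
    """Record of one full pipeline run."""

    config: dict
    seed: int
    version: str
    timestamp: str
    files: dict[str, str] = field(default_factory=dict)
    n_traces: int = 0
    e_ref_j: float = float("nan")
    transfer: dict[int, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "timestamp": self.timestamp,
                "files": self.files,
                "n_traces": self.n_traces,
                "e_ref_j": self.e_ref_j,
                "transfer": self.transfer,
            },
            indent=2,
        )


def _metrics_row(curve, profile, cond) -> dict:
    return {
        "drop_height_m": cond.drop_height,
        "n_layers": cond.n_layers,
        "specimen_id": cond.specimen_id,
        "repetition": cond.repetition,
        "peak_force_n": curve.peak.peak_force,
        "peak_disp_m": curve.peak.peak_displacement,
        "E_j": profile.total_energy,
        "EE_j": profile.elastic_energy,
        "EP_j": profile.plastic_energy,
    }


def analyze_traces(
    traces,
    config: StudyConfig,
) -> tuple[pd.DataFrame, list, float]:
    """Segment traces, compute per-test metrics and the reference energy.

    Returns ``(metrics, curves, e_ref)`` where ``metrics`` has one row per
    test including ``force_at_eref_n`` for tests that absorb at least E_ref.
    """
    curves = []
    rows = []
    for trace in traces:
        cond = trace.condition
        try:
            curve = process_trace(trace)
        except Exception as exc:
            raise RuntimeError(
                f"segmentation failed for {cond.specimen_id} rep {cond.repetition}: {exc}"
            ) from exc
        E, _ = absorbed_energy(curve.loading_displacement, curve.loading_force)
        EE = elastic_energy(curve.unloading_displacement, curve.unloading_force)
        EP = plastic_energy(E, EE, tol=max(1e-6, 0.005 * E))
        from .metrics import EnergyProfile

        profile = EnergyProfile(E, EE, EP, cumulative_energy=None, condition=cond)
        curves.append(curve)
        rows.append(_metrics_row(curve, profile, cond))
    metrics = pd.DataFrame(rows)

    # reference energy: first strike, single layer, highest drop height
    ref_mask = (
        (metrics["n_layers"] == min(config.layer_counts))
        & np.isclose(metrics["drop_height_m"], config.extra_drop_height)
        & (metrics["repetition"] == 1)
    )
    ref_energies = []
    for curve, is_ref in zip(curves, ref_mask):
        if not is_ref:
            continue
        try:
            ref_energies.append(
                energy_at_force_threshold(
                    curve.loading_displacement,
                    curve.loading_force,
                    config.force_threshold,
                )
            )
        except ThresholdNotReached:
            log.warning(
                "reference test %s never reaches %.0f N",
                curve.peak.condition,
                config.force_threshold,
            )
    e_ref = float(reference_energy(ref_energies)) if ref_energies else float("nan")

    # force at E_ref for every test that absorbs enough energy
    f_at_eref = []
    for curve in curves:
        try:
            f_at_eref.append(
                force_at_energy(
                    curve.loading_displacement, curve.loading_force, e_ref
                )
                if np.isfinite(e_ref)
                else np.nan
            )
        except EnergyNotReached:
            f_at_eref.append(np.nan)
    metrics["force_at_eref_n"] = f_at_eref
    return metrics, curves, e_ref


def run_full_study(
    config: Optional[StudyConfig] = None,
    params: Optional[FoamParams] = None,
    seed: int = 0,
    out_dir=None,
) -> tuple[RunManifest, dict]:
    """Run the complete study and return (manifest, results).

    ``results`` holds the in-memory tables: ``metrics``, ``undamped``,
    ``transfer`` (dict layer -> TransferFunction), ``table1``, ``anova``,
    ``e_ref`` and ``repeated`` (per-layer RepeatedLoadingResult).
    """
    config = config or StudyConfig()
    params = params or FoamParams()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "traces").mkdir(parents=True, exist_ok=True)

    traces, trace_manifest = generate_dataset(
        config, params, seed, out_dir=(out / "traces") if out else None
    )
    metrics, curves, e_ref = analyze_traces(traces, config)

    peaks = [c.peak for c in curves]
    undamped = undamped_force_table(peaks)
    tfs = transfer_functions(peaks, undamped)
    repeated = build_table1(metrics, e_ref, config)
    t1 = table1_frame(repeated)
    anova = anova_frame(repeated)

    tf_frame = pd.DataFrame(
        [
            {
                "n_layers": n,
                "slope": tf.slope,
                "r2": tf.r_squared,
                "ci_lo": tf.ci95[0],
                "ci_hi": tf.ci95[1],
                "n": tf.n_points,
            }
            for n, tf in sorted(tfs.items())
        ]
    )

    manifest = RunManifest(
        config=config.to_dict(),
        seed=seed,
        version=_pkg_version(),
        timestamp=datetime.now(timezone.utc).isoformat(),
        n_traces=len(traces),
        e_ref_j=e_ref,
        transfer={
            n: {"slope": tf.slope, "r2": tf.r_squared} for n, tf in tfs.items()
        },
    )

    results = {
        "metrics": metrics,
        "undamped": undamped,
        "transfer": tfs,
        "transfer_frame": tf_frame,
        "table1": t1,
        "anova": anova,
        "e_ref": e_ref,
        "repeated": repeated,
        "trace_manifest": trace_manifest,
    }

    if out is not None:
        files = {
            "metrics": "metrics.csv",
            "undamped": "undamped_forces.csv",
            "transfer": "transfer_functions.csv",
            "table1": "table1.csv",
            "anova": "anova.csv",
        }
        metrics.to_csv(out / files["metrics"], index=False)
        undamped.to_csv(out / files["undamped"], index=False)
        tf_frame.to_csv(out / files["transfer"], index=False)
        t1.to_csv(out / files["table1"], index=False)
        anova.to_csv(out / files["anova"], index=False)
        summary = report_summary(results)
        (out / "summary.txt").write_text(summary)
        files["summary"] = "summary.txt"
        manifest.files = files
        (out / "run_manifest.json").write_text(manifest.to_json())
    return manifest, results


def _pkg_version() -> str:
    from . import __version__

    return __version__


def report_summary(results: dict, predictions: Optional[list] = None) -> str:
    """Human-readable study report.

    ``predictions`` is an optional list of ``(label, measured_kN, n_layers)``
    whose undamped equivalents are appended using the fitted slopes.
    """
    required = {"transfer", "table1", "anova", "e_ref"}
    missing = required - set(results)
    if missing:
        raise ValueError(f"missing result tables: {sorted(missing)}")
    tfs = results["transfer"]
    lines = []
    lines.append("Falling-weight impact study summary")
    lines.append("===================================")
    lines.append(f"Reference energy E_ref: {results['e_ref']:.0f} J")
    lines.append("")
    lines.append("Transfer functions (undamped = slope x measured):")
    for n, tf in sorted(tfs.items()):
        lines.append(
            f"  {n} layer(s): slope {tf.slope:.1f} "
            f"(95% CI {tf.ci95[0]:.1f}-{tf.ci95[1]:.1f}), R^2 = {tf.r_squared:.3f}, "
            f"n = {tf.n_points}"
        )
    single = min(tfs)
    from .undamped import attenuation_ratio

    for n in sorted(tfs):
        if n == single:
            continue
        ratio = attenuation_ratio(tfs[n], tfs[single])
        lines.append(
            f"  {n} layers attenuate {ratio:.1f}x more than {single} layer(s)"
        )
    lines.append("")
    lines.append("Repeated loading (force at E_ref, mean +/- SD):")
    t1 = results["table1"]
    for _, row in t1.iterrows():
        inc = "" if row["increase_pct"] is None or pd.isna(row["increase_pct"]) else (
            f"  +{row['increase_pct']:.0f}%"
        )
        p = (
            ""
            if row["p_value"] is None or pd.isna(row["p_value"])
            else f"  p = {row['p_value']:.3f}"
        )
        lines.append(
            f"  layer {row['layer']}, rep {row['repetition']}: "
            f"{row['mean_n']:.0f} +/- {row['std_n']:.0f} N{inc}{p}"
        )
    lines.append("")
    lines.append("Repeated-measures ANOVA per layer:")
    for _, row in results["anova"].iterrows():
        lines.append(
            f"  layer {row['layer']}: F = {row['F']:.2f}, p = {row['p']:.4g}, "
            f"eta^2 = {row['eta_squared']:.3f}"
        )
    if predictions:
        from .undamped import predict_undamped

        lines.append("")
        lines.append("Undamped-force predictions:")
        for label, kn, n_layers in predictions:
            und = predict_undamped(kn, tfs[n_layers])
            lines.append(
                f"  {label}: measured {kn:.1f} kN through {n_layers} layer(s) "
                f"-> undamped {und:.1f} kN"
            )
    return "\n".join(lines) + "\n"
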