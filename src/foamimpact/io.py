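"""File formats: trace CSV, study-config YAML, result tables.

Trace CSV contract: header ``time_s,disp_a_m,disp_b_m,force_n``, one row per
sample, one file per test named ``{height_cm}cm_L{layers}_S{specimen}_R{rep}.csv``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyConfig, TestCondition
from .simulator import ImpactTrace

TRACE_COLUMNS = ["time_s", "disp_a_m", "disp_b_m", "force_n"]

__all__ = [
    "trace_filename",
    "write_trace_csv",
    "read_trace_csv",
    "load_config",
    "save_config",
    "TRACE_COLUMNS",
]


def trace_filename(condition: TestCondition) -> str:
    h_cm = round(condition.drop_height * 100)
    return (
        f"{h_cm}cm_L{condition.n_layers}_S{condition.specimen_id}"
        f"_R{condition.repetition}.csv"
    )


def write_trace_csv(trace: ImpactTrace, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "disp_a_m": trace.disp_a,
            "disp_b_m": trace.disp_b,
            "force_n": trace.force,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace_csv(path, condition: TestCondition | None = None) -> ImpactTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except OSError as exc:  # surface the offending path
        raise OSError(f"cannot read trace file {path}: {exc}") from exc
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
    if condition is None:
        condition = condition_from_filename(path.name)
    return ImpactTrace(
        time=df["time_s"].to_numpy(),
        disp_a=df["disp_a_m"].to_numpy(),
        disp_b=df["disp_b_m"].to_numpy(),
        force=df["force_n"].to_numpy(),
        condition=condition,
        truth=None,
    )


def condition_from_filename(name: str) -> TestCondition:
    """Recover the test condition from the canonical trace filename."""
    stem = Path(name).stem
    try:
        h_part, l_part, rest = stem.split("_", 2)
        sid, rep_part = rest[1:].rsplit("_R", 1)  # rest starts with 'S'
        return TestCondition(
            drop_height=float(h_part.removesuffix("cm")) / 100.0,
            n_layers=int(l_part.removeprefix("L")),
            specimen_id=sid,
            repetition=int(rep_part),
        )
    except (ValueError, IndexError) as exc:
        raise ValueError(f"cannot parse trace filename {name!r}") from exc


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return StudyConfig.from_dict(data)


def save_config(config: StudyConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path
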