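"""Readers, writers and cohort-level inclusion filtering.

On-disk formats are plain TSV throughout: ROI time series (header = ROI
names, one row per volume), BIDS-style events tables, 6-column motion
parameters, and a participants table.  Readers reorder/validate against the
parcellation scheme; writers round-trip losslessly at float precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EVENT_TYPES, MotionTrace, RoiTimeSeries, SubjectRecord, TaskEventTable
from .errors import ParseError, SchemaError, StateError
from .parcellation import ParcellationScheme

_FLOAT_FMT = "%.10g"


def read_timeseries(path, scheme: ParcellationScheme, subject: str = "",
                    condition: str = "rest", tr_seconds: float = 2.0) -> RoiTimeSeries:
    """Read a TSV time series and reorder columns to canonical ROI order."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    missing = [r for r in scheme.roi_names if r not in cols]
    extra = [c for c in cols if c not in set(scheme.roi_names)]
    if missing or extra:
        raise SchemaError(
            f"{path}: ROI columns do not match scheme "
            f"(missing {missing[:5]}, extra {extra[:5]})"
        )
    for col in cols:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
    data = df[list(scheme.roi_names)].to_numpy(dtype=float)
    return RoiTimeSeries(subject=subject, condition=condition, data=data, tr_seconds=tr_seconds)


def write_timeseries(ts: RoiTimeSeries, scheme: ParcellationScheme, path) -> None:
    pd.DataFrame(ts.data, columns=list(scheme.roi_names)).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_events(path) -> TaskEventTable:
    """Read a BIDS-dialect events.tsv (onset/duration/trial_type plus load,
    trial_id, correct, response_time) into a validated table."""
    df = pd.read_csv(path, sep="\t")
    if "trial_type" in df.columns:
        df = df.rename(columns={"trial_type": "event_type"})
    missing = set(TaskEventTable.REQUIRED) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: events table missing columns {sorted(missing)}")
    bad = set(df["event_type"].dropna()) - set(EVENT_TYPES)
    if bad:
        raise ParseError(f"{path}: unknown event types {sorted(bad)}")
    df["load"] = pd.to_numeric(df["load"], errors="coerce").astype("Float64")
    df["response_time"] = pd.to_numeric(df["response_time"], errors="coerce")
    # correct: accept 0/1, True/False, or empty (no response)
    df["correct"] = df["correct"].map(
        lambda v: None if (v is None or (isinstance(v, float) and math.isnan(v)) or v == "")
        else bool(int(v)) if str(v) in {"0", "1", "0.0", "1.0"}
        else str(v).lower() in {"true", "t", "yes"}
    )
    return TaskEventTable(df)


def write_events(table: TaskEventTable, path) -> None:
    out = table.events.copy()
    out = out.rename(columns={"event_type": "trial_type"})
    out["correct"] = out["correct"].map(lambda v: "" if v is None else int(bool(v)))
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, na_rep="n/a")


def read_motion(path) -> MotionTrace:
    arr = np.loadtxt(path, ndmin=2)
    return MotionTrace(params=arr)


def write_motion(trace: MotionTrace, path) -> None:
    np.savetxt(path, trace.params, fmt=_FLOAT_FMT, delimiter="\t")


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject", "age_group", "sex", "scanner"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: participants table needs columns {sorted(need)}")
    return df


def write_participants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Inclusion / QC filtering


@dataclass
class Exclusion:
    subject: str
    rule: str
    detail: str


#: QC bounds: strict accuracy inequality, inclusive motion bounds.
EASY_LOAD = 1
MIN_EASY_ACCURACY = 0.5  # exclusive: accuracy must exceed chance
MAX_ABS_DISPLACEMENT_MM = 4.0  # inclusive
MAX_FD_MM = 2.0  # inclusive


def apply_inclusion_filters(
    cohort: list[SubjectRecord],
) -> tuple[list[SubjectRecord], list[Exclusion]]:
    """Keep subjects performing above chance at the easy load whose every run
    stays within the motion bounds; log each exclusion with the violated rule.

    Rules are conjunctive, so the included set is order-independent.
    """
    included: list[SubjectRecord] = []
    log: list[Exclusion] = []
    for rec in cohort:
        if not rec.behavior:
            raise StateError(f"{rec.subject}: behavior not scored before filtering")
        if not rec.motion or any(m.mean_fd is None for m in rec.motion.values()):
            raise StateError(f"{rec.subject}: motion not summarized before filtering")
        reasons: list[Exclusion] = []
        easy = [b for b in rec.behavior if b.load == EASY_LOAD]
        if not easy:
            raise StateError(f"{rec.subject}: no easy-load behavior summary")
        if not easy[0].accuracy > MIN_EASY_ACCURACY:
            reasons.append(Exclusion(rec.subject, "easy_load_accuracy",
                                     f"accuracy {easy[0].accuracy:.3f} ≤ {MIN_EASY_ACCURACY}"))
        for run, trace in rec.motion.items():
            if trace.max_abs_displacement > MAX_ABS_DISPLACEMENT_MM:
                reasons.append(Exclusion(
                    rec.subject, "max_abs_displacement",
                    f"{run}: {trace.max_abs_displacement:.2f} mm > {MAX_ABS_DISPLACEMENT_MM}"))
            if np.max(trace.fd) > MAX_FD_MM:
                reasons.append(Exclusion(
                    rec.subject, "max_framewise_displacement",
                    f"{run}: {np.max(trace.fd):.2f} mm > {MAX_FD_MM}"))
        if reasons:
            log.extend(reasons)
        else:
            included.append(rec)
    return included, log
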