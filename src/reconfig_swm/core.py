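"""Domain containers shared across the pipeline.

All tabular payloads are pandas objects; matrices are numpy arrays.  The
containers validate their own invariants on construction so that malformed
inputs fail at the boundary rather than deep inside a stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError, StructureError
from .parcellation import ParcellationScheme

EVENT_TYPES = (
    "blank",
    "fixation",
    "encoding",
    "maintenance",
    "probe",
    "response",
    "inter_trial_blank",
    "baseline",
)

LOADS = (1, 3, 5)
CONDITIONS = ("rest", "task_run1", "task_run2")
TRIALS_PER_BLOCK = 10


@dataclass
class RoiTimeSeries:
    """One run's T×R matrix of BOLD-like values in canonical ROI order."""

    subject: str
    condition: str
    data: np.ndarray
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise DataError(
                f"{self.subject}/{self.condition}: time series must be T×R with T ≥ 2, "
                f"got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError(f"{self.subject}/{self.condition}: non-finite values in time series")
        if self.tr_seconds <= 0:
            raise DataError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RoiTimeSeries":
        return replace(self, data=data)


@dataclass
class TaskEventTable:
    """Events of one task run; onsets in seconds from the first retained volume.

    Columns: onset, duration, event_type, load, trial_id, correct,
    response_time.  ``load``, ``correct`` and ``response_time`` are nullable.
    """

    events: pd.DataFrame

    REQUIRED = ("onset", "duration", "event_type", "load", "trial_id", "correct", "response_time")

    def __post_init__(self) -> None:
        ev = self.events
        missing = set(self.REQUIRED) - set(ev.columns)
        if missing:
            raise SchemaError(f"event table missing columns {sorted(missing)}")
        bad = set(ev["event_type"]) - set(EVENT_TYPES)
        if bad:
            raise SchemaError(f"unknown event types {sorted(bad)}")
        if not ev["onset"].is_monotonic_increasing:
            raise StructureError("event onsets must be non-decreasing")
        self._validate_blocks(ev)

    @staticmethod
    def _validate_blocks(ev: pd.DataFrame) -> None:
        has_trial = ev["trial_id"].notna().to_numpy()
        tid = ev["trial_id"].to_numpy()[has_trial]
        load = ev["load"].to_numpy(dtype=float)[has_trial]
        etype = ev["event_type"].to_numpy()[has_trial]
        codes, uniq = pd.factorize(tid)
        first = np.unique(codes, return_index=True)[1]
        trial_loads, per_load = np.unique(load[first], return_counts=True)
        if set(trial_loads.astype(int)) != set(LOADS):
            raise StructureError(
                f"run must contain loads {set(LOADS)}, got {set(trial_loads.astype(int))}")
        if np.any(per_load != TRIALS_PER_BLOCK):
            bad = trial_loads[per_load != TRIALS_PER_BLOCK][0]
            n = per_load[per_load != TRIALS_PER_BLOCK][0]
            raise StructureError(
                f"load {int(bad)}: block has {n} trials, expected {TRIALS_PER_BLOCK}")
        for phase in ("encoding", "maintenance", "probe"):
            counts = np.bincount(codes[etype == phase], minlength=len(uniq))
            if np.any(counts != 1):
                off = uniq[np.flatnonzero(counts != 1)[0]]
                raise StructureError(
                    f"trial {off}: expected exactly one {phase} event, got "
                    f"{counts[counts != 1][0]}")

    def block_interval(self, load: int) -> tuple[float, float]:
        """[start, end] of the load's block: first trial onset to the end of
        the last trial's probe window (within-block inter-trial blanks are
        inside this interval; inter-block baselines are not)."""
        ev = self.events
        mask = (ev["load"].to_numpy(dtype=float) == load) & ev["trial_id"].notna().to_numpy()
        if not mask.any():
            raise StructureError(f"load {load} absent from run")
        onset = ev["onset"].to_numpy(dtype=float)
        start = float(onset[mask].min())
        probes = mask & (ev["event_type"].to_numpy() == "probe")
        end = float((onset[probes] + ev["duration"].to_numpy(dtype=float)[probes]).max())
        return start, end

    def trial_outcomes(self) -> pd.DataFrame:
        """One row per trial: load, correct, response_time."""
        ev = self.events
        trials = ev[ev["trial_id"].notna() & (ev["event_type"] == "probe")]
        return trials[["trial_id", "load", "correct", "response_time"]].reset_index(drop=True)


@dataclass
class MotionTrace:
    """Six rigid-body parameters per volume plus derived FD summaries.

    ``params`` columns: 3 translations (mm) then 3 rotations (radians).
    ``fd`` is the framewise displacement series (length T−1), filled in by
    the conditioning stage.
    """

    params: np.ndarray
    fd: Optional[np.ndarray] = None
    mean_fd: Optional[float] = None
    max_abs_displacement: Optional[float] = None

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise SchemaError(f"motion parameters must be T×6, got {self.params.shape}")
        if self.fd is not None and len(self.fd) != len(self.params) - 1:
            raise SchemaError("FD series length must be T − 1")


@dataclass
class BehaviorSummary:
    subject: str
    load: int
    n_trials: int
    accuracy: float
    mean_rt_correct: Optional[float]


@dataclass
class SubjectRecord:
    """Everything the pipeline holds for one subject."""

    subject: str
    age_group: str  # young | old
    sex: str  # M | F
    scanner: str  # pre | post
    age: Optional[float] = None
    rest: Optional[RoiTimeSeries] = None
    task_runs: list[RoiTimeSeries] = field(default_factory=list)
    events: list[TaskEventTable] = field(default_factory=list)
    motion: dict[str, MotionTrace] = field(default_factory=dict)
    behavior: list[BehaviorSummary] = field(default_factory=list)
    truth: Optional[pd.DataFrame] = None  # synthetic ground truth (λ per load)

    def validate_complete(self) -> None:
        if self.rest is None or len(self.task_runs) != 2 or len(self.events) != 2:
            raise StructureError(
                f"{self.subject}: expected one rest run and two task runs with events"
            )
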