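"""Fisher-z functional connectivity matrices per condition."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LOADS, RoiTimeSeries, SubjectRecord, TaskEventTable
from .errors import DataError, StateError
from .parcellation import ParcellationScheme

#: Correlations are clipped to |r| ≤ 1 − CLIP_EPS before atanh so that
#: degenerate fixtures stay finite; realistic r is untouched.
CLIP_EPS = 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    return np.arctanh(np.clip(r, -1 + CLIP_EPS, 1 - CLIP_EPS))


@dataclass
class FCMatrix:
    """R×R symmetric Fisher-z connectivity for one condition.

    The diagonal is stored as 0 but is undefined; downstream edge sets
    exclude it by construction, never by inspecting values.
    """

    values: np.ndarray
    condition: str
    n_timepoints: int
    scheme: ParcellationScheme

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError(f"FC matrix must be square, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise DataError(f"{self.condition}: non-finite FC values")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise DataError(f"{self.condition}: FC matrix not symmetric")
        self.values = v


def compute_fc(ts: RoiTimeSeries, scheme: ParcellationScheme, condition: str) -> FCMatrix:
    """Pairwise Pearson r over time, clipped and Fisher r-to-z transformed."""
    if ts.n_volumes < 3:
        raise DataError(f"{condition}: need ≥3 timepoints for FC, got {ts.n_volumes}")
    sd = ts.data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [scheme.roi_names[i] for i in dead[:5]]
        raise DataError(f"{condition}: zero-variance ROI(s) {names}")
    r = np.corrcoef(ts.data, rowvar=False)
    z = fisher_z(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float noise
    return FCMatrix(z, condition, ts.n_volumes, scheme)


def fc_per_condition(subject: SubjectRecord, scheme: ParcellationScheme,
                     conditioned_rest: RoiTimeSeries,
                     task_residuals: list[RoiTimeSeries],
                     task_events: list[TaskEventTable],
                     within_load: bool = False) -> dict[str, FCMatrix]:
    """Rest FC plus load-specific task FC (cross-run concatenated blocks);
    optionally the six per-run-per-load matrices for within-load validation."""
    from .conditioning import extract_load_blocks

    if conditioned_rest is None or not task_residuals:
        raise StateError(f"{subject.subject}: conditioned time series unavailable")
    out: dict[str, FCMatrix] = {
        "rest": compute_fc(conditioned_rest, scheme, "rest")
    }
    for load in LOADS:
        blocks = extract_load_blocks(task_residuals, task_events, load)
        out[f"dot{load}"] = compute_fc(blocks, scheme, f"dot{load}")
    if within_load:
        for load in LOADS:
            for run_idx in (0, 1):
                label = f"dot{load}_run{run_idx + 1}"
                seg = extract_load_blocks(
                    [task_residuals[run_idx]], [task_events[run_idx]], load
                )
                out[label] = compute_fc(seg, scheme, label)
    return out


def fc_to_frame(fc: FCMatrix) -> pd.DataFrame:
    return pd.DataFrame(fc.values, index=list(fc.scheme.roi_names),
                        columns=list(fc.scheme.roi_names))
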