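"""Task performance scoring: accuracy and mean correct-trial RT per load."""

from __future__ import annotations

import logging

import pandas as pd

from .core import LOADS, BehaviorSummary, TaskEventTable
from .errors import StateError

log = logging.getLogger(__name__)


def score_behavior(subject: str, event_tables: list[TaskEventTable]) -> list[BehaviorSummary]:
    """Pool trials across the two runs; accuracy = n_correct / n_trials,
    RT averaged over correct trials only.  No-response trials (correct is
    missing) count as incorrect and contribute no RT."""
    if len(event_tables) != 2:
        raise StateError(f"{subject}: need both runs' event tables, got {len(event_tables)}")
    trials = pd.concat([t.trial_outcomes() for t in event_tables], ignore_index=True)
    out: list[BehaviorSummary] = []
    for load in LOADS:
        grp = trials[trials["load"] == load]
        n = len(grp)
        missing = grp["correct"].isna()
        if missing.any():
            log.info("%s load %d: %d no-response trial(s) scored incorrect",
                     subject, load, int(missing.sum()))
        correct_mask = grp["correct"].map(lambda v: bool(v) if pd.notna(v) else False)
        n_correct = int(correct_mask.sum())
        rts = grp.loc[correct_mask, "response_time"].dropna()
        out.append(BehaviorSummary(
            subject=subject, load=int(load), n_trials=n,
            accuracy=n_correct / n if n else float("nan"),
            mean_rt_correct=float(rts.mean()) if len(rts) else None,
        ))
    return out


def behavior_frame(summaries: list[BehaviorSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in summaries])
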