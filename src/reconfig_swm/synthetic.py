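"""Synthetic two-group cohort generator.

Emulates the statistical structure the analysis assumes, without any real
data: block-structured resting covariance with group-dependent network
segregation (young more segregated than old), load-dependent rest-to-task
reconfiguration (a mixing weight λ per group × load, larger for old and
non-decreasing in load), task-evoked activation, polynomial drift and an
FD-locked motion artifact, and behavior whose accuracy is coupled to
reconfiguration efficiency through the same λ.

Design dimensions follow the study conditions: one 235-volume rest run at
TR 2 s, two task runs of roughly 170 volumes each, one 10-trial block per
load (1/3/5 dots) per run, 5 lead-in volumes that conditioning trims.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LOADS, MotionTrace, RoiTimeSeries, SubjectRecord, TaskEventTable
from .errors import ParameterError
from .parcellation import ParcellationScheme, make_scheme, reduced_scheme


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortSpec:
    """All generator knobs; defaults are the cohort conditions used throughout."""

    n_young: int = 40
    n_old: int = 40
    n_rois: int = 430
    scheme: ParcellationScheme | None = None
    # network segregation: within- and between-network correlations per group
    w_g: dict = field(default_factory=lambda: {"young": 0.35, "old": 0.25})
    b_g: dict = field(default_factory=lambda: {"young": 0.05, "old": 0.12})
    # reconfiguration mixing weight per group × load (non-decreasing in load,
    # old ≥ young at every load)
    lambda_g: dict = field(default_factory=lambda: {
        "young": (0.10, 0.15, 0.20), "old": (0.25, 0.32, 0.40)})
    # subject-level SD of the λ offset; sized so the planted similarity–
    # accuracy coupling has the partial-correlation magnitude (~0.3)
    # reported for such brain–behavior associations
    tau: float = 0.12
    # acquisition / design timing (seconds)
    tr_seconds: float = 2.0
    rest_volumes: int = 235
    lead_in_volumes: int = 5
    blank_s: float = 1.0
    fixation_s: float = 0.5
    encoding_per_dot_s: float = 0.5
    maintenance_s: float = 3.0
    probe_s: float = 2.0
    jitter_range_s: tuple[float, float] = (2.5, 4.5)
    baseline_s: float = 4.0
    trials_per_block: int = 10
    # signal components
    activation_gain: float = 1.0
    drift_sd: float = 0.5
    motion_artifact_gain: float = 0.3
    motion_mu_g: dict = field(default_factory=lambda: {"young": 0.05, "old": 0.07})
    motion_sigma_g: dict = field(default_factory=lambda: {"young": 0.02, "old": 0.03})
    # behavior coupling: p(correct) = logistic(a0 − a1·λ − load_pen − group_pen + ε)
    a0: float = 3.0
    a1: float = 4.0
    load_penalty: tuple[float, float, float] = (0.0, 0.7, 1.4)
    group_penalty: dict = field(default_factory=lambda: {"young": 0.0, "old": 0.5})
    behavior_noise_sd: float = 0.5
    rt_base_s: float = 0.7
    rt_load_s: float = 0.08
    rt_lambda_s: float = 0.3
    rt_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for g in ("young", "old"):
            lams = self.lambda_g[g]
            if any(not 0 <= l <= 1 for l in lams):
                raise ParameterError(f"lambdas for {g} must lie in [0, 1]: {lams}")
            if any(lams[i] > lams[i + 1] for i in range(len(lams) - 1)):
                raise ParameterError(f"lambdas for {g} must be non-decreasing: {lams}")
            for v in (self.w_g[g], self.b_g[g]):
                if not -1 < v < 1:
                    raise ParameterError(f"correlation {v} outside (−1, 1)")
        if any(lo > yo for lo, yo in
               zip(self.lambda_g["young"], self.lambda_g["old"])):
            raise ParameterError("lambda_old must be ≥ lambda_young at every load")
        if self.scheme is None:
            self.scheme = (make_scheme() if self.n_rois == 430
                           else reduced_scheme(self.n_rois))
        if self.scheme.n_rois != self.n_rois:
            raise ParameterError(
                f"scheme has {self.scheme.n_rois} ROIs, spec says {self.n_rois}")


def build_network_covariance(scheme: ParcellationScheme, w: float, b: float) -> np.ndarray:
    """Unit-diagonal block covariance: w for same-network pairs, b otherwise."""
    if not (-1 < w < 1 and -1 < b < 1):
        raise ParameterError(f"correlations (w={w}, b={b}) must lie in (−1, 1)")
    nets = np.asarray(scheme.networks)
    same = nets[:, None] == nets[None, :]
    cov = np.where(same, w, b)
    np.fill_diagonal(cov, 1.0)
    if np.linalg.eigvalsh(cov)[0] <= 0:
        raise ParameterError(f"(w={w}, b={b}) yields a non-positive-definite covariance")
    return cov


def alt_covariance(cov_rest: np.ndarray, scheme: ParcellationScheme,
                   seed: int) -> np.ndarray:
    """A genuinely different topology with the same spectrum: the rest
    covariance conjugated by a fixed, seeded ROI permutation (equivalently,
    a permutation of network labels)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(scheme.n_rois)
    return cov_rest[np.ix_(perm, perm)]


def subject_condition_covariance(cov_rest: np.ndarray, cov_alt: np.ndarray,
                                 lam: float) -> np.ndarray:
    """Σ_task = (1−λ)·Σ_rest + λ·Σ_alt; λ=0 returns Σ_rest exactly."""
    if not 0 <= lam <= 1:
        raise ParameterError(f"lambda {lam} outside [0, 1]")
    if lam == 0:
        return cov_rest
    if lam == 1:
        return cov_alt
    return (1.0 - lam) * cov_rest + lam * cov_alt


# ---------------------------------------------------------------------------
# Event/run construction


def _build_run_events(loads_order, outcomes: pd.DataFrame, spec: CohortSpec,
                      rng: np.random.Generator) -> TaskEventTable:
    """One run's events: 3 blocks (one load each) of 10 trials, separated by
    4 s baselines.  ``outcomes`` has columns load, trial_index, correct, rt."""
    rows = []
    t = 0.0
    trial_counter = 0
    for b_idx, load in enumerate(loads_order):
        block_outcomes = outcomes[outcomes["load"] == load].reset_index(drop=True)
        for k in range(spec.trials_per_block):
            tid = f"t{trial_counter:03d}"
            trial_counter += 1
            correct = bool(block_outcomes.loc[k, "correct"])
            rt = float(block_outcomes.loc[k, "rt"])
            phases = [
                ("blank", spec.blank_s),
                ("fixation", spec.fixation_s),
                ("encoding", spec.encoding_per_dot_s * load),
                ("maintenance", spec.maintenance_s),
                ("probe", spec.probe_s),
            ]
            for etype, dur in phases:
                rows.append({"onset": t, "duration": dur, "event_type": etype,
                             "load": load, "trial_id": tid,
                             "correct": correct, "response_time": rt})
                if etype == "probe":
                    rows.append({"onset": t + min(rt, dur), "duration": 0.2,
                                 "event_type": "response", "load": load,
                                 "trial_id": tid, "correct": correct,
                                 "response_time": rt})
                t += dur
            if k < spec.trials_per_block - 1:
                jit = float(rng.uniform(*spec.jitter_range_s))
                rows.append({"onset": t, "duration": jit,
                             "event_type": "inter_trial_blank", "load": load,
                             "trial_id": tid, "correct": correct,
                             "response_time": rt})
                t += jit
        if b_idx < len(loads_order) - 1:
            rows.append({"onset": t, "duration": spec.baseline_s,
                         "event_type": "baseline", "load": None,
                         "trial_id": None, "correct": None, "response_time": None})
            t += spec.baseline_s
    df = pd.DataFrame(rows)
    df["load"] = df["load"].astype("Float64")
    return TaskEventTable(df)


def simulate_behavior(spec: CohortSpec, group: str, lam_by_load: dict[int, float],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Per-trial outcomes for one subject: 20 trials per load across 2 runs.

    Accuracy couples negatively to λ (more reconfiguration → worse), with
    load and group penalties and a per-subject logit noise term; RTs are
    lognormal, increasing in load and λ, drawn for every trial (all trials
    are responded; correctness decides whether the RT enters scoring).
    """
    eps = rng.normal(0.0, spec.behavior_noise_sd)
    rows = []
    for li, load in enumerate(LOADS):
        lam = lam_by_load[load]
        p = _logistic(spec.a0 - spec.a1 * lam - spec.load_penalty[li]
                      - spec.group_penalty[group] + eps)
        n = 2 * spec.trials_per_block
        correct = rng.random(n) < p
        mu = np.log(spec.rt_base_s + spec.rt_load_s * li + spec.rt_lambda_s * lam)
        rt = np.exp(rng.normal(mu, spec.rt_sigma, size=n))
        for k in range(n):
            rows.append({"load": load, "trial_index": k, "run": k // spec.trials_per_block,
                         "correct": bool(correct[k]), "rt": float(rt[k]),
                         "p_correct": float(p), "lambda": float(lam)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-series synthesis


def _simulate_motion(n_volumes: int, mu: float, rng: np.random.Generator) -> MotionTrace:
    """Random-walk rigid-body parameters whose mean FD is ≈ mu."""
    step_t = mu / 4.8  # 3 translation + radius-scaled rotation terms, E|N| = σ√(2/π)
    steps = np.column_stack([
        rng.normal(0.0, step_t, size=(n_volumes - 1, 3)),
        rng.normal(0.0, step_t / 50.0, size=(n_volumes - 1, 3)),
    ])
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(params=params)


def _structured_noise(n_volumes: int, scheme: ParcellationScheme, spec: CohortSpec,
                      motion: MotionTrace, artifact_loading: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Polynomial drift plus a rank-one FD-locked motion artifact.

    The artifact's spatial loading is fixed per subject (motion corrupts the
    same regions in every run); drift coefficients are drawn per run.
    """
    R = scheme.n_rois
    t = np.linspace(-1, 1, n_volumes)
    basis = np.column_stack([t, t**2])
    drift = basis @ rng.normal(0.0, spec.drift_sd, size=(2, R))
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + 50.0 * np.abs(d[:, 3:]).sum(axis=1)
    fd_series = np.concatenate([[0.0], fd])
    fd_series = fd_series - fd_series.mean()
    artifact = spec.motion_artifact_gain * np.outer(
        fd_series / (fd_series.std() + 1e-12), artifact_loading)
    return drift + artifact


def _sample_segments(assign: np.ndarray, chols: dict[int, np.ndarray],
                     rng: np.random.Generator) -> np.ndarray:
    """Sample each volume from the covariance its segment key maps to."""
    T = len(assign)
    R = next(iter(chols.values())).shape[0]
    Z = rng.standard_normal((T, R))
    X = np.empty((T, R))
    for key, L in chols.items():
        idx = np.flatnonzero(assign == key)
        if idx.size:
            X[idx] = Z[idx] @ L.T
    return X


def simulate_subject(spec: CohortSpec, subject: str, group: str, sex: str,
                     scanner: str, age: float, cov_rest: np.ndarray,
                     cov_alt: np.ndarray, rng: np.random.Generator) -> SubjectRecord:
    """One subject: rest run, two task runs with events/motion, ground truth."""
    scheme = spec.scheme
    R = scheme.n_rois
    tr = spec.tr_seconds
    delta = rng.normal(0.0, spec.tau)
    lam_by_load = {
        load: float(np.clip(spec.lambda_g[group][li] + delta, 0.0, 1.0))
        for li, load in enumerate(LOADS)
    }
    artifact_loading = rng.normal(0.0, 1.0, size=R)
    # per-subject motion level: within-group spread with overlapping
    # group distributions, as real cohorts show
    motion_mu = float(max(0.01, rng.normal(spec.motion_mu_g[group],
                                           spec.motion_sigma_g[group])))
    chol_rest = np.linalg.cholesky(cov_rest)
    chol_task = {
        load: np.linalg.cholesky(
            subject_condition_covariance(cov_rest, cov_alt, lam_by_load[load]))
        for load in LOADS
    }

    # ---- rest run: lead-in + 235 volumes from Σ_rest
    T_rest = spec.lead_in_volumes + spec.rest_volumes
    motion_rest = _simulate_motion(T_rest, motion_mu, rng)
    rest = _sample_segments(np.zeros(T_rest, dtype=int), {0: chol_rest}, rng)
    rest += _structured_noise(T_rest, scheme, spec, motion_rest, artifact_loading, rng)
    rest_ts = RoiTimeSeries(subject, "rest", rest, tr)

    # ---- behavior, then the two task runs embedding the outcomes
    outcomes = simulate_behavior(spec, group, lam_by_load, rng)
    task_runs: list[RoiTimeSeries] = []
    events_list: list[TaskEventTable] = []
    motion: dict[str, MotionTrace] = {"rest": motion_rest}
    from .conditioning import SignalConfig, build_task_regressors

    sig = SignalConfig(volumes_to_trim=spec.lead_in_volumes)
    for run_idx in (0, 1):
        loads_order = list(rng.permutation(LOADS))
        run_out = outcomes[outcomes["run"] == run_idx]
        events = _build_run_events(loads_order, run_out, spec, rng)
        run_end = float((events.events["onset"] + events.events["duration"]).max())
        T_task = int(np.ceil((run_end + spec.baseline_s) / tr))
        T_total = spec.lead_in_volumes + T_task
        # segment assignment on the retained timeline; lead-in counts as rest
        assign = np.zeros(T_total, dtype=int)
        mid = (np.arange(T_task) + 0.5) * tr
        for load in LOADS:
            start, end = events.block_interval(load)
            assign[spec.lead_in_volumes:][(mid >= start) & (mid <= end)] = load
        chols = {0: chol_rest, **{l: chol_task[l] for l in LOADS}}
        X = _sample_segments(assign, chols, rng)
        if spec.activation_gain > 0:
            design = build_task_regressors(events, T_task, tr, sig)
            mains = design.values[:, [i for i, lab in enumerate(design.labels)
                                      if not lab.endswith("_derivative")]]
            loadings = rng.normal(0.0, 1.0, size=(mains.shape[1], R))
            X[spec.lead_in_volumes:] += spec.activation_gain * (mains @ loadings)
        mtrace = _simulate_motion(T_total, motion_mu, rng)
        X += _structured_noise(T_total, scheme, spec, mtrace, artifact_loading, rng)
        cond = f"task_run{run_idx + 1}"
        task_runs.append(RoiTimeSeries(subject, cond, X, tr))
        events_list.append(events)
        motion[cond] = mtrace

    truth = pd.DataFrame({
        "subject": subject, "load": list(LOADS),
        "lambda": [lam_by_load[l] for l in LOADS],
        "p_correct": [outcomes[outcomes["load"] == l]["p_correct"].iloc[0] for l in LOADS],
    })
    return SubjectRecord(
        subject=subject, age_group=group, sex=sex, scanner=scanner, age=age,
        rest=rest_ts, task_runs=task_runs, events=events_list,
        motion=motion, truth=truth,
    )


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> list[SubjectRecord]:
    """The full two-group cohort, deterministic in (spec, seed)."""
    seed = spec.seed if seed is None else seed
    scheme = spec.scheme
    cov = {g: build_network_covariance(scheme, spec.w_g[g], spec.b_g[g])
           for g in ("young", "old")}
    # one fixed topology permutation per cohort, shared by both groups
    alt = {g: alt_covariance(cov[g], scheme, seed=seed + 104729) for g in cov}
    cohort: list[SubjectRecord] = []
    meta = ([("young", i) for i in range(spec.n_young)]
            + [("old", i) for i in range(spec.n_old)])
    age_mu_sd = {"young": (24.8, 4.2), "old": (65.1, 6.6)}
    for idx, (group, k) in enumerate(meta):
        rng = np.random.default_rng([seed, idx])
        subject = f"sub-{group[0].upper()}{k + 1:03d}"
        sex = "M" if rng.random() < 0.5 else "F"
        # scanner upgrade mid-collection affected only the older cohort
        scanner = "pre" if group == "young" else ("pre" if rng.random() < 21 / 34 else "post")
        age = float(rng.normal(*age_mu_sd[group]))
        cohort.append(simulate_subject(spec, subject, group, sex, scanner, age,
                                       cov[group], alt[group], rng))
    return cohort


def cohort_truth(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.concat([rec.truth for rec in cohort], ignore_index=True)


def participants_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject": r.subject, "age_group": r.age_group, "sex": r.sex,
        "scanner": r.scanner, "age": r.age,
    } for r in cohort])
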