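"""ROI-level signal conditioning.

Task runs: trim leading volumes, then one joint OLS regression of
task-activation regressors (HRF-convolved boxcars plus their temporal
derivatives) and nuisance series (six motion parameters, global signal),
then load-block extraction.  Rest runs: trim, nuisance regression, then
second-order polynomial detrend and zero-phase band-pass (0.009–0.1 Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MotionTrace, RoiTimeSeries, TaskEventTable
from .errors import DataError, ParameterError, SchemaError, StructureError

log = logging.getLogger(__name__)

#: Event classes modeled as task-activation regressors.  "fixation" pools
#: the blanks/fixations between trials; correct/wrong span whole trials.
REGRESSOR_CLASSES = (
    "encoding",
    "maintenance",
    "probe",
    "response",
    "fixation",
    "correct_trial",
    "wrong_trial",
)

_FIXATION_LIKE = {"blank", "fixation", "inter_trial_blank"}


@dataclass
class SignalConfig:
    """Tunable conditioning parameters (seconds, Hz, mm)."""

    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hrf_length_s: float = 32.0
    band_hz: tuple[float, float] = (0.009, 0.1)
    taper_hz: float = 0.0  # >0 smooths the band edges at the cost of idempotence
    detrend_order: int = 2
    volumes_to_trim: int = 5
    fd_radius_mm: float = 50.0
    oversample: int = 10

    def validate(self, tr_seconds: float) -> None:
        low, high = self.band_hz
        nyquist = 0.5 / tr_seconds
        if not (0 < low < high < nyquist):
            raise ParameterError(
                f"band edges {self.band_hz} invalid for Nyquist {nyquist:.4g} Hz"
            )


@dataclass
class DesignMatrix:
    """T×K task design: main/derivative column pairs, all-zero columns dropped."""

    values: np.ndarray
    labels: list[str]
    tr_seconds: float
    dropped: list[str] = field(default_factory=list)


def canonical_hrf(tr_seconds: float, length_s: float | None = None,
                  config: SignalConfig | None = None) -> np.ndarray:
    """Double-gamma hemodynamic response kernel sampled at the TR.

    The response gamma's mode sits at ``hrf_peak_s`` and the undershoot
    gamma's at ``hrf_undershoot_s``; the kernel is peak-normalized to 1.
    """
    config = config or SignalConfig()
    if tr_seconds <= 0:
        raise ParameterError("tr_seconds must be positive")
    length_s = config.hrf_length_s if length_s is None else length_s
    if length_s < config.hrf_peak_s:
        raise ParameterError(
            f"kernel length {length_s} s shorter than response peak {config.hrf_peak_s} s"
        )
    t = np.arange(0.0, length_s + 0.5 * tr_seconds, tr_seconds)
    # shape a = peak/dispersion + 1 puts the gamma mode exactly at the peak
    a1 = config.hrf_peak_s / config.hrf_dispersion + 1.0
    a2 = config.hrf_undershoot_s / config.hrf_undershoot_dispersion + 1.0
    kernel = (
        sps.gamma.pdf(t, a1, scale=config.hrf_dispersion)
        - config.hrf_undershoot_ratio
        * sps.gamma.pdf(t, a2, scale=config.hrf_undershoot_dispersion)
    )
    return kernel / kernel.max()


def _event_intervals(events: TaskEventTable) -> dict[str, list[tuple[float, float]]]:
    """(onset, duration) lists per regressor class."""
    ev = events.events
    etype = ev["event_type"].to_numpy()
    onset = ev["onset"].to_numpy(dtype=float)
    dur = ev["duration"].to_numpy(dtype=float)
    out: dict[str, list[tuple[float, float]]] = {}
    fix = np.isin(etype, tuple(_FIXATION_LIKE))
    out["fixation"] = list(zip(onset[fix], dur[fix]))
    for cls in ("encoding", "maintenance", "probe", "response"):
        m = etype == cls
        out[cls] = list(zip(onset[m], dur[m]))
    # correct/wrong regressors: boxcar over the whole trial, initial blank
    # through probe end (distinct from the sum of the phase regressors)
    has_trial = ev["trial_id"].notna().to_numpy()
    codes, uniq = pd.factorize(ev["trial_id"].to_numpy()[has_trial])
    t_on = onset[has_trial]
    starts = np.full(len(uniq), np.inf)
    np.minimum.at(starts, codes, t_on)
    probe_rows = etype[has_trial] == "probe"
    probe_trial = codes[probe_rows]
    probe_end = (t_on + dur[has_trial])[probe_rows]
    correct = np.array([bool(c) for c in
                        ev["correct"].to_numpy()[has_trial][probe_rows]])
    t0 = starts[probe_trial]
    spans = probe_end - t0
    out["correct_trial"] = list(zip(t0[correct], spans[correct]))
    out["wrong_trial"] = list(zip(t0[~correct], spans[~correct]))
    return out


def build_task_regressors(events: TaskEventTable, n_volumes: int, tr_seconds: float,
                          config: SignalConfig | None = None) -> DesignMatrix:
    """HRF-convolved boxcar per event class plus its first-difference
    temporal derivative; all-zero columns are dropped and logged."""
    config = config or SignalConfig()
    run_end = n_volumes * tr_seconds
    intervals = _event_intervals(events)
    for cls, spans in intervals.items():
        for onset, dur in spans:
            if onset + dur > run_end + 1e-9:
                raise StructureError(
                    f"{cls} event at {onset:.1f}+{dur:.1f}s extends past run end {run_end:.1f}s"
                )
    dt = tr_seconds / config.oversample
    n_fine = n_volumes * config.oversample
    hrf = canonical_hrf(dt, config=config)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    dropped: list[str] = []
    for cls in REGRESSOR_CLASSES:
        spans = intervals[cls]
        edges = np.zeros(n_fine + 1)
        if spans:
            arr = np.asarray(spans, dtype=float)
            i0 = np.round(arr[:, 0] / dt).astype(int)
            i1 = np.maximum(i0 + 1, np.round((arr[:, 0] + arr[:, 1]) / dt).astype(int))
            np.add.at(edges, np.clip(i0, 0, n_fine), 1.0)
            np.add.at(edges, np.clip(i1, 0, n_fine), -1.0)
        boxcar = (np.cumsum(edges[:-1]) > 0).astype(float)
        conv = np.convolve(boxcar, hrf)[:n_fine]
        main = conv[:: config.oversample]  # sample at volume onsets
        if not np.any(main):
            dropped.append(cls)
            log.info("design matrix: dropping all-zero column %s", cls)
            continue
        deriv = np.diff(main, prepend=main[0])
        cols.extend([main, deriv])
        labels.extend([cls, f"{cls}_derivative"])
    return DesignMatrix(np.column_stack(cols), labels, tr_seconds, dropped)


def regress_out(ts: RoiTimeSeries, regressors: np.ndarray,
                labels: list[str] | None = None) -> RoiTimeSeries:
    """Per-ROI OLS residuals against the regressors plus an intercept.

    All-zero regressor columns are dropped (logged); remaining rank
    deficiency raises, naming the collinear columns.
    """
    X = np.asarray(regressors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != ts.n_volumes:
        raise SchemaError(
            f"regressors have {X.shape[0]} rows for {ts.n_volumes} volumes"
        )
    labels = labels or [f"x{i}" for i in range(X.shape[1])]
    # constant columns (all-zero or all-equal) are spanned by the intercept
    keep = [i for i in range(X.shape[1]) if np.ptp(X[:, i]) > 0]
    if len(keep) < X.shape[1]:
        dropped = [labels[i] for i in range(X.shape[1]) if i not in keep]
        log.info("regress_out: dropping constant columns %s", dropped)
        X = X[:, keep]
        labels = [labels[i] for i in keep]
    Xd = np.column_stack([np.ones(ts.n_volumes), X])
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        raise DataError(
            f"design rank {rank} < {Xd.shape[1]} columns; collinear among {labels}"
        )
    beta, *_ = np.linalg.lstsq(Xd, ts.data, rcond=None)
    return ts.with_data(ts.data - Xd @ beta)


def bandpass_detrend_rest(ts: RoiTimeSeries, config: SignalConfig | None = None) -> RoiTimeSeries:
    """Second-order polynomial detrend plus zero-phase band-pass, realized
    as one orthogonal projection.

    The output lies in the span of the in-band Fourier modes and is exactly
    orthogonal to the polynomial trend basis, so re-applying the operation
    is a no-op (projections are idempotent) and the band edges are exact.
    A cosine taper of ``taper_hz`` can optionally smooth the edges; it
    applies a fractional gain and therefore trades idempotence for reduced
    ringing.
    """
    config = config or SignalConfig()
    config.validate(ts.tr_seconds)
    T = ts.n_volumes
    freqs = np.fft.rfftfreq(T, ts.tr_seconds)
    low, high = config.band_hz
    w = config.taper_hz
    t = np.linspace(-1.0, 1.0, T)
    P = np.column_stack([t**k for k in range(config.detrend_order + 1)])
    if w > 0:
        # tapered variant: sequential detrend then cosine-edged mask
        beta, *_ = np.linalg.lstsq(P, ts.data, rcond=None)
        detrended = ts.data - P @ beta
        mask = np.zeros_like(freqs)
        mask[(freqs >= low) & (freqs <= high)] = 1.0
        lo = (freqs >= low - w) & (freqs < low)
        mask[lo] = 0.5 * (1 + np.cos(np.pi * (low - freqs[lo]) / w))
        hi = (freqs > high) & (freqs <= high + w)
        mask[hi] = 0.5 * (1 + np.cos(np.pi * (freqs[hi] - high) / w))
        out = np.fft.irfft(np.fft.rfft(detrended, axis=0) * mask[:, None],
                           n=T, axis=0)
        return ts.with_data(out)
    bins = np.flatnonzero((freqs >= low) & (freqs <= high))
    t_idx = np.arange(T)
    cols = []
    for k in bins:
        cols.append(np.cos(2 * np.pi * k * t_idx / T))
        if 0 < k < T / 2:
            cols.append(np.sin(2 * np.pi * k * t_idx / T))
    B = np.column_stack(cols)
    # basis of (in-band span) ∩ (trend complement): null space of PᵀB
    M = P.T @ B
    _, s, Vt = np.linalg.svd(M, full_matrices=True)
    rank = int(np.sum(s > s.max() * 1e-10)) if len(s) else 0
    N = Vt[rank:].T
    Q, _ = np.linalg.qr(B @ N)
    return ts.with_data(Q @ (Q.T @ ts.data))


def trim_volumes(ts: RoiTimeSeries, config: SignalConfig | None = None) -> RoiTimeSeries:
    config = config or SignalConfig()
    n = config.volumes_to_trim
    if ts.n_volumes <= n + 2:
        raise DataError(f"cannot trim {n} volumes from a {ts.n_volumes}-volume run")
    return ts.with_data(ts.data[n:])


def extract_load_blocks(run_residuals: list[RoiTimeSeries],
                        run_events: list[TaskEventTable], load: int,
                        demean_segments: bool = True) -> RoiTimeSeries:
    """Concatenate the load's block volumes across runs, in run order.

    A volume belongs to the block when its midpoint falls inside
    [first trial onset, last trial probe end]; within-block inter-trial
    blanks are therefore kept while inter-block baselines are discarded.
    Each run's segment is mean-centered before concatenation by default.
    """
    if len(run_residuals) != len(run_events):
        raise SchemaError("need one event table per task run")
    segments = []
    for ts, events in zip(run_residuals, run_events):
        start, end = events.block_interval(load)
        mid = (np.arange(ts.n_volumes) + 0.5) * ts.tr_seconds
        seg = ts.data[(mid >= start) & (mid <= end)]
        if seg.shape[0] == 0:
            raise StructureError(f"load {load}: no volumes inside block interval")
        if demean_segments:
            seg = seg - seg.mean(axis=0)
        segments.append(seg)
    first = run_residuals[0]
    return RoiTimeSeries(
        subject=first.subject, condition=f"dot{load}",
        data=np.concatenate(segments, axis=0), tr_seconds=first.tr_seconds,
    )


def block_volume_indices(events: TaskEventTable, n_volumes: int,
                         tr_seconds: float, load: int) -> np.ndarray:
    """Volume indices of the load's block in one run (midpoint rule)."""
    start, end = events.block_interval(load)
    mid = (np.arange(n_volumes) + 0.5) * tr_seconds
    return np.flatnonzero((mid >= start) & (mid <= end))


def compute_fd(motion: MotionTrace | np.ndarray,
               config: SignalConfig | None = None) -> MotionTrace:
    """Framewise displacement in Power's convention.

    FD_t = Σ|Δ translations| + r · Σ|Δ rotations| with r = 50 mm;
    max_abs_displacement is the largest Euclidean translation from the
    first-volume reference position.
    """
    config = config or SignalConfig()
    params = motion.params if isinstance(motion, MotionTrace) else np.asarray(motion, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise SchemaError(f"motion parameters must be T×6, got {params.shape}")
    if params.shape[0] < 2:
        raise SchemaError("need at least 2 volumes to compute FD")
    d = np.diff(params, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + config.fd_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    disp = np.linalg.norm(params[:, :3] - params[0, :3], axis=1)
    return MotionTrace(
        params=params, fd=fd, mean_fd=float(fd.mean()),
        max_abs_displacement=float(disp.max()),
    )


# ---------------------------------------------------------------------------
# Per-run conditioning pipelines


def condition_rest_run(ts: RoiTimeSeries, motion: MotionTrace,
                       config: SignalConfig | None = None) -> tuple[RoiTimeSeries, MotionTrace]:
    """trim → nuisance regression (6 motion params + global signal) →
    detrend + band-pass.  Returns the conditioned run and trimmed motion."""
    config = config or SignalConfig()
    trimmed = trim_volumes(ts, config)
    mtrim = compute_fd(motion.params[config.volumes_to_trim:], config)
    nuis = np.column_stack([mtrim.params, trimmed.data.mean(axis=1)])
    labels = [f"motion_{i}" for i in range(6)] + ["global_signal"]
    resid = regress_out(trimmed, nuis, labels)
    return bandpass_detrend_rest(resid, config), mtrim


def condition_task_run(ts: RoiTimeSeries, events: TaskEventTable, motion: MotionTrace,
                       config: SignalConfig | None = None,
                       joint: bool = True) -> tuple[RoiTimeSeries, MotionTrace, DesignMatrix]:
    """trim → joint activation + nuisance regression (single OLS model).

    ``joint=False`` runs the two projections sequentially (activation first)
    for sensitivity checks; the default single model avoids order dependence.
    """
    config = config or SignalConfig()
    trimmed = trim_volumes(ts, config)
    mtrim = compute_fd(motion.params[config.volumes_to_trim:], config)
    design = build_task_regressors(events, trimmed.n_volumes, trimmed.tr_seconds, config)
    nuis = np.column_stack([mtrim.params, trimmed.data.mean(axis=1)])
    nuis_labels = [f"motion_{i}" for i in range(6)] + ["global_signal"]
    if joint:
        X = np.column_stack([design.values, nuis])
        resid = regress_out(trimmed, X, design.labels + nuis_labels)
    else:
        resid = regress_out(trimmed, design.values, design.labels)
        resid = regress_out(resid, nuis, nuis_labels)
    return resid, mtrim, design
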