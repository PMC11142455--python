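"""End-to-end orchestration: simulate → condition → connect → similarity →
behavior → stats, with deterministic stage seeds and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .behavior import behavior_frame, score_behavior
from .conditioning import SignalConfig, compute_fd, condition_rest_run, condition_task_run
from .connectivity import fc_per_condition, fc_to_frame
from .core import SubjectRecord
from .errors import ReconfigError
from .parcellation import write_scheme
from .similarity import (averaged_fc, rest_task_similarities,
                         stepwise_similarities, within_load_similarity)
from .stats import (StatsConfig, association_battery, build_behavior_model_table,
                    build_model_table, fit_group_load_model, tukey_posthoc)
from .synthetic import CohortSpec, cohort_truth, participants_frame, simulate_cohort

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    signal: SignalConfig = field(default_factory=SignalConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    within_load: bool = False
    averaged_fc_validation: bool = False
    motion_matched_subset: bool = False
    rt_covariate: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortSpec(**raw["cohort"])
        if "signal" in raw:
            sig = dict(raw["signal"])
            if "band_hz" in sig:
                sig["band_hz"] = tuple(sig["band_hz"])
            kwargs["signal"] = SignalConfig(**sig)
        if "stats" in raw:
            kwargs["stats"] = StatsConfig(**raw["stats"])
        for key in ("within_load", "averaged_fc_validation",
                    "motion_matched_subset", "rt_covariate", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def analyze_subject(rec: SubjectRecord, config: PipelineConfig) -> dict:
    """Condition one subject's runs, build FC matrices and all similarity
    records, score behavior, and summarize motion."""
    rec.validate_complete()
    sig = config.signal
    try:
        rest_cond, rest_motion = condition_rest_run(rec.rest, rec.motion["rest"], sig)
        task_res = []
        task_motion = []
        for run_idx, run in enumerate(rec.task_runs):
            resid, mtrim, _ = condition_task_run(
                run, rec.events[run_idx], rec.motion[run.condition], sig)
            task_res.append(resid)
            task_motion.append(mtrim)
        fcs = fc_per_condition(rec, config.cohort.scheme, rest_cond,
                               task_res, rec.events, within_load=config.within_load)
    except ReconfigError as exc:
        raise type(exc)(f"subject {rec.subject}: {exc}") from exc
    scheme = config.cohort.scheme
    sims = [rest_task_similarities(rec.subject, fcs, scheme),
            stepwise_similarities(rec.subject, fcs, scheme)]
    if config.within_load:
        sims.append(within_load_similarity(rec.subject, fcs, scheme))
    avg = None
    if config.averaged_fc_validation:
        avg = pd.concat([averaged_fc(fcs[f"dot{l}"], scheme) for l in (1, 3, 5)],
                        ignore_index=True)
        avg.insert(0, "subject", rec.subject)
    behavior = score_behavior(rec.subject, rec.events)
    return {
        "subject": rec.subject,
        "behavior_summaries": behavior,
        "motion_summaries": {"rest": rest_motion,
                             "task_run1": task_motion[0],
                             "task_run2": task_motion[1]},
        "similarities": pd.concat(sims, ignore_index=True),
        "behavior": behavior_frame(behavior),
        "averaged_fc": avg,
        "fcs": fcs,
        "metadata": {
            "subject": rec.subject, "age_group": rec.age_group, "sex": rec.sex,
            "scanner": rec.scanner, "age": rec.age,
            "rest_motion": rest_motion.mean_fd,
            "task_motion": float(np.mean([m.mean_fd for m in task_motion])),
        },
    }


def analyze_cohort(cohort: list[SubjectRecord], config: PipelineConfig,
                   apply_filters: bool = True) -> dict:
    from dataclasses import replace

    per_subject = [analyze_subject(rec, config) for rec in cohort]
    metadata = pd.DataFrame([r["metadata"] for r in per_subject])
    if apply_filters:
        scored = [replace(rec, behavior=r["behavior_summaries"],
                          motion=r["motion_summaries"])
                  for rec, r in zip(cohort, per_subject)]
        included, exclusions = rio.apply_inclusion_filters(scored)
        keep = {r.subject for r in included}
    else:
        keep = {r.subject for r in cohort}
        exclusions = []
    per_subject = [r for r in per_subject if r["subject"] in keep]
    sims = pd.concat([r["similarities"] for r in per_subject], ignore_index=True)
    beh = pd.concat([r["behavior"] for r in per_subject], ignore_index=True)
    avg = (pd.concat([r["averaged_fc"] for r in per_subject], ignore_index=True)
           if config.averaged_fc_validation else None)
    return {
        "similarities": sims, "behavior": beh,
        "metadata": metadata[metadata["subject"].isin(keep)].reset_index(drop=True),
        "averaged_fc": avg,
        "exclusions": pd.DataFrame([vars(e) for e in exclusions]),
        "per_subject": per_subject,
    }


def motion_matched_young_subset(metadata: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Largest young subset whose mean FD (rest and task) does not differ
    from the old group at two-sample α; drops the farthest-from-old-mean
    young subject until both tests clear."""
    from scipy import stats as sps

    young = metadata[metadata["age_group"] == "young"].copy()
    old = metadata[metadata["age_group"] == "old"]
    if old.empty or young.empty:
        return list(young["subject"])
    while len(young) > 2:
        ps = [sps.ttest_ind(young[c], old[c]).pvalue for c in ("task_motion", "rest_motion")]
        if min(ps) >= alpha:
            break
        dist = sum(np.abs(young[c] - old[c].mean()) / (old[c].std() + 1e-12)
                   for c in ("task_motion", "rest_motion"))
        young = young.drop(dist.idxmax())
    return list(young["subject"])


def run_statistics(results: dict, config: PipelineConfig,
                   with_bootstrap: bool = False) -> dict:
    """Group × load models, post hocs, and the association battery."""
    sims, beh, meta = results["similarities"], results["behavior"], results["metadata"]
    anova_rows = []
    posthoc_rows = []
    for outcome in ("accuracy", "mean_rt_correct"):
        tab = build_behavior_model_table(beh, meta, outcome)
        f = fit_group_load_model(tab, config.stats.df_mode)
        f.insert(0, "outcome", outcome)
        anova_rows.append(f)
        ph = tukey_posthoc(tab)
        ph.insert(0, "outcome", outcome)
        posthoc_rows.append(ph)
    for comparison in ("rest_task", "stepwise"):
        scopes = sorted(sims.loc[sims["comparison"] == comparison, "scope"].unique())
        for scope in scopes:
            tab = build_model_table(sims, meta, comparison, scope)
            if tab["Y"].isna().any() or len(tab) == 0:
                continue
            f = fit_group_load_model(tab, config.stats.df_mode)
            f.insert(0, "outcome", f"{comparison}:{scope}")
            anova_rows.append(f)
            if scope == "global":
                ph = tukey_posthoc(tab)
                ph.insert(0, "outcome", f"{comparison}:{scope}")
                posthoc_rows.append(ph)
    assoc = association_battery(
        sims, beh, meta, config.stats,
        outcomes=("accuracy", "mean_rt_correct"), with_bootstrap=with_bootstrap)
    return {
        "anova": pd.concat(anova_rows, ignore_index=True),
        "posthoc": pd.concat(posthoc_rows, ignore_index=True),
        "associations": assoc,
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Simulate, analyze, fit, and write everything under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config.cohort, seed=stage_seed(config.seed, "simulate"))
    results = analyze_cohort(cohort, config)
    stats_out = run_statistics(results, config)
    if config.motion_matched_subset:
        matched = motion_matched_young_subset(results["metadata"])
        keep = set(matched) | set(
            results["metadata"].loc[results["metadata"]["age_group"] == "old", "subject"])
        sub = {
            "similarities": results["similarities"][
                results["similarities"]["subject"].isin(keep)],
            "behavior": results["behavior"][results["behavior"]["subject"].isin(keep)],
            "metadata": results["metadata"][results["metadata"]["subject"].isin(keep)],
        }
        stats_matched = run_statistics(sub, config)
        stats_out["anova_motion_matched"] = stats_matched["anova"]
        stats_out["associations_motion_matched"] = stats_matched["associations"]

    results["similarities"].to_csv(outdir / "similarities.tsv", sep="\t", index=False)
    results["behavior"].to_csv(outdir / "behavior.tsv", sep="\t", index=False)
    results["metadata"].to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    results["exclusions"].to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    if results["averaged_fc"] is not None:
        results["averaged_fc"].to_csv(outdir / "averaged_fc.tsv", sep="\t", index=False)
    for name in ("anova", "posthoc", "associations"):
        stats_out[name].to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    truth = cohort_truth(cohort)
    truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    n_fc = len(results["per_subject"][0]["fcs"]) if results["per_subject"] else 0
    manifest = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate",)},
        "n_subjects_simulated": len(cohort),
        "n_subjects_included": int(results["metadata"]["subject"].nunique()),
        "fc_matrices_per_subject": n_fc,
        "similarity_records": int(len(results["similarities"])),
        "toggles": {
            "within_load": config.within_load,
            "averaged_fc_validation": config.averaged_fc_validation,
            "motion_matched_subset": config.motion_matched_subset,
            "rt_covariate": config.rt_covariate,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {**results, **stats_out, "manifest": manifest, "cohort": cohort}


def write_cohort(cohort: list[SubjectRecord], scheme, outdir) -> None:
    """Persist a simulated cohort in the on-disk formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_scheme(scheme, outdir / "parcellation.tsv")
    rio.write_participants(participants_frame(cohort), outdir / "participants.tsv")
    cohort_truth(cohort).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    for rec in cohort:
        sdir = outdir / rec.subject
        sdir.mkdir(exist_ok=True)
        rio.write_timeseries(rec.rest, scheme, sdir / "rest_bold.tsv")
        rio.write_motion(rec.motion["rest"], sdir / "rest_motion.tsv")
        for i, run in enumerate(rec.task_runs):
            rio.write_timeseries(run, scheme, sdir / f"task_run{i + 1}_bold.tsv")
            rio.write_events(rec.events[i], sdir / f"task_run{i + 1}_events.tsv")
            rio.write_motion(rec.motion[run.condition], sdir / f"task_run{i + 1}_motion.tsv")


def read_cohort(indir, scheme=None) -> tuple[list[SubjectRecord], "object"]:
    """Load a cohort previously written by :func:`write_cohort`."""
    from .parcellation import read_scheme

    indir = Path(indir)
    if scheme is None:
        scheme = read_scheme(indir / "parcellation.tsv")
    parts = rio.read_participants(indir / "participants.tsv")
    cohort = []
    for _, row in parts.iterrows():
        sdir = indir / row["subject"]
        rec = SubjectRecord(
            subject=row["subject"], age_group=row["age_group"], sex=row["sex"],
            scanner=row["scanner"], age=float(row.get("age", np.nan)),
            rest=rio.read_timeseries(sdir / "rest_bold.tsv", scheme,
                                     subject=row["subject"], condition="rest"),
            motion={"rest": rio.read_motion(sdir / "rest_motion.tsv")},
        )
        for i in (1, 2):
            cond = f"task_run{i}"
            rec.task_runs.append(rio.read_timeseries(
                sdir / f"task_run{i}_bold.tsv", scheme,
                subject=row["subject"], condition=cond))
            rec.events.append(rio.read_events(sdir / f"task_run{i}_events.tsv"))
            rec.motion[cond] = rio.read_motion(sdir / f"task_run{i}_motion.tsv")
        cohort.append(rec)
    return cohort, scheme


def write_report(results: dict, outdir) -> None:
    """Summary figures and tables for a completed run."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sims, beh, meta = results["similarities"], results["behavior"], results["metadata"]
    merged = sims.merge(meta[["subject", "age_group"]], on="subject")
    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    bmeta = beh.merge(meta[["subject", "age_group"]], on="subject")
    for ax, (df, val, title) in zip(axes, [
        (bmeta, "accuracy", "SWM accuracy"),
        (merged[(merged["comparison"] == "rest_task") & (merged["scope"] == "global")],
         "z", "Rest–task global FC similarity"),
        (merged[(merged["comparison"] == "stepwise") & (merged["scope"] == "global")],
         "z", "Stepwise global FC similarity"),
    ]):
        key = "load" if "load" in df.columns else "pair"
        g = df.groupby(["age_group", key])[val].agg(["mean", "sem"]).reset_index()
        for grp, sub in g.groupby("age_group"):
            ax.errorbar(sub[key].astype(str), sub["mean"], yerr=sub["sem"],
                        marker="o", capsize=3, label=grp)
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "group_load_summary.png", dpi=120)
    plt.close(fig)

    assoc = results.get("associations")
    if assoc is not None:
        if assoc.empty or not assoc["significant"].any():
            assoc = pd.concat([assoc, pd.DataFrame([{
                "age_group": "-", "comparison": "-", "pair": "-", "scope": "-",
                "outcome": "none significant", "rho": np.nan, "p": np.nan,
            }])], ignore_index=True)
        assoc.to_csv(outdir / "associations_report.tsv", sep="\t", index=False)
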