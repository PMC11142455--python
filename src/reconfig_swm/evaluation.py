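"""Replicate-based recovery and calibration studies.

These drive the package end to end on simulated cohorts — generate,
condition, connect, measure similarity, score behavior, fit — and report
detection/calibration rates.  Problem sizes are chosen so a full study runs
on one CPU in minutes; the methods note records the sizes used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import compute_fc
from .core import LOADS, SubjectRecord
from .pipeline import PipelineConfig
from .similarity import build_edge_sets, similarity
from .stats import StatsConfig, bootstrap_se, fit_group_load_model, partial_spearman
from .synthetic import CohortSpec, simulate_cohort


def global_rest_task_table(cohort: list[SubjectRecord], config: PipelineConfig) -> pd.DataFrame:
    """Condition every subject and return one row per subject × load with the
    global rest–task similarity z, behavior, and model covariates.

    A lean path over the same conditioning/connectivity/similarity
    operations the full pipeline uses, computing only the global scope.
    """
    from .behavior import score_behavior
    from .conditioning import condition_rest_run, condition_task_run, extract_load_blocks

    scheme = config.cohort.scheme
    es_global = build_edge_sets(scheme)["global"]
    rows = []
    for rec in cohort:
        rest_cond, rest_motion = condition_rest_run(rec.rest, rec.motion["rest"], config.signal)
        task_res, task_fd = [], []
        for i, run in enumerate(rec.task_runs):
            resid, mtrim, _ = condition_task_run(run, rec.events[i],
                                                 rec.motion[run.condition], config.signal)
            task_res.append(resid)
            task_fd.append(mtrim.mean_fd)
        fc_rest = compute_fc(rest_cond, scheme, "rest")
        behavior = {b.load: b for b in score_behavior(rec.subject, rec.events)}
        for load in LOADS:
            blocks = extract_load_blocks(task_res, rec.events, load)
            fc_task = compute_fc(blocks, scheme, f"dot{load}")
            _, z = similarity(fc_task, fc_rest, es_global)
            rows.append({
                "subject": rec.subject, "age_group": rec.age_group, "sex": rec.sex,
                "scanner": rec.scanner, "age": rec.age, "load": f"dot{load}",
                "z": z, "accuracy": behavior[load].accuracy,
                "mean_rt_correct": behavior[load].mean_rt_correct,
                "task_motion": float(np.mean(task_fd)),
                "rest_motion": rest_motion.mean_fd,
            })
    return pd.DataFrame(rows)


def exchangeable_null_spec(spec: CohortSpec) -> CohortSpec:
    """A copy of ``spec`` in which the groups are exchangeable for the brain
    outcome: λ, segregation (w, b) and motion level all equalized to the
    young values.  Behavioral penalties are untouched."""
    return CohortSpec(
        n_young=spec.n_young, n_old=spec.n_old, n_rois=spec.n_rois,
        scheme=spec.scheme,
        w_g={"young": spec.w_g["young"], "old": spec.w_g["young"]},
        b_g={"young": spec.b_g["young"], "old": spec.b_g["young"]},
        lambda_g={"young": spec.lambda_g["young"], "old": spec.lambda_g["young"]},
        tau=spec.tau, activation_gain=spec.activation_gain,
        motion_mu_g={"young": spec.motion_mu_g["young"], "old": spec.motion_mu_g["young"]},
        motion_sigma_g={"young": spec.motion_sigma_g["young"],
                        "old": spec.motion_sigma_g["young"]},
        seed=spec.seed,
    )


def group_effect_rejection_rate(n_replicates: int, seed: int,
                                spec: CohortSpec | None = None,
                                null: bool = False, alpha: float = 0.05,
                                df_mode: str = "lmm_satterthwaite") -> float:
    """Fraction of replicate cohorts in which the age-group main effect on
    global rest–task similarity is rejected.

    The random-intercept mode is used because each subject contributes one
    correlated row per load and age group is a between-subject factor.
    """
    base = spec or CohortSpec(n_young=40, n_old=40, n_rois=60)
    if null:
        base = exchangeable_null_spec(base)
    hits = 0
    for rep in range(n_replicates):
        rep_seed = (seed + 7919 * rep) % (2**31)
        cohort = simulate_cohort(base, seed=rep_seed)
        tab = global_rest_task_table(cohort, PipelineConfig(cohort=base))
        model_tab = tab.rename(columns={"z": "Y"})[
            ["Y", "age_group", "load", "sex", "task_motion", "rest_motion",
             "scanner", "subject"]]
        fit = fit_group_load_model(model_tab, df_mode)
        p = float(fit.loc[fit["term"] == "age_group", "p"].iloc[0])
        hits += p < alpha
    return hits / n_replicates


def coupling_recovery_rates(n_replicates: int, seed: int, n_subjects: int = 100,
                            n_rois: int = 30, null: bool = False,
                            alpha: float = 0.05) -> tuple[float, float]:
    """(fraction of replicates with positive partial Spearman, fraction
    significant) for dot3 global rest–task similarity vs dot3 accuracy in a
    single-group cohort; ``null=True`` decouples behavior from λ (a1=0)."""
    frac_pos = 0
    frac_sig = 0
    for rep in range(n_replicates):
        rep_seed = (seed + 104729 * rep) % (2**31)
        kwargs = dict(n_young=n_subjects, n_old=0, n_rois=n_rois)
        if null:
            kwargs["a1"] = 0.0
        spec = CohortSpec(**kwargs)
        cohort = simulate_cohort(spec, seed=rep_seed)
        tab = global_rest_task_table(cohort, PipelineConfig(cohort=spec))
        sub = tab[tab["load"] == "dot3"].copy()
        covs = np.column_stack([
            sub["age"], (sub["sex"] == "F").astype(float),
            sub["task_motion"], sub["rest_motion"],
        ])
        res = partial_spearman(sub["z"].to_numpy(), sub["accuracy"].to_numpy(), covs)
        frac_pos += res.rho > 0
        frac_sig += res.p < alpha
    return frac_pos / n_replicates, frac_sig / n_replicates


def spearman_type1_rate(n_sims: int, n: int, k: int, seed: int,
                        alpha: float = 0.05) -> float:
    """Type-I error of partial_spearman on independent Gaussian data."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        C = rng.standard_normal((n, k))
        hits += partial_spearman(x, y, C).p < alpha
    return hits / n_sims


def bootstrap_se_calibration(n_datasets: int, n: int, rho: float,
                             n_boot: int, seed: int) -> tuple[float, float]:
    """(mean bootstrap SE, empirical SD of rho across replicate datasets)
    for bivariate normal data with correlation ``rho``."""
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov)
    ses, rhos = [], []
    for i in range(n_datasets):
        xy = rng.standard_normal((n, 2)) @ L.T
        cfg = StatsConfig(seed=int(rng.integers(2**31)))
        res = bootstrap_se(xy[:, 0], xy[:, 1], None, cfg, n_iterations=n_boot)
        ses.append(res.bootstrap_se)
        rhos.append(res.rho)
    return float(np.mean(ses)), float(np.std(rhos, ddof=1))
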