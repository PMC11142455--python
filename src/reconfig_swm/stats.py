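"""Group × load inference and covariate-adjusted brain–behavior associations.

The group-level model is

    Y ~ age_group * load + sex + task_motion + rest_motion + scanner (+ 1|subject)

fitted either as fixed-effects OLS (``fixed_ols``: the denominator df equal
N_obs − n_coefficients, matching F_{2,420}-style reporting for 143 subjects
× 3 loads) or as a random-intercept mixed model with Satterthwaite-
approximated denominator df (``lmm_satterthwaite``).  Post hocs are
Tukey-Kramer contrasts of covariate-adjusted cell means on the studentized
range distribution.  Associations are partial Spearman correlations
(rank-residualization, average ranks for ties) with subject-resampling
bootstrap standard errors, gated per network by Bonferroni at 0.05/9.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .errors import DataError, JoinError, SchemaError

log = logging.getLogger(__name__)

FORMULA = "Y ~ age_group * load + sex + task_motion + rest_motion + scanner"
TERMS = ("age_group", "load", "age_group:load", "sex",
         "task_motion", "rest_motion", "scanner")


@dataclass
class StatsConfig:
    n_networks: int = 9
    family_alpha: float = 0.05
    bootstrap_iterations: int = 10_000
    seed: int = 0
    df_mode: str = "fixed_ols"  # or lmm_satterthwaite

    @property
    def per_network_alpha(self) -> float:
        return self.family_alpha / self.n_networks


@dataclass
class AssociationResult:
    rho: float
    p: float
    n: int
    covariates: list[str] = field(default_factory=list)
    bootstrap_se: Optional[float] = None
    degenerate_fraction: float = 0.0


def _check_model_table(rows: pd.DataFrame) -> pd.DataFrame:
    need = {"Y", "age_group", "load", "sex", "task_motion", "rest_motion",
            "scanner", "subject"}
    missing = need - set(rows.columns)
    if missing:
        raise SchemaError(f"model table missing columns {sorted(missing)}")
    rows = rows.copy()
    for col in ("age_group", "load", "sex", "scanner", "subject"):
        rows[col] = rows[col].astype(str)
    # warn (but keep the term) when scanner is single-level inside a cell
    for (g, l), cell in rows.groupby(["age_group", "load"]):
        if cell["scanner"].nunique() == 1:
            log.warning("scanner has a single level within cell (%s, %s); term retained", g, l)
            break
    return rows


def fit_group_load_model(rows: pd.DataFrame, df_mode: str = "fixed_ols") -> pd.DataFrame:
    """Per-term F tests.  Returns columns term, F, df1, df2, p."""
    rows = _check_model_table(rows)
    if df_mode == "fixed_ols":
        return _fit_ols(rows)
    if df_mode == "lmm_satterthwaite":
        return _fit_lmm_satterthwaite(rows)
    raise SchemaError(f"unknown df_mode {df_mode!r}")


def _fit_ols(rows: pd.DataFrame):
    # motion covariates that are identically zero (e.g. rest motion for a
    # task-only outcome) carry no information and are dropped, so the
    # residual df reflects only the informative coefficients
    formula = FORMULA
    dropped = [c for c in ("task_motion", "rest_motion")
               if (rows[c] == 0).all()]
    # single-level categorical covariates contribute no columns and break
    # the term-wise F machinery; drop them explicitly
    dropped += [c for c in ("sex", "scanner") if rows[c].nunique() < 2]
    for c in dropped:
        log.info("fixed_ols: dropping uninformative covariate %s", c)
        formula = formula.replace(f" + {c}", "")
    res = smf.ols(formula, data=rows).fit()
    if res.model.exog.shape[1] != np.linalg.matrix_rank(res.model.exog):
        names = res.model.exog_names
        raise DataError(f"rank-deficient design among {names}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(res, typ=2)
    out = []
    for term in TERMS:
        if term in dropped or term not in table.index:
            continue  # single-level categorical terms contribute no columns
        row = table.loc[term]
        out.append({"term": term, "F": float(row["F"]), "df1": int(row["df"]),
                    "df2": int(res.df_resid), "p": float(row["PR(>F)"])})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Random-intercept model with Satterthwaite df


def _reml_neg2loglik(theta, y, X, groups_idx):
    """−2 × REML log-likelihood for V_i = σ²I + τ²J (profile over β)."""
    s2, t2 = theta
    if s2 <= 0 or t2 < 0:
        return np.inf
    XtVX = 0.0
    XtVy = 0.0
    logdet = 0.0
    quad_parts = []
    for idx in groups_idx:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        # V⁻¹ = (1/σ²)(I − c J), c = τ²/(σ² + n τ²) by Sherman–Morrison
        c = t2 / (s2 + ni * t2)
        Xs, ys = Xi.sum(axis=0), yi.sum()
        XtVX += (Xi.T @ Xi - c * np.outer(Xs, Xs)) / s2
        XtVy += (Xi.T @ yi - c * Xs * ys) / s2
        logdet += (ni - 1) * np.log(s2) + np.log(s2 + ni * t2)
        quad_parts.append((Xi, yi, c))
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for Xi, yi, c in quad_parts:
        ri = yi - Xi @ beta
        rs = ri.sum()
        quad += (ri @ ri - c * rs * rs) / s2
    sign, logdet_XtVX = np.linalg.slogdet(XtVX)
    return logdet + logdet_XtVX + quad


#: Sum-to-zero coding so each term's coefficient block tests its marginal
#: (type-III style) effect rather than the effect at the reference level.
_LMM_FORMULA = ("Y ~ C(age_group, Sum) * C(load, Sum) + C(sex, Sum) "
                "+ task_motion + rest_motion + C(scanner, Sum)")
_LMM_TERM_MAP = {
    "C(age_group, Sum)": "age_group",
    "C(load, Sum)": "load",
    "C(age_group, Sum):C(load, Sum)": "age_group:load",
    "C(sex, Sum)": "sex",
    "task_motion": "task_motion",
    "rest_motion": "rest_motion",
    "C(scanner, Sum)": "scanner",
}


def _fit_lmm_satterthwaite(rows: pd.DataFrame):
    import patsy

    y_dm, X_dm = patsy.dmatrices(_LMM_FORMULA, rows, return_type="dataframe")
    y = np.asarray(y_dm).ravel()
    X = np.asarray(X_dm)
    design_info = X_dm.design_info
    groups = rows["subject"].to_numpy()
    groups_idx = [np.flatnonzero(groups == g) for g in pd.unique(groups)]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    s2 = float(mixed.scale)
    t2 = float(np.asarray(mixed.cov_re)[0, 0])
    theta = np.array([s2, max(t2, 1e-10)])

    def beta_cov(th):
        s2_, t2_ = th
        XtVX = 0.0
        XtVy = 0.0
        for idx in groups_idx:
            Xi, yi = X[idx], y[idx]
            c = t2_ / (s2_ + len(idx) * t2_)
            Xs, ys = Xi.sum(axis=0), yi.sum()
            XtVX += (Xi.T @ Xi - c * np.outer(Xs, Xs)) / s2_
            XtVy += (Xi.T @ yi - c * Xs * ys) / s2_
        cov = np.linalg.inv(XtVX)
        return cov, cov @ XtVy

    cov_beta, beta = beta_cov(theta)

    # asymptotic covariance of (σ², τ²): inverse Hessian of −2·REML/2
    h = np.maximum(1e-6, 1e-4 * theta)
    H = np.zeros((2, 2))
    f0 = _reml_neg2loglik(theta, y, X, groups_idx)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            fpp = _reml_neg2loglik(theta + ei + ej, y, X, groups_idx)
            fpm = _reml_neg2loglik(theta + ei - ej, y, X, groups_idx)
            fmp = _reml_neg2loglik(theta - ei + ej, y, X, groups_idx)
            fmm = _reml_neg2loglik(theta - ei - ej, y, X, groups_idx)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j]) / 2.0
    try:
        var_theta = 2.0 * np.linalg.inv(H + H.T)  # Var(θ̂) ≈ 2 A⁻¹ with A = Hessian of −2ℓ
    except np.linalg.LinAlgError:
        var_theta = np.full((2, 2), np.nan)

    def satterthwaite_df(contrast):
        def f(th):
            cov, _ = beta_cov(th)
            return float(contrast @ cov @ contrast)
        grad = np.zeros(2)
        for i in range(2):
            ei = np.eye(2)[i] * h[i]
            grad[i] = (f(theta + ei) - f(theta - ei)) / (2 * h[i])
        denom = grad @ var_theta @ grad
        if not np.isfinite(denom) or denom <= 0:
            return float(len(y) - X.shape[1])
        return 2.0 * f(theta) ** 2 / denom

    out = []
    slices = {_LMM_TERM_MAP.get(k, k): v for k, v in design_info.term_name_slices.items()}
    for term in TERMS:
        sl = slices.get(term)
        if sl is None:
            continue
        L = np.zeros((sl.stop - sl.start, X.shape[1]))
        for k, col in enumerate(range(sl.start, sl.stop)):
            L[k, col] = 1.0
        q = L.shape[0]
        M = L @ cov_beta @ L.T
        Fval = float(beta @ L.T @ np.linalg.solve(M, L @ beta)) / q
        # lmerTest construction: per-eigenvector 1-df Satterthwaite dfs pooled
        eigval, eigvec = np.linalg.eigh(M)
        nus = []
        for m in range(q):
            c = eigvec[:, m] @ L
            nus.append(satterthwaite_df(c))
        nus = np.asarray(nus)
        good = nus > 2
        if good.any():
            E = float(np.sum(nus[good] / (nus[good] - 2)))
            df2 = 2 * E / (E - q) if E > q else float(len(y) - X.shape[1])
        else:
            df2 = float(len(y) - X.shape[1])
        p = float(sps.f.sf(Fval, q, df2))
        out.append({"term": term, "F": Fval, "df1": q, "df2": df2, "p": p})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Post hoc and multiplicity


def tukey_posthoc(rows: pd.DataFrame) -> pd.DataFrame:
    """All pairwise age_group × load cell contrasts of covariate-adjusted
    means, with studentized-range-adjusted p values."""
    rows = _check_model_table(rows)
    res = smf.ols(FORMULA, data=rows).fit()
    design_info = res.model.data.design_info
    import patsy

    cells = rows.groupby(["age_group", "load"]).size()
    if (cells == 0).any():
        raise DataError("empty age_group × load cell")
    cov_means = {
        "sex": rows["sex"].mode()[0], "scanner": rows["scanner"].mode()[0],
        "task_motion": rows["task_motion"].mean(),
        "rest_motion": rows["rest_motion"].mean(),
    }
    grid = [(g, l) for g in sorted(rows["age_group"].unique())
            for l in sorted(rows["load"].unique())]
    rows_pred = pd.DataFrame([{**cov_means, "age_group": g, "load": l} for g, l in grid])
    Xg = np.asarray(patsy.build_design_matrices([design_info], rows_pred)[0])
    beta = res.params.to_numpy()
    covb = res.cov_params().to_numpy()
    means = Xg @ beta
    k = len(grid)
    df = res.df_resid
    out = []
    for i, j in itertools.combinations(range(k), 2):
        c = Xg[i] - Xg[j]
        diff = float(means[i] - means[j])
        se = float(np.sqrt(c @ covb @ c))
        t = diff / se
        q = abs(t) * np.sqrt(2.0)
        p_unadj = float(2 * sps.t.sf(abs(t), df))
        p_adj = float(np.clip(sps.studentized_range.sf(q, k, df), 0, 1))
        out.append({
            "cell_a": f"{grid[i][0]}|{grid[i][1]}", "cell_b": f"{grid[j][0]}|{grid[j][1]}",
            "estimate": diff, "se": se, "p_unadjusted": p_unadj,
            "p_tukey": max(p_adj, p_unadj),
        })
    return pd.DataFrame(out)


def bonferroni_gate(p_values: Sequence[float] | dict, config: StatsConfig | None = None) -> np.ndarray:
    """Per-network significance flags: p < family_alpha / n_networks."""
    config = config or StatsConfig()
    vals = np.asarray(list(p_values.values()) if isinstance(p_values, dict)
                      else p_values, dtype=float)
    if vals.size != config.n_networks:
        raise SchemaError(
            f"expected one p per network ({config.n_networks}), got {vals.size}")
    return vals < config.per_network_alpha


# ---------------------------------------------------------------------------
# Partial Spearman with bootstrap SE


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return sps.rankdata(a, axis=axis)  # average ranks for ties


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), C]) if C.size else np.ones((len(v), 1))
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_spearman(x, y, covariates=None,
                     covariate_names: list[str] | None = None) -> AssociationResult:
    """Spearman correlation of x and y after rank-residualizing both on the
    (ranked) covariates.  p from the t approximation with df = n − 2 − k."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None:
        C = np.empty((len(x), 0))
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    n = len(x)
    if len(y) != n or (k and C.shape[0] != n):
        raise SchemaError("x, y and covariates must share length")
    if n < k + 4:
        raise DataError(f"n={n} too small for {k} covariates")
    rx, ry = _rank(x), _rank(y)
    if rx.std() == 0 or ry.std() == 0:
        raise DataError("constant variable after ranking")
    rC = _rank(C, axis=0) if k else C
    ex, ey = _residualize(rx, rC), _residualize(ry, rC)
    sx, sy = ex.std(), ey.std()
    if sx == 0 or sy == 0:
        raise DataError("residual variance zero in partial Spearman")
    rho = float(np.clip((ex @ ey) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return AssociationResult(rho=rho, p=p, n=n,
                             covariates=covariate_names or [f"c{i}" for i in range(k)])


def bootstrap_se(x, y, covariates=None, config: StatsConfig | None = None,
                 n_iterations: int | None = None) -> AssociationResult:
    """Partial Spearman with a subject-resampling bootstrap SE.

    Resamples rows with replacement, recomputes rho per iteration
    (vectorized), and reports the SD over non-degenerate iterations.
    """
    config = config or StatsConfig()
    B = n_iterations or config.bootstrap_iterations
    base = partial_spearman(x, y, covariates)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    C = (np.empty((len(x), 0)) if covariates is None else np.asarray(covariates, float))
    if C.ndim == 1:
        C = C[:, None]
    n, k = len(x), C.shape[1]
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(B, n))
    xb, yb = x[idx], y[idx]
    degenerate = (np.ptp(xb, axis=1) == 0) | (np.ptp(yb, axis=1) == 0)
    rx = _rank(xb, axis=1)
    ry = _rank(yb, axis=1)
    if k:
        rC = np.stack([_rank(C[idx, j], axis=1) for j in range(k)], axis=2)
        X = np.concatenate([np.ones((B, n, 1)), rC], axis=2)
    else:
        X = np.ones((B, n, 1))
    XtX = np.einsum("bni,bnj->bij", X, X)
    Xtx = np.einsum("bni,bn->bi", X, rx)
    Xty = np.einsum("bni,bn->bi", X, ry)
    bx = np.linalg.solve(XtX, Xtx[..., None])[..., 0]
    by = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    ex = rx - np.einsum("bni,bi->bn", X, bx)
    ey = ry - np.einsum("bni,bi->bn", X, by)
    num = np.einsum("bn,bn->b", ex, ey)
    den = np.sqrt(np.einsum("bn,bn->b", ex, ex) * np.einsum("bn,bn->b", ey, ey))
    ok = ~degenerate & (den > 0)
    rhos = np.clip(num[ok] / den[ok], -1, 1)
    frac_bad = 1.0 - ok.mean()
    if frac_bad > 0.10:
        warnings.warn(f"{frac_bad:.1%} degenerate bootstrap resamples", stacklevel=2)
    base.bootstrap_se = float(rhos.std(ddof=1)) if len(rhos) > 1 else 0.0
    base.degenerate_fraction = float(frac_bad)
    return base


# ---------------------------------------------------------------------------
# Association battery


def _pair_to_load(pair: str) -> int:
    """Behavioral load paired with a similarity pair: the higher load."""
    return int(pair.split("-")[0].removeprefix("dot").split("r")[0])


def association_battery(similarities: pd.DataFrame, behavior: pd.DataFrame,
                        metadata: pd.DataFrame, config: StatsConfig | None = None,
                        outcomes: Sequence[str] = ("accuracy",),
                        with_bootstrap: bool = False) -> pd.DataFrame:
    """Per age group: partial Spearman between FC similarity and behavior.

    Pairing rule: rest–task pair dotℓ–rest and stepwise pair higher–lower
    both map to behavior at the higher load ℓ.  Covariates: age, sex, mean
    task FD; rest–task comparisons add mean rest FD; the older group adds
    scanner.  Global scopes are judged at uncorrected α; intra/inter scopes
    at the 9-network Bonferroni gate.
    """
    config = config or StatsConfig()
    need_meta = {"subject", "age_group", "age", "sex", "task_motion", "rest_motion", "scanner"}
    if not need_meta <= set(metadata.columns):
        raise SchemaError(f"metadata needs columns {sorted(need_meta)}")
    rows = []
    sim = similarities.merge(metadata, on="subject", how="left", validate="many_to_one")
    if sim["age_group"].isna().any():
        bad = sorted(sim.loc[sim["age_group"].isna(), "subject"].unique())
        raise JoinError(f"subjects missing from metadata: {bad[:5]}")
    for (group, comparison, pair, scope), grp in sim.groupby(
            ["age_group", "comparison", "pair", "scope"]):
        load = _pair_to_load(pair)
        beh = behavior[behavior["load"] == load]
        for outcome in outcomes:
            tab = grp.merge(beh[["subject", outcome]], on="subject", how="inner")
            tab = tab.dropna(subset=["z", outcome])
            if len(tab) < 8:
                continue
            cov_cols = ["age", "sex_num", "task_motion"]
            tab["sex_num"] = (tab["sex"] == "F").astype(float)
            if comparison in ("rest_task", "within_load") or "rest" in pair:
                cov_cols.append("rest_motion")
            if group == "old" and tab["scanner"].nunique() > 1:
                tab["scanner_num"] = (tab["scanner"] == "post").astype(float)
                cov_cols.append("scanner_num")
            covs = tab[cov_cols].to_numpy()
            if with_bootstrap:
                res = bootstrap_se(tab["z"].to_numpy(), tab[outcome].to_numpy(),
                                   covs, config)
            else:
                res = partial_spearman(tab["z"].to_numpy(), tab[outcome].to_numpy(),
                                       covs, covariate_names=cov_cols)
            gate = "uncorrected" if scope == "global" else "bonferroni_networks"
            alpha = (config.family_alpha if scope == "global"
                     else config.per_network_alpha)
            rows.append({
                "age_group": group, "comparison": comparison, "pair": pair,
                "scope": scope, "outcome": outcome, "rho": res.rho, "p": res.p,
                "n": res.n, "bootstrap_se": res.bootstrap_se,
                "gate": gate, "significant": res.p < alpha,
                "covariates": ",".join(cov_cols),
            })
    return pd.DataFrame(rows)


def build_model_table(similarities: pd.DataFrame, metadata: pd.DataFrame,
                      comparison: str, scope: str = "global") -> pd.DataFrame:
    """Long-format table for fit_group_load_model from similarity records.

    For stepwise task–task pairs rest_motion is set to zero exactly.
    """
    sub = similarities[(similarities["comparison"] == comparison)
                       & (similarities["scope"] == scope)].copy()
    sub = sub.merge(metadata, on="subject", how="left", validate="many_to_one")
    if sub["age_group"].isna().any():
        bad = sorted(sub.loc[sub["age_group"].isna(), "subject"].unique())
        raise JoinError(f"subjects missing from metadata: {bad[:5]}")
    task_task = ~sub["pair"].str.contains("rest")
    sub.loc[task_task, "rest_motion"] = 0.0
    return pd.DataFrame({
        "Y": sub["z"].to_numpy(), "age_group": sub["age_group"],
        "load": sub["pair"], "sex": sub["sex"],
        "task_motion": sub["task_motion"], "rest_motion": sub["rest_motion"],
        "scanner": sub["scanner"], "subject": sub["subject"],
    }).reset_index(drop=True)


def build_behavior_model_table(behavior: pd.DataFrame, metadata: pd.DataFrame,
                               outcome: str = "accuracy") -> pd.DataFrame:
    tab = behavior.merge(metadata, on="subject", how="left", validate="many_to_one")
    if tab["age_group"].isna().any():
        bad = sorted(tab.loc[tab["age_group"].isna(), "subject"].unique())
        raise JoinError(f"subjects missing from metadata: {bad[:5]}")
    return pd.DataFrame({
        "Y": tab[outcome].to_numpy(), "age_group": tab["age_group"],
        "load": "dot" + tab["load"].astype(int).astype(str),
        "sex": tab["sex"], "task_motion": tab["task_motion"],
        "rest_motion": tab["rest_motion"], "scanner": tab["scanner"],
        "subject": tab["subject"],
    }).dropna(subset=["Y"]).reset_index(drop=True)
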