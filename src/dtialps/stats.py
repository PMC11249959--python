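"""Cohort statistics: descriptives, covariate-adjusted group comparisons
with FDR-corrected pre-defined contrasts, association models, ALPS
Z-score stratification, and the longitudinal mixed model of disease
severity.

Group comparisons are linear models ``outcome ~ group + covariates``
whose estimated marginal means (EMMs) are evaluated at the covariate
means (continuous) and observed marginal proportions (categorical).
Only the declared contrast family is tested, with Benjamini-Hochberg
adjustment inside the family.  The progression model is a linear mixed
model with random intercepts and slopes per subject, REML estimation
and Wald z inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

# Pre-defined comparison families (Fig-1-style): three stage-level
# contrasts, nine mutation-by-stage contrasts.
STAGE_FAMILY = (
    ("NC_young", "presymptomatic"),
    ("NC_old", "symptomatic"),
    ("presymptomatic", "symptomatic"),
)
MUTATION_STAGE_FAMILY = tuple(
    [("NC_young", f"presymptomatic_{m}") for m in ("C9orf72", "GRN", "MAPT")]
    + [("NC_old", f"symptomatic_{m}") for m in ("C9orf72", "GRN", "MAPT")]
    + [(f"presymptomatic_{m}", f"symptomatic_{m}") for m in ("C9orf72", "GRN", "MAPT")]
)


def expected_onset(age, family_mean_onset):
    """Years to expected onset: age minus the family's mean onset age.

    Negative values are before the expected onset.  Missing family
    onset propagates as NaN rather than raising.
    """
    age = np.asarray(age, dtype=float)
    onset = np.asarray(family_mean_onset, dtype=float)
    out = age - onset
    return float(out) if out.ndim == 0 else out


def stratify_alps(values, nc_mean: float, nc_sd: float):
    """Classify ALPS values as 'low' (Z < -1), 'high' (Z > 1) or 'average'.

    The Z = +/-1 boundaries fall in 'average' (the extreme classes are
    defined by strict inequalities).  The reference is the pooled
    non-carrier mean and SD.
    """
    if nc_sd <= 0:
        raise ValueError("nc_sd must be positive")
    z = (np.asarray(values, dtype=float) - nc_mean) / nc_sd
    out = np.where(z > 1, "high", np.where(z < -1, "low", "average"))
    return out if out.ndim else str(out)


def fdr_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def add_stage4(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add a 'stage4' column pooling carriers by stage and splitting NC by age class."""
    df = cohort.copy()
    df["stage4"] = np.where(
        df["mutation"] == "NC", "NC_" + df["nc_age_class"].astype(str), df["stage"]
    )
    return df


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def _build_design(df: pd.DataFrame, grouping: str | None, covariates,
                  group_levels=None):
    """Hand-built design matrix: intercept, treatment-coded group dummies,
    numeric covariates as-is, categorical covariates treatment-coded.

    Returns (X DataFrame, group_levels, covariate metadata) where the
    metadata records, per categorical covariate, its levels, enabling
    the EMM reference grid.
    """
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    if grouping is not None:
        if group_levels is None:
            group_levels = sorted(df[grouping].unique())
        for lev in group_levels[1:]:
            X[f"{grouping}[{lev}]"] = (df[grouping] == lev).astype(float)
    meta = {}
    for cov in covariates:
        s = df[cov]
        if _is_numeric(s):
            X[cov] = s.astype(float)
            meta[cov] = None
        else:
            levels = sorted(s.unique())
            for lev in levels[1:]:
                X[f"{cov}[{lev}]"] = (s == lev).astype(float)
            meta[cov] = levels
    return X, group_levels, meta


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy elimination
        cols, kept = list(X.columns), []
        for c in cols:
            trial = kept + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                kept.append(c)
        dropped = [c for c in cols if c not in kept]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dropped}")


@dataclass
class EMMResult:
    """Estimated marginal means and the pre-defined contrast family."""

    emms: dict[str, dict]                 # group -> {emm, se, n}
    contrasts: list[dict]                 # {a, b, estimate, se, p_raw, p_fdr}
    outcome: str
    grouping: str
    covariates: tuple[str, ...]
    model_df_resid: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "grouping": self.grouping,
            "covariates": list(self.covariates),
            "emms": self.emms, "contrasts": self.contrasts,
        }


def adjusted_group_comparison(cohort: pd.DataFrame, outcome: str, grouping: str,
                              covariates=("age", "sex", "site"),
                              family=None) -> EMMResult:
    """Covariate-adjusted linear model with EMMs and FDR-corrected contrasts.

    ``family`` is the declared list of (group_a, group_b) pairs; only
    those are tested and the BH correction runs within this family.
    Missing outcome values are dropped (complete-case).
    """
    df = cohort.dropna(subset=[outcome, grouping, *covariates])
    counts = df[grouping].value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each compared group needs >= 2 subjects and >= 2 groups present")
    levels = sorted(counts.index)
    if family is None:
        family = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    for a, b in family:
        if a not in levels or b not in levels:
            raise ValueError(f"contrast ({a}, {b}) references a group absent from the data")

    X, levels, meta = _build_design(df, grouping, covariates, group_levels=levels)
    _check_full_rank(X)
    res = sm.OLS(df[outcome].astype(float), X).fit()

    # EMM reference row: covariate means / observed level proportions
    ref = pd.Series(0.0, index=X.columns)
    ref["const"] = 1.0
    for cov in covariates:
        if meta[cov] is None:
            ref[cov] = df[cov].astype(float).mean()
        else:
            for lev in meta[cov][1:]:
                ref[f"{cov}[{lev}]"] = (df[cov] == lev).mean()

    cov_params = res.cov_params()
    emms = {}
    rows = {}
    for g in levels:
        row = ref.copy()
        for lev in levels[1:]:
            row[f"{grouping}[{lev}]"] = 1.0 if lev == g else 0.0
        rows[g] = row
        est = float(row @ res.params)
        se = float(np.sqrt(row @ cov_params @ row))
        emms[g] = {"emm": est, "se": se, "n": int(counts[g])}

    contrasts = []
    for a, b in family:
        l_vec = rows[a] - rows[b]
        est = float(l_vec @ res.params)
        se = float(np.sqrt(l_vec @ cov_params @ l_vec))
        t = est / se
        p = 2 * sps.t.sf(abs(t), res.df_resid)
        contrasts.append({"a": a, "b": b, "estimate": est, "se": se, "p_raw": float(p)})
    adj = fdr_adjust([c["p_raw"] for c in contrasts])
    for c, pa in zip(contrasts, adj):
        c["p_fdr"] = float(pa)
        c["significant"] = bool(pa < 0.05)

    return EMMResult(emms=emms, contrasts=contrasts, outcome=outcome,
                     grouping=grouping, covariates=tuple(covariates),
                     model_df_resid=float(res.df_resid))


@dataclass
class AssociationFit:
    beta: float
    se: float
    p: float
    n: int
    r_squared: float
    x: str
    y: str
    log_y: bool

    def to_dict(self) -> dict:
        return {"x": self.x, "y": self.y, "log_y": self.log_y, "beta": self.beta,
                "se": self.se, "p": self.p, "n": self.n, "r_squared": self.r_squared}


def association_model(cohort: pd.DataFrame, y: str, x: str,
                      covariates=("age", "sex", "site"),
                      log_transform_y: bool = False) -> AssociationFit:
    """Linear association of y with x, adjusted for covariates.

    Plasma outcomes are natural-log transformed when requested;
    non-positive values under the log are an error naming the subjects.
    """
    df = cohort.dropna(subset=[y, x, *covariates])
    if len(df) < len(covariates) + 3:
        raise ValueError(f"too few complete cases ({len(df)}) for the model")
    yv = df[y].astype(float)
    if log_transform_y:
        bad = df.loc[yv <= 0, "id"].tolist() if "id" in df else list(df.index[yv <= 0])
        if bad:
            raise ValueError(f"non-positive {y} values under log transform for: {bad}")
        yv = np.log(yv)
    X, _, _ = _build_design(df, None, [x, *covariates])
    _check_full_rank(X)
    res = sm.OLS(yv, X).fit()
    return AssociationFit(
        beta=float(res.params[x]), se=float(res.bse[x]),
        p=float(res.pvalues[x]), n=int(len(df)),
        r_squared=float(res.rsquared), x=x, y=y, log_y=log_transform_y,
    )


@dataclass
class LMMFit:
    """Longitudinal mixed-model output.

    ``stratum_slopes`` are the per-stratum time slopes (time coefficient
    plus the stratum's interaction term); ``slope_contrasts`` their
    pairwise differences, both with Wald z p-values.
    """

    fixed_effects: dict[str, dict]        # name -> {estimate, se, p}
    stratum_slopes: dict[str, dict]       # stratum -> {slope, se, ci_low, ci_high, p}
    slope_contrasts: list[dict]           # {a, b, estimate, se, p}
    vc: dict[str, float]                  # variance components
    interaction_test: dict                # joint Wald chi2 on the interaction terms
    converged: bool
    n_subjects: int
    n_obs: int
    diagnostics: str = ""

    def to_dict(self) -> dict:
        return {
            "fixed_effects": self.fixed_effects,
            "stratum_slopes": self.stratum_slopes,
            "slope_contrasts": self.slope_contrasts,
            "vc": self.vc, "interaction_test": self.interaction_test,
            "converged": self.converged,
            "n_subjects": self.n_subjects, "n_obs": self.n_obs,
        }


def lmm_progression(visits: pd.DataFrame, cohort: pd.DataFrame,
                    covariates=("age", "sex", "site"),
                    outcome: str = "cdr_ftld_latent",
                    reference_stratum: str = "average") -> LMMFit:
    """Mixed model of longitudinal severity by baseline ALPS stratum.

    Fixed effects: time, stratum, stratum x time, the covariates and
    baseline severity; random intercept and slope per subject (REML).
    Requires a 'stratum' column on the visits (as produced by the
    longitudinal generator) or a 'stratum' column on the cohort.
    """
    if outcome not in visits.columns:
        outcome = "cdr_ftld"
    base_cols = ["id", *covariates, "cdr_ftld_latent"]
    merged = visits.merge(cohort[base_cols].rename(
        columns={"cdr_ftld_latent": "baseline_cdr"}), on="id", how="left")
    merged = merged.dropna(subset=[outcome, "time", "stratum", "baseline_cdr", *covariates])
    n_per = merged.groupby("id")["time"].nunique()
    if (n_per >= 2).sum() == 0:
        raise ValueError("all subjects have a single visit; no slope is identifiable")

    strata = [s for s in ("low", "average", "high") if s in set(merged["stratum"])]
    if reference_stratum not in strata:
        reference_stratum = strata[0]
    others = [s for s in strata if s != reference_stratum]
    X = pd.DataFrame({"const": np.ones(len(merged))}, index=merged.index)
    X["time"] = merged["time"].astype(float)
    for s in others:
        X[f"stratum[{s}]"] = (merged["stratum"] == s).astype(float)
        X[f"time:stratum[{s}]"] = X[f"stratum[{s}]"] * X["time"]
    X["baseline_cdr"] = merged["baseline_cdr"].astype(float)
    for cov in covariates:
        s = merged[cov]
        if _is_numeric(s):
            X[cov] = s.astype(float)
        else:
            for lev in sorted(s.unique())[1:]:
                X[f"{cov}[{lev}]"] = (s == lev).astype(float)
    _check_full_rank(X)

    exog_re = X[["const", "time"]]
    model = sm.MixedLM(merged[outcome].astype(float), X, groups=merged["id"],
                       exog_re=exog_re)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
            if not res.converged:
                res = model.fit(reml=True, method="powell", maxiter=500)
        except Exception:
            res = model.fit(reml=True, method="powell", maxiter=500)
    converged = bool(res.converged)

    params = res.params[: X.shape[1]]
    bse = res.bse[: X.shape[1]]
    cov_fe = res.cov_params().iloc[: X.shape[1], : X.shape[1]]
    fixed = {
        name: {"estimate": float(params[name]), "se": float(bse[name]),
               "p": float(2 * sps.norm.sf(abs(params[name] / bse[name])))}
        for name in X.columns
    }

    def _wald(l_vec: pd.Series):
        est = float(l_vec @ params)
        var = max(float(l_vec @ cov_fe.to_numpy() @ l_vec), 0.0)  # guard round-off
        se = float(np.sqrt(var))
        z = est / se if se > 0 else np.inf * np.sign(est)
        return est, se, float(2 * sps.norm.sf(abs(z)))

    slope_rows = {}
    for s in strata:
        l_vec = pd.Series(0.0, index=X.columns)
        l_vec["time"] = 1.0
        if s != reference_stratum:
            l_vec[f"time:stratum[{s}]"] = 1.0
        slope_rows[s] = l_vec
    stratum_slopes = {}
    for s, l_vec in slope_rows.items():
        est, se, p = _wald(l_vec)
        stratum_slopes[s] = {"slope": est, "se": se,
                             "ci_low": est - 1.959963984540054 * se,
                             "ci_high": est + 1.959963984540054 * se, "p": p}
    slope_contrasts = []
    for i, a in enumerate(strata):
        for b in strata[i + 1:]:
            est, se, p = _wald(slope_rows[a] - slope_rows[b])
            slope_contrasts.append({"a": a, "b": b, "estimate": est, "se": se, "p": p})

    inter_names = [f"time:stratum[{s}]" for s in others]
    if inter_names:
        beta = params[inter_names].to_numpy()
        vmat = cov_fe.loc[inter_names, inter_names].to_numpy()
        chi2 = float(beta @ np.linalg.solve(vmat, beta))
        dof = len(inter_names)
        inter = {"chi2": chi2, "df": dof, "p": float(sps.chi2.sf(chi2, dof))}
    else:
        inter = {"chi2": 0.0, "df": 0, "p": 1.0}

    vc = {
        "var_intercept": float(res.cov_re.iloc[0, 0]),
        "var_slope": float(res.cov_re.iloc[1, 1]),
        "cov_intercept_slope": float(res.cov_re.iloc[0, 1]),
        "var_residual": float(res.scale),
    }
    return LMMFit(fixed_effects=fixed, stratum_slopes=stratum_slopes,
                  slope_contrasts=slope_contrasts, vc=vc,
                  interaction_test=inter, converged=converged,
                  n_subjects=int(merged["id"].nunique()), n_obs=int(len(merged)),
                  diagnostics="" if converged else "optimizer did not converge")


def describe_cohort(cohort: pd.DataFrame, grouping: str,
                    variables=None) -> pd.DataFrame:
    """Per-group descriptives with omnibus tests.

    Continuous variables: mean (SD) per group and a Kruskal-Wallis rank
    sum p-value.  Categorical variables: % (n) per group and a
    chi-square test of equal proportions (no continuity correction).
    All-missing variables are omitted with a warning.
    """
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in (grouping, "id") and not c.startswith("_")]
    groups = sorted(cohort[grouping].dropna().unique())
    out_rows = []
    for var in variables:
        s = cohort[var]
        if s.dropna().empty:
            warnings.warn(f"variable {var!r} is all-missing; omitted from the table")
            continue
        row = {"variable": var}
        if _is_numeric(s):
            samples = []
            for g in groups:
                vals = s[cohort[grouping] == g].dropna().astype(float)
                row[g] = f"{vals.mean():.2f} ({vals.std(ddof=1):.2f})" if len(vals) else "-"
                if len(vals):
                    samples.append(vals.to_numpy())
            if len(samples) >= 2:
                if len(np.unique(np.concatenate(samples))) == 1:
                    row["p"] = 1.0  # all values identical: H = 0 by definition
                else:
                    row["p"] = float(sps.kruskal(*samples).pvalue)
            else:
                row["p"] = np.nan
        else:
            levels = sorted(s.dropna().unique())
            target = levels[0]
            table = []
            for g in groups:
                vals = s[cohort[grouping] == g].dropna()
                k = int((vals == target).sum())
                n = int(len(vals))
                row[g] = f"{100 * k / n:.0f}% ({k})" if n else "-"
                if n:
                    table.append([k, n - k])
            tab = np.asarray(table)
            if tab.shape[0] >= 2 and tab.sum(axis=0).min() > 0:
                row["p"] = float(sps.chi2_contingency(tab, correction=False).pvalue)
            else:
                row["p"] = np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)
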