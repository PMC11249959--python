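"""GENFI-like synthetic cohorts: cross-sectional tables and longitudinal visits.

The generator reproduces the statistical structure the analyses assume:
eight demographic groups (young/old non-carriers; presymptomatic and
symptomatic C9orf72 / GRN / MAPT carriers) with group-level ALPS means,
covariate distributions, association slopes tying disease severity and
plasma markers to ALPS, and per-subject longitudinal severity
trajectories whose slope depends on the baseline ALPS stratum.

Group ALPS means and their standard errors follow the published
estimated marginal means; subject-level SDs are recovered as
SE * sqrt(n) per group, since only SEs are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUP_ORDER = (
    "NC_young", "NC_old",
    "presymptomatic_C9orf72", "presymptomatic_GRN", "presymptomatic_MAPT",
    "symptomatic_C9orf72", "symptomatic_GRN", "symptomatic_MAPT",
)

# label -> (n, alps_mean, alps_se, age_mean, age_sd, female_frac, edu_mean, edu_sd)
_GROUP_DEFAULTS = {
    "NC_young":               (50, 1.32, 0.02, 40, 6, 0.58, 15, 3),
    "NC_old":                 (33, 1.29, 0.03, 62, 7, 0.61, 14, 3),
    "presymptomatic_C9orf72": (68, 1.28, 0.02, 44, 11, 0.59, 14, 3),
    "presymptomatic_GRN":     (88, 1.32, 0.02, 45, 12, 0.68, 15, 4),
    "presymptomatic_MAPT":    (43, 1.28, 0.03, 39, 9, 0.56, 15, 3),
    "symptomatic_C9orf72":    (44, 1.19, 0.03, 62, 8, 0.34, 13, 3),
    "symptomatic_GRN":        (31, 1.24, 0.03, 62, 9, 0.42, 12, 3),
    "symptomatic_MAPT":       (17, 1.21, 0.04, 59, 10, 0.35, 15, 3),
}


@dataclass(frozen=True)
class GroupSpec:
    n: int
    alps_mean: float
    alps_se: float
    age_mean: float
    age_sd: float
    female_frac: float
    edu_mean: float
    edu_sd: float

    @property
    def alps_sd(self) -> float:
        # Table prints SEs of estimated marginal means; subject SD = SE * sqrt(n)
        return self.alps_se * np.sqrt(self.n)


@dataclass(frozen=True)
class CohortSpec:
    """Cross-sectional generator settings.

    Association slopes are the generative truths the fitted models are
    expected to recover: severity (CDR-FTLD) and log-plasma markers are
    linear in ALPS with the given coefficients; years to expected onset
    is linear in ALPS for presymptomatic carriers.
    """

    groups: dict[str, GroupSpec] = field(default_factory=lambda: {
        k: GroupSpec(*v) for k, v in _GROUP_DEFAULTS.items()
    })
    cdr_slope: float = -1.16
    cdr_intercept: float = 2.0
    cdr_noise_sd: float = 0.5
    log_nfl_slope: float = -0.28
    log_nfl_intercept: float = 3.35
    log_nfl_noise_sd: float = 0.5
    log_gfap_slope: float = -0.10
    log_gfap_intercept: float = 4.92
    log_gfap_noise_sd: float = 0.4
    onset_slope: float = -9.94
    onset_intercept: float = -2.1
    onset_noise_sd: float = 10.0
    nfl_missing_frac: float = 90 / 374
    gfap_missing_frac: float = 139 / 374
    n_sites: int = 5
    n_plasma_sites: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for label, g in self.groups.items():
            if label not in GROUP_ORDER:
                raise ValueError(f"unknown group label {label!r}")
            if g.n < 0:
                raise ValueError(f"{label}: group size must be >= 0")
            if g.alps_se < 0 or g.age_sd < 0:
                raise ValueError(f"{label}: dispersions must be >= 0")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def make_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """One row per subject.

    Columns: id, group, mutation (C9orf72/GRN/MAPT/NC), stage
    (presymptomatic/symptomatic/NA), nc_age_class (young/old/NA), age,
    sex, site, plasma_site, education, alps_left/right/mean, cdr_ftld
    (instrument scale: floored at 0, rounded to 0.5), cdr_ftld_latent,
    years_to_onset (carriers), nfl, gfap.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for label in GROUP_ORDER:
        g = spec.groups.get(label)
        if g is None or g.n == 0:
            continue
        if label.startswith("NC_"):
            mutation, stage = "NC", "NA"
            nc_age_class = label.split("_")[1]
        else:
            stage, mutation = label.split("_", 1)
            nc_age_class = "NA"
        for _ in range(g.n):
            sid += 1
            alps = rng.normal(g.alps_mean, g.alps_sd)
            # hemispheric indices scatter around the bilateral mean
            delta = rng.normal(0.0, 0.02)
            rows.append({
                "id": f"S{sid:04d}",
                "group": label,
                "mutation": mutation,
                "stage": stage,
                "nc_age_class": nc_age_class,
                "age": float(np.clip(rng.normal(g.age_mean, g.age_sd), 18, 95)),
                "sex": "F" if rng.random() < g.female_frac else "M",
                "site": f"site{rng.integers(spec.n_sites) + 1}",
                "plasma_site": f"lab{rng.integers(spec.n_plasma_sites) + 1}",
                "education": float(np.clip(rng.normal(g.edu_mean, g.edu_sd), 5, 25)),
                "alps_mean": alps,
                "alps_left": alps + delta,
                "alps_right": alps - delta,
            })
    df = pd.DataFrame(rows)
    carrier = df["mutation"] != "NC"

    cdr_latent = (spec.cdr_intercept + spec.cdr_slope * df["alps_mean"]
                  + rng.normal(0, spec.cdr_noise_sd, len(df)))
    df["cdr_ftld_latent"] = np.where(carrier, cdr_latent,
                                     np.abs(rng.normal(0, 0.1, len(df))))
    df["cdr_ftld"] = np.round(np.clip(df["cdr_ftld_latent"], 0, None) * 2) / 2

    log_nfl = (spec.log_nfl_intercept + spec.log_nfl_slope * df["alps_mean"]
               + rng.normal(0, spec.log_nfl_noise_sd, len(df)))
    log_gfap = (spec.log_gfap_intercept + spec.log_gfap_slope * df["alps_mean"]
                + rng.normal(0, spec.log_gfap_noise_sd, len(df)))
    df["nfl"] = np.exp(log_nfl)
    df["gfap"] = np.exp(log_gfap)
    df.loc[rng.random(len(df)) < spec.nfl_missing_frac, "nfl"] = np.nan
    df.loc[rng.random(len(df)) < spec.gfap_missing_frac, "gfap"] = np.nan

    yto = np.full(len(df), np.nan)
    presym = (df["stage"] == "presymptomatic").to_numpy()
    sym = (df["stage"] == "symptomatic").to_numpy()
    yto[presym] = (spec.onset_intercept
                   + spec.onset_slope * df.loc[presym, "alps_mean"]
                   + rng.normal(0, spec.onset_noise_sd, presym.sum()))
    yto[sym] = np.abs(rng.normal(3.0, 3.0, sym.sum()))  # past expected onset
    df["years_to_onset"] = yto
    return df


@dataclass(frozen=True)
class LongitudinalSpec:
    """Visit-level generator settings.

    ``visit_count_probs`` gives the probability of a carrier having
    1..6 visits; the default mirrors the published follow-up pattern
    (282 baseline-only-or-more, 180 with >= 2 evaluations ... 640
    evaluations in total).  ``stratum_slopes`` are CDR-FTLD units/year
    for low / average / high baseline ALPS.
    """

    visit_count_probs: tuple[float, ...] = (
        102 / 282, 75 / 282, 50 / 282, 40 / 282, 12 / 282, 3 / 282)
    visit_spacing_years: float = 1.0
    stratum_slopes: dict[str, float] = field(default_factory=lambda: {
        "low": 0.20, "average": 0.05, "high": -0.01})
    random_intercept_sd: float = 0.15
    random_slope_sd: float = 0.04
    residual_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.stratum_slopes
        if not (s["low"] >= s["average"] >= s["high"]):
            raise ValueError(
                "stratum slopes must be ordered slope(low) >= slope(average) >= slope(high)")
        if min(self.random_intercept_sd, self.random_slope_sd, self.residual_sd) < 0:
            raise ValueError("SDs must be >= 0")
        if abs(sum(self.visit_count_probs) - 1.0) > 1e-9:
            raise ValueError("visit_count_probs must sum to 1")

    def with_seed(self, seed: int) -> "LongitudinalSpec":
        return replace(self, seed=seed)


def nc_reference(cohort: pd.DataFrame, column: str = "alps_mean"):
    """Pooled mean and SD of the ALPS index over all non-carriers."""
    nc = cohort.loc[cohort["mutation"] == "NC", column]
    if len(nc) < 2:
        raise ValueError("need >= 2 non-carriers for the Z-score reference")
    return float(nc.mean()), float(nc.std(ddof=1))


def make_longitudinal(cohort: pd.DataFrame,
                      spec: LongitudinalSpec = LongitudinalSpec()) -> pd.DataFrame:
    """Visit table for mutation carriers.

    CDR-FTLD at time t is baseline + (stratum slope + subject random
    slope) * t + random intercept + residual noise; the instrument-scale
    column is floored at 0, the latent column is kept continuous.
    Strata come from baseline ALPS Z-scores against the pooled
    non-carrier reference.
    """
    from .stats import stratify_alps

    rng = np.random.default_rng(spec.seed)
    nc_mean, nc_sd = nc_reference(cohort)
    carriers = cohort[cohort["mutation"] != "NC"]
    strata = stratify_alps(carriers["alps_mean"].to_numpy(), nc_mean, nc_sd)

    n_counts = len(spec.visit_count_probs)
    rows = []
    for (_, subj), stratum in zip(carriers.iterrows(), strata):
        k = int(rng.choice(n_counts, p=spec.visit_count_probs)) + 1
        b0 = rng.normal(0, spec.random_intercept_sd)
        b1 = rng.normal(0, spec.random_slope_sd)
        slope = spec.stratum_slopes[stratum] + b1
        base = subj["cdr_ftld_latent"]
        for v in range(k):
            t = v * spec.visit_spacing_years
            latent = base + slope * t + b0 + rng.normal(0, spec.residual_sd)
            rows.append({
                "id": subj["id"],
                "time": t,
                "stratum": stratum,
                "cdr_ftld_latent": latent,
                "cdr_ftld": max(latent, 0.0),
            })
    return pd.DataFrame(rows)
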