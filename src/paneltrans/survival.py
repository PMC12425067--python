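"""Incidence, Kaplan–Meier, time-varying Cox regression and its diagnostics.

The regression engine is the counting-process Cox partial likelihood with
Efron tie handling (Newton–Raphson), as implemented by
:class:`lifelines.CoxTimeVaryingFitter`; this module defines the three preset
adjustment sets, the adversity exposure codings, the proportional-hazards
diagnostic on scaled Schoenfeld residuals, subgroup/interaction analysis and
the five sensitivity variants.

Model presets
-------------
* Model 1: age, sex, race.
* Model 2: Model 1 + marital status (married), education, living
  arrangement, alcohol, smoking, vigorous activity.
* Model 3: Model 2 + the seven chronic diseases and the three scale totals
  (depression, sleep, cognition) as time-varying covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohort import ALL_DISEASES, build_counting_process, collapse_to_subject

__all__ = [
    "MODEL_COVARIATES",
    "EXPOSURE_COLUMNS",
    "CoxFit",
    "incidence_rate",
    "person_years",
    "kaplan_meier",
    "fit_cox_timevarying",
    "fit_cox_baseline",
    "schoenfeld_ph_test",
    "subgroup_interaction",
    "run_sensitivity",
    "add_exposure_columns",
]

MODEL_COVARIATES = {
    1: ["age", "sex_male", "race_black", "race_other"],
    2: ["age", "sex_male", "race_black", "race_other", "married", "edu_high",
        "live_others", "alcohol", "smoke", "vig_act"],
    3: ["age", "sex_male", "race_black", "race_other", "married", "edu_high",
        "live_others", "alcohol", "smoke", "vig_act"] + ALL_DISEASES
        + ["cesd_total", "jss_total", "tics_total"],
}

EXPOSURE_COLUMNS = {
    "any": ["any_ace"],
    "type": ["ace_trauma", "ace_family", "ace_social"],
    "count": ["ace_count_1", "ace_count_2", "ace_count_3p"],
    "score": ["ace_total"],
}


@dataclass
class CoxFit:
    """Summary of a fitted proportional-hazards model."""

    summary: pd.DataFrame  # term, coef, hr, se, lo, hi, p
    log_likelihood: float
    n_events: int
    model: str
    fitter: object = None

    def hr(self, term: str) -> float:
        return float(self.summary.set_index("term").loc[term, "hr"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.summary.set_index("term").loc[term]
        return float(row["lo"]), float(row["hi"])


def incidence_rate(events: int, person_years: float) -> tuple[float, float, float]:
    """Incidence rate per 1000 person-years with a normal-approximation 95% CI
    (lower bound truncated at zero)."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    rate = 1000.0 * events / person_years
    se = 1000.0 * np.sqrt(events) / person_years
    return rate, max(0.0, rate - 1.96 * se), rate + 1.96 * se


def person_years(intervals: pd.DataFrame) -> float:
    return float((intervals["stop"] - intervals["start"]).sum())


def add_exposure_columns(intervals: pd.DataFrame) -> pd.DataFrame:
    """Add count-category dummies derived from ``ace_count_cat``."""
    out = intervals.copy()
    if "ace_count_cat" in out.columns:
        out["ace_count_1"] = (out["ace_count_cat"] == "1").astype(int)
        out["ace_count_2"] = (out["ace_count_cat"] == "2").astype(int)
        out["ace_count_3p"] = (out["ace_count_cat"] == "3+").astype(int)
    return out


def kaplan_meier(intervals: pd.DataFrame, group_col: str):
    """Per-group Kaplan–Meier curves (time to first outcome from baseline)
    and the log-rank p across groups.

    Groups with zero at-risk time are dropped with a warning.
    """
    subj = collapse_to_subject(intervals)
    curves = {}
    kept = []
    for g, grp in subj.groupby(group_col):
        if grp["duration"].sum() <= 0:
            import warnings

            warnings.warn(f"group {g!r} has zero at-risk time; dropped", stacklevel=2)
            continue
        km = KaplanMeierFitter(label=str(g))
        km.fit(grp["duration"], event_observed=grp["event"].astype(int))
        curves[g] = km
        kept.append(g)
    sub = subj[subj[group_col].isin(kept)]
    if len(kept) >= 2:
        lr = multivariate_logrank_test(sub["duration"], sub[group_col],
                                       sub["event"].astype(int))
        p = float(lr.p_value)
    else:
        p = np.nan
    return curves, p


def _summarize_lifelines(fitter, model: str) -> CoxFit:
    s = fitter.summary
    out = pd.DataFrame({
        "term": s.index,
        "coef": s["coef"].to_numpy(),
        "hr": np.exp(s["coef"].to_numpy()),
        "se": s["se(coef)"].to_numpy(),
        "lo": np.exp(s["coef"].to_numpy() - 1.96 * s["se(coef)"].to_numpy()),
        "hi": np.exp(s["coef"].to_numpy() + 1.96 * s["se(coef)"].to_numpy()),
        "p": s["p"].to_numpy(),
    }).reset_index(drop=True)
    n_events = int(getattr(fitter, "event_observed", pd.Series(dtype=float)).sum()) \
        if hasattr(fitter, "event_observed") else 0
    return CoxFit(summary=out, log_likelihood=float(fitter.log_likelihood_),
                  n_events=n_events, model=model, fitter=fitter)


def fit_cox_timevarying(intervals: pd.DataFrame, covariates, model: str = "custom") -> CoxFit:
    """Fit the counting-process Cox model with Efron ties.

    ``covariates`` is the explicit column list (exposure terms plus
    adjustments).  Raises on singular designs, naming the collinear columns.
    """
    covariates = list(covariates)
    if intervals["event"].sum() == 0:
        raise ValueError("no events in the data; Cox model not estimable")
    df = intervals[["id", "start", "stop", "event"] + covariates].copy()
    df["event"] = df["event"].astype(int)
    for c in covariates:
        df[c] = df[c].astype(float)
    const = [c for c in covariates if df[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant (non-estimable) covariates: {const}")
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    try:
        ctv.fit(df, id_col="id", event_col="event", start_col="start", stop_col="stop")
    except np.linalg.LinAlgError as exc:
        corr = df[covariates].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax()
        raise ValueError(f"singular information matrix; near-collinear covariates {pair}") from exc
    fit = _summarize_lifelines(ctv, model)
    fit.n_events = int(df["event"].sum())
    return fit


def fit_cox_baseline(subjects: pd.DataFrame, covariates) -> CoxFit:
    """Traditional Cox fit with all covariates frozen at baseline."""
    covariates = list(covariates)
    df = subjects[["duration", "event"] + covariates].copy()
    df["event"] = df["event"].astype(int)
    for c in covariates:
        df[c] = df[c].astype(float)
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col="duration", event_col="event")
    fit = _summarize_lifelines(cph, "baseline")
    fit.n_events = int(df["event"].sum())
    return fit


def schoenfeld_ph_test(fit: CoxFit, intervals: pd.DataFrame, covariates) -> pd.DataFrame:
    """Grambsch–Therneau proportional-hazards test on scaled Schoenfeld
    residuals, identity time transform.

    Regresses the scaled residuals on event time and forms the score-type
    chi-square per covariate plus a global test (term ``GLOBAL``).
    """
    covariates = list(covariates)
    d = int(intervals["event"].astype(bool).sum())
    if d <= len(covariates):
        raise ValueError("fewer events than covariates; residual test undefined")
    beta = fit.summary.set_index("term").loc[covariates, "coef"].to_numpy(dtype=float)
    order = list(fit.fitter.params_.index)
    Vfull = np.asarray(fit.fitter.variance_matrix_, dtype=float)
    idx = [order.index(c) for c in covariates]
    V = Vfull[np.ix_(idx, idx)]

    df = intervals[["start", "stop", "event"] + covariates].copy()
    events = df[df["event"].astype(bool)].sort_values("stop")

    X = df[covariates].to_numpy(dtype=float)
    start = df["start"].to_numpy(dtype=float)
    stop = df["stop"].to_numpy(dtype=float)
    risk_score = np.exp(X @ beta)

    resid = np.empty((d, len(covariates)))
    times = np.empty(d)
    for k, (_, ev) in enumerate(events.iterrows()):
        t = float(ev["stop"])
        at_risk = (start < t) & (stop >= t)
        w = risk_score[at_risk]
        xbar = (w[:, None] * X[at_risk]).sum(axis=0) / w.sum()
        resid[k] = ev[covariates].to_numpy(dtype=float) - xbar
        times[k] = t

    g = times - times.mean()
    gsum = float((g**2).sum())
    u = g @ resid  # length p, unscaled
    # per-covariate: scaled residuals r* = d V r, Var(Σ g r*) = d gsum V
    ustar = d * (resid @ V) * g[:, None]
    u_scaled = ustar.sum(axis=0)
    var_scaled = d * gsum * np.diag(V)
    chisq = u_scaled**2 / var_scaled
    rows = [{"term": c, "chisq": float(chisq[j]), "df": 1,
             "p": float(stats.chi2.sf(chisq[j], 1))} for j, c in enumerate(covariates)]
    global_chisq = float(d / gsum * (u @ V @ u))
    rows.append({"term": "GLOBAL", "chisq": global_chisq, "df": len(covariates),
                 "p": float(stats.chi2.sf(global_chisq, len(covariates)))})
    return pd.DataFrame(rows)


def subgroup_interaction(intervals: pd.DataFrame, modifier: str,
                         exposure: str = "any_ace", adjust=None) -> dict:
    """Stratified exposure effects plus a Wald interaction test.

    Fits the adjusted model within each level of a binary ``modifier`` and, in
    the pooled data, adds an exposure×modifier product term whose Wald p is
    the interaction test.  Strata without events are reported non-estimable.
    """
    adjust = list(adjust if adjust is not None else MODEL_COVARIATES[3])
    adjust = [c for c in adjust if c != modifier and c != exposure]
    result: dict = {"modifier": modifier, "strata": {}}
    for level, grp in intervals.groupby(modifier):
        sub_adjust = [c for c in adjust if grp[c].astype(float).nunique() > 1]
        try:
            if grp["event"].sum() == 0 or grp[exposure].astype(float).nunique() <= 1:
                raise ValueError("no events or constant exposure in stratum")
            fit = fit_cox_timevarying(grp, [exposure] + sub_adjust, model=f"{modifier}={level}")
            result["strata"][level] = {
                "hr": fit.hr(exposure), "ci": fit.ci(exposure),
                "p": float(fit.summary.set_index("term").loc[exposure, "p"]),
                "n_events": fit.n_events,
            }
        except (ValueError, np.linalg.LinAlgError) as exc:
            result["strata"][level] = {"non_estimable": str(exc)}
    pooled = intervals.copy()
    pooled["_interaction"] = pooled[exposure].astype(float) * pooled[modifier].astype(float)
    fit = fit_cox_timevarying(pooled, [exposure, modifier, "_interaction"] + adjust,
                              model="pooled")
    result["interaction_p"] = float(fit.summary.set_index("term").loc["_interaction", "p"])
    result["pooled_fit"] = fit
    return result


def run_sensitivity(variant: int, scored: pd.DataFrame, aces: pd.DataFrame,
                    exposure: str = "any", horizon: float | None = None) -> CoxFit:
    """The five robustness re-analyses of the main (Model 3) association.

    1. drop participants whose outcome occurs within two years of baseline;
    2. drop participants whose outcome occurs at their first follow-up
       interview;
    3. replace the seven disease indicators with their time-varying count;
    4. traditional Cox with every covariate frozen at baseline;
    5. Fine–Gray subdistribution-hazard model with death as the competing
       event (baseline covariates).
    """
    intervals = add_exposure_columns(build_counting_process(scored, aces, horizon=horizon))
    expo = EXPOSURE_COLUMNS[exposure]
    covars = expo + MODEL_COVARIATES[3]

    if variant == 1:
        ev = intervals[intervals["event"]]
        drop = set(ev.loc[ev["stop"] <= 2.0, "id"])
        return fit_cox_timevarying(intervals[~intervals["id"].isin(drop)], covars,
                                   model="sensitivity-1")
    if variant == 2:
        first = intervals.sort_values("start").groupby("id").head(1)
        drop = set(first.loc[first["event"], "id"])
        return fit_cox_timevarying(intervals[~intervals["id"].isin(drop)], covars,
                                   model="sensitivity-2")
    if variant == 3:
        iv = intervals.copy()
        iv["disease_count"] = iv[ALL_DISEASES].astype(float).sum(axis=1)
        covars3 = expo + [c for c in MODEL_COVARIATES[3] if c not in ALL_DISEASES] + \
            ["disease_count"]
        return fit_cox_timevarying(iv, covars3, model="sensitivity-3")
    if variant == 4:
        subjects = add_exposure_columns(collapse_to_subject(intervals))
        return fit_cox_baseline(subjects, covars)
    if variant == 5:
        from .competing import fit_fine_gray

        subjects = add_exposure_columns(collapse_to_subject(intervals))
        subjects["event_type"] = np.where(subjects["event"], 1,
                                          np.where(subjects["competing_death"], 2, 0))
        return fit_fine_gray(subjects, "duration", "event_type", covars)
    raise ValueError(f"unknown sensitivity variant {variant!r} (expected 1..5)")
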