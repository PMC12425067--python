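"""Cohort construction for biennial panel data.

The long cohort file has one row per participant per interview wave.  This
module reads and writes that format, fills gaps in time-varying covariates by
carrying observations forward (and backward at the series head), applies the
four inclusion criteria, classifies each participant-wave into one of five
health states, and expands the panel into counting-process risk intervals for
time-varying survival regression.

Five health states
------------------
1. no physical conditions and no mental-health symptoms,
2. physical conditions only (any of diabetes, stroke, heart disease, cancer),
3. mental-health symptoms only (depressive symptoms and/or cognitive
   impairment from the scored scales),
4. both physical conditions and mental-health symptoms,
5. physician-diagnosed psychiatric disorder — the absorbing state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scales import DEPRESSION_CUTOFF, IMPAIRMENT_CUTOFF, INSOMNIA_CUTOFF

__all__ = [
    "COHORT_COLUMNS",
    "ACE_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_aces",
    "write_aces",
    "impute_carry",
    "impute_cohort",
    "apply_inclusion",
    "score_cohort",
    "classify_state",
    "build_counting_process",
    "collapse_to_subject",
    "ace_frame",
    "PC_DISEASES",
    "COVARIATE_COLUMNS",
]

CESD_ITEMS = [f"cesd{i}" for i in range(1, 9)]
JSS_ITEMS = [f"jss{i}" for i in range(1, 5)]
TICS_ITEMS = ["tics_mem", "tics_att", "tics_calc"]

#: the four chronic conditions that define the "physical conditions" axis
PC_DISEASES = ["dm", "cancer", "heart", "stroke"]
ALL_DISEASES = PC_DISEASES + ["htn", "lung", "arthritis"]

COHORT_COLUMNS = (
    ["id", "wave", "time_years", "age", "sex", "race", "marital", "edu_high",
     "live_others", "vig_act", "alcohol", "smoke"]
    + ALL_DISEASES
    + CESD_ITEMS
    + JSS_ITEMS
    + TICS_ITEMS
    + ["psy_dx", "died", "observed"]
)

ACE_COLUMNS = ["id"] + [f"ace{i}" for i in range(1, 10)]

# columns eligible for carry-forward/backward imputation (per participant)
IMPUTABLE_COLUMNS = (
    ["marital", "edu_high", "live_others", "vig_act", "alcohol", "smoke"]
    + ALL_DISEASES
    + CESD_ITEMS
    + JSS_ITEMS
    + TICS_ITEMS
)

#: covariates carried onto counting-process intervals (besides scale totals)
COVARIATE_COLUMNS = (
    ["age", "sex_male", "race_black", "race_other", "married", "edu_high",
     "live_others", "vig_act", "alcohol", "smoke"]
    + ALL_DISEASES
    + ["cesd_total", "jss_total", "tics_total"]
)


def read_cohort(path) -> pd.DataFrame:
    """Read the long cohort CSV (empty fields are missing)."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str, "race": str, "marital": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    return df[COHORT_COLUMNS].sort_values(["id", "wave"], kind="stable").reset_index(drop=True)


def write_cohort(df: pd.DataFrame, path) -> None:
    df[COHORT_COLUMNS].to_csv(path, index=False)


def read_aces(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in ACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ACE file missing columns: {missing}")
    return df[ACE_COLUMNS]


def write_aces(df: pd.DataFrame, path) -> None:
    df[ACE_COLUMNS].to_csv(path, index=False)


def impute_carry(series, variable: str = "", participant: str = "") -> list:
    """Fill gaps by last observation carried forward, heads by next observation
    carried backward.  Raises if every value is missing."""
    values = list(series)
    is_missing = [v is None or (isinstance(v, float) and np.isnan(v)) for v in values]
    if all(is_missing):
        raise ValueError(
            f"cannot impute all-missing series (variable={variable!r}, participant={participant!r})"
        )
    out = list(values)
    last = None
    for i, (v, miss) in enumerate(zip(values, is_missing)):
        if miss:
            out[i] = last
        else:
            last = v
    # heads: carry the first observed value backward
    first = next(v for v, miss in zip(values, is_missing) if not miss)
    for i in range(len(out)):
        if out[i] is None:
            out[i] = first
        else:
            break
    return out


def impute_cohort(df: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Apply carry-forward/backward imputation per participant at observed waves.

    Unobserved waves (no interview) never gain rows; only gaps within a
    participant's observed rows are filled.
    """
    columns = list(columns) if columns is not None else list(IMPUTABLE_COLUMNS)
    out = df.sort_values(["id", "wave"], kind="stable").copy()
    obs = out["observed"] == 1
    for col in columns:
        grouped = out.loc[obs].groupby("id", sort=False)[col]
        filled = grouped.ffill()
        filled = filled.groupby(out.loc[obs, "id"], sort=False).bfill()
        still = filled.isna()
        if still.any():
            pid = out.loc[obs].loc[still, "id"].iloc[0]
            raise ValueError(
                f"cannot impute all-missing series (variable={col!r}, participant={pid!r})"
            )
        out.loc[obs, col] = filled
    return out


def apply_inclusion(cohort: pd.DataFrame, aces: pd.DataFrame, min_age: float = 50.0):
    """Apply the four inclusion criteria in order; return the filtered cohort
    and the number of participants removed at each step.

    Criteria: (1) age >= ``min_age`` at baseline; (2) interviewed at least
    once after baseline; (3) adversity inventory available; (4) free of the
    outcome diagnosis at baseline.
    """
    flow: dict[str, int] = {}
    obs = cohort[cohort["observed"] == 1]
    baseline = obs.sort_values("wave", kind="stable").groupby("id", sort=False).head(1)

    keep = set(baseline.loc[baseline["age"] >= min_age, "id"])
    flow["below_min_age"] = baseline["id"].nunique() - len(keep)

    n_obs = obs[obs["id"].isin(keep)].groupby("id").size()
    with_followup = set(n_obs[n_obs >= 2].index)
    flow["no_followup"] = len(keep) - len(with_followup)
    keep = with_followup

    ace_ids = set(aces.dropna(subset=[f"ace{i}" for i in range(1, 10)])["id"])
    with_ace = keep & ace_ids
    flow["no_ace_assessment"] = len(keep) - len(with_ace)
    keep = with_ace

    base_dx = set(baseline.loc[baseline["psy_dx"] == 1, "id"])
    final = keep - base_dx
    flow["baseline_disorder"] = len(keep) - len(final)

    filtered = cohort[cohort["id"].isin(final)].reset_index(drop=True)
    if filtered.empty:
        import warnings

        warnings.warn("inclusion filtering removed every participant", stacklevel=2)
    return filtered, flow


def classify_state(pc: bool, ms: bool, psy_dx: bool) -> int:
    """Map the physical-condition, mental-symptom and diagnosis flags to a state 1..5."""
    if psy_dx:
        return 5
    if pc and ms:
        return 4
    if ms:
        return 3
    if pc:
        return 2
    return 1


def score_cohort(
    df: pd.DataFrame,
    depression_cutoff: int = DEPRESSION_CUTOFF,
    insomnia_cutoff: int = INSOMNIA_CUTOFF,
    impairment_cutoff: int = IMPAIRMENT_CUTOFF,
) -> pd.DataFrame:
    """Score scales on every observed row and attach the five-level health state.

    Adds columns ``cesd_total``, ``depression_flag``, ``jss_total``,
    ``insomnia_flag``, ``tics_total``, ``cog_impair_flag``, ``pc``, ``ms``
    and ``state``.  Rows must be free of missing scale items (run
    :func:`impute_cohort` first).
    """
    out = df.copy()
    obs = out["observed"] == 1
    cesd = out.loc[obs, CESD_ITEMS].to_numpy(dtype=float)
    if np.isnan(cesd).any():
        raise ValueError("missing CESD items after imputation")
    rev = np.zeros(8)
    rev[[3, 5]] = 1  # items 4 and 6 reverse scored
    cesd_total = (cesd * (1 - rev) + (1 - cesd) * rev).sum(axis=1)

    jss = out.loc[obs, JSS_ITEMS].to_numpy(dtype=float)
    if np.isnan(jss).any():
        raise ValueError("missing JSS items after imputation")
    jss_total = (4 - jss[:, :3]).sum(axis=1) + jss[:, 3]

    tics = out.loc[obs, TICS_ITEMS].to_numpy(dtype=float)
    if np.isnan(tics).any():
        raise ValueError("missing TICS domains after imputation")
    tics_total = tics.sum(axis=1)

    out.loc[obs, "cesd_total"] = cesd_total
    out.loc[obs, "depression_flag"] = (cesd_total >= depression_cutoff).astype(float)
    out.loc[obs, "jss_total"] = jss_total
    out.loc[obs, "insomnia_flag"] = (jss_total >= insomnia_cutoff).astype(float)
    out.loc[obs, "tics_total"] = tics_total
    out.loc[obs, "cog_impair_flag"] = (tics_total <= impairment_cutoff).astype(float)

    pc = out.loc[obs, PC_DISEASES].to_numpy(dtype=float)
    if np.isnan(pc).any():
        raise ValueError("missing disease flags after imputation")
    pc_any = pc.max(axis=1)
    ms_any = np.maximum(out.loc[obs, "depression_flag"], out.loc[obs, "cog_impair_flag"])
    out.loc[obs, "pc"] = pc_any
    out.loc[obs, "ms"] = ms_any

    dx = out.loc[obs, "psy_dx"].to_numpy(dtype=float)
    state = np.where(dx == 1, 5, np.where((pc_any == 1) & (ms_any == 1), 4,
                     np.where(ms_any == 1, 3, np.where(pc_any == 1, 2, 1))))
    out.loc[obs, "state"] = state.astype(float)
    return out


def ace_frame(aces: pd.DataFrame) -> pd.DataFrame:
    """Per-participant adversity summary columns derived from the raw items."""
    item_cols = [f"ace{i}" for i in range(1, 10)]
    items = aces[item_cols].to_numpy(dtype=float) > 0
    total = items.sum(axis=1)
    out = pd.DataFrame({
        "id": aces["id"],
        "ace_total": total,
        "any_ace": (total > 0).astype(int),
        "ace_trauma": items[:, 0:4].any(axis=1).astype(int),
        "ace_family": items[:, 4:7].any(axis=1).astype(int),
        "ace_social": items[:, 7:9].any(axis=1).astype(int),
        "ace_count_cat": np.select([total == 0, total == 1, total == 2],
                                   ["0", "1", "2"], default="3+"),
    })
    return out.reset_index(drop=True)


def _encode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate encoding for model matrices (dummies for sex/race/marital)."""
    out = df.copy()
    out["sex_male"] = (out["sex"] == "male").astype(int)
    out["race_black"] = (out["race"] == "black").astype(int)
    out["race_other"] = (out["race"] == "other").astype(int)
    out["married"] = (out["marital"] == "married").astype(int)
    return out


def build_counting_process(scored: pd.DataFrame, aces: pd.DataFrame | None = None,
                           horizon: float | None = None) -> pd.DataFrame:
    """Expand a scored cohort into counting-process risk intervals.

    One interval per inter-wave gap, covariates frozen at the interval's
    opening wave.  ``event`` marks the interview at which the outcome
    diagnosis is first reported (right-endpoint convention); follow-up stops
    there.  A trailing exit row (``died=1, observed=0``) extends the last
    interval to the exit time with ``competing_death`` set.
    """
    df = _encode_covariates(scored).sort_values(["id", "wave"], kind="stable")
    bad = df.groupby("id")["time_years"].diff().le(0)
    if bad.any():
        pid = df.loc[bad, "id"].iloc[0]
        raise ValueError(f"non-monotone interview times for participant {pid!r}")

    visits = df[df["observed"] == 1].copy()
    grp = visits.groupby("id", sort=False)
    visits["_stop"] = grp["time_years"].shift(-1)
    visits["_next_dx"] = grp["psy_dx"].shift(-1)
    base = visits[visits["_stop"].notna()].copy()
    base["start"] = base["time_years"]
    base["stop"] = base["_stop"]
    base["event"] = base["_next_dx"] == 1
    base["competing_death"] = False
    # follow-up stops at the first reported diagnosis
    cum = base.groupby("id", sort=False)["event"].cumsum()
    base = base[(cum == 0) | ((cum == 1) & base["event"])]

    # a recorded exit (death) after the last interview marks the final
    # interval of never-diagnosed subjects as ending in the competing event;
    # follow-up time itself still ends at the last interview
    exits = df[(df["observed"] == 0) & (df["died"] == 1)]
    if not exits.empty:
        event_ids = set(base.loc[base["event"], "id"])
        died_ids = set(exits["id"]) - event_ids
        last_idx = base[base["id"].isin(died_ids)].groupby("id", sort=False).tail(1).index
        base.loc[last_idx, "competing_death"] = True

    cols = ["id", "start", "stop", "event", "competing_death"] + COVARIATE_COLUMNS
    intervals = base[cols].copy()
    if horizon is not None and not intervals.empty:
        intervals = intervals[intervals["start"] < horizon].copy()
        over = intervals["stop"] > horizon
        intervals.loc[over, "stop"] = horizon
        intervals.loc[over, "event"] = False
    if intervals.empty:
        return intervals
    intervals = intervals.sort_values(["id", "start"], kind="stable").reset_index(drop=True)
    if aces is not None:
        intervals = intervals.merge(ace_frame(aces), on="id", how="left")
    return intervals


def collapse_to_subject(intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-subject summary of the counting process: follow-up time from
    baseline, event indicator, competing-death indicator and baseline
    (first-interval) covariates."""
    iv = intervals.sort_values(["id", "start"], kind="stable")
    if "competing_death" not in iv.columns:
        iv = iv.assign(competing_death=False)
    grp = iv.groupby("id", sort=False)
    first = iv.drop_duplicates("id", keep="first").set_index("id")
    last = iv.drop_duplicates("id", keep="last").set_index("id")
    out = first.drop(columns=["start", "stop", "event", "competing_death"]).copy()
    out["duration"] = last["stop"].astype(float)
    out["event"] = grp["event"].any()
    out["competing_death"] = last["competing_death"].astype(bool)
    return out.reset_index()
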