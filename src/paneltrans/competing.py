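"""Competing-risk estimation: Aalen–Johansen cumulative incidence and the
Fine–Gray subdistribution-hazard model.

Death can preclude the outcome diagnosis, so the naive one-minus-KM curve
overstates cumulative incidence.  The Aalen–Johansen estimator allocates risk
mass between the two causes so that CIF₁(t) + CIF₂(t) + S(t) = 1 exactly at
every time.  The Fine–Gray model regresses the subdistribution hazard — the
hazard of the outcome keeping competing-event subjects in the risk set — on
baseline covariates, with inverse-probability-of-censoring weights from the
censoring-distribution Kaplan–Meier (Geskus's counting-process construction);
the weighted Efron partial likelihood is maximised by
:class:`lifelines.CoxTimeVaryingFitter`.  With no competing events the
construction reduces exactly to the ordinary Cox model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxTimeVaryingFitter

from .survival import CoxFit, _summarize_lifelines

__all__ = ["aalen_johansen_cif", "fit_fine_gray", "censoring_survival"]


def aalen_johansen_cif(durations, event_types) -> pd.DataFrame:
    """Aalen–Johansen cumulative incidence for two competing causes.

    ``event_types``: 0 = censored, 1 = primary outcome, 2 = competing event.
    Returns a step-function table with columns ``t``, ``cif1``, ``cif2`` and
    ``surv``; the three sum to one at every step.
    """
    durations = np.asarray(durations, dtype=float)
    event_types = np.asarray(event_types, dtype=int)
    if durations.shape != event_types.shape:
        raise ValueError("durations and event_types must have the same length")
    order = np.argsort(durations, kind="stable")
    durations, event_types = durations[order], event_types[order]

    rows = [{"t": 0.0, "cif1": 0.0, "cif2": 0.0, "surv": 1.0}]
    n = len(durations)
    surv, cif1, cif2 = 1.0, 0.0, 0.0
    i = 0
    while i < n:
        t = durations[i]
        j = i
        d1 = d2 = c = 0
        while j < n and durations[j] == t:
            d1 += event_types[j] == 1
            d2 += event_types[j] == 2
            c += event_types[j] == 0
            j += 1
        at_risk = n - i
        if d1 + d2 > 0:
            cif1 += surv * d1 / at_risk
            cif2 += surv * d2 / at_risk
            surv *= 1.0 - (d1 + d2) / at_risk
            rows.append({"t": t, "cif1": cif1, "cif2": cif2, "surv": surv})
        i = j
    return pd.DataFrame(rows)


def censoring_survival(durations, event_types):
    """Kaplan–Meier of the censoring distribution, returned as a left-limit
    evaluator G(t−): treats censorings as events and events as censorings."""
    durations = np.asarray(durations, dtype=float)
    censored = np.asarray(event_types, dtype=int) == 0
    order = np.argsort(durations, kind="stable")
    durations, censored = durations[order], censored[order]
    times, values = [0.0], [1.0]
    n = len(durations)
    surv = 1.0
    i = 0
    while i < n:
        t = durations[i]
        j = i
        d = 0
        while j < n and durations[j] == t:
            d += censored[j]
            j += 1
        if d > 0:
            surv *= 1.0 - d / (n - i)
            times.append(t)
            values.append(surv)
        i = j
    times = np.asarray(times)
    values = np.asarray(values)

    def g_minus(t: float) -> float:
        # value just before t: last step strictly below t
        idx = np.searchsorted(times, t, side="left") - 1
        return float(values[max(idx, 0)])

    return g_minus


def fit_fine_gray(subjects: pd.DataFrame, duration_col: str, event_type_col: str,
                  covariates) -> CoxFit:
    """Fine–Gray subdistribution-hazard fit on baseline covariates.

    Subjects with the competing event stay in the risk set after their event
    time with weight G(t−)/G(T−) from the censoring Kaplan–Meier, piecewise
    constant between primary-event times.  Returns subdistribution hazard
    ratios with Wald intervals.
    """
    covariates = list(covariates)
    dur = subjects[duration_col].to_numpy(dtype=float)
    etype = subjects[event_type_col].to_numpy(dtype=int)
    if not np.isin(etype, [0, 1, 2]).all():
        raise ValueError("event types must be 0 (censored), 1 (outcome) or 2 (competing)")
    if (etype == 1).sum() == 0:
        raise ValueError("no primary events")
    g_minus = censoring_survival(dur, etype)
    event_times = np.unique(dur[etype == 1])

    rows = []
    X = subjects[covariates].astype(float).reset_index(drop=True)
    for i in range(len(subjects)):
        base = {"fg_id": i, **{c: X.loc[i, c] for c in covariates}}
        t_i, e_i = dur[i], etype[i]
        rows.append({**base, "start": 0.0, "stop": t_i, "event": int(e_i == 1), "w": 1.0})
        if e_i == 2:
            g_T = g_minus(t_i)
            prev = t_i
            for t_e in event_times[event_times > t_i]:
                w = g_minus(t_e) / g_T if g_T > 0 else 0.0
                if w <= 0:
                    break
                rows.append({**base, "start": prev, "stop": t_e, "event": 0, "w": w})
                prev = t_e
    df = pd.DataFrame(rows)
    ctv = CoxTimeVaryingFitter(penalizer=0.0)
    ctv.fit(df, id_col="fg_id", event_col="event", start_col="start", stop_col="stop",
            weights_col="w")
    fit = _summarize_lifelines(ctv, "fine-gray")
    fit.n_events = int((etype == 1).sum())
    return fit
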