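"""Panel-observed five-state continuous-time Markov model.

States 1–4 are transient, state 5 (psychiatric disorder) is absorbing.  The
process is observed only at interview times, so the likelihood of a pair of
consecutive observations (s_k at t_k, s_{k+1} at t_{k+1}) is the matrix
exponential entry P(Δt)[s_k, s_{k+1}] with P(t) = exp(Qt).

A single binary or continuous covariate may act multiplicatively on every
allowed transition intensity, q_ij(z) = q⁰_ij · exp(β_ij z) — the panel
analogue of per-transition proportional hazards.  Parameters are estimated by
maximising the panel log-likelihood over log q⁰_ij (positivity without
constraints) and β_ij with L-BFGS-B, using analytic gradients computed from
Fréchet derivatives of the matrix exponential.  Standard errors come from the
inverse observed information (finite differences of the analytic gradient).

Death is treated as right-censoring here: a participant who dies simply
contributes no further observation pairs.  Competing-risk analysis of death
lives in :mod:`paneltrans.competing`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad_vec
from scipy.linalg import expm, expm_frechet
from scipy.optimize import minimize

__all__ = [
    "N_STATES",
    "default_transitions",
    "build_intensity_matrix",
    "transition_probability",
    "aggregate_panel",
    "panel_loglik",
    "fit_msm",
    "MsmFit",
    "msm_hazard_ratios",
    "probability_curves",
    "cumulative_absorption",
    "expected_duration",
    "empirical_transition_table",
    "extract_pairs",
]

N_STATES = 5
ABSORBING = 4  # 0-based index of state 5


def default_transitions() -> list[tuple[int, int]]:
    """All 16 allowed transitions: each transient state to every other state."""
    return [(i, j) for i in range(4) for j in range(N_STATES) if j != i]


def build_intensity_matrix(off_diagonals, covariates=None, betas=None,
                           transitions=None) -> np.ndarray:
    """Assemble a 5×5 intensity matrix Q.

    ``off_diagonals`` maps (i, j) (0-based) to the baseline intensity
    q⁰_ij ≥ 0; ``betas`` maps (i, j) to a per-transition log hazard ratio and
    ``covariates`` is the scalar covariate value z, giving
    q_ij(z) = q⁰_ij · exp(β_ij z).  Diagonals are set to minus the row sums
    and the absorbing row is identically zero.
    """
    if transitions is None:
        if isinstance(off_diagonals, dict):
            transitions = list(off_diagonals.keys())
            off_diagonals = [off_diagonals[t] for t in transitions]
        else:
            transitions = default_transitions()
    Q = np.zeros((N_STATES, N_STATES))
    for (i, j), q0 in zip(transitions, off_diagonals):
        if q0 < 0:
            raise ValueError(f"baseline intensity q[{i + 1}->{j + 1}] must be >= 0, got {q0}")
        if i == ABSORBING:
            raise ValueError("no transitions may leave the absorbing state")
        rate = float(q0)
        if betas is not None and covariates is not None:
            beta = betas.get((i, j), 0.0) if isinstance(betas, dict) else betas[(i, j)]
            rate *= np.exp(beta * covariates)
        Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=1)
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to one for a valid intensity matrix."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    P = expm(np.asarray(Q, dtype=float) * t)
    # matrix exponential can stray below 0 / above 1 by roundoff only
    return np.clip(P, 0.0, 1.0)


def extract_pairs(scored: pd.DataFrame, covariate: str | None = None) -> pd.DataFrame:
    """Consecutive observed state pairs per participant.

    Returns columns ``from_state``, ``to_state`` (1-based), ``dt`` and
    optionally the covariate value in force at the pair's opening interview.
    Pairs after absorption are not emitted (the absorbing state ends
    follow-up).
    """
    rows = []
    obs = scored[scored["observed"] == 1]
    for pid, grp in obs.sort_values(["id", "wave"], kind="stable").groupby("id", sort=False):
        states = grp["state"].to_numpy()
        times = grp["time_years"].to_numpy()
        for k in range(len(grp) - 1):
            if states[k] == 5:
                break
            row = {"id": pid, "from_state": int(states[k]), "to_state": int(states[k + 1]),
                   "dt": float(times[k + 1] - times[k])}
            if covariate is not None:
                row["z"] = float(grp.iloc[k][covariate])
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_panel(pairs: pd.DataFrame, has_covariate: bool) -> list[tuple[float, float, np.ndarray]]:
    """Collapse observation pairs into (dt, z, 5×5 count matrix) cells.

    The likelihood only depends on pairs through these counts, so one matrix
    exponential per cell suffices regardless of cohort size.
    """
    cells = []
    keys = ["dt", "z"] if has_covariate else ["dt"]
    for key, grp in pairs.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        dt = key[0]
        z = key[1] if has_covariate else 0.0
        C = np.zeros((N_STATES, N_STATES))
        for (i, j), n in grp.groupby(["from_state", "to_state"]).size().items():
            C[i - 1, j - 1] = n
        cells.append((float(dt), float(z), C))
    return cells


def _unpack(params: np.ndarray, transitions, has_covariate: bool):
    k = len(transitions)
    logq = params[:k]
    betas = params[k:] if has_covariate else np.zeros(k)
    return logq, betas


def _q_matrix(logq, betas, z, transitions) -> np.ndarray:
    Q = np.zeros((N_STATES, N_STATES))
    rates = np.exp(logq + betas * z)
    for (i, j), r in zip(transitions, rates):
        Q[i, j] = r
    Q[np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=1)
    return Q


def panel_loglik(params, cells, transitions=None, has_covariate=False,
                 return_grad=False):
    """Panel log-likelihood Σ C_ij log P(Δt)_ij and (optionally) its gradient.

    A zero-probability observed transition (impossible under the transition
    mask) yields −inf with a diagnostic.
    """
    if transitions is None:
        transitions = default_transitions()
    params = np.asarray(params, dtype=float)
    logq, betas = _unpack(params, transitions, has_covariate)
    k = len(transitions)
    nparam = len(params)
    ll = 0.0
    grad = np.zeros(nparam)
    for dt, z, C in cells:
        Q = _q_matrix(logq, betas, z, transitions)
        P = expm(Q * dt)
        mask = C > 0
        if np.any(P[mask] <= 0):
            bad = np.argwhere(mask & (P <= 0))[0]
            raise ValueError(
                f"observed transition {bad[0] + 1}->{bad[1] + 1} has zero probability "
                f"under the transition mask"
            )
        ll += float((C[mask] * np.log(P[mask])).sum())
        if return_grad:
            W = np.where(mask, C / np.where(P > 0, P, 1.0), 0.0)
            rates = np.exp(logq + betas * z)
            for p_idx in range(nparam):
                t_idx = p_idx % k
                i, j = transitions[t_idx]
                scale = rates[t_idx] if p_idx < k else rates[t_idx] * z
                if scale == 0.0:
                    continue
                dQ = np.zeros((N_STATES, N_STATES))
                dQ[i, j] = scale
                dQ[i, i] = -scale
                _, dP = expm_frechet(Q * dt, dQ * dt)
                grad[p_idx] += float((W * dP).sum())
    if return_grad:
        return ll, grad
    return ll


def _crude_rates(pairs: pd.DataFrame, transitions, floor: float = 1e-3) -> np.ndarray:
    """Initial intensities: transition counts divided by time at risk in the
    origin state, floored to keep the log-scale start finite."""
    time_at_risk = pairs.groupby("from_state")["dt"].sum()
    counts = pairs.groupby(["from_state", "to_state"]).size()
    rates = np.full(len(transitions), floor)
    for t_idx, (i, j) in enumerate(transitions):
        tar = time_at_risk.get(i + 1, 0.0)
        n = counts.get((i + 1, j + 1), 0)
        if tar > 0 and n > 0:
            rates[t_idx] = max(n / tar, floor)
    return rates


@dataclass
class MsmFit:
    """Fitted panel Markov model."""

    transitions: list[tuple[int, int]]
    log_q: np.ndarray
    betas: np.ndarray | None
    covariate: str | None
    log_likelihood: float
    se_log_q: np.ndarray | None
    se_betas: np.ndarray | None
    converged: bool
    n_pairs: int
    covariance: np.ndarray | None = None
    trace: list[float] = field(default_factory=list)

    @property
    def q_matrix(self) -> np.ndarray:
        """Baseline intensity matrix (covariate at zero)."""
        return _q_matrix(self.log_q, np.zeros(len(self.transitions)), 0.0, self.transitions)

    def q_matrix_at(self, z: float) -> np.ndarray:
        betas = self.betas if self.betas is not None else np.zeros(len(self.transitions))
        return _q_matrix(self.log_q, betas, z, self.transitions)

    def intensity_table(self) -> pd.DataFrame:
        rows = []
        for t_idx, (i, j) in enumerate(self.transitions):
            q = float(np.exp(self.log_q[t_idx]))
            se = self.se_log_q[t_idx] if self.se_log_q is not None else np.nan
            rows.append({
                "from_state": i + 1, "to_state": j + 1, "q": q,
                "q_lo": q * np.exp(-1.96 * se) if np.isfinite(se) else np.nan,
                "q_hi": q * np.exp(1.96 * se) if np.isfinite(se) else np.nan,
            })
        return pd.DataFrame(rows)


def fit_msm(data, covariate: str | None = None, transitions=None,
            prune_unobserved: bool = False, maxiter: int = 500) -> MsmFit:
    """Maximum-likelihood fit of the panel Markov model.

    ``data`` is either a scored cohort frame (with ``state``/``time_years``)
    or a pre-extracted pair frame from :func:`extract_pairs`.  ``covariate``
    names a single column acting on every allowed transition.  With
    ``prune_unobserved`` the transition mask drops transitions never observed
    as consecutive pairs (they are unidentifiable and fixed at zero).
    """
    if transitions is None:
        transitions = default_transitions()
    if "from_state" in data.columns:
        pairs = data
    else:
        pairs = extract_pairs(data, covariate=covariate)
    if pairs.empty or not pairs["to_state"].ne(pairs["from_state"]).any():
        raise ValueError("no observed transitions; model not identifiable")

    if prune_unobserved:
        observed = set(
            (i - 1, j - 1)
            for (i, j), _ in pairs.groupby(["from_state", "to_state"]).size().items()
            if i != j
        )
        transitions = [t for t in transitions if t in observed]

    has_cov = covariate is not None
    cells = aggregate_panel(pairs, has_covariate=has_cov)
    k = len(transitions)
    x0 = np.concatenate([np.log(_crude_rates(pairs, transitions)),
                         np.zeros(k) if has_cov else np.zeros(0)])

    trace: list[float] = []

    def objective(x):
        ll, g = panel_loglik(x, cells, transitions, has_cov, return_grad=True)
        return -ll, -g

    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   callback=lambda xk: trace.append(-objective(xk)[0]),
                   options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7})
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(f"panel Markov fit failed to converge: {res.message}")

    xhat = res.x
    cov = _observed_information_inverse(xhat, cells, transitions, has_cov)
    se = np.sqrt(np.diag(cov)) if cov is not None else None
    logq, betas = _unpack(xhat, transitions, has_cov)
    return MsmFit(
        transitions=list(transitions),
        log_q=logq.copy(),
        betas=betas.copy() if has_cov else None,
        covariate=covariate,
        log_likelihood=-float(res.fun),
        se_log_q=se[:k] if se is not None else None,
        se_betas=se[k:] if (se is not None and has_cov) else None,
        converged=bool(res.success),
        n_pairs=len(pairs),
        covariance=cov,
        trace=trace,
    )


def _observed_information_inverse(xhat, cells, transitions, has_cov):
    """Covariance of the MLE from central finite differences of the analytic
    gradient; None when the observed information is not positive definite."""
    n = len(xhat)
    H = np.zeros((n, n))
    h = 1e-5
    for p in range(n):
        xp, xm = xhat.copy(), xhat.copy()
        xp[p] += h
        xm[p] -= h
        _, gp = panel_loglik(xp, cells, transitions, has_cov, return_grad=True)
        _, gm = panel_loglik(xm, cells, transitions, has_cov, return_grad=True)
        H[p] = (gp - gm) / (2 * h)
    info = -(H + H.T) / 2.0
    try:
        eigvals = np.linalg.eigvalsh(info)
        if eigvals.min() <= 0:
            return None
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None


def msm_hazard_ratios(fit: MsmFit) -> pd.DataFrame:
    """Per-transition hazard ratios exp(β) with 95% Wald intervals."""
    if fit.betas is None:
        raise ValueError("fit has no covariate")
    rows = []
    for t_idx, (i, j) in enumerate(fit.transitions):
        beta = float(fit.betas[t_idx])
        se = float(fit.se_betas[t_idx]) if fit.se_betas is not None else np.nan
        rows.append({
            "from_state": i + 1, "to_state": j + 1,
            "hr": float(np.exp(beta)),
            "hr_lo": float(np.exp(beta - 1.96 * se)) if np.isfinite(se) else np.nan,
            "hr_hi": float(np.exp(beta + 1.96 * se)) if np.isfinite(se) else np.nan,
            "beta": beta, "se": se,
        })
    return pd.DataFrame(rows)


def probability_curves(Q: np.ndarray, grid, initial_state: int | None = None) -> pd.DataFrame:
    """Transition-probability curves P_ij(t) on a time grid (states 1-based).

    ``initial_state`` restricts output to one origin row; otherwise all five
    origins are emitted.
    """
    rows = []
    for t in grid:
        P = transition_probability(Q, float(t))
        origins = [initial_state] if initial_state is not None else range(1, N_STATES + 1)
        for i in origins:
            for j in range(1, N_STATES + 1):
                rows.append({"t": float(t), "from_state": i, "to_state": j,
                             "p": float(P[i - 1, j - 1])})
    return pd.DataFrame(rows)


def cumulative_absorption(Q: np.ndarray, horizon: float) -> np.ndarray:
    """Probability of having entered the absorbing state by ``horizon``, per
    transient initial state (length 4)."""
    P = transition_probability(Q, horizon)
    return P[:4, ABSORBING].copy()


def expected_duration(Q: np.ndarray, horizon: float, initial_distribution=None):
    """Expected total time in each state over [0, horizon] and the
    standardized percentage of the horizon it represents.

    E_j = ∫₀^T Σ_i π_i P_ij(t) dt, with π the initial state distribution
    (default: all mass in state 1).  Percentages sum to 100.
    """
    if initial_distribution is None:
        pi = np.zeros(N_STATES)
        pi[0] = 1.0
    else:
        pi = np.asarray(initial_distribution, dtype=float)
        if len(pi) == 4:
            pi = np.append(pi, 0.0)
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
    Q = np.asarray(Q, dtype=float)

    occupancy, err = quad_vec(lambda t: pi @ expm(Q * t), 0.0, horizon, epsabs=1e-10)
    if err > 1e-6:
        raise RuntimeError(f"occupancy quadrature failed: error estimate {err:.2e}")
    pct = 100.0 * occupancy / horizon
    return occupancy, pct


def empirical_transition_table(scored: pd.DataFrame, group_col: str | None = None):
    """Observed consecutive-wave transition counts and row percentages.

    Returns a dict mapping group label (or ``"all"``) to
    ``(counts, row_percent)`` 5×5 arrays.
    """
    pairs = extract_pairs(scored, covariate=group_col)
    out = {}
    groups = [("all", pairs)] if group_col is None else list(pairs.groupby("z"))
    for label, grp in groups:
        C = np.zeros((N_STATES, N_STATES))
        for (i, j), n in grp.groupby(["from_state", "to_state"]).size().items():
            C[i - 1, j - 1] = n
        rowsum = C.sum(axis=1, keepdims=True)
        pct = np.divide(100.0 * C, rowsum, out=np.zeros_like(C), where=rowsum > 0)
        out[label] = (C, pct)
    return out
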