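"""Synthetic biennial panel cohorts from a ground-truth five-state CTMC.

The generator emulates the structure of a large U.S. aging panel survey:
participants aged 50+ at baseline, interviewed every two years over a
22-year horizon, a nine-item childhood-adversity inventory fixed at baseline,
time-varying lifestyle and disease covariates, a latent five-state
continuous-time Markov process with one absorbing state (psychiatric
disorder), independent exponential mortality, and random missed visits.

The latent process is simulated exactly (Gillespie algorithm) with
piecewise-constant intensities between wave boundaries — the same assumption
the panel estimator makes, so parameter recovery is a clean test of the
estimator rather than of a model mismatch.  Observation emits raw scale items
and disease flags whose scores reproduce the latent state under
:func:`paneltrans.cohort.score_cohort` (emission–classification consistency).

Default ground-truth intensities are round numbers in the 0.01–0.15 per-year
range; the default adversity effect raises the healthy→physical,
healthy→mental, healthy→disorder and physical→comorbid intensities by 19.0%,
25.3%, 85.9% and 13.8% respectively.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import ACE_COLUMNS, COHORT_COLUMNS

__all__ = [
    "SimulationConfig",
    "simulate_ctmc_path",
    "observe_panel",
    "generate_cohort",
    "default_q0",
    "default_log_hr",
]

N_STATES = 5
ABSORBING = 4


def default_q0() -> dict[tuple[int, int], float]:
    """Round-number baseline intensities (per year, 0-based state indices)."""
    return {
        (0, 1): 0.10, (0, 2): 0.10, (0, 3): 0.02, (0, 4): 0.010,
        (1, 0): 0.05, (1, 2): 0.02, (1, 3): 0.13, (1, 4): 0.012,
        (2, 0): 0.06, (2, 1): 0.05, (2, 3): 0.12, (2, 4): 0.015,
        (3, 0): 0.02, (3, 1): 0.08, (3, 2): 0.04, (3, 4): 0.020,
    }


def default_log_hr() -> dict[str, dict[tuple[int, int], float]]:
    """Adversity multiplies four forward intensities (19.0%, 25.3%, 85.9%, 13.8%)."""
    return {
        "any_ace": {
            (0, 1): float(np.log(1.190)),
            (0, 2): float(np.log(1.253)),
            (0, 4): float(np.log(1.859)),
            (1, 3): float(np.log(1.138)),
        }
    }


# baseline Bernoulli probabilities for free covariates
_BASELINE_COVARIATES = {
    "edu_high": 0.432,
    "live_others": 0.774,
    "vig_act": 0.521,
    "alcohol": 0.325,
    "smoke": 0.130,
    "htn": 0.447,
    "lung": 0.056,
    "arthritis": 0.531,
}

# per-wave dynamics of the free covariates: symmetric flips for lifestyle,
# one-way incidence for chronic flags
_FLIP_PROB = {"live_others": 0.03, "vig_act": 0.06, "alcohol": 0.04, "smoke": 0.02}
_ONSET_PROB = {"htn": 0.02, "lung": 0.005, "arthritis": 0.02}


@dataclass
class SimulationConfig:
    """Ground truth and observation design for one synthetic cohort."""

    n_participants: int = 1000
    horizon_years: float = 22.0
    wave_spacing_years: float = 2.0
    seed: int = 0
    # item prevalences chosen so roughly a third of participants carry any
    # adversity, concentrated in a few common items
    ace_prevalence: tuple[float, ...] = (0.05, 0.02, 0.03, 0.08, 0.02, 0.05, 0.04, 0.08, 0.05)
    true_q0: dict = field(default_factory=default_q0)
    true_log_hr: dict = field(default_factory=default_log_hr)
    initial_state_probs: tuple[float, ...] = (0.55, 0.27, 0.08, 0.10)
    death_rate: float = 0.025  # per-year exponential mortality hazard
    missing_visit_prob: float = 0.08
    age_mean: float = 65.0
    age_sd: float = 8.0
    female_prob: float = 0.572
    race_probs: tuple[float, ...] = (0.85, 0.116, 0.034)  # white, black, other
    marital_probs: tuple[float, ...] = (0.731, 0.10, 0.139, 0.03)

    def validate(self) -> None:
        probs = list(self.ace_prevalence) + [self.missing_visit_prob] + \
            list(self.initial_state_probs) + [self.female_prob] + \
            list(self.race_probs) + list(self.marital_probs)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if len(self.ace_prevalence) != 9:
            raise ValueError("ace_prevalence needs 9 item probabilities")
        if any(q < 0 for q in self.true_q0.values()):
            raise ValueError("baseline intensities must be non-negative")
        if any(i == ABSORBING for (i, _j) in self.true_q0):
            raise ValueError("no intensities may leave the absorbing state")
        if self.death_rate < 0 or self.n_participants <= 0:
            raise ValueError("death_rate must be >= 0 and n_participants > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown simulation config keys: {unknown}")
        d = dict(d)
        for key in ("true_q0",):
            if key in d and isinstance(d[key], dict):
                d[key] = {_parse_transition(k): v for k, v in d[key].items()}
        if "true_log_hr" in d:
            d["true_log_hr"] = {
                cov: {_parse_transition(k): v for k, v in eff.items()}
                for cov, eff in d["true_log_hr"].items()
            }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def manifest(self) -> dict:
        """JSON-serializable echo of the ground truth."""
        d = dataclasses.asdict(self)
        d["true_q0"] = {f"{i + 1}->{j + 1}": v for (i, j), v in self.true_q0.items()}
        d["true_log_hr"] = {
            cov: {f"{i + 1}->{j + 1}": v for (i, j), v in eff.items()}
            for cov, eff in self.true_log_hr.items()
        }
        return d


def _parse_transition(key) -> tuple[int, int]:
    if isinstance(key, tuple):
        return key
    i, j = str(key).split("->")
    return int(i) - 1, int(j) - 1


def _q_matrix(q0: dict, log_hr: dict, covariates: dict) -> np.ndarray:
    Q = np.zeros((N_STATES, N_STATES))
    for (i, j), base in q0.items():
        rate = base
        for cov, effects in log_hr.items():
            if (i, j) in effects:
                rate *= float(np.exp(effects[(i, j)] * covariates.get(cov, 0.0)))
        Q[i, j] = rate
    Q[np.arange(N_STATES), np.arange(N_STATES)] = -Q.sum(axis=1)
    return Q


def simulate_ctmc_path(q_of_time, horizon: float, rng: np.random.Generator,
                       initial_state: int = 0, boundaries=None):
    """Exact simulation of a CTMC with piecewise-constant intensities.

    ``q_of_time(t)`` returns the 5×5 intensity matrix in force at time ``t``;
    it may only change value at the supplied ``boundaries`` (e.g. wave
    times).  Returns a list of ``(state, entry_time)`` pairs (0-based
    states), ending at absorption or the horizon.  A transient state with
    zero exit rate simply holds until the horizon.
    """
    boundaries = sorted(b for b in (boundaries or []) if 0.0 < b < horizon)
    path = [(initial_state, 0.0)]
    t, state = 0.0, initial_state
    b_idx = 0
    while t < horizon and state != ABSORBING:
        while b_idx < len(boundaries) and boundaries[b_idx] <= t:
            b_idx += 1
        seg_end = boundaries[b_idx] if b_idx < len(boundaries) else horizon
        Q = q_of_time(t)
        rate = -Q[state, state]
        if rate <= 0:
            t = seg_end
            continue
        hold = rng.exponential(1.0 / rate)
        if t + hold >= seg_end:
            t = seg_end
            continue
        t += hold
        probs = np.clip(Q[state], 0.0, None)
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(N_STATES, p=probs))
        path.append((state, t))
    return path


def _state_at(path, t: float) -> int:
    state = path[0][0]
    for s, entry in path:
        if entry <= t:
            state = s
        else:
            break
    return state


def observe_panel(path, schedule, missing_visit_prob: float, rng: np.random.Generator,
                  death_time: float = np.inf):
    """Read the latent path at scheduled visits.

    The baseline visit is never missed.  Observation stops after the
    absorbing state is first seen (follow-up for the outcome ends there) or
    at death; a death between visits is reported at the next scheduled wave
    (an exit record with latent state ``None``).  Returns a list of
    ``(wave_index, time, latent_state_or_None)``.
    """
    out = []
    for k, t in enumerate(schedule):
        if t >= death_time:
            out.append((k, t, None))  # exit record
            break
        if k > 0 and rng.random() < missing_visit_prob:
            continue
        state = _state_at(path, t)
        out.append((k, t, state))
        if state == ABSORBING:
            break
    return out


def _cesd_items_for_total(total: int) -> list[int]:
    """Eight binary items whose reverse-scored total equals ``total``.

    Positions 4 and 6 (1-based) are the reverse-scored items; a response of
    1 there contributes zero.
    """
    direct_positions = [0, 1, 2, 4, 6, 7]
    n_direct = min(total, 6)
    items = [0] * 8
    for p in direct_positions[:n_direct]:
        items[p] = 1
    items[3] = 0 if total >= 7 else 1
    items[5] = 0 if total >= 8 else 1
    return items


def _tics_domains_for_total(total: int) -> tuple[int, int, int]:
    """Split a 0–27 total into (memory<=20, attention<=5, calculation<=2)."""
    calc = min(2, total)
    att = min(5, total - calc)
    mem = total - calc - att
    return mem, att, calc


class _Emitter:
    """Draws raw items and disease flags consistent with a latent state."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.pc_set: list[str] | None = None  # persistent disease choice

    def pc_flags(self, need_pc: bool) -> dict[str, int]:
        flags = {d: 0 for d in ("dm", "cancer", "heart", "stroke")}
        if need_pc:
            if self.pc_set is None:
                first = self.rng.choice(["heart", "dm", "cancer", "stroke"],
                                        p=[0.40, 0.35, 0.20, 0.05])
                self.pc_set = [str(first)]
                if self.rng.random() < 0.3:
                    extra = self.rng.choice(["heart", "dm", "cancer", "stroke"])
                    if extra not in self.pc_set:
                        self.pc_set.append(str(extra))
            for d in self.pc_set:
                flags[d] = 1
        return flags

    def symptom_items(self, need_ms: bool) -> dict:
        rng = self.rng
        if need_ms:
            mode = rng.choice(3, p=[0.55, 0.30, 0.15])  # depression / cognition / both
            depressed = mode in (0, 2)
            impaired = mode in (1, 2)
        else:
            depressed = impaired = False
        if depressed:
            cesd_total = int(rng.choice([4, 5, 6, 7, 8], p=[0.50, 0.25, 0.15, 0.07, 0.03]))
        else:
            cesd_total = int(rng.choice([0, 1, 2, 3], p=[0.45, 0.30, 0.15, 0.10]))
        if impaired:
            tics_total = int(rng.integers(5, 12))
        else:
            tics_total = int(np.clip(round(rng.normal(16.5, 3.5)), 12, 27))
        # sleep items do not enter the state; calibrated to a 6.71 mean total
        jss = [int(rng.choice([1, 2, 3], p=[0.12, 0.33, 0.55])) for _ in range(3)]
        jss.append(int(rng.choice([1, 2, 3])))
        out = {}
        for i, v in enumerate(_cesd_items_for_total(cesd_total), start=1):
            out[f"cesd{i}"] = v
        for i, v in enumerate(jss, start=1):
            out[f"jss{i}"] = v
        mem, att, calc = _tics_domains_for_total(tics_total)
        out.update({"tics_mem": mem, "tics_att": att, "tics_calc": calc})
        return out


def generate_cohort(config: SimulationConfig):
    """Simulate a full cohort.

    Returns ``(cohort_df, ace_df, truth)`` where ``truth`` holds the config
    manifest and the per-participant latent paths.  Deterministic given the
    config seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_participants)

    n_waves = int(round(config.horizon_years / config.wave_spacing_years)) + 1
    schedule = [k * config.wave_spacing_years for k in range(n_waves)]

    cohort_rows, ace_rows, paths = [], [], {}
    pi = np.asarray(config.initial_state_probs, dtype=float)
    pi = pi / pi.sum()

    for idx in range(config.n_participants):
        rng = np.random.default_rng(children[idx])
        pid = f"P{idx:06d}"

        ace_items = (rng.random(9) < np.asarray(config.ace_prevalence)).astype(int)
        ace_rows.append({"id": pid, **{f"ace{i + 1}": int(v) for i, v in enumerate(ace_items)}})
        any_ace = int(ace_items.any())

        base_age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 50.0, 95.0))
        sex = "female" if rng.random() < config.female_prob else "male"
        race = str(rng.choice(["white", "black", "other"], p=np.asarray(config.race_probs) /
                              np.sum(config.race_probs)))
        marital = str(rng.choice(
            ["married", "divorced_separated", "widowed", "never_married_other"],
            p=np.asarray(config.marital_probs) / np.sum(config.marital_probs)))

        # free covariates per wave (piecewise-constant between waves)
        cov_series: dict[str, list[int]] = {}
        for name, p0 in _BASELINE_COVARIATES.items():
            vals = [int(rng.random() < p0)]
            for _ in range(1, n_waves):
                v = vals[-1]
                if name in _FLIP_PROB and rng.random() < _FLIP_PROB[name]:
                    v = 1 - v
                elif name in _ONSET_PROB and v == 0 and rng.random() < _ONSET_PROB[name]:
                    v = 1
                vals.append(v)
            cov_series[name] = vals

        def cov_at(t: float) -> dict:
            k = min(int(t // config.wave_spacing_years), n_waves - 1)
            d = {name: vals[k] for name, vals in cov_series.items()}
            d["any_ace"] = any_ace
            d["ace_total"] = int(ace_items.sum())
            return d

        def q_of_time(t: float) -> np.ndarray:
            return _q_matrix(config.true_q0, config.true_log_hr, cov_at(t))

        s0 = int(rng.choice(4, p=pi))
        death_time = rng.exponential(1.0 / config.death_rate) if config.death_rate > 0 else np.inf
        path = simulate_ctmc_path(q_of_time, config.horizon_years, rng,
                                  initial_state=s0, boundaries=schedule[1:])
        paths[pid] = path

        visits = observe_panel(path, schedule, config.missing_visit_prob, rng,
                               death_time=death_time)
        emitter = _Emitter(rng)
        for wave, t, latent in visits:
            row = {c: np.nan for c in COHORT_COLUMNS}
            row.update({"id": pid, "wave": wave, "time_years": t})
            if latent is None:  # exit record: death reported, no interview
                row.update({"psy_dx": np.nan, "died": 1, "observed": 0})
                cohort_rows.append(row)
                continue
            state = latent + 1
            need_pc = state in (2, 4)
            need_ms = state in (3, 4)
            row.update({
                "age": round(base_age + t, 1), "sex": sex, "race": race, "marital": marital,
                "edu_high": cov_series["edu_high"][wave],
                "live_others": cov_series["live_others"][wave],
                "vig_act": cov_series["vig_act"][wave],
                "alcohol": cov_series["alcohol"][wave],
                "smoke": cov_series["smoke"][wave],
                "htn": cov_series["htn"][wave],
                "lung": cov_series["lung"][wave],
                "arthritis": cov_series["arthritis"][wave],
                "psy_dx": int(state == 5), "died": 0, "observed": 1,
            })
            row.update(emitter.pc_flags(need_pc if state != 5 else False))
            if state == 5:
                # items are irrelevant to the state once diagnosed; emit a
                # symptom-free pattern for completeness
                row.update(emitter.symptom_items(False))
            else:
                row.update(emitter.symptom_items(need_ms))
            cohort_rows.append(row)

    cohort = pd.DataFrame(cohort_rows, columns=COHORT_COLUMNS)
    aces = pd.DataFrame(ace_rows, columns=ACE_COLUMNS)
    truth = {"config": config.manifest(), "paths": paths}
    return cohort, aces, truth


def write_outputs(cohort: pd.DataFrame, aces: pd.DataFrame, truth: dict, outdir) -> None:
    """Write the cohort/ACE CSVs and a JSON manifest echoing the truth."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(outdir / "cohort.csv", index=False)
    aces.to_csv(outdir / "aces.csv", index=False)
    manifest = {"config": truth["config"],
                "n_paths": len(truth["paths"])}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
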