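"""Individual-level stop-screen trial simulator with known true overdiagnosis.

The generator emulates a two-arm trial of a one-off screen. Every subject
carries latent counterfactual times: ``t_clinical``, when the cancer would
present clinically without screening (drawn from an age-specific
piecewise-constant incidence hazard; possibly never), and ``t_death``, the
other-cause death time (drawn from a life table). Screening works through a
lead-time mechanism: an attender's cancer is detectable at the screen iff
its counterfactual presentation falls within the subject's drawn lead time
L, i.e. ``t_clinical <= L`` — such subjects are recorded screen-detected at
time 0. Everyone else behaves as a control: the first of clinical
presentation, death and administrative censoring is observed.

The oracle label is the verbal definition of overdiagnosis itself: a
screen-detected cancer whose host dies of other causes before the cancer
would have presented. Because the latent times are retained, every
downstream estimator in the package can be checked against direct
enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable, make_gompertz_lifetable

__all__ = [
    "TrialSimConfig",
    "simulate_trial",
    "true_overdiagnosis_fraction",
    "write_records",
    "read_records",
    "make_gompertz_lifetable",
]

RECORD_COLUMNS = ["arm", "entry_age", "observed_time", "observed_event",
                  "screen_detected"]
ORACLE_COLUMNS = ["t_clinical", "t_death", "lead_time", "overdiagnosed_true",
                  "contaminated"]

#: simulation never tracks ages beyond this; residual mass becomes t = inf
_MAX_AGE = 151


@dataclass(frozen=True)
class TrialSimConfig:
    """Parameters of a simulated one-off-screen trial.

    Parameters
    ----------
    n_screen, n_control : int
        Arm sizes (>= 1).
    incidence_hazard : float or LifeTable
        Annual hazard of counterfactual clinical presentation; a scalar
        means constant over age, a LifeTable gives piecewise-constant
        age-specific hazards (flat beyond its last age).
    mortality : LifeTable or None
        Other-cause death hazards by age; ``None`` switches competing
        death off entirely.
    attendance : float
        Probability in [0, 1] of accepting the one-off screen. Test
        sensitivity is folded into this single parameter.
    lead_time_mean : float
        Mean of the lead-time distribution in years. Exponential by
        default; ``lead_time_shape != 1`` selects a Weibull with that
        shape and the same mean.
    entry_age_dist : int or dict[int, float]
        Entry age at randomisation: a single integer age, or a discrete
        distribution ``{age: probability}`` summing to 1.
    followup_max : float
        Administrative censoring time in years (may be ``inf``).
    seed : int
        RNG seed; mandatory — one generator stream per run.
    contamination_rate : float
        Probability that a control subject undergoes the same screening
        mechanism at time 0 (detected cancers surface immediately but are
        not flagged screen-detected); off by default.
    """

    n_screen: int
    n_control: int
    incidence_hazard: float | LifeTable
    mortality: LifeTable | None
    seed: int
    attendance: float = 1.0
    lead_time_mean: float = 10.0
    lead_time_shape: float = 1.0
    entry_age_dist: int | dict = 60
    followup_max: float = 15.0
    contamination_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_screen < 1 or self.n_control < 1:
            raise ValueError("arm sizes must be >= 1")
        for name in ("attendance", "contamination_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if isinstance(self.incidence_hazard, (int, float)):
            h = float(self.incidence_hazard)
            if not math.isfinite(h) or h < 0:
                raise ValueError("incidence_hazard must be finite and >= 0")
        if self.lead_time_mean <= 0 or self.lead_time_shape <= 0:
            raise ValueError("lead-time parameters must be positive")
        if self.followup_max <= 0:
            raise ValueError("followup_max must be positive")
        if isinstance(self.entry_age_dist, dict):
            probs = np.array(list(self.entry_age_dist.values()), dtype=float)
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("entry_age_dist probabilities must sum to 1")
        if self.seed is None:
            raise ValueError("seed is required")


def _age_hazard_array(source: float | LifeTable, age_min: int) -> np.ndarray:
    """Annual hazards for ages age_min.._MAX_AGE-1, flat beyond any table."""
    n = _MAX_AGE - age_min
    if isinstance(source, (int, float)):
        return np.full(n, float(source))
    ages = np.arange(age_min, _MAX_AGE)
    # silent flat extrapolation: tracking latent times to extreme ages is
    # the simulator's job, not an analyst-facing table lookup
    idx = np.clip(ages - source.age_min, 0, source.ages.size - 1)
    out = source.hazard[idx].copy()
    out[ages < source.age_min] = source.hazard[0]
    return out


def _sample_piecewise_exponential(
    rng: np.random.Generator, entry_ages: np.ndarray, source: float | LifeTable | None
) -> np.ndarray:
    """Draw latent times (years from entry) by inverse-CDF from a
    piecewise-constant age hazard; ``inf`` where the cumulative hazard is
    exhausted (or the source is None)."""
    m = entry_ages.size
    if source is None:
        return np.full(m, np.inf)
    out = np.empty(m)
    e = rng.exponential(size=m)
    for a0 in np.unique(entry_ages):
        sel = entry_ages == a0
        h = _age_hazard_array(source, int(a0))
        bounds = np.concatenate(([0.0], np.cumsum(h)))
        ei = e[sel]
        idx = np.searchsorted(bounds, ei, side="right") - 1
        idx = np.minimum(idx, h.size - 1)
        safe_h = np.where(h[idx] > 0, h[idx], np.nan)
        t = idx + (ei - bounds[idx]) / safe_h
        t = np.where(ei >= bounds[-1], np.inf, t)
        out[sel] = np.where(np.isnan(t) & (ei < bounds[-1]), np.inf, t)
    return out


def _draw_lead_times(rng, cfg, m: int) -> np.ndarray:
    if cfg.lead_time_shape == 1.0:
        return rng.exponential(cfg.lead_time_mean, size=m)
    scale = cfg.lead_time_mean / math.gamma(1.0 + 1.0 / cfg.lead_time_shape)
    return scale * rng.weibull(cfg.lead_time_shape, size=m)


def simulate_trial(config: TrialSimConfig) -> pd.DataFrame:
    """Simulate the trial; returns one row per subject.

    Columns ``arm, entry_age, observed_time, observed_event,
    screen_detected`` form the analyst-visible record; ``t_clinical,
    t_death, lead_time, overdiagnosed_true, contaminated`` are oracle
    fields. Deterministic given the config's seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_screen + config.n_control
    arm = np.array(["screen"] * config.n_screen + ["control"] * config.n_control)

    if isinstance(config.entry_age_dist, dict):
        ages = np.array(sorted(config.entry_age_dist), dtype=int)
        probs = np.array([config.entry_age_dist[a] for a in ages], dtype=float)
        entry_age = rng.choice(ages, size=n, p=probs / probs.sum())
    else:
        entry_age = np.full(n, int(config.entry_age_dist))

    t_clinical = _sample_piecewise_exponential(rng, entry_age, config.incidence_hazard)
    t_death = _sample_piecewise_exponential(rng, entry_age, config.mortality)
    lead_time = _draw_lead_times(rng, config, n)

    screened = (arm == "screen") & (rng.random(n) < config.attendance)
    contaminated = (arm == "control") & (rng.random(n) < config.contamination_rate)
    detectable = t_clinical <= lead_time
    screen_detected = screened & detectable
    early_dx = screen_detected | (contaminated & detectable)

    t_censor = config.followup_max
    obs_time = np.minimum(np.minimum(t_clinical, t_death), t_censor)
    cancer_first = (
        np.isfinite(t_clinical) & (t_clinical <= t_death) & (t_clinical <= t_censor)
    )
    death_first = ~cancer_first & np.isfinite(t_death) & (t_death <= t_censor)
    event = np.where(cancer_first, "cancer", np.where(death_first, "death", "censored"))
    obs_time = np.where(early_dx, 0.0, obs_time)
    event = np.where(early_dx, "cancer", event)
    overdiagnosed = screen_detected & (t_death < t_clinical)

    return pd.DataFrame(
        {
            "arm": arm,
            "entry_age": entry_age,
            "observed_time": obs_time,
            "observed_event": event,
            "screen_detected": screen_detected,
            "t_clinical": t_clinical,
            "t_death": t_death,
            "lead_time": lead_time,
            "overdiagnosed_true": overdiagnosed,
            "contaminated": contaminated,
        }
    )


def true_overdiagnosis_fraction(records: pd.DataFrame, horizon: float = math.inf) -> float:
    """Oracle overdiagnosis among screen-detected cancers.

    A screen-detected cancer counts as overdiagnosed within ``horizon``
    years when it would not have been diagnosed in that window absent
    screening: either the host dies first or the horizon ends first
    (``min(t_death, horizon) < t_clinical``). With ``horizon = inf`` this is
    the lifetime definition.
    """
    det = records[records["screen_detected"].astype(bool)]
    if len(det) == 0:
        raise ValueError("no screen-detected subjects; fraction undefined")
    diagnosed_anyway = (det["t_clinical"] <= horizon) & (
        det["t_clinical"] <= det["t_death"]
    )
    return float(1.0 - diagnosed_anyway.mean())


def write_records(records: pd.DataFrame, path, oracle: bool = False) -> None:
    """Write subject records as CSV; oracle columns only behind the flag."""
    cols = RECORD_COLUMNS + (ORACLE_COLUMNS if oracle else [])
    cols = [c for c in cols if c in records.columns]
    records[cols].to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV missing columns: {missing}")
    return df
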