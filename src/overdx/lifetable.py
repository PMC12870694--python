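"""Age-indexed annual mortality hazards: loading, cause deletion, survival.

A :class:`LifeTable` holds the competing-mortality hazard ``h2(a)`` for each
single year of age ``[a, a+1)``. Interval survival over ages ``b..c-1`` is

    S2(b, c) = exp(-sum_{a=b}^{c-1} h2(a)),

so ``S2(a, a+1)`` covers exactly one year of age and ``S2(b, b) = 1``.
Hazards are piecewise constant within each year of age; ages beyond the
table's maximum are extrapolated at the last tabulated value (with a
warning), which is needed e.g. when projecting 15 years forward from age 80
with a table that stops at 90.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._warnings import ExtrapolationWarning, HazardFloorWarning

__all__ = [
    "LifeTable",
    "load_lifetable",
    "cause_deleted",
    "survival_between",
    "death_probability",
    "make_gompertz_lifetable",
    "calibrate_lifetable",
]


@dataclass(frozen=True)
class LifeTable:
    """Annual hazard per single year of age on a gapless integer age grid.

    Parameters
    ----------
    ages : ndarray of int
        Consecutive integer ages ``[age_min, age_max]``.
    hazard : ndarray of float
        Annual hazard (units 1/year) for the interval ``[a, a+1)``;
        non-negative.
    """

    ages: np.ndarray
    hazard: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        hazard = np.asarray(self.hazard, dtype=float)
        if ages.ndim != 1 or ages.size == 0:
            raise ValueError("ages must be a non-empty 1-d array")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be consecutive integers with no gaps")
        if hazard.shape != ages.shape:
            raise ValueError("hazard must have the same length as ages")
        if not np.all(np.isfinite(hazard)) or np.any(hazard < 0):
            raise ValueError("hazards must be finite and non-negative")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "hazard", hazard)

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def hazard_at(self, age, extrapolate: bool = True) -> np.ndarray:
        """Hazard at integer age(s), extrapolating flat beyond the grid."""
        age = np.asarray(age, dtype=int)
        below = age < self.age_min
        above = age > self.age_max
        if np.any(below):
            raise ValueError(
                f"age {age[below].min()} below life-table minimum {self.age_min}"
            )
        if np.any(above):
            if not extrapolate:
                raise ValueError(
                    f"age {age[above].max()} beyond life-table maximum {self.age_max}"
                )
            warnings.warn(
                f"ages beyond {self.age_max} use the last tabulated hazard",
                ExtrapolationWarning,
                stacklevel=2,
            )
        idx = np.clip(age - self.age_min, 0, self.ages.size - 1)
        return self.hazard[idx]

    def survival_between(self, b: int, c: int) -> float:
        return survival_between(self, b, c)

    def death_probability(self, a: int, t: int) -> float:
        return death_probability(self, a, t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "mx": self.hazard})


def load_lifetable(path, column_kind: str) -> LifeTable:
    """Read a life-table CSV with columns ``age`` and ``qx`` or ``mx``.

    ``qx`` (annual death probability) is converted to a hazard via
    ``h = -log(1 - qx)``; ``mx`` (central rate) is taken directly as the
    piecewise-constant hazard.
    """
    if column_kind not in ("qx", "mx"):
        raise ValueError("column_kind must be 'qx' or 'mx'")
    df = pd.read_csv(path)
    if "age" not in df.columns or column_kind not in df.columns:
        raise ValueError(f"CSV must have columns 'age' and '{column_kind}'")
    if df["age"].duplicated().any():
        raise ValueError("duplicate ages in life table")
    df = df.sort_values("age")
    ages = df["age"].to_numpy(dtype=int)
    vals = df[column_kind].to_numpy(dtype=float)
    if column_kind == "qx":
        if np.any(vals < 0) or np.any(vals >= 1):
            raise ValueError("qx must lie in [0, 1)")
        hazard = -np.log1p(-vals)
    else:
        hazard = vals
    return LifeTable(ages=ages, hazard=hazard)


def cause_deleted(all_cause: LifeTable, cause: LifeTable) -> LifeTable:
    """Other-cause hazards: subtract one cause's mortality from all-cause.

    Restricted to the overlapping age range; differences that would be
    negative are floored at 0 with a :class:`HazardFloorWarning`.
    """
    lo = max(all_cause.age_min, cause.age_min)
    hi = min(all_cause.age_max, cause.age_max)
    if lo > hi:
        raise ValueError("life tables have no overlapping ages")
    ages = np.arange(lo, hi + 1)
    h_all = all_cause.hazard[ages - all_cause.age_min]
    h_cause = cause.hazard[ages - cause.age_min]
    diff = h_all - h_cause
    if np.any(diff < 0):
        warnings.warn(
            f"cause-specific hazard exceeds all-cause at {int((diff < 0).sum())} "
            "age(s); floored at 0",
            HazardFloorWarning,
            stacklevel=2,
        )
        diff = np.maximum(diff, 0.0)
    return LifeTable(ages=ages, hazard=diff)


def survival_between(lt: LifeTable, b: int, c: int) -> float:
    """``S2(b, c) = exp(-sum_{a=b}^{c-1} h2(a))``; equals 1 when b == c.

    Ages past the table's maximum use its last hazard (flat extrapolation,
    warned once per call).
    """
    if b > c:
        raise ValueError("need b <= c")
    if b < lt.age_min:
        raise ValueError(f"age {b} below life-table minimum {lt.age_min}")
    if b == c:
        return 1.0
    h = lt.hazard_at(np.arange(b, c))
    return float(np.exp(-h.sum()))


def death_probability(lt: LifeTable, a: int, t: int) -> float:
    """Probability of death within ``t`` years from exact age ``a``."""
    return 1.0 - survival_between(lt, a, a + t)


def make_gompertz_lifetable(
    b: float, g: float, age_min: int = 50, age_max: int = 100
) -> LifeTable:
    """Gompertz hazard ``h(a) = b * exp(g * (a - age_min))`` by integer age.

    ``b`` is the hazard at the reference (youngest) age and ``g`` the
    log-hazard slope per year of age; ``g = 0`` gives a constant hazard.
    """
    if b <= 0:
        raise ValueError("baseline hazard b must be positive")
    if g < 0:
        raise ValueError("log-hazard slope g must be non-negative")
    if age_min >= age_max:
        raise ValueError("need age_min < age_max")
    ages = np.arange(age_min, age_max + 1)
    return LifeTable(ages=ages, hazard=b * np.exp(g * (ages - age_min)))


def calibrate_lifetable(
    targets: dict[int, float],
    horizon: int = 15,
    age_min: int | None = None,
    age_max: int | None = None,
) -> LifeTable:
    """Construct a life table whose ``horizon``-year death probabilities match
    given targets exactly.

    The log-hazard is modelled as a polynomial in age with one coefficient
    per target; the coefficients are solved (``scipy.optimize.fsolve``) so
    that ``1 - S2(a, a + horizon)`` equals each target. With targets that
    increase in age the fitted hazard is smooth and increasing, resembling
    a period life table. Used to build synthetic stand-ins for national
    tables from published summary death probabilities.

    Parameters
    ----------
    targets : dict
        ``{age: death probability within `horizon` years}``; at least two
        entries, probabilities in (0, 1).
    horizon : int
        Years over which each target probability applies.
    age_min, age_max : int, optional
        Grid bounds; default from youngest target to oldest target +
        horizon.
    """
    if len(targets) < 2:
        raise ValueError("need at least two calibration targets")
    t_ages = np.array(sorted(targets), dtype=int)
    q = np.array([targets[a] for a in t_ages], dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("target probabilities must lie in (0, 1)")
    if age_min is None:
        age_min = int(t_ages[0])
    if age_max is None:
        age_max = int(t_ages[-1]) + horizon
    ages = np.arange(age_min, age_max + 1)
    cum_target = -np.log1p(-q)
    x = (ages - age_min) / 10.0  # scaled age keeps the polynomial well conditioned

    def hazard_of(coef: np.ndarray) -> np.ndarray:
        return np.exp(np.polyval(coef[::-1], x))

    def residual(coef: np.ndarray) -> np.ndarray:
        h = hazard_of(coef)
        return np.array(
            [
                h[(ages >= a) & (ages < a + horizon)].sum() - ct
                for a, ct in zip(t_ages, cum_target)
            ]
        )

    x0 = np.zeros(len(t_ages))
    x0[0] = np.log(cum_target[0] / horizon)
    if len(t_ages) > 1:
        span = (t_ages[-1] - t_ages[0]) / 10.0
        x0[1] = (np.log(cum_target[-1]) - np.log(cum_target[0])) / max(span, 0.1)
    coef, info, ier, msg = optimize.fsolve(residual, x0, full_output=True)
    if ier != 1 or np.max(np.abs(residual(coef))) > 1e-8:
        raise RuntimeError(f"life-table calibration did not converge: {msg}")
    return LifeTable(ages=ages, hazard=hazard_of(coef))
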