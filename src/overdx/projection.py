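"""Crude excess (overdiagnosis) by age via piecewise-constant-hazard
competing risks.

Two risks compete for a screen-detected cancer after the screen: the
cancer's counterfactual clinical presentation, with annual excess hazards
``h1(k)`` (k years after screening), and other-cause death, with hazards
``h2(a + k - 1)`` at the subject's age at the start of interval k. With both
hazards constant within each one-year interval, the probability that the
cancer presents in interval k is

    w_k = h1(k) / (h1(k) + h2(a+k-1))
          * (1 - exp(-(h1(k) + h2(a+k-1))))
          * S1(k-1) * S2(a, a+k-1),

the classical competing-risks interval decomposition using survival to the
START of the interval. Overdiagnosis within horizon t is everything that is
not a counterfactual presentation:

    O(a, t) = 1 - sum_{k=1}^t w_k.

This start-of-interval convention is the one consistent with the method's
limiting cases: with h2 = 0 the sum telescopes exactly to 1 - S1(t), so
crude excess equals net excess when nobody dies, and total probability
(presentations + deaths + survivors) is conserved exactly. During the
plateau (h1 = 0) w_k = 0 by convention (the 0/0 limit), but those intervals
still deplete S2 — early deaths are what drive O above S1(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .excess import ExcessSurvival
from .lifetable import LifeTable

__all__ = ["OverdiagnosisProjection", "crude_excess", "overdiagnosis_by_age"]


@dataclass(frozen=True)
class OverdiagnosisProjection:
    """Projected overdiagnosis for one age at screening.

    ``components`` holds the per-interval presentation probabilities w_k
    (k = 1..horizon) for audit; ``death_components`` the symmetric death
    terms; ``survivor`` the mass still event-free at the horizon. The three
    sum to 1.
    """

    age: int
    horizon: int
    O: float
    components: np.ndarray
    death_components: np.ndarray
    survivor: float

    def __post_init__(self) -> None:
        if not 0 <= self.O <= 1:
            raise ValueError("O must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        k = np.arange(1, self.horizon + 1)
        return pd.DataFrame(
            {
                "age": self.age,
                "k": k,
                "w_presentation": self.components,
                "w_death": self.death_components,
            }
        )


def crude_excess(
    S1: ExcessSurvival, lt: LifeTable, a: int, t: int | None = None
) -> OverdiagnosisProjection:
    """Projected overdiagnosis O(a, t) for screening age ``a``, horizon ``t``.

    ``t`` defaults to the excess-survival horizon T and cannot exceed it.
    Life-table ages past the table maximum follow the table's flat
    extrapolation policy (warned there).
    """
    if t is None:
        t = S1.T
    if not 1 <= t <= S1.T:
        raise ValueError(f"horizon t must be in 1..{S1.T}")
    ages_needed = np.arange(a, a + t)
    h2 = lt.hazard_at(ages_needed)
    h1 = S1.h1[:t]
    s1_start = S1.S1[:t]  # S1(k-1), k = 1..t
    s2_start = np.exp(-np.concatenate(([0.0], np.cumsum(h2[:-1]))))  # S2(a, a+k-1)
    total = h1 + h2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac1 = np.where(h1 > 0, h1 / total, 0.0)
        frac2 = np.where(total > 0, h2 / total, 0.0)
    depletion = -np.expm1(-total)  # 1 - exp(-(h1+h2))
    start_mass = s1_start * s2_start
    w1 = frac1 * depletion * start_mass
    w2 = frac2 * depletion * start_mass
    survivor = float(S1.S1[t] * np.exp(-h2.sum()))
    O = 1.0 - float(w1.sum())
    O = min(max(O, 0.0), 1.0)
    return OverdiagnosisProjection(
        age=int(a), horizon=int(t), O=O, components=w1, death_components=w2,
        survivor=survivor,
    )


def overdiagnosis_by_age(
    S1: ExcessSurvival, lt: LifeTable, ages, t: int | None = None
) -> pd.DataFrame:
    """O(a, t) for each age in ``ages`` as a tidy table.

    Columns: age, horizon, O (proportion of screen-detected cancers
    projected not to have presented clinically within the horizon).
    """
    rows = [crude_excess(S1, lt, int(a), t) for a in ages]
    return pd.DataFrame(
        {
            "age": [r.age for r in rows],
            "horizon": [r.horizon for r in rows],
            "O": [r.O for r in rows],
        }
    )
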