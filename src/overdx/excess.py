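"""Net excess incidence relative to screen-detected cases.

The central statistic of the excess-incidence approach to overdiagnosis is

    E(t) = min(1, (F_A(t) - F_B(t)) / R_A),

the between-arm difference in net cumulative incidence relative to the
fraction R_A of randomised subjects with cancer detected at the one-off
screen. E(t) is the proportion of screen-detected cancers that have not yet
surfaced as a matching deficit ("compensatory drop") in the screened arm; at
long follow-up it estimates overdiagnosis in the absence of competing death.

Treating E(t) = S1(t) as the survival function of the counterfactual
clinical-presentation time among screen-detected cancers gives annual excess
hazards h1(k) = log S1(k-1) - log S1(k), which feed the competing-risks
projection (see :mod:`overdx.projection`).

Internal arithmetic is on the proportion scale; the confidence-interval
helpers accept percent because published summaries print percent —
conversion is explicit at that boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._warnings import CapWarning, MonotoneRepairWarning, NegativeExcessWarning
from .netrisk import NetRiskCurve, interpolate_yearly

__all__ = [
    "ExcessSurvival",
    "ExcessEstimate",
    "net_excess",
    "crude_excess_from_counts",
    "se_from_ci",
    "excess_ci",
    "linearized_excess_survival",
    "excess_survival_from_curves",
    "contamination_adjust",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ExcessSurvival:
    """Yearly excess-survival values S1(k) and annual excess hazards h1(k).

    ``S1`` has length ``T + 1`` (k = 0..T) with S1(0) = 1, non-increasing and
    strictly positive; ``h1[k-1] = log S1(k-1) - log S1(k)`` for k = 1..T.
    ``t0`` marks the plateau: h1(k) = 0 for k <= t0 (no screen-detected
    cancer would have presented clinically that early).
    """

    T: int
    t0: int
    S1: np.ndarray
    h1: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        S1 = np.asarray(self.S1, dtype=float)
        if S1.shape != (self.T + 1,):
            raise ValueError(f"S1 must have length T+1 = {self.T + 1}")
        if abs(S1[0] - 1.0) > 1e-12:
            raise ValueError("S1(0) must equal 1")
        if np.any(S1 <= 0):
            raise ValueError("S1 must be strictly positive up to the horizon")
        if np.any(np.diff(S1) > 1e-12):
            raise ValueError("S1 must be non-increasing")
        if not 0 <= self.t0 < self.T:
            raise ValueError("need 0 <= t0 < T")
        S1 = np.minimum.accumulate(np.minimum(S1, 1.0))
        h1 = np.log(S1[:-1]) - np.log(S1[1:])
        h1 = np.maximum(h1, 0.0)  # kill -0.0 / rounding dust
        object.__setattr__(self, "S1", S1)
        object.__setattr__(self, "h1", h1)

    def hazard(self, k: int) -> float:
        """Annual excess hazard for year k (1-based)."""
        if not 1 <= k <= self.T:
            raise ValueError(f"k must be in 1..{self.T}")
        return float(self.h1[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": np.arange(self.T + 1),
                "S1": self.S1,
                "h1": np.insert(self.h1, 0, np.nan),
            }
        )


@dataclass(frozen=True)
class ExcessEstimate:
    """Excess proportion at time t with its normal-theory 95% interval."""

    t: float
    E: float
    se: float
    ci_lo: float
    ci_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_lo <= min(self.E, self.ci_hi) + 1e-12):
            raise ValueError("require 0 <= ci_lo <= min(E, ci_hi)")
        if self.ci_hi > 1 + 1e-12:
            raise ValueError("ci_hi must not exceed 1 after capping")


def net_excess(FA_t: float, FB_t: float, RA: float) -> float:
    """``min(1, (FA - FB) / RA)``; negative excess floored at 0 with warning."""
    if RA <= 0:
        raise ValueError("RA must be positive")
    for v in (FA_t, FB_t):
        if not 0 <= v < 1:
            raise ValueError("net incidence inputs must lie in [0, 1)")
    e = (FA_t - FB_t) / RA
    if e < 0:
        warnings.warn(
            "negative excess floored at 0 (overdiagnosis is a proportion)",
            NegativeExcessWarning,
            stacklevel=2,
        )
        return 0.0
    if e > 1:
        warnings.warn("excess capped at 1 (100% of screen-detected cases)",
                      CapWarning, stacklevel=2)
        return 1.0
    return e


def crude_excess_from_counts(YA: int, nA: int, YB: int, nB: int, RA: float) -> float:
    """Excess from observed cumulative cancer counts under complete follow-up."""
    if nA <= 0 or nB <= 0:
        raise ValueError("arm sizes must be positive")
    if not (0 <= YA <= nA and 0 <= YB <= nB):
        raise ValueError("counts must satisfy 0 <= Yj <= nj")
    return net_excess(YA / nA, YB / nB, RA)


def se_from_ci(ci_lo: float, ci_hi: float) -> float:
    """Standard error recovered from a symmetric 95% CI: width / (2 * 1.96)."""
    if ci_hi < ci_lo:
        raise ValueError("reversed confidence bounds")
    return (ci_hi - ci_lo) / (2 * 1.96)


def excess_ci(diff: float, seA: float, seB: float, RA: float) -> ExcessEstimate:
    """Excess estimate with z-statistic CI from per-arm standard errors.

    All inputs on the percent scale (as printed in trial reports): ``diff``
    is FA - FB in percentage points, ``seA``/``seB`` the per-arm SEs of the
    net incidences, ``RA`` the screen-detection rate in percent. The ratios
    are scale-free, so the returned :class:`ExcessEstimate` is a proportion
    of screen-detected cases; the lower bound is floored at 0 and the upper
    capped at 1.
    """
    if seA < 0 or seB < 0:
        raise ValueError("standard errors must be non-negative")
    if RA <= 0:
        raise ValueError("RA must be positive")
    se_diff = float(np.hypot(seA, seB))
    e = diff / RA
    lo = (diff - 1.96 * se_diff) / RA
    hi = (diff + 1.96 * se_diff) / RA
    clamp = lambda v: min(max(v, 0.0), 1.0)
    return ExcessEstimate(
        t=np.nan, E=clamp(e), se=se_diff / RA, ci_lo=clamp(lo), ci_hi=clamp(hi)
    )


def linearized_excess_survival(E_T: float, T: int = 15, t0: int = 3) -> ExcessSurvival:
    """Linear-decline excess survival: plateau at 1 to t0, then straight to E_T.

    The slope is ``(1 - E_T) / (T - t0)`` per year — e.g. E_T = 0.117,
    T = 15, t0 = 3 gives a decline of 7.36% of screen-detected cases per
    year. Annual hazards follow from the log identity.
    """
    if not 0 < E_T <= 1:
        raise ValueError("E_T must lie in (0, 1]")
    if not 0 <= t0 < T:
        raise ValueError("need 0 <= t0 < T")
    k = np.arange(T + 1, dtype=float)
    slope = (1.0 - E_T) / (T - t0)
    S1 = np.where(k <= t0, 1.0, 1.0 - slope * (k - t0))
    return ExcessSurvival(T=T, t0=t0, S1=S1)


def excess_survival_from_curves(
    curveA: NetRiskCurve, curveB: NetRiskCurve, RA: float, T: int = 15
) -> ExcessSurvival:
    """Nonparametric excess survival from a pair of net-risk curves.

    S1(k) = min(1, (FA(k) - FB(k)) / RA) on the integer grid, made
    non-increasing by a running minimum (warned when applied). Any
    non-positive S1(k) on the grid is rejected — use the linearized form
    for such noisy inputs.
    """
    if RA <= 0:
        raise ValueError("RA must be positive")
    cA = interpolate_yearly(curveA, T)
    cB = interpolate_yearly(curveB, T)
    raw = (cA.F - cB.F) / RA
    S1 = np.minimum(raw, 1.0)
    S1[0] = 1.0
    if np.any(S1[1:] <= 0):
        k_bad = int(np.argmax(S1[1:] <= 0)) + 1
        raise ValueError(
            f"excess survival non-positive at k={k_bad}; the nonparametric form "
            "is undefined there — use linearized_excess_survival instead"
        )
    if np.any(raw[1:] > 1):
        warnings.warn("excess capped at 1 on part of the grid", CapWarning,
                      stacklevel=2)
    mono = np.minimum.accumulate(S1)
    if np.any(mono < S1 - 1e-12):
        warnings.warn(
            "excess survival repaired to non-increasing by running minimum",
            MonotoneRepairWarning,
            stacklevel=2,
        )
    t0 = int(np.max(np.nonzero(mono >= 1.0)[0])) if mono[1] >= 1.0 else 0
    t0 = min(t0, T - 1)
    return ExcessSurvival(T=T, t0=t0, S1=mono)


def contamination_adjust(E: float, uptake: float, contamination: float) -> float:
    """Scale excess for control-arm PSA testing: E * uptake / (uptake - cont).

    ``uptake`` and ``contamination`` are percentages of each arm ever
    tested; the adjustment treats the measured between-arm contrast as
    diluted by the factor (uptake - contamination)/uptake. Works on
    whatever scale ``E`` is given (percent or proportion).
    """
    if not 0 < uptake <= 100:
        raise ValueError("uptake must lie in (0, 100]")
    if not 0 <= contamination < uptake:
        raise ValueError("need 0 <= contamination < uptake")
    return E * uptake / (uptake - contamination)
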