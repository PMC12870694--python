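"""Model/Results front door for the overdiagnosis analysis.

:class:`OverdiagnosisModel` bundles the method's three inputs — per-arm net
cumulative incidence (as curves, published summary statistics, or
individual records), the screen-detection rate R_A, and an other-cause life
table — and ``fit()`` returns an :class:`OverdiagnosisResults` carrying the
excess estimate with its confidence interval, the excess-survival function
S1 with annual hazards, and the competing-risks projection of overdiagnosis
by age, plus a ``summary()`` table.

Typical use::

    from overdx import OverdiagnosisModel, datasets

    cap = datasets.cap_trial_summary()
    model = OverdiagnosisModel.from_summary(
        cap.F_screen, cap.ci_screen, cap.F_control, cap.ci_control,
        detected=cap.detected, invited=cap.invited,
        lifetable=datasets.synthetic_other_cause_lifetable(),
    )
    res = model.fit(ages=[50, 59, 64, 70, 80])
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import excess as _ex
from .excess import ExcessEstimate, ExcessSurvival
from .hrcurve import HazardRatioCurve, hazard_ratio_curve
from .lifetable import LifeTable
from .netrisk import NetRiskCurve, kaplan_meier_net_risk
from .projection import overdiagnosis_by_age

__all__ = ["OverdiagnosisModel", "OverdiagnosisResults"]


class OverdiagnosisModel:
    """Excess-incidence overdiagnosis model for a one-off-screen trial.

    Parameters
    ----------
    screen_detection_rate : float
        R_A, proportion of those randomised to screening with cancer
        detected at the one-off screen.
    curve_screen, curve_control : NetRiskCurve, optional
        Per-arm net cumulative incidence over follow-up.
    F_screen, F_control : float, optional
        Alternatively, the net incidences at the horizon only
        (proportions), with optional per-arm standard errors ``se_screen``,
        ``se_control`` for the CI chain.
    lifetable : LifeTable, optional
        Other-cause (cause-deleted) mortality; required for the by-age
        projection step.
    horizon : int
        Follow-up horizon T in years (default 15).
    plateau : int
        Years t0 after the screen during which no screen-detected cancer
        would have presented clinically (default 3).
    """

    def __init__(
        self,
        screen_detection_rate: float,
        *,
        curve_screen: NetRiskCurve | None = None,
        curve_control: NetRiskCurve | None = None,
        F_screen: float | None = None,
        F_control: float | None = None,
        se_screen: float = 0.0,
        se_control: float = 0.0,
        lifetable: LifeTable | None = None,
        horizon: int = 15,
        plateau: int = 3,
    ) -> None:
        if screen_detection_rate <= 0:
            raise ValueError("screen_detection_rate must be positive")
        if (curve_screen is None) != (curve_control is None):
            raise ValueError("provide both curves or neither")
        if curve_screen is None and (F_screen is None or F_control is None):
            raise ValueError("provide either curves or horizon net incidences")
        self.screen_detection_rate = float(screen_detection_rate)
        self.curve_screen = curve_screen
        self.curve_control = curve_control
        self.lifetable = lifetable
        self.horizon = int(horizon)
        self.plateau = int(plateau)
        if curve_screen is not None and F_screen is None:
            F_screen = float(np.interp(horizon, curve_screen.times, curve_screen.F))
            F_control = float(np.interp(horizon, curve_control.times, curve_control.F))
            if curve_screen.se is not None and se_screen == 0.0:
                se_screen = float(
                    np.interp(horizon, curve_screen.times, curve_screen.se)
                )
                se_control = float(
                    np.interp(horizon, curve_control.times, curve_control.se)
                )
        self.F_screen = float(F_screen)
        self.F_control = float(F_control)
        self.se_screen = float(se_screen)
        self.se_control = float(se_control)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_summary(
        cls,
        F_screen: float,
        ci_screen: tuple[float, float],
        F_control: float,
        ci_control: tuple[float, float],
        detected: int,
        invited: int,
        scale: str = "percent",
        lifetable: LifeTable | None = None,
        horizon: int = 15,
        plateau: int = 3,
    ) -> "OverdiagnosisModel":
        """Build from published summary statistics (the printed-numbers path).

        ``scale`` applies to the incidences and CIs; the detection rate is
        taken from the raw counts. Per-arm SEs are recovered from the CI
        widths (width / 3.92).
        """
        if scale not in ("percent", "proportion"):
            raise ValueError("scale must be 'percent' or 'proportion'")
        f = 0.01 if scale == "percent" else 1.0
        return cls(
            screen_detection_rate=detected / invited,
            F_screen=F_screen * f,
            F_control=F_control * f,
            se_screen=_ex.se_from_ci(*ci_screen) * f,
            se_control=_ex.se_from_ci(*ci_control) * f,
            lifetable=lifetable,
            horizon=horizon,
            plateau=plateau,
        )

    @classmethod
    def from_curves(
        cls,
        curve_screen: NetRiskCurve,
        curve_control: NetRiskCurve,
        screen_detection_rate: float,
        lifetable: LifeTable | None = None,
        horizon: int = 15,
        plateau: int = 3,
    ) -> "OverdiagnosisModel":
        """Build from full per-arm net-risk curves (e.g. digitized)."""
        return cls(
            screen_detection_rate,
            curve_screen=curve_screen,
            curve_control=curve_control,
            lifetable=lifetable,
            horizon=horizon,
            plateau=plateau,
        )

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        lifetable: LifeTable | None = None,
        horizon: int = 15,
        plateau: int = 3,
        screen_detection_rate: float | None = None,
    ) -> "OverdiagnosisModel":
        """Build from individual subject records via Kaplan-Meier.

        R_A defaults to the screen-detected fraction of the screening arm.
        """
        cs = kaplan_meier_net_risk(records, "screen")
        cc = kaplan_meier_net_risk(records, "control")
        if screen_detection_rate is None:
            screen = records[records["arm"] == "screen"]
            screen_detection_rate = float(screen["screen_detected"].mean())
        return cls(
            screen_detection_rate,
            curve_screen=cs,
            curve_control=cc,
            lifetable=lifetable,
            horizon=horizon,
            plateau=plateau,
        )

    # ------------------------------------------------------------------ #
    def fit(
        self, ages=None, method: str = "linearized"
    ) -> "OverdiagnosisResults":
        """Estimate excess, excess survival and overdiagnosis by age.

        ``method`` selects the S1 construction: ``"linearized"`` (plateau
        then straight-line decline to E(T), the headline specification) or
        ``"nonparametric"`` (yearly capped excess from the curves; requires
        curves).
        """
        if method not in ("linearized", "nonparametric"):
            raise ValueError("method must be 'linearized' or 'nonparametric'")
        RA = self.screen_detection_rate
        diff = self.F_screen - self.F_control
        est = _ex.excess_ci(
            diff * 100.0,
            self.se_screen * 100.0,
            self.se_control * 100.0,
            RA * 100.0,
        )
        est = ExcessEstimate(
            t=float(self.horizon), E=est.E, se=est.se, ci_lo=est.ci_lo,
            ci_hi=est.ci_hi,
        )
        if method == "nonparametric":
            if self.curve_screen is None:
                raise ValueError("nonparametric S1 requires per-arm curves")
            s1 = _ex.excess_survival_from_curves(
                self.curve_screen, self.curve_control, RA, self.horizon
            )
        else:
            s1 = _ex.linearized_excess_survival(
                max(est.E, 1e-12), self.horizon, self.plateau
            )
        od = None
        if ages is not None:
            if self.lifetable is None:
                raise ValueError("overdiagnosis by age requires a life table")
            od = overdiagnosis_by_age(s1, self.lifetable, ages, self.horizon)
        return OverdiagnosisResults(
            model=self, excess=est, excess_survival=s1, overdiagnosis=od,
            method=method,
        )

    def hazard_ratio(self, grid=None, bandwidth: float = 2.0) -> HazardRatioCurve:
        """Smoothed between-arm incidence hazard ratio over follow-up."""
        if self.curve_screen is None:
            raise ValueError("hazard-ratio curve requires per-arm curves")
        return hazard_ratio_curve(
            self.curve_screen, self.curve_control, grid=grid, bandwidth=bandwidth
        )


@dataclass
class OverdiagnosisResults:
    """Fitted quantities of an :class:`OverdiagnosisModel`.

    Attributes
    ----------
    excess : ExcessEstimate
        E(T) with SE and capped/floored 95% CI (proportions).
    excess_survival : ExcessSurvival
        S1(k) and annual excess hazards h1(k).
    overdiagnosis : DataFrame or None
        Columns age, horizon, O — present when ages and a life table were
        supplied.
    """

    model: OverdiagnosisModel
    excess: ExcessEstimate
    excess_survival: ExcessSurvival
    overdiagnosis: pd.DataFrame | None
    method: str

    def contamination_scenario(self, uptake: float, contamination: float) -> float:
        """Excess (percent) rescaled for control-arm testing dilution."""
        return _ex.contamination_adjust(
            self.excess.E * 100.0, uptake, contamination
        )

    @property
    def annual_decline(self) -> float:
        """Post-plateau linear decline of excess, proportion per year."""
        m = self.model
        return (1.0 - self.excess.E) / (m.horizon - m.plateau)

    def summary(self) -> str:
        m = self.model
        e = self.excess
        lines = [
            "        Excess-incidence overdiagnosis model",
            "=" * 56,
            f"Horizon T:                     {m.horizon} years",
            f"Plateau t0:                    {m.plateau} years",
            f"Screen-detection rate R_A:     {m.screen_detection_rate * 100:.2f}%",
            f"Net incidence, screening arm:  {m.F_screen * 100:.2f}%",
            f"Net incidence, control arm:    {m.F_control * 100:.2f}%",
            "-" * 56,
            f"Net excess E(T):               {e.E * 100:.1f}% of screen-detected",
            f"  95% CI:                      {e.ci_lo * 100:.1f}% to {e.ci_hi * 100:.1f}%",
            f"  SE:                          {e.se * 100:.2f}%",
            f"S1 construction:               {self.method}",
            f"Annual decline after plateau:  {self.annual_decline * 100:.2f}%/yr",
        ]
        if self.overdiagnosis is not None:
            lines.append("-" * 56)
            lines.append("Projected overdiagnosis by age (competing mortality):")
            for _, row in self.overdiagnosis.iterrows():
                lines.append(
                    f"  age {int(row['age']):3d}: O(a,{int(row['horizon'])}) = "
                    f"{row['O'] * 100:.0f}%"
                )
        lines.append("=" * 56)
        return "\n".join(lines)

    # ---- plotting ----------------------------------------------------- #
    def plot_excess(self, ax=None):
        """Plot S1(k), the excess-survival function."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s1 = self.excess_survival
        ax.step(np.arange(s1.T + 1), s1.S1 * 100, where="post")
        ax.set_xlabel("years since screening")
        ax.set_ylabel("excess, % of screen-detected cases")
        ax.set_ylim(0, 105)
        return ax

    def plot_overdiagnosis(self, ax=None):
        """Plot projected overdiagnosis against age at screening."""
        import matplotlib.pyplot as plt

        if self.overdiagnosis is None:
            raise ValueError("no by-age projection in this fit")
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.overdiagnosis["age"], self.overdiagnosis["O"] * 100, "o-")
        ax.set_xlabel("age at screening")
        ax.set_ylabel("projected overdiagnosis, %")
        return ax
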