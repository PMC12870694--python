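"""Net cumulative incidence curves F(t) per trial arm.

"Net" risk is cumulative incidence in the hypothetical world with competing
death removed: the Kaplan-Meier complement ``F = 1 - S`` with both deaths
and administrative loss treated as independent censoring. Curves can also be
ingested from CSV (e.g. digitized from a published figure), in which case
the scale (percent vs proportion) must be stated, never guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from ._warnings import MonotoneRepairWarning, NoEventsWarning

__all__ = ["NetRiskCurve", "kaplan_meier_net_risk", "read_curve", "interpolate_yearly"]

#: maximum monotonicity violation repaired silently on ingested curves
MONOTONE_TOLERANCE = 0.002


@dataclass(frozen=True)
class NetRiskCurve:
    """Net cumulative incidence over follow-up time for one trial arm.

    ``F`` is non-decreasing in ``[0, 1)``; ``se``/``ci_lo``/``ci_hi`` are
    optional pointwise standard errors and 95% bounds on F.
    """

    arm: str
    times: np.ndarray
    F: np.ndarray
    se: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        F = np.asarray(self.F, dtype=float)
        if times.ndim != 1 or times.shape != F.shape:
            raise ValueError("times and F must be 1-d arrays of equal length")
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(F < 0) or np.any(F >= 1):
            raise ValueError("F must lie in [0, 1)")
        if np.any(np.diff(F) < 0):
            raise ValueError("F must be non-decreasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "F", F)
        for name in ("se", "ci_lo", "ci_hi"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != times.shape:
                    raise ValueError(f"{name} must match times in length")
                object.__setattr__(self, name, v)
        if self.ci_lo is not None and np.any(self.ci_lo > F + 1e-12):
            raise ValueError("ci_lo must not exceed F")
        if self.ci_hi is not None and np.any(self.ci_hi < F - 1e-12):
            raise ValueError("ci_hi must not be below F")

    def at(self, t, column: str = "F") -> np.ndarray:
        """Right-continuous step evaluation of F (or se/ci_lo/ci_hi) at t."""
        values = getattr(self, column)
        if values is None:
            raise ValueError(f"curve has no {column}")
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        if np.any(idx < 0):
            raise ValueError("t precedes the curve's first time point")
        return values[idx]

    def to_frame(self) -> pd.DataFrame:
        out = {"time": self.times, "value": self.F}
        for name in ("se", "ci_lo", "ci_hi"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return pd.DataFrame(out)


def kaplan_meier_net_risk(
    records: pd.DataFrame, arm: str, loglog_ci: bool = False
) -> NetRiskCurve:
    """Product-limit net cumulative incidence for one arm.

    Deaths and censorings both count as censoring for the cancer endpoint.
    F = 1 - S with Greenwood-formula standard errors; by default the 95% CI
    is the plain normal approximation on F clamped to [0, 1] (matching
    downstream SE recovery from symmetric CI widths), with the log-log
    transform available via ``loglog_ci``.

    Ties between an event and a censoring at the same time follow the
    standard convention: events precede censorings.
    """
    sub = records[records["arm"] == arm]
    if len(sub) == 0:
        raise ValueError(f"no records in arm {arm!r}")
    durations = sub["observed_time"].to_numpy(dtype=float)
    if np.any(durations < 0):
        raise ValueError("observed_time must be non-negative")
    events = (sub["observed_event"] == "cancer").to_numpy()

    if not events.any():
        warnings.warn(
            f"arm {arm!r} has no cancer events; F is identically 0",
            NoEventsWarning,
            stacklevel=2,
        )
        tmax = float(durations.max())
        times = np.array([0.0, tmax]) if tmax > 0 else np.array([0.0])
        z = np.zeros_like(times)
        return NetRiskCurve(arm=arm, times=times, F=z, se=z, ci_lo=z, ci_hi=z)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    tab = kmf.event_table
    # Greenwood: var S(t) = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))
    d = tab["observed"].to_numpy(dtype=float)
    n = tab["at_risk"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    cumvar = np.cumsum(np.where(d > 0, terms, 0.0))
    S = kmf.survival_function_.iloc[:, 0].to_numpy()
    se = S * np.sqrt(cumvar)
    se = np.where(np.isfinite(se), se, 0.0)  # after S hits 0 the variance term is moot
    times = tab.index.to_numpy(dtype=float)  # shared index, includes t=0
    F = 1.0 - S
    if loglog_ci:
        # log-log bands on S map to bands on F with ends swapped
        ci = kmf.confidence_interval_survival_function_
        ci_lo = 1.0 - ci.iloc[:, 1].to_numpy()
        ci_hi = 1.0 - ci.iloc[:, 0].to_numpy()
    else:
        ci_lo = np.clip(F - 1.96 * se, 0.0, 1.0)
        ci_hi = np.clip(F + 1.96 * se, 0.0, 1.0)
    # F < 1 is a NetRiskCurve invariant; a fully-observed cohort can reach 1
    F = np.minimum(F, 1.0 - 1e-12)
    return NetRiskCurve(arm=arm, times=times, F=F, se=se, ci_lo=ci_lo, ci_hi=ci_hi)


def read_curve(path, scale: str, arm: str = "curve") -> NetRiskCurve:
    """Read a (time, value[, ci_lo, ci_hi]) CSV as a net-risk curve.

    ``scale`` is mandatory: ``"percent"`` divides by 100, ``"proportion"``
    passes through. Small non-monotonicities (digitization jitter) up to
    0.002 on the proportion scale are repaired by a running maximum with a
    warning; anything larger is rejected.
    """
    if scale not in ("percent", "proportion"):
        raise ValueError("scale must be 'percent' or 'proportion'")
    df = pd.read_csv(path)
    if "time" not in df.columns or "value" not in df.columns:
        raise ValueError("curve CSV must have columns 'time' and 'value'")
    df = df.sort_values("time")
    factor = 0.01 if scale == "percent" else 1.0
    times = df["time"].to_numpy(dtype=float)
    F = df["value"].to_numpy(dtype=float) * factor

    repaired = np.maximum.accumulate(F)
    worst = float(np.max(repaired - F)) if len(F) else 0.0
    if worst > MONOTONE_TOLERANCE:
        raise ValueError(
            f"curve decreases by {worst:.4f} (> {MONOTONE_TOLERANCE}) even after "
            "running-maximum repair tolerance; refusing to ingest"
        )
    if worst > 0:
        warnings.warn(
            f"non-monotone curve repaired by running maximum (max change {worst:.4g})",
            MonotoneRepairWarning,
            stacklevel=2,
        )
    kw = {}
    for col, name in (("ci_lo", "ci_lo"), ("ci_hi", "ci_hi")):
        if col in df.columns:
            kw[name] = df[col].to_numpy(dtype=float) * factor
    if "ci_lo" in kw:
        kw["ci_lo"] = np.minimum(kw["ci_lo"], repaired)
    if "ci_hi" in kw:
        kw["ci_hi"] = np.maximum(kw["ci_hi"], repaired)
    return NetRiskCurve(arm=arm, times=times, F=repaired, **kw)


def interpolate_yearly(curve: NetRiskCurve, T: int) -> NetRiskCurve:
    """Linear interpolation of F onto the integer grid 0..T; F(0) = 0."""
    if curve.times[-1] < T:
        raise ValueError(
            f"curve ends at t={curve.times[-1]:g}, cannot interpolate to T={T}"
        )
    grid = np.arange(T + 1, dtype=float)
    F = np.interp(grid, curve.times, curve.F, left=0.0)
    F[0] = 0.0
    F = np.maximum.accumulate(F)
    kw = {}
    for name in ("se", "ci_lo", "ci_hi"):
        v = getattr(curve, name)
        if v is not None:
            kw[name] = np.interp(grid, curve.times, v, left=0.0)
    if "ci_lo" in kw:
        kw["ci_lo"] = np.minimum(kw["ci_lo"], F)
    if "ci_hi" in kw:
        kw["ci_hi"] = np.maximum(kw["ci_hi"], F)
    return NetRiskCurve(arm=curve.arm, times=grid, F=F, **kw)
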