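"""Incidence hazard ratio over follow-up time — the compensatory-drop
diagnostic.

From each arm's net-risk curve the cumulative hazard is Λ(t) = -log(1 -
F(t)). The arm-specific hazard at t is the local slope of Λ, estimated by
local-linear regression of Λ on t with a fixed bandwidth; the hazard ratio
is the ratio of slopes. After a one-off screen the ratio is expected to be
far above 1 early (screen-detected cases) and to dip below 1 while the
screened arm's deficit of early-diagnosed cancers plays out; excess
incidence overestimates overdiagnosis until that dip has closed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netrisk import NetRiskCurve

__all__ = ["HazardRatioCurve", "cumulative_hazard", "hazard_ratio_curve"]


@dataclass(frozen=True)
class HazardRatioCurve:
    """Smoothed hazard-ratio estimates on an evaluation grid.

    ``hr`` is NaN where undefined (denominator slope <= 0); ``defined``
    flags usable points and ``edge`` marks grid points whose smoothing
    neighborhood is one-sided (within one bandwidth of the support ends),
    where estimates carry extra boundary bias.
    """

    times: np.ndarray
    hr: np.ndarray
    bandwidth: float
    defined: np.ndarray
    edge: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "hr": self.hr,
                "defined": self.defined,
                "edge": self.edge,
            }
        )


def cumulative_hazard(curve: NetRiskCurve) -> tuple[np.ndarray, np.ndarray]:
    """Λ(t) = -log(1 - F(t)) at the curve's own time points."""
    if np.any(curve.F >= 1):
        raise ValueError("F must be < 1 for a finite cumulative hazard")
    return curve.times.copy(), -np.log1p(-curve.F)


def _local_linear_slope(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Derivative dy/dx on ``grid`` from tricube-weighted local-linear fits."""
    slopes = np.full(grid.shape, np.nan)
    for i, t in enumerate(grid):
        u = (x - t) / bandwidth
        w = np.where(np.abs(u) < 1, (1 - np.abs(u) ** 3) ** 3, 0.0)
        if np.count_nonzero(w) < 2:
            # fall back to the nearest points so edge grid points stay usable
            order = np.argsort(np.abs(x - t))[:4]
            w = np.zeros_like(w)
            w[order] = 1.0
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 0:
            continue
        slopes[i] = (w * (x - xm) * (y - ym)).sum() / sxx
    return slopes


def hazard_ratio_curve(
    curveA: NetRiskCurve,
    curveB: NetRiskCurve,
    grid=None,
    bandwidth: float = 2.0,
) -> HazardRatioCurve:
    """Smoothed hazard ratio hA(t)/hB(t) between two arms.

    Slopes of each arm's cumulative hazard are estimated by local-linear
    regression (tricube kernel, fixed bandwidth in years). Grid points
    where the denominator slope is not positive are masked as undefined
    rather than clipped.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo = max(curveA.times[0], curveB.times[0])
    hi = min(curveA.times[-1], curveB.times[-1])
    if grid is None:
        grid = np.linspace(lo, hi, 61)
    grid = np.asarray(grid, dtype=float)
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError("grid extends beyond the curves' common support")
    tA, lamA = cumulative_hazard(curveA)
    tB, lamB = cumulative_hazard(curveB)
    sA = _local_linear_slope(tA, lamA, grid, bandwidth)
    sB = _local_linear_slope(tB, lamB, grid, bandwidth)
    with np.errstate(divide="ignore", invalid="ignore"):
        hr = np.where((sB > 0) & np.isfinite(sA), sA / sB, np.nan)
    hr = np.where(hr <= 0, np.nan, hr)
    defined = np.isfinite(hr)
    edge = (grid < lo + bandwidth) | (grid > hi - bandwidth)
    return HazardRatioCurve(
        times=grid, hr=hr, bandwidth=float(bandwidth), defined=defined, edge=edge
    )
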