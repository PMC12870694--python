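"""Built-in reference inputs.

Two kinds of convenience data ship with the package, both tiny and both
reconstructed at call time rather than stored:

* the published summary statistics of the CAP trial of a one-off PSA
  screen (per-arm 15-year net cumulative incidence with 95% CIs, and the
  baseline screen-detection count), which are the printed inputs to the
  excess-incidence arithmetic; and
* a SYNTHETIC stand-in for the English male 2021-23 period life table,
  calibrated so that its 15-year death probabilities at ages 50/59/64/70/80
  exactly reproduce the published 10/20/30/49/89%, with a typical log-linear
  prostate-cancer mortality schedule available for cause deletion. It is a
  smooth (quartic log-hazard) approximation, not the national table: hazard
  detail between and beyond the calibration ages is interpolated, so
  results using it agree with the national table only to about a couple of
  percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lifetable import LifeTable, cause_deleted, calibrate_lifetable

__all__ = [
    "CapSummary",
    "cap_trial_summary",
    "synthetic_english_male_lifetable",
    "synthetic_prostate_mortality",
    "synthetic_other_cause_lifetable",
]


@dataclass(frozen=True)
class CapSummary:
    """Published CAP trial summary statistics (percent scale).

    ``F_screen``/``F_control`` are 15-year net cumulative prostate-cancer
    incidences by arm with 95% CIs; ``detected``/``invited`` give the
    baseline screen-detection count; ``uptake`` is the percentage of the
    screening arm with a valid PSA test and ``contamination`` the trialists'
    upper estimate of cumulative control-arm testing.
    """

    F_screen: float = 7.08
    ci_screen: tuple[float, float] = (6.95, 7.21)
    F_control: float = 6.94
    ci_control: tuple[float, float] = (6.82, 7.06)
    detected: int = 2249
    invited: int = 189386
    uptake: float = 36.0
    contamination: float = 15.0
    followup_years: int = 15

    @property
    def screen_detection_rate(self) -> float:
        """R_A as a proportion, from the raw counts."""
        return self.detected / self.invited


def cap_trial_summary() -> CapSummary:
    """The CAP one-off-screen trial's published 15-year summary numbers."""
    return CapSummary()


#: published 15-year death probabilities for English men (2021-23 period
#: rates), the calibration constraints for the synthetic table
ENGLISH_MALE_15Y_DEATH_PROBS = {50: 0.10, 59: 0.20, 64: 0.30, 70: 0.49, 80: 0.89}


def synthetic_english_male_lifetable() -> LifeTable:
    """Synthetic all-cause English male life table (ages 50-95).

    Calibrated so 15-year death probabilities at ages 50/59/64/70/80 equal
    the published 10/20/30/49/89% exactly; smooth in between. A stand-in
    for the national single-year table, which cannot be bundled.
    """
    return calibrate_lifetable(ENGLISH_MALE_15Y_DEATH_PROBS, horizon=15)


def synthetic_prostate_mortality(
    age_min: int = 50, age_max: int = 95
) -> LifeTable:
    """Synthetic prostate-cancer-specific mortality, log-linear in age.

    h(a) = 2e-4 * exp(0.11 * (a - 60)) per year — the typical order of
    magnitude and age gradient of prostate-cancer death rates among all
    English men (roughly 7e-5 at 50 rising to 5e-3 at 90). Used only to
    cause-delete the synthetic all-cause table.
    """
    ages = np.arange(age_min, age_max + 1)
    return LifeTable(ages=ages, hazard=2e-4 * np.exp(0.11 * (ages - 60)))


def synthetic_other_cause_lifetable() -> LifeTable:
    """Synthetic cause-deleted (all-cause minus prostate cancer) table."""
    return cause_deleted(
        synthetic_english_male_lifetable(), synthetic_prostate_mortality()
    )
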