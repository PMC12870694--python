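"""Warning categories raised by overdx computations.

Every warning-generating event in the pipeline (a cap engaging, a negative
excess floored, a monotone repair, a hazard floored at zero, a life-table
extrapolation) uses a distinct category so callers and the run log can
account for each occurrence.
"""

__all__ = [
    "OverdxWarning",
    "CapWarning",
    "NegativeExcessWarning",
    "MonotoneRepairWarning",
    "HazardFloorWarning",
    "ExtrapolationWarning",
    "NoEventsWarning",
]


class OverdxWarning(UserWarning):
    """Base class for all overdx warnings."""


class CapWarning(OverdxWarning):
    """Excess proportion capped at 1 (100% of screen-detected cases)."""


class NegativeExcessWarning(OverdxWarning):
    """Negative excess floored at 0: overdiagnosis is a proportion."""


class MonotoneRepairWarning(OverdxWarning):
    """A curve violating its monotonicity invariant was repaired."""


class HazardFloorWarning(OverdxWarning):
    """Cause-deleted hazard would be negative; floored at 0."""


class ExtrapolationWarning(OverdxWarning):
    """Ages beyond the life table's range use the last tabulated hazard."""


class NoEventsWarning(OverdxWarning):
    """No events observed; the estimated incidence curve is identically 0."""
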