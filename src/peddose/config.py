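"""Per-care-area alert configuration.

Every threshold here is configurable per care area; the defaults are the
hospital-wide baseline values: 10% weight-change and actual-vs-dosing
variance thresholds, daily actual-weight update cadence, 3rd/97th growth
percentile warning band.  Dosing-weight staleness defaults to 3 days since
the update cadence follows unit protocol rather than a fixed rule.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AlertConfig:
    """Thresholds governing the weight-integrity alert suite for one care area."""

    care_area: str = "default"
    #: relative change (vs previous same-kind weight) above which a popup fires
    weight_change_fraction: float = 0.10
    #: relative actual-vs-dosing discrepancy above which a popup fires
    actual_dosing_variance_fraction: float = 0.10
    #: days after which an un-updated actual weight is tagged stale
    stale_days_actual: int = 1
    #: days after which an un-updated dosing weight is tagged stale
    stale_days_dosing: int = 3
    #: growth-percentile warning band (warn outside [low, high])
    percentile_low: float = 3.0
    percentile_high: float = 97.0

    def __post_init__(self) -> None:
        for name in ("weight_change_fraction", "actual_dosing_variance_fraction"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        for name in ("stale_days_actual", "stale_days_dosing"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 < self.percentile_low < self.percentile_high < 100.0:
            raise ValueError("percentile band must satisfy 0 < low < high < 100")
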