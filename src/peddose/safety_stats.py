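"""Pre/post deployment analysis of voluntarily reported adverse drug events.

For each unit and period the inputs are three counts: reports filed, the
subset scored as harmful adverse drug events (ADEs, severity >= 3), and
patient days.  From these the module computes the ADE proportion of reports
(with Wald binomial 95% confidence intervals), the ADE rate per 1000 patient
days (with the analogous interval treating each patient day as a Bernoulli
trial), percent changes between the periods, and Pearson chi-square tests of
the two comparisons:

* proportion comparison — 2x2 table of (ADE, non-ADE) reports by period;
* rate comparison — 2x2 table of (ADE, ADE-free patient days) by period.

Chi-square tests use no continuity correction.  Display convention is
half-up rounding, one decimal for percents and rates, three for p-values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from ._common import round_half_up


@dataclass(frozen=True)
class UnitPeriodCounts:
    """Report/ADE/patient-day counts for one unit in one period."""

    unit: str
    period: str  # pre | post
    n_reports: int
    n_ades: int
    patient_days: int

    def __post_init__(self) -> None:
        if self.period not in ("pre", "post"):
            raise ValueError("period must be 'pre' or 'post'")
        if min(self.n_reports, self.n_ades) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_ades > self.n_reports:
            raise ValueError("ADEs cannot exceed total reports")
        if self.patient_days <= 0:
            raise ValueError("patient_days must be positive")


def rate_per_1000(n_ades: int, patient_days: int) -> float:
    """ADE rate per 1000 patient days."""
    if patient_days <= 0:
        raise ValueError("patient_days must be positive")
    return 1000.0 * n_ades / patient_days


def proportion_ci(k: int, n: int, confidence: float = 0.95) -> tuple:
    """Binomial proportion with a Wald (normal-approximation) interval.

    Returns ``(percent, lower, upper)`` on the percent scale; the lower
    bound is clipped at 0 and the upper at 100.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = k / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    return 100.0 * p, max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half))


def rate_ci(n_ades: int, patient_days: int, confidence: float = 0.95) -> tuple:
    """Rate per 1000 patient days with a Wald interval (patient days as
    Bernoulli trials).  Returns ``(rate, lower, upper)``; lower clipped at 0."""
    pct, lo, hi = proportion_ci(n_ades, patient_days, confidence)
    return pct * 10.0, max(0.0, lo * 10.0), hi * 10.0


def percent_change(pre_value: float, post_value: float) -> float:
    """Relative change of post vs pre, in percent."""
    if pre_value == 0:
        raise ValueError("pre_value must be nonzero")
    return 100.0 * (post_value - pre_value) / pre_value


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple:
    """Pearson chi-square for the 2x2 table [[a, b], [c, d]].

    No continuity correction; df = 1; upper-tail p-value.  Raises on a zero
    row or column margin (the statistic is undefined there).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero margin")
    if np.array_equal(table[0], table[1]):
        # Identical rows: statistic is exactly 0 (avoids float fuzz).
        return 0.0, 1.0
    statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(statistic), float(p)


@dataclass(frozen=True)
class PeriodSummary:
    counts: UnitPeriodCounts
    proportion_pct: float
    proportion_ci: tuple
    rate: float
    rate_ci: tuple


@dataclass(frozen=True)
class PrePostReport:
    """All pre/post quantities for one unit, unrounded.

    ``rows()`` renders the display table at the conventional precision.
    """

    unit: str
    pre: PeriodSummary
    post: PeriodSummary
    proportion_change_pct: float
    proportion_chi2: float
    proportion_p: float
    rate_change_pct: float
    rate_chi2: float
    rate_p: float

    def rows(self) -> list:
        def ci(pair):
            return f"{round_half_up(pair[0]):.1f}-{round_half_up(pair[1]):.1f}"

        return [
            ("No. events", self.pre.counts.n_reports, self.post.counts.n_reports),
            ("No. ADEs", self.pre.counts.n_ades, self.post.counts.n_ades),
            (
                "% ADEs (CI)",
                f"{round_half_up(self.pre.proportion_pct):.1f} ({ci(self.pre.proportion_ci)})",
                f"{round_half_up(self.post.proportion_pct):.1f} ({ci(self.post.proportion_ci)})",
            ),
            (
                "% change (p value)",
                f"{round_half_up(self.proportion_change_pct):.1f} "
                f"({round_half_up(self.proportion_p, 3):.3f})",
                "",
            ),
            ("No. patient days", self.pre.counts.patient_days, self.post.counts.patient_days),
            (
                "ADEs per 1000 patient days (CI)",
                f"{round_half_up(self.pre.rate):.1f} ({ci(self.pre.rate_ci)})",
                f"{round_half_up(self.post.rate):.1f} ({ci(self.post.rate_ci)})",
            ),
            (
                "% change (p value)",
                f"{round_half_up(self.rate_change_pct):.1f} "
                f"({round_half_up(self.rate_p, 3):.3f})",
                "",
            ),
        ]


def _summarize(counts: UnitPeriodCounts) -> PeriodSummary:
    pct, lo, hi = proportion_ci(counts.n_ades, counts.n_reports)
    rate, rlo, rhi = rate_ci(counts.n_ades, counts.patient_days)
    return PeriodSummary(
        counts=counts,
        proportion_pct=pct,
        proportion_ci=(lo, hi),
        rate=rate,
        rate_ci=(rlo, rhi),
    )


def compare_pre_post(pre: UnitPeriodCounts, post: UnitPeriodCounts) -> PrePostReport:
    """Assemble the full pre/post comparison for one unit."""
    if pre.unit != post.unit:
        raise ValueError(f"unit mismatch: {pre.unit!r} vs {post.unit!r}")
    if pre.period != "pre" or post.period != "post":
        raise ValueError("arguments must be the pre and post period counts, in order")
    s_pre, s_post = _summarize(pre), _summarize(post)
    prop_chi2, prop_p = chi_square_2x2(
        pre.n_ades, pre.n_reports - pre.n_ades, post.n_ades, post.n_reports - post.n_ades
    )
    rate_chi2, rate_p = chi_square_2x2(
        pre.n_ades, pre.patient_days - pre.n_ades, post.n_ades, post.patient_days - post.n_ades
    )
    return PrePostReport(
        unit=pre.unit,
        pre=s_pre,
        post=s_post,
        proportion_change_pct=percent_change(s_pre.proportion_pct, s_post.proportion_pct),
        proportion_chi2=prop_chi2,
        proportion_p=prop_p,
        rate_change_pct=percent_change(s_pre.rate, s_post.rate),
        rate_chi2=rate_chi2,
        rate_p=rate_p,
    )


def load_counts(path) -> list:
    """Read a unit-period counts table (CSV: unit, period, events, ades,
    patient_days) into :class:`UnitPeriodCounts` records."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                UnitPeriodCounts(
                    unit=row["unit"],
                    period=row["period"],
                    n_reports=int(row["events"]),
                    n_ades=int(row["ades"]),
                    patient_days=int(row["patient_days"]),
                )
            )
    return records


def reports_from_counts(records: list) -> dict:
    """Pair up pre/post records per unit and build each unit's report."""
    by_unit: dict = {}
    for record in records:
        by_unit.setdefault(record.unit, {})[record.period] = record
    reports = {}
    for unit, periods in by_unit.items():
        if set(periods) != {"pre", "post"}:
            raise ValueError(f"unit {unit!r} needs exactly one pre and one post row")
        reports[unit] = compare_pre_post(periods["pre"], periods["post"])
    return reports
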