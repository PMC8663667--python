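"""HbA1c percent time-in-control by Rosendaal linear interpolation.

The Rosendaal method, devised for INR time-in-therapeutic-range, assigns
each calendar day between two successive laboratory measurements a linearly
interpolated value; the percent time in control (A1c%TIC) is then the share
of days whose interpolated HbA1c lies strictly below the control threshold
(default 8.0%).

Two span conventions are supported for the denominator:

``covered``
    days from the first to the last in-year measurement (the standard
    Rosendaal convention; the default).
``full``
    the whole calendar year, extending the first and last measurements
    outward as constants.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptySeriesError, ValidationError

CONTROL_THRESHOLD = 8.0  # HbA1c %, "in control" means strictly below

HBA1C_MIN, HBA1C_MAX = 3.0, 20.0


@dataclass(frozen=True)
class HbA1cSeries:
    """One patient's dated HbA1c measurements.

    ``measurements`` is a sequence of ``(date, hba1c_percent)`` pairs with
    strictly increasing dates and values within the assay range
    [3.0, 20.0] %.
    """

    patient_id: object
    measurements: tuple = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "measurements", tuple(self.measurements))
        dates = [m[0] for m in self.measurements]
        for d0, d1 in zip(dates, dates[1:]):
            if d1 <= d0:
                raise ValidationError("measurements: dates must be strictly increasing")
        for _, v in self.measurements:
            if not (HBA1C_MIN <= v <= HBA1C_MAX):
                raise ValidationError(
                    f"measurements: hba1c_percent {v} outside [{HBA1C_MIN}, {HBA1C_MAX}]"
                )

    def in_year(self, year: int) -> "HbA1cSeries":
        kept = [(d, v) for d, v in self.measurements if d.year == year]
        return HbA1cSeries(self.patient_id, kept)


@dataclass(frozen=True)
class DailyCurve:
    """One interpolated HbA1c value per covered day."""

    year: int
    values: np.ndarray
    covered_span: tuple  # (first_date, last_date), inclusive

    @property
    def n_days(self) -> int:
        return len(self.values)


def year_length(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


def interpolate_daily(series: HbA1cSeries, year: int, span: str = "covered") -> DailyCurve:
    """Chord-interpolate a measurement series onto a daily grid.

    Only measurements dated within ``year`` are used.  A single in-year
    measurement yields a one-day span carrying its value (or, with
    ``span="full"``, a constant year-long curve).
    """
    if span not in ("covered", "full"):
        raise ValidationError(f"span: must be 'covered' or 'full', got {span!r}")
    meas = [(d, v) for d, v in series.measurements if d.year == year]
    if not meas:
        raise EmptySeriesError(
            f"patient {series.patient_id}: no HbA1c measurements in {year}"
        )
    jan1 = dt.date(year, 1, 1)
    days = np.array([(d - jan1).days for d, _ in meas], dtype=float)
    vals = np.array([v for _, v in meas], dtype=float)
    if span == "covered":
        lo, hi = int(days[0]), int(days[-1])
    else:
        lo, hi = 0, year_length(year) - 1
    grid = np.arange(lo, hi + 1, dtype=float)
    # np.interp holds endpoints constant outside the measurement span,
    # which is exactly the "full" convention's extrapolation rule.
    values = np.interp(grid, days, vals)
    return DailyCurve(
        year=year,
        values=values,
        covered_span=(jan1 + dt.timedelta(days=lo), jan1 + dt.timedelta(days=hi)),
    )


def percent_time_in_control(curve: DailyCurve, threshold: float = CONTROL_THRESHOLD) -> float:
    """Percent of covered days with interpolated HbA1c strictly below threshold."""
    if curve.n_days == 0:
        raise EmptySeriesError("empty daily curve")
    return 100.0 * float(np.count_nonzero(curve.values < threshold)) / curve.n_days


def percent_time_above(curve: DailyCurve, threshold: float = CONTROL_THRESHOLD) -> float:
    """Percent of covered days strictly above threshold (days exactly at the
    threshold belong to neither side)."""
    if curve.n_days == 0:
        raise EmptySeriesError("empty daily curve")
    return 100.0 * float(np.count_nonzero(curve.values > threshold)) / curve.n_days


def mean_hba1c(series: HbA1cSeries, year: int) -> float:
    """Unweighted arithmetic mean of the raw in-year measurements."""
    vals = [v for d, v in series.measurements if d.year == year]
    if not vals:
        raise EmptySeriesError(
            f"patient {series.patient_id}: no HbA1c measurements in {year}"
        )
    return float(np.mean(vals))


def classify_baseline_uncontrolled(
    series: HbA1cSeries,
    year: int,
    threshold: float = CONTROL_THRESHOLD,
    span: str = "covered",
) -> bool:
    """Baseline 'uncontrolled diabetes' sampling rule.

    True iff the raw-lab mean exceeds the threshold AND time in control is
    below 25% of the covered period.
    """
    curve = interpolate_daily(series, year, span=span)
    return mean_hba1c(series, year) > threshold and percent_time_in_control(curve, threshold) < 25.0


def classify_outcome_control(
    series: HbA1cSeries,
    year: int,
    threshold: float = CONTROL_THRESHOLD,
    span: str = "covered",
) -> str:
    """Good / poor / neither control classification.

    good    below-threshold time >= 75% of the period
    poor    above-threshold time >= 75% of the period
    neither otherwise; days exactly at the threshold count toward neither.
    """
    curve = interpolate_daily(series, year, span=span)
    if percent_time_in_control(curve, threshold) >= 75.0:
        return "good"
    if percent_time_above(curve, threshold) >= 75.0:
        return "poor"
    return "neither"


@dataclass(frozen=True)
class GlycemicSummary:
    patient_id: object
    year: int
    a1c_tic_percent: float
    mean_hba1c: float
    n_measurements: int
    control_class: str


def summarize(
    series: HbA1cSeries,
    year: int,
    threshold: float = CONTROL_THRESHOLD,
    span: str = "covered",
) -> GlycemicSummary:
    curve = interpolate_daily(series, year, span=span)
    tic = percent_time_in_control(curve, threshold)
    above = percent_time_above(curve, threshold)
    control_class = "good" if tic >= 75.0 else ("poor" if above >= 75.0 else "neither")
    return GlycemicSummary(
        patient_id=series.patient_id,
        year=year,
        a1c_tic_percent=tic,
        mean_hba1c=mean_hba1c(series, year),
        n_measurements=sum(1 for d, _ in series.measurements if d.year == year),
        control_class=control_class,
    )


def series_from_frame(labs: pd.DataFrame) -> list[HbA1cSeries]:
    """Build one HbA1cSeries per patient from a long labs table
    (patient_id, date, value); rows are sorted by date per patient."""
    out = []
    for pid, grp in labs.groupby("patient_id", sort=True):
        grp = grp.sort_values("date")
        meas = [(d.date() if hasattr(d, "date") else d, float(v))
                for d, v in zip(grp["date"], grp["value"])]
        out.append(HbA1cSeries(pid, meas))
    return out


def summarize_all(
    labs: pd.DataFrame,
    year: int,
    threshold: float = CONTROL_THRESHOLD,
    span: str = "covered",
) -> pd.DataFrame:
    """Per-patient glycemic summary table for one calendar year.

    Patients with no in-year measurement are silently absent from the
    output (the pipeline logs them as exclusions).
    """
    rows = []
    for series in series_from_frame(labs):
        try:
            s = summarize(series, year, threshold, span)
        except EmptySeriesError:
            continue
        rows.append(
            dict(
                patient_id=s.patient_id,
                year=s.year,
                a1c_tic_percent=s.a1c_tic_percent,
                mean_hba1c=s.mean_hba1c,
                n_measurements=s.n_measurements,
                control_class=s.control_class,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "year",
            "a1c_tic_percent",
            "mean_hba1c",
            "n_measurements",
            "control_class",
        ],
    )
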