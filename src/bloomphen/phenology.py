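"""Cumulative-sums-of-anomalies detector for bloom phenology metrics.

Given a complete composite chlorophyll series, the detector finds the main
growth period of the annual cycle:

1. a threshold is set at the series median plus 5 % (``median * 1.05``);
2. anomalies are the series minus the threshold; their cumulative sum rises
   while chlorophyll sits above the threshold and falls while below, so the
   gradient of the cumulative sum — identically the anomaly series — changes
   sign exactly at the threshold crossings;
3. initiation is the first composite of the above-threshold excursion that
   contains the series maximum (the growth peak); termination is the first
   composite after the peak where the gradient turns negative; duration is
   the number of composites between the two.

Zero anomalies are neither a rise nor a fall; ties at the maximum resolve to
the first occurrence; a series that starts above threshold gets an
``initiation_at_start`` flag; several distinct excursions set
``multiple_growth_periods`` and the metrics describe the excursion holding
the global peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Set

import numpy as np

from .errors import ProcessingError, ValidationError
from .timeseries import ChlTimeSeries


@dataclass
class PhenologyMetrics:
    """Detected growth-period timings plus the diagnostic series behind them."""

    source: str
    threshold: float
    initiation_index: Optional[int]
    peak_index: Optional[int]
    termination_index: Optional[int]
    initiation_date: Optional[date]
    peak_date: Optional[date]
    termination_date: Optional[date]
    duration_periods: Optional[int]
    anomalies: np.ndarray
    cumsum: np.ndarray
    gradient: np.ndarray
    flags: Set[str] = field(default_factory=set)
    origin_date: Optional[date] = None
    period_days: int = 5

    def to_dict(self) -> dict:
        iso = lambda d: None if d is None else d.isoformat()
        return {
            "source": self.source,
            "threshold": self.threshold,
            "initiation_index": self.initiation_index,
            "peak_index": self.peak_index,
            "termination_index": self.termination_index,
            "initiation_date": iso(self.initiation_date),
            "peak_date": iso(self.peak_date),
            "termination_date": iso(self.termination_date),
            "duration_periods": self.duration_periods,
            "flags": sorted(self.flags),
        }


def compute_threshold(series: ChlTimeSeries, rule: str = "median_x1.05") -> float:
    """Bloom threshold: series median plus 5 %.

    ``median * 1.05`` is the convention of the threshold-criterion
    literature; ``rule="median_plus_0.05"`` switches to an absolute offset of
    0.05 in series units.
    """
    v = series.values
    if len(v) == 0:
        raise ValidationError("series", "empty series")
    if not series.is_complete:
        raise ValidationError("series", "threshold needs a complete series")
    med = float(np.median(v))
    if rule == "median_x1.05":
        return med * 1.05
    if rule == "median_plus_0.05":
        return med + 0.05
    raise ValidationError("rule", f"unknown threshold rule {rule!r}")


def anomaly_cumsum(series: ChlTimeSeries, threshold: float):
    """Anomalies, their cumulative sum, and the cumulative sum's gradient.

    The gradient is the first difference of the cumulative sum with
    ``gradient[0] = anomalies[0]``, hence identically equal to the anomaly
    series (telescoping) — kept as a separate output because sign changes of
    this gradient are what define the timings.
    """
    anomalies = series.values - threshold
    cumsum = np.cumsum(anomalies)
    gradient = np.diff(cumsum, prepend=0.0)
    return anomalies, cumsum, gradient


def _excursions(anomalies: np.ndarray) -> list:
    """Maximal runs of strictly positive anomalies as (start, stop) pairs."""
    pos = anomalies > 0
    runs = []
    start = None
    for k, flag in enumerate(pos):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            runs.append((start, k))
            start = None
    if start is not None:
        runs.append((start, len(pos)))
    return runs


def detect_metrics(series: ChlTimeSeries,
                   threshold_rule: str = "median_x1.05",
                   threshold: Optional[float] = None) -> PhenologyMetrics:
    """Detect initiation, peak, termination and duration of the main growth period.

    ``threshold`` overrides the rule when given (useful for diagnostics).
    Metrics land as bin indices and as the bin-start calendar dates;
    ``duration_periods = termination_index - initiation_index``.
    """
    if len(series) < 3:
        raise ValidationError("series", "need >= 3 composites")
    if not series.is_complete:
        raise ValidationError("series", "detector needs a gap-free series")
    thr = compute_threshold(series, threshold_rule) if threshold is None \
        else float(threshold)
    anomalies, cumsum, gradient = anomaly_cumsum(series, thr)
    flags: Set[str] = set()
    m = PhenologyMetrics(series.source, thr, None, None, None, None, None,
                         None, None, anomalies, cumsum, gradient, flags,
                         series.origin_date, series.period_days)

    runs = _excursions(anomalies)
    if not runs:
        flags.add("no_initiation")
        return m
    if len(runs) > 1:
        flags.add("multiple_growth_periods")

    peak = int(np.argmax(series.values))  # first occurrence on ties
    main = next(((s, e) for s, e in runs if s <= peak < e), None)
    if main is None:  # peak below threshold cannot happen when runs exist
        flags.add("no_initiation")
        return m
    initiation = main[0]
    if initiation == 0:
        flags.add("initiation_at_start")

    termination = None
    for k in range(peak + 1, len(anomalies)):
        if anomalies[k] < 0:
            termination = k
            break
    if termination is None:
        flags.add("no_termination")

    m.initiation_index = initiation
    m.peak_index = peak
    m.initiation_date = series.bin_start_date(initiation)
    m.peak_date = series.bin_start_date(peak)
    if termination is not None:
        m.termination_index = termination
        m.termination_date = series.bin_start_date(termination)
        m.duration_periods = termination - initiation
    return m
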