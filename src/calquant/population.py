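"""Population metrics: triggering fractions, pattern fractions, triggering times.

Fractions of single / oscillatory / sustained responses use the number of
*triggered* cells as denominator; the triggering time is summarized by its
median because its distribution is long-tailed. Replicates are combined as
arithmetic mean with sample standard deviation, and triggering times as the
mean of the per-replicate medians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_PATTERNS = ("single", "oscillatory", "sustained")


@dataclass
class PopulationSummary:
    """Per-acquisition response statistics."""

    n_cells: int
    n_triggered: int
    triggering_fraction: float
    single_peak_fraction: float
    oscillatory_fraction: float
    sustained_fraction: float
    median_triggering_time_s: float
    condition_label: Optional[str] = None
    koff_per_s: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


@dataclass
class ReplicateAggregate:
    """Mean +/- sd of each fraction across replicates."""

    summaries: Sequence[PopulationSummary]
    n_cells_total: int
    triggering_fraction_mean: float
    triggering_fraction_sd: float
    single_peak_fraction_mean: float
    single_peak_fraction_sd: float
    oscillatory_fraction_mean: float
    oscillatory_fraction_sd: float
    sustained_fraction_mean: float
    sustained_fraction_sd: float
    mean_median_triggering_time_s: float
    condition_label: Optional[str] = None


def summarize(
    classifications: pd.DataFrame,
    condition_label: Optional[str] = None,
    koff_per_s: Optional[float] = None,
) -> PopulationSummary:
    """Summarize one acquisition's per-cell classification table.

    Pattern fractions are of triggered cells; with no triggered cells they
    are reported missing (NaN), not zero. The median triggering time covers
    triggered cells with a defined time.
    """
    if len(classifications) == 0:
        raise ValueError("cannot summarize an empty classification table")
    n_cells = len(classifications)
    trig = classifications[classifications["triggering"].astype(bool)]
    n_triggered = len(trig)

    if n_triggered:
        fracs = {
            p: float((trig["archetype"] == p).sum() / n_triggered) for p in _PATTERNS
        }
        times = trig["triggering_time_s"].dropna()
        median_time = float(np.median(times)) if len(times) else math.nan
    else:
        fracs = {p: math.nan for p in _PATTERNS}
        median_time = math.nan

    return PopulationSummary(
        n_cells=n_cells,
        n_triggered=n_triggered,
        triggering_fraction=n_triggered / n_cells,
        single_peak_fraction=fracs["single"],
        oscillatory_fraction=fracs["oscillatory"],
        sustained_fraction=fracs["sustained"],
        median_triggering_time_s=median_time,
        condition_label=condition_label,
        koff_per_s=koff_per_s,
    )


def _mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if len(arr) == 0:
        return math.nan, math.nan
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else math.nan
    return float(np.mean(arr)), sd


def aggregate_replicates(
    summaries: Sequence[PopulationSummary], condition_label: Optional[str] = None
) -> ReplicateAggregate:
    """Combine replicate acquisitions of one condition.

    Replicates with no triggered cells contribute nothing to the
    fractions-of-triggered means (their pattern fractions are undefined);
    this is logged rather than silently treated as zero.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 replicates to aggregate")
    empty = [i for i, s in enumerate(summaries) if s.n_triggered == 0]
    if empty:
        log.warning(
            "replicates %s have no triggered cells; excluded from "
            "fraction-of-triggered means", empty,
        )

    tf = _mean_sd([s.triggering_fraction for s in summaries])
    sf = _mean_sd([s.single_peak_fraction for s in summaries])
    of = _mean_sd([s.oscillatory_fraction for s in summaries])
    uf = _mean_sd([s.sustained_fraction for s in summaries])
    mt = _mean_sd([s.median_triggering_time_s for s in summaries])
    return ReplicateAggregate(
        summaries=list(summaries),
        n_cells_total=int(sum(s.n_cells for s in summaries)),
        triggering_fraction_mean=tf[0],
        triggering_fraction_sd=tf[1],
        single_peak_fraction_mean=sf[0],
        single_peak_fraction_sd=sf[1],
        oscillatory_fraction_mean=of[0],
        oscillatory_fraction_sd=of[1],
        sustained_fraction_mean=uf[0],
        sustained_fraction_sd=uf[1],
        mean_median_triggering_time_s=mt[0],
        condition_label=condition_label,
    )


def compare_conditions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Welch two-sample t test on replicate-level values.

    Returns (t statistic, two-sided p). Plain plumbing for condition
    comparisons; no multiplicity correction is applied.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per condition")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
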