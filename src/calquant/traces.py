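"""Trace normalization, baseline estimation, derivative signals and peaks.

All traces of one acquisition share a single normalization constant: the
maximum raw intensity any cell reaches during the terminal ionomycin
window. This compensates inhomogeneous dye loading while preserving
relative response amplitudes across the population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d


@dataclass
class CalciumTrace:
    """One cell's time series, ready for classification.

    ``normalized`` is the raw trace divided by the population's ionomycin
    maximum; ``baseline`` is this cell's resting level on the normalized
    scale, estimated from the first post-landing frames.
    """

    cell_id: int
    times_s: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    baseline: float
    landing_frame: int
    analysis_end_frame: int

    @property
    def window(self) -> np.ndarray:
        """Baseline-subtracted normalized values over the analysis window."""
        return self.normalized[self.landing_frame : self.analysis_end_frame] - self.baseline


@dataclass
class PeakSet:
    """Peaks of a derivative signal: frames, heights, effective threshold."""

    peak_frames: np.ndarray
    peak_heights: np.ndarray
    threshold_used: float

    @property
    def n_peaks(self) -> int:
        return len(self.peak_frames)


def normalization_constant(
    traces: pd.DataFrame, ionomycin_window: Tuple[int, int], value_col: str = "intensity"
) -> float:
    """Population normalization constant M: max raw intensity over the window."""
    start, end = ionomycin_window
    if end <= start:
        raise ValueError("ionomycin window is empty")
    sel = traces[(traces["frame"] >= start) & (traces["frame"] < end)]
    if sel.empty:
        raise ValueError("no trace samples fall inside the ionomycin window")
    m = float(np.nanmax(sel[value_col].to_numpy()))
    if not m > 0:
        raise ValueError("non-positive population maximum; cannot normalize")
    return m


def normalize_population(
    traces: pd.DataFrame,
    ionomycin_window: Tuple[int, int],
    value_col: str = "intensity",
) -> Tuple[pd.DataFrame, float]:
    """Divide every trace by the population's ionomycin-window maximum.

    Returns a copy of the table with a ``normalized`` column and the
    constant used. The maximizing sample attains exactly 1.0, making
    normalization idempotent and invariant to global intensity rescaling.
    """
    m = normalization_constant(traces, ionomycin_window, value_col)
    out = traces.copy()
    out["normalized"] = out[value_col] / m
    return out, m


def estimate_baseline(
    values: np.ndarray,
    landing_frame: int,
    baseline_window_frames: int = 25,
    analysis_end_frame: Optional[int] = None,
) -> float:
    """Median of the first post-landing frames: the cell's resting level.

    The window [landing, landing + baseline_window) must hold at least 3
    frames and stay inside the analysis window.
    """
    end = landing_frame + baseline_window_frames
    limit = analysis_end_frame if analysis_end_frame is not None else len(values)
    if end > limit:
        raise ValueError("baseline window extends past the analysis end")
    window = np.asarray(values[landing_frame:end], dtype=float)
    window = window[~np.isnan(window)]
    if len(window) < 3:
        raise ValueError("need at least 3 post-landing frames for a baseline")
    return float(np.median(window))


def smooth(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; edges use nearest-value padding."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    return uniform_filter1d(np.asarray(values, dtype=float), size=window, mode="nearest")


def derivative(values: np.ndarray, smooth_window: int = 5) -> np.ndarray:
    """Finite-difference rate of change per frame of the smoothed trace.

    Central differences in the interior, one-sided at the ends. A short
    moving average precedes differencing because finite differences amplify
    frame-to-frame noise; the window is short relative to flux rise times.
    """
    y = np.asarray(values, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 frames to differentiate")
    return np.gradient(smooth(y, smooth_window))


def robust_sigma(values: np.ndarray) -> float:
    """Gaussian-consistent spread estimate from the median absolute deviation."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def _local_maxima(series: np.ndarray) -> np.ndarray:
    """Interior local maxima; a plateau counts once, at its first frame."""
    idx = []
    n = len(series)
    i = 1
    while i < n - 1:
        if series[i] > series[i - 1]:
            j = i
            while j + 1 < n and series[j + 1] == series[i]:
                j += 1
            if j < n - 1 and series[j + 1] < series[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def find_peaks(
    series: np.ndarray, min_threshold: float, min_separation_frames: int = 1
) -> PeakSet:
    """Local maxima with height >= ``min_threshold``, at least
    ``min_separation_frames`` apart.

    Within a violating pair the higher peak wins; exact ties resolve toward
    the earlier frame. Endpoints are not peaks.
    """
    if not min_threshold > 0:
        raise ValueError("min_threshold must be positive")
    series = np.asarray(series, dtype=float)
    candidates = _local_maxima(series)
    candidates = candidates[series[candidates] >= min_threshold]

    # greedy selection: highest first, earlier frame on ties
    order = sorted(candidates, key=lambda i: (-series[i], i))
    kept: list = []
    for i in order:
        if all(abs(i - k) >= min_separation_frames for k in kept):
            kept.append(i)
    kept.sort()
    frames = np.asarray(kept, dtype=int)
    return PeakSet(
        peak_frames=frames,
        peak_heights=series[frames] if len(frames) else np.empty(0),
        threshold_used=float(min_threshold),
    )


def build_traces(
    normalized: pd.DataFrame,
    landing_frames: Optional[pd.Series] = None,
    analysis_end_frame: Optional[int] = None,
    baseline_window_frames: int = 25,
    frame_interval_s: float = 0.82,
) -> list:
    """Assemble :class:`CalciumTrace` objects from a normalized long table.

    ``normalized`` must carry cell_id, frame and normalized columns (as
    produced by :func:`normalize_population`); ``landing_frames`` maps
    cell_id to landing frame (default 0 for trace-only inputs without
    landing metadata).
    """
    out = []
    for cell_id, grp in normalized.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        vals = grp["normalized"].to_numpy()
        raw = grp["intensity"].to_numpy() if "intensity" in grp else vals.copy()
        times = (
            grp["time_s"].to_numpy()
            if "time_s" in grp
            else grp["frame"].to_numpy() * frame_interval_s
        )
        landing = 0
        if landing_frames is not None and cell_id in landing_frames.index:
            landing = int(landing_frames.loc[cell_id])
        end = analysis_end_frame if analysis_end_frame is not None else len(vals)
        end = min(end, len(vals))
        baseline = estimate_baseline(
            vals, landing, baseline_window_frames, analysis_end_frame=end
        )
        out.append(
            CalciumTrace(
                cell_id=int(cell_id),
                times_s=times,
                raw=raw,
                normalized=vals,
                baseline=baseline,
                landing_frame=landing,
                analysis_end_frame=end,
            )
        )
    return out
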