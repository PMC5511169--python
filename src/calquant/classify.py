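"""Fourier-domain triggering classification, pattern sorting, triggering time.

A cell's baseline-subtracted normalized trace over its analysis window
(landing to the start of the ionomycin surge) is Fourier transformed; the
DC term is discarded and the remaining complex components are compared
against a single modulus threshold, the *triggering radius*. Noise-only
traces scatter tightly around the origin of the complex plane, while
calcium fluxes push components outward; a cell is called triggering when
strictly more than 10% of its non-DC components fall outside the radius.

Triggering cells are then sorted by counting peaks in the derivative of
the intensity trace: two or more peaks above the minimum threshold is
oscillatory, one peak with appreciable post-peak decay is a single flux,
and one peak with shallow or no decay (or a rise without a discrete
derivative peak) is sustained. The triggering time is the lag from landing
to the first derivative peak, i.e. to the steepest rise of the first flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .traces import CalciumTrace, PeakSet, derivative, find_peaks, robust_sigma, smooth

#: Radius clamp for the automatic mode, on the 1/N-scaled modulus scale.
AUTO_RADIUS_BOUNDS = (1e-4, 1.0)


@dataclass
class FourierSignature:
    """Non-DC DFT components of one analysis-window trace.

    Components are the 1/N-scaled DFT values at k = 1 .. N-1 (DC excluded),
    so moduli are on the normalized-intensity amplitude scale and obey
    conjugate symmetry for real input.
    """

    components: np.ndarray
    n_points: int
    radius_used: float
    fraction_outside: float

    @property
    def moduli(self) -> np.ndarray:
        return np.abs(self.components)

    @property
    def energy(self) -> float:
        """Total non-DC spectral energy = variance of the windowed trace."""
        return float(np.sum(self.moduli**2))


def _window_dft(x: np.ndarray) -> np.ndarray:
    """1/N-scaled DFT with the DC term removed."""
    n = len(x)
    return np.fft.fft(x)[1:] / n


def fourier_signature(
    trace: Union[CalciumTrace, np.ndarray], radius: float
) -> FourierSignature:
    """Fourier signature of a trace's analysis window.

    Accepts a :class:`CalciumTrace` (its baseline-subtracted window is
    used) or a bare array already on that scale. The window must hold at
    least 8 frames.
    """
    x = trace.window if isinstance(trace, CalciumTrace) else np.asarray(trace, float)
    if len(x) < 8:
        raise ValueError("analysis window shorter than 8 frames")
    if np.any(np.isnan(x)):
        raise ValueError("analysis window contains missing frames")
    if not radius > 0:
        raise ValueError("triggering radius must be positive")
    comps = _window_dft(x)
    fraction = float(np.mean(np.abs(comps) > radius))
    return FourierSignature(
        components=comps,
        n_points=len(comps),
        radius_used=float(radius),
        fraction_outside=fraction,
    )


def classify_triggering(
    signature: FourierSignature, fraction_threshold: float = 0.10
) -> bool:
    """Strictly more than ``fraction_threshold`` of components outside the radius."""
    return signature.fraction_outside > fraction_threshold


def auto_radius(
    signatures: Sequence[FourierSignature],
    noise_fraction: float = 0.25,
    quantile: float = 0.99,
    bounds: Tuple[float, float] = AUTO_RADIUS_BOUNDS,
) -> float:
    """Data-driven triggering radius from the population's noise floor.

    The quarter of cells with the lowest spectral energy (equivalently, the
    lowest trace variance) serves as a noise-proxy population; the radius is
    the 99th percentile of their pooled component moduli, clamped to
    ``bounds``. Requires at least 20 cells; with fewer, pass an explicit
    radius.
    """
    if len(signatures) < 20:
        raise ValueError("auto radius needs >= 20 cells; pass an explicit radius")
    energies = np.array([s.energy for s in signatures])
    n_noise = max(1, int(np.ceil(noise_fraction * len(signatures))))
    quiet = np.argsort(energies, kind="stable")[:n_noise]
    pooled = np.concatenate([signatures[i].moduli for i in quiet])
    radius = float(np.quantile(pooled, quantile))
    return float(np.clip(radius, *bounds))


@dataclass
class ResponseClassification:
    """Per-cell classification record."""

    cell_id: int
    triggering: bool
    archetype: str
    n_peaks: int
    triggering_time_s: Optional[float]
    fraction_outside: float
    radius_used: float
    peak_threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        if self.archetype == "none" and self.triggering:
            raise ValueError("archetype 'none' implies non-triggering")
        if self.archetype == "oscillatory" and self.n_peaks < 2:
            raise ValueError("oscillatory requires at least 2 peaks")


def detect_flux_peaks(
    trace: CalciumTrace,
    min_peak_threshold: float = 0.01,
    peak_sigma_factor: float = 3.5,
    min_separation_frames: int = 12,
    smooth_window: int = 5,
) -> PeakSet:
    """Derivative peaks of one trace over its analysis window.

    The effective height threshold is the larger of the configured floor
    and ``peak_sigma_factor`` robust standard deviations of the derivative
    signal, so the flux-counting rule adapts to each trace's noise level;
    the threshold actually applied is recorded in the result.
    """
    window = trace.normalized[trace.landing_frame : trace.analysis_end_frame]
    deriv = derivative(window, smooth_window)
    threshold = max(min_peak_threshold, peak_sigma_factor * robust_sigma(deriv))
    peaks = find_peaks(deriv, threshold, min_separation_frames)
    return PeakSet(
        peak_frames=peaks.peak_frames + trace.landing_frame,
        peak_heights=peaks.peak_heights,
        threshold_used=peaks.threshold_used,
    )


def classify_pattern(
    trace: CalciumTrace,
    peaks: PeakSet,
    sustained_decay_fraction: float = 0.2,
    decay_fit_window_frames: int = 100,
    smooth_window: int = 5,
    triggering: bool = True,
) -> str:
    """Sort a triggering cell into single / oscillatory / sustained.

    Two or more derivative peaks above the threshold is oscillatory. With
    one peak, the post-peak intensity slope decides: a linear fit over the
    decay window whose magnitude is below ``sustained_decay_fraction`` x
    (amplitude / window) marks a shallow-or-no-decay, i.e. sustained,
    response; otherwise the cell had a single flux. A triggering cell with
    no discrete derivative peak (a slow rise) is reported sustained.
    """
    if not triggering:
        return "none"
    if peaks.n_peaks >= 2:
        return "oscillatory"
    if peaks.n_peaks == 0:
        return "sustained"

    y = smooth(trace.normalized, smooth_window)
    end = trace.analysis_end_frame
    deriv_peak = int(peaks.peak_frames[0])
    # crest of the flux: intensity maximum shortly after the steepest rise
    search_end = min(deriv_peak + 2 * smooth_window + 10, end)
    crest = deriv_peak + int(np.argmax(y[deriv_peak:search_end]))
    fit_end = min(crest + decay_fit_window_frames, end)
    if fit_end - crest < 10:
        return "sustained"  # too close to the window end to observe decay
    segment = y[crest:fit_end]
    slope = float(np.polyfit(np.arange(len(segment)), segment, 1)[0])
    amplitude = float(y[crest] - trace.baseline)
    threshold = sustained_decay_fraction * amplitude / len(segment)
    return "sustained" if abs(slope) < threshold else "single"


def triggering_time(
    peaks: PeakSet, landing_frame: int, frame_interval_s: float = 0.82
) -> Optional[float]:
    """Seconds from landing to the first flux (first derivative peak).

    Returns None (reported as missing) when no peak was found.
    """
    if peaks.n_peaks == 0:
        return None
    dt = (int(peaks.peak_frames[0]) - landing_frame) * frame_interval_s
    if dt < 0:
        raise ValueError("first peak precedes the landing frame")
    return float(dt)


def classify_cell(
    trace: CalciumTrace,
    radius: float,
    fraction_threshold: float = 0.10,
    min_peak_threshold: float = 0.01,
    peak_sigma_factor: float = 3.5,
    min_separation_frames: int = 12,
    smooth_window: int = 5,
    sustained_decay_fraction: float = 0.2,
    decay_fit_window_frames: int = 100,
    frame_interval_s: float = 0.82,
) -> ResponseClassification:
    """Full per-cell classification: triggering, archetype, triggering time."""
    signature = fourier_signature(trace, radius)
    triggering = classify_triggering(signature, fraction_threshold)
    peaks = detect_flux_peaks(
        trace, min_peak_threshold, peak_sigma_factor, min_separation_frames, smooth_window
    )
    archetype = classify_pattern(
        trace,
        peaks,
        sustained_decay_fraction,
        decay_fit_window_frames,
        smooth_window,
        triggering=triggering,
    )
    t_trig = (
        triggering_time(peaks, trace.landing_frame, frame_interval_s)
        if triggering
        else None
    )
    return ResponseClassification(
        cell_id=trace.cell_id,
        triggering=triggering,
        archetype=archetype,
        n_peaks=peaks.n_peaks if triggering else peaks.n_peaks,
        triggering_time_s=t_trig,
        fraction_outside=signature.fraction_outside,
        radius_used=signature.radius_used,
        peak_threshold_used=peaks.threshold_used,
    )


def classify_population(
    traces: Iterable[CalciumTrace],
    radius: Union[float, str] = "auto",
    fraction_threshold: float = 0.10,
    frame_interval_s: float = 0.82,
    **peak_kwargs,
) -> Tuple[pd.DataFrame, float]:
    """Classify every cell of an acquisition; returns (table, radius used).

    With ``radius="auto"`` the triggering radius is resolved from the
    population's noise floor (see :func:`auto_radius`) before any cell is
    classified.
    """
    traces = list(traces)
    if isinstance(radius, str):
        if radius != "auto":
            raise ValueError(f"radius must be a float or 'auto', got {radius!r}")
        probe = [fourier_signature(t, 1.0) for t in traces]
        resolved = auto_radius(probe)
    else:
        resolved = float(radius)

    rows = []
    for trace in traces:
        c = classify_cell(
            trace,
            resolved,
            fraction_threshold=fraction_threshold,
            frame_interval_s=frame_interval_s,
            **peak_kwargs,
        )
        rows.append(
            {
                "cell_id": c.cell_id,
                "triggering": c.triggering,
                "archetype": c.archetype,
                "n_peaks": c.n_peaks,
                "fraction_outside": c.fraction_outside,
                "radius_used": c.radius_used,
                "peak_threshold_used": c.peak_threshold_used,
                "triggering_time_s": c.triggering_time_s,
            }
        )
    columns = [
        "cell_id", "triggering", "archetype", "n_peaks", "fraction_outside",
        "radius_used", "peak_threshold_used", "triggering_time_s",
    ]
    return pd.DataFrame(rows, columns=columns), resolved
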