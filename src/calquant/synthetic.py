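"""Ground-truth-labeled synthetic calcium traces and image stacks.

The generator emulates the assay geometry the pipeline targets: sparsely
seeded cells land on a coverslip over the first minutes of a ~14-minute
acquisition (1000 frames at 0.82 s), respond with one of four flux
archetypes, and a terminal ionomycin surge (final 100 frames) forces every
cell toward its maximal indicator fluorescence.

Flux archetypes
---------------
single
    One transient: linear rise over ``rise_frames`` followed by an
    exponential decay with time constant ``decay_frames``.
oscillatory
    ``n_fluxes`` (>= 2) such transients spaced ``flux_period_frames`` apart.
sustained
    One rise to a plateau whose decay constant is ``sustained_decay_factor``
    times slower than a single flux (shallow or no decay).
none
    Baseline plus noise only.

Ground-truth labels record, for every flux, both the intensity-peak frame
(end of the rise) and the flux-time frame (midpoint of the rise, the
instant of steepest influx, which is what a derivative-peak detector
localizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import ImageStack

ARCHETYPES = ("single", "oscillatory", "sustained", "none")


@dataclass
class TraceModel:
    """Parameters of one synthetic per-cell calcium trace (normalized a.u.)."""

    archetype: str = "single"
    landing_frame: int = 50
    trigger_delay_frames: int = 0
    amplitude: float = 0.8
    rise_frames: int = 10
    decay_frames: int = 80
    sustained_decay_factor: float = 10.0
    n_fluxes: Optional[int] = None
    flux_period_frames: int = 60
    noise_sd: float = 0.05
    baseline_level: float = 0.1

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.archetype != "none" and not self.amplitude > 0:
            raise ValueError("amplitude must be positive for responding archetypes")
        if self.archetype == "oscillatory":
            if self.n_fluxes is None:
                self.n_fluxes = 3
            if self.n_fluxes < 2:
                raise ValueError("oscillatory traces need n_fluxes >= 2")
            if self.flux_period_frames < 1:
                raise ValueError("flux_period_frames must be >= 1")
        elif self.n_fluxes is not None:
            raise ValueError("n_fluxes is only meaningful for oscillatory traces")
        if self.rise_frames < 1 or self.decay_frames < 1:
            raise ValueError("rise_frames and decay_frames must be >= 1")
        if self.landing_frame < 0 or self.trigger_delay_frames < 0:
            raise ValueError("frame offsets must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def onset_frame(self) -> int:
        """Frame at which the first flux starts rising."""
        return self.landing_frame + self.trigger_delay_frames


@dataclass
class GroundTruthLabel:
    """Per-cell ground truth for generator output."""

    archetype: str
    landing_frame: int
    onset_frame: int
    flux_frames: np.ndarray  # steepest-rise instant of each flux
    peak_frames: np.ndarray  # intensity maximum of each flux

    @property
    def responding(self) -> bool:
        return self.archetype != "none"

    @property
    def first_flux_frame(self) -> Optional[int]:
        return int(self.flux_frames[0]) if len(self.flux_frames) else None


def _pulse(t: np.ndarray, onset: int, amplitude: float, rise: int, tau: float) -> np.ndarray:
    """One flux: linear rise over ``rise`` frames, then exponential decay."""
    y = np.zeros_like(t, dtype=float)
    rising = (t >= onset) & (t <= onset + rise)
    y[rising] = amplitude * (t[rising] - onset) / rise
    decaying = t > onset + rise
    y[decaying] = amplitude * np.exp(-(t[decaying] - onset - rise) / tau)
    return y


def clean_trace(model: TraceModel, frame_count: int) -> Tuple[np.ndarray, GroundTruthLabel]:
    """Noise-free trace and its ground truth (baseline included, no ionomycin)."""
    if frame_count <= model.onset_frame + model.rise_frames:
        raise ValueError("frame_count must exceed onset_frame + rise_frames")
    t = np.arange(frame_count)
    y = np.full(frame_count, model.baseline_level, dtype=float)

    onsets: list = []
    if model.archetype == "single":
        onsets = [model.onset_frame]
        tau = float(model.decay_frames)
    elif model.archetype == "oscillatory":
        onsets = [
            model.onset_frame + i * model.flux_period_frames
            for i in range(model.n_fluxes or 0)
        ]
        tau = float(model.decay_frames)
    elif model.archetype == "sustained":
        onsets = [model.onset_frame]
        tau = model.sustained_decay_factor * model.decay_frames
    else:  # none
        tau = float(model.decay_frames)

    # pulses whose rise would not complete inside the acquisition are
    # neither rendered nor labeled (an oscillating cell may outlast the movie)
    onsets = [o for o in onsets if o + model.rise_frames < frame_count]
    for onset in onsets:
        y += _pulse(t, onset, model.amplitude, model.rise_frames, tau)

    flux_frames = np.array([o + model.rise_frames // 2 for o in onsets], dtype=int)
    peak_frames = np.array([o + model.rise_frames for o in onsets], dtype=int)
    label = GroundTruthLabel(
        archetype=model.archetype,
        landing_frame=model.landing_frame,
        onset_frame=model.onset_frame,
        flux_frames=flux_frames,
        peak_frames=peak_frames,
    )
    return y, label


def apply_ionomycin(
    y: np.ndarray, start_frame: int, gain: float, ramp_frames: int = 10
) -> np.ndarray:
    """Drive a trace toward ``gain`` x its pre-surge maximum from ``start_frame``.

    Models the terminal ionophore addition that forces maximal indicator
    fluorescence in every viable cell; used downstream for population
    normalization.
    """
    if gain < 1:
        raise ValueError("ionomycin_gain must be >= 1")
    if not 0 < start_frame < len(y):
        raise ValueError("ionomycin start must fall inside the trace")
    out = y.copy()
    target = gain * float(np.max(y[:start_frame]))
    ramp_end = min(start_frame + ramp_frames, len(y))
    frac = np.linspace(0, 1, ramp_end - start_frame, endpoint=False) + 1 / max(
        ramp_end - start_frame, 1
    )
    out[start_frame:ramp_end] = y[start_frame:ramp_end] * (1 - frac) + target * frac
    out[ramp_end:] = target
    return out


def generate_trace(
    model: TraceModel,
    frame_count: int,
    seed: Union[int, np.random.Generator, None] = None,
    ionomycin_start_frame: Optional[int] = None,
    ionomycin_gain: float = 1.25,
) -> Tuple[np.ndarray, GroundTruthLabel]:
    """Generate one noisy trace plus ground truth.

    Noise is additive Gaussian with sd ``model.noise_sd``; the optional
    ionomycin surge is applied to the clean signal before noise.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    y, label = clean_trace(model, frame_count)
    if ionomycin_start_frame is not None:
        y = apply_ionomycin(y, ionomycin_start_frame, ionomycin_gain)
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, size=frame_count)
    return y, label


def _label_row(cell_id: int, label: GroundTruthLabel) -> Dict:
    return {
        "cell_id": cell_id,
        "archetype": label.archetype,
        "landing_frame": label.landing_frame,
        "onset_frame": label.onset_frame,
        "first_flux_frame": label.first_flux_frame,
        "n_fluxes_true": len(label.flux_frames),
        "flux_frames": ";".join(str(f) for f in label.flux_frames),
        "peak_frames": ";".join(str(f) for f in label.peak_frames),
    }


def _draw_model(
    rng: np.random.Generator,
    archetype: str,
    frame_count: int,
    analysis_end: int,
    base: TraceModel,
) -> TraceModel:
    """Draw landing frame and trigger delay for one cell of a population.

    Cells land over the first ~35% of the pre-ionomycin window (they are
    pipetted at acquisition start and sediment); the flux follows landing
    after a delay of at least 30 frames (so the 25-frame baseline window is
    flux-free) with an exponential tail, mirroring long-tailed triggering
    times.
    """
    landing_lo = min(5, max(1, analysis_end // 6))
    landing = int(rng.integers(landing_lo, max(landing_lo + 1, int(0.35 * analysis_end))))
    delay_floor = min(30, max(1, analysis_end // 8))
    delay = delay_floor + int(rng.exponential(120))
    latest = analysis_end - base.rise_frames - 2 * base.decay_frames
    kwargs = dict(
        archetype=archetype,
        landing_frame=landing,
        noise_sd=base.noise_sd,
        amplitude=base.amplitude,
        rise_frames=base.rise_frames,
        decay_frames=base.decay_frames,
        sustained_decay_factor=base.sustained_decay_factor,
        baseline_level=base.baseline_level,
        flux_period_frames=base.flux_period_frames,
    )
    if archetype == "oscillatory":
        n_fluxes = int(rng.integers(2, 5))
        latest -= (n_fluxes - 1) * base.flux_period_frames
        kwargs["n_fluxes"] = n_fluxes
        # oscillations return toward baseline between spikes: keep the
        # inter-flux decay shorter than the period so pulses do not ratchet
        kwargs["decay_frames"] = min(base.decay_frames, base.flux_period_frames // 2)
    hard_cap = analysis_end - base.rise_frames - 2 - landing  # first flux must fit
    if hard_cap < 1:
        raise ValueError(
            "analysis window too short for the requested trace geometry"
        )
    onset_cap = max(landing + delay_floor, latest)
    delay = min(delay, max(delay_floor, onset_cap - landing), hard_cap)
    kwargs["trigger_delay_frames"] = delay
    return TraceModel(**kwargs)


def generate_population(
    n_per_archetype: Union[Dict[str, int], Sequence[int]],
    frame_count: int = 1000,
    seed: int = 0,
    trace_params: Optional[TraceModel] = None,
    ionomycin_start_frame: Optional[int] = 900,
    ionomycin_gain: float = 1.25,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a labeled trace population as CSV-ready long tables.

    Returns ``(traces, labels)``: ``traces`` has one row per cell and frame
    (cell_id, frame, time_s, intensity); ``labels`` one row per cell.
    Deterministic for a fixed seed.
    """
    if not isinstance(n_per_archetype, dict):
        n_per_archetype = dict(zip(ARCHETYPES, n_per_archetype))
    unknown = set(n_per_archetype) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetypes: {sorted(unknown)}")
    if any(n < 0 for n in n_per_archetype.values()):
        raise ValueError("archetype counts must be >= 0")

    base = trace_params or TraceModel()
    analysis_end = ionomycin_start_frame or frame_count
    rng = np.random.default_rng(seed)
    trace_rows = []
    label_rows = []
    cell_id = 0
    frames = np.arange(frame_count)
    for archetype in ARCHETYPES:
        for _ in range(n_per_archetype.get(archetype, 0)):
            model = _draw_model(rng, archetype, frame_count, analysis_end, base)
            y, label = generate_trace(
                model,
                frame_count,
                seed=rng,
                ionomycin_start_frame=ionomycin_start_frame,
                ionomycin_gain=ionomycin_gain,
            )
            trace_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell_id,
                        "frame": frames,
                        "time_s": frames * 0.82,
                        "intensity": y,
                    }
                )
            )
            label_rows.append(_label_row(cell_id, label))
            cell_id += 1

    if not trace_rows:
        traces = pd.DataFrame(columns=["cell_id", "frame", "time_s", "intensity"])
        labels = pd.DataFrame(columns=list(_label_row(0, GroundTruthLabel("none", 0, 0, np.array([]), np.array([]))).keys()))
        return traces, labels
    return pd.concat(trace_rows, ignore_index=True), pd.DataFrame(label_rows)


@dataclass
class StackModel:
    """Parameters of one synthetic movie (defaults mirror the target assay)."""

    n_cells: int = 50
    frame_count: int = 1000
    frame_interval_s: float = 0.82
    image_shape: Tuple[int, int] = (512, 512)
    cell_radius_px: float = 6.0
    psf_sigma_px: float = 1.0
    ionomycin_start_frame: int = 900
    ionomycin_gain: float = 1.25
    archetype_mix: Tuple[float, float, float, float] = (0.3, 0.2, 0.1, 0.4)
    intensity_scale: float = 1000.0
    peak_snr: float = 10.0
    trace_params: TraceModel = field(default_factory=lambda: TraceModel(noise_sd=0.0))
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.archetype_mix, dtype=float)
        if mix.shape != (4,) or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
            raise ValueError("archetype_mix must be 4 non-negative values summing to 1")
        if not 0 < self.ionomycin_start_frame < self.frame_count:
            raise ValueError("ionomycin_start_frame must fall inside the acquisition")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")


def _place_centroids(model: StackModel, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping cell positions (bounded retries)."""
    margin = 3 * model.cell_radius_px
    min_sep = 2.5 * model.cell_radius_px
    ny, nx = model.image_shape
    if ny <= 2 * margin or nx <= 2 * margin:
        raise ValueError("image too small for the requested cell radius")
    centroids: list = []
    attempts = 0
    max_attempts = 200 * max(model.n_cells, 1)
    while len(centroids) < model.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {model.n_cells} non-overlapping cells in "
                f"{model.image_shape}"
            )
        cand = np.array(
            [rng.uniform(margin, ny - margin), rng.uniform(margin, nx - margin)]
        )
        if all(np.hypot(*(cand - c)) >= min_sep for c in centroids):
            centroids.append(cand)
    return np.asarray(centroids).reshape(model.n_cells, 2)


def generate_stack(model: StackModel) -> Tuple[ImageStack, pd.DataFrame]:
    """Render a synthetic movie plus its ground-truth table.

    Each cell is a Gaussian spot (sigma = cell_radius_px / 2, blurred by the
    PSF) that appears at its landing frame with temporal intensity from its
    trace model; the terminal ionomycin surge multiplies each cell toward
    ``ionomycin_gain`` x its own pre-surge maximum. Additive Gaussian read
    noise is calibrated so the brightest spot peak has the requested SNR.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(model.seed)
    centroids = _place_centroids(model, rng)
    archetypes = rng.choice(ARCHETYPES, size=model.n_cells, p=model.archetype_mix)

    ny, nx = model.image_shape
    frames = np.zeros((model.frame_count, ny, nx), dtype=np.float64)

    spot_sigma = model.cell_radius_px / 2.0
    half = int(np.ceil(3 * spot_sigma + 3 * model.psf_sigma_px))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    profile = np.exp(-(yy**2 + xx**2) / (2 * spot_sigma**2))
    if model.psf_sigma_px > 0:
        profile = gaussian_filter(profile, model.psf_sigma_px)
    profile /= profile.max()

    truth_rows = []
    traces = np.zeros((model.n_cells, model.frame_count))
    for cid in range(model.n_cells):
        cell_model = _draw_model(
            rng,
            str(archetypes[cid]),
            model.frame_count,
            model.ionomycin_start_frame,
            model.trace_params,
        )
        y, label = clean_trace(cell_model, model.frame_count)
        y = apply_ionomycin(y, model.ionomycin_start_frame, model.ionomycin_gain)
        y[: label.landing_frame] = 0.0  # cell absent before landing
        traces[cid] = y

        cy, cx = centroids[cid]
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(0, iy - half), min(ny, iy + half + 1)
        x0, x1 = max(0, ix - half), min(nx, ix + half + 1)
        p = profile[
            y0 - (iy - half) : profile.shape[0] - ((iy + half + 1) - y1),
            x0 - (ix - half) : profile.shape[1] - ((ix + half + 1) - x1),
        ]
        frames[:, y0:y1, x0:x1] += (
            model.intensity_scale * y[:, None, None] * p[None, :, :]
        )

        row = _label_row(cid, label)
        row.update({"y": cy, "x": cx, "radius_px": model.cell_radius_px})
        truth_rows.append(row)

    peak_signal = model.intensity_scale * (
        model.trace_params.baseline_level + model.trace_params.amplitude
    )
    noise_sd = peak_signal / model.peak_snr if model.peak_snr > 0 else 0.0
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    offset = 4 * noise_sd  # keep the background above zero after noise
    frames = np.clip(frames + offset, 0, None)

    stack = ImageStack(
        frames=frames.astype(np.float32),
        frame_interval_s=model.frame_interval_s,
        ionomycin_start_frame=model.ionomycin_start_frame,
    )
    columns = [
        "cell_id", "y", "x", "radius_px", "archetype", "landing_frame",
        "onset_frame", "first_flux_frame", "n_fluxes_true", "flux_frames",
        "peak_frames",
    ]
    truth = pd.DataFrame(truth_rows, columns=columns) if truth_rows else pd.DataFrame(columns=columns)
    return stack, truth


def measured_spot_traces(stack: ImageStack, truth: pd.DataFrame, radius_px: float) -> pd.DataFrame:
    """Re-measure per-frame mean spot intensity with the true centroids/masks.

    Utility for validating the renderer: background-subtracted mean
    intensity inside the true disk, per cell and frame.
    """
    ny, nx = stack.frames.shape[1:]
    yy, xx = np.mgrid[:ny, :nx]
    rows = []
    for _, r in truth.iterrows():
        mask = (yy - r.y) ** 2 + (xx - r.x) ** 2 <= radius_px**2
        bg = np.median(stack.frames[:, ~mask], axis=1)
        vals = stack.frames[:, mask].mean(axis=1) - bg
        rows.append(
            pd.DataFrame(
                {"cell_id": int(r.cell_id), "frame": np.arange(stack.n_frames), "intensity": vals}
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["cell_id", "frame", "intensity"])
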