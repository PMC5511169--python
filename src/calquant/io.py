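"""Reading and writing of movie stacks, run configuration, and result tables.

Movies are single-channel time-lapse stacks (T x Y x X). Plain multi-page
TIFF and OME-TIFF are supported; per-plane acquisition times are taken from
OME metadata when present, otherwise synthesized from a user-supplied frame
interval.
"""

from __future__ import annotations

import hashlib
import json
import time
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from . import __version__


class StackError(ValueError):
    """Raised for malformed or unsupported image stacks."""


@dataclass
class ImageStack:
    """A one-channel T x Y x X movie with per-frame timestamps.

    Attributes
    ----------
    frames:
        Intensity array of shape (T, Y, X), non-negative.
    frame_interval_s:
        Nominal frame spacing in seconds.
    timestamps_s:
        Per-frame acquisition times in seconds, strictly increasing.
    pixel_size_um:
        Optional lateral pixel size in micrometers.
    ionomycin_start_frame:
        First frame of the terminal ionomycin window, if known.
    """

    frames: np.ndarray
    frame_interval_s: float
    timestamps_s: np.ndarray = field(default=None)  # type: ignore[assignment]
    pixel_size_um: Optional[float] = None
    ionomycin_start_frame: Optional[int] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise StackError(f"expected a T x Y x X array, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise StackError("a stack needs at least two frames")
        if np.issubdtype(self.frames.dtype, np.floating) and np.nanmin(self.frames) < 0:
            raise StackError("frame intensities must be non-negative")
        if self.timestamps_s is None:
            self.timestamps_s = np.arange(self.n_frames) * float(self.frame_interval_s)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.timestamps_s.shape != (self.n_frames,):
            raise StackError("timestamps must have one entry per frame")
        if not np.all(np.diff(self.timestamps_s) > 0):
            raise StackError("timestamps must be strictly increasing")
        if self.ionomycin_start_frame is not None and not (
            0 < self.ionomycin_start_frame <= self.n_frames
        ):
            raise StackError("ionomycin_start_frame outside the acquisition")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape


def _ome_plane_times(ome_xml: str) -> Optional[np.ndarray]:
    """Extract per-plane DeltaT values (seconds) from OME-XML, if complete."""
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag.split("}")[0] + "}"
    planes = root.findall(f".//{ns}Image/{ns}Pixels/{ns}Plane")
    times = []
    for plane in planes:
        dt = plane.get("DeltaT")
        if dt is None:
            return None
        times.append(float(dt))
    return np.asarray(times) if times else None


def read_stack(
    path: Union[str, Path],
    frame_interval_s: Optional[float] = None,
    ionomycin_start_frame: Optional[int] = None,
    channel: Optional[int] = None,
) -> ImageStack:
    """Read a single-channel TIFF / OME-TIFF time series.

    Timestamps come from OME per-plane ``DeltaT`` metadata when present and
    strictly increasing; otherwise they are synthesized from
    ``frame_interval_s``. Missing both is an error, as is a multi-channel
    stack without an explicit ``channel`` selector.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        ome_xml = tif.ome_metadata

    if data.ndim == 2:
        raise StackError("single image, not a time series")
    if data.ndim == 4:
        # channel-bearing stack: (T, C, Y, X) or RGB/sample pages (T, Y, X, S)
        if channel is None:
            raise StackError(
                "multi-channel stack: pass channel=<int> to select one channel"
            )
        channel_axis = 1 if data.shape[1] <= 8 <= data.shape[-1] else -1
        data = np.take(data, channel, axis=channel_axis)
    if data.ndim != 3:
        raise StackError(f"cannot interpret stack of shape {data.shape}")

    timestamps = _ome_plane_times(ome_xml) if ome_xml else None
    if timestamps is not None and (
        len(timestamps) != data.shape[0] or not np.all(np.diff(timestamps) > 0)
    ):
        timestamps = None
    if timestamps is None and frame_interval_s is None:
        raise StackError(
            "no usable OME timestamps; pass frame_interval_s (e.g. 0.82)"
        )
    if timestamps is not None and not np.all(np.diff(timestamps) > 0):
        raise StackError("non-monotonic timestamps in metadata")
    if frame_interval_s is None:
        frame_interval_s = float(np.median(np.diff(timestamps)))

    return ImageStack(
        frames=data,
        frame_interval_s=frame_interval_s,
        timestamps_s=timestamps,
        ionomycin_start_frame=ionomycin_start_frame,
    )


def write_stack(path: Union[str, Path], stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF (pixel-exact for integer dtypes)."""
    tifffile.imwrite(str(path), stack.frames, photometric="minisblack")


class LevelSetConfig(BaseModel):
    """Distance-regularized level-set parameters (see segmentation module)."""

    model_config = ConfigDict(extra="forbid")

    mu: float = Field(default=0.2, gt=0)
    lambda_: float = Field(default=5.0, alias="lambda")
    alpha: float = -3.0
    epsilon: float = Field(default=1.5, gt=0)
    sigma: float = Field(default=1.5, gt=0)
    time_step: float = Field(default=1.0, gt=0)
    iterations: int = Field(default=300, gt=0)
    edge_contrast_fraction: float = Field(default=0.25, gt=0, le=1)

    @model_validator(mode="after")
    def _stability(self) -> "LevelSetConfig":
        if self.time_step * self.mu >= 0.25:
            raise ValueError("DRLSE stability requires time_step * mu < 0.25")
        return self


class DetectionConfig(BaseModel):
    """Blob-detection (Laplacian-of-Gaussian) parameters."""

    model_config = ConfigDict(extra="forbid")

    min_sigma: float = Field(default=2.0, gt=0)
    max_sigma: float = Field(default=8.0, gt=0)
    detection_threshold: float = Field(default=0.03, gt=0)


class RunConfig(BaseModel):
    """Validated run configuration with documented defaults.

    The triggering radius is the single user-set classification parameter;
    ``"auto"`` selects a data-driven radius from the population's noise
    floor. The fraction threshold implements the strict more-than-10% rule.
    """

    model_config = ConfigDict(extra="forbid")

    triggering_radius: Union[float, Literal["auto"]] = 0.34
    triggering_fraction_threshold: float = 0.10
    min_peak_threshold: float = Field(default=0.01, gt=0)
    peak_sigma_factor: float = Field(default=3.5, ge=0)
    min_separation_frames: int = Field(default=12, ge=1)
    baseline_window_frames: int = Field(default=25, ge=3)
    smooth_window_frames: int = Field(default=5, ge=1)
    decay_fit_window_frames: int = Field(default=100, ge=10)
    frame_interval_s: float = Field(default=0.82, gt=0)
    ionomycin_start_frame: Optional[int] = Field(default=900, ge=1)
    analysis_end_frame: Optional[int] = Field(default=None, ge=8)
    detection: DetectionConfig = DetectionConfig()
    drls: LevelSetConfig = LevelSetConfig()
    seed: int = 0

    @field_validator("triggering_radius")
    @classmethod
    def _radius_valid(cls, v):
        if isinstance(v, str):
            return v
        if not v > 0:
            raise ValueError("triggering_radius must be positive or 'auto'")
        return v

    @field_validator("triggering_fraction_threshold")
    @classmethod
    def _fraction_valid(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("triggering_fraction_threshold must lie in (0, 1)")
        return v

    @model_validator(mode="after")
    def _window_consistent(self) -> "RunConfig":
        if (
            self.analysis_end_frame is not None
            and self.ionomycin_start_frame is not None
            and self.analysis_end_frame > self.ionomycin_start_frame
        ):
            raise ValueError(
                "analysis_end_frame must not extend into the ionomycin window"
            )
        return self

    @property
    def auto_radius(self) -> bool:
        return self.triggering_radius == "auto"

    def resolve_analysis_end(self, n_frames: int) -> int:
        """Classification window end: explicit end, else ionomycin start, else T."""
        if self.analysis_end_frame is not None:
            return min(self.analysis_end_frame, n_frames)
        if self.ionomycin_start_frame is not None:
            return min(self.ionomycin_start_frame, n_frames)
        return n_frames


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML key-value config; an empty file yields all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping of keys to values")
    return RunConfig(**data)


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_CSV_KW = dict(index=False, float_format="%.9g")  # byte-stable output


def write_results(
    traces: Optional[pd.DataFrame],
    classifications: pd.DataFrame,
    summary,
    out_dir: Union[str, Path],
    config: Optional[RunConfig] = None,
    radius_used: Optional[float] = None,
    seed: Optional[int] = None,
    input_hashes: Optional[dict] = None,
) -> dict:
    """Write result CSVs plus a JSON run manifest; returns written paths.

    CSV contents are deterministic for identical inputs; only the manifest
    carries a wall-clock timestamp.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if traces is not None:
        paths["traces"] = out / "traces.csv"
        traces.to_csv(paths["traces"], **_CSV_KW)
    paths["classifications"] = out / "classifications.csv"
    classifications.to_csv(paths["classifications"], **_CSV_KW)
    if summary is not None:
        paths["summary"] = out / "summary.csv"
        summary_df = summary if isinstance(summary, pd.DataFrame) else summary.to_frame()
        summary_df.to_csv(paths["summary"], **_CSV_KW)

    manifest = {
        "software": "calquant",
        "version": __version__,
        "seed": seed,
        "triggering_radius_resolved": radius_used,
        "config": json.loads(config.model_dump_json(by_alias=True)) if config else None,
        "input_hashes": input_hashes or {},
        "written_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def read_traces(path: Union[str, Path]) -> pd.DataFrame:
    """Read a long-format trace table (cell_id, frame, intensity[, ...])."""
    df = pd.read_csv(path)
    required = {"cell_id", "frame", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table missing columns: {sorted(missing)}")
    return df
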