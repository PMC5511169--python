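"""End-to-end orchestration: simulate/read -> segment -> normalize -> classify -> summarize."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import segmentation, synthetic
from .classify import classify_population
from .io import ImageStack, RunConfig, file_sha256, read_stack, read_traces, write_results
from .population import summarize
from .traces import build_traces, normalize_population

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An identifiable pipeline stage failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _run(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc


def run_pipeline(
    config: RunConfig,
    out_dir: Union[str, Path],
    stack_path: Optional[Union[str, Path]] = None,
    trace_csv: Optional[Union[str, Path]] = None,
    simulate: Optional[synthetic.StackModel] = None,
    condition_label: Optional[str] = None,
) -> Path:
    """Run the full analysis and write results to ``out_dir``.

    Exactly one input source must be given: a stack on disk, a per-cell
    trace CSV (trace-only mode, bypassing segmentation), or a synthetic
    stack model. Deterministic for fixed config/seed and fixed inputs.
    """
    sources = [s for s in (stack_path, trace_csv, simulate) if s is not None]
    if len(sources) != 1:
        raise ValueError("pass exactly one of stack_path, trace_csv, simulate")

    input_hashes = {}
    landing = None
    stack: Optional[ImageStack] = None

    if simulate is not None:
        stack, truth = _run("simulate", synthetic.generate_stack, simulate)
        log.info("simulated stack: %d cells, %d frames", simulate.n_cells, stack.n_frames)
    elif stack_path is not None:
        stack = _run(
            "read",
            read_stack,
            stack_path,
            frame_interval_s=config.frame_interval_s,
            ionomycin_start_frame=config.ionomycin_start_frame,
        )
        input_hashes[str(stack_path)] = file_sha256(stack_path)

    if stack is not None:
        end = config.resolve_analysis_end(stack.n_frames)
        records = _run(
            "detect",
            segmentation.detect_cells,
            stack,
            min_sigma=config.detection.min_sigma,
            max_sigma=config.detection.max_sigma,
            detection_threshold=config.detection.detection_threshold,
            analysis_end_frame=end,
        )
        log.info("detected %d cells", len(records))
        records = _run(
            "segment", segmentation.segment_cells, stack, records, config.drls, end
        )
        raw = _run("extract", segmentation.extract_traces, stack, records)
        landing = pd.Series(
            {r.cell_id: r.landing_frame for r in records}, name="landing_frame"
        )
        n_frames = stack.n_frames
        ionomycin_start = config.ionomycin_start_frame or n_frames
    else:
        raw = _run("read-traces", read_traces, trace_csv)
        input_hashes[str(trace_csv)] = file_sha256(trace_csv)
        if raw.empty:
            raise StageError("normalize", ValueError("no cells to analyze"))
        if "landing_frame" in raw.columns:
            landing = raw.groupby("cell_id")["landing_frame"].first()
        n_frames = int(raw["frame"].max()) + 1
        ionomycin_start = config.ionomycin_start_frame or n_frames
        end = config.resolve_analysis_end(n_frames)

    if raw.empty or raw["cell_id"].nunique() == 0:
        raise StageError("normalize", ValueError("no cells to analyze"))

    normalized, norm_constant = _run(
        "normalize", normalize_population, raw, (ionomycin_start, n_frames)
    )
    traces = _run(
        "traces",
        build_traces,
        normalized,
        landing_frames=landing,
        analysis_end_frame=end,
        baseline_window_frames=config.baseline_window_frames,
        frame_interval_s=config.frame_interval_s,
    )
    log.info("normalized %d traces (M = %.6g)", len(traces), norm_constant)

    classifications, radius_used = _run(
        "classify",
        classify_population,
        traces,
        radius=config.triggering_radius,
        fraction_threshold=config.triggering_fraction_threshold,
        frame_interval_s=config.frame_interval_s,
        min_peak_threshold=config.min_peak_threshold,
        peak_sigma_factor=config.peak_sigma_factor,
        min_separation_frames=config.min_separation_frames,
        smooth_window=config.smooth_window_frames,
        decay_fit_window_frames=config.decay_fit_window_frames,
    )
    log.info(
        "classified %d cells (radius %.6g): %d triggering",
        len(classifications), radius_used, int(classifications["triggering"].sum()),
    )
    summary = _run("summarize", summarize, classifications, condition_label)

    out_tables = normalized.copy()
    if landing is not None:
        out_tables = out_tables.merge(
            landing.rename("landing_frame"), left_on="cell_id", right_index=True, how="left"
        )
    paths = _run(
        "write",
        write_results,
        out_tables,
        classifications,
        summary,
        out_dir,
        config=config,
        radius_used=radius_used,
        seed=config.seed,
        input_hashes=input_hashes,
    )
    log.info("results written to %s", out_dir)
    return Path(out_dir)
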