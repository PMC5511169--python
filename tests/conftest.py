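"""Shared fixtures: small synthetic populations and stacks."""

from __future__ import annotations

import numpy as np
import pytest

from calquant import synthetic
from calquant.traces import build_traces, normalize_population


@pytest.fixture(scope="session")
def noiseless_population():
    """40 noiseless traces, 10 per archetype, full acquisition geometry."""
    traces, labels = synthetic.generate_population(
        dict(single=10, oscillatory=10, sustained=10, none=10),
        frame_count=1000,
        seed=7,
        trace_params=synthetic.TraceModel(noise_sd=0.0),
        ionomycin_start_frame=900,
    )
    return traces, labels


@pytest.fixture(scope="session")
def noiseless_traces(noiseless_population):
    """CalciumTrace objects for the noiseless population."""
    traces_df, labels = noiseless_population
    normalized, _ = normalize_population(traces_df, (900, 1000))
    landing = labels.set_index("cell_id")["landing_frame"]
    return build_traces(normalized, landing_frames=landing, analysis_end_frame=900), labels


@pytest.fixture(scope="session")
def spot_stack():
    """20-cell synthetic movie at peak SNR 10 with ground truth."""
    model = synthetic.StackModel(
        n_cells=20,
        frame_count=240,
        image_shape=(256, 256),
        ionomycin_start_frame=200,
        peak_snr=10.0,
        seed=3,
    )
    stack, truth = synthetic.generate_stack(model)
    return model, stack, truth


def brute_force_dft(x: np.ndarray) -> np.ndarray:
    """O(N^2) reference DFT, 1/N-scaled, DC excluded (independent oracle)."""
    n = len(x)
    out = np.empty(n - 1, dtype=complex)
    for k in range(1, n):
        acc = 0.0 + 0.0j
        for t in range(n):
            acc += x[t] * np.exp(-2j * np.pi * k * t / n)
        out[k - 1] = acc / n
    return out
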