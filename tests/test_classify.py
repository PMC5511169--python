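"""Fourier-domain triggering classification, pattern sorting, triggering time."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calquant import synthetic
from calquant.classify import (
    auto_radius,
    classify_cell,
    classify_pattern,
    classify_population,
    classify_triggering,
    detect_flux_peaks,
    fourier_signature,
    triggering_time,
)
from calquant.traces import PeakSet, build_traces, normalize_population
from tests.conftest import brute_force_dft


class TestFourierSignature:
    def test_constant_trace_has_zero_components(self):
        sig = fourier_signature(np.full(100, 0.0), radius=0.01)
        assert np.allclose(sig.moduli, 0.0)
        assert sig.fraction_outside == 0.0
        assert sig.n_points == 99

    def test_cosine_closed_form(self):
        """cos(2*pi*n/N): 1/N-scaled moduli 0.5 at k in {1, N-1}, 0 elsewhere."""
        n = 100
        x = np.cos(2 * np.pi * np.arange(n) / n)
        sig = fourier_signature(x, radius=0.34)
        moduli = sig.moduli
        assert np.isclose(moduli[0], 0.5)  # k=1
        assert np.isclose(moduli[-1], 0.5)  # k=99
        assert np.allclose(np.delete(moduli, [0, 98]), 0.0, atol=1e-12)
        assert np.isclose(sig.fraction_outside, 2 / 99)

    def test_conjugate_symmetry_for_real_input(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        sig = fourier_signature(x, radius=0.1)
        # component at k and N-k are conjugates: moduli symmetric
        assert np.allclose(sig.moduli, sig.moduli[::-1])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for n in (8, 33, 128):
            x = rng.normal(size=n)
            sig = fourier_signature(x, radius=0.1)
            ref = brute_force_dft(x)
            err = np.max(np.abs(sig.components - ref)) / np.max(np.abs(ref))
            assert err < 1e-10

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="8 frames"):
            fourier_signature(np.zeros(7), radius=0.1)

    def test_fraction_outside_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        radii = np.linspace(1e-4, 0.2, 25)
        fractions = [fourier_signature(x, r).fraction_outside for r in radii]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_modulus_spectrum_invariant_to_circular_shift(self):
        model = synthetic.TraceModel(archetype="single", landing_frame=0,
                                     trigger_delay_frames=100, noise_sd=0.0)
        y, _ = synthetic.clean_trace(model, 512)
        x = y - model.baseline_level
        base = fourier_signature(x, 0.001)
        for shift in (13, 200):
            rolled = fourier_signature(np.roll(x, shift), 0.001)
            assert np.allclose(rolled.moduli, base.moduli, atol=1e-12)
            assert rolled.fraction_outside == base.fraction_outside

    def test_amplitude_scaling_never_decreases_fraction(self):
        model = synthetic.TraceModel(archetype="single", landing_frame=0,
                                     trigger_delay_frames=80, noise_sd=0.0)
        y, _ = synthetic.clean_trace(model, 600)
        x = y - model.baseline_level
        f1 = fourier_signature(x, 0.002).fraction_outside
        f2 = fourier_signature(1.7 * x, 0.002).fraction_outside
        assert f2 >= f1


class TestClassifyTriggering:
    def test_strictly_more_than_threshold(self):
        """The 10% rule is strict: exactly 10% is non-triggering."""
        sig_at = fourier_signature(np.zeros(100), 0.1)
        sig_at.fraction_outside = 0.10
        assert classify_triggering(sig_at, 0.10) is False
        sig_above = fourier_signature(np.zeros(100), 0.1)
        sig_above.fraction_outside = 0.101
        assert classify_triggering(sig_above, 0.10) is True
        sig_zero = fourier_signature(np.zeros(100), 0.1)
        assert classify_triggering(sig_zero, 0.10) is False


class TestAutoRadius:
    def _signatures(self, traces):
        return [fourier_signature(t, 1.0) for t in traces]

    def test_needs_twenty_cells(self):
        sigs = self._signatures([np.random.default_rng(0).normal(size=64)] * 19)
        with pytest.raises(ValueError, match="20 cells"):
            auto_radius(sigs)

    def test_constant_population_clamps_to_lower_bound(self):
        sigs = self._signatures([np.zeros(128)] * 30)
        assert auto_radius(sigs) == 1e-4

    def test_pure_noise_population_rarely_triggers(self):
        """Auto radius on 500 noise traces keeps false triggering <= 5%."""
        rng = np.random.default_rng(3)
        traces = [rng.normal(0, 0.05, 500) for _ in range(500)]
        sigs = self._signatures(traces)
        radius = auto_radius(sigs)
        frac_trig = np.mean(
            [classify_triggering(fourier_signature(t, radius)) for t in traces]
        )
        assert frac_trig <= 0.05

    def test_mixed_population_recovers_labels(self):
        """Flux vs noise separation at the method's operating noise level.

        Trace noise of ~0.01 a.u. matches mask-averaged imaging traces
        (pixel noise shrinks by sqrt(mask area) on extraction).
        """
        rng = np.random.default_rng(4)
        traces, labels = [], []
        for i in range(60):
            if i % 2 == 0:
                model = synthetic.TraceModel(
                    archetype="single", landing_frame=0,
                    trigger_delay_frames=int(rng.integers(50, 400)), noise_sd=0.0,
                )
                y, _ = synthetic.clean_trace(model, 900)
                labels.append(True)
            else:
                y = np.full(900, 0.1)
                labels.append(False)
            traces.append(y - 0.1 + rng.normal(0, 0.01, 900))
        sigs = self._signatures(traces)
        radius = auto_radius(sigs)
        pred = [classify_triggering(fourier_signature(t, radius)) for t in traces]
        assert np.mean(np.array(pred) == np.array(labels)) >= 0.95


class TestPatternAndTime:
    def test_noiseless_archetypes_map_exactly(self, noiseless_traces):
        """single/oscillatory/sustained/none all classified exactly (auto radius)."""
        traces, labels = noiseless_traces
        table, radius = classify_population(traces, radius="auto")
        merged = table.merge(labels, on="cell_id", suffixes=("_pred", "_true"))
        assert (merged["archetype_pred"] == merged["archetype_true"]).all()
        assert (
            merged["triggering"] == (merged["archetype_true"] != "none")
        ).all()

    def test_oscillatory_rule_fires_at_exactly_two_peaks(self, noiseless_traces):
        traces, _ = noiseless_traces
        trace = traces[0]
        one = PeakSet(np.array([100]), np.array([0.1]), 0.01)
        two = PeakSet(np.array([100, 200]), np.array([0.1, 0.1]), 0.01)
        assert classify_pattern(trace, two, triggering=True) == "oscillatory"
        assert classify_pattern(trace, one, triggering=True) != "oscillatory"

    def test_non_triggering_is_none_regardless_of_peaks(self, noiseless_traces):
        traces, _ = noiseless_traces
        two = PeakSet(np.array([100, 200]), np.array([0.1, 0.1]), 0.01)
        assert classify_pattern(traces[0], two, triggering=False) == "none"

    def test_zero_peaks_with_triggering_falls_back_to_sustained(self, noiseless_traces):
        traces, _ = noiseless_traces
        empty = PeakSet(np.array([], dtype=int), np.array([]), 0.01)
        assert classify_pattern(traces[0], empty, triggering=True) == "sustained"

    def test_triggering_time_arithmetic(self):
        peaks = PeakSet(np.array([80]), np.array([0.1]), 0.01)
        assert triggering_time(peaks, landing_frame=50, frame_interval_s=0.82) == pytest.approx(24.6)
        at_landing = PeakSet(np.array([50]), np.array([0.1]), 0.01)
        assert triggering_time(at_landing, 50) == 0.0
        none = PeakSet(np.array([], dtype=int), np.array([]), 0.01)
        assert triggering_time(none, 50) is None

    def test_triggering_time_recovered_on_noiseless_population(self, noiseless_traces):
        traces, labels = noiseless_traces
        lab = labels.set_index("cell_id")
        for trace in traces:
            row = lab.loc[trace.cell_id]
            if row.archetype == "none":
                continue
            peaks = detect_flux_peaks(trace)
            t = triggering_time(peaks, trace.landing_frame)
            est_frame = t / 0.82 + trace.landing_frame
            assert abs(est_frame - row.first_flux_frame) <= 2

    def test_oscillatory_requires_two_peaks_invariant(self, noiseless_traces):
        traces, _ = noiseless_traces
        table, _ = classify_population(traces, radius="auto")
        osc = table[table.archetype == "oscillatory"]
        assert (osc.n_peaks >= 2).all()


class TestClassifyCell:
    def test_record_consistency(self, noiseless_traces):
        traces, _ = noiseless_traces
        rec = classify_cell(traces[0], radius=1e-3)
        assert rec.radius_used == 1e-3
        assert 0.0 <= rec.fraction_outside <= 1.0
        if rec.archetype == "none":
            assert not rec.triggering

    def test_explicit_radius_bypasses_auto(self, noiseless_traces):
        traces, _ = noiseless_traces
        table, radius = classify_population(traces, radius=0.34)
        assert radius == 0.34
        assert (table.radius_used == 0.34).all()


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_dft_oracle_equivalence_property(seed):
    """FFT path and brute-force DFT agree to 1e-10 on random inputs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 96))
    x = rng.normal(size=n)
    sig = fourier_signature(x, 0.1)
    ref = brute_force_dft(x)
    assert np.max(np.abs(sig.components - ref)) <= 1e-10 * max(1.0, np.max(np.abs(ref)))
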