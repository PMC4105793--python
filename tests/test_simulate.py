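"""Forward-model tests: kernels, superposition, coupling-driven beat trains."""

import numpy as np
import pytest

from pulsedecomp import (
    BeatTrainSpec,
    ComponentSpec,
    make_component_pulse,
    synthesize_central_pulse,
    synthesize_peripheral_stream,
)
from pulsedecomp.errors import InvalidParameterError

from conftest import FS, drifting_train


class TestComponentPulse:
    def test_zero_amplitude_gives_all_zero_segment(self):
        out = make_component_pulse(200.0, amplitude=0.0)
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_140ms_pulse_spans_70_samples_at_500hz(self):
        out = make_component_pulse(140.0, amplitude=1.0, sampling_rate=500.0)
        assert out.samples.size == 70

    def test_peak_equals_amplitude_and_matches_bruteforce_argmax(self):
        out = make_component_pulse(300.0, amplitude=2.5)
        # exhaustive-scan argmax oracle
        best_i, best_v = 0, -np.inf
        for i, v in enumerate(out.samples):
            if v > best_v:
                best_i, best_v = i, v
        assert best_v == pytest.approx(2.5)
        assert best_i == int(np.argmax(out.samples))

    def test_zero_valued_at_both_ends(self):
        out = make_component_pulse(250.0, amplitude=1.0)
        assert out.samples[0] == 0.0 and out.samples[-1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("duration,fs", [(0.0, 500.0), (-5.0, 500.0), (100.0, 0.0)])
    def test_invalid_parameters_rejected(self, duration, fs):
        with pytest.raises(InvalidParameterError):
            make_component_pulse(duration, amplitude=1.0, sampling_rate=fs)


class TestCentralPulse:
    def test_no_reflections_equals_bare_ejection_pulse(self):
        spec = ComponentSpec(
            lvet_ms=300.0, t12_ms=100.0, t13_ms=280.0,
            r_renal=0.0, r_iliac=0.0, n_harmonics=0, tail_tau_ms=0.0,
        )
        stream, _ = synthesize_central_pulse(spec, FS)
        bare = make_component_pulse(300.0, spec.amplitude_mmHg, FS)
        n = bare.samples.size
        np.testing.assert_allclose(stream.samples[:n], bare.samples, atol=1e-12)
        np.testing.assert_allclose(stream.samples[n:], 0.0, atol=1e-12)

    def test_nonoverlapping_p3_peak_is_reflection_coefficient_times_p1(self):
        # closed-form superposition: without tails and overlap, the envelope
        # at the P3 arrival is exactly r_iliac * P1 peak amplitude
        spec = ComponentSpec(
            lvet_ms=60.0, t12_ms=100.0, t13_ms=280.0,
            r_renal=0.17, r_iliac=0.35, tail_tau_ms=0.0,
        )
        stream, _ = synthesize_central_pulse(spec, FS)
        i3 = int(round(280.0 * FS / 1000.0))
        window = stream.samples[i3 : i3 + int(60.0 * FS / 1000.0)]
        assert window.max() == pytest.approx(0.35 * spec.amplitude_mmHg, rel=1e-9)

    def test_superposition_is_linear_in_amplitude(self):
        kw = dict(lvet_ms=300.0, t12_ms=100.0, t13_ms=280.0)
        s1, _ = synthesize_central_pulse(ComponentSpec(amplitude_mmHg=20.0, **kw), FS)
        s2, _ = synthesize_central_pulse(ComponentSpec(amplitude_mmHg=40.0, **kw), FS)
        np.testing.assert_allclose(s2.samples, 2.0 * s1.samples, rtol=1e-12)

    def test_p2_window_peak_increases_strictly_with_renal_reflection(self):
        peaks = []
        for r in (0.1, 0.3, 0.5, 0.8):
            spec = ComponentSpec(lvet_ms=300.0, t12_ms=100.0, t13_ms=280.0, r_renal=r)
            stream, truth = synthesize_central_pulse(spec, FS)
            i2 = int(round(truth.t2_ms * FS / 1000.0))
            half = int(25 * FS / 1000)
            peaks.append(stream.samples[i2 - half : i2 + half].max())
        assert np.all(np.diff(peaks) > 0)

    def test_truncation_warns_when_window_too_short(self, caplog):
        spec = ComponentSpec(lvet_ms=300.0, t12_ms=100.0, t13_ms=280.0)
        with caplog.at_level("WARNING", logger="pulsedecomp.simulate"):
            synthesize_central_pulse(spec, FS, window_ms=300.0)
        assert any("truncated" in rec.message for rec in caplog.records)


class TestPeripheralStream:
    def test_cumsum_integration_reproduces_internal_envelope(self, coupling):
        """The emitted derivative stream is exactly the first difference of
        the constructed envelope: cumulative sum inverts it to machine
        tolerance (noise-free)."""
        train = drifting_train(n_beats=5, noise_sd=0.0)
        stream, _ = synthesize_peripheral_stream(train)
        env = np.cumsum(stream.samples) / stream.sampling_rate
        # re-derive: d1 = diff(env)*fs  =>  env must be consistent
        d1_back = np.diff(env, prepend=0.0) * stream.sampling_rate
        np.testing.assert_allclose(d1_back, stream.samples, rtol=1e-9, atol=1e-9)
        assert env.min() > -1e-6  # envelope stays above the diastolic floor

    def test_ground_truth_t13_within_physiological_window(self):
        train = drifting_train(n_beats=40)
        _, truth = synthesize_peripheral_stream(train)
        assert truth["t13_ms"].between(180.0, 450.0).all()

    def test_coupling_consistency_systole_reproduced_exactly(self, coupling):
        model_s, _ = coupling
        train = drifting_train(n_beats=30, noise_sd=0.0)
        _, truth = synthesize_peripheral_stream(train)
        np.testing.assert_allclose(
            model_s.gain * truth["p2p1"] + model_s.offset, truth["systole"], rtol=1e-12
        )

    def test_out_of_range_targets_clamped_with_warning(self, coupling):
        train = BeatTrainSpec(
            n_beats=5,
            mean_ibi_ms=900.0,
            ibi_sd_ms=0.0,
            systole_series=250.0,  # implies P2P1 ~ 2.5, beyond the 1.5 cap
            diastole_series=100.0,
            coupling=coupling,
            noise_sd=0.0,
            seed=0,
        )
        with pytest.warns(UserWarning, match="clamped"):
            _, truth = synthesize_peripheral_stream(train)
        assert truth["clamped"].all()
        assert truth.attrs["n_clamped"] == 5
        assert truth["p2p1"].max() <= 1.5

    def test_identical_seeds_give_bit_identical_streams(self):
        s1, t1 = synthesize_peripheral_stream(drifting_train(n_beats=10, noise_sd=5.0, seed=11))
        s2, t2 = synthesize_peripheral_stream(drifting_train(n_beats=10, noise_sd=5.0, seed=11))
        np.testing.assert_array_equal(s1.samples, s2.samples)
        assert t1.equals(t2)

    def test_invalid_train_rejected(self, coupling):
        with pytest.raises(InvalidParameterError):
            BeatTrainSpec(
                n_beats=3, mean_ibi_ms=900.0, ibi_sd_ms=0.0,
                systole_series=100.0, diastole_series=110.0,  # diastole > systole
                coupling=coupling,
            )
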