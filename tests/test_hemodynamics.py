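"""Impedance-cardiographic and blood-pressure derivations."""

import numpy as np
import pytest

from physioarousal import cardiac, hemodynamics, synth
from physioarousal.cardiac import BeatSeries
from physioarousal.hemodynamics import EnsembleBeat


def _template_ensemble(b_ms=80.0, z_ms=120.0, x_ms=380.0, amp=1.0, n_beats=30):
    """Half-sine upstroke peaking at Z plus an X notch, as one ensemble."""
    t = np.arange(-100.0, 551.0)
    w = np.zeros_like(t)
    width = 2 * (z_ms - b_ms)
    rise = (t >= b_ms) & (t <= b_ms + width)
    w[rise] = amp * np.sin(np.pi * (t[rise] - b_ms) / width)
    notch = np.abs(t - x_ms) <= 40.0
    w[notch] -= 0.3 * amp * np.cos(np.pi * (t[notch] - x_ms) / 80.0) ** 2
    return EnsembleBeat(w, t, n_beats=n_beats)


class TestPreprocessDzdt:
    def test_mains_attenuated(self):
        t = np.arange(0, 20, 1 / 500)
        x = np.sin(2 * np.pi * 50 * t)
        out = hemodynamics.preprocess_dzdt(x, 500.0)
        core = out[1600:-1600]  # steady state
        assert np.sqrt(np.mean(core ** 2)) <= 0.05 * np.sqrt(np.mean(x ** 2))

    def test_band_stop_passes_dc(self):
        out = hemodynamics.preprocess_dzdt(np.full(5000, 2.5), 500.0)
        assert np.allclose(out[20:-20], 2.5, atol=0.01)

    def test_upsampling_doubles_length(self):
        out = hemodynamics.preprocess_dzdt(np.zeros(4000), 500.0)
        assert len(out) == 8000


class TestEnsembleAverage:
    def test_identical_sweeps_equal_single_sweep(self):
        rate = 1000.0
        tmpl = np.sin(np.linspace(0, np.pi, 651))
        beats = np.arange(1.0, 16.0, 1.0)
        sig = np.zeros(int(17 * rate))
        for b in beats:
            i = int(b * rate) - 100
            sig[i:i + 651] += tmpl
        ens = hemodynamics.ensemble_average(sig, BeatSeries(beats), (0.0, 17.0))
        np.testing.assert_allclose(ens.waveform, tmpl, atol=1e-12)

    def test_median_robust_to_outlier_sweep(self):
        rate = 1000.0
        tmpl = np.sin(np.linspace(0, np.pi, 651))
        beats = np.arange(1.0, 14.0, 1.0)
        sig = np.zeros(int(15 * rate))
        for b in beats:
            i = int(b * rate) - 100
            sig[i:i + 651] += tmpl
        sig[int(5.2 * rate):int(5.3 * rate)] += 50.0  # movement artifact in one sweep
        ens = hemodynamics.ensemble_average(sig, BeatSeries(beats), (0.0, 15.0))
        np.testing.assert_allclose(ens.waveform, tmpl, atol=1e-9)

    def test_too_few_beats_missing(self):
        ens = hemodynamics.ensemble_average(
            np.zeros(20000), BeatSeries(np.arange(1.0, 6.0)), (0.0, 20.0))
        assert ens is None

    def test_latencies_preserved_from_recording(self, clean_recording, clean_beats):
        truth = clean_recording.truth
        dzdt = hemodynamics.preprocess_dzdt(
            clean_recording.channels["dzdt"].samples,
            clean_recording.channels["dzdt"].rate)
        ens = hemodynamics.ensemble_average(dzdt, clean_beats, (0.0, 240.0))
        pts = hemodynamics.detect_bzx(ens)
        assert pts.valid
        assert pts.b == pytest.approx(truth.pep - 20.0, abs=2.0)
        assert pts.x - pts.b == pytest.approx(truth.lvet, abs=2.0)


class TestDetectBzx:
    def test_template_latencies_recovered(self):
        pts = hemodynamics.detect_bzx(_template_ensemble())
        assert pts.valid
        assert pts.b == pytest.approx(80.0, abs=2.0)
        assert pts.z == pytest.approx(120.0, abs=2.0)
        assert pts.x == pytest.approx(380.0, abs=2.0)

    def test_amplitude_scaling_invariance(self):
        a = hemodynamics.detect_bzx(_template_ensemble(amp=1.0))
        b = hemodynamics.detect_bzx(_template_ensemble(amp=10.0))
        assert (a.b, a.z, a.x) == (b.b, b.z, b.x)

    def test_monotone_ramp_flagged_missing(self):
        t = np.arange(-100.0, 551.0)
        ramp = EnsembleBeat(np.linspace(0, 1, t.size), t, n_beats=20)
        pts = hemodynamics.detect_bzx(ramp)
        assert not pts.valid


class TestScalarDerivations:
    @pytest.mark.parametrize("b_ms, expected", [(80.0, 100.0), (0.0, 20.0), (55.0, 75.0)])
    def test_pep_arithmetic(self, b_ms, expected):
        assert hemodynamics.pep_from_b(b_ms) == expected

    def test_kubicek_hand_value(self):
        sv = hemodynamics.stroke_volume_kubicek(27.0, 48.28, 0.3, 1.0)
        assert sv == pytest.approx(135.0 * (48.28 / 27.0) ** 2 * 0.3 * 1.0)

    def test_kubicek_zero_flow(self):
        assert hemodynamics.stroke_volume_kubicek(27.0, 48.28, 0.3, 0.0) == 0.0

    def test_kubicek_quadratic_in_distance(self):
        sv1 = hemodynamics.stroke_volume_kubicek(30.0, 24.0, 0.3, 1.0)
        sv2 = hemodynamics.stroke_volume_kubicek(30.0, 48.0, 0.3, 1.0)
        assert sv2 == pytest.approx(4.0 * sv1)

    def test_kubicek_rejects_zero_impedance(self):
        with pytest.raises(ValueError):
            hemodynamics.stroke_volume_kubicek(0.0, 48.0, 0.3, 1.0)

    @pytest.mark.parametrize("sv, hr, expected", [
        (70.0, 70.0, 4.9), (0.0, 70.0, 0.0), (70.0, 140.0, 9.8)])
    def test_cardiac_output(self, sv, hr, expected):
        assert hemodynamics.cardiac_output(sv, hr) == pytest.approx(expected)

    @pytest.mark.parametrize("sys, dia, expected", [
        (120.0, 80.0, 93.3333), (100.0, 100.0, 100.0), (150.0, 90.0, 110.0)])
    def test_mean_arterial_pressure(self, sys, dia, expected):
        assert hemodynamics.mean_arterial_pressure(sys, dia) == pytest.approx(
            expected, abs=1e-3)

    def test_map_rejects_inverted_reading(self):
        with pytest.raises(ValueError):
            hemodynamics.mean_arterial_pressure(80.0, 120.0)

    @pytest.mark.parametrize("map_, co, expected", [(100.0, 5.0, 20.0), (0.0, 5.0, 0.0)])
    def test_tpr(self, map_, co, expected):
        assert hemodynamics.total_peripheral_resistance(map_, co) == expected

    def test_tpr_guards_zero_co(self):
        with pytest.raises(ValueError):
            hemodynamics.total_peripheral_resistance(100.0, 0.0)

    def test_tpr_times_co_is_map(self):
        for map_, co in [(93.3, 5.2), (110.0, 7.7), (85.0, 3.3)]:
            tpr = hemodynamics.total_peripheral_resistance(map_, co)
            assert tpr * co == pytest.approx(map_, rel=1e-12)


class TestBpSlots:
    READINGS = ((120.0, 80.0), (130.0, 85.0), (125.0, 82.0))

    def test_three_distinct_map_values_over_segments(self):
        seg_map = hemodynamics.assign_bp_slots(self.READINGS)
        assert len(seg_map) == 10
        assert len(set(seg_map.values())) == 3
        assert seg_map["BL"] == pytest.approx(280.0 / 3)
        assert seg_map["Q1"] == seg_map["R1"]
        assert seg_map["Q2"] == seg_map["R2a"] == seg_map["R2f"]

    def test_missing_reading_propagates(self):
        seg_map = hemodynamics.assign_bp_slots(((120.0, 80.0), None, (125.0, 82.0)))
        assert seg_map["Q1"] is None and seg_map["R1"] is None
        assert seg_map["Q2"] is not None

    def test_identical_readings_constant_map(self):
        seg_map = hemodynamics.assign_bp_slots(((120.0, 80.0),) * 3)
        assert len(set(seg_map.values())) == 1


class TestStrokeVolumeRoundTrip:
    def test_sv_matches_closed_form_on_clean_recording(self, clean_recording, clean_beats):
        truth = clean_recording.truth
        dzdt = hemodynamics.preprocess_dzdt(
            clean_recording.channels["dzdt"].samples,
            clean_recording.channels["dzdt"].rate)
        ens = hemodynamics.ensemble_average(dzdt, clean_beats, (0.0, 240.0))
        pts = hemodynamics.detect_bzx(ens)
        dzdt_max = ens.waveform[np.searchsorted(ens.time_ms, pts.z)]
        sv = hemodynamics.stroke_volume_kubicek(
            truth.z0, truth.electrode_distance, (pts.x - pts.b) / 1000.0, dzdt_max)
        sv_true = hemodynamics.stroke_volume_kubicek(
            truth.z0, truth.electrode_distance, truth.lvet / 1000.0, truth.dzdt_max)
        assert sv == pytest.approx(sv_true, rel=0.03)
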