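import numpy as np
import pytest

from hemowave.errors import InsufficientDataError, LandmarkError, SegmentationError
from hemowave.preprocessing import (
    EnsembleBeat,
    detect_r_peaks,
    ensemble_average,
    locate_ejection,
    summarize_beat,
)
from hemowave.synthetic_data import SyntheticConfig, generate_recording

from conftest import analyze_tube, clean_config


class TestRPeakDetection:
    def test_clean_signal_peaks_at_beat_onsets(self):
        record, truth = generate_recording(clean_config(n_beats=10))
        seg = detect_r_peaks(record.channels["ecg"], record.fs_hz)
        assert len(seg.r_peak_indices) == 10
        assert np.max(np.abs(seg.r_peak_indices - truth.onset_indices)) <= 2

    def test_noisy_signal_no_extra_or_missed_beats(self, rng):
        record, truth = generate_recording(clean_config(n_beats=10))
        noisy = record.channels["ecg"] + rng.normal(0, 0.1, record.n_samples)
        seg = detect_r_peaks(noisy, record.fs_hz)
        assert len(seg.r_peak_indices) == 10
        assert np.max(np.abs(seg.r_peak_indices - truth.onset_indices)) <= 3

    def test_flat_line_raises(self):
        with pytest.raises(SegmentationError):
            detect_r_peaks(np.zeros(5000), 1000.0)

    def test_rr_intervals_strictly_positive(self):
        record, _ = generate_recording(SyntheticConfig(seed=5))
        seg = detect_r_peaks(record.channels["ecg"], record.fs_hz)
        assert np.all(seg.rr_s > 0)
        assert np.all(np.diff(seg.r_peak_indices) > 0)


class TestEnsembleAverage:
    def test_identical_beats_average_to_any_input_beat(self):
        record, _, seg, beat = analyze_tube(clean_config(gamma=0.4))
        i0, i1 = seg.r_peak_indices[0], seg.r_peak_indices[1]
        first = record.channels["aop"][i0:i1]
        assert len(beat.p_mmhg) == len(first)
        assert np.max(np.abs(beat.p_mmhg - first)) < 1e-9 * np.max(np.abs(first))

    def test_too_few_beats_raises_with_count(self):
        record, _ = generate_recording(clean_config(n_beats=7))
        seg = detect_r_peaks(record.channels["ecg"], record.fs_hz)
        with pytest.raises(InsufficientDataError, match="6"):
            ensemble_average(record, seg, n_beats=8)

    def test_noise_suppressed_by_sqrt_n_beats(self):
        """Averaging 8 beats leaves residual noise ~ sigma/sqrt(8)."""
        sigma = 1.0
        ratios = []
        for seed in range(20):
            clean = clean_config(seed=seed)
            noisy = clean_config(seed=seed, noise_sd_pressure_mmhg=sigma)
            rec_c, _ = generate_recording(clean)
            rec_n, _ = generate_recording(noisy)
            seg = detect_r_peaks(rec_c.channels["ecg"], rec_c.fs_hz)
            beat_c = ensemble_average(rec_c, seg)
            beat_n = ensemble_average(rec_n, seg)
            ratios.append(np.std(beat_n.p_mmhg - beat_c.p_mmhg) / sigma)
        target = 1 / np.sqrt(8)
        assert target - 0.1 < np.mean(ratios) < target + 0.1

    def test_linear_in_inputs(self):
        """avg(a*x) = a*avg(x): ensemble averaging is a linear operator."""
        record, _ = generate_recording(clean_config(gamma=0.3))
        seg = detect_r_peaks(record.channels["ecg"], record.fs_hz)
        beat = ensemble_average(record, seg)
        record.channels["aop"] = 2.0 * record.channels["aop"]
        doubled = ensemble_average(record, seg)
        assert np.allclose(doubled.p_mmhg, 2.0 * beat.p_mmhg, rtol=1e-12, atol=1e-9)

    def test_velocity_derived_from_flow_when_missing(self):
        record, _ = generate_recording(clean_config())
        expected_u = record.channels["velocity"]
        del record.channels["velocity"]
        seg = detect_r_peaks(record.channels["ecg"], record.fs_hz)
        beat = ensemble_average(record, seg, probe_area_cm2=3.0)
        i0, i1 = seg.r_peak_indices[0], seg.r_peak_indices[1]
        assert np.allclose(beat.u_m_s, expected_u[i0:i1], rtol=1e-9, atol=1e-12)


class TestEjectionLandmarks:
    def test_synthetic_window_recovered_within_5_ms(self):
        config = clean_config(gamma=0.0)
        _, truth, _, beat = analyze_tube(config)
        assert beat.ejection_onset_s == pytest.approx(0.0, abs=0.005)
        assert beat.ejection_end_s == pytest.approx(
            truth.ejection_duration_s, abs=0.005
        )

    def test_rectangular_pulse_edges(self):
        fs = 1000.0
        q = np.zeros(500)
        q[100:300] = 200.0
        beat = EnsembleBeat(fs_hz=fs, p_mmhg=np.full(500, 100.0), q_ml_s=q)
        onset, end = locate_ejection(beat)
        assert onset == pytest.approx(0.1, abs=0.005)
        assert end == pytest.approx(0.3, abs=0.005)

    def test_zero_flow_raises(self):
        beat = EnsembleBeat(
            fs_hz=1000.0, p_mmhg=np.full(100, 100.0), q_ml_s=np.zeros(100)
        )
        with pytest.raises(LandmarkError):
            locate_ejection(beat)


class TestBeatSummary:
    def test_pulse_pressure_identity_and_map(self):
        p = np.array([90.4, 100.0, 114.0, 95.0])
        beat = EnsembleBeat(fs_hz=1000.0, p_mmhg=p)
        s = summarize_beat(beat)
        assert s.pp_mmhg == pytest.approx(s.sbp_mmhg - s.dbp_mmhg)
        assert s.pp_mmhg == pytest.approx(114.0 - 90.4)
        assert s.map_mmhg == pytest.approx(p.mean())

    def test_constant_pressure_gives_zero_pp_and_derivatives(self):
        beat = EnsembleBeat(
            fs_hz=1000.0,
            p_mmhg=np.full(400, 100.0),
            lvp_mmhg=np.full(400, 100.0),
        )
        s = summarize_beat(beat)
        assert s.pp_mmhg == 0.0
        assert s.lv_dpdt_max_mmhg_s == 0.0 and s.lv_dpdt_min_mmhg_s == 0.0

    def test_missing_lvp_flags_fields_absent(self):
        beat = EnsembleBeat(fs_hz=1000.0, p_mmhg=np.array([90.0, 95.0, 92.0]))
        s = summarize_beat(beat)
        assert s.lv_dpdt_max_mmhg_s is None and s.co_l_min is None

    def test_cardiac_output_matches_stroke_volume_times_hr(self):
        """Mean flow over the beat equals SV x HR (no-reflection tube)."""
        config = clean_config(gamma=0.0)
        _, _, seg, beat = analyze_tube(config)
        s = summarize_beat(beat, seg)
        t_eject = config.ejection_fraction_of_cycle * 60.0 / config.heart_rate_bpm
        sv_ml = config.peak_flow_ml_s * (2 / np.pi) * t_eject
        expected_co = sv_ml * config.heart_rate_bpm / 1000.0
        assert s.co_l_min == pytest.approx(expected_co, rel=0.02)
        assert s.hr_bpm == pytest.approx(config.heart_rate_bpm, rel=0.01)
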