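"""Generator contracts: determinism, spectral placement, IPFM self-consistency."""

import numpy as np
import pytest

from cardioresp import synth
from cardioresp.types import BeatSeries


class TestRespiration:
    def test_zero_amplitude_gives_zero_airflow(self):
        spec = synth.SynthSubjectSpec(resp_amp_ml=0.0)
        flow = synth.gen_respiration(spec)
        assert np.all(flow.samples == 0.0)

    def test_ilv_spectrum_peaks_at_breathing_rate(self):
        spec = synth.SynthSubjectSpec(resp_freq_hz=0.25, resp_freq_jitter=0.0, resp_wideband_frac=0.0)
        ilv = synth.gen_ilv(spec)
        freqs = np.fft.rfftfreq(ilv.n, 1.0 / ilv.fs)
        power = np.abs(np.fft.rfft(ilv.samples)) ** 2
        assert abs(freqs[np.argmax(power)] - 0.25) < 1.0 / spec.duration_s

    def test_spectral_placement_within_band(self):
        # >= 95% of respiration power within resp_freq +- 0.05 Hz
        spec = synth.SynthSubjectSpec(seed=5)
        flow = synth.gen_respiration(spec)
        freqs = np.fft.rfftfreq(flow.n, 1.0 / flow.fs)
        power = np.abs(np.fft.rfft(flow.samples)) ** 2
        band = (freqs >= spec.resp_freq_hz - 0.05) & (freqs <= spec.resp_freq_hz + 0.05)
        assert power[band].sum() / power.sum() >= 0.95

    def test_airflow_integrates_to_ilv(self):
        # cumulative integral of the generated airflow tracks gen_ilv
        spec = synth.SynthSubjectSpec(seed=2)
        flow = synth.gen_respiration(spec)
        ilv = synth.gen_ilv(spec)
        # the airflow is mean-removed, so its integral matches the ILV only
        # up to a linear drift; compare after removing an LS line from both
        def detrend_line(v, t):
            coef = np.polynomial.polynomial.polyfit(t, v, 1)
            return v - np.polynomial.polynomial.polyval(t, coef)

        t = flow.times()
        vol = detrend_line(np.cumsum(flow.samples) / flow.fs, t)
        ref = detrend_line(ilv.samples, t)
        assert np.sqrt(np.mean((vol - ref) ** 2)) < 0.05 * np.std(ref)

    def test_determinism(self):
        spec = synth.SynthSubjectSpec(seed=9)
        a = synth.gen_respiration(spec)
        b = synth.gen_respiration(spec)
        np.testing.assert_array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("bad", [{"resp_freq_hz": 0.1}, {"fs_raw": 50}, {"duration_s": -1}])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(ValueError):
            synth.SynthSubjectSpec(**bad)


class TestBeatTimes:
    def test_constant_rate_when_unmodulated(self):
        spec = synth.SynthSubjectSpec(
            true_ir=synth.IrKernel((0.0,), (0.0,)),
            lf_osc=(0.09, 0.0),
            noise_sd_ms=0.0,
            resp_freq_jitter=0.0,
        )
        beats = synth.gen_beat_times(spec, synth.gen_ilv(spec))
        # all intervals equal the baseline within event quantization (2 raw samples)
        assert np.all(np.abs(beats.rri_ms - spec.rri_baseline_ms) <= 2000.0 / spec.fs_raw)

    def test_single_tap_kernel_matches_convolution_oracle(self):
        # brute-force oracle: RRI(t) = baseline + h0 * ILV(t); beat intervals
        # must track that profile at the interval midpoints
        spec = synth.SynthSubjectSpec(
            true_ir=synth.IrKernel((0.0,), (0.1,)),
            lf_osc=(0.09, 0.0),
            noise_sd_ms=0.0,
            resp_freq_jitter=0.0,
            resp_wideband_frac=0.0,
        )
        ilv = synth.gen_ilv(spec)
        beats = synth.gen_beat_times(spec, ilv)
        profile = spec.rri_baseline_ms + 0.1 * ilv.samples  # direct convolution (1 tap)
        mid = (beats.r_times_s[:-1] + beats.r_times_s[1:]) / 2
        expected = np.interp(mid, ilv.times(), profile)
        assert np.ptp(beats.rri_ms) > 60  # modulation actually present
        # error budget: interval averaging of the 0.25 Hz modulation
        # (~8% of the 40 ms amplitude) plus 2 samples of event quantization
        assert np.max(np.abs(beats.rri_ms - expected)) < 10.0

    def test_noise_changes_sequence_not_mean(self):
        specs = [synth.SynthSubjectSpec(noise_sd_ms=10.0, seed=s) for s in (1, 2)]
        rri = [synth.gen_beat_times(s, synth.gen_ilv(s)).rri_ms for s in specs]
        assert not np.array_equal(rri[0], rri[1])
        se = np.hypot(np.std(rri[0]) / np.sqrt(rri[0].size), np.std(rri[1]) / np.sqrt(rri[1].size))
        assert abs(np.mean(rri[0]) - np.mean(rri[1])) < 3 * se

    def test_causality_cross_correlation_peaks_at_delay(self):
        # xcorr of ILV with the coupling-driven RRI residual peaks at the
        # kernel delay (single-tap kernel so the peak is unambiguous)
        delay = 0.75
        spec = synth.SynthSubjectSpec(
            true_ir=synth.IrKernel((0.0,), (0.1,), delay_s=delay),
            noise_sd_ms=0.0,
            resp_freq_jitter=0.0,
        )
        ilv = synth.gen_ilv(spec)
        residual = spec.true_ir.apply(ilv)
        fs4 = 4.0
        t4 = np.arange(0, spec.duration_s, 1 / fs4)
        x = np.interp(t4, ilv.times(), ilv.samples)
        r = np.interp(t4, ilv.times(), residual)
        lags = np.arange(-20, 21)
        xc = [np.corrcoef(x[20:-20], r[20 + k : r.size - 20 + k])[0, 1] for k in lags]
        peak_lag_s = lags[int(np.argmax(xc))] / fs4
        assert peak_lag_s >= 0
        assert abs(peak_lag_s - delay) <= 1 / fs4

    def test_nonpositive_rri_profile_rejected(self):
        spec = synth.SynthSubjectSpec(lf_osc=(0.09, 2000.0), noise_sd_ms=0.0)
        with pytest.raises(ValueError, match="non-positive"):
            synth.gen_beat_times(spec, synth.gen_ilv(spec))


class TestEcg:
    def test_maxima_at_prescribed_beat_times(self):
        beats = BeatSeries(np.arange(1.0, 30.0, 1.0))
        ecg = synth.gen_ecg(beats, fs_raw=250.0)
        for bt in beats.r_times_s:
            lo, hi = int((bt - 0.4) * 250), int((bt + 0.4) * 250)
            peak = lo + int(np.argmax(ecg.samples[lo:hi]))
            assert abs(peak - bt * 250) <= 1

    def test_empty_beats_error(self):
        with pytest.raises(ValueError):
            synth.gen_ecg(BeatSeries(np.array([1.0])), 250.0)

    def test_amplitude_linearity(self):
        beats = BeatSeries(np.arange(1.0, 10.0, 1.0))
        a = synth.gen_ecg(beats, 250.0, amplitude=1.0)
        b = synth.gen_ecg(beats, 250.0, amplitude=3.0)
        np.testing.assert_allclose(b.samples, 3.0 * a.samples, atol=1e-12)

    def test_qrs_dominates_background(self):
        beats = BeatSeries(np.arange(1.0, 30.0, 1.0))
        ecg = synth.gen_ecg(beats, 250.0)
        assert np.ptp(ecg.samples) >= 5 * 0.05 * 2  # QRS >= 5x baseline wander


class TestCohort:
    def test_default_counts(self):
        recs = synth.gen_cohort(synth.SynthCohortSpec(seed=0))
        assert len(recs) == 29
        assert sum(r.label for r in recs) == 18

    def test_minimal_cohort(self):
        recs = synth.gen_cohort(synth.SynthCohortSpec(n_case=2, n_control=2, seed=0))
        assert len(recs) == 4

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            synth.SynthCohortSpec(n_case=1, n_control=5)

    def test_cohort_determinism(self):
        a = synth.gen_cohort(synth.SynthCohortSpec(n_case=2, n_control=2, seed=7))
        b = synth.gen_cohort(synth.SynthCohortSpec(n_case=2, n_control=2, seed=7))
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.ecg.samples, rb.ecg.samples)
            np.testing.assert_array_equal(ra.airflow.samples, rb.airflow.samples)
            assert ra.ground_truth["dg_hf"] == rb.ground_truth["dg_hf"]

    def test_ground_truth_carries_kernel_and_band_gains(self):
        rec = synth.gen_cohort(synth.SynthCohortSpec(n_case=2, n_control=2, seed=1))[0]
        gt = rec.ground_truth
        assert gt["dg_hf"] > 0 and gt["dg_lf"] > 0
        assert len(gt["kernel_lags_s"]) == len(gt["kernel_coeffs"])
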