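import numpy as np
import pytest

from nirsync import (
    NoiseSpec,
    bandpass,
    build_montage,
    build_schedule,
    intensity_to_od,
    od_to_hb,
    qc_heartband,
    require_roi_coverage,
    simulate_dyad,
    spline_motion_correct,
)
from nirsync.mbll import hb_to_od
from nirsync.preprocess import ChannelQcReport, InputError, OdSeries, preprocess_recording
from nirsync.simulate import RawRecording, inject_motion

FS = 7.81


def _recording_from_intensity(I, montage=None, fs=FS):
    montage = montage or build_montage("single-1")
    return RawRecording("S1", montage, I, fs)


class TestIntensityToOd:
    def test_constant_intensity_gives_zero_od(self):
        I = np.full((1, 2, 500), 3.7)
        od = intensity_to_od(_recording_from_intensity(I))
        assert np.allclose(od.data, 0.0)

    def test_log_identity_at_single_sample(self):
        I = np.ones((1, 2, 1000))
        # one sample at mean * e^{-1}: OD there is 1 up to the tiny mean shift
        I[0, 0, 100] = np.exp(-1.0)
        od = intensity_to_od(_recording_from_intensity(I))
        mean_i = I[0, 0].mean()
        expected = (1.0 + np.log(mean_i)) - (-np.log(I[0, 0] / mean_i)).mean()
        assert od.data[0, 0, 100] == pytest.approx(expected, abs=1e-12)

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        I = np.exp(0.05 * rng.standard_normal((1, 2, 400))) * 2.0
        od1 = intensity_to_od(_recording_from_intensity(I))
        od2 = intensity_to_od(_recording_from_intensity(7.3 * I))
        assert np.allclose(od1.data, od2.data, atol=1e-12)

    def test_zero_temporal_mean(self):
        rng = np.random.default_rng(1)
        I = np.exp(0.1 * rng.standard_normal((1, 2, 300)))
        od = intensity_to_od(_recording_from_intensity(I))
        assert np.allclose(od.data.mean(axis=2), 0.0, atol=1e-14)

    def test_nonpositive_intensity_raises(self):
        I = np.ones((1, 2, 100))
        I[0, 1, 50] = 0.0
        with pytest.raises(InputError, match="channel"):
            intensity_to_od(_recording_from_intensity(I))


class TestMbll:
    def test_zero_od_zero_hb(self):
        od = OdSeries(np.zeros((1, 2, 50)), FS, (760, 850))
        hb = od_to_hb(od)
        assert np.allclose(hb.data, 0.0)

    def test_round_trip_exact(self):
        rng = np.random.default_rng(2)
        hbo = rng.standard_normal((3, 200))
        hbr = rng.standard_normal((3, 200))
        od = hb_to_od(hbo, hbr)
        hb = od_to_hb(OdSeries(od - od.mean(axis=-1, keepdims=True), FS, (760, 850)))
        hbo_c = hbo - hbo.mean(axis=-1, keepdims=True)
        hbr_c = hbr - hbr.mean(axis=-1, keepdims=True)
        assert np.max(np.abs(hb.data[:, 0] - hbo_c)) < 1e-10
        assert np.max(np.abs(hb.data[:, 1] - hbr_c)) < 1e-10

    def test_unit_hbo_recovered(self):
        hbo = np.ones((1, 10))
        hbr = np.zeros((1, 10))
        od = hb_to_od(hbo, hbr)
        hb = od_to_hb(OdSeries(od, FS, (760, 850)))
        assert np.allclose(hb.data[:, 0], 1.0, atol=1e-10)
        assert np.allclose(hb.data[:, 1], 0.0, atol=1e-10)

    def test_doubling_dpf_halves_concentrations(self):
        rng = np.random.default_rng(3)
        od = OdSeries(rng.standard_normal((1, 2, 60)) * 0.01, FS, (760, 850))
        hb6 = od_to_hb(od, dpf=6.0)
        hb12 = od_to_hb(od, dpf=12.0)
        assert np.allclose(hb12.data, hb6.data / 2)


class TestBandpass:
    def _sine_od(self, f, n=4096, amp=1.0, offset=0.0):
        t = np.arange(n) / FS
        x = amp * np.sin(2 * np.pi * f * t) + offset
        return OdSeries(np.tile(x, (1, 2, 1)).reshape(1, 2, n) * 1.0, FS, (760, 850))

    def test_passband_gain_and_zero_phase(self):
        od = bandpass(self._sine_od(0.1))
        y = od.data[0, 0]
        x = self._sine_od(0.1).data[0, 0]
        core = slice(500, -500)
        t = np.arange(len(x))[core] / FS
        # amplitude at the driving frequency by quadrature projection
        proj = np.hypot(
            2 * np.mean(y[core] * np.sin(2 * np.pi * 0.1 * t)),
            2 * np.mean(y[core] * np.cos(2 * np.pi * 0.1 * t)),
        )
        assert 0.9 <= proj <= 1.0 + 1e-6
        lags = np.arange(-20, 21)
        xc = [np.dot(y[500:-500], np.roll(x, l)[500:-500]) for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_dc_removed(self):
        od = OdSeries(np.full((1, 2, 2000), 5.0), FS, (760, 850))
        out = bandpass(od)
        assert np.max(np.abs(out.data.mean(axis=2))) < 1e-3

    def test_stopband_attenuation_2hz(self):
        od = bandpass(self._sine_od(2.0))
        y = od.data[0, 0][500:-500]
        x = self._sine_od(2.0).data[0, 0][500:-500]
        atten_db = 20 * np.log10(x.std() / max(y.std(), 1e-300))
        assert atten_db >= 20

    def test_idempotence_in_band(self):
        """A second pass changes strictly-in-band content by <1% RMS."""
        rng = np.random.default_rng(4)
        od = OdSeries(rng.standard_normal((1, 2, 4096)), FS, (760, 850))
        once = bandpass(od)
        twice = bandpass(once)
        d1 = once.data[0, 0][400:-400]
        d2 = twice.data[0, 0][400:-400]
        w = np.hanning(len(d1))  # window out stop-band leakage
        f = np.fft.rfftfreq(len(d1), d=1 / FS)
        core = (f >= 0.05) & (f <= 0.16)
        a = np.fft.rfft(d1 * w)[core]
        b = np.fft.rfft(d2 * w)[core]
        assert np.linalg.norm(b - a) / np.linalg.norm(a) < 0.01

    def test_bad_cutoffs_rejected(self):
        od = OdSeries(np.zeros((1, 2, 100)), FS, (760, 850))
        with pytest.raises(ValueError):
            bandpass(od, 0.5, 0.01)
        with pytest.raises(ValueError):
            bandpass(od, 0.01, 5.0)


class TestSplineMotionCorrection:
    def test_artifact_free_signal_untouched(self):
        t = np.arange(3000) / FS
        x = 0.01 * np.sin(2 * np.pi * 0.1 * t)
        od = OdSeries(np.tile(x, 2).reshape(1, 2, -1).copy(), FS, (760, 850))
        out, intervals = spline_motion_correct(od)
        assert intervals == [[]]
        assert np.allclose(out.data, od.data - od.data.mean(axis=2, keepdims=True))

    def _corrupted_pair(self, n_spikes, n_shifts, seed=5):
        m = build_montage("single-1")
        s = build_schedule(0, trials_per_block=4, rest_s=30.0)
        clean, _ = simulate_dyad(m, s, seed=seed)
        dirty, log = inject_motion(clean, n_spikes, n_shifts, seed=seed)
        return clean, dirty, log

    def test_baseline_shift_reduced_90_percent(self):
        clean, dirty, log = self._corrupted_pair(0, 1)
        od_d = intensity_to_od(dirty)
        corrected, _ = spline_motion_correct(od_d)
        fs = dirty.fs_hz
        k = int(log.shifts[0] * fs)
        w = int(5 * fs)

        def step(x):
            return abs(x[k + w // 2: k + 3 * w].mean() - x[k - 3 * w: k - w // 2].mean())

        before = step(od_d.data[0, 0])
        after = step(corrected.data[0, 0])
        assert after <= 0.1 * before

    def test_spike_correction_tracks_clean_signal(self):
        clean, dirty, _ = self._corrupted_pair(3, 0)
        od_c = intensity_to_od(clean)
        od_d = intensity_to_od(dirty)
        corrected, intervals = spline_motion_correct(od_d)
        assert len(intervals[0]) >= 1
        r = np.corrcoef(corrected.data[0, 0], od_c.data[0, 0])[0, 1]
        assert r >= 0.95

    def test_invalid_p_rejected(self):
        od = OdSeries(np.zeros((1, 2, 100)), FS, (760, 850))
        with pytest.raises(ValueError):
            spline_motion_correct(od, p_smooth=1.5)


class TestHeartbandQc:
    def _dyad_recording(self, seed=0, cardiac_amp=0.15):
        m = build_montage("mini-8")
        s = build_schedule(0, trials_per_block=4, rest_s=30.0)
        noise = NoiseSpec(cardiac_amp=cardiac_amp)
        rec, _ = simulate_dyad(m, s, noise=noise, seed=seed)
        return rec

    def test_cardiac_channels_pass(self):
        rep = qc_heartband(self._dyad_recording())
        assert rep.retention_fraction == 1.0
        assert all(0.8 <= p <= 1.5 for p in rep.peak_hz)

    def test_roi_counts_sum_to_passing(self):
        rep = qc_heartband(self._dyad_recording(seed=1))
        assert sum(rep.roi_pass_counts.values()) == sum(rep.passed)

    def test_white_noise_false_positive_rate(self):
        """Pure-noise channels pass in <10% of seeds at the default SNR."""
        m = build_montage("single-1")
        n = int(90 * FS)
        hits = 0
        trials = 100
        rng = np.random.default_rng(123)
        for _ in range(trials):
            I = np.exp(0.01 * rng.standard_normal((1, 2, n)))
            rec = RawRecording("S1", m, I, FS)
            rep = qc_heartband(rec)
            hits += int(rep.passed[0])
        assert hits / trials < 0.10

    def test_short_recording_rejected(self):
        m = build_montage("single-1")
        I = np.ones((1, 2, int(30 * FS)))
        with pytest.raises(InputError):
            qc_heartband(RawRecording("S1", m, I, FS))


class TestRoiCoverage:
    def _report(self, passed):
        rois = ["lDLPFC", "lDLPFC", "lTPJ", "lTPJ"]
        return ChannelQcReport([1, 2, 3, 4], rois, passed, [1.1] * 4, [5.0] * 4)

    def test_full_coverage_passes(self):
        ok, bad = require_roi_coverage(self._report([True] * 4))
        assert ok and bad == []

    def test_single_channel_roi_fails_and_is_named(self):
        ok, bad = require_roi_coverage(self._report([True, True, True, False]))
        assert not ok and bad == ["lTPJ"]

    def test_zero_threshold_always_passes(self):
        ok, _ = require_roi_coverage(self._report([False] * 4), min_per_roi=0)
        assert ok


def test_preprocessing_deterministic(sim_pair):
    ra, _ = sim_pair
    h1 = preprocess_recording(ra)
    h2 = preprocess_recording(ra)
    assert np.array_equal(h1.data, h2.data)


def test_preprocessed_band_limited(hb_pair):
    """Out-of-band power after the 0.01-0.50 Hz filter is <5%."""
    from scipy import signal as sps

    ha, _ = hb_pair
    x = ha.data[0, 0]
    f, p = sps.welch(x, fs=FS, nperseg=1024)
    in_band = (f >= 0.008) & (f <= 0.55)
    assert p[~in_band].sum() / p.sum() < 0.05
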