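import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirsync import CouplingSpec, WtcParams, band_average, cwt_morlet, wtc
from nirsync.coherence import (
    CLAMP_EPS,
    EmptySelectionError,
    ValidationError,
    condition_coherence,
)

from oracles import cwt_direct, wtc_brute

FS = 7.81
#: grid on which the sampled analytic wavelet is alias-free (>=4 samples/scale)
ORACLE_PARAMS = WtcParams(s0=4 / FS)


class TestCwt:
    def test_sinusoid_peak_period(self):
        t = np.arange(2048) / FS
        x = np.sin(2 * np.pi * t / 10.0)
        W = cwt_morlet(x, FS)
        power = (np.abs(W.coefficients) ** 2).mean(axis=1)
        peak = W.fourier_periods[np.argmax(power)]
        assert abs(np.log2(peak / 10.0)) <= 0.5 / 12  # within half a sub-octave

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 256))
        Wx = cwt_morlet(x, FS).coefficients
        Wy = cwt_morlet(y, FS).coefficients
        Ws = cwt_morlet(x + y, FS).coefficients
        Wa = cwt_morlet(2.5 * x, FS).coefficients
        assert np.allclose(Ws, Wx + Wy, atol=1e-10)
        assert np.allclose(Wa, 2.5 * Wx, atol=1e-10)

    def test_direct_convolution_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        W = cwt_morlet(x, FS, ORACLE_PARAMS)
        Wd = cwt_direct(x, FS, W.scales)
        err = np.max(np.abs(W.coefficients - Wd)) / np.max(np.abs(Wd))
        assert err < 1e-6

    def test_scale_grid_dyadic(self):
        W = cwt_morlet(np.random.default_rng(1).standard_normal(512), FS)
        ratios = W.scales[1:] / W.scales[:-1]
        assert np.allclose(ratios, 2 ** (1 / 12))
        assert np.all(np.diff(W.scales) > 0)
        assert W.scales[0] == pytest.approx(2 / FS)

    def test_coi_symmetric_efolding(self):
        W = cwt_morlet(np.zeros(100) + np.random.default_rng(2).standard_normal(100), FS)
        assert np.allclose(W.coi, W.coi[::-1])
        # e-folding: at time index t, max valid scale is t*dt/sqrt(2)
        t = 30
        assert W.coi[t] == pytest.approx(W.params.fourier_factor * t / FS / np.sqrt(2))

    def test_nan_rejected(self):
        x = np.ones(64)
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            cwt_morlet(x, FS)


class TestWtc:
    def test_self_coherence_is_one(self):
        x = np.random.default_rng(3).standard_normal(512)
        m = wtc(x, x, FS)
        assert np.all(m.r2 >= 1 - 1e-6)
        assert np.all(m.r2 <= 1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 300))
        assert np.max(np.abs(wtc(x, y, FS).r2 - wtc(y, x, FS).r2)) < 1e-10

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(0.01, 100.0),
        seed=st.integers(0, 10_000),
    )
    def test_amplitude_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 200))
        r_ref = wtc(x, y, FS).r2
        r_scaled = wtc(a * x, b * y, FS).r2
        assert np.max(np.abs(r_ref - r_scaled)) < 1e-10

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 200))
        m = wtc(x, y, FS, ORACLE_PARAMS)
        r2b = wtc_brute(x, y, FS, m.scales, ORACLE_PARAMS.dj)
        assert np.max(np.abs(m.r2 - r2b)) < 1e-6

    def test_independent_noise_low_in_band(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(10):
            x, y = rng.standard_normal((2, 4096))
            v, _ = band_average(wtc(x, y, FS))
            vals.append(v)
        assert np.mean(vals) < 0.5

    def test_shared_band_component_raises_low_frequency_coherence(self):
        rng = np.random.default_rng(8)
        t = np.arange(4096) / FS
        s = np.sin(2 * np.pi * 0.1 * t)
        x = s + rng.standard_normal(4096)
        y = s + rng.standard_normal(4096)
        m = wtc(x, y, FS)
        i10 = np.argmin(np.abs(m.fourier_periods - 10.0))
        i2 = np.argmin(np.abs(m.fourier_periods - 2.0))
        assert m.r2[i10].mean() > m.r2[i2].mean()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            wtc(np.zeros(100), np.zeros(99), FS)


class TestBandAverage:
    def _matrix(self, n=1024):
        return wtc(*np.random.default_rng(9).standard_normal((2, n)), FS)

    def test_constant_field_mean(self):
        m = self._matrix()
        m.r2[:] = 0.37
        v, k = band_average(m)
        assert v == pytest.approx(0.37)
        assert k > 0

    def test_band_period_selection(self):
        """0.05-0.16 Hz selects Fourier periods spanning ~6.25 to 20 s."""
        m = self._matrix(4096)
        sel = (m.fourier_periods >= 1 / 0.16) & (m.fourier_periods <= 1 / 0.05)
        periods = m.fourier_periods[sel]
        assert periods.min() >= 6.25
        assert periods.min() <= 6.25 * 2 ** (1 / 12)
        assert periods.max() <= 20.0
        assert periods.max() >= 20.0 * 2 ** (-1 / 12)

    def test_coi_exclusion_reduces_points(self):
        m = self._matrix(600)
        _, k_in = band_average(m, exclude_coi=False)
        _, k_out = band_average(m, exclude_coi=True)
        assert k_out < k_in

    def test_segment_restriction(self):
        m = self._matrix(2048)
        _, k_all = band_average(m, exclude_coi=False)
        _, k_seg = band_average(m, segments=[(60.0, 120.0)], exclude_coi=False)
        assert 0 < k_seg < k_all

    def test_empty_selection_raises(self):
        m = self._matrix(256)
        with pytest.raises(EmptySelectionError):
            band_average(m, band_hz=(0.0001, 0.0002))


class TestConditionCoherence:
    def test_emits_5x_channels_rows(self, hb_pair, short_schedule):
        ha, hb = hb_pair
        tab = condition_coherence(ha, hb, short_schedule, "HbR",
                                  dyad_id="d1", min_part_s=40)
        assert len(tab) == 5 * 8
        assert set(tab["condition"]) == {
            "FreePlay", "PredictionDifferent", "PredictionSame", "Control", "Rest"
        }
        per = tab.groupby("channel").size()
        assert (per == 5).all()
        assert ((tab["wtc_value"] >= CLAMP_EPS) & (tab["wtc_value"] <= 1 - CLAMP_EPS)).all()

    def test_condition_value_is_mean_of_parts(self, hb_pair, short_schedule):
        from nirsync.coherence import SegmentCwtCache, channel_condition_values, _pair_group_values

        ha, hb = hb_pair
        cA = SegmentCwtCache(ha, short_schedule, "HbR")
        cB = SegmentCwtCache(hb, short_schedule, "HbR")
        vals = dict(
            (c, v) for c, v, _ in channel_condition_values(cA, cB, 1)
        )
        # recompute FreePlay block values independently and average
        fp_idx = [
            i for i, seg in enumerate(short_schedule.segments)
            if seg.kind == "task" and seg.condition == "FreePlay"
        ]
        block_vals = []
        for n, idxs in cA.groups.items():
            got, _ = _pair_group_values(cA, cB, 1, n, (0.05, 0.16), True)
            for i, v in zip(idxs, got):
                if i in fp_idx:
                    block_vals.append(v)
        assert len(block_vals) == 2
        assert vals["FreePlay"] == pytest.approx(np.mean(block_vals))

    def test_short_part_rejected(self, hb_pair, short_schedule):
        ha, hb = hb_pair
        with pytest.raises(ValidationError, match="FreePlay"):
            condition_coherence(ha, hb, short_schedule, min_part_s=120.0)

    def test_coupled_dyad_freeplay_exceeds_control(
        self, mini_montage, short_schedule
    ):
        """kappa=0.9 in FreePlay vs 0 in Control separates the conditions
        (mean over a handful of seeds)."""
        from conftest import simulate_hb_set

        coupling = CouplingSpec(
            kappa={"FreePlay": 0.9, "PredictionDifferent": 0.0,
                   "PredictionSame": 0.0, "Control": 0.0, "Rest": 0.0},
            roi_gain={},
        )
        diffs = []
        hbs = simulate_hb_set(mini_montage, short_schedule, coupling, 5, 500)
        for ha, hb in hbs.values():
            tab = condition_coherence(ha, hb, short_schedule, "HbR", min_part_s=40)
            g = tab.groupby("condition")["wtc_value"].mean()
            diffs.append(g["FreePlay"] - g["Control"])
        assert np.mean(diffs) > 0.05
        assert np.mean(diffs) > 0
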