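"""Morlet wavelet-transform coherence (WTC) between paired fNIRS time series.

The continuous wavelet transform follows the standard dyadic-scale-grid
construction (scales ``s_j = s0 * 2**(j*dj)``, default 12 sub-octaves per
octave) with a complex Morlet mother wavelet (center frequency ``omega0 = 6``
rad).  Coherence is the smoothed, normalized cross-spectrum

    R2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

with S a Gaussian smoothing in time (sd = s) followed by a boxcar smoothing
across scales spanning 0.6 octave — the convention of the widely used
cross-wavelet toolbox.  Values are band-averaged over the analysis band
(default 0.05-0.16 Hz, i.e. Fourier periods ~6.25-20 s), outside the cone of
influence by default, and aggregated per condition segment into the
per-dyad coherence table (5 conditions x channels).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, irfft, next_fast_len, rfft

from .preprocess import HbSeries
from .schedule import CONDITIONS, SessionSchedule, Segment, segment_slice


class EmptySelectionError(ValueError):
    """Band/segment/COI masking left no points to average."""


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# continuous wavelet transform


@dataclass(frozen=True)
class WtcParams:
    """Scale-grid, wavelet and smoothing parameters.

    ``s0``/``max_scale_frac`` set the dyadic grid (default smallest scale
    2/fs, largest scale = series duration / 4).  ``min_period_s`` /
    ``max_period_s`` optionally truncate the grid to the periods a pipeline
    actually consumes, which speeds up segment-wise coherence considerably.
    """

    dj: float = 1.0 / 12.0
    omega0: float = 6.0
    s0: float | None = None
    max_scale_frac: float = 0.25
    min_period_s: float | None = None
    max_period_s: float | None = None
    scale_smooth_octaves: float = 0.6
    pad_factor: int = 4

    @property
    def fourier_factor(self) -> float:
        return 4 * np.pi / (self.omega0 + np.sqrt(2 + self.omega0**2))


@dataclass
class CwtResult:
    coefficients: np.ndarray    # (n_scales, n_times) complex
    scales: np.ndarray          # s
    fourier_periods: np.ndarray  # s
    coi: np.ndarray             # per-time maximum valid period (s)
    dt: float
    params: WtcParams


def _scale_grid(n: int, dt: float, params: WtcParams) -> np.ndarray:
    ff = params.fourier_factor
    s0 = params.s0 if params.s0 is not None else 2 * dt
    smax = n * dt * params.max_scale_frac
    if params.min_period_s is not None:
        s0 = max(s0, params.min_period_s / ff)
    if params.max_period_s is not None:
        smax = min(smax, params.max_period_s / ff)
    if smax < s0:
        smax = s0
    J = int(np.floor(np.log2(smax / s0) / params.dj))
    return s0 * 2.0 ** (params.dj * np.arange(J + 1))


def _next_pow2(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(2, n))))


def _pad_len(n: int) -> int:
    # smallest fast FFT length >= n (5-smooth), keeps linear-convolution exactness
    return next_fast_len(n, real=False)


def cwt_morlet(
    x: np.ndarray, fs_hz: float, params: WtcParams | None = None
) -> CwtResult:
    """Morlet continuous wavelet transform on a dyadic scale grid.

    Zero-padded FFT implementation; equivalent to direct time-domain
    convolution of the (zero-extended) series with the scaled wavelets.
    The transform is linear in the input.
    """
    params = params or WtcParams()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("cwt_morlet expects a 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValueError("input series contains NaN/inf")
    n = x.size
    dt = 1.0 / fs_hz
    if n < 8:
        raise ValueError("series too short for a wavelet transform")

    scales = _scale_grid(n, dt, params)
    P = _pad_len(params.pad_factor * n)
    xhat = fft(x - x.mean(), P)
    omega = 2 * np.pi * np.fft.fftfreq(P, d=dt)

    # Morlet filter bank, unit-energy normalization per Torrence-Compo
    sw = scales[:, None] * omega[None, :]
    psi_hat = (np.pi**-0.25) * np.exp(-0.5 * (sw - params.omega0) ** 2) * (omega[None, :] > 0)
    norm = np.sqrt(2 * np.pi * scales / dt)
    W = ifft(xhat[None, :] * psi_hat * norm[:, None], axis=1)[:, :n]

    periods = params.fourier_factor * scales
    dist = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi = params.fourier_factor * dist / np.sqrt(2.0)  # e-folding time sqrt(2)*s
    return CwtResult(W, scales, periods, coi, dt, params)


def _cwt_batch(X: np.ndarray, fs_hz: float, params: WtcParams) -> tuple:
    """Transform a batch of equal-length series: (m, n) -> (m, S, n).

    Returns (W, scales, periods, coi); identical per-series results to
    :func:`cwt_morlet`, batched through the FFTs.
    """
    m, n = X.shape
    dt = 1.0 / fs_hz
    scales = _scale_grid(n, dt, params)
    P = _pad_len(params.pad_factor * n)
    xhat = fft(X - X.mean(axis=1, keepdims=True), P, axis=-1)
    omega = 2 * np.pi * np.fft.fftfreq(P, d=dt)
    sw = scales[:, None] * omega[None, :]
    psi_hat = (np.pi**-0.25) * np.exp(-0.5 * (sw - params.omega0) ** 2) * (omega[None, :] > 0)
    psi_hat *= np.sqrt(2 * np.pi * scales / dt)[:, None]
    W = ifft(xhat[:, None, :] * psi_hat[None, :, :], axis=-1)[..., :n]
    periods = params.fourier_factor * scales
    dist = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
    coi = params.fourier_factor * dist / np.sqrt(2.0)
    return W, scales, periods, coi


# ---------------------------------------------------------------------------
# smoothing operators


@lru_cache(maxsize=64)
def _gauss_kernel_bank_fft(n: int, scales_key: tuple, dt: float) -> tuple:
    """FFT of the per-scale Gaussian time kernels (sd = scale), cached."""
    sigmas = np.array(scales_key) / dt  # in samples
    radii = np.maximum(1, (4.0 * sigmas + 0.5).astype(int))
    rmax = int(radii.max())
    P = _pad_len(n + 2 * rmax + 1)
    bank = np.zeros((len(sigmas), P))
    for i, (sig, r) in enumerate(zip(sigmas, radii)):
        k = np.arange(-r, r + 1)
        g = np.exp(-0.5 * (k / sig) ** 2)
        g /= g.sum()
        bank[i, :r + 1] = g[r:]
        bank[i, P - r:] = g[:r]
    return rfft(bank, axis=1), P


@lru_cache(maxsize=64)
def _gauss_kernel_bank_fft32(n: int, scales_key: tuple, dt: float) -> tuple:
    bank, P = _gauss_kernel_bank_fft(n, scales_key, dt)
    return bank.astype(np.complex64), P


def _smooth_time(Z: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Convolve along time (last axis) with per-scale Gaussians (sd = scale).

    ``Z`` is (..., n_scales, n_times); zero boundary handling.
    """
    n = Z.shape[-1]
    single = Z.dtype in (np.float32, np.complex64)
    maker = _gauss_kernel_bank_fft32 if single else _gauss_kernel_bank_fft
    bank_fft, P = maker(n, tuple(scales.tolist()), dt)

    def conv(real):
        return irfft(rfft(real, P, axis=-1) * bank_fft, P, axis=-1)[..., :n]

    if np.iscomplexobj(Z):
        return conv(Z.real) + 1j * conv(Z.imag)
    return conv(Z)


def _scale_boxcar(width_bins: float) -> np.ndarray:
    """Symmetric odd-length boxcar of total (fractional) width in scale bins."""
    w = max(1.0, width_bins)
    m = int(np.ceil((w - 1) / 2))
    kernel = np.ones(2 * m + 1)
    if m > 0:
        kernel[0] = kernel[-1] = (w - (2 * m - 1)) / 2
    return kernel / kernel.sum()


def _smooth_scale(Z: np.ndarray, params: WtcParams) -> np.ndarray:
    """Fractional boxcar across scales (axis -2), edge-renormalized."""
    kernel = _scale_boxcar(params.scale_smooth_octaves / params.dj)
    m = (len(kernel) - 1) // 2
    S = Z.shape[-2]
    num = np.zeros_like(Z)
    for j, kj in enumerate(kernel):
        off = j - m
        lo_dst, hi_dst = max(0, -off), min(S, S - off)
        lo_src, hi_src = max(0, off), min(S, S + off)
        src = Z[..., lo_src:hi_src, :]
        dst = num[..., lo_dst:hi_dst, :]
        if kj == 1.0:
            dst += src
        else:
            dst += kj * src
    den = np.convolve(np.ones(S), kernel, mode="same").astype(Z.real.dtype)
    num /= den[:, None]
    return num


def smooth(Z: np.ndarray, scales: np.ndarray, dt: float, params: WtcParams) -> np.ndarray:
    """The WTC smoothing operator S: Gaussian in time then boxcar in scale."""
    return _smooth_scale(_smooth_time(Z, scales, dt), params)


# ---------------------------------------------------------------------------
# wavelet coherence


@dataclass
class WtcMatrix:
    r2: np.ndarray              # (n_scales, n_times) in [0, 1]
    scales: np.ndarray
    fourier_periods: np.ndarray
    coi: np.ndarray
    dt: float
    params: WtcParams


def _smoothed_power(W: np.ndarray, scales: np.ndarray, dt: float, params: WtcParams):
    return smooth((np.abs(W) ** 2) / scales[:, None], scales, dt, params)


def wtc_from_cwt(
    Wx: CwtResult, Wy: CwtResult, Sxx: np.ndarray | None = None, Syy: np.ndarray | None = None
) -> WtcMatrix:
    """Coherence from two precomputed transforms on the same grid."""
    if Wx.coefficients.shape != Wy.coefficients.shape:
        raise ValueError("transforms are not on a common grid")
    p = Wx.params
    s, dt = Wx.scales, Wx.dt
    if Sxx is None:
        Sxx = _smoothed_power(Wx.coefficients, s, dt, p)
    if Syy is None:
        Syy = _smoothed_power(Wy.coefficients, s, dt, p)
    Sxy = smooth(Wx.coefficients * np.conj(Wy.coefficients) / s[:, None], s, dt, p)
    r2 = np.abs(Sxy) ** 2 / (Sxx * Syy)
    np.clip(r2, 0.0, 1.0, out=r2)
    return WtcMatrix(r2, s, Wx.fourier_periods, Wx.coi, dt, p)


def wtc(
    x: np.ndarray, y: np.ndarray, fs_hz: float, params: WtcParams | None = None
) -> WtcMatrix:
    """Wavelet-transform coherence of two equal-length series."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    params = params or WtcParams()
    Wx = cwt_morlet(x, fs_hz, params)
    Wy = cwt_morlet(y, fs_hz, params)
    return wtc_from_cwt(Wx, Wy)


DEFAULT_BAND_HZ = (0.05, 0.16)


def band_average(
    w: WtcMatrix,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    segments: list[tuple[float, float]] | None = None,
    exclude_coi: bool = True,
) -> tuple[float, int]:
    """Mean coherence over the period band and time segments.

    Periods are selected in ``[1/high, 1/low]`` s; times inside ``segments``
    (whole series when None); points under the cone of influence are dropped
    when ``exclude_coi``.  Returns (mean, number of averaged points).
    """
    lo, hi = band_hz
    pmask = (w.fourier_periods >= 1.0 / hi) & (w.fourier_periods <= 1.0 / lo)
    if not pmask.any():
        raise EmptySelectionError(f"no scales with period in [{1 / hi:.3g}, {1 / lo:.3g}] s")
    n = w.r2.shape[1]
    if segments is None:
        tmask = np.ones(n, bool)
    else:
        tmask = np.zeros(n, bool)
        t = np.arange(n) * w.dt
        for a, b in segments:
            tmask |= (t >= a) & (t < b)
    sel = np.outer(pmask, tmask)
    if exclude_coi:
        sel &= w.fourier_periods[:, None] <= w.coi[None, :]
    k = int(sel.sum())
    if k == 0:
        raise EmptySelectionError("band/segment/COI selection is empty")
    return float(w.r2[sel].mean()), k


# ---------------------------------------------------------------------------
# per-segment transform cache and the condition-level coherence table

CLAMP_EPS = 1e-6

#: Scale grid used by the segment-wise pipeline: dropping periods far outside
#: the analysis band leaves band averages unchanged but speeds things up.
PIPELINE_PARAMS = WtcParams(min_period_s=3.0, max_period_s=40.0)


class SegmentCwtCache:
    """Per-channel wavelet transforms of one subject, batched by segment length.

    Pseudo-dyad permutation re-uses each subject's transforms across all of
    its pairings; only the smoothed cross-spectrum depends on the pair.
    Segments of equal length share one scale grid and go through the FFTs as
    a single batch.
    """

    def __init__(
        self,
        hb: HbSeries,
        schedule: SessionSchedule,
        chromophore: str = "HbR",
        params: WtcParams = PIPELINE_PARAMS,
    ):
        self.hb = hb
        self.schedule = schedule
        self.chromophore = chromophore
        self.params = params
        # group segment indices by sample count
        groups: dict[int, list[int]] = {}
        fs = schedule.fs_hz
        for i, seg in enumerate(schedule.segments):
            sl = segment_slice(seg, fs)
            groups.setdefault(sl.stop - sl.start, []).append(i)
        self.groups = groups
        self._store: dict[tuple[int, int], tuple] = {}  # (channel, n) -> (W, auto)
        self._grid: dict[int, tuple] = {}               # n -> (scales, periods, coi)

    def grid(self, n: int) -> tuple:
        if n not in self._grid:
            dt = 1.0 / self.schedule.fs_hz
            scales = _scale_grid(n, dt, self.params)
            periods = self.params.fourier_factor * scales
            dist = np.minimum(np.arange(n), np.arange(n)[::-1]) * dt
            coi = self.params.fourier_factor * dist / np.sqrt(2.0)
            self._grid[n] = (scales, periods, coi)
        return self._grid[n]

    def batch(self, channel: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(W, smoothed auto power), each (n_segments_of_length_n, S, n)."""
        key = (channel, n)
        if key not in self._store:
            fs = self.schedule.fs_hz
            x = self.hb.chromophore(self.chromophore)[channel - 1]
            X = np.stack(
                [x[segment_slice(self.schedule.segments[i], fs)] for i in self.groups[n]]
            )
            W, scales, _, _ = _cwt_batch(X, fs, self.params)
            auto = smooth(
                (np.abs(W) ** 2) / scales[:, None], scales, 1.0 / fs, self.params
            )
            # single precision is ample for band-averaged coherence and
            # halves both memory and smoothing cost across pairings
            self._store[key] = (W.astype(np.complex64), auto.astype(np.float32))
        return self._store[key]

    def drop_channel(self, channel: int) -> None:
        """Free cached transforms of one channel (memory control)."""
        for key in [k for k in self._store if k[0] == channel]:
            del self._store[key]


@lru_cache(maxsize=256)
def _band_mask(periods_key: tuple, coi_key: tuple, band: tuple, exclude_coi: bool):
    periods = np.array(periods_key)
    coi = np.array(coi_key)
    lo, hi = band
    pmask = (periods >= 1.0 / hi) & (periods <= 1.0 / lo)
    sel = np.repeat(pmask[:, None], len(coi), axis=1)
    if exclude_coi:
        sel &= periods[:, None] <= coi[None, :]
    return sel, int(sel.sum())


def _pair_group_values(
    cacheA: SegmentCwtCache,
    cacheB: SegmentCwtCache,
    channel: int,
    n: int,
    band_hz: tuple[float, float],
    exclude_coi: bool,
) -> tuple[np.ndarray, int]:
    """Per-segment band-averaged coherence for one equal-length group."""
    Wx, Sxx = cacheA.batch(channel, n)
    Wy, Syy = cacheB.batch(channel, n)
    scales, periods, coi = cacheA.grid(n)
    p = cacheA.params
    dt = 1.0 / cacheA.schedule.fs_hz
    inv_s = (1.0 / scales)[:, None].astype(Wx.real.dtype)
    Sxy = smooth(Wx * np.conj(Wy) * inv_s, scales, dt, p)
    r2 = np.abs(Sxy) ** 2 / (Sxx * Syy)
    np.clip(r2, 0.0, 1.0, out=r2)
    sel, count = _band_mask(
        tuple(periods.tolist()), tuple(coi.tolist()), band_hz, exclude_coi
    )
    if count == 0:
        raise EmptySelectionError("band/COI selection is empty for a segment group")
    vals = np.tensordot(r2, sel.astype(r2.dtype), axes=([1, 2], [0, 1])) / count
    return vals.astype(float), count


def validate_parts(schedule: SessionSchedule, min_part_s: float) -> None:
    for cond in CONDITIONS:
        for seg in schedule.task_segments(cond):
            if seg.duration_s < min_part_s:
                raise ValidationError(
                    f"condition {cond} part of {seg.duration_s:.1f} s is shorter "
                    f"than the required {min_part_s:.0f} s"
                )


def channel_condition_values(
    cacheA: SegmentCwtCache,
    cacheB: SegmentCwtCache,
    channel: int,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    exclude_coi: bool = True,
) -> list[tuple[str, float, int]]:
    """(condition, band value, n_points) for one channel of one pairing.

    Task conditions average their two block values; rest segments are pooled
    with point-count weights into the Rest pseudo-condition.
    """
    schedule = cacheA.schedule
    # band value + point count per segment index, computed group-batched
    seg_vals: dict[int, tuple[float, int]] = {}
    for n, indices in cacheA.groups.items():
        vals, count = _pair_group_values(cacheA, cacheB, channel, n, band_hz, exclude_coi)
        for i, v in zip(indices, vals):
            seg_vals[i] = (float(v), count)

    out = []
    for cond in CONDITIONS:
        vals = [
            seg_vals[i]
            for i, seg in enumerate(schedule.segments)
            if seg.kind == "task" and seg.condition == cond
        ]
        out.append(
            (cond, float(np.mean([v for v, _ in vals])), int(np.sum([k for _, k in vals])))
        )
    rest = [
        seg_vals[i] for i, seg in enumerate(schedule.segments) if seg.kind == "rest"
    ]
    rv = np.array([v for v, _ in rest])
    rn = np.array([k for _, k in rest])
    out.append(("Rest", float(np.average(rv, weights=rn)), int(rn.sum())))
    return out


def condition_coherence(
    hbA: HbSeries,
    hbB: HbSeries,
    schedule: SessionSchedule,
    chromophore: str = "HbR",
    *,
    dyad_id: str = "dyad",
    params: WtcParams = PIPELINE_PARAMS,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    exclude_coi: bool = True,
    min_part_s: float = 120.0,
    caches: tuple[SegmentCwtCache, SegmentCwtCache] | None = None,
) -> pd.DataFrame:
    """Band-averaged coherence per condition and channel for one (pseudo-)dyad.

    Each condition's two trial blocks are processed separately and the two
    block values averaged; all resting phases are band-averaged and pooled
    (point-count weighted) into a single Rest value.  Emits 5 x n_channels
    rows with columns (dyad, condition, channel, roi, chromophore,
    wtc_value, n_points); values are clamped to (eps, 1-eps).
    """
    if caches is None:
        cacheA = SegmentCwtCache(hbA, schedule, chromophore, params)
        cacheB = SegmentCwtCache(hbB, schedule, chromophore, params)
    else:
        cacheA, cacheB = caches
    validate_parts(schedule, min_part_s)

    montage = hbA.montage if hbA.montage is not None else hbB.montage
    rows = []
    for ch in montage.channels:
        for cond, v, k in channel_condition_values(
            cacheA, cacheB, ch.index, band_hz, exclude_coi
        ):
            rows.append((dyad_id, cond, ch.index, ch.roi, chromophore, v, k))

    df = pd.DataFrame(
        rows, columns=["dyad", "condition", "channel", "roi", "chromophore",
                       "wtc_value", "n_points"]
    )
    df["wtc_value"] = df["wtc_value"].clip(CLAMP_EPS, 1 - CLAMP_EPS)
    return df


def coherence_by_period(
    hbA: HbSeries,
    hbB: HbSeries,
    schedule: SessionSchedule,
    chromophore: str = "HbR",
    params: WtcParams = PIPELINE_PARAMS,
    exclude_coi: bool = True,
) -> pd.DataFrame:
    """Grand-average coherence as a function of Fourier period per condition.

    Used for the coherence-over-period report figure; averages r2 over time
    (per condition's task segments, and over rests for Rest) at every scale.
    """
    fs = schedule.fs_hz
    recs = []
    groups = {c: schedule.task_segments(c) for c in CONDITIONS}
    groups["Rest"] = schedule.rest_segments
    montage = hbA.montage
    for cond, segs in groups.items():
        acc: dict[float, list[float]] = {}
        for seg in segs:
            sl = segment_slice(seg, fs)
            for ch in montage.channels:
                x = hbA.chromophore(chromophore)[ch.index - 1, sl]
                y = hbB.chromophore(chromophore)[ch.index - 1, sl]
                m = wtc(x, y, fs, params)
                valid = (
                    m.fourier_periods[:, None] <= m.coi[None, :]
                    if exclude_coi
                    else np.ones_like(m.r2, bool)
                )
                with np.errstate(invalid="ignore"):
                    mean_per_scale = np.where(
                        valid.any(axis=1),
                        (m.r2 * valid).sum(axis=1) / np.maximum(valid.sum(axis=1), 1),
                        np.nan,
                    )
                for p, v in zip(m.fourier_periods, mean_per_scale):
                    if np.isfinite(v):
                        acc.setdefault(round(float(p), 6), []).append(float(v))
        for p, vs in sorted(acc.items()):
            recs.append((cond, p, float(np.mean(vs))))
    return pd.DataFrame(recs, columns=["condition", "period_s", "coherence"])
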