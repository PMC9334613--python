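"""Forward simulation of raw dyadic fNIRS recordings with controllable coupling.

Each subject's per-channel hemodynamics are built from

* an independent band-limited (default 0.05-0.16 Hz) Gaussian-process
  component, plus a *shared* band-limited component common to both subjects
  of a dyad, mixed with a time-varying weight ``w(t) = kappa(cond) * g(cond,
  roi)`` so that the expected inter-brain coherence in the analysis band is
  controlled per condition and region;
* physiological nuisance: cardiac (~1.1 Hz) and respiratory (~0.25 Hz)
  oscillations, an *independent-per-subject* Mayer wave (~0.1 Hz, so
  physiological noise cannot masquerade as coupling), 1/f drift and white
  noise.

HbR is generated with negative polarity relative to HbO.  Concentrations are
pushed through the Beer-Lambert forward model and exponentiated to strictly
positive intensities at 760/850 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .mbll import DEFAULT_EXTINCTION_TABLE, WAVELENGTHS_NM, hb_to_od
from .montage import Montage, ROIS
from .schedule import SessionSchedule, segment_slice


@dataclass
class CouplingSpec:
    """Condition- and ROI-dependent inter-brain coupling strengths.

    ``kappa`` maps each condition (plus ``"Rest"``) to the *shared-variance
    fraction* of the band-limited hemodynamic component, in [0, 1]: the
    expected inter-subject correlation of the band signal is ~kappa (mixing
    weight sqrt(kappa)), so band coherence rises as ~kappa^2 and the
    coupling grid is resolvable at realistic replicate counts.  kappa = 0
    means no coupling; kappa = 1 makes the partners' band components
    identical.  ``roi_gain`` maps ``(condition, roi)`` to a multiplicative
    gain on the fraction (missing entries default to 1).  Defaults encode
    the qualitative pattern the analysis is designed to detect: coupling
    during Free Play exceeds the prediction conditions, rest coupling is
    weaker than task coupling, the Control condition is uncoupled, and the
    right TPJ gain is maximal during Free Play.
    """

    kappa: dict[str, float] = field(
        default_factory=lambda: {
            "FreePlay": 0.70,
            "PredictionDifferent": 0.55,
            "PredictionSame": 0.55,
            "Control": 0.0,
            "Rest": 0.30,
        }
    )
    roi_gain: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("FreePlay", "rTPJ"): 1.3}
    )
    band_hz: tuple[float, float] = (0.05, 0.16)
    seed: int = 0

    def validate(self, fs_hz: float) -> None:
        for c, k in self.kappa.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kappa[{c!r}]={k} outside [0, 1]")
        lo, hi = self.band_hz
        if not 0.0 < lo < hi:
            raise ValueError("coupling band must satisfy 0 < low < high")
        if hi >= fs_hz / 2:
            raise ValueError(
                f"coupling band high edge {hi} Hz is at/above Nyquist ({fs_hz / 2} Hz)"
            )

    def weight(self, condition: str, roi: str) -> float:
        """Mixing weight of the shared component: sqrt(variance fraction)."""
        g = self.roi_gain.get((condition, roi), 1.0)
        frac = float(np.clip(self.kappa.get(condition, 0.0) * g, 0.0, 1.0))
        return float(np.sqrt(frac))


@dataclass
class NoiseSpec:
    """Amplitudes (uM) of the physiological and instrumental components."""

    hb_amp: float = 0.40          # band-limited hemodynamic signal
    cardiac_amp: float = 0.15
    cardiac_hz: float = 1.1
    resp_amp: float = 0.10
    resp_hz: float = 0.25
    mayer_amp: float = 0.12
    mayer_band_hz: tuple[float, float] = (0.08, 0.12)
    drift_amp: float = 0.20
    white_amp: float = 0.03
    hbr_ratio: float = -1.0 / 3.0  # HbR polarity/scale relative to HbO
    hbr_white_amp: float = 0.01

    @classmethod
    def silent(cls) -> "NoiseSpec":
        """All nuisance components off (pure coupled/uncoupled signal)."""
        return cls(
            cardiac_amp=0.0, resp_amp=0.0, mayer_amp=0.0,
            drift_amp=0.0, white_amp=0.0, hbr_white_amp=0.0,
        )


@dataclass
class Event:
    onset_s: float
    duration_s: float
    label: str


@dataclass
class RawRecording:
    """Per-subject two-wavelength intensity time series on a montage."""

    subject_id: str
    montage: Montage
    intensity: np.ndarray         # (n_channels, n_wavelengths, n_time), > 0
    fs_hz: float
    events: list[Event] = field(default_factory=list)
    wavelengths_nm: tuple[int, ...] = WAVELENGTHS_NM
    truth: dict | None = None     # simulator ground truth (hbo/hbr arrays)

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_times(self) -> int:
        return self.intensity.shape[2]

    def validate(self) -> None:
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (channels, wavelengths, time)")
        if self.intensity.shape[1] != len(self.wavelengths_nm):
            raise ValueError("one intensity row per wavelength required")
        if not np.all(self.intensity > 0):
            raise ValueError("intensities must be strictly positive")


@lru_cache(maxsize=32)
def _butter_sos(order, lo, hi, fs):
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _bandlimited_noise(rng, n, fs, band, order=4):
    sos = _butter_sos(order, band[0], band[1], fs)
    pad = int(fs * 30)
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))
    x = x[pad: pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_drift(rng, n, fs):
    # spectral shaping ~ 1/f with a low-frequency floor
    m = next_fast_len(n)
    white = rng.standard_normal(m)
    spec = rfft(white)
    f = rfftfreq(m, d=1.0 / fs)
    x = irfft(spec / np.sqrt(f + 0.01), m)[:n]
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillation(rng, n, fs, f0, jitter=0.03):
    # narrowband oscillation with slow random phase drift
    dphi = 2 * np.pi * f0 / fs + jitter * rng.standard_normal(n) / np.sqrt(fs)
    return np.sin(np.cumsum(dphi) + rng.uniform(0, 2 * np.pi))


def coupling_weights(
    montage: Montage, schedule: SessionSchedule, coupling: CouplingSpec
) -> np.ndarray:
    """Per-(ROI, time) mixing weight w(t) implied by schedule and coupling."""
    n = schedule.n_samples
    w = np.zeros((len(ROIS), n))
    for seg in schedule.segments:
        cond = "Rest" if seg.kind == "rest" else seg.condition
        sl = segment_slice(seg, schedule.fs_hz)
        for i, roi in enumerate(ROIS):
            w[i, sl] = coupling.weight(cond, roi)
    return w


def simulate_dyad(
    montage: Montage,
    schedule: SessionSchedule,
    coupling: CouplingSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> tuple[RawRecording, RawRecording]:
    """Simulate one dyad's pair of raw recordings; reproducible from ``seed``."""
    coupling = CouplingSpec() if coupling is None else coupling
    noise = NoiseSpec() if noise is None else noise
    fs = schedule.fs_hz
    coupling.validate(fs)

    n = schedule.n_samples
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, coupling.seed & 0x7FFFFFFF])

    # shared band-limited component, one per ROI, common to both subjects
    shared = {roi: _bandlimited_noise(rng, n, fs, coupling.band_hz) for roi in ROIS}
    w_roi = coupling_weights(montage, schedule, coupling)
    roi_idx = {roi: i for i, roi in enumerate(ROIS)}

    events = [
        Event(seg.start_s, seg.duration_s, f"{seg.kind}:{seg.condition}"
              + (f":{seg.block}" if seg.block else ""))
        for seg in schedule.segments
    ]

    recs = []
    for subj in (1, 2):
        hbo = np.empty((montage.n_channels, n))
        hbr = np.empty_like(hbo)
        cardiac = _oscillation(rng, n, fs, noise.cardiac_hz)
        resp = _oscillation(rng, n, fs, noise.resp_hz)
        mayer = (
            _bandlimited_noise(rng, n, fs, noise.mayer_band_hz)
            if noise.mayer_amp > 0 else np.zeros(n)
        )
        for k, ch in enumerate(montage.channels):
            w = w_roi[roi_idx[ch.roi]]
            indep = _bandlimited_noise(rng, n, fs, coupling.band_hz)
            sig = noise.hb_amp * (np.sqrt(1.0 - w**2) * indep + w * shared[ch.roi])
            nuis = (
                noise.cardiac_amp * cardiac * (1 + 0.05 * rng.standard_normal())
                + noise.resp_amp * resp * (1 + 0.05 * rng.standard_normal())
                + noise.mayer_amp * mayer
                + (noise.drift_amp * _pink_drift(rng, n, fs) if noise.drift_amp > 0 else 0.0)
                + (noise.white_amp * rng.standard_normal(n) if noise.white_amp > 0 else 0.0)
            )
            o = sig + nuis
            r = noise.hbr_ratio * o
            if noise.hbr_white_amp > 0:
                r = r + noise.hbr_white_amp * rng.standard_normal(n)
            hbo[k] = o - o.mean()
            hbr[k] = r - r.mean()

        od = hb_to_od(hbo, hbr, table_id=DEFAULT_EXTINCTION_TABLE)
        base = rng.uniform(0.5, 2.0, size=(montage.n_channels, od.shape[1]))
        intensity = base[..., None] * np.exp(-od)
        rec = RawRecording(
            subject_id=f"S{subj}",
            montage=montage,
            intensity=intensity,
            fs_hz=fs,
            events=list(events),
            truth={"hbo": hbo, "hbr": hbr, "coupling": coupling, "seed": seed},
        )
        rec.validate()
        recs.append(rec)
    return recs[0], recs[1]


@dataclass
class ArtifactLog:
    spikes: list[tuple[float, float]]   # (onset_s, duration_s)
    shifts: list[float]                 # onset_s of each baseline shift


def inject_motion(
    recording: RawRecording,
    n_spikes: int = 0,
    n_shifts: int = 0,
    seed: int = 0,
    *,
    spike_od: float = 0.3,
    shift_od: float = 0.15,
) -> tuple[RawRecording, ArtifactLog]:
    """Add motion artifacts (OD-domain spikes and baseline shifts) to a copy.

    Returns the corrupted recording and a log of the true artifact times so
    that correction routines can be scored against ground truth.
    """
    if n_spikes < 0 or n_shifts < 0:
        raise ValueError("artifact counts must be >= 0")
    rng = np.random.default_rng(seed)
    n = recording.n_times
    fs = recording.fs_hz
    od_extra = np.zeros(n)
    log = ArtifactLog([], [])
    margin = int(5 * fs)
    for _ in range(n_spikes):
        t0 = int(rng.integers(margin, n - margin))
        dur = rng.uniform(0.5, 1.5)
        width = max(2, int(dur * fs))
        tt = np.arange(n)
        prof = np.exp(-0.5 * ((tt - t0) / (width / 4)) ** 2)
        od_extra += spike_od * rng.choice([-1.0, 1.0]) * prof
        log.spikes.append((t0 / fs, dur))
    for _ in range(n_shifts):
        t0 = int(rng.integers(margin, n - margin))
        od_extra[t0:] += shift_od * rng.choice([-1.0, 1.0])
        log.shifts.append(t0 / fs)

    intensity = recording.intensity * np.exp(-od_extra)[None, None, :]
    out = replace(recording, intensity=intensity)
    return out, log
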