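"""Sentence-level voice quality features.

The vocal feature vector summarizes a read sentence (two repeated
utterances, averaged): pitch location and spread statistics from a
pitch track, plus harmonic-to-noise ratio (HNR), cepstral peak
prominence (CPP) and 12 mel-frequency cepstral coefficients (MFCC)
from windowed audio frames.  The reference analysis window is 2**11
samples at 44.1 kHz, i.e. 46.4 ms.

HNR follows the autocorrelation definition: with r the normalized
autocorrelation at the pitch lag, HNR = 10*log10(r/(1-r)) dB, capped to
[-60, +60].  CPP is the height of the cepstral peak in the 60-500 Hz
pitch band above a straight line regressed on the cepstrum.  Both are
standard published definitions; the constants live in module-level
defaults and can be overridden per call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.fft import dct, irfft, rfft

log = logging.getLogger(__name__)

REFERENCE_SAMPLE_RATE = 44100.0
REFERENCE_FRAME_SAMPLES = 2 ** 11
HNR_CAP_DB = 60.0
CPP_PITCH_BAND_HZ = (60.0, 500.0)
CPP_TREND_START_S = 1e-3
N_MEL_FILTERS = 26
N_MFCC = 12


class SilentFrameError(ValueError):
    """The audio frame carries no energy."""


@dataclass(frozen=True)
class AudioFrame:
    """One analysis window of mono audio."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("frame must be a non-empty 1-D array")

    def is_silent(self) -> bool:
        return not np.any(self.samples)


@dataclass(frozen=True)
class PitchTrack:
    """Frame times (s), f0 estimates (Hz) and voicing flags."""

    times: np.ndarray
    f0: np.ndarray
    voiced: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f0, dtype=float)
        v = np.asarray(self.voiced, dtype=bool)
        if not (t.shape == f.shape == v.shape):
            raise ValueError("times, f0 and voiced must have equal length")
        if np.any(f[v] <= 0):
            raise ValueError("voiced frames must have positive f0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "f0", f)
        object.__setattr__(self, "voiced", v)


class PitchSummary(NamedTuple):
    sF0: float
    sFCV: float
    sF10: float
    sF50: float
    sF90: float
    sFHL: float
    sDT: float


def window_duration(sample_rate: float, n_samples: int) -> float:
    """Window duration in milliseconds for ``n_samples`` at ``sample_rate``."""
    if sample_rate <= 0 or n_samples <= 0:
        raise ValueError("sample rate and sample count must be positive")
    return n_samples / sample_rate * 1000.0


def pitch_summary(track: PitchTrack) -> PitchSummary:
    """Location/spread statistics of the voiced pitch distribution.

    sF0 is the mean voiced f0; sFCV the coefficient of variation
    (SD/mean, sample SD); sF10/sF50/sF90 the linearly interpolated
    percentiles; sFHL = (sF90-sF50)/(sF50-sF10), a skew measure of the
    pitch distribution (NaN when the lower half-spread vanishes); sDT
    the span from first to last voiced frame in seconds.
    """
    v = track.voiced
    if not np.any(v):
        raise ValueError("pitch track has no voiced frames")
    f = track.f0[v]
    t = track.times[v]
    mean = float(np.mean(f))
    # exact zero for a constant track (no floating-point residue)
    if f.size == 1 or np.ptp(f) == 0.0:
        sd = 0.0
    else:
        sd = float(np.std(f, ddof=1))
    p10, p50, p90 = (float(x) for x in np.percentile(f, [10, 50, 90]))
    lower = p50 - p10
    if lower == 0.0:
        log.warning("sF50 == sF10; sFHL undefined, set to NaN")
        fhl = float("nan")
    else:
        fhl = (p90 - p50) / lower
    return PitchSummary(mean, sd / mean, p10, p50, p90, fhl,
                        float(t[-1] - t[0]))


def _autocorr_at(x: np.ndarray, lag: int) -> float:
    a, b = x[:-lag] if lag else x, x[lag:]
    denom = math.sqrt(float(np.dot(a, a)) * float(np.dot(b, b)))
    if denom == 0.0:
        return 0.0
    return float(np.dot(a, b)) / denom


def harmonic_noise_ratio(frame: AudioFrame, f0: float) -> float:
    """Autocorrelation HNR in dB at the given fundamental frequency.

    The normalized autocorrelation is maximized over lags within 20% of
    the nominal pitch period (with parabolic peak refinement); for a
    harmonic signal of power Ph plus noise of power Pn the peak is
    r = Ph/(Ph+Pn), so 10*log10(r/(1-r)) recovers the energy ratio.
    """
    if frame.is_silent():
        raise SilentFrameError("cannot compute HNR of an all-zero frame")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    x = frame.samples - np.mean(frame.samples)
    period = frame.sample_rate / f0
    lo = max(1, int(math.floor(period * 0.8)))
    hi = min(frame.samples.size - 2, int(math.ceil(period * 1.2)))
    if hi < lo or frame.samples.size < 2 * period:
        raise ValueError("frame too short for the requested pitch period")
    lags = np.arange(lo, hi + 1)
    r = np.array([_autocorr_at(x, int(l)) for l in lags])
    k = int(np.argmax(r))
    r_peak = r[k]
    if 0 < k < r.size - 1:  # parabolic refinement of the peak value
        denom = r[k - 1] - 2 * r[k] + r[k + 1]
        if denom < 0:
            r_peak = r[k] - (r[k + 1] - r[k - 1]) ** 2 / (8 * denom)
    cap = 10 ** (HNR_CAP_DB / 10)
    if r_peak >= cap / (1 + cap):
        return HNR_CAP_DB
    if r_peak <= 1 / (1 + cap):
        return -HNR_CAP_DB
    return 10.0 * math.log10(r_peak / (1.0 - r_peak))


def cepstral_peak_prominence(
    frame: AudioFrame,
    pitch_band_hz: Tuple[float, float] = CPP_PITCH_BAND_HZ,
) -> float:
    """CPP in dB: cepstral peak in the pitch quefrency band minus the
    value, at the peak quefrency, of a line regressed on the cepstrum
    from 1 ms up to the band's upper quefrency."""
    if frame.is_silent():
        raise SilentFrameError("cannot compute CPP of an all-zero frame")
    x = frame.samples * np.hamming(frame.samples.size)
    spec = np.abs(rfft(x))
    # relative floor: keeps the log spectrum's dynamic range bounded
    # without letting an absolute constant dominate narrow-band frames
    logmag = 20.0 * np.log10(np.maximum(spec, spec.max() * 1e-8))
    ceps = irfft(logmag, n=frame.samples.size)
    q = np.arange(frame.samples.size) / frame.sample_rate
    q_lo, q_hi = 1.0 / pitch_band_hz[1], 1.0 / pitch_band_hz[0]
    band = (q >= q_lo) & (q <= q_hi)
    if not np.any(band):
        raise ValueError("frame too short for the pitch quefrency band")
    trend_sel = (q >= CPP_TREND_START_S) & (q <= q_hi)
    slope, intercept = np.polyfit(q[trend_sel], ceps[trend_sel], 1)
    k = np.flatnonzero(band)[int(np.argmax(ceps[band]))]
    return float(ceps[k] - (slope * q[k] + intercept))


def _mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, sample_rate: float) -> np.ndarray:
    edges = _mel_inv(np.linspace(_mel(0.0), _mel(sample_rate / 2.0), n_filters + 2))
    freqs = np.arange(n_fft // 2 + 1) * sample_rate / n_fft
    fb = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, mid, hi = edges[i], edges[i + 1], edges[i + 2]
        up = (freqs >= lo) & (freqs <= mid)
        down = (freqs > mid) & (freqs <= hi)
        if mid > lo:
            fb[i, up] = (freqs[up] - lo) / (mid - lo)
        if hi > mid:
            fb[i, down] = (hi - freqs[down]) / (hi - mid)
    return fb


def mfcc12(frame: AudioFrame, n_filters: int = N_MEL_FILTERS) -> np.ndarray:
    """Mel-frequency cepstral coefficients 1..12 (0th excluded).

    Hamming window, power spectrum, triangular mel filterbank over
    0..Nyquist, log energies, orthonormal DCT-II.  Dropping coefficient
    0 makes the vector invariant to overall gain.
    """
    if frame.is_silent():
        raise SilentFrameError("cannot compute MFCC of an all-zero frame")
    x = frame.samples * np.hamming(frame.samples.size)
    power = np.abs(rfft(x)) ** 2
    fb = _mel_filterbank(n_filters, frame.samples.size, frame.sample_rate)
    energies = fb @ power
    loge = np.log(np.maximum(energies, 1e-300))
    coeffs = dct(loge, type=2, norm="ortho")
    return np.asarray(coeffs[1:N_MFCC + 1], dtype=float)


@dataclass
class SentenceFeatures:
    """The 21-entry sentence feature vector: 9 scalars + 12 MFCC."""

    sF0: float
    sFCV: float
    sF10: float
    sF50: float
    sF90: float
    sFHL: float
    sDT: float
    sHNR: float
    sCPP: float
    mfcc: Tuple[float, ...] = field(default=tuple([float("nan")] * N_MFCC))

    def __post_init__(self):
        self.mfcc = tuple(float(v) for v in self.mfcc)
        if len(self.mfcc) != N_MFCC:
            raise ValueError(f"expected {N_MFCC} MFCC values, got {len(self.mfcc)}")

    @staticmethod
    def field_names() -> List[str]:
        return ["sF0", "sFCV", "sF10", "sF50", "sF90", "sFHL", "sDT",
                "sHNR", "sCPP"] + [f"sMFCC{i}" for i in range(1, N_MFCC + 1)]

    def to_array(self) -> np.ndarray:
        return np.array([self.sF0, self.sFCV, self.sF10, self.sF50, self.sF90,
                         self.sFHL, self.sDT, self.sHNR, self.sCPP, *self.mfcc])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "SentenceFeatures":
        a = list(map(float, a))
        return cls(*a[:9], mfcc=tuple(a[9:21]))


def utterance_features(
    track: PitchTrack,
    frames: Optional[Sequence[AudioFrame]] = None,
    frame_f0: Optional[Sequence[float]] = None,
) -> SentenceFeatures:
    """Features of a single utterance.

    Pitch statistics come from the track; HNR/CPP/MFCC are averaged
    over the supplied voiced frames (NaN when no frames are given, e.g.
    when only a pitch track is available).
    """
    ps = pitch_summary(track)
    if frames:
        if frame_f0 is None:
            frame_f0 = [ps.sF0] * len(frames)
        hnr = float(np.mean([harmonic_noise_ratio(fr, f0)
                             for fr, f0 in zip(frames, frame_f0)]))
        cpp = float(np.mean([cepstral_peak_prominence(fr) for fr in frames]))
        mf = tuple(np.mean([mfcc12(fr) for fr in frames], axis=0))
    else:
        hnr = cpp = float("nan")
        mf = tuple([float("nan")] * N_MFCC)
    return SentenceFeatures(*ps, hnr, cpp, mfcc=mf)


def sentence_features(
    utterance1: SentenceFeatures,
    utterance2: SentenceFeatures,
) -> Tuple[SentenceFeatures, List[str]]:
    """Average two repeated utterances field-wise.

    Where one utterance has a NaN field the other is used alone and the
    field name is returned in the flag list; both NaN leaves NaN
    (also flagged).
    """
    a1, a2 = utterance1.to_array(), utterance2.to_array()
    names = SentenceFeatures.field_names()
    out = np.empty_like(a1)
    flags: List[str] = []
    for i in range(a1.size):
        n1, n2 = math.isnan(a1[i]), math.isnan(a2[i])
        if n1 and n2:
            out[i] = float("nan")
            flags.append(names[i])
        elif n1 or n2:
            out[i] = a2[i] if n1 else a1[i]
            flags.append(names[i])
            log.warning("field %s NaN in one utterance; using the other", names[i])
        else:
            out[i] = 0.5 * (a1[i] + a2[i])
    return SentenceFeatures.from_array(out), flags
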