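"""Voice-source feature extraction.

Computes the fourteen features used as inversion inputs: F0, SPL, CPP,
HNR, SHR, the harmonic amplitude differences H1-H2 / H1-H4 / H1-H2k /
H1-H5k measured on the spectrum of the flow derivative, and the glottal
aerodynamic measures Qmean, Qamp, CQ, MFDR, MFAR.  Also provides the
z-score standardization applied to feature/parameter tables before
network training.

All extractors operate on a :class:`~voiceinv.source.SourceSignal` and
are deterministic for fixed input.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .source import AIR_DENSITY, SourceSignal

#: Canonical feature order (CSV columns, network inputs).
FEATURE_NAMES: Tuple[str, ...] = (
    "F0",
    "SPL",
    "CPP",
    "HNR",
    "SHR",
    "H1H2",
    "H1H4",
    "H1H2k",
    "H1H5k",
    "Qmean",
    "Qamp",
    "CQ",
    "MFDR",
    "MFAR",
)


class UnvoicedError(ValueError):
    """No detectable periodicity in the signal — voiced features undefined."""


@dataclass(frozen=True)
class VoiceFeatures:
    """The fourteen voice features of one analysis span.

    Units: F0 Hz; SPL dB re 20 uPa at 0.3 m; CPP/HNR and harmonic
    differences dB; SHR dimensionless in [0, 1]; Qmean L/s; Qamp L/s
    (peak-to-peak); CQ fraction of the cycle in [0, 1]; MFDR/MFAR L/s^2.
    """

    F0: float
    SPL: float
    CPP: float
    HNR: float
    SHR: float
    H1H2: float
    H1H4: float
    H1H2k: float
    H1H5k: float
    Qmean: float
    Qamp: float
    CQ: float
    MFDR: float
    MFAR: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "VoiceFeatures":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} values")
        return cls(**dict(zip(FEATURE_NAMES, values.tolist())))


def _frames(x: np.ndarray, frame: int, hop: int):
    n = (len(x) - frame) // hop + 1
    if n < 1:
        return np.empty((0, frame))
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def estimate_f0(
    signal: SourceSignal,
    search_band: Tuple[float, float] = (50.0, 600.0),
    *,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    voicing_threshold: float = 0.30,
) -> float:
    """Fundamental frequency by framewise normalized autocorrelation.

    40 ms frames, 10 ms hop; per frame the mean is removed, the biased
    autocorrelation is computed via FFT, and the highest peak inside the
    lag band is refined by parabolic interpolation.  The median over
    voiced frames is returned.

    Raises :class:`UnvoicedError` when no frame has a normalized
    autocorrelation peak above ``voicing_threshold`` inside the band.
    """
    fs = signal.sample_rate
    x = signal.flow
    frame = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    fmin, fmax = search_band
    lag_min = max(2, int(math.floor(fs / fmax)))
    lag_max = int(math.ceil(fs / fmin))
    if lag_max >= frame:
        raise ValueError("frame too short for the requested search band")
    fr = _frames(x, frame, hop)
    if fr.shape[0] == 0:
        fr = (x - np.mean(x))[None, :]
        frame = fr.shape[1]
        if lag_max >= frame:
            raise UnvoicedError("signal too short for F0 analysis")
    fr = fr - fr.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * frame)))
    spec = np.fft.rfft(fr, n=nfft, axis=1)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : lag_max + 2]
    # linear taper of the biased autocorrelation estimate; peak *selection*
    # stays on the (stable) biased values, but the parabolic refinement uses
    # locally unbiased values so it is not skewed toward smaller lags
    taper = np.maximum(1.0 - np.arange(lag_max + 2) / frame, 1.0 / frame)
    r0 = ac[:, 0]
    voiced_f0 = []
    for i in range(ac.shape[0]):
        if r0[i] <= 0:
            continue
        r = ac[i] / r0[i]
        seg = r[lag_min : lag_max + 1]
        best = float(np.max(seg))
        if best < voicing_threshold:
            continue
        # octave-error guard: among local maxima comparable to the global
        # peak, take the smallest lag (the true period, not a multiple)
        interior = seg[1:-1]
        is_peak = (interior >= seg[:-2]) & (interior >= seg[2:])
        cand = np.flatnonzero(is_peak & (interior >= 0.9 * best)) + 1
        k = int(cand[0]) if len(cand) else int(np.argmax(seg))
        lag = lag_min + k
        # parabolic refinement on the locally unbiased autocorrelation
        if 1 <= lag < len(r) - 1:
            ym, y0, yp = (r[lag - 1 : lag + 2] / taper[lag - 1 : lag + 2]).tolist()
            denom = ym - 2.0 * y0 + yp
            if denom < 0:
                lag = lag + 0.5 * (ym - yp) / denom
        voiced_f0.append(fs / lag)
    if not voiced_f0:
        raise UnvoicedError("no periodicity detected in search band")
    return float(np.median(voiced_f0))


def _peak_amplitude(
    mag: np.ndarray, freqs: np.ndarray, target: float, half_width: float
) -> float:
    """Max spectral magnitude within +/- half_width of target, with
    parabolic interpolation in dB for sub-bin accuracy."""
    lo = np.searchsorted(freqs, target - half_width)
    hi = np.searchsorted(freqs, target + half_width)
    hi = min(hi, len(mag))
    if hi - lo < 1:
        raise ValueError(f"no spectral bins near {target} Hz")
    k = lo + int(np.argmax(mag[lo:hi]))
    if 1 <= k < len(mag) - 1 and mag[k] > 0:
        db = 20.0 * np.log10(np.maximum(mag[k - 1 : k + 2], mag[k] * 1e-12))
        denom = db[0] - 2.0 * db[1] + db[2]
        if denom < 0:
            amp_db = db[1] - 0.25 * (db[0] - db[2]) ** 2 / denom / 2.0
            return float(10.0 ** (amp_db / 20.0))
    return float(mag[k])


def harmonic_differences(
    signal: SourceSignal, f0: float
) -> Tuple[float, float, float, float]:
    """H1-H2, H1-H4, H1-H2k, H1-H5k (dB) on the flow-derivative spectrum.

    Harmonic amplitudes are located by local peak search within +/- f0/4
    of the nominal frequency (k*f0 for k = 1, 2, 4; the harmonics nearest
    2 and 5 kHz).  Amplitudes indistinguishable from the spectral noise
    floor are clamped at the floor (with a warning).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    fs = signal.sample_rate
    if 5000.0 >= fs / 2:
        raise ValueError("H1-H5k requires sample_rate > 10 kHz")
    x = signal.derivative
    if len(x) < 10 * fs / f0:
        raise ValueError("need at least 10 periods for harmonic analysis")
    w = np.hanning(len(x))
    nfft = 1 << int(np.ceil(np.log2(len(x) * 4)))
    mag = np.abs(np.fft.rfft((x - np.mean(x)) * w, n=nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    floor = float(np.median(mag))

    def harm(k: int) -> float:
        a = _peak_amplitude(mag, freqs, k * f0, f0 / 4.0)
        if a <= floor:
            warnings.warn(
                f"harmonic {k} near noise floor; clamped", RuntimeWarning, stacklevel=3
            )
            return floor if floor > 0 else 1e-300
        return a

    h1 = harm(1)
    h2 = harm(2)
    h4 = harm(4)
    k2k = max(1, int(round(2000.0 / f0)))
    k5k = max(1, int(round(5000.0 / f0)))
    h2k = harm(k2k)
    h5k = harm(k5k)
    to_db = lambda a, b: 20.0 * math.log10(a / b)
    return (to_db(h1, h2), to_db(h1, h4), to_db(h1, h2k), to_db(h1, h5k))


def cpp(
    signal: SourceSignal,
    *,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    quefrency_band: Tuple[float, float] = (1.0 / 600.0, 1.0 / 50.0),
) -> float:
    """Cepstral peak prominence (dB), frame-averaged.

    Per 40 ms Hann frame: log-magnitude spectrum (dB) -> real cepstrum ->
    highest peak in the 1/600..1/50 s quefrency band, measured above a
    least-squares line fitted to the cepstrum over that band
    (Hillenbrand construction).  Invariant to amplitude scaling.
    """
    fs = signal.sample_rate
    x = signal.flow
    if len(x) < 0.1 * fs:
        raise ValueError("need at least 0.1 s of signal for CPP")
    frame = int(round(frame_s * fs))
    hop = int(round(hop_s * fs))
    fr = _frames(x, frame, hop)
    if fr.shape[0] == 0:
        raise ValueError("signal shorter than one analysis frame")
    fr = (fr - fr.mean(axis=1, keepdims=True)) * np.hanning(frame)
    nfft = 1 << int(np.ceil(np.log2(2 * frame)))
    mag = np.abs(np.fft.rfft(fr, n=nfft, axis=1))
    ref = np.max(mag, axis=1, keepdims=True)
    db = 20.0 * np.log10(np.maximum(mag, ref * 1e-12))
    ceps = np.fft.irfft(db, n=nfft, axis=1)
    q = np.arange(nfft // 2 + 1) / fs
    band = (q >= quefrency_band[0]) & (q <= quefrency_band[1])
    qb = q[band]
    cb = ceps[:, : nfft // 2 + 1][:, band]
    # least-squares line per frame over the quefrency band
    A = np.vstack([qb, np.ones_like(qb)]).T
    coef, *_ = np.linalg.lstsq(A, cb.T, rcond=None)
    trend = (A @ coef).T
    prominence = np.max(cb - trend, axis=1)
    return float(np.mean(prominence))


def hnr(signal: SourceSignal, f0: float, *, cap_db: float = 60.0) -> float:
    """Harmonic-to-noise ratio (dB) by period-synchronous averaging.

    The signal is chopped into integer-sample periods; the harmonic part
    is the tiled mean cycle, the noise part is the residual.  The power
    ratio is capped at ``cap_db``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    fs = signal.sample_rate
    period = int(round(fs / f0))
    if period < 2:
        raise ValueError("period below 2 samples")
    x = signal.flow
    k = len(x) // period
    if k < 2:
        raise UnvoicedError("need at least 2 complete periods for HNR")
    x = x[: k * period] - np.mean(x[: k * period])
    cycles = x.reshape(k, period)
    mean_cycle = cycles.mean(axis=0)
    residual = cycles - mean_cycle
    p_h = float(np.mean(mean_cycle**2))
    p_n = float(np.mean(residual**2))
    if p_n <= p_h * 10.0 ** (-cap_db / 10.0):
        return cap_db
    return min(cap_db, 10.0 * math.log10(p_h / p_n))


def shr(signal: SourceSignal, f0: Optional[float] = None, *, max_harmonics: int = 10) -> float:
    """Subharmonic-to-harmonic ratio in [0, 1].

    Sums spectral peak amplitudes at harmonics k*f0 and at the odd
    half-multiples (k - 1/2)*f0 (the subharmonics generated by
    period-two alternation) and returns their ratio, clamped to [0, 1].
    """
    if f0 is None:
        f0 = estimate_f0(signal)
    fs = signal.sample_rate
    x = signal.flow - np.mean(signal.flow)
    w = np.hanning(len(x))
    nfft = 1 << int(np.ceil(np.log2(len(x) * 4)))
    mag = np.abs(np.fft.rfft(x * w, n=nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    kmax = min(max_harmonics, int((fs / 2 - f0 / 4) / f0))
    if kmax < 1:
        raise ValueError("f0 too high for SHR analysis")
    a_h = sum(
        _peak_amplitude(mag, freqs, k * f0, f0 / 8.0) for k in range(1, kmax + 1)
    )
    a_s = sum(
        _peak_amplitude(mag, freqs, (k - 0.5) * f0, f0 / 8.0)
        for k in range(1, kmax + 1)
    )
    if a_h <= 0:
        return 0.0
    return float(np.clip(a_s / a_h, 0.0, 1.0))


def flow_pulse_metrics(
    signal: SourceSignal, f0: float, *, cq_threshold: float = 0.05
) -> Tuple[float, float, float, float, float]:
    """(Qmean, Qamp, CQ, MFDR, MFAR) of the glottal flow.

    Cycle-averaged over integer-sample periods: Qamp is the mean
    peak-to-peak amplitude, CQ the mean fraction of the period with flow
    within ``cq_threshold`` of the cycle minimum (relative to the cycle
    amplitude), MFDR/MFAR the mean steepest fall/rise of the flow
    (magnitudes, from the stored derivative).
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    fs = signal.sample_rate
    period = int(round(fs / f0))
    if period < 2:
        raise ValueError("period below 2 samples")
    k = len(signal.flow) // period
    if k < 1:
        raise ValueError("signal shorter than one period")
    x = signal.flow[: k * period].reshape(k, period)
    d = signal.derivative[: k * period].reshape(k, period)
    qmean = float(np.mean(signal.flow))
    cmax = x.max(axis=1)
    cmin = x.min(axis=1)
    amp = cmax - cmin
    qamp = float(np.mean(amp))
    thresh = cmin + cq_threshold * amp
    cq = float(np.mean(np.mean(x <= thresh[:, None], axis=1)))
    mfdr = float(np.mean(np.maximum((-d).max(axis=1), 0.0)))
    mfar = float(np.mean(np.maximum(d.max(axis=1), 0.0)))
    return qmean, qamp, cq, mfdr, mfar


def spl_from_source(signal: SourceSignal, distance: float = 0.3) -> float:
    """SPL (dB re 20 uPa) at ``distance`` via monopole radiation.

    Far-field pressure p(t) = rho_air * dU/dt / (4 pi r) with U in
    m^3/s; SPL = 20 log10(p_rms / 20 uPa).  Returns -inf for a constant
    flow (no radiated sound).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    du = signal.derivative_si()
    p = AIR_DENSITY * du / (4.0 * math.pi * distance)
    rms = float(np.sqrt(np.mean(p**2)))
    if rms <= 0:
        return float("-inf")
    return 20.0 * math.log10(rms / 20e-6)


def extract_features(
    signal: SourceSignal,
    *,
    search_band: Tuple[float, float] = (50.0, 600.0),
    spl_distance: float = 0.3,
) -> VoiceFeatures:
    """Extract all fourteen features from a glottal flow signal.

    Raises :class:`UnvoicedError` for aperiodic input (silence, noise).
    """
    f0 = estimate_f0(signal, search_band)
    h1h2, h1h4, h1h2k, h1h5k = harmonic_differences(signal, f0)
    qmean, qamp, cq, mfdr, mfar = flow_pulse_metrics(signal, f0)
    return VoiceFeatures(
        F0=f0,
        SPL=spl_from_source(signal, spl_distance),
        CPP=cpp(signal),
        HNR=hnr(signal, f0),
        SHR=shr(signal, f0),
        H1H2=h1h2,
        H1H4=h1h4,
        H1H2k=h1h2k,
        H1H5k=h1h5k,
        Qmean=qmean,
        Qamp=qamp,
        CQ=cq,
        MFDR=mfdr,
        MFAR=mfar,
    )


# ---------------------------------------------------------------------------
# z-score standardization


@dataclass
class ZScoreStats:
    """Per-column mean and sample (ddof=1) standard deviation."""

    names: Tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.names) == len(self.mean) == len(self.sd)):
            raise ValueError("names/mean/sd length mismatch")
        if np.any(self.sd <= 0):
            bad = [n for n, s in zip(self.names, self.sd) if s <= 0]
            raise ValueError(f"non-positive standard deviation for columns: {bad}")

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreStats":
        return cls(tuple(d["names"]), np.array(d["mean"]), np.array(d["sd"]))


def zscore_fit(table, names: Optional[Sequence[str]] = None) -> ZScoreStats:
    """Fit per-column z-score statistics on a DataFrame or 2-D array.

    Raises ValueError naming any zero-variance column.
    """
    import pandas as pd

    if isinstance(table, pd.DataFrame):
        names = tuple(table.columns)
        values = table.to_numpy(dtype=float)
    else:
        values = np.asarray(table, dtype=float)
        if names is None:
            names = tuple(f"col{i}" for i in range(values.shape[1]))
        names = tuple(names)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 rows")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = sd <= 0
    if np.any(zero):
        bad = [n for n, z in zip(names, zero) if z]
        raise ValueError(f"zero-variance columns: {bad}")
    return ZScoreStats(names, mean, sd)


def zscore_apply(stats: ZScoreStats, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return (values - stats.mean) / stats.sd


def zscore_invert(stats: ZScoreStats, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return values * stats.sd + stats.mean
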