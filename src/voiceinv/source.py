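"""Surrogate glottal-flow forward model.

Maps the nine physiological control parameters to glottal flow waveforms
(and to synthetic /pa/-utterance pressure/flow channels) with a kinematic
pulse model.  The surrogate is *not* a continuum-mechanics simulation: it
is an explicit, documented map chosen so that every extractable voice
feature responds plausibly and monotonically to the physiology —
subglottal pressure drives flow amplitude and loudness, the glottal angle
drives DC leakage and aspiration noise, fold length and stiffness set the
fundamental frequency via an ideal-string law.

All flow values are stored in L/s; internal aerodynamic computations are
in SI (m, m^3/s, Pa).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .params import ParamRanges, PhysioParams, RangeError

#: Vocal fold tissue density, kg/m^3.
TISSUE_DENSITY = 1040.0
#: Air density, kg/m^3.
AIR_DENSITY = 1.2

MIN_SAMPLE_RATE = 8000.0
MIN_DURATION = 0.2


def effective_stress(p: PhysioParams) -> float:
    """Effective tension (Pa) governing the string-law F0.

    Weighted combination of the cover, body and transverse stiffness
    moduli; the cover dominates since the mucosal wave carries most of
    the oscillation.
    """
    return 1000.0 * (
        p.cover_stiffness + 0.3 * p.body_stiffness + 0.2 * p.transverse_stiffness
    )


def f0_closed_form(p: PhysioParams) -> float:
    """Ideal-string fundamental frequency: F0 = (1/2L) sqrt(sigma_eff/rho)."""
    length_m = p.vf_length / 1000.0
    return (1.0 / (2.0 * length_m)) * math.sqrt(effective_stress(p) / TISSUE_DENSITY)


def open_quotient(p: PhysioParams) -> float:
    """Fraction of the cycle with non-zero flow; rises with abduction, thin folds."""
    oq = 0.35 + 0.02 * p.glottal_angle + 0.03 * (5.0 - p.vf_thickness)
    return float(np.clip(oq, 0.30, 0.95))


def speed_quotient(p: PhysioParams) -> float:
    """Rise/fall time ratio of the pulse; stiff body skews the pulse right."""
    sq = 1.5 + 0.1 * p.body_stiffness / p.cover_stiffness
    return float(np.clip(sq, 1.1, 4.0))


def bernoulli_velocity(ps_pa: float) -> float:
    """Glottal jet velocity (m/s) from the driving pressure."""
    return math.sqrt(2.0 * max(ps_pa, 0.0) / AIR_DENSITY)


def vibration_amplitude(p: PhysioParams) -> float:
    """Fold vibration amplitude (m): grows with pressure, shrinks with cover stiffness."""
    d = 1.5e-3 * (p.subglottal_pressure / 800.0) * (30.0 / p.cover_stiffness)
    return float(np.clip(d, 0.0, 3e-3))


def ac_flow_amplitude(p: PhysioParams) -> float:
    """Peak AC flow (m^3/s) of the glottal pulse."""
    length_m = p.vf_length / 1000.0
    return 0.3 * length_m * vibration_amplitude(p) * bernoulli_velocity(
        p.subglottal_pressure
    )


def dc_leak(p: PhysioParams) -> float:
    """DC flow (m^3/s) through the triangular posterior gap set by the glottal angle."""
    length_m = p.vf_length / 1000.0
    gap_area = 0.5 * length_m**2 * math.tan(max(p.glottal_angle, 0.0) * math.pi / 360.0)
    return gap_area * bernoulli_velocity(p.subglottal_pressure)


@dataclass
class SourceSignal:
    """A sampled glottal flow waveform with its time derivative.

    ``flow`` is volume velocity in the unit named by ``flow_unit``
    (default L/s); ``derivative`` is its time derivative (same unit per
    second), by central differences with one-sided endpoints.
    """

    flow: np.ndarray
    sample_rate: float
    derivative: np.ndarray
    duration: float
    flow_unit: str = "L/s"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        self.derivative = np.asarray(self.derivative, dtype=float)
        if self.flow.shape != self.derivative.shape:
            raise ValueError("flow and derivative must have equal length")
        if self.sample_rate < MIN_SAMPLE_RATE:
            raise ValueError(f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz")

    @classmethod
    def from_flow(
        cls, flow: np.ndarray, sample_rate: float, flow_unit: str = "L/s", meta=None
    ) -> "SourceSignal":
        flow = np.asarray(flow, dtype=float)
        deriv = np.gradient(flow, 1.0 / sample_rate)
        return cls(
            flow=flow,
            sample_rate=sample_rate,
            derivative=deriv,
            duration=len(flow) / sample_rate,
            flow_unit=flow_unit,
            meta=meta or {},
        )

    def flow_si(self) -> np.ndarray:
        """Flow in m^3/s regardless of stored unit."""
        if self.flow_unit == "m3/s":
            return self.flow
        return self.flow / 1000.0

    def derivative_si(self) -> np.ndarray:
        if self.flow_unit == "m3/s":
            return self.derivative
        return self.derivative / 1000.0


@dataclass
class UtteranceChannels:
    """Two-channel /pa/-utterance recording: intraoral pressure + oral flow."""

    intraoral_pressure: np.ndarray  # Pa
    oral_flow: np.ndarray  # L/s
    sample_rate: float
    #: ordered (kind in {"p","a"}, start s, end s)
    segment_labels: List[Tuple[str, float, float]]
    meta: dict = field(default_factory=dict)


@lru_cache(maxsize=8)
def _aspiration_sos(sample_rate: float):
    """Band-pass (500 Hz .. min(4 kHz, 0.45 fs)) shaping the aspiration noise."""
    high = min(4000.0, 0.45 * sample_rate)
    return sps.butter(4, [500.0, high], btype="bandpass", fs=sample_rate, output="sos")


def _cycle_table(
    param_at: Callable[[float], PhysioParams],
    duration: float,
    rng: np.random.Generator,
    jitter: float,
    shimmer: float,
):
    """Walk cycle-by-cycle through [0, duration), evaluating parameters at
    each cycle onset.  Returns per-cycle arrays (start, Tp, To, amp, dc)."""
    starts, tp_l, to_l, amp_l, dc_l = [], [], [], [], []
    t = 0.0
    while t < duration:
        p = param_at(t)
        f0 = f0_closed_form(p)
        period = (1.0 / f0) * (1.0 + jitter * rng.standard_normal())
        period = max(period, 0.25 / f0)
        oq, sq = open_quotient(p), speed_quotient(p)
        t_open = oq * period
        t_rise = t_open * sq / (1.0 + sq)
        amp = ac_flow_amplitude(p) * max(0.0, 1.0 + shimmer * rng.standard_normal())
        starts.append(t)
        tp_l.append(t_rise)
        to_l.append(t_open)
        amp_l.append(amp)
        dc_l.append(dc_leak(p))
        t += period
    return (
        np.array(starts),
        np.array(tp_l),
        np.array(to_l),
        np.array(amp_l),
        np.array(dc_l),
    )


def _render_flow(
    param_at: Callable[[float], PhysioParams],
    duration: float,
    sample_rate: float,
    rng: np.random.Generator,
    jitter: float,
    shimmer: float,
    aspiration: bool,
) -> np.ndarray:
    """Render the pulse train (m^3/s) on the sample grid."""
    n = int(round(duration * sample_rate))
    tgrid = np.arange(n) / sample_rate
    starts, tp, to, amp, dc = _cycle_table(param_at, duration, rng, jitter, shimmer)
    idx = np.clip(np.searchsorted(starts, tgrid, side="right") - 1, 0, len(starts) - 1)
    tau = tgrid - starts[idx]
    tpi, toi = tp[idx], to[idx]
    tni = toi - tpi
    # Rosenberg-type polynomial pulse: cubic rise, parabolic fall, closed phase.
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(tpi > 0, tau / np.where(tpi > 0, tpi, 1.0), 1.0)
        rise = 3.0 * u**2 - 2.0 * u**3
        w = np.where(tni > 0, (tau - tpi) / np.where(tni > 0, tni, 1.0), 1.0)
        fall = 1.0 - w**2
    g = np.where(tau < tpi, rise, np.where(tau < toi, fall, 0.0))
    flow = dc[idx] + amp[idx] * g
    if aspiration:
        dci = dc[idx]
        if np.any(dci > 0):
            noise = rng.standard_normal(n)
            noise = sps.sosfilt(_aspiration_sos(sample_rate), noise)
            rms = float(np.sqrt(np.mean(noise**2)))
            if rms > 0:
                flow = flow + noise / rms * (0.2 * dci)
    return flow


def synthesize_glottal_flow(
    params: PhysioParams,
    duration: float = 0.25,
    sample_rate: float = 16000.0,
    noise_seed: int = 0,
    *,
    ranges: ParamRanges | None = None,
    jitter: float = 0.005,
    shimmer: float = 0.02,
    aspiration: bool = True,
) -> SourceSignal:
    """Synthesize a steady glottal flow waveform for one parameter set.

    The waveform is a Rosenberg-type pulse train at the string-law F0,
    riding on the DC leakage flow, with optional per-cycle jitter/shimmer
    and band-limited aspiration noise whose RMS is 20% of the DC flow.
    Identical arguments give bitwise-identical output.

    Raises :class:`RangeError` when ``params`` falls outside ``ranges``
    (zero subglottal pressure is permitted and yields silence).
    """
    if duration < MIN_DURATION:
        raise ValueError(f"duration must be >= {MIN_DURATION} s, got {duration}")
    if sample_rate < MIN_SAMPLE_RATE:
        raise ValueError(f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz")
    (ranges or ParamRanges()).check(params)
    rng = np.random.default_rng(noise_seed)
    flow_si = _render_flow(
        lambda t: params, duration, sample_rate, rng, jitter, shimmer, aspiration
    )
    meta = {"params": params, "f0_nominal": f0_closed_form(params)}
    return SourceSignal.from_flow(flow_si * 1000.0, sample_rate, "L/s", meta)


ParamTrack = Sequence[Tuple[float, PhysioParams]]


def _track_interpolator(track: ParamTrack) -> Callable[[float], PhysioParams]:
    """Piecewise-linear interpolation of each parameter field over time."""
    if len(track) == 0:
        raise ValueError("params_track must be non-empty")
    times = np.array([t for t, _ in track], dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("params_track times must be non-decreasing")
    mat = np.array([p.to_array() for _, p in track])

    def at(t: float) -> PhysioParams:
        vals = [float(np.interp(t, times, mat[:, j])) for j in range(mat.shape[1])]
        return PhysioParams.from_array(vals)

    return at


def synthesize_timevarying_flow(
    params_track: ParamTrack,
    duration: float,
    sample_rate: float = 16000.0,
    seed: int = 0,
    *,
    jitter: float = 0.005,
    shimmer: float = 0.02,
    aspiration: bool = True,
) -> SourceSignal:
    """Voiced glottal flow whose physiology varies over time.

    Parameters are linearly interpolated between track anchors and
    re-evaluated at each glottal cycle onset.  Used to emulate gestures
    such as the adduction/abduction alternation of running speech while
    keeping phonation continuous.
    """
    if duration < MIN_DURATION:
        raise ValueError(f"duration must be >= {MIN_DURATION} s")
    at = _track_interpolator(params_track)
    rng = np.random.default_rng(seed)
    flow_si = _render_flow(at, duration, sample_rate, rng, jitter, shimmer, aspiration)
    return SourceSignal.from_flow(
        flow_si * 1000.0, sample_rate, "L/s", {"track": list(params_track)}
    )


def _raised_cosine_ramp(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, n)))


def synthesize_pa_utterance(
    params_track: ParamTrack,
    n_reps: int,
    sample_rate: float = 16000.0,
    seed: int = 0,
    *,
    p_dur: float = 0.12,
    vowel_dur: float = 0.25,
    ramp: float = 0.03,
) -> UtteranceChannels:
    """Synthesize a /papapa.../ utterance's aerodynamic channels.

    During each /p/ occlusion the intraoral pressure rises to the
    commanded subglottal pressure (the basis of the intraoral-pressure
    ground-truth protocol) and the oral flow is blocked except for a
    brief release transient; during each vowel the oral flow equals the
    glottal flow (no vocal tract) and the intraoral pressure falls to
    near zero.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (interpolation needs two plosive peaks)")
    at = _track_interpolator(params_track)
    rng = np.random.default_rng(seed)
    rep_dur = p_dur + vowel_dur
    total = n_reps * rep_dur
    n = int(round(total * sample_rate))
    pressure = np.zeros(n)
    flow = np.zeros(n)
    labels: List[Tuple[str, float, float]] = []
    n_ramp = max(2, int(round(ramp * sample_rate)))

    for k in range(n_reps):
        t_p0 = k * rep_dur
        t_v0 = t_p0 + p_dur
        t_v1 = t_v0 + vowel_dur
        labels.append(("p", t_p0, t_v0))
        labels.append(("a", t_v0, t_v1))
        i_p0, i_v0 = int(round(t_p0 * sample_rate)), int(round(t_v0 * sample_rate))
        i_v1 = min(int(round(t_v1 * sample_rate)), n)

        p_mid = at(t_p0 + 0.5 * p_dur)
        ps_cmd = p_mid.subglottal_pressure
        # intraoral pressure: ramp up, hold exactly at the commanded Ps, ramp down
        seg = np.full(i_v0 - i_p0, ps_cmd)
        seg[:n_ramp] = ps_cmd * _raised_cosine_ramp(n_ramp)
        seg[-n_ramp:] = ps_cmd * _raised_cosine_ramp(n_ramp)[::-1]
        pressure[i_p0:i_v0] = seg

        # oral flow: release transient at the /p/ release, then glottal flow
        v_mid = at(t_v0 + 0.5 * vowel_dur)
        vowel = synthesize_glottal_flow(
            v_mid,
            duration=max(vowel_dur, MIN_DURATION),
            sample_rate=sample_rate,
            noise_seed=int(rng.integers(0, 2**31 - 1)),
        ).flow[: i_v1 - i_v0]
        fade = _raised_cosine_ramp(min(n_ramp, len(vowel)))
        vowel[: len(fade)] *= fade
        flow[i_v0 : i_v0 + len(vowel)] = vowel
        n_rel = max(2, int(round(0.015 * sample_rate)))
        rel = (
            0.1
            * math.sqrt(ps_cmd / 800.0)
            * np.exp(-np.arange(n_rel) / (0.004 * sample_rate))
        )
        i_rel = max(i_v0 - n_rel, i_p0)
        flow[i_rel:i_v0] += rel[: i_v0 - i_rel]

    # small sensor noise on the pressure channel (well below peak-detection
    # prominence) so the channel is not pathologically flat
    pressure += 0.5 * rng.standard_normal(n)
    return UtteranceChannels(
        intraoral_pressure=pressure,
        oral_flow=flow,
        sample_rate=sample_rate,
        segment_labels=labels,
        meta={"n_reps": n_reps, "p_dur": p_dur, "vowel_dur": vowel_dur, "seed": seed},
    )


def vowel_flow_signals(channels: UtteranceChannels) -> List[SourceSignal]:
    """Slice the oral-flow channel into one SourceSignal per vowel segment.

    Without a vocal tract the oral flow during a vowel *is* the glottal
    flow, so these slices can go straight to feature extraction.
    """
    fs = channels.sample_rate
    out = []
    for kind, t0, t1 in channels.segment_labels:
        if kind != "a":
            continue
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        sig = SourceSignal.from_flow(
            channels.oral_flow[i0:i1].copy(), fs, "L/s", {"span": (t0, t1)}
        )
        out.append(sig)
    return out
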