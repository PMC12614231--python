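"""Intraoral-pressure ground-truth protocol for /pa/ utterances.

During a /p/ occlusion the intraoral pressure equilibrates with the
subglottal pressure, so the peak intraoral pressure of each /p/ is an
indirect measurement of Ps; linear interpolation between consecutive
/p/ peaks approximates the ground-truth Ps during the intervening
vowel.  This module locates the plosive peaks, builds the interpolant,
applies the vocal-tract SPL correction, and assembles per-vowel
(features, truth) pairs for evaluation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .features import VoiceFeatures, extract_features, UnvoicedError
from .source import SourceSignal, UtteranceChannels, vowel_flow_signals


class ProtocolError(ValueError):
    """The utterance does not support the interpolation protocol."""


@dataclass(frozen=True)
class PlosivePeaks:
    """Ordered (time s, pressure Pa) of the detected /p/ pressure peaks."""

    times: np.ndarray
    pressures: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "pressures", p)
        if t.shape != p.shape or t.ndim != 1:
            raise ValueError("times and pressures must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if np.any(p <= 0):
            raise ValueError("peak pressures must be positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class GroundTruthPs:
    """Piecewise-linear Ps(t) anchored at the plosive peaks.

    Defined only on [first anchor, last anchor]; no extrapolation.
    """

    anchor_times: np.ndarray
    anchor_pressures: np.ndarray

    @classmethod
    def from_peaks(cls, peaks: PlosivePeaks) -> "GroundTruthPs":
        return cls(peaks.times.copy(), peaks.pressures.copy())

    def __call__(self, query_times) -> np.ndarray:
        q = np.atleast_1d(np.asarray(query_times, dtype=float))
        t0, t1 = self.anchor_times[0], self.anchor_times[-1]
        bad = (q < t0) | (q > t1)
        if np.any(bad):
            raise ProtocolError(
                f"query times {q[bad].tolist()} outside anchor span [{t0}, {t1}]"
            )
        return np.interp(q, self.anchor_times, self.anchor_pressures)


def detect_plosive_peaks(
    pressure,
    sample_rate: float,
    min_prominence: float = 200.0,
    min_separation: float = 0.15,
) -> PlosivePeaks:
    """Locate /p/ pressure peaks by prominence and minimum separation.

    Local maxima with prominence >= ``min_prominence`` (Pa) separated by
    at least ``min_separation`` (s); of two closer peaks the larger wins.
    Fewer than 2 peaks raise :class:`ProtocolError` (interpolation needs
    a bracketing pair).
    """
    pressure = np.asarray(pressure, dtype=float)
    distance = max(1, int(round(min_separation * sample_rate)))
    idx, _props = sps.find_peaks(pressure, prominence=min_prominence, distance=distance)
    if len(idx) < 2:
        raise ProtocolError(
            f"found {len(idx)} plosive peak(s); need at least 2 for interpolation"
        )
    return PlosivePeaks(times=idx / sample_rate, pressures=pressure[idx])


def interpolate_ps(peaks: PlosivePeaks, query_times) -> np.ndarray:
    """Ground-truth Ps at ``query_times`` by linear interpolation between peaks."""
    return GroundTruthPs.from_peaks(peaks)(query_times)


def correct_spl(measured_spl: float, correction_db: float = 15.0) -> float:
    """Remove the vocal-tract resonance gain from a measured SPL.

    The inversion networks are trained on source-only (no vocal tract)
    data, so the measured SPL is reduced by ``correction_db`` (default
    15 dB, the average gain of an /a/ vocal tract) before inversion.
    """
    return measured_spl - correction_db


@dataclass(frozen=True)
class ProtocolConfig:
    """Options for assembling per-vowel evaluation pairs."""

    steady_fraction: float = 0.5  # central portion of each vowel analysed
    spl_correction_db: float = 0.0  # 15.0 for microphone SPL through a vocal tract
    min_prominence: float = 200.0
    min_separation: float = 0.15


def build_eval_pairs(
    channels: UtteranceChannels,
    glottal_flow_per_vowel: Optional[Sequence[SourceSignal]] = None,
    peaks: Optional[PlosivePeaks] = None,
    config: ProtocolConfig = ProtocolConfig(),
) -> Tuple[List[VoiceFeatures], np.ndarray, List[Tuple[float, float]]]:
    """Assemble one (features, ground-truth Ps) pair per evaluable vowel.

    A vowel is evaluable when its midpoint lies between two detected
    plosive peaks.  Features come from the steady central portion
    (``steady_fraction``) of the vowel's glottal flow; SPL is corrected
    by ``spl_correction_db``.  Vowels without bracketing peaks, or whose
    flow is unvoiced, are skipped with a warning.

    Returns (features list, truth Ps array, analysed (start, end) spans).
    """
    if peaks is None:
        peaks = detect_plosive_peaks(
            channels.intraoral_pressure,
            channels.sample_rate,
            config.min_prominence,
            config.min_separation,
        )
    truth_fn = GroundTruthPs.from_peaks(peaks)
    vowel_segments = [
        (t0, t1) for kind, t0, t1 in channels.segment_labels if kind == "a"
    ]
    if glottal_flow_per_vowel is None:
        glottal_flow_per_vowel = vowel_flow_signals(channels)
    if len(glottal_flow_per_vowel) != len(vowel_segments):
        raise ValueError(
            f"{len(glottal_flow_per_vowel)} flow signals for "
            f"{len(vowel_segments)} vowel segments"
        )
    feats: List[VoiceFeatures] = []
    truths: List[float] = []
    spans: List[Tuple[float, float]] = []
    skipped = 0
    t_lo, t_hi = peaks.times[0], peaks.times[-1]
    for (t0, t1), flow in zip(vowel_segments, glottal_flow_per_vowel):
        mid = 0.5 * (t0 + t1)
        if not (t_lo <= mid <= t_hi):
            skipped += 1
            continue
        half = 0.5 * config.steady_fraction * (t1 - t0)
        fs = flow.sample_rate
        i0 = int(round((mid - half - t0) * fs))
        i1 = int(round((mid + half - t0) * fs))
        central = SourceSignal.from_flow(
            flow.flow[max(i0, 0) : i1], fs, flow.flow_unit
        )
        try:
            f = extract_features(central)
        except (UnvoicedError, ValueError):
            skipped += 1
            continue
        if config.spl_correction_db:
            f = VoiceFeatures(
                **{
                    **{n: getattr(f, n) for n in f.__dataclass_fields__},
                    "SPL": correct_spl(f.SPL, config.spl_correction_db),
                }
            )
        feats.append(f)
        truths.append(float(truth_fn(mid)[0]))
        spans.append((mid - half, mid + half))
    if skipped:
        warnings.warn(
            f"skipped {skipped} vowel segment(s) without bracketing peaks "
            "or detectable voicing",
            RuntimeWarning,
            stacklevel=2,
        )
    return feats, np.array(truths), spans
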