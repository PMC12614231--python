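"""Physiological parameter types for voice production inversion.

The inversion targets nine control parameters of phonation: vocal fold
geometry (length, vertical thickness, body- and cover-layer depths),
three stiffness moduli of the two-layer fold, the glottal angle between
the approximated folds (a proxy for adduction), and the subglottal
pressure driving phonation.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Dict, Iterator, List, Tuple

import numpy as np

#: Canonical parameter order used everywhere (CSV columns, network outputs).
PARAM_NAMES: Tuple[str, ...] = (
    "vf_length",
    "vf_thickness",
    "body_depth",
    "cover_depth",
    "body_stiffness",
    "cover_stiffness",
    "transverse_stiffness",
    "glottal_angle",
    "subglottal_pressure",
)

PARAM_UNITS: Dict[str, str] = {
    "vf_length": "mm",
    "vf_thickness": "mm",
    "body_depth": "mm",
    "cover_depth": "mm",
    "body_stiffness": "kPa",
    "cover_stiffness": "kPa",
    "transverse_stiffness": "kPa",
    "glottal_angle": "deg",
    "subglottal_pressure": "Pa",
}


class RangeError(ValueError):
    """A physiological parameter (or range) is outside its admissible bounds."""


@dataclass(frozen=True)
class PhysioParams:
    """One set of vocal physiological control parameters.

    Units: lengths/depths in mm, stiffnesses in kPa (longitudinal body and
    cover, plus transverse), glottal angle in degrees, subglottal pressure
    in Pa.  All geometric and stiffness fields must be positive; the angle
    and pressure must be non-negative (zero pressure means no phonation,
    zero angle means fully approximated folds).
    """

    vf_length: float
    vf_thickness: float
    body_depth: float
    cover_depth: float
    body_stiffness: float
    cover_stiffness: float
    transverse_stiffness: float
    glottal_angle: float
    subglottal_pressure: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES[:7]:
            if getattr(self, name) <= 0:
                raise RangeError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.glottal_angle < 0:
            raise RangeError(f"glottal_angle must be >= 0, got {self.glottal_angle}")
        if self.subglottal_pressure < 0:
            raise RangeError(
                f"subglottal_pressure must be >= 0, got {self.subglottal_pressure}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values) -> "PhysioParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values.tolist())))

    def replace(self, **kwargs) -> "PhysioParams":
        d = {n: getattr(self, n) for n in PARAM_NAMES}
        d.update(kwargs)
        return PhysioParams(**d)


def _default_bounds() -> Dict[str, Tuple[float, float]]:
    # Spans male/female/child phonation conditions reported in the literature.
    return {
        "vf_length": (10.0, 20.0),
        "vf_thickness": (2.0, 5.0),
        "body_depth": (4.0, 10.0),
        "cover_depth": (1.0, 4.0),
        "body_stiffness": (10.0, 80.0),
        "cover_stiffness": (10.0, 80.0),
        "transverse_stiffness": (10.0, 80.0),
        "glottal_angle": (0.0, 10.0),
        "subglottal_pressure": (200.0, 2000.0),
    }


@dataclass(frozen=True)
class ParamRanges:
    """Per-parameter (low, high) sampling bounds.

    Degenerate ``low == high`` ranges are accepted (the parameter is then
    held fixed); ``low > high`` is rejected.
    """

    bounds: Dict[str, Tuple[float, float]] = field(default_factory=_default_bounds)

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.bounds)
        if missing:
            raise RangeError(f"missing bounds for: {sorted(missing)}")
        extra = set(self.bounds) - set(PARAM_NAMES)
        if extra:
            raise RangeError(f"unknown parameters in bounds: {sorted(extra)}")
        for name, (lo, hi) in self.bounds.items():
            if not np.isfinite(lo) or not np.isfinite(hi) or lo > hi:
                raise RangeError(f"invalid range for {name}: ({lo}, {hi})")

    def __getitem__(self, name: str) -> Tuple[float, float]:
        return self.bounds[name]

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def with_bounds(self, **kwargs) -> "ParamRanges":
        b = dict(self.bounds)
        for name, pair in kwargs.items():
            b[name] = (float(pair[0]), float(pair[1]))
        return ParamRanges(b)

    def contains(self, params: PhysioParams) -> bool:
        """True if every field is within its bounds.

        Zero subglottal pressure is always admitted (silence), even when
        the sampling range starts above zero.
        """
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            v = getattr(params, name)
            if name == "subglottal_pressure" and v == 0.0:
                continue
            if not (lo <= v <= hi):
                return False
        return True

    def check(self, params: PhysioParams) -> None:
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            v = getattr(params, name)
            if name == "subglottal_pressure" and v == 0.0:
                continue
            if not (lo <= v <= hi):
                raise RangeError(f"{name}={v} outside [{lo}, {hi}]")


def sample_physio_params(
    ranges: ParamRanges, n: int, seed: int
) -> List[PhysioParams]:
    """Draw ``n`` parameter sets, each field uniform within its range.

    Sampling is column-wise in :data:`PARAM_NAMES` order from a single
    ``numpy`` Generator, so identical seeds give bitwise-identical output.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    cols = {}
    for name in PARAM_NAMES:
        lo, hi = ranges[name]
        cols[name] = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    return [
        PhysioParams(**{name: float(cols[name][i]) for name in PARAM_NAMES})
        for i in range(n)
    ]


def params_to_frame(params_list):
    """Stack parameter sets into a pandas DataFrame in canonical column order."""
    import pandas as pd

    data = np.array([p.to_array() for p in params_list])
    if data.size == 0:
        data = data.reshape(0, len(PARAM_NAMES))
    return pd.DataFrame(data, columns=list(PARAM_NAMES))
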