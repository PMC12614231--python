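"""Point-estimate and uncertainty metrics for inversion predictions.

MAE/MAPE quantify point accuracy, PIC (prediction interval coverage)
and CI-width statistics quantify the usefulness of the 95% intervals,
and an OLS regression of prediction on truth summarizes systematic
over/under-estimation (slope) and explained variance (R^2).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .params import PARAM_NAMES


def mae(pred, truth) -> float:
    """Mean absolute error, in the units of the inputs."""
    pred, truth = _check_pair(pred, truth)
    return float(np.mean(np.abs(pred - truth)))


def mape(pred, truth) -> float:
    """Mean absolute percentage error (%); truth values must be non-zero."""
    pred, truth = _check_pair(pred, truth)
    zero = np.flatnonzero(truth == 0)
    if len(zero):
        raise ValueError(f"MAPE undefined: zero truth at indices {zero.tolist()}")
    return float(100.0 * np.mean(np.abs(pred - truth) / np.abs(truth)))


def pic(lower, upper, truth) -> float:
    """Prediction interval coverage (%): fraction of truths inside [lower, upper].

    Bounds are inclusive, so a truth exactly on a bound counts as covered.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if not (lower.shape == upper.shape == truth.shape):
        raise ValueError("lower/upper/truth must have equal shapes")
    if truth.size == 0:
        raise ValueError("empty inputs")
    inside = (lower <= truth) & (truth <= upper)
    return float(100.0 * np.mean(inside))


def ci_width_stats(
    lower, upper, groups: Optional[Sequence] = None
) -> Dict[str, Tuple[float, float]]:
    """Mean and sample SD of the interval width, overall and per group.

    Returns {"all": (mean, sd), <group>: (mean, sd), ...}.  SD is 0 for a
    single interval.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape or lower.size == 0:
        raise ValueError("lower/upper must be non-empty with equal shapes")
    width = upper - lower
    out = {"all": (float(np.mean(width)), _sd(width))}
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape[0] != width.shape[0]:
            raise ValueError("groups length mismatch")
        for g in np.unique(groups):
            if str(g) == "":
                raise ValueError("empty group label")
            w = width[groups == g]
            out[str(g)] = (float(np.mean(w)), _sd(w))
    return out


def regression_fit(pred, truth) -> Tuple[float, float]:
    """OLS of prediction on truth (with intercept): (slope, R^2)."""
    pred, truth = _check_pair(pred, truth)
    if len(pred) < 2:
        raise ValueError("need at least 2 points for a regression")
    res = sstats.linregress(truth, pred)
    return float(res.slope), float(res.rvalue**2)


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def _check_pair(pred, truth):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if pred.size == 0:
        raise ValueError("empty inputs")
    return pred.ravel(), truth.ravel()


@dataclass
class EvalReport:
    """Per-parameter accuracy and CI summary for one model on one dataset.

    All values are in the parameter's physical units (Pa for subglottal
    pressure); rendered tables convert pressure to kPa.
    """

    param_names: Tuple[str, ...]
    mae: Dict[str, float]
    mape: Dict[str, float]
    pic: Dict[str, float]
    ci_width: Dict[str, Dict[str, Tuple[float, float]]]  # param -> group -> (mean, sd)
    slope: Dict[str, float]
    r2: Dict[str, float]
    n: int = 0
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "param_names": list(self.param_names),
                "mae": self.mae,
                "mape": self.mape,
                "pic": self.pic,
                "ci_width": {
                    p: {g: list(v) for g, v in d.items()}
                    for p, d in self.ci_width.items()
                },
                "slope": self.slope,
                "r2": self.r2,
                "n": self.n,
                "meta": self.meta,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(
            param_names=tuple(d["param_names"]),
            mae=d["mae"],
            mape=d["mape"],
            pic=d["pic"],
            ci_width={
                p: {g: tuple(v) for g, v in gd.items()}
                for p, gd in d["ci_width"].items()
            },
            slope=d["slope"],
            r2=d["r2"],
            n=d["n"],
            meta=d.get("meta", {}),
        )

    def render_table(self) -> str:
        """Text table of subglottal-pressure metrics (kPa) and per-group CIs."""
        ps = "subglottal_pressure"
        lines = ["metric                      value"]
        if ps in self.mae:
            lines.append(f"Ps MAE (kPa)                {self.mae[ps] / 1000.0:.3f}")
            lines.append(f"Ps MAPE (%)                 {self.mape.get(ps, float('nan')):.1f}")
            lines.append(f"Ps PIC (%)                  {self.pic.get(ps, float('nan')):.1f}")
            for g, (m, s) in self.ci_width.get(ps, {}).items():
                lines.append(
                    f"Ps CI ({g})".ljust(28) + f"{m / 1000.0:.3f} +/- {s / 1000.0:.3f}"
                )
        return "\n".join(lines)


def evaluate(
    predictions,
    truth,
    subject_labels: Optional[Sequence] = None,
    param_names: Tuple[str, ...] = PARAM_NAMES,
) -> EvalReport:
    """Aggregate metrics from a PredictionWithCI (or equivalent arrays).

    ``predictions`` must expose mean/lower/upper arrays of shape
    (n, n_params); ``truth`` is (n, n_params) or, when it has a single
    column, metrics are computed for the matching single parameter.
    """
    mean = np.asarray(predictions.mean, dtype=float)
    lower = np.asarray(predictions.lower, dtype=float)
    upper = np.asarray(predictions.upper, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if truth.ndim == 1:
        truth = truth[:, None]
    if mean.ndim == 1:
        mean, lower, upper = mean[:, None], lower[:, None], upper[:, None]
    if mean.shape[0] != truth.shape[0]:
        raise ValueError("prediction/truth row mismatch")
    if truth.shape[1] != mean.shape[1]:
        raise ValueError(
            f"truth has {truth.shape[1]} columns, predictions {mean.shape[1]}"
        )
    if len(param_names) != mean.shape[1]:
        raise ValueError("param_names length mismatch")
    d_mae, d_mape, d_pic, d_ci, d_slope, d_r2 = {}, {}, {}, {}, {}, {}
    for j, name in enumerate(param_names):
        d_mae[name] = mae(mean[:, j], truth[:, j])
        if np.all(truth[:, j] != 0):
            d_mape[name] = mape(mean[:, j], truth[:, j])
        d_pic[name] = pic(lower[:, j], upper[:, j], truth[:, j])
        d_ci[name] = ci_width_stats(lower[:, j], upper[:, j], subject_labels)
        if len(mean) >= 2 and np.std(truth[:, j]) > 0:
            d_slope[name], d_r2[name] = regression_fit(mean[:, j], truth[:, j])
    return EvalReport(
        param_names=tuple(param_names),
        mae=d_mae,
        mape=d_mape,
        pic=d_pic,
        ci_width=d_ci,
        slope=d_slope,
        r2=d_r2,
        n=len(mean),
    )
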