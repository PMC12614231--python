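"""End-to-end pipeline: simulate -> extract -> train -> predict -> evaluate.

Builds the training corpus by running the surrogate forward model over
sampled physiology and extracting the fourteen voice features, measures
the corpus's intrinsic feature noise, and orchestrates the demo
workflow (train both back-ends, evaluate on held-out rows and on a
synthetic /pa/ utterance, write reports and figures).
"""
from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .evaluation import EvalReport, evaluate
from .features import (
    FEATURE_NAMES,
    UnvoicedError,
    extract_features,
)
from .inversion import (
    NetworkSpec,
    TrainConfig,
    predict_bnn,
    predict_ensemble,
    save_model,
    train_bnn,
    train_ensemble,
)
from .params import PARAM_NAMES, ParamRanges, sample_physio_params
from .protocol import ProtocolConfig, build_eval_pairs, detect_plosive_peaks
from .source import synthesize_glottal_flow, synthesize_pa_utterance

log = logging.getLogger("voiceinv")

ALL_COLUMNS = (*FEATURE_NAMES, *PARAM_NAMES)


def make_corpus(
    n: int,
    seed: int,
    ranges: Optional[ParamRanges] = None,
    *,
    duration: float = 0.25,
    sample_rate: float = 16000.0,
    jitter: float = 0.005,
    shimmer: float = 0.02,
    feature_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate ``n`` voices and return the 14+9-column feature/parameter table.

    Parameter sets are drawn uniformly from ``ranges``; each is run
    through the surrogate forward model and feature extraction.  Draws
    whose waveform has no detectable voicing (strongly breathy corners
    of the space) are skipped and replaced; the skip count is recorded
    in ``df.attrs["n_unvoiced"]``.  ``feature_noise_sd`` optionally adds
    zero-mean Gaussian observation noise to every feature column, scaled
    by that column's SD (emulating measurement error on real data).
    """
    ranges = ranges or ParamRanges()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows = []
    n_unvoiced = 0
    sample_seed = int(rng.integers(0, 2**31 - 1))
    batch = max(16, int(n * 1.2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        while len(rows) < n:
            plist = sample_physio_params(ranges, batch, seed=sample_seed)
            sample_seed = int(rng.integers(0, 2**31 - 1))
            for p in plist:
                if len(rows) >= n:
                    break
                noise_seed = int(rng.integers(0, 2**31 - 1))
                sig = synthesize_glottal_flow(
                    p,
                    duration=duration,
                    sample_rate=sample_rate,
                    noise_seed=noise_seed,
                    ranges=ranges,
                    jitter=jitter,
                    shimmer=shimmer,
                )
                try:
                    f = extract_features(sig)
                except UnvoicedError:
                    n_unvoiced += 1
                    continue
                rows.append(np.concatenate([f.to_array(), p.to_array()]))
    df = pd.DataFrame(np.array(rows), columns=list(ALL_COLUMNS))
    if feature_noise_sd > 0:
        fcols = list(FEATURE_NAMES)
        sds = df[fcols].std(ddof=1).to_numpy()
        df[fcols] += feature_noise_sd * sds * rng.standard_normal((len(df), len(fcols)))
    df.attrs["n_unvoiced"] = n_unvoiced
    df.attrs["seed"] = seed
    df.attrs["feature_noise_sd"] = feature_noise_sd
    return df


def measure_feature_noise(
    ranges: Optional[ParamRanges] = None,
    n_points: int = 25,
    n_reps: int = 20,
    seed: int = 0,
    *,
    duration: float = 0.25,
    sample_rate: float = 16000.0,
    jitter: float = 0.005,
    shimmer: float = 0.02,
) -> np.ndarray:
    """Replicate SD of each feature under the generator's intrinsic noise.

    Synthesizes ``n_reps`` realizations (different noise seeds) at each
    of ``n_points`` fixed parameter sets and returns the RMS across
    points of the per-point feature SD — the corpus's effective
    measurement-noise level, in absolute feature units (length 14).
    """
    ranges = ranges or ParamRanges()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    plist = sample_physio_params(ranges, n_points * 3, seed=int(rng.integers(2**31)))
    sds = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for p in plist:
            if len(sds) >= n_points:
                break
            reps = []
            try:
                for _ in range(n_reps):
                    sig = synthesize_glottal_flow(
                        p,
                        duration=duration,
                        sample_rate=sample_rate,
                        noise_seed=int(rng.integers(2**31)),
                        ranges=ranges,
                        jitter=jitter,
                        shimmer=shimmer,
                    )
                    reps.append(extract_features(sig).to_array())
            except UnvoicedError:
                continue
            sds.append(np.std(np.array(reps), axis=0, ddof=1))
    if not sds:
        raise RuntimeError("no voiced parameter points found")
    return np.sqrt(np.mean(np.array(sds) ** 2, axis=0))


def add_feature_noise(
    df: pd.DataFrame, noise_sd: np.ndarray, seed: int
) -> pd.DataFrame:
    """Return a copy of ``df`` with absolute Gaussian noise added to features."""
    out = df.copy()
    rng = np.random.default_rng(seed)
    fcols = list(FEATURE_NAMES)
    out[fcols] = out[fcols].to_numpy() + np.asarray(noise_sd) * rng.standard_normal(
        (len(df), len(fcols))
    )
    return out


def train_test_split_rows(
    df: pd.DataFrame, test_fraction: float, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic random row split into (train, held-out test)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    n_test = int(round(test_fraction * len(df)))
    test_idx, train_idx = order[:n_test], order[n_test:]
    return df.iloc[train_idx].reset_index(drop=True), df.iloc[test_idx].reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# demo pipeline


@dataclass
class PipelineConfig:
    """All knobs of the demo pipeline, serializable to/from YAML.

    ``seed`` is the single global seed; every stage derives its own
    stream from it via ``SeedSequence(seed).spawn()`` in a fixed order
    (corpus, ensemble, bnn, utterance, evaluation noise), so two runs
    with the same config are identical.
    """

    seed: int = 0
    n_rows: int = 5000
    test_fraction: float = 0.1
    n_members: int = 10
    duration: float = 0.25
    sample_rate: float = 16000.0
    jitter: float = 0.005
    shimmer: float = 0.02
    feature_noise_sd: float = 0.0
    n_pa_reps: int = 5
    outdir: str = "voiceinv_demo"
    spec: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["train"]["split"] = list(d["train"]["split"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spec" in d and isinstance(d["spec"], dict):
            d["spec"] = NetworkSpec(**d["spec"])
        if "train" in d and isinstance(d["train"], dict):
            t = dict(d["train"])
            if "split" in t:
                t["split"] = tuple(t["split"])
            d["train"] = TrainConfig(**t)
        return cls(**d)

    def to_yaml(self, path: str) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_seeds(seed: int, n: int = 6):
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_demo(config: PipelineConfig) -> Dict[str, EvalReport]:
    """Run the full workflow and write reports/figures to ``config.outdir``.

    Stages: synthetic corpus -> train deep ensemble and BNN -> held-out
    evaluation -> synthetic /pa/ utterance protocol evaluation -> JSON
    reports + predicted-vs-truth scatter and Ps-track figures.  Returns
    {"ensemble": EvalReport, "bnn": EvalReport, "protocol_ensemble": ...}.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    s_corpus, s_ens, s_bnn, s_utt, s_eval, _ = _stage_seeds(config.seed)
    log.info("stage seeds: corpus=%d ensemble=%d bnn=%d utterance=%d", s_corpus, s_ens, s_bnn, s_utt)

    try:
        corpus = make_corpus(
            config.n_rows,
            s_corpus,
            duration=config.duration,
            sample_rate=config.sample_rate,
            jitter=config.jitter,
            shimmer=config.shimmer,
            feature_noise_sd=config.feature_noise_sd,
        )
    except Exception as exc:  # pragma: no cover - stage tagging
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    train_df, test_df = train_test_split_rows(corpus, config.test_fraction, s_eval)

    try:
        ens = train_ensemble(train_df, config.spec, config.train, config.n_members, s_ens)
        bnn = train_bnn(train_df, config.spec, config.train, s_bnn)
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc
    save_model(ens, str(out / "ensemble.npz"))
    save_model(bnn, str(out / "bnn.npz"))

    X_test = test_df[list(FEATURE_NAMES)].to_numpy()
    y_test = test_df[list(PARAM_NAMES)].to_numpy()
    pred_e = predict_ensemble(ens, X_test)
    pred_b = predict_bnn(bnn, X_test, seed=s_eval)
    reports = {
        "ensemble": evaluate(pred_e, y_test),
        "bnn": evaluate(pred_b, y_test),
    }

    # protocol stage: a /pa/ utterance with loudness variation and
    # alternating adduction
    from .params import PhysioParams

    base = PhysioParams(16.0, 3.5, 6.0, 2.0, 30.0, 30.0, 30.0, 2.0, 800.0)
    track = [
        (0.0, base.replace(subglottal_pressure=700.0)),
        (config.n_pa_reps * 0.37 * 0.5, base.replace(subglottal_pressure=1100.0)),
        (config.n_pa_reps * 0.37, base.replace(subglottal_pressure=800.0)),
    ]
    try:
        channels = synthesize_pa_utterance(
            track, config.n_pa_reps, config.sample_rate, seed=s_utt
        )
        peaks = detect_plosive_peaks(channels.intraoral_pressure, channels.sample_rate)
        feats, truth, spans = build_eval_pairs(channels, peaks=peaks, config=ProtocolConfig())
    except Exception as exc:
        raise RuntimeError(f"stage 'protocol' failed: {exc}") from exc
    F = np.array([f.to_array() for f in feats])
    ps_col = list(PARAM_NAMES).index("subglottal_pressure")
    prot_e = predict_ensemble(ens, F)
    prot_b = predict_bnn(bnn, F, seed=s_eval + 1)
    for name, pred in (("protocol_ensemble", prot_e), ("protocol_bnn", prot_b)):
        reports[name] = evaluate(
            type(pred)(
                mean=pred.mean[:, ps_col],
                lower=pred.lower[:, ps_col],
                upper=pred.upper[:, ps_col],
                samples=pred.samples[:, :, ps_col],
            ),
            truth,
            subject_labels=["S1"] * len(truth),
            param_names=("subglottal_pressure",),
        )

    for name, rep in reports.items():
        (out / f"report_{name}.json").write_text(rep.to_json())
    config.to_yaml(str(out / "config.yaml"))
    _write_figures(out, pred_e, y_test, ps_col, prot_e, truth, spans)
    return reports


def _write_figures(out, pred_e, y_test, ps_col, prot_e, truth, spans) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    t, p = y_test[:, ps_col], pred_e.mean[:, ps_col]
    ax.scatter(t, p, s=8, alpha=0.4)
    lim = [min(t.min(), p.min()), max(t.max(), p.max())]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("true subglottal pressure (Pa)")
    ax.set_ylabel("predicted subglottal pressure (Pa)")
    fig.tight_layout()
    fig.savefig(out / "scatter_ps.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 3.5))
    mids = [0.5 * (a + b) for a, b in spans]
    ax.fill_between(
        mids, prot_e.lower[:, ps_col], prot_e.upper[:, ps_col], alpha=0.3, label="95% CI"
    )
    ax.plot(mids, prot_e.mean[:, ps_col], "r.-", label="predicted Ps")
    ax.plot(mids, truth, "b.-", label="interpolated truth")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Ps (Pa)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "ps_track.png", dpi=110)
    plt.close(fig)
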