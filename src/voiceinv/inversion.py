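"""Uncertainty-aware voice inversion: 14 features -> 9 physiological parameters.

Two back-ends produce a predictive distribution, from which a mean and a
95% confidence interval are taken per parameter:

* **Deep ensemble** — independently initialized point networks, each
  trained on its own random 70/15/15 split of the corpus minimizing MSE
  with L2 regularization; the spread of member predictions quantifies
  (mostly epistemic) uncertainty.

* **Mean-field variational network (BNN)** — a Gaussian posterior over
  every weight and bias, fitted by maximizing the evidence lower bound
  (reparameterized sampling, Adam), with a learned homoscedastic
  observation noise per output; prediction samples the weight posterior
  and, by default, the observation noise (the posterior predictive).

Confidence intervals are the 2.5/97.5 percentiles of the sample matrix
(linear interpolation between order statistics); a Gaussian
mean +/- 1.96 SD variant is available via ``ci_method="gaussian"``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np

from . import _mlp
from ._mlp import Adam, Weights
from .features import FEATURE_NAMES, VoiceFeatures, ZScoreStats, zscore_fit
from .params import PARAM_NAMES

ARCHIVE_VERSION = "voiceinv-model-1"


class ModelIOError(IOError):
    """A model archive is missing, corrupt, or of an unknown version."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture shared by all networks: 14 -> 4 x 200 (tanh) -> 9."""

    input_dim: int = 14
    hidden_layers: int = 4
    hidden_width: int = 200
    output_dim: int = 9
    activation: str = "tanh"
    weight_decay: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_layers, self.hidden_width, self.output_dim) <= 0:
            raise ValueError("all NetworkSpec dimensions must be positive")
        if self.activation != "tanh":
            raise ValueError("only tanh hidden activation is supported")

    @property
    def dims(self):
        return _mlp.layer_dims(
            self.input_dim, self.hidden_layers, self.hidden_width, self.output_dim
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters for both back-ends.

    ``split`` is the per-member train/validation/test division of the
    corpus.  BNN-specific fields: ``prior_sd`` (zero-mean Gaussian prior
    on z-scored weights), ``mc_samples`` (weight draws per ELBO step),
    ``kl_anneal_frac`` (fraction of total steps over which the KL weight
    ramps linearly from 0 to 1).
    """

    split: Tuple[float, float, float] = (0.70, 0.15, 0.15)
    optimizer: str = "adam"
    learning_rate: float = 2e-3
    batch_size: int = 512
    max_epochs: int = 200
    patience: int = 15
    seed: int = 0
    prior_sd: float = 1.0
    mc_samples: int = 1
    kl_anneal_frac: float = 0.2
    ci_method: str = "percentile"  # or "gaussian"

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.split) or abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.ci_method not in ("percentile", "gaussian"):
            raise ValueError("ci_method must be 'percentile' or 'gaussian'")


@dataclass
class PredictionWithCI:
    """Per-parameter predictive mean, 95% bounds and the raw sample matrix.

    Shapes: ``mean``/``lower``/``upper`` are (n_inputs, 9); ``samples``
    is (n_samples, n_inputs, 9), all in physical units.
    """

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    samples: np.ndarray
    param_names: Tuple[str, ...] = PARAM_NAMES


def sorted_percentile(samples: np.ndarray, q: float, axis: int = 0) -> np.ndarray:
    """Percentile by linear interpolation between sorted order statistics.

    This is the CI definition used by both back-ends (equivalent to
    numpy's 'linear' method), implemented explicitly so the convention
    is pinned down by this package rather than by a library default.
    """
    s = np.sort(np.moveaxis(samples, axis, 0), axis=0)
    n = s.shape[0]
    pos = (q / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return (1.0 - frac) * s[lo] + frac * s[hi]


def _summarize(samples: np.ndarray, ci_method: str) -> PredictionWithCI:
    mean = samples.mean(axis=0)
    if ci_method == "gaussian":
        sd = samples.std(axis=0, ddof=1) if samples.shape[0] > 1 else np.zeros_like(mean)
        lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    else:
        lower = sorted_percentile(samples, 2.5)
        upper = sorted_percentile(samples, 97.5)
    return PredictionWithCI(mean=mean, lower=lower, upper=upper, samples=samples)


def _as_feature_matrix(features) -> np.ndarray:
    if isinstance(features, VoiceFeatures):
        X = features.to_array()[None, :]
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} feature columns, got {X.shape[1]}")
    return X


def _extract_xy(dataset) -> Tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame with the canonical 14+9 columns, or an (X, y) pair."""
    import pandas as pd

    if isinstance(dataset, pd.DataFrame):
        missing = [c for c in (*FEATURE_NAMES, *PARAM_NAMES) if c not in dataset.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        X = dataset[list(FEATURE_NAMES)].to_numpy(dtype=float)
        y = dataset[list(PARAM_NAMES)].to_numpy(dtype=float)
        return X, y
    X, y = dataset
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float)


def _member_split(n: int, split, rng: np.random.Generator):
    """Random 70/15/15 (by default) row split for one ensemble member."""
    order = rng.permutation(n)
    n_tr = int(round(split[0] * n))
    n_va = int(round(split[1] * n))
    return order[:n_tr], order[n_tr : n_tr + n_va], order[n_tr + n_va :]


def train_member(
    Xz: np.ndarray,
    yz: np.ndarray,
    spec: NetworkSpec,
    config: TrainConfig,
    member_seed,
) -> Tuple[Weights, dict]:
    """Train one ensemble member on z-scored data.

    The member draws its own train/validation/test split and its own
    initial weights from ``member_seed``; early stopping monitors the
    validation split.  Returns (weights, history); history records the
    split sizes and the loss curves.
    """
    n = len(Xz)
    if n < 100:
        raise ValueError(f"need at least 100 rows to train, got {n}")
    rng = np.random.default_rng(member_seed)
    tr, va, te = _member_split(n, config.split, rng)
    weights, hist = _mlp.train_point_network(
        Xz[tr],
        yz[tr],
        Xz[va],
        yz[va],
        spec.dims,
        rng,
        lr=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        weight_decay=spec.weight_decay,
    )
    hist["split_sizes"] = (len(tr), len(va), len(te))
    hist["test_mse"] = _mlp.mse(weights, Xz[te].astype(np.float32), yz[te].astype(np.float32))
    return weights, hist


@dataclass
class EnsembleModel:
    """Deep ensemble: member networks + shared z-score statistics."""

    members: List[Weights]
    spec: NetworkSpec
    config: TrainConfig
    feature_stats: ZScoreStats
    param_stats: ZScoreStats
    member_seeds: List[int] = field(default_factory=list)
    history: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an ensemble needs at least 2 members (CI undefined for 1)")


def train_ensemble(
    dataset,
    spec: NetworkSpec = NetworkSpec(),
    config: TrainConfig = TrainConfig(),
    n_members: int = 100,
    seed: int = 0,
) -> EnsembleModel:
    """Train ``n_members`` independent networks on the feature/parameter corpus.

    Member ``i`` derives its initialization and its random 70/15/15 row
    split from ``SeedSequence(seed).spawn()[i]``, so results depend only
    on (data content, seed, i) — not on corpus row order beyond content.
    Z-score statistics are fitted once on the full corpus and shared by
    all members (predictions then live in consistent physical units).
    """
    if n_members < 2:
        raise ValueError("n_members must be >= 2 (a single member has no CI)")
    X, y = _extract_xy(dataset)
    feature_stats = zscore_fit(X, FEATURE_NAMES)
    param_stats = zscore_fit(y, PARAM_NAMES)
    Xz = (X - feature_stats.mean) / feature_stats.sd
    yz = (y - param_stats.mean) / param_stats.sd
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_members)
    members, history = [], []
    for i in range(n_members):
        weights, hist = train_member(Xz, yz, spec, config, children[i])
        members.append(weights)
        history.append(hist)
    return EnsembleModel(
        members=members,
        spec=spec,
        config=config,
        feature_stats=feature_stats,
        param_stats=param_stats,
        member_seeds=list(range(n_members)),
        history=history,
    )


def predict_ensemble(model: EnsembleModel, features) -> PredictionWithCI:
    """Predict physiology with a 95% CI from the member prediction spread."""
    X = _as_feature_matrix(features)
    Xz = ((X - model.feature_stats.mean) / model.feature_stats.sd).astype(np.float32)
    outs = np.stack([_mlp.forward(w, Xz) for w in model.members]).astype(np.float64)
    samples = outs * model.param_stats.sd + model.param_stats.mean
    return _summarize(samples, model.config.ci_method)


# ---------------------------------------------------------------------------
# mean-field variational back-end


@dataclass
class BNNModel:
    """Mean-field Gaussian posterior over all weights and biases.

    ``mu``/``log_sd`` mirror the layer structure; ``log_noise_sd`` is the
    learned homoscedastic observation noise per output (z-scored units).
    """

    mu: Weights
    log_sd: Weights
    log_noise_sd: np.ndarray
    spec: NetworkSpec
    config: TrainConfig
    feature_stats: ZScoreStats
    param_stats: ZScoreStats
    history: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, (W, b) in enumerate(self.log_sd):
            if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite variational log-SDs")


def _sample_weights(mu: Weights, log_sd: Weights, rng: np.random.Generator) -> Weights:
    out = []
    for (Wm, bm), (Ws, bs) in zip(mu, log_sd):
        out.append(
            (
                Wm + np.exp(Ws) * rng.standard_normal(Wm.shape).astype(np.float32),
                bm + np.exp(bs) * rng.standard_normal(bm.shape).astype(np.float32),
            )
        )
    return out


def train_bnn(
    dataset,
    spec: NetworkSpec = NetworkSpec(),
    config: TrainConfig = TrainConfig(),
    seed: int = 0,
) -> BNNModel:
    """Fit the variational posterior by stochastic ELBO maximization.

    Minimizes  E_q[-log N(y | f(x, w), sigma)] + beta * KL(q || prior) / N
    per datum, with the reparameterization trick (``config.mc_samples``
    draws per step), Adam, and a linear KL ramp over the first
    ``config.kl_anneal_frac`` of steps.  The ELBO trace is recorded in
    ``history``; divergence raises ``FloatingPointError`` with the trace.
    """
    X, y = _extract_xy(dataset)
    n = len(X)
    if n < 100:
        raise ValueError(f"need at least 100 rows to train, got {n}")
    feature_stats = zscore_fit(X, FEATURE_NAMES)
    param_stats = zscore_fit(y, PARAM_NAMES)
    Xz = ((X - feature_stats.mean) / feature_stats.sd).astype(np.float32)
    yz = ((y - param_stats.mean) / param_stats.sd).astype(np.float32)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    tr, va, _te = _member_split(n, config.split, rng)
    Xtr, ytr, Xva, yva = Xz[tr], yz[tr], Xz[va], yz[va]
    n_tr = len(Xtr)
    out_dim = spec.output_dim

    mu = _mlp.init_weights(spec.dims, rng)
    log_sd = [
        (np.full_like(W, -5.0), np.full_like(b, -5.0)) for W, b in mu
    ]
    log_noise = np.full(out_dim, np.log(0.3), dtype=np.float32)
    flat = _mlp.flatten(mu) + _mlp.flatten(log_sd) + [log_noise]
    opt = Adam(flat, lr=config.learning_rate)

    steps_per_epoch = max(1, int(np.ceil(n_tr / config.batch_size)))
    total_steps = steps_per_epoch * config.max_epochs
    anneal_steps = max(1, int(config.kl_anneal_frac * total_steps))
    prior_sd = config.prior_sd

    elbo_trace: List[float] = []
    best_val = np.inf
    best = (_mlp.clone(mu), _mlp.clone(log_sd), log_noise.copy())
    bad_epochs = 0
    step = 0
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            B = len(xb)
            beta = min(1.0, (step + 1) / anneal_steps)
            inv_var = np.exp(-2.0 * log_noise)

            g_mu = [(np.zeros_like(W), np.zeros_like(b)) for W, b in mu]
            g_lsd = [(np.zeros_like(W), np.zeros_like(b)) for W, b in mu]
            g_lnoise = np.zeros_like(log_noise)
            nll_acc = 0.0
            for _s in range(config.mc_samples):
                eps = [
                    (
                        rng.standard_normal(W.shape).astype(np.float32),
                        rng.standard_normal(b.shape).astype(np.float32),
                    )
                    for W, b in mu
                ]
                w = [
                    (Wm + np.exp(Ws) * eW, bm + np.exp(bs) * eb)
                    for (Wm, bm), (Ws, bs), (eW, eb) in zip(mu, log_sd, eps)
                ]
                pred, cache = _mlp.forward(w, xb, return_cache=True)
                r = (pred - yb) * inv_var  # d(mean NLL)/d pred * B
                nll_acc += 0.5 * float(
                    np.mean(np.sum((pred - yb) ** 2 * inv_var, axis=1))
                ) + float(np.sum(log_noise))
                grads = _mlp.backward(w, cache, r / B)
                g_lnoise += 1.0 - np.mean((pred - yb) ** 2, axis=0) * inv_var
                for li, (gW, gb) in enumerate(grads):
                    Ws, bs = log_sd[li]
                    eW, eb = eps[li]
                    g_mu[li] = (g_mu[li][0] + gW, g_mu[li][1] + gb)
                    g_lsd[li] = (
                        g_lsd[li][0] + gW * eW * np.exp(Ws),
                        g_lsd[li][1] + gb * eb * np.exp(bs),
                    )
            scale = 1.0 / config.mc_samples
            kl_scale = beta / n_tr
            flat_grads: List[np.ndarray] = []
            for li in range(len(mu)):
                Wm, bm = mu[li]
                Ws, bs = log_sd[li]
                flat_grads.append(g_mu[li][0] * scale + kl_scale * Wm / prior_sd**2)
                flat_grads.append(g_mu[li][1] * scale + kl_scale * bm / prior_sd**2)
            for li in range(len(mu)):
                Ws, bs = log_sd[li]
                flat_grads.append(
                    g_lsd[li][0] * scale
                    + kl_scale * (np.exp(2.0 * Ws) / prior_sd**2 - 1.0)
                )
                flat_grads.append(
                    g_lsd[li][1] * scale
                    + kl_scale * (np.exp(2.0 * bs) / prior_sd**2 - 1.0)
                )
            flat_grads.append(g_lnoise * scale)
            opt.step(flat_grads)

            kl = sum(
                _mlp.gaussian_kl(Wm, np.exp(Ws), 0.0, prior_sd)
                + _mlp.gaussian_kl(bm, np.exp(bs), 0.0, prior_sd)
                for (Wm, bm), (Ws, bs) in zip(mu, log_sd)
            )
            neg_elbo = nll_acc * scale + beta * kl / n_tr
            if not np.isfinite(neg_elbo):
                raise FloatingPointError(
                    f"ELBO diverged at step {step}; trace tail: {elbo_trace[-5:]}"
                )
            elbo_trace.append(neg_elbo)
            step += 1

        val_mse = _mlp.mse(mu, Xva, yva)  # fit quality at the posterior mean
        if val_mse < best_val - 1e-7:
            best_val = val_mse
            best = (_mlp.clone(mu), _mlp.clone(log_sd), log_noise.copy())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    mu_b, log_sd_b, log_noise_b = best
    return BNNModel(
        mu=mu_b,
        log_sd=log_sd_b,
        log_noise_sd=log_noise_b,
        spec=spec,
        config=config,
        feature_stats=feature_stats,
        param_stats=param_stats,
        history={"neg_elbo": elbo_trace, "best_val_mse": best_val},
    )


def predict_bnn(
    model: BNNModel,
    features,
    n_samples: int = 100,
    seed: int = 0,
    *,
    include_noise: bool = True,
) -> PredictionWithCI:
    """Posterior(-predictive) sampling: ``n_samples`` weight draws per input.

    With ``include_noise`` (default) each draw also adds the learned
    observation noise, giving the posterior predictive; without it the
    samples reflect weight uncertainty only.
    """
    X = _as_feature_matrix(features)
    Xz = ((X - model.feature_stats.mean) / model.feature_stats.sd).astype(np.float32)
    rng = np.random.default_rng(seed)
    draws = []
    noise_sd = np.exp(model.log_noise_sd)
    for _ in range(n_samples):
        w = _sample_weights(model.mu, model.log_sd, rng)
        out = _mlp.forward(w, Xz).astype(np.float64)
        if include_noise:
            out = out + noise_sd * rng.standard_normal(out.shape)
        draws.append(out)
    samples = np.stack(draws) * model.param_stats.sd + model.param_stats.mean
    return _summarize(samples, model.config.ci_method)


# ---------------------------------------------------------------------------
# model persistence (single-file .npz archive)


def _pack_weights(prefix: str, weights: Weights, store: dict) -> None:
    for i, (W, b) in enumerate(weights):
        store[f"{prefix}_{i}_W"] = W
        store[f"{prefix}_{i}_b"] = b


def _unpack_weights(prefix: str, store, n_layers: int) -> Weights:
    return [
        (store[f"{prefix}_{i}_W"], store[f"{prefix}_{i}_b"]) for i in range(n_layers)
    ]


def save_model(model, path: str) -> None:
    """Write an ensemble or BNN model to a single .npz archive."""
    meta = {
        "version": ARCHIVE_VERSION,
        "spec": asdict(model.spec),
        "config": asdict(model.config),
        "feature_stats": model.feature_stats.to_dict(),
        "param_stats": model.param_stats.to_dict(),
    }
    store: dict = {}
    if isinstance(model, EnsembleModel):
        meta["kind"] = "ensemble"
        meta["n_members"] = len(model.members)
        for m, w in enumerate(model.members):
            _pack_weights(f"member{m}", w, store)
    elif isinstance(model, BNNModel):
        meta["kind"] = "bnn"
        _pack_weights("mu", model.mu, store)
        _pack_weights("logsd", model.log_sd, store)
        store["log_noise_sd"] = model.log_noise_sd
    else:
        raise TypeError(f"cannot save model of type {type(model)}")
    store["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **store)


def load_model(path: str):
    """Load a model archive written by :func:`save_model`."""
    try:
        with np.load(path) as store:
            data = dict(store)
    except (OSError, ValueError) as exc:
        raise ModelIOError(f"cannot read model archive {path!r}: {exc}") from exc
    try:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta.get("version") != ARCHIVE_VERSION:
            raise ModelIOError(f"unknown archive version: {meta.get('version')}")
        spec = NetworkSpec(**meta["spec"])
        cfg = meta["config"]
        cfg["split"] = tuple(cfg["split"])
        config = TrainConfig(**cfg)
        fstats = ZScoreStats.from_dict(meta["feature_stats"])
        pstats = ZScoreStats.from_dict(meta["param_stats"])
        n_layers = spec.hidden_layers + 1
        if meta["kind"] == "ensemble":
            members = [
                _unpack_weights(f"member{m}", data, n_layers)
                for m in range(meta["n_members"])
            ]
            return EnsembleModel(
                members=members,
                spec=spec,
                config=config,
                feature_stats=fstats,
                param_stats=pstats,
            )
        return BNNModel(
            mu=_unpack_weights("mu", data, n_layers),
            log_sd=_unpack_weights("logsd", data, n_layers),
            log_noise_sd=data["log_noise_sd"],
            spec=spec,
            config=config,
            feature_stats=fstats,
            param_stats=pstats,
        )
    except ModelIOError:
        raise
    except (KeyError, ValueError, TypeError) as exc:
        raise ModelIOError(f"corrupt model archive {path!r}: {exc}") from exc
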