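"""The pulse-decoder MLP.

A small multilayer perceptron (hidden sizes 40 and 20, leaky-ReLU
activations) maps each data point's standardized features to a single
scalar, the *logit Bayesian update* u_Bayes.  The posterior pulse
probability is obtained by adding the update to the prior's logit,

    logit p(x_k = 1 | features) = u_Bayes + logit p(x_k = 1 | last_k),

where the prior is the assumed protocol's (clipped) hazard.  Training
minimizes the Bernoulli cross-entropy of the posterior over
protocol-weighted minibatches with Adam.  The output layer is
zero-initialized, so an untrained decoder reproduces the prior exactly and
the bitrate estimate starts at 0 — the estimator is a lower bound, and
"no update" means "no information".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import FeatureStats, PulseDataset, sample_minibatch
from .protocol import StimulationProtocol

__all__ = ["TrainConfig", "PulseClassifier", "posterior_probability", "train",
           "loo_crossvalidate"]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class TrainConfig:
    hidden: tuple[int, ...] = (40, 20)
    leaky_slope: float = 0.01
    learning_rate: float = 1e-3
    steps: int = 3000
    batch_size: int = 10_000
    seed: int = 0
    impute_above: int | None = None
    # validation-based weight selection: a fraction of cells is held out of
    # the minibatch sampler and the returned weights are those with the best
    # validation cross-entropy.  Step 0 reproduces the prior exactly (the
    # output layer starts at zero), so a decoder that finds no real signal
    # validates best as "no update" and the bitrate estimate stays at 0
    # instead of going negative on held-out data.
    val_fraction: float = 0.1
    val_check_every: int = 25


@dataclass
class PulseClassifier:
    """MLP weights plus the feature-standardization statistics they expect."""

    weights: list           # [(W1, b1), (W2, b2), ...], last layer scalar output
    stats: FeatureStats
    config: TrainConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def input_width(self) -> int:
        return self.weights[0][0].shape[0]

    def forward(self, features: np.ndarray) -> np.ndarray:
        """u_Bayes for standardized feature rows."""
        u, _ = self._forward_cached(features)
        return u

    def _forward_cached(self, features: np.ndarray):
        a = np.asarray(features, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        if a.shape[1] != self.input_width:
            raise ValueError(
                f"feature width {a.shape[1]} != model input width {self.input_width}")
        slope = self.config.leaky_slope
        cache = []
        for i, (W, b) in enumerate(self.weights):
            z = a @ W + b
            cache.append((a, z))
            a = z if i == len(self.weights) - 1 else np.where(z > 0, z, slope * z)
        return a[:, 0], cache

    def save(self, path) -> None:
        """Single-archive serialization: weight arrays plus a JSON manifest
        (version, layer shapes, feature stats, training config)."""
        import dataclasses
        import json

        manifest = {
            "format_version": 1,
            "n_layers": len(self.weights),
            "config": dataclasses.asdict(self.config),
            "feature_mean": self.stats.mean.tolist(),
            "feature_sd": self.stats.sd.tolist(),
        }
        arrays = {"manifest": np.frombuffer(
            json.dumps(manifest).encode(), dtype=np.uint8)}
        for i, (W, b) in enumerate(self.weights):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "PulseClassifier":
        import json

        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode())
            if manifest.get("format_version") != 1:
                raise ValueError("unsupported model file version")
            weights = [(data[f"W{i}"], data[f"b{i}"])
                       for i in range(manifest["n_layers"])]
        cfg = manifest["config"]
        cfg["hidden"] = tuple(cfg["hidden"])
        stats = FeatureStats(np.asarray(manifest["feature_mean"]),
                             np.asarray(manifest["feature_sd"]))
        return cls(weights, stats, TrainConfig(**cfg))

    def backward(self, cache, dloss_du: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(u) per sample."""
        slope = self.config.leaky_slope
        grads = [None] * len(self.weights)
        delta = dloss_du[:, None]
        for i in reversed(range(len(self.weights))):
            a_in, z = cache[i]
            grads[i] = (a_in.T @ delta, delta.sum(axis=0))
            if i > 0:
                W, _ = self.weights[i]
                delta = delta @ W.T
                _, z_prev = cache[i - 1]
                delta = delta * np.where(z_prev > 0, 1.0, slope)
        return grads


def _init_weights(widths: list[int], rng) -> list:
    """Fan-in-scaled hidden layers; zero-initialized output layer."""
    weights = []
    for i, (n_in, n_out) in enumerate(zip(widths[:-1], widths[1:])):
        if i == len(widths) - 2:
            W = np.zeros((n_in, n_out))
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        weights.append((W, np.zeros(n_out)))
    return weights


def posterior_probability(u_bayes, prior) -> np.ndarray:
    """sigmoid(u_Bayes + logit prior); prior must lie strictly inside (0, 1)."""
    prior = np.asarray(prior, dtype=float)
    if np.any((prior <= 0) | (prior >= 1)):
        raise ValueError("prior must be in (0, 1); clip the hazard first")
    z = np.asarray(u_bayes, dtype=float) + np.log(prior) - np.log1p(-prior)
    return 1.0 / (1.0 + np.exp(-z))


def train(
    dataset: PulseDataset,
    protocol: StimulationProtocol,
    config: TrainConfig = TrainConfig(),
    seed: int | None = None,
) -> PulseClassifier:
    """Fit the decoder by Adam on protocol-weighted minibatches.

    The loss is the Bernoulli cross-entropy of the posterior (prior logit +
    u_Bayes) against the sampled pulse labels; it is computed in nats
    internally and traced in bits per point.
    """
    if dataset.stats is None:
        raise ValueError("standardize the dataset before training")
    if dataset.x.min() == dataset.x.max():
        raise ValueError("dataset contains a single class; cannot train")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    d = dataset.features.shape[1]
    widths = [d, *config.hidden, 1]
    model = PulseClassifier(_init_weights(widths, rng), dataset.stats, config)

    # split cells into sampling and validation subsets
    n_cells = len(dataset.cells)
    sample_ds, val_feats, val_x, val_prior_logit = dataset, None, None, None
    if config.val_fraction > 0 and n_cells >= 5:
        n_val = max(1, int(round(config.val_fraction * n_cells)))
        val_cells = rng.choice(n_cells, size=n_val, replace=False)
        mask = np.zeros(n_cells, dtype=bool)
        mask[val_cells] = True
        sample_ds = dataset.subset_cells(np.flatnonzero(~mask))
        val_ds = dataset.subset_cells(np.flatnonzero(mask))
        if len(val_ds) and val_ds.x.min() != val_ds.x.max():
            val_feats = val_ds.standardized()
            val_x = val_ds.x
            val_prior_logit = protocol.prior_logit(val_ds.last)
        if not sample_ds.groups or sample_ds.x.min() == sample_ds.x.max():
            sample_ds = dataset
            val_feats = None

    def val_ce(weights) -> float:
        saved = model.weights
        model.weights = weights
        u = model.forward(val_feats)
        model.weights = saved
        z = u + val_prior_logit
        post = 1.0 / (1.0 + np.exp(-z))
        return float(-(val_x * np.log(np.clip(post, 1e-12, None))
                       + (1 - val_x) * np.log(np.clip(1 - post, 1e-12, None))).mean())

    best_weights = [(W.copy(), b.copy()) for W, b in model.weights]
    best_ce = val_ce(best_weights) if val_feats is not None else np.inf

    # Adam state
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in model.weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trace = np.empty(config.steps)

    for step in range(config.steps):
        rows, x, true_last = sample_minibatch(
            sample_ds, protocol, config.batch_size, rng=rng,
            impute_above=config.impute_above,
        )
        feats = sample_ds.standardized(rows, true_last=true_last)
        prior_logit = protocol.prior_logit(true_last.astype(int))
        u, cache = model._forward_cached(feats)
        z = u + prior_logit
        post = 1.0 / (1.0 + np.exp(-z))
        # cross-entropy in nats; traced in bits/point
        ce = -(x * np.log(np.clip(post, 1e-12, None))
               + (1 - x) * np.log(np.clip(1 - post, 1e-12, None))).mean()
        trace[step] = ce / LN2
        dldu = (post - x) / len(x)
        grads = model.backward(cache, dldu)
        t = step + 1
        lr = config.learning_rate
        new_weights = []
        for i, ((W, b), (gW, gb)) in enumerate(zip(model.weights, grads)):
            mW, mb = m[i]
            vW, vb = v[i]
            mW = beta1 * mW + (1 - beta1) * gW
            mb = beta1 * mb + (1 - beta1) * gb
            vW = beta2 * vW + (1 - beta2) * gW**2
            vb = beta2 * vb + (1 - beta2) * gb**2
            m[i], v[i] = (mW, mb), (vW, vb)
            mWh, mbh = mW / (1 - beta1**t), mb / (1 - beta1**t)
            vWh, vbh = vW / (1 - beta2**t), vb / (1 - beta2**t)
            new_weights.append((W - lr * mWh / (np.sqrt(vWh) + eps),
                                b - lr * mbh / (np.sqrt(vbh) + eps)))
        model.weights = new_weights
        if val_feats is not None and (step + 1) % config.val_check_every == 0:
            ce_now = val_ce(model.weights)
            if ce_now < best_ce:
                best_ce = ce_now
                best_weights = [(W.copy(), b.copy()) for W, b in model.weights]
    if val_feats is not None:
        model.weights = best_weights
    model.loss_trace = trace
    return model


def loo_crossvalidate(
    dataset: PulseDataset,
    protocol: StimulationProtocol,
    config: TrainConfig = TrainConfig(),
):
    """Leave-one-replicate-out check that the decoder does not overfit replicates.

    For each replicate, trains on the remaining replicates and evaluates the
    population bitrate on *all* data; reports the delta against the
    all-replicate model.  Returns a list of dicts, one per fold.
    """
    from .bitrate import evaluate_bitrate  # local import to avoid a cycle

    reps = dataset.replicates
    if len(reps) < 2:
        raise ValueError("leave-one-out requires at least 2 replicates")
    full_model = train(dataset, protocol, config)
    b_full = evaluate_bitrate(full_model, dataset, protocol).population_bitrate
    out = []
    cell_rep = np.array([c.replicate_id for c in dataset.cells])
    for rep in reps:
        keep_cells = np.flatnonzero(cell_rep != rep)
        fold_ds = dataset.subset_cells(keep_cells)
        model = train(fold_ds, protocol, config)
        b = evaluate_bitrate(model, dataset, protocol).population_bitrate
        out.append({"held_out": rep, "bitrate": b, "bitrate_all_data": b_full,
                    "delta": b - b_full})
    return out
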