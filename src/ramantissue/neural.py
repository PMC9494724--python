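"""Small neural spectral classifiers: a 1D dense network and a 2D 1×1-conv network.

Two fixed architectures over the 650-slot peak features:

* ``ann1d`` — intensities only (the slot order carries no wavenumber
  information): 650 → three hidden layers of 8 rectified units → 4-way
  softmax output.
* ``cnn2d`` — (wavenumber, intensity) pairs: each of the 650 slots is passed
  through two successive banks of 32 1×1 convolution filters (i.e. per-slot
  linear maps 2→32 and 32→32 with shared weights and ReLU), the 650×32
  activation is flattened and passed through one 512-unit hidden layer to the
  4-way softmax output.  Keeping the wavenumber channel is what lets this
  model absorb per-session differences in the recorded wavenumber range that
  defeat a pure intensity-vector model.

Training minimises cross-entropy with the Adam optimiser; everything is
implemented with seeded numpy arithmetic, so identical data + seed give
bit-identical weights.  The wavenumber channel of 2D features is standardised
with the training-set mean/std (raw cm⁻¹ values would dwarf unit-scale
intensities); zero-padded slots stay at zero in both channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .evaluation import ConfusionMatrix
from .preprocess import PeakFeatures
from .spectra_io import CLASS_ORDER, TissueClass

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture selector; layer sizes are fixed per kind."""

    kind: str  # "ann1d" or "cnn2d"
    feature_length: int = 650
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.kind not in ("ann1d", "cnn2d"):
            raise ValueError("kind must be 'ann1d' or 'cnn2d'")

    def kind_mode(self) -> str:
        """Feature mode this architecture consumes ('1d' or '2d')."""
        return "1d" if self.kind == "ann1d" else "2d"


@dataclass
class TrainConfig:
    learning_rate: float = 5e-3
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


@dataclass
class TrainedModel:
    spec: NetworkSpec
    weights: dict[str, np.ndarray]
    label_order: tuple[TissueClass, ...]
    train_config: TrainConfig
    training_log: list[float] = field(default_factory=list)
    wn_mean: float = 0.0
    wn_std: float = 1.0


def _init_weights(spec: NetworkSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    def he(n_in, n_out):
        return (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(np.float32)

    w: dict[str, np.ndarray] = {}
    if spec.kind == "ann1d":
        sizes = [spec.feature_length, 8, 8, 8, spec.n_classes]
        for i in range(4):
            w[f"W{i}"] = he(sizes[i], sizes[i + 1])
            w[f"b{i}"] = np.zeros(sizes[i + 1], dtype=np.float32)
    else:
        w["C0"] = he(2, 32)
        w["c0"] = np.zeros(32, dtype=np.float32)
        w["C1"] = he(32, 32)
        w["c1"] = np.zeros(32, dtype=np.float32)
        w["W2"] = he(spec.feature_length * 32, 512)
        w["b2"] = np.zeros(512, dtype=np.float32)
        w["W3"] = he(512, spec.n_classes)
        w["b3"] = np.zeros(spec.n_classes, dtype=np.float32)
    return w


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(spec: NetworkSpec, w: dict[str, np.ndarray], X: np.ndarray,
             keep: bool = False):
    """Probabilities for a batch; with ``keep`` also the activations for backprop."""
    cache: dict[str, np.ndarray] = {}
    if spec.kind == "ann1d":
        a = X
        acts = [a]
        for i in range(4):
            z = a @ w[f"W{i}"] + w[f"b{i}"]
            a = np.maximum(z, 0.0) if i < 3 else z
            acts.append(a)
        probs = _softmax(acts[-1])
        if keep:
            cache["acts"] = acts
    else:
        n = X.shape[0]
        h0 = np.maximum(X.reshape(-1, 2) @ w["C0"] + w["c0"], 0.0)
        h1 = np.maximum(h0 @ w["C1"] + w["c1"], 0.0)
        flat = h1.reshape(n, -1)
        h2 = np.maximum(flat @ w["W2"] + w["b2"], 0.0)
        logits = h2 @ w["W3"] + w["b3"]
        probs = _softmax(logits)
        if keep:
            cache.update(x2=X.reshape(-1, 2), h0=h0, h1=h1, flat=flat, h2=h2)
    return (probs, cache) if keep else probs


def _backward(spec: NetworkSpec, w, X, probs, onehot, cache) -> dict[str, np.ndarray]:
    n = X.shape[0]
    g: dict[str, np.ndarray] = {}
    dlogits = (probs - onehot) / n
    if spec.kind == "ann1d":
        acts = cache["acts"]
        d = dlogits
        for i in range(3, -1, -1):
            g[f"W{i}"] = acts[i].T @ d
            g[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = (d @ w[f"W{i}"].T) * (acts[i] > 0)
    else:
        g["W3"] = cache["h2"].T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        dh2 = (dlogits @ w["W3"].T) * (cache["h2"] > 0)
        g["W2"] = cache["flat"].T @ dh2
        g["b2"] = dh2.sum(axis=0)
        dflat = (dh2 @ w["W2"].T).reshape(-1, 32) * (cache["h1"] > 0)
        g["C1"] = cache["h0"].T @ dflat
        g["c1"] = dflat.sum(axis=0)
        dh0 = (dflat @ w["C1"].T) * (cache["h0"] > 0)
        g["C0"] = cache["x2"].T @ dh0
        g["c0"] = dh0.sum(axis=0)
    return g


def _assemble(features: Sequence[PeakFeatures], spec: NetworkSpec) -> np.ndarray:
    mode = spec.kind_mode()
    X = []
    for f in features:
        if f.mode != mode or f.length != spec.feature_length:
            raise ValueError(
                f"feature mode/length ({f.mode}, {f.length}) does not match "
                f"network {spec.kind} ({mode}, {spec.feature_length})")
        X.append(f.as_array())
    return np.stack(X).astype(np.float32)


def _standardize_wn(X: np.ndarray, mean: float, std: float) -> np.ndarray:
    out = X.copy()
    pads = out[:, :, 1] == 0.0
    out[:, :, 0] = (out[:, :, 0] - mean) / std
    out[:, :, 0][pads] = 0.0
    return out


def train(
    features: Sequence[PeakFeatures],
    labels: Sequence[TissueClass],
    spec: NetworkSpec,
    train_config: TrainConfig | None = None,
) -> TrainedModel:
    """Fit the network by mini-batch Adam on softmax cross-entropy.

    Requires at least two classes.  The per-epoch mean loss is recorded in
    ``training_log``; the run is fully determined by ``train_config.seed``.
    """
    tc = train_config or TrainConfig()
    labels = [TissueClass(l) for l in labels]
    if len(set(labels)) < 2:
        raise ValueError("training requires at least two classes")
    X = _assemble(features, spec)
    y = np.array([CLASS_ORDER.index(l) for l in labels])
    if len(X) != len(y):
        raise ValueError("features and labels differ in length")

    wn_mean, wn_std = 0.0, 1.0
    if spec.kind == "cnn2d":
        nonpad = X[:, :, 1] > 0
        vals = X[:, :, 0][nonpad]
        wn_mean = float(vals.mean()) if vals.size else 0.0
        wn_std = float(vals.std()) or 1.0
        X = _standardize_wn(X, wn_mean, wn_std)

    rng = np.random.default_rng(tc.seed)
    w = _init_weights(spec, rng)
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(vv) for k, vv in w.items()}
    onehot_full = np.eye(spec.n_classes, dtype=np.float32)[y]
    log: list[float] = []
    t = 0
    for _ in range(tc.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            Xb, yb = X[idx], onehot_full[idx]
            probs, cache = _forward(spec, w, Xb, keep=True)
            losses.append(float(-(yb * np.log(probs + 1e-12)).sum() / len(idx)))
            grads = _backward(spec, w, Xb, probs, yb, cache)
            t += 1
            for k in w:
                m[k] = tc.adam_beta1 * m[k] + (1 - tc.adam_beta1) * grads[k]
                v[k] = tc.adam_beta2 * v[k] + (1 - tc.adam_beta2) * grads[k] ** 2
                mhat = m[k] / (1 - tc.adam_beta1 ** t)
                vhat = v[k] / (1 - tc.adam_beta2 ** t)
                w[k] = w[k] - tc.learning_rate * mhat / (np.sqrt(vhat) + tc.adam_eps)
        log.append(float(np.mean(losses)))
    return TrainedModel(spec=spec, weights=w, label_order=CLASS_ORDER,
                        train_config=tc, training_log=log,
                        wn_mean=wn_mean, wn_std=wn_std)


def predict(model: TrainedModel, features: PeakFeatures | Sequence[PeakFeatures]) -> np.ndarray:
    """Class-probability vector(s); rows sum to 1 and follow ``label_order``."""
    single = isinstance(features, PeakFeatures)
    X = _assemble([features] if single else features, model.spec)
    if model.spec.kind == "cnn2d":
        X = _standardize_wn(X, model.wn_mean, model.wn_std)
    probs = _forward(model.spec, model.weights, X)
    return probs[0] if single else probs


def predict_classes(model: TrainedModel, features: Sequence[PeakFeatures]) -> list[TissueClass]:
    probs = predict(model, features)
    return [model.label_order[int(i)] for i in np.argmax(np.atleast_2d(probs), axis=1)]


def evaluate_split(
    features: Sequence[PeakFeatures],
    labels: Sequence[TissueClass],
    spec: NetworkSpec,
    train_fraction: float = 0.7,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    groups: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Stratified train/test split, fit, and held-out confusion matrix.

    The split is stratified by class (and additionally by ``groups``, e.g.
    map ids, when given) so no class is absent from either side at small n.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = [TissueClass(l) for l in labels]
    tc = train_config or TrainConfig(seed=seed)
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[int]] = {}
    for i, l in enumerate(labels):
        key = (l, groups[i]) if groups is not None else (l,)
        strata.setdefault(key, []).append(i)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for key in sorted(strata, key=str):
        idx = np.array(strata[key])
        idx = idx[rng.permutation(len(idx))]
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    model = train([features[i] for i in train_idx], [labels[i] for i in train_idx],
                  spec, tc)
    predicted = predict_classes(model, [features[i] for i in test_idx])
    return ConfusionMatrix.from_predictions([labels[i] for i in test_idx], predicted)


# ---------------------------------------------------------------------------
# persistence: single .npz container with a YAML header entry
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path) -> None:
    header = yaml.safe_dump({
        "version": _FORMAT_VERSION,
        "kind": model.spec.kind,
        "feature_length": model.spec.feature_length,
        "n_classes": model.spec.n_classes,
        "label_order": [c.value for c in model.label_order],
        "wn_mean": model.wn_mean,
        "wn_std": model.wn_std,
        "train_config": vars(model.train_config),
        "training_log": model.training_log,
    })
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
             **model.weights)


def load_model(path) -> TrainedModel:
    data = np.load(path)
    header = yaml.safe_load(bytes(data["__header__"]).decode())
    if header.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {header.get('version')}")
    spec = NetworkSpec(kind=header["kind"], feature_length=header["feature_length"],
                       n_classes=header["n_classes"])
    weights = {k: data[k] for k in data.files if k != "__header__"}
    tc = TrainConfig(**header["train_config"])
    return TrainedModel(spec=spec, weights=weights,
                        label_order=tuple(TissueClass(c) for c in header["label_order"]),
                        train_config=tc, training_log=list(header["training_log"]),
                        wn_mean=header["wn_mean"], wn_std=header["wn_std"])
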