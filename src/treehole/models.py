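"""Three progressively refined risk classifiers over a pluggable encoder.

Stage 1 trains a single affine head (with dropout) on sentence vectors of
rule-labeled comments.  Stage 2 freezes the encoder and trains a deeper
head — two embed_dim-wide affine layers, each followed by ReLU, dropout and
batch normalization, then an affine output — on the corrected label tier.
Stage 3 reduces the sentence vector to ``reduce_dim`` (64 by default) with
two affine layers, concatenates the ten normalized psychological features
into a 74-long fused vector, and classifies with a final affine + sigmoid.

The default encoder is a signed character n-gram (n = 1..3) hashing
embedder: deterministic given (text, seed), dependency-free, and
CPU-cheap.  A transformer sentence encoder can be plugged in where the
optional ``torch``/``transformers`` extra is installed; with the hashing
encoder, stage 1's "train the encoder too" is a deliberate no-op since the
hash features have no trainable parameters.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .psych_features import PsychFeatureVector, count_features

HIGH, LOW = "high", "low"


class ConfigError(ValueError):
    pass


# Conventional Adam step size for a freshly initialised shallow head on
# fixed features; the transformer path fine-tunes pretrained weights and
# uses the much smaller published rate.
DEFAULT_LEARNING_RATES = {"hashing": 0.01, "transformer": 2e-5}


@dataclass(frozen=True)
class ModelConfig:
    encoder: str = "hashing"
    embed_dim: int = 768
    dropout: float = 0.1
    learning_rate: float | None = None  # None -> backend default
    max_chars: int = 128
    batch_train: int = 8
    batch_val: int = 16
    batch_test: int = 16
    reduce_dim: int = 64
    seed: int = 0
    epochs: int = 5
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.encoder not in ("hashing", "transformer"):
            raise ConfigError(f"unknown encoder {self.encoder!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if not self.reduce_dim < self.embed_dim:
            raise ConfigError("reduce_dim must be smaller than embed_dim")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError("threshold must be in (0, 1)")

    @property
    def lr(self) -> float:
        return (
            self.learning_rate
            if self.learning_rate is not None
            else DEFAULT_LEARNING_RATES[self.encoder]
        )


class HashingEncoder:
    """Signed character n-gram hashing into ``embed_dim`` buckets.

    Each n-gram (n = 1..3) of the first ``max_chars`` characters is hashed
    (keyed by the seed) to a bucket and a sign; the count vector is then
    L2-normalized.  The empty string maps to the zero vector.
    """

    trainable = False

    def __init__(self, embed_dim: int, max_chars: int, seed: int) -> None:
        self.embed_dim = embed_dim
        self.max_chars = max_chars
        self.seed = seed
        self._cache: dict[str, tuple[int, float]] = {}

    def _slot(self, gram: str) -> tuple[int, float]:
        hit = self._cache.get(gram)
        if hit is None:
            digest = hashlib.blake2b(
                gram.encode("utf-8"), digest_size=8, salt=struct.pack("<q", self.seed)
            ).digest()
            h = int.from_bytes(digest, "little")
            hit = (h % self.embed_dim, 1.0 if (h >> 33) & 1 else -1.0)
            self._cache[gram] = hit
        return hit

    def encode(self, text: str) -> np.ndarray:
        vec = np.zeros(self.embed_dim)
        text = text[: self.max_chars]
        for n in (1, 2, 3):
            for i in range(len(text) - n + 1):
                idx, sign = self._slot(text[i : i + n])
                vec[idx] += sign
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def encode_many(self, texts: Sequence[str]) -> np.ndarray:
        return np.vstack([self.encode(t) for t in texts]) if texts else np.zeros((0, self.embed_dim))


class TransformerEncoder:
    """Optional transformer sentence-encoder backend (requires extras)."""

    trainable = True

    def __init__(self, embed_dim: int, max_chars: int, seed: int) -> None:
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:
            raise ConfigError(
                "the transformer encoder requires the optional 'transformer' extra "
                "(pip install treehole[transformer]) and a pretrained checkpoint; "
                "use encoder='hashing' for a dependency-free backend"
            ) from exc
        raise NotImplementedError("transformer backend wiring is left to deployments")


def make_encoder(config: ModelConfig):
    cls = {"hashing": HashingEncoder, "transformer": TransformerEncoder}[config.encoder]
    return cls(config.embed_dim, config.max_chars, config.seed)


def encode(text: str, config: ModelConfig) -> np.ndarray:
    """One sentence vector of length ``embed_dim`` for ``text``."""
    return make_encoder(config).encode(text)


@dataclass
class TrainedModel:
    stage: str  # model1 | model2 | model3
    config: ModelConfig
    networks: dict[str, nn.Network]
    encoder: object = None
    meta: dict = field(default_factory=dict)
    # training-set mean of the sentence vectors; subtracted before the head.
    # Hashing features share a large common direction (common vocabulary),
    # and centering removes it so the head sees per-comment variation only.
    center: np.ndarray | None = None

    def encoder_state_hash(self) -> str:
        """Fingerprint of the encoder state (hash parameters for the default)."""
        enc = self.encoder
        payload = json.dumps(
            {"embed_dim": enc.embed_dim, "max_chars": enc.max_chars, "seed": enc.seed}
        ).encode()
        return hashlib.sha256(payload).hexdigest()


def _labels_to_y(labels: Sequence[str]) -> np.ndarray:
    y = np.array([1.0 if lab == HIGH else 0.0 for lab in labels])
    if len(set(labels)) < 2:
        raise ValueError("training requires both classes to be present")
    return y


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _forward_all(
    networks: dict[str, nn.Network], X: np.ndarray, F: np.ndarray | None, training: bool
) -> np.ndarray:
    """Logits for any stage; model3 concatenates features after the trunk."""
    if "trunk" in networks:
        reduced = networks["trunk"].forward(X, training)
        fused = np.hstack([reduced, F])
        return networks["head"].forward(fused, training)
    return networks["head"].forward(X, training)


def _backward_all(networks: dict[str, nn.Network], dlogits: np.ndarray) -> None:
    if "trunk" in networks:
        dfused = networks["head"].backward(dlogits)
        reduce_dim = networks["head"].layers[0].params["W"].shape[0] - count_features()
        networks["trunk"].backward(dfused[:, :reduce_dim])
    else:
        networks["head"].backward(dlogits)


def _fit(
    networks: dict[str, nn.Network],
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
    F: np.ndarray | None = None,
) -> dict:
    """Mini-batch Adam / binary cross-entropy with best-epoch selection.

    A 10% holdout tracks validation cross-entropy; the parameters of the
    epoch with the lowest validation loss win (validation F1 is recorded
    alongside for reporting).  Loss is the selection criterion because it
    stays unbiased when the labels carry no signal, where F1 selection
    would drift toward all-positive states.
    """
    n = X.shape[0]
    order = rng.permutation(n)
    n_val = max(2, int(round(0.1 * n))) if n >= 20 else 0
    val_idx, tr_idx = order[:n_val], order[n_val:]
    if n_val and (len(set(y[val_idx])) < 2 or len(set(y[tr_idx])) < 2):
        n_val = 0
        tr_idx = order
    opts = [nn.Adam(net, lr=config.lr) for net in networks.values()]
    best_loss, best_f1, best_state = np.inf, None, None
    history: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(len(tr_idx))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(perm), config.batch_train):
            idx = tr_idx[perm[start : start + config.batch_train]]
            logits = _forward_all(
                networks, X[idx], None if F is None else F[idx], training=True
            )
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            _backward_all(networks, dlogits)
            for opt in opts:
                opt.step()
            epoch_loss += loss
            n_batches += 1
        entry = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)}
        if n_val:
            logits = _forward_all(
                networks, X[val_idx], None if F is None else F[val_idx], training=False
            )
            val_loss, _ = nn.bce_with_logits(logits, y[val_idx])
            val_pred = (nn.sigmoid(logits.ravel()) >= config.threshold).astype(float)
            entry["val_loss"] = val_loss
            entry["val_f1"] = _binary_f1(y[val_idx], val_pred)
            if val_loss < best_loss:
                best_loss = val_loss
                best_f1 = entry["val_f1"]
                best_state = {k: {n_: v.copy() for n_, v in net.state().items()}
                              for k, net in networks.items()}
        history.append(entry)
    if best_state is not None:
        for k, net in networks.items():
            net.load_state(best_state[k])
    return {"history": history, "val_f1": best_f1}


def train_model1(
    labeled: Sequence[tuple[str, str]], config: ModelConfig | None = None
) -> TrainedModel:
    """Stage 1: encoder -> dropout -> affine -> sigmoid on rule labels."""
    config = config or ModelConfig()
    texts, labels = zip(*labeled) if labeled else ((), ())
    y = _labels_to_y(labels)
    encoder = make_encoder(config)
    X = encoder.encode_many(list(texts))
    center = X.mean(axis=0)
    X = X - center
    rng = np.random.default_rng(config.seed)
    head = nn.Network(
        [
            nn.Dropout(config.dropout, rng),
            nn.Linear(config.embed_dim, 1, rng),
        ]
    )
    networks = {"head": head}
    meta = _fit(networks, X, y, config, rng)
    return TrainedModel("model1", config, networks, encoder, meta, center)


def train_model2(
    base: TrainedModel,
    labeled: Sequence[tuple[str, str]],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Stage 2: frozen encoder, deep head on the corrected (easy) tier."""
    if base.stage != "model1":
        raise ValueError(f"model2 must build on a model1 base, got {base.stage}")
    config = config or base.config
    texts, labels = zip(*labeled) if labeled else ((), ())
    y = _labels_to_y(labels)
    X = base.encoder.encode_many(list(texts))
    center = X.mean(axis=0)
    X = X - center
    rng = np.random.default_rng(config.seed + 1)
    d = config.embed_dim
    head = nn.Network(
        [
            nn.Linear(d, d, rng),
            nn.ReLU(),
            nn.Dropout(config.dropout, rng),
            nn.BatchNorm(d),
            nn.Linear(d, d, rng),
            nn.ReLU(),
            nn.Dropout(config.dropout, rng),
            nn.BatchNorm(d),
            nn.Linear(d, 1, rng),
        ]
    )
    networks = {"head": head}
    meta = _fit(networks, X, y, config, rng)
    return TrainedModel("model2", config, networks, base.encoder, meta, center)


# intermediate width of the two-layer reduction trunk
_TRUNK_HIDDEN = 256


def train_model3(
    base: TrainedModel,
    labeled_with_features: Sequence[tuple[str, PsychFeatureVector, str]],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Stage 3: frozen encoder, 64-D reduction, fusion with the 10 features."""
    if base.stage not in ("model1", "model2"):
        raise ValueError(f"model3 must build on an earlier stage, got {base.stage}")
    config = config or base.config
    texts = [t for t, _, _ in labeled_with_features]
    feats = [f for _, f, _ in labeled_with_features]
    labels = [lab for _, _, lab in labeled_with_features]
    y = _labels_to_y(labels)
    F = np.vstack([f.as_array() for f in feats])
    if F.shape[1] != count_features():
        raise ValueError(f"feature vectors must have {count_features()} entries")
    X = base.encoder.encode_many(texts)
    center = X.mean(axis=0)
    X = X - center
    rng = np.random.default_rng(config.seed + 2)
    trunk = nn.Network(
        [
            nn.Linear(config.embed_dim, _TRUNK_HIDDEN, rng),
            nn.ReLU(),
            nn.Linear(_TRUNK_HIDDEN, config.reduce_dim, rng),
            nn.ReLU(),
        ]
    )
    fusion_dim = config.reduce_dim + count_features()
    head = nn.Network([nn.Linear(fusion_dim, 1, rng)])
    networks = {"trunk": trunk, "head": head}
    meta = _fit(networks, X, y, config, rng, F=F)
    meta["fusion_dim"] = fusion_dim
    return TrainedModel("model3", config, networks, base.encoder, meta, center)


def fused_vector(model: TrainedModel, text: str, features: PsychFeatureVector) -> np.ndarray:
    """The concatenated internal vector the stage-3 classifier sees."""
    if model.stage != "model3":
        raise ValueError("fused_vector is only defined for model3")
    x = model.encoder.encode(text)[None, :]
    if model.center is not None:
        x = x - model.center
    reduced = model.networks["trunk"].forward(x, training=False)
    return np.hstack([reduced, features.as_array()[None, :]]).ravel()


def predict_proba(
    model: TrainedModel,
    texts: Sequence[str],
    features: Sequence[PsychFeatureVector] | None = None,
) -> np.ndarray:
    needs_features = model.stage == "model3"
    if needs_features and features is None:
        raise ValueError("model3 prediction requires psychological feature vectors")
    if not needs_features and features is not None:
        raise ValueError(f"{model.stage} does not accept feature vectors")
    X = model.encoder.encode_many(list(texts))
    if model.center is not None:
        X = X - model.center
    F = None
    if needs_features:
        F = np.vstack([f.as_array() for f in features])
        if F.shape[0] != len(texts):
            raise ValueError("one feature vector per text is required")
    logits = _forward_all(model.networks, X, F, training=False)
    return nn.sigmoid(logits.ravel())


def predict(
    model: TrainedModel,
    text: str,
    features: PsychFeatureVector | None = None,
) -> tuple[float, str]:
    """(probability, binary label) for one comment; ties go to "high"."""
    prob = float(
        predict_proba(model, [text], None if features is None else [features])[0]
    )
    return prob, HIGH if prob >= model.config.threshold else LOW


def predict_labels(
    model: TrainedModel,
    texts: Sequence[str],
    features: Sequence[PsychFeatureVector] | None = None,
) -> list[str]:
    probs = predict_proba(model, texts, features)
    return [HIGH if p >= model.config.threshold else LOW for p in probs]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Single-file .npz with a JSON config header embedded."""
    arrays: dict[str, np.ndarray] = {}
    for key, net in model.networks.items():
        for name, value in net.state().items():
            arrays[f"{key}/{name}"] = value
    if model.center is not None:
        arrays["__center__"] = model.center
    header = json.dumps(
        {"stage": model.stage, "config": asdict(model.config), "meta": _jsonable(model.meta)}
    )
    np.savez_compressed(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=float))


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        config = ModelConfig(**header["config"])
        rng = np.random.default_rng(config.seed)
        # rebuild architectures, then overwrite parameters
        stage = header["stage"]
        if stage == "model1":
            nets = {"head": nn.Network([nn.Dropout(config.dropout, rng),
                                        nn.Linear(config.embed_dim, 1, rng)])}
        elif stage == "model2":
            d = config.embed_dim
            nets = {"head": nn.Network([
                nn.Linear(d, d, rng), nn.ReLU(), nn.Dropout(config.dropout, rng), nn.BatchNorm(d),
                nn.Linear(d, d, rng), nn.ReLU(), nn.Dropout(config.dropout, rng), nn.BatchNorm(d),
                nn.Linear(d, 1, rng)])}
        else:
            nets = {
                "trunk": nn.Network([
                    nn.Linear(config.embed_dim, _TRUNK_HIDDEN, rng), nn.ReLU(),
                    nn.Linear(_TRUNK_HIDDEN, config.reduce_dim, rng), nn.ReLU()]),
                "head": nn.Network([nn.Linear(config.reduce_dim + count_features(), 1, rng)]),
            }
        for key, net in nets.items():
            prefix = f"{key}/"
            net.load_state({
                k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)
            })
        center = data["__center__"] if "__center__" in data.files else None
    return TrainedModel(
        stage, config, nets, make_encoder(config), header.get("meta", {}), center
    )
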