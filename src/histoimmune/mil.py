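"""Multiple-instance learning on whole-slide tile bags.

A slide is a bag of fixed-size RGB tiles with one ordinal immune-level label;
tiles carry no individual labels.  Ordinal targets use a cumulative multi-hot
encoding (class c -> c+1 leading ones), trained with element-wise binary
cross-entropy on logits, so each output bit answers "is the class >= k?".

Three permutation-invariant aggregators are provided:

- ``mean``      — unweighted average of instance embeddings (CNN baseline);
- ``att``       — gated attention pooling (tanh * sigmoid gate, softmax
                  weights over instances);
- ``att_trans`` — a transformer encoder over the instance set (no positional
                  encoding) followed by gated attention pooling.

Training uses AdamW with cosine annealing; for ``att_trans`` the transformer
block sits in a separate optimizer parameter group with a lower learning rate
and weight decay 0.1.  Evaluation reports accuracy and quadratic-weighted
Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn import (
    AdamW,
    CosineAnnealing,
    GatedAttention,
    Linear,
    Module,
    SmallConvEncoder,
    Tensor,
    TransformerEncoderLayer,
    bce_with_logits,
)

__all__ = [
    "TileBag",
    "AttentionOutput",
    "MilModelSpec",
    "MILModel",
    "MILClassifier",
    "tile_slide",
    "select_instances",
    "encode_ordinal",
    "decode_ordinal",
    "gated_attention_pool",
    "mil_forward",
    "train_mil",
    "evaluate_mil",
    "qwk",
]


@dataclass
class TileBag:
    """One slide's sampled tile set and its ordinal label.

    ``instances`` is (N, H, W, 3), either uint8 in [0, 255] or float in
    [0, 1]; models rescale uint8 to [0, 1] on the fly so bags can stay
    memory-compact.
    """

    slide_id: str
    instances: np.ndarray
    label: int
    instance_coords: list[tuple[int, int]] | None = None

    def __post_init__(self):
        if self.instances.ndim != 4 or self.instances.shape[-1] != 3:
            raise ValueError("instances must be (N, H, W, 3)")
        if self.instances.shape[0] < 1:
            raise ValueError("a bag needs at least one instance")


@dataclass
class AttentionOutput:
    weights: np.ndarray  # (N,) attention weights, sum to 1
    bag_embedding: np.ndarray  # (d,)
    logits: np.ndarray | None = None  # (C,)


@dataclass
class MilModelSpec:
    mode: str = "att"  # "mean" | "att" | "att_trans"
    n_classes: int = 2
    d: int = 128
    attention_dim: int = 64
    transformer_layers: int = 1
    transformer_heads: int = 4
    encoder_channels: tuple[int, int, int] = (8, 16, 32)

    def __post_init__(self):
        if self.mode not in ("mean", "att", "att_trans"):
            raise ValueError(f"unknown MIL mode {self.mode!r}")
        if self.d <= 0 or self.n_classes < 2:
            raise ValueError("need d > 0 and n_classes >= 2")


# -- tiling and instance selection --------------------------------------------

def tile_slide(image, tile: int, level: int = 0) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Cut a non-overlapping row-major grid of tiles from an image.

    ``image`` is an (H, W, 3) array or a path to a (possibly pyramidal) TIFF,
    in which case ``level`` selects the pyramid level.  Coordinates are
    0-based pixel offsets of each half-open [r, r+tile) x [c, c+tile) window;
    partial edge tiles are discarded.
    """
    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        import tifffile

        with tifffile.TiffFile(image) as tf:
            series = tf.series[0]
            arr = series.levels[level].asarray() if series.levels else series.asarray()
        image = np.asarray(arr)
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    h, w = image.shape[:2]
    if h < tile or w < tile:
        raise ValueError(f"image {h}x{w} smaller than one {tile}px tile")
    tiles = []
    for r in range(0, h - tile + 1, tile):
        for c in range(0, w - tile + 1, tile):
            tiles.append((image[r : r + tile, c : c + tile], (r, c)))
    return tiles


def select_instances(tiles: list, k: int, seed: int = 0, mode: str = "train"):
    """Pick up to k instances from a slide's tiles.

    Train mode ranks tiles by ascending mean pixel intensity and takes the k
    darkest — on H&E, dark means tissue-rich ("min" sort).  Eval mode keeps
    the deterministic grid, uniformly subsampling k tiles (seeded, original
    order preserved) only when more than k are present.  Bags smaller than k
    are kept whole, never padded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    arrays = [t[0] if isinstance(t, tuple) else t for t in tiles]
    if mode == "train":
        means = np.array([float(np.mean(a)) for a in arrays])
        order = np.argsort(means, kind="stable")[:k]
        return [tiles[i] for i in sorted(order)]
    if mode == "eval":
        if len(tiles) <= k:
            return list(tiles)
        idx = np.random.default_rng(seed).choice(len(tiles), size=k, replace=False)
        return [tiles[i] for i in sorted(idx)]
    raise ValueError(f"unknown selection mode {mode!r}")


# -- ordinal codec -------------------------------------------------------------

def encode_ordinal(label: int, n_classes: int) -> np.ndarray:
    """Cumulative multi-hot: bits[0..label] = 1, the rest 0 (length C)."""
    if not 0 <= label < n_classes:
        raise ValueError(f"label {label} out of range [0, {n_classes})")
    bits = np.zeros(n_classes, dtype=np.float32)
    bits[: label + 1] = 1.0
    return bits


def decode_ordinal(probs: np.ndarray) -> int:
    """Inverse of the cumulative encoding: max(0, #(p > 0.5) - 1).

    Monotone in every probability; the floor at 0 absorbs the vacuous first
    bit being predicted off.
    """
    probs = np.asarray(probs)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return max(0, int((probs > 0.5).sum()) - 1)


# -- model ---------------------------------------------------------------------

class MILModel(Module):
    """Encoder + aggregator + linear head, as specified by a MilModelSpec."""

    def __init__(self, spec: MilModelSpec, rng: np.random.Generator, encoder: Module | None = None):
        self.spec = spec
        self.encoder = encoder or SmallConvEncoder(spec.d, rng, channels=spec.encoder_channels)
        self.attention = GatedAttention(spec.d, spec.attention_dim, rng)
        self.transformer = (
            [TransformerEncoderLayer(spec.d, spec.transformer_heads, rng) for _ in range(spec.transformer_layers)]
            if spec.mode == "att_trans"
            else []
        )
        self.head = Linear(spec.d, spec.n_classes, rng)

    def transformer_parameters(self) -> list[Tensor]:
        return [p for layer in self.transformer for p in layer.parameters()]

    def base_parameters(self) -> list[Tensor]:
        trans = {id(p) for p in self.transformer_parameters()}
        return [p for p in self.parameters() if id(p) not in trans]

    def forward(self, instances: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """instances (N, H, W, 3) in [0, 1] -> (weights, bag embedding, logits)."""
        x = Tensor(np.ascontiguousarray(instances.transpose(0, 3, 1, 2), dtype=np.float32))
        h = self.encoder(x)  # (N, d)
        if self.spec.mode == "att_trans":
            for layer in self.transformer:
                h = layer(h)
        if self.spec.mode == "mean":
            n = h.shape[0]
            bag = h.mean(axis=0, keepdims=True)
            weights = Tensor(np.full(n, 1.0 / n, dtype=np.float32))
        else:
            weights, bag = self.attention(h)
        logits = self.head(bag).reshape(-1)
        return weights, bag.reshape(-1), logits


def _to_unit(instances: np.ndarray) -> np.ndarray:
    if instances.dtype == np.uint8:
        return instances.astype(np.float32) / 255.0
    return np.asarray(instances, dtype=np.float32)


def gated_attention_pool(features: np.ndarray, attention: GatedAttention) -> AttentionOutput:
    """Apply a gated-attention module to precomputed instance features."""
    weights, bag = attention(Tensor(np.asarray(features, dtype=np.float32)))
    return AttentionOutput(weights=weights.data.copy(), bag_embedding=bag.data.reshape(-1).copy())


def mil_forward(model: MILModel, bag) -> AttentionOutput:
    """Forward one bag (TileBag or raw (N,H,W,3) array) without gradients."""
    instances = bag.instances if isinstance(bag, TileBag) else bag
    weights, emb, logits = model.forward(_to_unit(instances))
    return AttentionOutput(
        weights=weights.data.copy(), bag_embedding=emb.data.copy(), logits=logits.data.copy()
    )


def _augment_bag(instances: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips and 90-degree rotations, per tile."""
    out = instances.copy()
    for i in range(out.shape[0]):
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        if rng.random() < 0.5:
            out[i] = out[i, ::-1, :]
        out[i] = np.rot90(out[i], k=int(rng.integers(0, 4)))
    return out


class MILClassifier(BaseEstimator, ClassifierMixin):
    """Weakly supervised ordinal bag classifier (scikit-learn interface).

    ``fit(bags, labels)`` takes a list of bags — TileBag or (N, H, W, 3)
    arrays — and one ordinal label per bag.  The loss is mean element-wise
    binary cross-entropy between bag logits and the cumulative encoding.

    The default learning rate suits the built-in small encoder trained from
    scratch; with a pretrained backbone much smaller rates (order 3e-5) are
    appropriate.  For ``att_trans`` the transformer parameters form a
    separate AdamW group at ``lr * transformer_lr_ratio`` with weight decay
    ``transformer_weight_decay``; all other parameters share the base rate.
    """

    def __init__(
        self,
        mode: str = "att",
        n_classes: int = 2,
        d: int = 128,
        attention_dim: int = 64,
        transformer_layers: int = 1,
        transformer_heads: int = 4,
        encoder_channels: tuple[int, int, int] = (8, 16, 32),
        epochs: int = 30,
        lr: float = 1e-3,
        transformer_lr_ratio: float = 0.2,
        transformer_weight_decay: float = 0.1,
        batch_bags: int = 4,
        k_instances: int = 44,
        augment: bool = True,
        patience: int = 5,
        min_epochs: int = 10,
        seed: int = 0,
    ):
        self.mode = mode
        self.n_classes = n_classes
        self.d = d
        self.attention_dim = attention_dim
        self.transformer_layers = transformer_layers
        self.transformer_heads = transformer_heads
        self.encoder_channels = encoder_channels
        self.epochs = epochs
        self.lr = lr
        self.transformer_lr_ratio = transformer_lr_ratio
        self.transformer_weight_decay = transformer_weight_decay
        self.batch_bags = batch_bags
        self.k_instances = k_instances
        self.augment = augment
        self.patience = patience
        self.min_epochs = min_epochs
        self.seed = seed

    # -- helpers ---------------------------------------------------------------
    def _spec(self) -> MilModelSpec:
        return MilModelSpec(
            mode=self.mode,
            n_classes=self.n_classes,
            d=self.d,
            attention_dim=self.attention_dim,
            transformer_layers=self.transformer_layers,
            transformer_heads=self.transformer_heads,
            encoder_channels=tuple(self.encoder_channels),
        )

    @staticmethod
    def _instances(bag) -> np.ndarray:
        return bag.instances if isinstance(bag, TileBag) else np.asarray(bag)

    def _prep(self, bag, mode: str, seed: int) -> np.ndarray:
        inst = self._instances(bag)
        if inst.shape[0] > self.k_instances:
            chosen = select_instances(list(inst), self.k_instances, seed=seed, mode=mode)
            inst = np.stack(chosen)
        return inst

    def fit(self, bags, labels, val_bags=None, val_labels=None):
        labels = np.asarray(labels, dtype=int)
        if len(bags) != len(labels):
            raise ValueError("one label per bag required")
        if np.any(labels < 0) or np.any(labels >= self.n_classes):
            raise ValueError("labels must lie in [0, n_classes)")
        if not len(bags):
            raise ValueError("need at least one training bag")
        use_early_stop = val_bags is not None
        if use_early_stop and (val_labels is None or not len(val_bags)):
            raise ValueError("early stopping requires a non-empty validation set")

        rng = np.random.default_rng(self.seed)
        model = MILModel(self._spec(), rng)
        groups = [{"params": model.base_parameters(), "lr": self.lr}]
        if model.transformer:
            groups.append(
                {
                    "params": model.transformer_parameters(),
                    "lr": self.lr * self.transformer_lr_ratio,
                    "weight_decay": self.transformer_weight_decay,
                }
            )
        opt = AdamW(groups)
        sched = CosineAnnealing(opt, t_max=self.epochs, eta_min=self.lr * 0.01)

        train_inst = [self._prep(b, "train", self.seed) for b in bags]
        targets = [encode_ordinal(c, self.n_classes) for c in labels]
        self.history_ = {"train_loss": [], "val_metric": []}
        best_metric, best_state, best_epoch = -np.inf, None, -1
        n = len(train_inst)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_bags):
                idx = order[start : start + self.batch_bags]
                losses = None
                for i in idx:
                    inst = train_inst[i]
                    if self.augment:
                        inst = _augment_bag(inst, rng)
                    _, _, logits = model.forward(_to_unit(inst))
                    loss = bce_with_logits(logits, targets[i])
                    losses = loss if losses is None else losses + loss
                batch_loss = losses * (1.0 / len(idx))
                opt.zero_grad()
                batch_loss.backward()
                opt.step()
                epoch_loss += float(batch_loss.data) * len(idx)
            sched.step()
            self.history_["train_loss"].append(epoch_loss / n)
            if use_early_stop:
                self.model_ = model
                metric = self._val_metric(val_bags, np.asarray(val_labels, dtype=int))
                self.history_["val_metric"].append(metric)
                if metric > best_metric:
                    best_metric, best_state, best_epoch = metric, model.state_dict(), epoch
                elif epoch + 1 >= self.min_epochs and epoch - best_epoch >= self.patience:
                    break
        if best_state is not None:
            model.load_state_dict(best_state)
        self.model_ = model
        self.best_val_metric_ = best_metric if use_early_stop else None
        self.classes_ = np.arange(self.n_classes)
        return self

    def _val_metric(self, bags, labels) -> float:
        """Validation QWK, falling back to accuracy for binary labels."""
        pred = self.predict(bags)
        if self.n_classes == 2:
            return float(np.mean(pred == labels))
        return qwk(pred, labels, self.n_classes)

    def predict_logits(self, bags) -> np.ndarray:
        out = []
        for j, bag in enumerate(bags):
            inst = self._prep(bag, "eval", self.seed + j)
            out.append(mil_forward(self.model_, _to_unit(inst)).logits)
        return np.stack(out)

    def predict(self, bags) -> np.ndarray:
        logits = self.predict_logits(bags)
        probs = 1.0 / (1.0 + np.exp(-logits))
        return np.array([decode_ordinal(p) for p in probs])

    def attention_weights(self, bag) -> np.ndarray:
        inst = self._instances(bag)
        return mil_forward(self.model_, _to_unit(inst)).weights

    def save(self, path) -> None:
        """Single-file checkpoint with the model spec and config embedded."""
        import json

        arrays = {f"p{j}": w for j, w in enumerate(self.model_.state_dict())}
        np.savez_compressed(path, meta=json.dumps(self.get_params(), default=list), **arrays)

    @classmethod
    def load(cls, path) -> "MILClassifier":
        import json

        with np.load(path, allow_pickle=False) as data:
            params = json.loads(str(data["meta"]))
            params["encoder_channels"] = tuple(params["encoder_channels"])
            clf = cls(**params)
            model = MILModel(clf._spec(), np.random.default_rng(0))
            model.load_state_dict([data[f"p{j}"] for j in range(len(model.parameters()))])
            clf.model_ = model
            clf.classes_ = np.arange(clf.n_classes)
        return clf


# -- functional wrappers and metrics -------------------------------------------

def train_mil(train_bags, train_labels, val_bags, val_labels, spec: MilModelSpec | None = None, **config) -> MILClassifier:
    """Fit a MILClassifier from bag lists; spec fields override defaults."""
    if spec is not None:
        config.setdefault("mode", spec.mode)
        config.setdefault("n_classes", spec.n_classes)
        config.setdefault("d", spec.d)
        config.setdefault("attention_dim", spec.attention_dim)
        config.setdefault("transformer_layers", spec.transformer_layers)
        config.setdefault("transformer_heads", spec.transformer_heads)
        config.setdefault("encoder_channels", spec.encoder_channels)
    clf = MILClassifier(**config)
    return clf.fit(train_bags, train_labels, val_bags=val_bags, val_labels=val_labels)


def evaluate_mil(model: MILClassifier, bags, labels) -> dict:
    """Accuracy, quadratic-weighted kappa and per-bag predictions."""
    labels = np.asarray(labels, dtype=int)
    pred = model.predict(bags)
    return {
        "accuracy": float(np.mean(pred == labels)),
        "qwk": qwk(pred, labels, model.n_classes),
        "predictions": pred,
    }


def qwk(pred, true, n_classes: int) -> float:
    """Quadratic-weighted Cohen's kappa.

    kappa = 1 - sum(w * O) / sum(w * E) with w_ij = (i - j)^2 / (C - 1)^2,
    O the observed confusion matrix and E the outer product of its marginals
    scaled to the same total.  Identical vectors give 1; the degenerate case
    of zero expected disagreement (both vectors constant and equal) is 1.
    """
    if n_classes < 2:
        raise ValueError("QWK needs at least 2 classes")
    p = np.asarray(pred, dtype=int)
    t = np.asarray(true, dtype=int)
    if p.shape != t.shape or p.size < 1:
        raise ValueError("pred and true must be equal-length and non-empty")
    o = np.zeros((n_classes, n_classes))
    np.add.at(o, (p, t), 1.0)
    e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
    ij = np.arange(n_classes)
    w = (ij[:, None] - ij[None, :]) ** 2 / (n_classes - 1) ** 2
    denom = (w * e).sum()
    if denom == 0:
        return 1.0
    return float(1.0 - (w * o).sum() / denom)
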