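"""Pluggable feature extractors and trainable classifiers.

Two desk-scale reference backbones implement the backbone contract:

``reference_cnn``
    A small convolutional network (one 3x3 conv layer, an average-pooled
    hidden dense layer, a softmax head) written in numpy and trained with
    Adam. Training is fully deterministic given the seed. The "body" is
    conv + hidden layer; the "head" is the final dense layer.

``deterministic_texture``
    A non-neural extractor: pooled local texture statistics (grid-cell
    mean, standard deviation, and gradient magnitudes) with a logistic
    regression head. The body has no trainable parameters, so transforms
    are identical across calls.

Large pretrained architectures (AlexNet-/VGG-style) plug in behind the
same contract; the mechanisms built on top (class decomposition, the
freeze-and-replace transfer protocol, slice selection) are
backbone-agnostic. The transfer protocol itself is
:func:`freeze_and_replace_head`: snapshot and freeze the body, attach a
fresh head for the new task, and retrain only the head.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression

from .decomposition import FeatureMatrix
from .exceptions import ValidationError
from .volume_io import SliceSet

BACKBONE_NAMES = ("reference_cnn", "deterministic_texture")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults mirror the published protocol (200 epochs, batch size 50,
    Adam at 1e-4); tests and desk-scale runs reduce the epoch count.
    """

    epochs: int = 200
    batch_size: int = 50
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")


@dataclass(frozen=True)
class BackboneSpec:
    """Which backbone to build and how much of its tail is trainable.

    ``n_trainable_tail_layers`` counts body layers unfrozen from the top
    (the head is always trainable during initial fits): 0 = head only,
    1 = hidden dense layer too, >= 2 = the whole body.
    """

    name: str = "reference_cnn"
    input_size: Tuple[int, int] = (32, 32)
    n_trainable_tail_layers: int = 2
    head_classes: int = 2

    def __post_init__(self):
        if self.name not in BACKBONE_NAMES:
            raise ValidationError(f"unknown backbone: {self.name!r}")
        if self.head_classes < 2:
            raise ValidationError("head_classes must be >= 2")
        if self.n_trainable_tail_layers < 0:
            raise ValidationError("n_trainable_tail_layers must be >= 0")


@dataclass
class ModelState:
    """Parameter snapshot with stable content digests."""

    body_digest: str
    head_digest: str
    frozen: Dict[str, bool]


def _digest(arrays: Sequence[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=np.float64).tobytes())
    return h.hexdigest()


def _prep_images(slices: SliceSet, size: Tuple[int, int],
                 normalize: bool) -> np.ndarray:
    """Stack slice images into (N, H, W) float64, resized to `size`."""
    out = np.empty((len(slices), size[0], size[1]))
    for i, r in enumerate(slices):
        img = np.asarray(r.image, dtype=float)
        if img.shape != tuple(size):
            img = resize(img, size, anti_aliasing=True, preserve_range=True)
        if normalize:
            lo, hi = img.min(), img.max()
            img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
        out[i] = img
    return out


def _check_labels(slices: SliceSet) -> List[str]:
    labels = [r.label for r in slices]
    if any(l is None for l in labels):
        raise ValidationError("all slices must be labeled for training")
    return labels


# ---------------------------------------------------------------------------
# deterministic_texture backbone
# ---------------------------------------------------------------------------

class DeterministicTextureExtractor:
    """Pooled local texture statistics on a fixed grid.

    The image is resized to ``input_size`` and divided into a ``grid x
    grid`` cell mosaic; each cell contributes its mean, standard
    deviation, and mean absolute horizontal/vertical finite differences
    (4 * grid**2 features). Stateless: no parameters are learned.
    """

    name = "deterministic_texture"

    def __init__(self, spec: BackboneSpec, grid: int = 4):
        self.spec = spec
        self.grid = grid
        self.trained_on: Optional[frozenset] = None

    def body_digest(self) -> str:
        cfg = f"{self.name}|{self.spec.input_size}|{self.grid}".encode()
        return hashlib.sha256(cfg).hexdigest()

    @property
    def n_features(self) -> int:
        return 4 * self.grid * self.grid

    def transform(self, slices: SliceSet) -> FeatureMatrix:
        X = _prep_images(slices, self.spec.input_size, normalize=False)
        n, h, w = X.shape
        g = self.grid
        ch, cw = h // g, w // g
        X = X[:, :ch * g, :cw * g]
        cells = X.reshape(n, g, ch, g, cw)
        mean = cells.mean(axis=(2, 4))
        std = cells.std(axis=(2, 4))
        # per-cell gradient means (each cell's own finite differences)
        gx = np.zeros((n, g, g))
        gy = np.zeros((n, g, g))
        for a in range(g):
            for b in range(g):
                patch = X[:, a * ch:(a + 1) * ch, b * cw:(b + 1) * cw]
                gx[:, a, b] = np.abs(np.diff(patch, axis=2)).mean(axis=(1, 2))
                gy[:, a, b] = np.abs(np.diff(patch, axis=1)).mean(axis=(1, 2))
        feats = np.concatenate([
            mean.reshape(n, -1), std.reshape(n, -1),
            gx.reshape(n, -1), gy.reshape(n, -1),
        ], axis=1)
        ids = [r.sample_id for r in slices]
        return FeatureMatrix(feats, ids, [r.label for r in slices])


class TextureClassifier:
    """Deterministic texture features with a logistic-regression head."""

    name = "deterministic_texture"

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        self.extractor = DeterministicTextureExtractor(spec)
        self.seed = seed
        self._head: Optional[LogisticRegression] = None
        self.classes_: Optional[np.ndarray] = None
        self.trained_on: Optional[frozenset] = None
        self._frozen_body_digest: Optional[str] = None

    def body_digest(self) -> str:
        return self.extractor.body_digest()

    def head_digest(self) -> str:
        if self._head is None:
            return _digest([np.zeros(1)])
        return _digest([self._head.coef_, self._head.intercept_])

    def state(self) -> ModelState:
        return ModelState(self.body_digest(), self.head_digest(),
                          frozen={"body": True, "head": False})

    def fit(self, slices: SliceSet, cfg: TrainConfig) -> "TextureClassifier":
        labels = _check_labels(slices)
        classes = np.array(sorted(set(labels)))
        if len(classes) < 2:
            raise ValidationError("training requires >= 2 classes")
        if len(classes) != self.spec.head_classes:
            raise ValidationError(
                f"head expects {self.spec.head_classes} classes, "
                f"data has {len(classes)}"
            )
        fm = self.extractor.transform(slices)
        self._head = LogisticRegression(max_iter=2000, C=1.0,
                                        random_state=cfg.seed)
        self._head.fit(fm.X, labels)
        self.classes_ = self._head.classes_
        self.trained_on = frozenset(r.subject_id for r in slices)
        return self

    def predict_scores(self, slices: SliceSet) -> Tuple[np.ndarray, List[str]]:
        if self._head is None:
            raise ValidationError("classifier not fitted")
        fm = self.extractor.transform(slices)
        return self._head.predict_proba(fm.X), list(self.classes_)

    def transform(self, slices: SliceSet) -> FeatureMatrix:
        return self.extractor.transform(slices)

    def replace_head(self, n_new_classes: int, seed: int) -> None:
        self._frozen_body_digest = self.body_digest()
        self._head = None
        self.classes_ = None
        self.seed = seed
        self.spec = BackboneSpec(self.spec.name, self.spec.input_size,
                                 0, n_new_classes)


# ---------------------------------------------------------------------------
# reference_cnn backbone
# ---------------------------------------------------------------------------

class ReferenceCNN:
    """A small seeded convolutional classifier in pure numpy.

    Architecture: 3x3 conv (``n_filters`` maps, zero padding 1) -> ReLU ->
    ``pool x pool`` average pooling -> dense hidden layer (``n_hidden``,
    ReLU) -> dense softmax head. Trained with Adam on cross-entropy.
    The body is {conv, hidden}; the head is the final dense layer. The
    penultimate (hidden-layer) activations are the extracted features.
    """

    name = "reference_cnn"

    def __init__(self, spec: BackboneSpec, n_filters: int = 8,
                 n_hidden: int = 32, pool: int = 4, seed: int = 0):
        self.spec = spec
        self.n_filters = n_filters
        self.n_hidden = n_hidden
        self.pool = pool
        self.seed = seed
        h, w = spec.input_size
        if h % pool or w % pool:
            raise ValidationError("input_size must be divisible by the pool size")
        self._flat = n_filters * (h // pool) * (w // pool)
        rng = np.random.default_rng(seed)
        # He-style init for ReLU layers
        self.params = {
            "conv_W": rng.normal(0, np.sqrt(2 / 9), (n_filters, 9)),
            "conv_b": np.zeros(n_filters),
            "h_W": rng.normal(0, np.sqrt(2 / self._flat), (self._flat, n_hidden)),
            "h_b": np.zeros(n_hidden),
            "head_W": rng.normal(0, np.sqrt(1 / n_hidden),
                                 (n_hidden, spec.head_classes)),
            "head_b": np.zeros(spec.head_classes),
        }
        self.classes_: Optional[np.ndarray] = None
        self.trained_on: Optional[frozenset] = None
        self._frozen_body_digest: Optional[str] = None
        self.loss_history: List[float] = []

    # ---- parameter bookkeeping ----

    _BODY = ("conv_W", "conv_b", "h_W", "h_b")
    _HEAD = ("head_W", "head_b")

    def body_digest(self) -> str:
        return _digest([self.params[k] for k in self._BODY])

    def head_digest(self) -> str:
        return _digest([self.params[k] for k in self._HEAD])

    def state(self) -> ModelState:
        frozen = {k: k not in self._trainable_keys() for k in self.params}
        return ModelState(self.body_digest(), self.head_digest(), frozen)

    def _trainable_keys(self) -> List[str]:
        keys = list(self._HEAD)
        tail = self.spec.n_trainable_tail_layers
        if tail >= 1:
            keys += ["h_W", "h_b"]
        if tail >= 2:
            keys += ["conv_W", "conv_b"]
        return keys

    # ---- forward / backward ----

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        n, h, w = X.shape
        Xp = np.pad(X, ((0, 0), (1, 1), (1, 1)))
        return np.stack([Xp[:, u:u + h, v:v + w]
                         for u in range(3) for v in range(3)], axis=1)

    def _forward(self, X: np.ndarray) -> dict:
        n, h, w = X.shape
        p = self.pool
        cols = self._im2col(X)                              # (n, 9, h, w)
        conv = np.einsum("nkhw,fk->nfhw", cols, self.params["conv_W"])
        conv += self.params["conv_b"][None, :, None, None]
        relu1 = np.maximum(conv, 0)
        pooled = relu1.reshape(n, self.n_filters, h // p, p, w // p, p)
        pooled = pooled.mean(axis=(3, 5))
        flat = pooled.reshape(n, -1)
        hid = flat @ self.params["h_W"] + self.params["h_b"]
        relu2 = np.maximum(hid, 0)
        logits = relu2 @ self.params["head_W"] + self.params["head_b"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return {"cols": cols, "conv": conv, "flat": flat, "hid": hid,
                "relu2": relu2, "probs": probs, "shape": (n, h, w)}

    def _backward(self, cache: dict, y_onehot: np.ndarray) -> dict:
        n, h, w = cache["shape"]
        p = self.pool
        dlogits = (cache["probs"] - y_onehot) / n
        grads = {
            "head_W": cache["relu2"].T @ dlogits,
            "head_b": dlogits.sum(axis=0),
        }
        drelu2 = dlogits @ self.params["head_W"].T
        dhid = drelu2 * (cache["hid"] > 0)
        grads["h_W"] = cache["flat"].T @ dhid
        grads["h_b"] = dhid.sum(axis=0)
        dflat = dhid @ self.params["h_W"].T
        dpool = dflat.reshape(n, self.n_filters, h // p, w // p)
        dconv = np.repeat(np.repeat(dpool, p, axis=2), p, axis=3) / (p * p)
        dconv = dconv * (cache["conv"] > 0)
        grads["conv_W"] = np.einsum("nfhw,nkhw->fk", dconv, cache["cols"])
        grads["conv_b"] = dconv.sum(axis=(0, 2, 3))
        return grads

    # ---- training ----

    def fit(self, slices: SliceSet, cfg: TrainConfig) -> "ReferenceCNN":
        labels = _check_labels(slices)
        classes = np.array(sorted(set(labels)))
        if len(classes) < 2:
            raise ValidationError("training requires >= 2 classes")
        if len(classes) != self.spec.head_classes:
            raise ValidationError(
                f"head expects {self.spec.head_classes} classes, "
                f"data has {len(classes)}"
            )
        self.classes_ = classes
        cls_index = {c: i for i, c in enumerate(classes)}
        X = _prep_images(slices, self.spec.input_size, normalize=True)
        y = np.zeros((len(labels), len(classes)))
        for i, l in enumerate(labels):
            y[i, cls_index[l]] = 1.0
        rng = np.random.default_rng(cfg.seed)
        keys = self._trainable_keys()
        m = {k: np.zeros_like(self.params[k]) for k in keys}
        v = {k: np.zeros_like(self.params[k]) for k in keys}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        self.loss_history = []
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                cache = self._forward(X[idx])
                pr = np.clip(cache["probs"], 1e-12, None)
                losses.append(-float(np.mean(
                    np.log(pr[np.arange(len(idx)), y[idx].argmax(axis=1)]))))
                grads = self._backward(cache, y[idx])
                t += 1
                for k in keys:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1 ** t)
                    vh = v[k] / (1 - b2 ** t)
                    self.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            self.loss_history.append(float(np.mean(losses)))
        self.trained_on = frozenset(r.subject_id for r in slices)
        return self

    def predict_scores(self, slices: SliceSet) -> Tuple[np.ndarray, List[str]]:
        if self.classes_ is None:
            raise ValidationError("classifier not fitted")
        X = _prep_images(slices, self.spec.input_size, normalize=True)
        return self._forward(X)["probs"], list(self.classes_)

    def transform(self, slices: SliceSet) -> FeatureMatrix:
        """Penultimate-layer (hidden ReLU) activations as features."""
        X = _prep_images(slices, self.spec.input_size, normalize=True)
        cache = self._forward(X)
        feats = np.maximum(cache["hid"], 0)
        return FeatureMatrix(feats, [r.sample_id for r in slices],
                             [r.label for r in slices])

    def replace_head(self, n_new_classes: int, seed: int) -> None:
        self._frozen_body_digest = self.body_digest()
        rng = np.random.default_rng(seed)
        self.params["head_W"] = rng.normal(
            0, np.sqrt(1 / self.n_hidden), (self.n_hidden, n_new_classes))
        self.params["head_b"] = np.zeros(n_new_classes)
        self.classes_ = None
        self.spec = BackboneSpec(self.spec.name, self.spec.input_size,
                                 0, n_new_classes)


# ---------------------------------------------------------------------------
# public contract functions
# ---------------------------------------------------------------------------

def build_backbone(spec: BackboneSpec, seed: int = 0):
    if spec.name == "reference_cnn":
        return ReferenceCNN(spec, seed=seed)
    return TextureClassifier(spec, seed=seed)


def fit_extractor(backbone: BackboneSpec, images: SliceSet, cfg: TrainConfig):
    """Fit a feature extractor by training the configured tail + head.

    The returned object exposes ``transform(slices) -> FeatureMatrix``
    taken from the penultimate representation. The texture backbone has
    nothing to train and is returned as-is (its transform is stateless);
    the CNN backbone is trained on the parent labels.
    """
    model = build_backbone(backbone, seed=cfg.seed)
    if backbone.name == "deterministic_texture":
        model.extractor.trained_on = frozenset(r.subject_id for r in images)
        model.trained_on = model.extractor.trained_on
        return model
    model.fit(images, cfg)
    return model


def fit_classifier(backbone: BackboneSpec, images: SliceSet, cfg: TrainConfig):
    """Train a classifier whose ``predict_scores`` rows sum to 1.

    ``backbone.head_classes`` must equal the number of distinct labels in
    the data (e.g. four subclasses after decomposing two parent classes).
    """
    model = build_backbone(backbone, seed=cfg.seed)
    model.fit(images, cfg)
    return model


def freeze_and_replace_head(model, n_new_classes: int, seed: int = 0):
    """Freeze the trained body and attach a fresh head for a new task.

    Records the body parameter digest, replaces the head with a newly
    initialized one of ``n_new_classes`` outputs, and marks only the head
    trainable. Subsequent ``fit`` calls must leave the body digest
    unchanged. Replacing the head again keeps only the latest head.
    """
    if n_new_classes < 2:
        raise ValidationError("n_new_classes must be >= 2")
    if getattr(model, "classes_", None) is None and model._frozen_body_digest is None:
        raise ValidationError("model must be trained before transfer")
    model.replace_head(n_new_classes, seed)
    return model


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(model, out_dir) -> None:
    """Save a classifier as a directory: JSON metadata + parameter blobs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "backbone": asdict(model.spec),
        "name": model.name,
        "body_digest": model.body_digest(),
        "head_digest": model.head_digest(),
        "classes": None if model.classes_ is None else list(map(str, model.classes_)),
    }
    if isinstance(model, ReferenceCNN):
        np.savez(out_dir / "params.npz", **model.params)
        meta["arch"] = {"n_filters": model.n_filters, "n_hidden": model.n_hidden,
                        "pool": model.pool, "seed": model.seed}
    else:
        if model._head is not None:
            np.savez(out_dir / "params.npz", coef=model._head.coef_,
                     intercept=model._head.intercept_,
                     classes=np.asarray(model._head.classes_, dtype=str))
        meta["arch"] = {"seed": model.seed}
    (out_dir / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(in_dir):
    in_dir = Path(in_dir)
    meta = json.loads((in_dir / "model.json").read_text())
    spec = BackboneSpec(**{k: tuple(v) if k == "input_size" else v
                           for k, v in meta["backbone"].items()})
    if meta["name"] == "reference_cnn":
        model = ReferenceCNN(spec, **{k: meta["arch"][k]
                                      for k in ("n_filters", "n_hidden", "pool", "seed")})
        data = np.load(in_dir / "params.npz")
        model.params = {k: data[k] for k in model.params}
    else:
        model = TextureClassifier(spec, seed=meta["arch"]["seed"])
        pfile = in_dir / "params.npz"
        if pfile.exists():
            data = np.load(pfile, allow_pickle=False)
            head = LogisticRegression(max_iter=2000)
            head.coef_ = data["coef"]
            head.intercept_ = data["intercept"]
            head.classes_ = data["classes"]
            model._head = head
    if meta["classes"] is not None:
        model.classes_ = np.array(meta["classes"])
    return model
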