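"""Class decomposition: cluster each class into subclasses and back.

Class decomposition eases the learning of irregular class boundaries by
splitting each parent class into k subclasses (k-means within the class),
relabeling samples with subclass labels, training a classifier on the
subclass problem, and reassembling subclass predictions back to parent
classes. Dimensionality is first reduced with PCA (features are
standardized after reduction), and silhouette scores per parent class
diagnose how well-separated the discovered subclasses are.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.preprocessing import StandardScaler

from .exceptions import ValidationError
from .volume_io import SliceRecord, SliceSet

logger = logging.getLogger(__name__)

SUBCLASS_SEP = "#"


@dataclass
class FeatureMatrix:
    """An (n_samples, n_features) matrix with aligned ids and labels."""

    X: np.ndarray
    sample_ids: List[str]
    labels: List[Optional[str]]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2D")
        if len(self.sample_ids) != self.X.shape[0] or len(self.labels) != self.X.shape[0]:
            raise ValidationError("sample_ids and labels must align with rows of X")
        if not np.isfinite(self.X).all():
            raise ValidationError("feature matrix must be finite")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class DecompositionMap:
    """Bijection between parent classes and subclass labels.

    ``subclass_of`` maps each subclass label back to its parent;
    ``assignments`` maps sample_id -> subclass label. Subclass labels use
    the invertible syntax ``"<parent>#<cluster_index>"``.
    """

    k_per_class: Dict[str, int]
    subclass_of: Dict[str, str]
    assignments: Dict[str, str]
    centroids: Dict[str, np.ndarray]
    seed: int

    def parent(self, subclass_label: str) -> str:
        if subclass_label not in self.subclass_of:
            raise ValidationError(f"unknown subclass label: {subclass_label!r}")
        return self.subclass_of[subclass_label]

    @property
    def subclass_labels(self) -> List[str]:
        return sorted(self.subclass_of)

    def to_json(self) -> str:
        return json.dumps({
            "k_per_class": self.k_per_class,
            "subclass_of": self.subclass_of,
            "assignments": self.assignments,
            "centroids": {k: v.tolist() for k, v in self.centroids.items()},
            "seed": self.seed,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecompositionMap":
        d = json.loads(text)
        return cls(
            k_per_class=d["k_per_class"],
            subclass_of=d["subclass_of"],
            assignments=d["assignments"],
            centroids={k: np.asarray(v) for k, v in d["centroids"].items()},
            seed=d["seed"],
        )


class ReductionModel:
    """PCA projection plus post-reduction standardization, fitted once.

    ``n_components`` may be an integer count or a fraction in (0, 1), in
    which case the smallest count reaching that explained-variance share
    is selected. Fitted on training rows only to avoid leakage.
    """

    def __init__(self, n_components: Union[int, float] = 0.95):
        self.n_components = n_components
        self._pca: Optional[PCA] = None
        self._scaler: Optional[StandardScaler] = None
        self.trained_on: Optional[frozenset] = None

    @property
    def fitted(self) -> bool:
        return self._pca is not None

    def fit(self, train: FeatureMatrix) -> "ReductionModel":
        if self.fitted:
            raise ValidationError("ReductionModel is fitted exactly once")
        n, p = train.X.shape
        if n < 2:
            raise ValidationError("need at least 2 samples to fit a reduction")
        nc = self.n_components
        if isinstance(nc, int):
            if nc > min(n, p):
                raise ValidationError(
                    f"requested {nc} components from {n} samples x {p} features"
                )
        # sklearn's fractional n_components uses full SVD; cap at min(n,p)
        self._pca = PCA(n_components=nc, svd_solver="full", random_state=0)
        Z = self._pca.fit_transform(train.X)
        self._scaler = StandardScaler().fit(Z)
        self.trained_on = frozenset(train.sample_ids)
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not self.fitted:
            raise ValidationError("ReductionModel not fitted")
        Z = self._scaler.transform(self._pca.transform(fm.X))
        return FeatureMatrix(Z, list(fm.sample_ids), list(fm.labels))

    def inverse_transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if not self.fitted:
            raise ValidationError("ReductionModel not fitted")
        X = self._pca.inverse_transform(self._scaler.inverse_transform(fm.X))
        return FeatureMatrix(X, list(fm.sample_ids), list(fm.labels))

    @property
    def n_components_(self) -> int:
        return int(self._pca.n_components_)

    @property
    def explained_variance_ratio_(self) -> np.ndarray:
        return self._pca.explained_variance_ratio_


def fit_reduction(train: FeatureMatrix,
                  n_components: Union[int, float] = 0.95) -> ReductionModel:
    """Fit a :class:`ReductionModel` on training data only."""
    return ReductionModel(n_components).fit(train)


def subclass_label(parent: str, idx: int) -> str:
    return f"{parent}{SUBCLASS_SEP}{idx}"


def decompose(train: FeatureMatrix, k_per_class: Union[int, Dict[str, int]] = 2,
              seed: int = 0, allow_fallback: bool = True) -> DecompositionMap:
    """Cluster each parent class into k subclasses with seeded k-means.

    Classes with fewer samples than the requested k fall back to k=1 with
    a logged warning (or raise when ``allow_fallback`` is False).
    Deterministic given (data, k_per_class, seed): 10 restarts, tolerance
    1e-6, at most 300 iterations.
    """
    labels = [l for l in train.labels]
    if any(l is None for l in labels):
        raise ValidationError("decompose requires labeled samples")
    classes = sorted(set(labels))
    if isinstance(k_per_class, int):
        k_per_class = {c: k_per_class for c in classes}
    subclass_of: Dict[str, str] = {}
    assignments: Dict[str, str] = {}
    centroids: Dict[str, np.ndarray] = {}
    k_used: Dict[str, int] = {}
    for c in classes:
        idx = [i for i, l in enumerate(labels) if l == c]
        k = int(k_per_class.get(c, 1))
        if k < 1:
            raise ValidationError(f"k for class {c!r} must be >= 1")
        if len(idx) < k:
            if not allow_fallback:
                raise ValidationError(
                    f"class {c!r} has {len(idx)} samples < k={k}"
                )
            logger.warning("class %r has %d samples < k=%d; falling back to k=1",
                           c, len(idx), k)
            k = 1
        Xc = train.X[idx]
        if k == 1:
            assign = np.zeros(len(idx), dtype=int)
            cents = Xc.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=k, n_init=10, tol=1e-6, max_iter=300,
                        random_state=seed)
            assign = km.fit_predict(Xc)
            cents = km.cluster_centers_
        # relabel clusters by ascending centroid norm so numbering is
        # stable across runs regardless of k-means' internal ordering
        order = np.argsort(np.linalg.norm(cents, axis=1), kind="stable")
        remap = {old: new for new, old in enumerate(order)}
        nonempty = 0
        for j in range(k):
            lbl = subclass_label(c, remap[j])
            subclass_of[lbl] = c
            centroids[lbl] = cents[j]
            if (assign == j).any():
                nonempty += 1
        for row, a in zip(idx, assign):
            assignments[train.sample_ids[row]] = subclass_label(c, remap[a])
        k_used[c] = k
        if nonempty < k:
            logger.warning("class %r: only %d of %d clusters nonempty", c,
                           nonempty, k)
    return DecompositionMap(k_per_class=k_used, subclass_of=subclass_of,
                            assignments=assignments, centroids=centroids,
                            seed=seed)


def relabel(dataset: Union[SliceSet, FeatureMatrix],
            dmap: DecompositionMap) -> Union[SliceSet, FeatureMatrix]:
    """Replace parent labels with subclass labels from the map.

    Every sample must be present in ``dmap.assignments``; the sample count
    is unchanged and mapping each new label through ``subclass_of``
    reproduces the original labels.
    """
    if isinstance(dataset, FeatureMatrix):
        new_labels = []
        for sid in dataset.sample_ids:
            if sid not in dmap.assignments:
                raise ValidationError(f"sample {sid!r} not in decomposition map")
            new_labels.append(dmap.assignments[sid])
        return FeatureMatrix(dataset.X, list(dataset.sample_ids), new_labels)
    records = []
    for r in dataset:
        if r.sample_id not in dmap.assignments:
            raise ValidationError(f"sample {r.sample_id!r} not in decomposition map")
        records.append(SliceRecord(
            image=r.image, subject_id=r.subject_id, slice_index=r.slice_index,
            label=dmap.assignments[r.sample_id], stratum=r.stratum,
            entropy=r.entropy,
        ))
    return SliceSet(records, provenance={**dataset.provenance,
                                         "relabeled": True})


def reassemble(pred, dmap: DecompositionMap, mode: str = "argmax_map",
               subclass_order: Optional[Sequence[str]] = None):
    """Map subclass predictions back to parent classes.

    Parameters
    ----------
    pred : sequence of subclass labels, or (n_samples, n_subclasses) scores
        Hard labels or per-subclass probability rows (each summing to 1).
    mode : {"argmax_map", "prob_sum"}
        argmax_map: parent of the highest-scoring (or given) subclass.
        prob_sum: parent score is the sum of its subclasses' scores; the
        prediction is the argmax parent.
    subclass_order : column order of `pred` when scores are given;
        defaults to ``dmap.subclass_labels`` (sorted).

    Returns
    -------
    parent_labels : list of str
    parent_scores : (n_samples, n_parents) array over sorted parents, or
        None when hard labels were given. Rows sum to 1.
    """
    if mode not in ("argmax_map", "prob_sum"):
        raise ValidationError(f"unknown reassembly mode: {mode}")
    arr = np.asarray(pred)
    parents = sorted(set(dmap.subclass_of.values()))
    if arr.ndim == 1 and arr.dtype.kind in "USO":
        # hard subclass labels
        return [dmap.parent(l) for l in pred], None
    if arr.ndim != 2:
        raise ValidationError("scores must be an (n_samples, n_subclasses) array")
    order = list(subclass_order) if subclass_order is not None else dmap.subclass_labels
    if arr.shape[1] != len(order):
        raise ValidationError("score columns do not match subclass order")
    for l in order:
        dmap.parent(l)  # raises on unknown subclass
    if (arr < 0).any():
        raise ValidationError("scores must be nonnegative")
    if mode == "prob_sum" and np.abs(arr.sum(axis=1) - 1).max() > 1e-6:
        raise ValidationError("prob_sum requires score rows summing to 1")
    parent_idx = {p: i for i, p in enumerate(parents)}
    member = np.zeros((len(order), len(parents)))
    for j, l in enumerate(order):
        member[j, parent_idx[dmap.parent(l)]] = 1.0
    if mode == "prob_sum":
        scores = arr @ member
    else:
        # winner-take-all on subclasses, then renormalized parent scores
        # carried over from the subclass mass for reporting
        scores = arr @ member
        winners = np.asarray(order)[arr.argmax(axis=1)]
        labels = [dmap.parent(w) for w in winners]
        with np.errstate(invalid="ignore"):
            norm = scores.sum(axis=1, keepdims=True)
            scores = np.where(norm > 0, scores / norm, 1.0 / len(parents))
        return labels, scores
    norm = scores.sum(axis=1, keepdims=True)
    scores = np.where(norm > 0, scores / norm, 1.0 / len(parents))
    labels = [parents[i] for i in scores.argmax(axis=1)]
    return labels, scores


def silhouette_by_class(features: FeatureMatrix,
                        dmap: DecompositionMap) -> Dict[str, Optional[float]]:
    """Mean silhouette of each parent class's subclass clustering.

    Computed within each parent over its own samples and subclass
    assignments, in the feature space given (the space clustering saw).
    Parents with fewer than 2 nonempty subclasses are reported as None.
    """
    out: Dict[str, Optional[float]] = {}
    parents = sorted(set(dmap.subclass_of.values()))
    for c in parents:
        idx = [i for i, l in enumerate(features.labels) if l == c]
        subs = [dmap.assignments.get(features.sample_ids[i]) for i in idx]
        if any(s is None for s in subs):
            raise ValidationError(f"class {c!r}: samples missing from map")
        if len(set(subs)) < 2:
            out[c] = None
            continue
        out[c] = float(silhouette_score(features.X[idx], subs, metric="euclidean"))
    return out
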