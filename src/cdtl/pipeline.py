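"""Two-stage class-decomposition transfer learning (CDTL).

Stage 1 trains the decomposed *base* classifier on an easy binary task
(disease vs control): select informative slices by GLCM entropy, fit a
feature extractor, reduce + scale the features, split each class into k
subclasses by k-means, and train a subclass classifier. Stage 2 transfers
the base classifier to the harder *target* task (stable vs progressive
impairment): freeze the body, attach a fresh binary head, train the head
on the target's middle slices.

Evaluation is subject-grouped: all slices of a subject stay on the same
side of every split, and stratified at the subject level. The
:class:`CDTL` model / :class:`CDTLResults` pair is the high-level
interface; ``train_base``/``transfer_to_target``/``run_cv`` are the
underlying operations.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import decomposition as dc
from . import evaluation as ev
from . import model_adapters as ma
from . import slice_selection as ss
from .exceptions import StageError, ValidationError
from .volume_io import SliceSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SliceRule:
    """How to pick informative slices: 'top_entropy', 'middle', or 'all'."""

    method: str = "top_entropy"
    n: int = 20

    def __post_init__(self):
        if self.method not in ("top_entropy", "middle", "all"):
            raise ValidationError(f"unknown slice rule: {self.method}")
        if self.n < 1:
            raise ValidationError("slice rule n must be >= 1")

    def apply(self, slices: SliceSet, glcm: ss.GLCMConfig) -> SliceSet:
        if self.method == "top_entropy":
            return ss.select_top_entropy(slices, self.n, glcm)
        if self.method == "middle":
            return ss.select_middle(slices, self.n)
        return slices


@dataclass(frozen=True)
class CDTLConfig:
    """All knobs of the two-stage procedure.

    Defaults mirror the published protocol: top-20 entropy slices for the
    base task, middle-30 for the target, k=2 subclasses per class, PCA to
    95% explained variance, 10 folds, a 90/10 subject holdout. The
    positive class defaults to the lexicographically first label (which
    matches both AD/CN and pMCI/sMCI naming); set it explicitly for other
    label schemes.
    """

    glcm: ss.GLCMConfig = field(default_factory=ss.GLCMConfig)
    base_slice_rule: SliceRule = field(
        default_factory=lambda: SliceRule("top_entropy", 20))
    target_slice_rule: SliceRule = field(
        default_factory=lambda: SliceRule("middle", 30))
    k_per_class: Union[int, Dict[str, int]] = 2
    reduction: Union[int, float] = 0.95
    backbone: ma.BackboneSpec = field(default_factory=ma.BackboneSpec)
    train: ma.TrainConfig = field(default_factory=ma.TrainConfig)
    reassembly_mode: str = "argmax_map"
    folds: int = 10
    holdout_fraction: float = 0.10
    oversample: bool = False
    oversample_by_stratum: bool = False
    decompose_target: bool = False
    aggregation: str = "slice_majority"
    positive_label: Optional[str] = None
    n_boot: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if not (0 < self.holdout_fraction < 1):
            raise ValidationError("holdout_fraction must be in (0, 1)")
        if self.aggregation not in ("slice_majority", "mean_score"):
            raise ValidationError(f"unknown aggregation: {self.aggregation}")


def _positive_label(classes: Sequence[str], cfg: CDTLConfig) -> str:
    if cfg.positive_label is not None:
        if cfg.positive_label not in classes:
            raise ValidationError(
                f"positive_label {cfg.positive_label!r} not among {list(classes)}")
        return cfg.positive_label
    return sorted(classes)[0]


def _subject_ids_of_samples(sample_ids) -> set:
    return {s.rsplit(":", 1)[0] for s in sample_ids}


@dataclass
class BaseModel:
    """The fitted stage-1 (decomposed base) classifier."""

    extractor: object
    reduction: dc.ReductionModel
    dmap: dc.DecompositionMap
    classifier: object
    parent_classes: List[str]
    config: CDTLConfig
    trained_subjects: frozenset
    silhouettes: Dict[str, Optional[float]]

    def predict_slices(self, slices: SliceSet):
        """Per-slice parent labels and parent score rows (sorted parents)."""
        scores, order = self.classifier.predict_scores(slices)
        labels, pscores = dc.reassemble(scores, self.dmap,
                                        mode=self.config.reassembly_mode,
                                        subclass_order=order)
        return labels, pscores, sorted(set(self.dmap.subclass_of.values()))


@dataclass
class TargetModel:
    """The fitted stage-2 (transferred) binary classifier."""

    classifier: object
    base_body_digest: str
    parent_classes: List[str]
    config: CDTLConfig
    trained_subjects: frozenset
    dmap: Optional[dc.DecompositionMap] = None

    def predict_slices(self, slices: SliceSet):
        scores, order = self.classifier.predict_scores(slices)
        if self.dmap is not None:
            labels, pscores = dc.reassemble(scores, self.dmap,
                                            mode=self.config.reassembly_mode,
                                            subclass_order=order)
            return labels, pscores, sorted(set(self.dmap.subclass_of.values()))
        labels = [order[i] for i in np.asarray(scores).argmax(axis=1)]
        return labels, np.asarray(scores), list(order)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as e:  # tag the failing stage
        if isinstance(e, StageError):
            raise
        raise StageError(name, e) from e


def train_base(base_data: SliceSet, cfg: CDTLConfig) -> BaseModel:
    """Train the decomposed base classifier.

    Order of stages: slice selection -> fit_extractor -> transform ->
    fit_reduction (+ scaling) -> decompose -> relabel -> fit_classifier
    on subclass labels.
    """
    classes = sorted({r.label for r in base_data})
    if None in classes or len(classes) != 2:
        raise ValidationError("base task requires two labeled parent classes")
    selected = _stage("slice_selection", cfg.base_slice_rule.apply,
                      base_data, cfg.glcm)
    ext_spec = replace(cfg.backbone, head_classes=len(classes))
    extractor = _stage("fit_extractor", ma.fit_extractor, ext_spec, selected,
                       cfg.train)
    features = _stage("transform", extractor.transform, selected)
    red = _stage("fit_reduction", dc.fit_reduction, features, cfg.reduction)
    reduced = red.transform(features)
    dmap = _stage("decompose", dc.decompose, reduced, cfg.k_per_class,
                  cfg.seed)
    sil = dc.silhouette_by_class(reduced, dmap)
    relabeled = _stage("relabel", dc.relabel, selected, dmap)
    n_sub = len(dmap.subclass_of)
    clf_spec = replace(cfg.backbone, head_classes=n_sub)
    classifier = _stage("fit_classifier", ma.fit_classifier, clf_spec,
                        relabeled, cfg.train)
    subjects = frozenset(base_data.subject_ids)
    for comp, comp_subjects in (
            ("extractor", extractor.trained_on),
            ("reduction", _subject_ids_of_samples(red.trained_on)),
            ("classifier", classifier.trained_on)):
        if comp_subjects is not None and not set(comp_subjects) <= subjects:
            raise StageError(comp, ValidationError(
                "component fitted on subjects outside the training set"))
    return BaseModel(extractor=extractor, reduction=red, dmap=dmap,
                     classifier=classifier, parent_classes=classes,
                     config=cfg, trained_subjects=subjects, silhouettes=sil)


def transfer_to_target(base: BaseModel, target_data: SliceSet,
                       cfg: CDTLConfig) -> TargetModel:
    """Transfer the base classifier to a binary target task.

    Applies the target slice rule, freezes the base classifier's body,
    replaces the head with a fresh binary one, and retrains the head
    only. The body digest is verified unchanged after retraining. When
    ``cfg.decompose_target`` is set the target classes are decomposed
    first (off by default: the published protocol trains the target
    directly as binary).
    """
    classes = sorted({r.label for r in target_data})
    if None in classes or len(classes) != 2:
        raise ValidationError("target task requires two labeled classes")
    selected = _stage("slice_selection", cfg.target_slice_rule.apply,
                      target_data, cfg.glcm)
    clf = copy.deepcopy(base.classifier)
    dmap = None
    train_set = selected
    n_new = 2
    if cfg.decompose_target:
        features = _stage("transform", base.extractor.transform, selected)
        red = _stage("fit_reduction", dc.fit_reduction, features, cfg.reduction)
        dmap = _stage("decompose", dc.decompose, red.transform(features),
                      cfg.k_per_class, cfg.seed)
        train_set = _stage("relabel", dc.relabel, selected, dmap)
        n_new = len(dmap.subclass_of)
    digest_before = clf.body_digest()
    clf = _stage("freeze_and_replace_head", ma.freeze_and_replace_head,
                 clf, n_new, cfg.seed)
    clf = _stage("fit_head", clf.fit, train_set, cfg.train)
    if clf.body_digest() != digest_before:
        raise RuntimeError(
            "internal consistency error: body parameters changed during "
            "head-only retraining")
    return TargetModel(classifier=clf, base_body_digest=digest_before,
                       parent_classes=classes, config=cfg,
                       trained_subjects=frozenset(target_data.subject_ids),
                       dmap=dmap)


def predict_subject(model: Union[BaseModel, TargetModel], slices: SliceSet,
                    aggregation: str = "slice_majority"):
    """Aggregate one subject's slice predictions to a subject decision.

    slice_majority: modal slice-level label; ties broken by the higher
    mean parent score. mean_score: average the parent score rows, then
    argmax. Returns ``(label, mean_scores_dict)``.
    """
    if len(slices) < 1:
        raise ValidationError("predict_subject needs >= 1 slice")
    if aggregation not in ("slice_majority", "mean_score"):
        raise ValidationError(f"unknown aggregation: {aggregation}")
    labels, scores, order = model.predict_slices(slices)
    mean_scores = np.asarray(scores).mean(axis=0)
    by_label = {l: float(s) for l, s in zip(order, mean_scores)}
    if aggregation == "mean_score":
        winner = order[int(mean_scores.argmax())]
        return winner, by_label
    votes: Dict[str, int] = {}
    for l in labels:
        votes[l] = votes.get(l, 0) + 1
    top = max(votes.values())
    tied = sorted(l for l, v in votes.items() if v == top)
    if len(tied) > 1:
        tied.sort(key=lambda l: (-by_label.get(l, 0.0), l))
    return tied[0], by_label


def grouped_stratified_folds(subject_labels: Dict[str, str], n_folds: int,
                             seed: int) -> List[Tuple[List[str], List[str]]]:
    """Subject-grouped, label-stratified folds.

    Within each class, subjects are shuffled (seeded) and dealt
    round-robin to folds, so every subject is held out exactly once and
    per-class fold sizes differ by at most one subject.
    """
    rng = np.random.default_rng(seed)
    by_class: Dict[str, List[str]] = {}
    for sid in sorted(subject_labels):
        by_class.setdefault(subject_labels[sid], []).append(sid)
    for c, subs in sorted(by_class.items()):
        if len(subs) < n_folds:
            raise ValidationError(
                f"class {c!r} has {len(subs)} subjects < {n_folds} folds")
    test_sets: List[List[str]] = [[] for _ in range(n_folds)]
    for c in sorted(by_class):
        subs = list(by_class[c])
        rng.shuffle(subs)
        for i, sid in enumerate(subs):
            test_sets[i % n_folds].append(sid)
    all_subjects = set(subject_labels)
    return [(sorted(all_subjects - set(t)), sorted(t)) for t in test_sets]


def holdout_split(data: SliceSet, cfg: CDTLConfig) -> Tuple[SliceSet, SliceSet]:
    """Single subject-grouped stratified split (1 - holdout_fraction) / holdout."""
    subject_labels = {sid: data.subject_label(sid) for sid in data.subject_ids}
    rng = np.random.default_rng(cfg.seed)
    test: List[str] = []
    by_class: Dict[str, List[str]] = {}
    for sid in sorted(subject_labels):
        by_class.setdefault(subject_labels[sid], []).append(sid)
    for c in sorted(by_class):
        subs = list(by_class[c])
        rng.shuffle(subs)
        n_test = max(1, int(round(len(subs) * cfg.holdout_fraction)))
        test.extend(subs[:n_test])
    train = sorted(set(subject_labels) - set(test))
    return data.subset_subjects(train), data.subset_subjects(sorted(test))


@dataclass
class FoldResult:
    """Evaluation of one CV fold at both reporting levels."""

    fold: int
    train_subjects: List[str]
    test_subjects: List[str]
    subject_report: ev.EvaluationReport
    slice_report: ev.EvaluationReport
    stratum_reports: Dict[str, ev.EvaluationReport] = field(default_factory=dict)
    #: subjects each fitted component actually saw (leakage audit trail)
    component_fit_subjects: Dict[str, frozenset] = field(default_factory=dict)


def _evaluate_model(model, test_data: SliceSet, cfg: CDTLConfig,
                    slice_rule: SliceRule, positive: str,
                    fold: Optional[int] = None) -> Tuple[ev.EvaluationReport,
                                                         ev.EvaluationReport,
                                                         Dict[str, ev.EvaluationReport]]:
    selected = slice_rule.apply(test_data, cfg.glcm)
    pos_col = None
    y_true_subj, y_pred_subj, score_subj, strata = [], [], [], []
    y_true_slice, y_pred_slice, score_slice = [], [], []
    for sid, sub in selected.groupby_subject():
        truth = sub.subject_label(sid)
        labels, scores, order = model.predict_slices(sub)
        if pos_col is None:
            pos_col = order.index(positive)
        pred, by_label = predict_subject(model, sub, cfg.aggregation)
        y_true_subj.append(truth)
        y_pred_subj.append(pred)
        score_subj.append(by_label[positive])
        strata.append(next(iter(sub)).stratum)
        y_true_slice.extend([truth] * len(sub))
        y_pred_slice.extend(labels)
        score_slice.extend(np.asarray(scores)[:, pos_col].tolist())
    subject_report = ev.evaluate_predictions(
        y_true_subj, y_pred_subj, positive, scores=score_subj,
        n_boot=cfg.n_boot, seed=cfg.seed, fold=fold)
    slice_report = ev.evaluate_predictions(
        y_true_slice, y_pred_slice, positive, scores=score_slice,
        n_boot=cfg.n_boot, seed=cfg.seed, fold=fold)
    stratum_reports: Dict[str, ev.EvaluationReport] = {}
    for st in sorted({s for s in strata if s is not None}):
        idx = [i for i, s in enumerate(strata) if s == st]
        stratum_reports[st] = ev.evaluate_predictions(
            [y_true_subj[i] for i in idx], [y_pred_subj[i] for i in idx],
            positive, scores=[score_subj[i] for i in idx],
            n_boot=cfg.n_boot, seed=cfg.seed, stratum=st, fold=fold)
    return subject_report, slice_report, stratum_reports


def run_cv(data: SliceSet, cfg: CDTLConfig, stage: str = "base",
           base_model: Optional[BaseModel] = None) -> List[FoldResult]:
    """Subject-grouped stratified cross-validation of either stage.

    Each fold trains on the remaining subjects' slices (optionally
    oversampled) and evaluates on the held-out subjects, reporting both
    subject-level and slice-level metrics. Reproducible given the seed.
    """
    if stage not in ("base", "target"):
        raise ValidationError("stage must be 'base' or 'target'")
    if stage == "target" and base_model is None:
        raise ValidationError("target stage requires a base_model")
    subject_labels = {sid: data.subject_label(sid) for sid in data.subject_ids}
    if any(l is None for l in subject_labels.values()):
        raise ValidationError("all subjects must be labeled")
    classes = sorted(set(subject_labels.values()))
    positive = _positive_label(classes, cfg)
    folds = grouped_stratified_folds(subject_labels, cfg.folds, cfg.seed)
    rule = cfg.base_slice_rule if stage == "base" else cfg.target_slice_rule
    results = []
    for i, (train_subjects, test_subjects) in enumerate(folds):
        train_data = data.subset_subjects(train_subjects)
        if cfg.oversample:
            train_data = ev.oversample(train_data,
                                       by_stratum=cfg.oversample_by_stratum,
                                       seed=cfg.seed + i)
        if stage == "base":
            model = train_base(train_data, cfg)
        else:
            model = transfer_to_target(base_model, train_data, cfg)
        # oversampled duplicates carry a "+dup" suffix on the origin id
        trained = {s.split("+dup")[0] for s in model.trained_subjects}
        if not trained <= set(train_subjects):
            raise RuntimeError("leakage: model trained on non-training subjects")
        components: Dict[str, frozenset] = {
            "classifier": frozenset(model.classifier.trained_on or ())}
        if stage == "base":
            components["extractor"] = frozenset(model.extractor.trained_on or ())
            components["reduction"] = frozenset(
                _subject_ids_of_samples(model.reduction.trained_on))
        test_data = data.subset_subjects(test_subjects)
        subject_report, slice_report, stratum_reports = _evaluate_model(
            model, test_data, cfg, rule, positive, fold=i)
        results.append(FoldResult(
            fold=i, train_subjects=list(train_subjects),
            test_subjects=list(test_subjects),
            subject_report=subject_report, slice_report=slice_report,
            stratum_reports=stratum_reports,
            component_fit_subjects=components))
    return results


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_base_model(model: BaseModel, out_dir) -> None:
    """Save a fitted BaseModel as a directory of JSON + array blobs."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ma.save_model(model.classifier, out / "classifier")
    ma.save_model(model.extractor, out / "extractor")
    pca = model.reduction._pca
    scaler = model.reduction._scaler
    np.savez(out / "reduction.npz", components=pca.components_,
             mean=pca.mean_, explained_variance=pca.explained_variance_,
             scaler_mean=scaler.mean_, scaler_scale=scaler.scale_)
    (out / "decomposition.json").write_text(model.dmap.to_json())
    (out / "meta.json").write_text(json.dumps({
        "parent_classes": model.parent_classes,
        "trained_subjects": sorted(model.trained_subjects),
        "silhouettes": model.silhouettes,
        "reduction_n_components": model.reduction.n_components
        if isinstance(model.reduction.n_components, int)
        else float(model.reduction.n_components),
    }, indent=2))


def load_base_model(in_dir, cfg: Optional[CDTLConfig] = None) -> BaseModel:
    """Load a BaseModel saved by :func:`save_base_model`."""
    import json
    from pathlib import Path
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler
    inp = Path(in_dir)
    meta = json.loads((inp / "meta.json").read_text())
    classifier = ma.load_model(inp / "classifier")
    extractor = ma.load_model(inp / "extractor")
    data = np.load(inp / "reduction.npz")
    red = dc.ReductionModel(meta["reduction_n_components"])
    pca = PCA(n_components=data["components"].shape[0])
    pca.components_ = data["components"]
    pca.mean_ = data["mean"]
    pca.explained_variance_ = data["explained_variance"]
    pca.n_components_ = data["components"].shape[0]
    scaler = StandardScaler()
    scaler.mean_ = data["scaler_mean"]
    scaler.scale_ = data["scaler_scale"]
    red._pca, red._scaler = pca, scaler
    red.trained_on = frozenset(f"{s}:0" for s in meta["trained_subjects"])
    dmap = dc.DecompositionMap.from_json(
        (inp / "decomposition.json").read_text())
    return BaseModel(extractor=extractor, reduction=red, dmap=dmap,
                     classifier=classifier,
                     parent_classes=meta["parent_classes"],
                     config=cfg or CDTLConfig(),
                     trained_subjects=frozenset(meta["trained_subjects"]),
                     silhouettes=meta["silhouettes"])


# ---------------------------------------------------------------------------
# statsmodels-style facade
# ---------------------------------------------------------------------------

class CDTL:
    """The two-stage CDTL model over a base and (optionally) a target task.

    Parameters
    ----------
    base_data : SliceSet
        Labeled slices of the easy binary task (e.g. disease vs control).
    target_data : SliceSet, optional
        Labeled slices of the hard binary task (e.g. stable vs
        progressive). When given, :meth:`fit` also runs the transfer stage.
    config : CDTLConfig, optional

    Examples
    --------
    >>> model = CDTL(base_slices, target_slices, config=CDTLConfig(seed=7))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, base_data: SliceSet,
                 target_data: Optional[SliceSet] = None,
                 config: Optional[CDTLConfig] = None):
        self.base_data = base_data
        self.target_data = target_data
        self.config = config or CDTLConfig()

    def fit(self) -> "CDTLResults":
        """Train on a (1 - holdout) subject split and evaluate the holdout."""
        cfg = self.config
        base_train, base_test = holdout_split(self.base_data, cfg)
        if cfg.oversample:
            base_train = ev.oversample(base_train,
                                       by_stratum=cfg.oversample_by_stratum,
                                       seed=cfg.seed)
        base_model = train_base(base_train, cfg)
        # the configured positive label may belong to the target task only
        positive_base = cfg.positive_label \
            if cfg.positive_label in base_model.parent_classes \
            else sorted(base_model.parent_classes)[0]
        base_report, base_slice_report, _ = _evaluate_model(
            base_model, base_test, cfg, cfg.base_slice_rule, positive_base)
        target_model = None
        target_report = target_slice_report = None
        if self.target_data is not None:
            tgt_train, tgt_test = holdout_split(self.target_data, cfg)
            if cfg.oversample:
                tgt_train = ev.oversample(tgt_train,
                                          by_stratum=cfg.oversample_by_stratum,
                                          seed=cfg.seed)
            target_model = transfer_to_target(base_model, tgt_train, cfg)
            positive_tgt = cfg.positive_label \
                if cfg.positive_label in target_model.parent_classes \
                else sorted(target_model.parent_classes)[0]
            target_report, target_slice_report, _ = _evaluate_model(
                target_model, tgt_test, cfg, cfg.target_slice_rule,
                positive_tgt)
        return CDTLResults(self, base_model, target_model, base_report,
                           base_slice_report, target_report,
                           target_slice_report)


def _fmt(x) -> str:
    return "undef" if x is None else f"{x:.4f}"


class CDTLResults:
    """Fitted CDTL stages with their holdout evaluations."""

    def __init__(self, model: CDTL, base_model: BaseModel,
                 target_model: Optional[TargetModel],
                 base_report, base_slice_report,
                 target_report, target_slice_report):
        self.model = model
        self.base_model = base_model
        self.target_model = target_model
        self.base_report = base_report
        self.base_slice_report = base_slice_report
        self.target_report = target_report
        self.target_slice_report = target_slice_report

    @property
    def silhouettes(self) -> Dict[str, Optional[float]]:
        """Per parent class mean silhouette of the base decomposition."""
        return self.base_model.silhouettes

    def cv(self, stage: str = "target") -> List[FoldResult]:
        """Cross-validate a stage on its full dataset."""
        if stage == "base":
            return run_cv(self.model.base_data, self.model.config, "base")
        if self.model.target_data is None:
            raise ValidationError("no target data attached")
        return run_cv(self.model.target_data, self.model.config, "target",
                      base_model=self.base_model)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Class-Decomposition Transfer Learning Results",
            "=" * 53,
            f"backbone: {cfg.backbone.name}    k per class: {cfg.k_per_class}"
            f"    seed: {cfg.seed}",
            f"base slice rule: {cfg.base_slice_rule.method}"
            f"(n={cfg.base_slice_rule.n})    "
            f"target: {cfg.target_slice_rule.method}"
            f"(n={cfg.target_slice_rule.n})",
            "-" * 53,
            "Base decomposition silhouettes:",
        ]
        for c, s in sorted(self.silhouettes.items()):
            lines.append(f"  {c}: {_fmt(s)}")
        for name, rep in (("Base task holdout (subject level)", self.base_report),
                          ("Target task holdout (subject level)",
                           self.target_report)):
            if rep is None:
                continue
            lines += [
                "-" * 53,
                f"{name}  [positive={rep.confusion.positive}, n={rep.n}]",
                f"  accuracy    {_fmt(rep.accuracy)}",
                f"  sensitivity {_fmt(rep.sensitivity)}"
                f"   specificity {_fmt(rep.specificity)}",
                f"  precision   {_fmt(rep.precision)}   f1          {_fmt(rep.f1)}",
            ]
            if rep.auc is not None:
                lo, hi = rep.auc_ci
                lines.append(
                    f"  auc         {rep.auc:.4f}   95% CI ({lo:.4f}, {hi:.4f})")
        lines.append("=" * 53)
        return "\n".join(lines)
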