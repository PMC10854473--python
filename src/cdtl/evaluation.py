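"""Binary-classification evaluation with imbalance-aware conveniences.

Confusion matrices, scalar metrics (accuracy, sensitivity/recall,
specificity, precision, F1), AUC by the rank (Mann-Whitney) formulation
with a seeded stratified bootstrap CI, per-stratum summaries, and
whole-subject minority-class oversampling.

Metrics whose denominator is zero (e.g. sensitivity when no positive
samples were evaluated) are reported as ``None`` — "undefined" — never
silently as 0 or 1. This matters for small strata containing a single
class, where accuracy can be 1.0 while F1 is meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .decomposition import FeatureMatrix
from .exceptions import ValidationError
from .volume_io import SliceRecord, SliceSet

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """2x2 counts ordered positive class first: [[TP, FN], [FP, TN]]."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive: str = "positive"
    negative: str = "negative"

    def __post_init__(self):
        for v in (self.tp, self.fn, self.fp, self.tn):
            if v < 0 or int(v) != v:
                raise ValidationError("confusion counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class EvaluationReport:
    """Scalar metrics tied to their confusion matrix.

    ``None`` marks an undefined metric (zero denominator or single-class
    scores for AUC).
    """

    confusion: ConfusionMatrix
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    auc: Optional[float] = None
    auc_ci: Optional[Tuple[float, float]] = None
    n: int = 0
    stratum: Optional[str] = None
    fold: Optional[int] = None

    @property
    def recall(self) -> Optional[float]:
        """Alias: recall and sensitivity are the same quantity."""
        return self.sensitivity

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "recall": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "f1": self.f1,
            "auc": self.auc, "auc_ci": self.auc_ci, "n": self.n,
            "stratum": self.stratum, "fold": self.fold,
            "confusion": {"tp": self.confusion.tp, "fn": self.confusion.fn,
                          "fp": self.confusion.fp, "tn": self.confusion.tn,
                          "positive": self.confusion.positive},
        }
        return d


def confusion(y_true: Sequence, y_pred: Sequence, positive) -> ConfusionMatrix:
    """Tally TP/FN/FP/TN with ``positive`` as the positive class."""
    if len(y_true) != len(y_pred):
        raise ValidationError("y_true and y_pred must have equal length")
    classes = set(y_true)
    if positive not in classes and len(classes) > 0:
        classes = classes | {positive}
    if len(classes) > 2:
        raise ValidationError(f"expected two classes, got {sorted(map(str, classes))}")
    unseen = set(y_pred) - classes
    if unseen:
        raise ValidationError(f"predictions contain unseen labels: {sorted(map(str, unseen))}")
    negative = next((c for c in sorted(map(str, classes)) if c != positive), "rest")
    tp = fn = fp = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp, fn, fp, tn, positive=str(positive),
                           negative=str(negative))


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(conf: ConfusionMatrix, stratum: Optional[str] = None,
            fold: Optional[int] = None) -> EvaluationReport:
    """Scalar metrics from a confusion matrix; zero denominators -> None."""
    if conf.total == 0:
        raise ValidationError("empty confusion matrix")
    acc = _ratio(conf.tp + conf.tn, conf.total)
    sens = _ratio(conf.tp, conf.tp + conf.fn)
    spec = _ratio(conf.tn, conf.tn + conf.fp)
    prec = _ratio(conf.tp, conf.tp + conf.fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return EvaluationReport(confusion=conf, accuracy=acc, sensitivity=sens,
                            specificity=spec, precision=prec, f1=f1,
                            n=conf.total, stratum=stratum, fold=fold)


def auc_mann_whitney(y_true: Sequence, scores: Sequence[float],
                     positive) -> Optional[float]:
    """AUC via average ranks; ties between classes count 0.5.

    Returns None when only one class is present.
    """
    y = np.asarray([t == positive for t in y_true])
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auc_with_ci(y_true: Sequence, scores: Sequence[float], positive,
                n_boot: int = 1000, seed: int = 0,
                alpha: float = 0.05):
    """AUC with a seeded stratified percentile-bootstrap CI.

    Resamples positives and negatives separately (so both classes appear
    in every replicate) and takes the (alpha/2, 1-alpha/2) percentiles of
    the bootstrap AUC distribution. Returns ``(auc, lo, hi)``; all None
    when only one class is present.
    """
    auc = auc_mann_whitney(y_true, scores, positive)
    if auc is None:
        return None, None, None
    y = np.asarray([t == positive for t in y_true])
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        ranks = rankdata(np.concatenate([bp, bn]))
        boots[b] = (ranks[:len(bp)].sum() - len(bp) * (len(bp) + 1) / 2) \
            / (len(bp) * len(bn))
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return auc, float(lo), float(hi)


def evaluate_predictions(y_true, y_pred, positive, scores=None,
                         n_boot: int = 1000, seed: int = 0,
                         stratum: Optional[str] = None,
                         fold: Optional[int] = None) -> EvaluationReport:
    """Convenience: confusion + metrics (+ AUC with CI when scores given)."""
    rep = metrics(confusion(y_true, y_pred, positive), stratum=stratum, fold=fold)
    if scores is not None:
        auc, lo, hi = auc_with_ci(y_true, scores, positive, n_boot=n_boot,
                                  seed=seed)
        rep.auc = auc
        rep.auc_ci = None if lo is None else (lo, hi)
    return rep


# ---------------------------------------------------------------------------
# oversampling
# ---------------------------------------------------------------------------

def _oversample_subjects(slices: SliceSet, seed: int,
                         subjects_by_class: Dict[str, List[str]]) -> List[SliceRecord]:
    """Duplicate whole minority-class subjects until class counts equalize."""
    rng = np.random.default_rng(seed)
    counts = {c: len(s) for c, s in subjects_by_class.items()}
    target = max(counts.values())
    extra: List[SliceRecord] = []
    for c in sorted(subjects_by_class):
        deficit = target - counts[c]
        if deficit == 0:
            continue
        picks = rng.choice(subjects_by_class[c], size=deficit, replace=True)
        for i, sid in enumerate(picks):
            new_id = f"{sid}+dup{i}"
            for r in slices.for_subject(sid):
                extra.append(SliceRecord(
                    image=r.image, subject_id=new_id,
                    slice_index=r.slice_index, label=r.label,
                    stratum=r.stratum, entropy=r.entropy,
                ))
    return extra


def oversample(data: Union[SliceSet, FeatureMatrix], by_stratum: bool = False,
               seed: int = 0) -> Union[SliceSet, FeatureMatrix]:
    """Balance binary class counts by duplicating minority samples.

    For a :class:`SliceSet`, duplication operates on whole subjects (all
    of a subject's slices are copied under a new suffixed subject id), so
    subject-grouped evaluation stays valid; counts equalized are subject
    counts. With ``by_stratum`` each stratum is balanced independently; a
    stratum containing a single class is left unchanged with a warning.
    All original samples are always retained. Intended for TRAINING data
    only; the pipeline enforces that.

    For a :class:`FeatureMatrix` each row is its own unit.
    """
    if isinstance(data, FeatureMatrix):
        labels = np.asarray(data.labels)
        classes = sorted(set(data.labels))
        if len(classes) != 2:
            raise ValidationError("oversample expects two classes")
        rng = np.random.default_rng(seed)
        counts = {c: int((labels == c).sum()) for c in classes}
        target = max(counts.values())
        rows, ids, labs = [data.X], list(data.sample_ids), list(data.labels)
        for c in classes:
            deficit = target - counts[c]
            if deficit:
                idx = np.flatnonzero(labels == c)
                picks = rng.choice(idx, size=deficit, replace=True)
                rows.append(data.X[picks])
                ids += [f"{data.sample_ids[i]}+dup{j}" for j, i in enumerate(picks)]
                labs += [c] * deficit
        return FeatureMatrix(np.vstack(rows), ids, labs)

    strata: Dict[Optional[str], List[str]] = {}
    for sid in data.subject_ids:
        rec = next(iter(data.for_subject(sid)))
        strata.setdefault(rec.stratum if by_stratum else None, []).append(sid)
    new_records = list(data.records)
    for s_i, (stratum, subjects) in enumerate(sorted(
            strata.items(), key=lambda kv: str(kv[0]))):
        by_class: Dict[str, List[str]] = {}
        for sid in subjects:
            lbl = data.subject_label(sid)
            if lbl is None:
                raise ValidationError(f"subject {sid!r} has no label")
            by_class.setdefault(lbl, []).append(sid)
        if len(by_class) < 2:
            logger.warning("stratum %r contains a single class; left unchanged",
                           stratum)
            continue
        if len(by_class) > 2:
            raise ValidationError("oversample expects binary labels")
        new_records.extend(_oversample_subjects(data, seed + s_i, by_class))
    return SliceSet(new_records, provenance={**data.provenance,
                                             "oversampled": True,
                                             "by_stratum": by_stratum})


def stratified_summary(reports: Sequence[EvaluationReport],
                       group_by: str = "stratum") -> pd.DataFrame:
    """Per-group mean and SD of each metric across fold reports.

    Groups on the report attribute named by ``group_by`` (``"stratum"``
    or ``"fold"``); a combined row labeled ``"all"`` aggregates every
    report. Undefined metrics are excluded from the mean/SD of their
    group (pandas NaN semantics).
    """
    cols = ["accuracy", "sensitivity", "specificity", "precision", "f1", "auc"]
    rows = []
    for r in reports:
        d = {c: (np.nan if getattr(r, c) is None else getattr(r, c)) for c in cols}
        d["group"] = getattr(r, group_by)
        d["n"] = r.n
        rows.append(d)
    df = pd.DataFrame(rows)
    df["group"] = df["group"].astype(object).where(df["group"].notna(), "unknown")
    out = []
    groups = sorted(df["group"].unique(), key=str)
    for g, sub in [(g, df[df["group"] == g]) for g in groups] + [("all", df)]:
        row = {"group": g, "n_reports": len(sub), "n_samples": int(sub["n"].sum())}
        for c in cols:
            row[f"{c}_mean"] = sub[c].mean()
            row[f"{c}_sd"] = sub[c].std(ddof=0) if len(sub) > 1 else 0.0
        out.append(row)
    return pd.DataFrame(out)
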