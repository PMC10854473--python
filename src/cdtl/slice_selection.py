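"""Informative-slice selection by gray-level co-occurrence entropy.

The axial slices at the center of a registered brain volume carry the most
texture; this module scores every slice by the entropy of its gray-level
co-occurrence matrix (GLCM) and selects either the top-N slices by entropy
(base task) or a centered window of N middle slices (target task).

The GLCM at offset (distance D, direction theta) is the joint distribution
p(i, j) of quantized gray levels at pixel pairs separated by that offset;
its entropy -sum p log p is maximal for complex texture and zero for a
constant image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .volume_io import SliceRecord, SliceSet

#: Row/column pixel offsets for the four standard GLCM directions.
#: Angles are measured counter-clockwise from the +column direction.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence parameters.

    distance : offset length D in pixels (>= 1)
    direction : one of {0, 45, 90, 135} degrees, or "mean4" to average the
        four per-angle normalized matrices entrywise
    levels : number of gray levels after quantization (>= 2)
    symmetric : count both orderings of each pixel pair
    log_base : "e" (entropy in nats) or "2" (bits)
    """

    distance: int = 1
    direction: object = 0
    levels: int = 64
    symmetric: bool = True
    log_base: str = "e"

    def __post_init__(self):
        if self.distance < 1:
            raise ValidationError("distance must be >= 1")
        if self.levels < 2:
            raise ValidationError("levels must be >= 2")
        if self.direction != "mean4" and self.direction not in _ANGLE_OFFSETS:
            raise ValidationError(
                f"direction must be one of {sorted(_ANGLE_OFFSETS)} or 'mean4'"
            )
        if self.log_base not in ("e", "2"):
            raise ValidationError("log_base must be 'e' or '2'")


@dataclass
class GLCMatrix:
    """A normalized co-occurrence matrix p(i, j) with its config."""

    p: np.ndarray
    config: GLCMConfig

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValidationError("GLCM must be square")
        if (self.p < 0).any():
            raise ValidationError("GLCM entries must be nonnegative")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValidationError("GLCM entries must sum to 1")


@dataclass(frozen=True)
class EntropyScore:
    subject_id: str
    slice_index: int
    entropy: float


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin an intensity image into ``levels`` gray levels.

    Bins [min, max] into ``levels`` equal-width bins:
    ``floor((x - min) / (max - min) * levels)`` clipped to ``levels - 1``.
    A constant image maps entirely to bin 0.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros(image.shape, dtype=np.int64)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _glcm_one_angle(image: np.ndarray, d: int, angle: int, levels: int,
                    symmetric: bool) -> np.ndarray:
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * d, dc * d
    h, w = image.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise DegenerateInputError(
            f"image of shape {image.shape} too small for offset "
            f"(D={d}, theta={angle})"
        )
    a = image[r0:r1, c0:c1].ravel()
    b = image[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(float)
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def compute_glcm(image: np.ndarray, config: GLCMConfig) -> GLCMatrix:
    """Compute the normalized GLCM of a quantized integer image.

    Counts co-occurrences of gray levels (i, j) at pixel pairs offset by
    distance D along the configured direction; with ``symmetric`` both
    orderings are counted. For ``"mean4"`` the four per-angle *normalized*
    matrices are averaged entrywise.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValidationError("GLCM input must be a 2D integer image")
    if image.min() < 0 or image.max() >= config.levels:
        raise ValidationError(
            f"image values must lie in [0, {config.levels})"
        )
    image = image.astype(np.int64)
    if config.direction == "mean4":
        mats = [
            _glcm_one_angle(image, config.distance, a, config.levels,
                            config.symmetric)
            for a in (0, 45, 90, 135)
        ]
        p = np.mean(mats, axis=0)
    else:
        p = _glcm_one_angle(image, config.distance, config.direction,
                            config.levels, config.symmetric)
    return GLCMatrix(p=p, config=config)


def glcm_entropy(glcm: GLCMatrix) -> float:
    """Entropy -sum p(i,j) log p(i,j) with 0 log 0 := 0.

    Units are nats for ``log_base='e'`` and bits for ``log_base='2'``.
    """
    p = glcm.p[glcm.p > 0]
    h = -float(np.sum(p * np.log(p)))
    if glcm.config.log_base == "2":
        h /= math.log(2)
    # guard tiny negative rounding on one-point distributions
    return max(h, 0.0)


def slice_entropy(image: np.ndarray, config: GLCMConfig) -> float:
    """Quantize a slice and return its GLCM entropy."""
    q = quantize(image, config.levels)
    return glcm_entropy(compute_glcm(q, config))


def rank_slices_by_entropy(slices: SliceSet,
                           config: Optional[GLCMConfig] = None) -> List[EntropyScore]:
    """Rank one subject's slices by GLCM entropy, descending.

    Ties are broken by ascending slice_index for determinism. All slices
    must come from a single subject: ranking is within-subject.
    """
    config = config or GLCMConfig()
    subjects = slices.subject_ids
    if len(subjects) > 1:
        raise ValidationError(
            f"rank_slices_by_entropy expects one subject, got {len(subjects)}"
        )
    scores = [
        EntropyScore(r.subject_id, r.slice_index,
                     slice_entropy(r.image, config))
        for r in slices
    ]
    return sorted(scores, key=lambda s: (-s.entropy, s.slice_index))


def select_top_entropy(slices: SliceSet, n: int = 20,
                       config: Optional[GLCMConfig] = None) -> SliceSet:
    """Per subject, keep the min(n, available) highest-entropy slices.

    The returned records carry their entropy score; within each subject
    they are ordered by descending entropy (ties by slice index).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    config = config or GLCMConfig()
    out = []
    for sid, sub in slices.groupby_subject():
        ranked = rank_slices_by_entropy(sub, config)
        keep = {s.slice_index: s.entropy for s in ranked[:n]}
        by_index = {r.slice_index: r for r in sub}
        for s in ranked[:n]:
            r = by_index[s.slice_index]
            out.append(SliceRecord(
                image=r.image, subject_id=r.subject_id,
                slice_index=r.slice_index, label=r.label,
                stratum=r.stratum, entropy=keep[s.slice_index],
            ))
    return SliceSet(out, provenance={**slices.provenance,
                                     "selection": f"top_entropy(n={n})"})


def select_middle(slices: SliceSet, n: int = 30) -> SliceSet:
    """Per subject, keep a centered contiguous window of min(n, N) slices.

    The window starts at floor((N - n) / 2) of the subject's slice-index
    order (0 when N <= n), where N is the subject's slice count.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    out = []
    for sid, sub in slices.groupby_subject():
        recs = sorted(sub.records, key=lambda r: r.slice_index)
        N = len(recs)
        start = max((N - n) // 2, 0)
        out.extend(recs[start:start + n])
    return SliceSet(out, provenance={**slices.provenance,
                                     "selection": f"middle(n={n})"})
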