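"""Download-free synthetic fixtures with the structure the pipeline assumes.

Three generators:

* :func:`make_phantom` — a volumetric texture phantom whose central axial
  band carries high-entropy (white-noise-like) texture while outer slices
  are smooth, so GLCM-entropy ranking must recover the central band.
* :func:`make_classification_task` — labeled 2D image sets where each
  class is a mixture of planted subclusters: images are linear mixtures
  of fixed smooth texture templates, with class and subcluster encoded as
  latent mixture weights. Subcluster separation is expressed in
  within-cluster standard-deviation units of the latent space.
* :func:`make_transfer_pair` — a base/target task pair drawn from the
  same template family, with target class means contracted toward each
  other (a harder task sharing feature structure, so transfer from the
  base task is beneficial by construction).

Slices within a subject share the subject's latent vector plus
independent slice noise, emulating the within-subject correlation that
makes subject-grouped cross-validation necessary. These generators do not
emulate anatomy, scanner physics, or atrophy patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .volume_io import SliceRecord, SliceSet, Volume3D

#: Latent dimensions: 0 = class axis, 1 = subcluster axis. Nuisance
#: variation comes from slice-level jitter and pixel noise.
_N_LATENT = 2
#: Templates are fixed across all tasks (shared feature structure).
_TEMPLATE_SEED = 20240917
#: Baseline class-mean separation (latent SD units) at class_overlap=0.
_BASE_CLASS_SEP = 12.0
#: Slice-level latent jitter around the subject latent (SD units).
_SLICE_NOISE_SD = 0.3
#: Pixel-level additive noise SD.
_PIXEL_NOISE_SD = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Texture phantom parameters.

    ``center_band_fraction`` of the axial depth (centered) is filled with
    high-variance texture of amplitude ``texture_scale``; outer slices
    hold smooth noise of amplitude ``background_noise``.
    """

    shape: Tuple[int, int, int] = (48, 48, 90)
    center_band_fraction: float = 1.0 / 3.0
    texture_scale: float = 1.0
    background_noise: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.shape[2] < 3:
            raise ValidationError("phantom depth must be >= 3")
        if not (0 < self.center_band_fraction <= 1):
            raise ValidationError("center_band_fraction must be in (0, 1]")
        if self.texture_scale <= self.background_noise:
            raise ValidationError("texture_scale must exceed background_noise")
        if self.background_noise < 0:
            raise ValidationError("background_noise must be >= 0")


@dataclass(frozen=True)
class TaskSpec:
    """Parameters of a synthetic labeled 2D classification task."""

    n_subjects_per_class: Dict[str, int] = field(
        default_factory=lambda: {"A": 20, "B": 20})
    slices_per_subject: int = 10
    n_subclusters_per_class: int = 2
    subcluster_separation: float = 8.0
    class_overlap: float = 0.0
    stratum_ratios: Optional[Dict[str, float]] = None
    image_size: Tuple[int, int] = (32, 32)
    #: "linear": classes separated along the class axis regardless of
    #: subcluster. "checkerboard": class means alternate sign with the
    #: subcluster (an XOR corner layout), so the class boundary is
    #: irregular and within-class bimodality is essential information.
    layout: str = "linear"
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.n_subjects_per_class.values()):
            raise ValidationError("need >= 1 subject per class")
        if self.slices_per_subject < 1 or self.n_subclusters_per_class < 1:
            raise ValidationError("counts must be >= 1")
        if self.subcluster_separation < 0 or self.class_overlap < 0:
            raise ValidationError("separation and overlap must be >= 0")
        if self.layout not in ("linear", "checkerboard"):
            raise ValidationError(f"unknown layout: {self.layout!r}")


@dataclass
class TaskData:
    """A generated task: slices plus hidden ground truth."""

    slices: SliceSet
    subject_class: Dict[str, str]
    subject_subcluster: Dict[str, int]

    def slice_subclusters(self) -> Dict[str, int]:
        """Hidden subcluster label per sample_id (slices inherit their
        subject's subcluster)."""
        return {r.sample_id: self.subject_subcluster[r.subject_id]
                for r in self.slices}


def band_indices(depth: int, fraction: float) -> List[int]:
    """Centered index band of round(depth * fraction) slices."""
    n_band = max(1, int(round(depth * fraction)))
    start = (depth - n_band) // 2
    return list(range(start, start + n_band))


def make_phantom(spec: PhantomSpec) -> Tuple[Volume3D, List[int]]:
    """Generate a texture phantom and its informative-band ground truth.

    Central-band slices are white noise plus a mid-scale component
    (maximal co-occurrence entropy after quantization); outer slices are
    heavily smoothed noise whose neighboring pixels are strongly
    correlated, hence lower GLCM entropy. With ``background_noise=0``
    outer slices are exactly constant (entropy 0).
    """
    h, w, depth = spec.shape
    rng = np.random.default_rng(spec.seed)
    truth = band_indices(depth, spec.center_band_fraction)
    band = set(truth)
    vox = np.zeros((h, w, depth))
    for k in range(depth):
        if k in band:
            plane = rng.normal(size=(h, w))
            plane += 0.3 * gaussian_filter(rng.normal(size=(h, w)), 2.0)
            vox[:, :, k] = spec.texture_scale * plane
        elif spec.background_noise > 0:
            smooth = gaussian_filter(rng.normal(size=(h, w)), 4.0)
            vox[:, :, k] = spec.background_noise * smooth
    vol = Volume3D(voxels=vox, spacing=(1.0, 1.0, 1.0),
                   axis_order=("sagittal", "coronal", "axial"),
                   subject_id=f"phantom{spec.seed}")
    return vol, truth


def _templates(image_size: Tuple[int, int]) -> np.ndarray:
    """Fixed smooth texture templates, one per latent dimension.

    Each template is a smooth random field confined to its own image
    quadrant (zero mean, unit SD within the quadrant, zero elsewhere), so
    pooled image statistics respond to each latent coordinate through its
    own spatial region and the planted geometry survives feature pooling
    without the axes mixing.
    """
    rng = np.random.default_rng(_TEMPLATE_SEED)
    h, w = image_size
    h2, w2 = h // 2, w // 2
    quads = [(0, 0), (0, w2), (h2, 0), (h2, w2)]
    out = np.zeros((_N_LATENT, h, w))
    for j in range(_N_LATENT):
        r0, c0 = quads[j % 4]
        block = gaussian_filter(rng.normal(size=(h2, w2)), min(h2, w2) / 4.0)
        block -= block.mean()
        out[j, r0:r0 + h2, c0:c0 + w2] = block / block.std()
    return out


def _allocate_strata(n: int, ratios: Optional[Dict[str, float]],
                     ) -> List[Optional[str]]:
    """Deterministic largest-remainder allocation of n subjects to strata."""
    if not ratios:
        return [None] * n
    keys = sorted(ratios)
    total = sum(ratios[k] for k in keys)
    exact = {k: n * ratios[k] / total for k in keys}
    counts = {k: int(np.floor(exact[k])) for k in keys}
    rem = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))[:rem]:
        counts[k] += 1
    out: List[Optional[str]] = []
    for k in keys:
        out.extend([k] * counts[k])
    return out


def _class_separation(class_overlap: float, sep_scale: float = 1.0) -> float:
    return _BASE_CLASS_SEP * np.exp(-class_overlap) * sep_scale


def make_classification_task(spec: TaskSpec, *, sep_scale: float = 1.0,
                             subject_prefix: str = "") -> TaskData:
    """Generate a labeled SliceSet with planted within-class subclusters.

    Latent geometry (unit within-cluster SD per dimension): class means
    sit at +/- sep/2 on latent axis 0 with sep = 12 * exp(-class_overlap);
    within each class, subcluster means are evenly spaced on axis 1 with
    spacing ``subcluster_separation``; remaining axes are nuisance. Each
    image is the latent-weighted sum of the fixed smooth templates plus
    small pixel noise. Cardinalities and strata match the spec exactly.
    """
    rng = np.random.default_rng(spec.seed)
    templates = _templates(spec.image_size)
    classes = sorted(spec.n_subjects_per_class)
    if len(classes) != 2:
        raise ValidationError("tasks are binary: give exactly 2 classes")
    csep = _class_separation(spec.class_overlap, sep_scale)
    S = spec.n_subclusters_per_class
    records: List[SliceRecord] = []
    subject_class: Dict[str, str] = {}
    subject_subcluster: Dict[str, int] = {}
    for ci, cls in enumerate(classes):
        n_subj = spec.n_subjects_per_class[cls]
        strata = _allocate_strata(n_subj, spec.stratum_ratios)
        for si in range(n_subj):
            sid = f"{subject_prefix}{cls}{si:04d}"
            sub = si % S  # exact, balanced subcluster allocation
            mean = np.zeros(_N_LATENT)
            if spec.layout == "checkerboard":
                mean[0] = (csep / 2.0) * (1 if (ci + sub) % 2 == 0 else -1)
            else:
                mean[0] = (ci - 0.5) * csep
            mean[1] = (sub - (S - 1) / 2.0) * spec.subcluster_separation
            subj_latent = mean + rng.normal(size=_N_LATENT)
            subject_class[sid] = cls
            subject_subcluster[sid] = sub
            for k in range(spec.slices_per_subject):
                latent = subj_latent + _SLICE_NOISE_SD * rng.normal(size=_N_LATENT)
                img = np.tensordot(latent, templates, axes=1)
                img += _PIXEL_NOISE_SD * rng.normal(size=spec.image_size)
                records.append(SliceRecord(
                    image=img, subject_id=sid, slice_index=k,
                    label=cls, stratum=strata[si],
                ))
    slices = SliceSet(records, provenance={"generator": "make_classification_task",
                                           "seed": spec.seed,
                                           "sep_scale": sep_scale})
    return TaskData(slices, subject_class, subject_subcluster)


def make_transfer_pair(base_spec: TaskSpec, target_shift: float = 0.5,
                       seed: Optional[int] = None) -> Tuple[TaskData, TaskData]:
    """A base task and a harder target task sharing feature structure.

    The target is drawn from the same template family with class means
    contracted toward each other by ``target_shift`` (fraction in [0, 1);
    0 means statistically identical to the base task). Target subjects
    are new, independent draws.
    """
    if not (0 <= target_shift < 1):
        raise ValidationError("target_shift must be in [0, 1)")
    base = make_classification_task(base_spec, subject_prefix="base-")
    tseed = base_spec.seed + 1 if seed is None else seed
    target_spec = replace(base_spec, seed=tseed)
    target = make_classification_task(target_spec,
                                      sep_scale=1.0 - target_shift,
                                      subject_prefix="tgt-")
    return base, target
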