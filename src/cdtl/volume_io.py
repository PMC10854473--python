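"""Volumetric image I/O and 2D axial slice datasets.

Reads registered 3D T1-weighted volumes (NIfTI), extracts ordered axial
slices, and persists slice datasets as PNG/JPEG images with a CSV manifest.
Volumes are assumed to be already preprocessed and registered upstream
(e.g. to MNI space); no skull stripping or resampling happens here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import DimensionalityError, ValidationError

logger = logging.getLogger(__name__)

#: Fixed manifest column order (documented interface).
MANIFEST_COLUMNS = ["subject_id", "slice_index", "label", "stratum", "path"]


@dataclass
class Volume3D:
    """A 3D voxel grid with spacing and axis-order metadata.

    Parameters
    ----------
    voxels : ndarray, shape (i, j, k)
        Scalar intensities, unmodified from the source file.
    spacing : tuple of float
        Per-axis voxel size in mm; all components > 0.
    axis_order : tuple of str
        Names of the three array axes; the axis named ``"axial"`` is the
        inferior->superior slicing direction.
    subject_id : str
        Opaque subject identifier.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    axis_order: tuple = ("sagittal", "coronal", "axial")
    subject_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.voxels.ndim} dimensions"
            )
        if any(d < 1 for d in self.voxels.shape):
            raise ValidationError("all volume dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing components must be > 0")
        if len(set(self.axis_order)) != 3:
            raise ValidationError("axis_order must name three distinct axes")
        if "axial" not in self.axis_order:
            raise ValidationError("axis_order must include an 'axial' axis")

    @property
    def axial_axis(self) -> int:
        return self.axis_order.index("axial")

    @property
    def n_axial_slices(self) -> int:
        return self.voxels.shape[self.axial_axis]


@dataclass
class SliceRecord:
    """A single 2D gray slice tied to its subject and position."""

    image: np.ndarray
    subject_id: str
    slice_index: int
    label: Optional[str] = None
    stratum: Optional[str] = None
    entropy: Optional[float] = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        if self.image.ndim != 2:
            raise DimensionalityError("slice image must be 2D")
        if self.slice_index < 0:
            raise ValidationError("slice_index must be >= 0")

    @property
    def sample_id(self) -> str:
        """Unique per-slice identifier used by decomposition assignments."""
        return f"{self.subject_id}:{self.slice_index}"


class SliceSet:
    """An ordered collection of :class:`SliceRecord` with provenance.

    Enforces uniqueness of ``(subject_id, slice_index)`` pairs.
    """

    def __init__(self, records: Iterable[SliceRecord], provenance: Optional[dict] = None):
        self.records = list(records)
        self.provenance = dict(provenance or {})
        seen = set()
        for r in self.records:
            key = (r.subject_id, r.slice_index)
            if key in seen:
                raise ValidationError(
                    f"duplicate (subject_id, slice_index) pair: {key}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SliceRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def subject_ids(self) -> list:
        """Unique subject ids in first-appearance order."""
        out, seen = [], set()
        for r in self.records:
            if r.subject_id not in seen:
                seen.add(r.subject_id)
                out.append(r.subject_id)
        return out

    @property
    def labels(self) -> list:
        return [r.label for r in self.records]

    def subject_label(self, subject_id: str) -> Optional[str]:
        """The (unique) label of a subject's slices.

        Raises
        ------
        ValidationError
            If the subject's slices carry inconsistent labels.
        """
        labels = {r.label for r in self.records if r.subject_id == subject_id}
        if len(labels) > 1:
            raise ValidationError(
                f"subject {subject_id!r} has inconsistent labels: {sorted(map(str, labels))}"
            )
        return labels.pop() if labels else None

    def subset_subjects(self, subjects: Iterable[str]) -> "SliceSet":
        wanted = set(subjects)
        return SliceSet(
            [r for r in self.records if r.subject_id in wanted],
            provenance={**self.provenance, "subset": True},
        )

    def for_subject(self, subject_id: str) -> "SliceSet":
        return self.subset_subjects([subject_id])

    def groupby_subject(self) -> Iterator[tuple]:
        for sid in self.subject_ids:
            yield sid, self.for_subject(sid)


def read_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) file into a :class:`Volume3D`.

    The axial axis is inferred from the header orientation codes; when the
    orientation is ambiguous the last array axis is assumed axial and a
    warning is logged (volumes registered to MNI space satisfy this).
    Intensities are returned unmodified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3D image, got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    names = ["sagittal", "coronal", "axial"]
    try:
        axcodes = nib.orientations.aff2axcodes(img.affine)
        # S/I codes mark the inferior->superior (axial slicing) axis.
        axial_axis = next(i for i, c in enumerate(axcodes) if c in ("S", "I"))
        # R/L -> sagittal, A/P -> coronal for the remaining axes.
        order = [None, None, None]
        order[axial_axis] = "axial"
        for i, c in enumerate(axcodes):
            if c in ("R", "L"):
                order[i] = "sagittal"
            elif c in ("A", "P"):
                order[i] = "coronal"
        if any(o is None for o in order):
            raise StopIteration
        axis_order = tuple(order)
    except StopIteration:
        logger.warning(
            "%s: ambiguous orientation header; assuming last axis is axial",
            path.name,
        )
        axis_order = ("sagittal", "coronal", "axial")
    return Volume3D(
        voxels=data,
        spacing=tuple(float(z) for z in zooms),
        axis_order=axis_order,
        subject_id=path.name.split(".")[0],
    )


def write_volume(vol: Volume3D, path) -> None:
    """Write a :class:`Volume3D` as NIfTI with its spacing in the header."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def extract_axial_slices(vol: Volume3D) -> SliceSet:
    """Re-slice a 3D volume into one 2D record per axial position.

    ``slice_index`` increases inferior->superior; the number of records
    equals the axial dimension of the volume.
    """
    ax = vol.axial_axis
    records = [
        SliceRecord(
            image=np.take(vol.voxels, k, axis=ax),
            subject_id=vol.subject_id,
            slice_index=k,
        )
        for k in range(vol.n_axial_slices)
    ]
    return SliceSet(records, provenance={"source": "extract_axial_slices",
                                         "subject_id": vol.subject_id})


def _rescale_per_volume(slices: SliceSet) -> dict:
    """Per-subject min-max ranges for 8-bit export.

    Rescaling is per-volume (not per-slice) so inter-slice intensity
    relations within a subject are preserved for entropy ranking.
    """
    ranges = {}
    for sid, sub in slices.groupby_subject():
        lo = min(float(r.image.min()) for r in sub)
        hi = max(float(r.image.max()) for r in sub)
        ranges[sid] = (lo, hi)
    return ranges


def write_slice_images(slices: SliceSet, out_dir, fmt: str = "png",
                       manifest_path=None) -> int:
    """Write one 8-bit image file per record plus a CSV manifest.

    Images are min-max rescaled per volume to [0, 255]. PNG is lossless;
    JPEG is supported for parity with legacy datasets and always logs a
    lossiness warning. Returns the number of manifest rows written.
    """
    fmt = fmt.lower()
    if fmt not in ("png", "jpeg", "jpg"):
        raise ValidationError(f"unsupported format: {fmt}")
    ext = "png" if fmt == "png" else "jpg"
    if fmt != "png":
        warnings.warn("JPEG is lossy; decoded pixels will deviate from the "
                      "8-bit originals", UserWarning, stacklevel=2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest_path is None:
        manifest_path = out_dir / "manifest.csv"
    ranges = _rescale_per_volume(slices)
    rows = []
    for r in slices:
        lo, hi = ranges[r.subject_id]
        span = hi - lo
        if span > 0:
            img8 = np.clip((r.image - lo) / span * 255.0, 0, 255).astype(np.uint8)
        else:
            img8 = np.zeros(r.image.shape, dtype=np.uint8)
        fname = f"{r.subject_id}_s{r.slice_index:04d}.{ext}"
        Image.fromarray(img8).save(out_dir / fname, quality=95)
        rows.append({
            "subject_id": r.subject_id,
            "slice_index": r.slice_index,
            "label": "" if r.label is None else r.label,
            "stratum": "" if r.stratum is None else r.stratum,
            "path": fname,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(manifest_path, index=False)
    return len(rows)


def read_slice_dataset(manifest_path) -> SliceSet:
    """Load a slice dataset from a manifest written by :func:`write_slice_images`.

    Labels and strata are attached from the manifest; empty cells become
    ``None``. Image paths are resolved relative to the manifest location.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"no such manifest: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype={"subject_id": str}, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest missing columns: {missing}")
    base = manifest_path.parent
    records = []
    for i, row in df.iterrows():
        img_path = base / str(row["path"])
        if not img_path.exists():
            raise FileNotFoundError(
                f"manifest row {i}: image file not found: {img_path}"
            )
        image = np.asarray(Image.open(img_path).convert("L"))
        records.append(SliceRecord(
            image=image,
            subject_id=str(row["subject_id"]),
            slice_index=int(row["slice_index"]),
            label=str(row["label"]) or None,
            stratum=str(row["stratum"]) or None,
        ))
    return SliceSet(records, provenance={"manifest": str(manifest_path)})
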