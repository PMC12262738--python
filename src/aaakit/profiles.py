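"""Core data model and I/O for aortic pixel-count profiles.

The whole toolkit operates on one simple signal per patient: the number of
segmented aorta pixels on each axial CTA slice, ordered superior to
inferior.  This module defines the containers for that signal
(:class:`SliceProfile`), for aneurysm extent annotations
(:class:`BoundaryAnnotation`), for binary mask stacks the profiles are
extracted from (:class:`MaskStack`), and for a set of patients
(:class:`Cohort`), together with CSV/TIFF/NIfTI readers and writers and the
8-bit contrast-stretch preprocessing step.

Conventions
-----------
* Slice index 0 is the most superior analyzed slice; indices increase
  toward the iliac bifurcation.
* Aneurysm boundaries are inclusive on both ends.
* Pixel counts are unit-less; no slice-thickness calibration is applied.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "SliceProfile",
    "BoundaryAnnotation",
    "MaskStack",
    "Cohort",
    "contrast_stretch",
    "extract_profile",
    "read_mask_stack",
    "load_cohort",
    "save_cohort",
]

PathLike = Union[str, Path]


@dataclass(frozen=True)
class SliceProfile:
    """One patient's ordered per-slice segmented-pixel counts.

    Parameters
    ----------
    patient_id
        Unique patient identifier.
    counts
        Non-negative integer pixel count per axial slice, index 0 being
        the most superior analyzed slice.
    """

    patient_id: str
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) < 1:
            raise ValueError(f"profile {self.patient_id!r}: needs at least one slice")
        if any(c < 0 for c in counts):
            raise ValueError(f"profile {self.patient_id!r}: negative pixel count")
        object.__setattr__(self, "counts", counts)

    @property
    def slice_count(self) -> int:
        return len(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class BoundaryAnnotation:
    """Inclusive start/end slice indices of an aneurysm (truth or prediction).

    ``present=False`` means no aneurysm; ``start``/``end`` are then ``None``.
    """

    patient_id: str
    present: bool
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.present:
            if self.start is None or self.end is None:
                raise ValueError(
                    f"annotation {self.patient_id!r}: present but start/end missing"
                )
            if not (0 <= self.start <= self.end):
                raise ValueError(
                    f"annotation {self.patient_id!r}: invalid interval "
                    f"[{self.start}, {self.end}]"
                )
        else:
            object.__setattr__(self, "start", None)
            object.__setattr__(self, "end", None)

    def slice_set(self) -> frozenset[int]:
        """The set of aneurysmal slice indices (empty when absent)."""
        if not self.present:
            return frozenset()
        return frozenset(range(self.start, self.end + 1))

    @property
    def extent(self) -> int:
        return 0 if not self.present else self.end - self.start + 1


@dataclass(frozen=True)
class MaskStack:
    """An ordered stack of same-shaped 2-D binary masks for one patient."""

    patient_id: str
    slices: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValueError(f"mask stack {self.patient_id!r}: empty")
        shape = self.slices[0].shape
        clean = []
        for i, s in enumerate(self.slices):
            arr = np.asarray(s)
            if arr.ndim != 2:
                raise ValueError(f"mask stack {self.patient_id!r}: slice {i} not 2-D")
            if arr.shape != shape:
                raise ValueError(
                    f"mask stack {self.patient_id!r}: slice {i} shape {arr.shape} "
                    f"differs from {shape}"
                )
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"mask stack {self.patient_id!r}: slice {i} has values other "
                    "than 0/1"
                )
            clean.append(arr.astype(np.uint8))
        object.__setattr__(self, "slices", tuple(clean))


@dataclass
class Cohort:
    """Profiles and (optionally) annotations for a set of patients."""

    profiles: dict[str, SliceProfile] = field(default_factory=dict)
    annotations: dict[str, BoundaryAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, prof in self.profiles.items():
            if prof.patient_id != pid:
                raise ValueError(f"profile keyed {pid!r} but carries id "
                                 f"{prof.patient_id!r}")
        for pid, ann in self.annotations.items():
            if pid not in self.profiles:
                raise ValueError(f"annotation for unknown patient {pid!r}")
            if ann.present and ann.end >= self.profiles[pid].slice_count:
                raise ValueError(
                    f"annotation {pid!r}: end {ann.end} beyond profile of "
                    f"{self.profiles[pid].slice_count} slices"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.profiles)

    def annotated_ids(self) -> list[str]:
        return sorted(self.annotations)

    def subset(self, ids: Sequence[str]) -> "Cohort":
        ids = list(ids)
        missing = [i for i in ids if i not in self.profiles]
        if missing:
            raise KeyError(f"patients not in cohort: {missing}")
        return Cohort(
            profiles={i: self.profiles[i] for i in ids},
            annotations={i: self.annotations[i] for i in ids if i in self.annotations},
        )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def contrast_stretch(
    image: np.ndarray, out_low: int = 10, out_high: int = 245
) -> np.ndarray:
    """Linearly map an image's intensity range onto ``[out_low, out_high]``.

    The affine map sends the image minimum to ``out_low`` and the maximum to
    ``out_high``; intermediate values are rounded half away from zero.  A
    constant image maps entirely to ``out_low``.

    Returns an 8-bit image.
    """
    if out_low >= out_high:
        raise ValueError("out_low must be < out_high")
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("cannot contrast-stretch an empty image")
    lo, hi = img.min(), img.max()
    if lo == hi:
        return np.full(img.shape, out_low, dtype=np.uint8)
    scaled = out_low + (img.astype(np.float64) - lo) * (out_high - out_low) / (hi - lo)
    return np.clip(_round_half_away(scaled), 0, 255).astype(np.uint8)


def extract_profile(stack: MaskStack) -> SliceProfile:
    """Count mask pixels per slice, preserving slice order."""
    counts = tuple(int(s.sum()) for s in stack.slices)
    return SliceProfile(patient_id=stack.patient_id, counts=counts)


def read_mask_stack(path: PathLike, patient_id: Optional[str] = None) -> MaskStack:
    """Read a binary mask stack from a multi-page TIFF or a NIfTI volume.

    Any nonzero voxel is treated as mask.  For NIfTI the slowest-varying
    axis (axis 0 after transposition of the canonical i,j,k volume) indexes
    slices.
    """
    path = Path(path)
    pid = patient_id or path.stem.split(".")[0]
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D NIfTI volume")
        slices = tuple((vol[:, :, k] != 0).astype(np.uint8) for k in range(vol.shape[2]))
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        pages = tifffile.imread(str(path))
        if pages.ndim == 2:
            pages = pages[None]
        slices = tuple((p != 0).astype(np.uint8) for p in pages)
    else:
        raise ValueError(f"{path}: unsupported mask-stack format")
    return MaskStack(patient_id=pid, slices=slices)


# ---------------------------------------------------------------------------
# cohort CSV I/O
# ---------------------------------------------------------------------------

PROFILE_COLUMNS = ["patient_id", "slice_index", "pixel_count"]
ANNOTATION_COLUMNS = ["patient_id", "start_slice", "end_slice", "present"]


def load_cohort(
    profiles_path: PathLike, annotations_path: Optional[PathLike] = None
) -> Cohort:
    """Load a cohort from the profiles CSV and optional annotations CSV.

    Profiles CSV: ``patient_id,slice_index,pixel_count`` with a 0-based
    contiguous ``slice_index`` per patient.  Annotations CSV:
    ``patient_id,start_slice,end_slice,present`` with empty start/end when
    ``present`` is 0.
    """
    df = pd.read_csv(profiles_path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{profiles_path}: missing columns {sorted(missing)}")

    profiles: dict[str, SliceProfile] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        pid = str(pid)
        dup = grp["slice_index"].duplicated()
        if dup.any():
            row = grp[dup].iloc[0]
            raise ValueError(
                f"{profiles_path}: duplicate slice_index {int(row['slice_index'])} "
                f"for patient {pid}"
            )
        grp = grp.sort_values("slice_index")
        idx = grp["slice_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ValueError(
                f"{profiles_path}: patient {pid} slice_index not 0-based contiguous"
            )
        counts = grp["pixel_count"].to_numpy()
        if (counts < 0).any():
            bad = int(idx[counts < 0][0])
            raise ValueError(
                f"{profiles_path}: negative pixel_count at patient {pid} "
                f"slice {bad}"
            )
        profiles[pid] = SliceProfile(patient_id=pid, counts=tuple(int(c) for c in counts))

    annotations: dict[str, BoundaryAnnotation] = {}
    if annotations_path is not None:
        adf = pd.read_csv(annotations_path)
        missing = set(ANNOTATION_COLUMNS) - set(adf.columns)
        if missing:
            raise ValueError(f"{annotations_path}: missing columns {sorted(missing)}")
        for _, row in adf.iterrows():
            pid = str(row["patient_id"])
            if pid not in profiles:
                raise ValueError(
                    f"{annotations_path}: annotation for patient {pid} with no profile"
                )
            present = bool(int(row["present"]))
            if present:
                if pd.isna(row["start_slice"]) or pd.isna(row["end_slice"]):
                    raise ValueError(
                        f"{annotations_path}: patient {pid} present=1 but empty "
                        "start/end"
                    )
                ann = BoundaryAnnotation(
                    patient_id=pid,
                    present=True,
                    start=int(row["start_slice"]),
                    end=int(row["end_slice"]),
                )
            else:
                ann = BoundaryAnnotation(patient_id=pid, present=False)
            if pid in annotations:
                raise ValueError(f"{annotations_path}: duplicate annotation for {pid}")
            annotations[pid] = ann

    return Cohort(profiles=profiles, annotations=annotations)


def save_cohort(
    cohort: Cohort,
    profiles_path: PathLike,
    annotations_path: Optional[PathLike] = None,
) -> None:
    """Write a cohort back to the CSV formats accepted by :func:`load_cohort`."""
    rows = [
        {"patient_id": pid, "slice_index": i, "pixel_count": c}
        for pid in cohort.patient_ids
        for i, c in enumerate(cohort.profiles[pid].counts)
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(profiles_path, index=False)

    if annotations_path is not None:
        arows = []
        for pid in cohort.annotated_ids():
            ann = cohort.annotations[pid]
            arows.append(
                {
                    "patient_id": pid,
                    "start_slice": ann.start if ann.present else "",
                    "end_slice": ann.end if ann.present else "",
                    "present": int(ann.present),
                }
            )
        pd.DataFrame(arows, columns=ANNOTATION_COLUMNS).to_csv(
            annotations_path, index=False
        )


def save_predictions(predictions: Mapping[str, BoundaryAnnotation], path: PathLike) -> None:
    """Write predicted boundaries in the annotations CSV dialect."""
    rows = []
    for pid in sorted(predictions):
        ann = predictions[pid]
        rows.append(
            {
                "patient_id": pid,
                "start_slice": ann.start if ann.present else "",
                "end_slice": ann.end if ann.present else "",
                "present": int(ann.present),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def load_predictions(path: PathLike) -> dict[str, BoundaryAnnotation]:
    """Read a predictions CSV (same dialect as annotations)."""
    adf = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(adf.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, BoundaryAnnotation] = {}
    for _, row in adf.iterrows():
        pid = str(row["patient_id"])
        present = bool(int(row["present"]))
        if present:
            out[pid] = BoundaryAnnotation(
                patient_id=pid, present=True,
                start=int(row["start_slice"]), end=int(row["end_slice"]),
            )
        else:
            out[pid] = BoundaryAnnotation(patient_id=pid, present=False)
    return out
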