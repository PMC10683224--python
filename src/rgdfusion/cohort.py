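"""Cohort preparation: labels from malignancy ratings, volume preprocessing,
and patient-disjoint cross-validation folds.

Label rule (LIDC-style 1-5 malignancy ratings, mean over readers):
mean <= 2.75 -> benign, mean >= 3.125 -> malignant, in between -> uncertain
(excluded downstream).  Volumes are resampled to 1 mm slice thickness, cropped
to 56x56x8 around the nodule centre and upsampled in-plane to 128x128 with
intensities min-max normalised to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeding import rng_for

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "UNCERTAIN",
    "NoduleVolume",
    "RatedNodule",
    "FoldSplit",
    "derive_label",
    "preprocess_volume",
    "make_folds",
    "load_manifest",
    "load_ratings",
    "read_nifti",
    "read_dicom_series",
]

BENIGN = "benign"
MALIGNANT = "malignant"
UNCERTAIN = "uncertain"

CROP_SHAPE = (8, 56, 56)  # (z, y, x)
TARGET_SHAPE = (8, 128, 128)
HU_WINDOW = (-1000.0, 400.0)  # standard lung window


@dataclass
class NoduleVolume:
    """One nodule voxel grid with spacing and provenance metadata.

    ``voxels`` is (z, y, x); ``spacing_mm`` is the voxel spacing in the same
    axis order.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patient_id: str = ""

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.voxels.shape)


@dataclass
class RatedNodule:
    """A nodule with its radiologist malignancy ratings and derived label."""

    patient_id: str
    ratings: tuple[float, ...]
    nodule_id: str = ""

    @property
    def mean_rating(self) -> float:
        return float(np.mean(self.ratings))

    @property
    def label(self) -> str:
        return derive_label(self.ratings)

    @property
    def included(self) -> bool:
        """Inclusion requires >= 3 readers and a non-uncertain label."""
        return len(self.ratings) >= 3 and self.label != UNCERTAIN


def derive_label(ratings) -> str:
    """Map malignancy ratings (each in [1, 5]) to benign/malignant/uncertain.

    The mean rating decides: <= 2.75 benign, >= 3.125 malignant, otherwise
    uncertain.  The boundary 2.75 goes to benign and 3.125 to malignant.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.size == 0:
        raise ValueError("at least one rating is required")
    if np.any((ratings < 1) | (ratings > 5)):
        raise ValueError("ratings must lie in [1, 5]")
    m = float(ratings.mean())
    if m <= 2.75:
        return BENIGN
    if m >= 3.125:
        return MALIGNANT
    return UNCERTAIN


def _window_normalize(v: np.ndarray) -> np.ndarray:
    """Window to the lung HU range when input looks like HU, then min-max."""
    v = np.asarray(v, dtype=np.float64)
    if v.min() < -0.5 or v.max() > 1.5:  # Hounsfield-unit input
        v = np.clip(v, *HU_WINDOW)
    lo, hi = float(v.min()), float(v.max())
    # constant volume maps to all-zeros; tolerance absorbs interpolation
    # ripple of order machine epsilon on constant fields
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def _crop_pad(v: np.ndarray, center: tuple[int, int, int], shape) -> np.ndarray:
    out = np.zeros(shape, dtype=np.float64)
    starts = [int(round(c)) - s // 2 for c, s in zip(center, shape)]
    src_lo = [max(0, st) for st in starts]
    src_hi = [min(dim, st + s) for st, s, dim in zip(starts, shape, v.shape)]
    dst_lo = [sl - st for sl, st in zip(src_lo, starts)]
    if all(hi > lo for lo, hi in zip(src_lo, src_hi)):
        sl_src = tuple(slice(lo, hi) for lo, hi in zip(src_lo, src_hi))
        sl_dst = tuple(
            slice(dlo, dlo + (hi - lo))
            for dlo, lo, hi in zip(dst_lo, src_lo, src_hi)
        )
        out[sl_dst] = v[sl_src]
    return out


def preprocess_volume(
    raw: NoduleVolume, center: tuple[int, int, int] | None = None
) -> NoduleVolume:
    """Standardise a raw volume to the 128x128x8 network input.

    Steps: resample z to 1 mm slice spacing (linear), crop 56x56x8 around
    ``center`` (zero-padded at borders; default centre of the volume), upsample
    in-plane to 128x128 (cubic), window + min-max normalise to [0, 1].
    """
    v = np.asarray(raw.voxels, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty volume")
    zs = float(raw.spacing_mm[0])
    if abs(zs - 1.0) > 1e-6:
        v = ndimage.zoom(v, (zs, 1.0, 1.0), order=1)
        if center is not None:
            center = (center[0] * zs, center[1], center[2])
    if center is None:
        center = tuple(s / 2 for s in v.shape)
    crop = _crop_pad(v, center, CROP_SHAPE)
    factors = (
        1.0,
        TARGET_SHAPE[1] / CROP_SHAPE[1],
        TARGET_SHAPE[2] / CROP_SHAPE[2],
    )
    up = ndimage.zoom(crop, factors, order=3)
    # cubic interpolation may overshoot; normalisation below re-ranges anyway
    out = _window_normalize(up)
    assert out.shape == TARGET_SHAPE
    return NoduleVolume(
        voxels=out.astype(np.float32),
        spacing_mm=(1.0, raw.spacing_mm[1] * CROP_SHAPE[1] / TARGET_SHAPE[1],
                    raw.spacing_mm[2] * CROP_SHAPE[2] / TARGET_SHAPE[2]),
        patient_id=raw.patient_id,
    )


@dataclass(frozen=True)
class FoldSplit:
    """Patient -> fold-index assignment for k-fold cross-validation."""

    fold_assignments: dict[str, int]
    k: int

    def fold_of(self, patient_id: str) -> int:
        return self.fold_assignments[patient_id]

    def test_patients(self, fold: int) -> set[str]:
        return {p for p, f in self.fold_assignments.items() if f == fold}

    def train_patients(self, fold: int) -> set[str]:
        return {p for p, f in self.fold_assignments.items() if f != fold}


def make_folds(nodules, k: int = 10, seed: int = 0) -> FoldSplit:
    """Patient-disjoint k-fold split balancing per-fold nodule counts.

    ``nodules`` is a sequence with a ``patient_id`` attribute (RatedNodule)
    or ``(.., .., patient_id)`` tuples.  All nodules of a patient land in the
    same fold.  Patients are shuffled deterministically by ``seed`` and then
    greedily assigned to the currently smallest fold (by nodule count), which
    keeps fold sizes as even as the patient grouping allows.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: dict[str, int] = {}
    for n in nodules:
        pid = n.patient_id if hasattr(n, "patient_id") else n[-1]
        counts[pid] = counts.get(pid, 0) + 1
    patients = sorted(counts)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, got {len(patients)}")
    rng = rng_for(seed, "folds", k)
    order = [patients[i] for i in rng.permutation(len(patients))]
    # largest patients first so the greedy balance is tight; shuffle breaks ties
    order.sort(key=lambda p: -counts[p])
    fold_sizes = [0] * k
    assign: dict[str, int] = {}
    for p in order:
        f = int(np.argmin(fold_sizes))
        assign[p] = f
        fold_sizes[f] += counts[p]
    return FoldSplit(fold_assignments=assign, k=k)


# ---------------------------------------------------------------------------
# readers


def load_manifest(manifest_csv: str | Path):
    """Load a raw-array cohort written by :func:`rgdfusion.phantom.write_cohort`.

    Returns a list of ``(NoduleVolume, label, patient_id)``.
    """
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv)
    root = manifest_csv.parent
    out = []
    for row in df.itertuples(index=False):
        path = root / row.file
        if path.suffix == ".npy":
            vox = np.load(path)
        else:
            vol = read_nifti(path, patient_id=str(row.patient_id))
            vox = vol.voxels
        out.append(
            (
                NoduleVolume(voxels=np.asarray(vox, dtype=np.float32),
                             patient_id=str(row.patient_id)),
                int(row.label),
                str(row.patient_id),
            )
        )
    return out


def load_ratings(ratings_csv: str | Path) -> list[RatedNodule]:
    """Ingest ratings from a CSV with columns
    ``patient_id, nodule_id, rating_1..rating_k`` (missing ratings blank)."""
    df = pd.read_csv(ratings_csv)
    rating_cols = [c for c in df.columns if c.startswith("rating_")]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ratings = tuple(
            float(d[c]) for c in rating_cols if pd.notna(d[c])
        )
        out.append(
            RatedNodule(
                patient_id=str(d["patient_id"]),
                nodule_id=str(d.get("nodule_id", "")),
                ratings=ratings,
            )
        )
    return out


def read_nifti(path: str | Path, patient_id: str = "") -> NoduleVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    return NoduleVolume(
        voxels=data.astype(np.float32),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        patient_id=patient_id,
    )


def read_dicom_series(directory: str | Path, patient_id: str = "") -> NoduleVolume:
    """Read a DICOM series directory into a (z, y, x) volume."""
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img).astype(np.float32)  # (z, y, x)
    sx, sy, sz = img.GetSpacing()
    return NoduleVolume(
        voxels=arr, spacing_mm=(float(sz), float(sy), float(sx)),
        patient_id=patient_id,
    )
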