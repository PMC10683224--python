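"""Synthetic lung-nodule phantoms.

Generates labelled 3D nodule crops so the whole classification pipeline can be
trained and evaluated at desk scale without a CT archive.  Two classes are
emulated in 56x56x8 voxel crops:

* **benign** - a smooth, homogeneous blob: an anisotropic ellipsoid softened by
  Gaussian blur.  Benign nodules on CT tend to have well-defined margins and
  uniform internal density.
* **malignant** - a spiculated, heterogeneous blob: an ellipsoid with radial
  spikes and a superimposed band-limited intensity texture.  Malignancy is
  associated with spiculated margins and increased internal heterogeneity,
  which is exactly the signal texture radiomics (LBP/HOG/GLCM) quantify.

One nodule per synthetic patient, so patient-disjoint cross-validation folds
are trivially well-defined.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._seeding import rng_for
from .cohort import NoduleVolume

__all__ = ["PhantomSpec", "generate_cohort", "write_cohort"]

BENIGN, MALIGNANT = 0, 1


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort.

    Attributes
    ----------
    n_per_class:
        Number of nodules per class (total cohort = 2x this).
    crop_shape:
        Voxel grid of each crop, (z, y, x).  Default 8 slices of 56x56,
        the crop size used around nodule centres in clinical CT pipelines.
    benign_smoothness:
        Gaussian blur sigma (voxels) applied to benign blobs.
    malignant_spike_count:
        Number of radial spicules added to each malignant nodule.
    malignant_texture_amplitude:
        Peak amplitude (fraction of the intensity range) of the band-limited
        heterogeneity texture inside malignant nodules.
    noise_sd:
        Standard deviation of additive Gaussian acquisition noise, as a
        fraction of the intensity range.
    seed:
        Master seed; identical specs generate bit-identical cohorts.
    """

    n_per_class: int = 100
    crop_shape: tuple[int, int, int] = (8, 56, 56)
    benign_smoothness: float = 2.0
    malignant_spike_count: int = 8
    malignant_texture_amplitude: float = 0.4
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.crop_shape) != 3 or any(s < 4 for s in self.crop_shape):
            raise ValueError("crop_shape must be 3 entries, each >= 4")
        if not 0.0 <= self.malignant_texture_amplitude <= 1.0:
            raise ValueError("malignant_texture_amplitude must be in [0, 1]")
        if self.malignant_spike_count < 0:
            raise ValueError("malignant_spike_count must be >= 0")


def _ellipsoid_distance(shape, center, radii, rng, wobble=0.0):
    """Normalised radial coordinate of an (optionally wobbled) ellipsoid."""
    zz, yy, xx = np.meshgrid(
        *(np.arange(s, dtype=np.float64) for s in shape), indexing="ij"
    )
    dz = (zz - center[0]) / radii[0]
    dy = (yy - center[1]) / radii[1]
    dx = (xx - center[2]) / radii[2]
    r = np.sqrt(dz * dz + dy * dy + dx * dx)
    if wobble > 0:
        # low-frequency boundary irregularity
        pert = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
        pert /= max(np.abs(pert).max(), 1e-12)
        r = r * (1.0 + wobble * pert)
    return r


def _bandlimited_texture(shape, rng, sigma_lo=0.7, sigma_hi=2.0):
    """Zero-mean band-limited noise field normalised to unit peak."""
    w = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(w, sigma_lo) - ndimage.gaussian_filter(w, sigma_hi)
    tex /= max(np.abs(tex).max(), 1e-12)
    return tex


def _benign_volume(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.crop_shape
    center = np.array(shape) / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    radii = np.array(
        [
            rng.uniform(1.8, 2.8),  # z: thin crop
            rng.uniform(9.0, 15.0),
            rng.uniform(9.0, 15.0),
        ]
    )
    r = _ellipsoid_distance(shape, center, radii, rng)
    vol = np.where(r <= 1.0, 0.75, 0.05).astype(np.float64)
    vol = ndimage.gaussian_filter(vol, sigma=spec.benign_smoothness)
    return vol


def _malignant_volume(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = spec.crop_shape
    center = np.array(shape) / 2.0 + rng.uniform(-1.5, 1.5, size=3)
    radii = np.array(
        [
            rng.uniform(1.6, 2.6),
            rng.uniform(7.0, 12.0),
            rng.uniform(7.0, 12.0),
        ]
    )
    r = _ellipsoid_distance(shape, center, radii, rng, wobble=0.25)
    core = r <= 1.0
    vol = np.where(core, 0.75, 0.05).astype(np.float64)

    # radial spicules: thin cones extending past the core boundary
    zz, yy, xx = np.meshgrid(
        *(np.arange(s, dtype=np.float64) for s in shape), indexing="ij"
    )
    pos = np.stack([zz - center[0], yy - center[1], xx - center[2]])
    dist = np.sqrt((pos**2).sum(axis=0)) + 1e-9
    unit = pos / dist
    mean_r = float(radii.mean())
    for _ in range(spec.malignant_spike_count):
        d = rng.standard_normal(3)
        d[0] *= 0.3  # mostly in-plane, as spiculation presents on axial slices
        d /= np.linalg.norm(d) + 1e-12
        align = (unit * d[:, None, None, None]).sum(axis=0)
        length = mean_r * rng.uniform(1.3, 1.8)
        spike = (align > 0.96) & (dist < length)
        vol[spike] = np.maximum(vol[spike], 0.7)

    # internal heterogeneity: band-limited texture confined to the nodule
    tex = _bandlimited_texture(shape, rng)
    vol = vol + spec.malignant_texture_amplitude * tex * core
    vol = ndimage.gaussian_filter(vol, sigma=0.8)
    return vol


def generate_cohort(spec: PhantomSpec) -> list[tuple[NoduleVolume, int, str]]:
    """Generate a balanced, labelled phantom cohort.

    Returns a list of ``(volume, label, patient_id)`` with exactly
    ``2 * n_per_class`` entries (labels 0 = benign, 1 = malignant), one unique
    patient per nodule, and voxel intensities in [0, 1].  Bit-identical for
    identical specs.
    """
    spec.validate()
    out: list[tuple[NoduleVolume, int, str]] = []
    for label, maker, tag in (
        (BENIGN, _benign_volume, "benign"),
        (MALIGNANT, _malignant_volume, "malignant"),
    ):
        for i in range(spec.n_per_class):
            rng = rng_for(spec.seed, "phantom", tag, i)
            vol = maker(spec, rng)
            if spec.noise_sd > 0:
                vol = vol + rng.normal(0.0, spec.noise_sd, size=vol.shape)
            vol = np.clip(vol, 0.0, 1.0)
            pid = f"P{tag[0].upper()}{i:04d}"
            out.append(
                (
                    NoduleVolume(
                        voxels=vol.astype(np.float32),
                        spacing_mm=(1.0, 1.0, 1.0),
                        patient_id=pid,
                    ),
                    label,
                    pid,
                )
            )
    return out


def write_cohort(
    cohort: list[tuple[NoduleVolume, int, str]],
    outdir: str | Path,
    fmt: str = "npy",
) -> Path:
    """Export a cohort as NIfTI or raw ``.npy`` volumes with a CSV manifest.

    The manifest (``manifest.csv``) columns are ``patient_id,label,file`` and
    are the ingestion contract of :mod:`rgdfusion.cohort`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if fmt not in {"npy", "nifti"}:
        raise ValueError(f"unknown export format: {fmt!r}")
    rows = []
    for vol, label, pid in cohort:
        if fmt == "npy":
            fname = f"{pid}.npy"
            np.save(outdir / fname, vol.voxels)
        else:
            import nibabel as nib

            fname = f"{pid}.nii"
            # NIfTI is (x, y, z); our arrays are (z, y, x)
            img = nib.Nifti1Image(
                np.asarray(vol.voxels).transpose(2, 1, 0), affine=np.eye(4)
            )
            nib.save(img, outdir / fname)
        rows.append({"patient_id": pid, "label": label, "file": fname})
    with open(outdir / "manifest.csv", "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["patient_id", "label", "file"])
        w.writeheader()
        w.writerows(rows)
    return outdir / "manifest.csv"
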