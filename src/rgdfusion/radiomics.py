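"""3D texture radiomics: volume LBP, 3D HOG and 3D GLCM descriptors.

The radiomics vector FR for one nodule is the concatenation of

* a volume local-binary-pattern histogram: for each interior voxel a
  (3P+2)-bit pattern built from thresholded intensity differences against the
  centre voxel -- the centre pixels of the slices L above and below, plus the P
  circular neighbours at radius R in the previous, current and next slice;
* a 3D histogram-of-oriented-gradients descriptor over an in-plane azimuth and
  an elevation angle, cell-wise and magnitude-weighted;
* energy / entropy / contrast / homogeneity of grey-level co-occurrence
  matrices along the 13 unique directions of the 26-neighbourhood, at
  distances 1,2,4,8 in-plane and 1,2,3,4 for directions with a z component.

All intensities are assumed in [0, 1] (cohort preprocessing guarantees this).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cohort import NoduleVolume

__all__ = [
    "LBPParams",
    "HOGParams",
    "GLCMParams",
    "RadiomicsVector",
    "lbp3d_histogram",
    "hog3d_descriptor",
    "glcm3d_features",
    "radiomics_vector",
    "GLCM_DIRECTIONS_INPLANE",
    "GLCM_DIRECTIONS_Z",
    "glcm_feature_names",
]


@dataclass(frozen=True)
class LBPParams:
    """Volume-LBP parameters: slice interval L, neighbours P, radius R."""

    L: int = 1
    P: int = 4
    R: float = 1.0

    def validate(self) -> None:
        if self.P < 1 or self.R <= 0 or self.L < 1:
            raise ValueError("require P >= 1, R > 0, L >= 1")

    @property
    def n_bits(self) -> int:
        return 3 * self.P + 2

    @property
    def n_patterns(self) -> int:
        return 2**self.n_bits


@dataclass(frozen=True)
class HOGParams:
    """3D-HOG geometry: cell tiling and orientation binning.

    Azimuth (the gradient projected to the XY plane) is binned unsigned over
    [0, pi); elevation (angle against the XY plane) over [-pi/2, pi/2].
    ``block_shape`` counts cells per normalisation block; ``None`` means one
    global block (global L2 normalisation).
    """

    cell_shape: tuple[int, int, int] = (4, 32, 32)  # (z, y, x)
    inplane_bins: int = 8
    elevation_bins: int = 4
    block_shape: tuple[int, int, int] | None = None

    def validate(self, vol_shape=None) -> None:
        if self.inplane_bins < 2 or self.elevation_bins < 2:
            raise ValueError("bins must be >= 2")
        if vol_shape is not None and any(
            s % c != 0 for s, c in zip(vol_shape, self.cell_shape)
        ):
            raise ValueError(
                f"cell_shape {self.cell_shape} does not tile volume {vol_shape}"
            )


@dataclass(frozen=True)
class GLCMParams:
    """3D-GLCM parameters: quantisation depth and per-direction distances."""

    gray_levels: int = 32
    z_direction_distances: tuple[int, ...] = (1, 2, 3, 4)
    inplane_distances: tuple[int, ...] = (1, 2, 4, 8)

    def validate(self) -> None:
        if self.gray_levels < 2:
            raise ValueError("gray_levels must be >= 2")
        if any(d <= 0 for d in self.z_direction_distances + self.inplane_distances):
            raise ValueError("distances must be positive integers")


# the 13 unique directions of the 26-neighbourhood (opposites merged),
# in (dz, dy, dx) order; in-plane first, then directions with a z component
GLCM_DIRECTIONS_INPLANE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (0, 1, 1),
    (0, 1, -1),
)
GLCM_DIRECTIONS_Z: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

_GLCM_STATS = ("energy", "entropy", "contrast", "homogeneity")


@dataclass
class RadiomicsVector:
    """Concatenated LBP / HOG / GLCM descriptor for one nodule."""

    lbp: np.ndarray
    hog: np.ndarray
    glcm: np.ndarray

    @property
    def fr(self) -> np.ndarray:
        return np.concatenate([self.lbp, self.hog, self.glcm])


# ---------------------------------------------------------------------------
# volume LBP


def _neighbor_offsets(P: int, R: float) -> list[tuple[float, float]]:
    """(dy, dx) offsets of the P circular neighbours at radius R.

    Neighbour p sits at angle 2*pi*p/P from the +x axis (dy measured down the
    row axis).  For P=4, R=1 these are the exact grid offsets
    (0,1), (1,0), (0,-1), (-1,0).
    """
    out = []
    for p in range(P):
        a = 2.0 * np.pi * p / P
        dy, dx = R * np.sin(a), R * np.cos(a)
        out.append((round(dy, 12), round(dx, 12)))
    return out


def _shift_plane(plane: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Sample ``plane`` at (y+dy, x+dx) with bilinear interpolation.

    Integer offsets reduce to exact shifts.  Out-of-range samples are edge
    padded; interior-margin cropping below makes them irrelevant for R <= 1.
    """
    if float(dy).is_integer() and float(dx).is_integer():
        dy, dx = int(dy), int(dx)
        pad = np.pad(plane, max(abs(dy), abs(dx), 1), mode="edge")
        m = max(abs(dy), abs(dx), 1)
        return pad[m + dy : m + dy + plane.shape[0], m + dx : m + dx + plane.shape[1]]
    yy, xx = np.meshgrid(
        np.arange(plane.shape[0], dtype=np.float64),
        np.arange(plane.shape[1], dtype=np.float64),
        indexing="ij",
    )
    return ndimage.map_coordinates(
        plane, [yy + dy, xx + dx], order=1, mode="nearest"
    )


def lbp3d_histogram(vol: NoduleVolume, params: LBPParams = LBPParams()) -> np.ndarray:
    """L1-normalised histogram of volume-LBP pattern numbers.

    Bit order (q = 0 .. 3P+1, pattern = sum v_q 2^q): centre of slice s-L;
    the P neighbours in slice s-L; the P neighbours in slice s; the P
    neighbours in slice s+L; centre of slice s+L.  Each bit is
    B(g - g_centre) with B(x) = 1 iff x >= 0.
    """
    params.validate()
    v = np.asarray(vol.voxels if hasattr(vol, "voxels") else vol, dtype=np.float64)
    L, P, R = params.L, params.P, params.R
    S = v.shape[0]
    if S < 2 * L + 1:
        raise ValueError(f"volume needs at least {2 * L + 1} slices, has {S}")
    margin = int(np.ceil(R))
    if v.shape[1] <= 2 * margin or v.shape[2] <= 2 * margin:
        raise ValueError("volume too small in-plane for the given radius")
    offsets = _neighbor_offsets(P, R)
    hist = np.zeros(params.n_patterns, dtype=np.float64)
    sl = (slice(margin, v.shape[1] - margin), slice(margin, v.shape[2] - margin))
    for s in range(L, S - L):
        center = v[s][sl]
        planes = {-L: v[s - L], 0: v[s], L: v[s + L]}
        bits = []
        bits.append(planes[-L][sl] >= center)  # v_0: centre of previous slice
        for dz in (-L, 0, L):  # v_1 .. v_3P: ring neighbours
            for dy, dx in offsets:
                bits.append(_shift_plane(planes[dz], dy, dx)[sl] >= center)
        bits.append(planes[L][sl] >= center)  # v_{3P+1}: centre of next slice
        pattern = np.zeros(center.shape, dtype=np.int64)
        for q, b in enumerate(bits):
            pattern += b.astype(np.int64) << q
        hist += np.bincount(pattern.ravel(), minlength=params.n_patterns)
    total = hist.sum()
    return hist / total if total > 0 else hist


# ---------------------------------------------------------------------------
# 3D HOG


def _gradients(v: np.ndarray):
    """[-1, 0, 1] gradient filter per axis, edge-replicated at the borders."""
    pads = []
    for ax in range(3):
        p = np.pad(
            v,
            [(1, 1) if a == ax else (0, 0) for a in range(3)],
            mode="edge",
        )
        sl_hi = [slice(2, None) if a == ax else slice(None) for a in range(3)]
        sl_lo = [slice(0, -2) if a == ax else slice(None) for a in range(3)]
        pads.append(p[tuple(sl_hi)] - p[tuple(sl_lo)])
    gz, gy, gx = pads
    return gx, gy, gz


def hog3d_descriptor(vol: NoduleVolume, params: HOGParams = HOGParams()) -> np.ndarray:
    """Cell-wise 2-angle orientation histogram of the 3D gradient field.

    Votes are weighted by gradient magnitude; blocks are L2-normalised and the
    concatenated descriptor is L2-normalised overall.  An all-constant volume
    yields the all-zero descriptor (no normalisation of a zero vector).
    """
    v = np.asarray(vol.voxels if hasattr(vol, "voxels") else vol, dtype=np.float64)
    if any(s < 3 for s in v.shape):
        raise ValueError("volume must be at least 3 voxels along each axis")
    params.validate(v.shape)
    gx, gy, gz = _gradients(v)
    mag = np.sqrt(gx * gx + gy * gy + gz * gz)
    azimuth = np.arctan2(gy, gx) % np.pi  # unsigned, [0, pi)
    elevation = np.arctan2(gz, np.hypot(gx, gy))  # [-pi/2, pi/2]

    nb_a, nb_e = params.inplane_bins, params.elevation_bins
    a_bin = np.minimum((azimuth / np.pi * nb_a).astype(int), nb_a - 1)
    e_bin = np.minimum(
        ((elevation + np.pi / 2) / np.pi * nb_e).astype(int), nb_e - 1
    )

    cz, cy, cx = params.cell_shape
    nz, ny, nx = v.shape[0] // cz, v.shape[1] // cy, v.shape[2] // cx
    zz, yy, xx = np.meshgrid(
        np.arange(v.shape[0]) // cz,
        np.arange(v.shape[1]) // cy,
        np.arange(v.shape[2]) // cx,
        indexing="ij",
    )
    flat_idx = (
        ((zz * ny + yy) * nx + xx) * (nb_a * nb_e) + a_bin * nb_e + e_bin
    ).ravel()
    hist = np.bincount(flat_idx, weights=mag.ravel(),
                       minlength=nz * ny * nx * nb_a * nb_e)
    cells = hist.reshape(nz, ny, nx, nb_a * nb_e)

    if params.block_shape is None:
        bz, by, bx = nz, ny, nx
    else:
        bz, by, bx = params.block_shape
    desc = []
    for iz in range(0, nz, bz):
        for iy in range(0, ny, by):
            for ix in range(0, nx, bx):
                block = cells[iz : iz + bz, iy : iy + by, ix : ix + bx].ravel()
                norm = np.linalg.norm(block)
                desc.append(block / norm if norm > 0 else block)
    out = np.concatenate(desc)
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


# ---------------------------------------------------------------------------
# 3D GLCM


def quantize(v: np.ndarray, gray_levels: int) -> np.ndarray:
    """Equal-width quantisation of [0, 1] intensities to integer levels."""
    q = np.floor(np.clip(v, 0.0, 1.0) * gray_levels).astype(np.int64)
    return np.minimum(q, gray_levels - 1)


def _cooccurrence(q: np.ndarray, disp, levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for displacement ``disp`` (dz,dy,dx)."""
    slices_a, slices_b = [], []
    for d, n in zip(disp, q.shape):
        if abs(d) >= n:
            return np.zeros((levels, levels), dtype=np.float64)
        if d >= 0:
            slices_a.append(slice(0, n - d))
            slices_b.append(slice(d, n))
        else:
            slices_a.append(slice(-d, n))
            slices_b.append(slice(0, n + d))
    a = q[tuple(slices_a)].ravel()
    b = q[tuple(slices_b)].ravel()
    m = np.bincount(a * levels + b, minlength=levels * levels).astype(np.float64)
    m = m.reshape(levels, levels)
    return m + m.T  # symmetric accumulation (both orders)


def _matrix_stats(m: np.ndarray) -> tuple[float, float, float, float]:
    total = m.sum()
    if total <= 0:
        return (0.0, 0.0, 0.0, 0.0)
    p = m / total
    nz = p[p > 0]
    levels = p.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    energy = float((p * p).sum())
    entropy = float(-(nz * np.log(nz)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    return energy, entropy, contrast, homogeneity


def _direction_distance_pairs(params: GLCMParams):
    for d in GLCM_DIRECTIONS_INPLANE:
        for dist in params.inplane_distances:
            yield d, dist
    for d in GLCM_DIRECTIONS_Z:
        for dist in params.z_direction_distances:
            yield d, dist


def glcm_feature_names(params: GLCMParams = GLCMParams()) -> list[str]:
    """Stable column names in the fixed (direction, distance, stat) order."""
    names = []
    for (dz, dy, dx), dist in _direction_distance_pairs(params):
        for stat in _GLCM_STATS:
            names.append(f"glcm_d{dz}{dy:+d}{dx:+d}_r{dist}_{stat}")
    return names


def glcm3d_features(vol: NoduleVolume, params: GLCMParams = GLCMParams()) -> np.ndarray:
    """Energy/entropy/contrast/homogeneity for every (direction, distance).

    Matrices whose displacement exceeds the volume extent along any axis are
    emitted as degenerate all-zero feature blocks with a warning.
    """
    params.validate()
    v = np.asarray(vol.voxels if hasattr(vol, "voxels") else vol, dtype=np.float64)
    q = quantize(v, params.gray_levels)
    feats = []
    for direction, dist in _direction_distance_pairs(params):
        disp = tuple(d * dist for d in direction)
        if any(abs(d) >= n for d, n in zip(disp, v.shape)):
            warnings.warn(
                f"GLCM displacement {disp} exceeds volume shape {v.shape}; "
                "emitting degenerate (all-zero) features",
                stacklevel=2,
            )
            feats.extend((0.0, 0.0, 0.0, 0.0))
            continue
        m = _cooccurrence(q, disp, params.gray_levels)
        feats.extend(_matrix_stats(m))
    return np.asarray(feats, dtype=np.float64)


def radiomics_vector(
    vol: NoduleVolume,
    lbp: LBPParams = LBPParams(),
    hog: HOGParams = HOGParams(),
    glcm: GLCMParams = GLCMParams(),
) -> RadiomicsVector:
    """Full radiomics descriptor FR = [LBP | HOG | GLCM] for one volume."""
    return RadiomicsVector(
        lbp=lbp3d_histogram(vol, lbp),
        hog=hog3d_descriptor(vol, hog),
        glcm=glcm3d_features(vol, glcm),
    )
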