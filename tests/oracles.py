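"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a descriptor or propagation rule by the most literal
possible method (per-voxel loops, explicit pair enumeration, step-by-step
matrix products) and is kept free of any code from the package's optimised
implementations.
"""

from __future__ import annotations

import numpy as np


def lbp_oracle(vol: np.ndarray, L: int, P: int, R: float) -> np.ndarray:
    """Per-voxel volume-LBP histogram by explicit bit enumeration.

    Neighbour p sits at (y + R*sin(2*pi*p/P), x + R*cos(2*pi*p/P)); bilinear
    interpolation for off-grid positions (exact for P=4, R=1).
    """
    vol = np.asarray(vol, dtype=np.float64)
    S, H, W = vol.shape
    n_bits = 3 * P + 2
    hist = np.zeros(2**n_bits)
    margin = int(np.ceil(R))

    def sample(plane, y, x):
        y0, x0 = int(np.floor(y)), int(np.floor(x))
        fy, fx = y - y0, x - x0
        y0c, x0c = min(max(y0, 0), H - 1), min(max(x0, 0), W - 1)
        y1c, x1c = min(y0c + 1, H - 1), min(x0c + 1, W - 1)
        if fy < 1e-9 and fx < 1e-9:
            return plane[y0c, x0c]
        return (
            plane[y0c, x0c] * (1 - fy) * (1 - fx)
            + plane[y0c, x1c] * (1 - fy) * fx
            + plane[y1c, x0c] * fy * (1 - fx)
            + plane[y1c, x1c] * fy * fx
        )

    offs = [
        (R * np.sin(2 * np.pi * p / P), R * np.cos(2 * np.pi * p / P))
        for p in range(P)
    ]
    for s in range(L, S - L):
        for y in range(margin, H - margin):
            for x in range(margin, W - margin):
                c = vol[s, y, x]
                bits = [vol[s - L, y, x] >= c]
                for dz in (-L, 0, L):
                    for dy, dx in offs:
                        bits.append(sample(vol[s + dz], y + dy, x + dx) >= c)
                bits.append(vol[s + L, y, x] >= c)
                pattern = sum(int(b) << q for q, b in enumerate(bits))
                hist[pattern] += 1
    total = hist.sum()
    return hist / total if total else hist


def hog_oracle(
    vol: np.ndarray,
    cell_shape: tuple[int, int, int],
    inplane_bins: int,
    elevation_bins: int,
) -> np.ndarray:
    """Voxel-loop 3D HOG with edge-replicated [-1,0,1] gradients and one
    global L2 normalisation block."""
    vol = np.asarray(vol, dtype=np.float64)
    Z, H, W = vol.shape
    cz, cy, cx = cell_shape
    nz, ny, nx = Z // cz, H // cy, W // cx
    hist = np.zeros((nz, ny, nx, inplane_bins * elevation_bins))
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                gz = vol[min(z + 1, Z - 1), y, x] - vol[max(z - 1, 0), y, x]
                gy = vol[z, min(y + 1, H - 1), x] - vol[z, max(y - 1, 0), x]
                gx = vol[z, y, min(x + 1, W - 1)] - vol[z, y, max(x - 1, 0)]
                mag = np.sqrt(gx * gx + gy * gy + gz * gz)
                az = np.arctan2(gy, gx) % np.pi
                el = np.arctan2(gz, np.hypot(gx, gy))
                a = min(int(az / np.pi * inplane_bins), inplane_bins - 1)
                e = min(
                    int((el + np.pi / 2) / np.pi * elevation_bins),
                    elevation_bins - 1,
                )
                hist[z // cz, y // cy, x // cx, a * elevation_bins + e] += mag
    out = hist.ravel()
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def glcm_oracle(
    q: np.ndarray, disp: tuple[int, int, int], levels: int
) -> tuple[float, float, float, float]:
    """Energy/entropy/contrast/homogeneity by explicit pair enumeration
    (symmetric: both orders counted)."""
    q = np.asarray(q)
    Z, H, W = q.shape
    m = np.zeros((levels, levels))
    for z in range(Z):
        for y in range(H):
            for x in range(W):
                z2, y2, x2 = z + disp[0], y + disp[1], x + disp[2]
                if 0 <= z2 < Z and 0 <= y2 < H and 0 <= x2 < W:
                    m[q[z, y, x], q[z2, y2, x2]] += 1
                    m[q[z2, y2, x2], q[z, y, x]] += 1
    total = m.sum()
    if total == 0:
        return (0.0, 0.0, 0.0, 0.0)
    p = m / total
    energy = (p**2).sum()
    nz = p[p > 0]
    entropy = -(nz * np.log(nz)).sum()
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    contrast = ((i - j) ** 2 * p).sum()
    homog = (p / (1 + np.abs(i - j))).sum()
    return (float(energy), float(entropy), float(contrast), float(homog))


def gcn_oracle(H0: np.ndarray, A: np.ndarray, W0: np.ndarray, W1: np.ndarray):
    """Step-by-step two-layer GCN: S = D^-1/2 (A+I) D^-1/2, two ReLU layers,
    concatenated node rows."""
    At = A + np.eye(A.shape[0])
    D = np.diag(At.sum(axis=1))
    Dinv = np.diag(1.0 / np.sqrt(np.diag(D)))
    S = Dinv @ At @ Dinv
    H1 = np.maximum(S @ H0 @ W0, 0)
    H2 = np.maximum(S @ H1 @ W1, 0)
    return np.concatenate([H2[i] for i in range(H2.shape[0])])


def auc_pairwise_oracle(pos, neg, tie_mode="strict") -> float:
    """Double loop over all (negative, positive) pairs."""
    wins = 0.0
    for n in neg:
        for p in pos:
            if p > n:
                wins += 1
            elif p == n and tie_mode == "half":
                wins += 0.5
    return wins / (len(pos) * len(neg))
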