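import warnings

import numpy as np
import pytest

from oracles import glcm_oracle, hog_oracle, lbp_oracle
from rgdfusion.radiomics import (
    GLCM_DIRECTIONS_INPLANE,
    GLCMParams,
    HOGParams,
    LBPParams,
    glcm3d_features,
    glcm_feature_names,
    hog3d_descriptor,
    lbp3d_histogram,
    quantize,
    radiomics_vector,
)
from rgdfusion.radiomics import _cooccurrence  # symmetry/normalisation checks


class TestLBP:
    def test_constant_volume_all_bits_set(self):
        hist = lbp3d_histogram(np.full((3, 5, 5), 0.4))
        assert hist.sum() == pytest.approx(1.0)
        assert hist[2**14 - 1] == pytest.approx(1.0)  # B(0)=1 for all 14 bits

    def test_monotone_intensity_invariance(self, rng):
        v = rng.random((5, 10, 10))
        h1 = lbp3d_histogram(v)
        h2 = lbp3d_histogram(np.sqrt(v) * 3.0 + 1.0)  # strictly increasing map
        np.testing.assert_array_equal(h1, h2)

    def test_single_bright_voxel_matches_enumeration(self):
        v = np.zeros((3, 3, 3))
        v[1, 1, 1] = 1.0
        params = LBPParams(L=1, P=4, R=1)
        np.testing.assert_allclose(
            lbp3d_histogram(v, params), lbp_oracle(v, 1, 4, 1), atol=1e-12
        )

    def test_matches_bruteforce_on_random_volumes(self, rng):
        for _ in range(3):
            v = rng.random((4, 7, 6))
            np.testing.assert_allclose(
                lbp3d_histogram(v), lbp_oracle(v, 1, 4, 1), atol=1e-12
            )

    def test_interpolated_neighbors_p8(self, rng):
        """P=8 at R=1 uses off-grid neighbours (bilinear); histogram still
        L1-normalised over 2^26 is too wide, so use P=2 off-axis instead."""
        v = rng.random((3, 6, 6))
        h = lbp3d_histogram(v, LBPParams(L=1, P=2, R=1.5))
        assert h.sum() == pytest.approx(1.0)
        assert h.size == 2**8

    def test_thin_volume_rejected(self):
        with pytest.raises(ValueError):
            lbp3d_histogram(np.zeros((2, 5, 5)))


class TestHOG:
    def test_constant_volume_zero_descriptor(self):
        d = hog3d_descriptor(np.full((4, 8, 8), 0.5),
                             HOGParams(cell_shape=(2, 4, 4)))
        np.testing.assert_array_equal(d, 0.0)

    def test_linear_ramp_votes_single_bin(self):
        z, y, x = np.meshgrid(np.arange(4), np.arange(8), np.arange(8),
                              indexing="ij")
        v = x.astype(float)  # gradient (1, 0, 0): azimuth 0, elevation 0
        params = HOGParams(cell_shape=(4, 8, 8), inplane_bins=8,
                           elevation_bins=4)
        d = hog3d_descriptor(v, params)
        hist = d.reshape(8, 4)
        # azimuth bin 0, elevation bin 2 ([-pi/2,pi/2) -> 0 lands in bin 2)
        mass = hist[0, 2]
        assert mass == pytest.approx(np.linalg.norm(d))
        assert np.count_nonzero(hist) == 1

    def test_matches_bruteforce_oracle(self, rng):
        v = rng.random((8, 16, 16))
        params = HOGParams(cell_shape=(4, 8, 8), inplane_bins=8,
                           elevation_bins=4)
        np.testing.assert_allclose(
            hog3d_descriptor(v, params),
            hog_oracle(v, (4, 8, 8), 8, 4),
            atol=1e-6,
        )

    def test_cells_must_tile_volume(self, rng):
        with pytest.raises(ValueError):
            hog3d_descriptor(rng.random((4, 9, 8)),
                             HOGParams(cell_shape=(2, 4, 4)))


class TestGLCM:
    def test_constant_volume_degenerate_stats(self):
        f = glcm3d_features(np.full((8, 12, 12), 0.7))
        f = f.reshape(-1, 4)
        np.testing.assert_allclose(f[:, 0], 1.0)  # energy
        np.testing.assert_allclose(f[:, 1], 0.0)  # entropy
        np.testing.assert_allclose(f[:, 2], 0.0)  # contrast
        np.testing.assert_allclose(f[:, 3], 1.0)  # homogeneity

    def test_hand_counted_2x2_plane(self):
        """[[0,1],[0,1]] at 2 grey levels, in-plane step (0,0,1), d=1:
        symmetric counts {(0,1):2, (1,0):2} -> p=0.5 each,
        energy 0.5, contrast 1.0, homogeneity 0.5."""
        v = np.array([[[0.0, 0.9], [0.0, 0.9]]])  # (1,2,2)
        params = GLCMParams(gray_levels=2, inplane_distances=(1,),
                            z_direction_distances=(1,))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # z displacements degenerate here
            feats = glcm3d_features(v, params)
        names = glcm_feature_names(params)
        idx = {n: i for i, n in enumerate(names)}
        assert feats[idx["glcm_d0+0+1_r1_energy"]] == pytest.approx(0.5)
        assert feats[idx["glcm_d0+0+1_r1_contrast"]] == pytest.approx(1.0)
        assert feats[idx["glcm_d0+0+1_r1_homogeneity"]] == pytest.approx(0.5)
        assert feats[idx["glcm_d0+0+1_r1_entropy"]] == pytest.approx(np.log(2))

    def test_matches_bruteforce_oracle(self, rng):
        v = rng.random((8, 16, 16))
        params = GLCMParams(gray_levels=8)
        feats = glcm3d_features(v, params).reshape(-1, 4)
        q = quantize(v, 8)
        k = 0
        from rgdfusion.radiomics import _direction_distance_pairs

        for direction, dist in _direction_distance_pairs(params):
            disp = tuple(d * dist for d in direction)
            expected = glcm_oracle(q, disp, 8)
            np.testing.assert_allclose(feats[k], expected, atol=1e-10)
            k += 1

    def test_probability_normalisation_and_symmetry(self, rng):
        q = quantize(rng.random((6, 10, 10)), 16)
        m = _cooccurrence(q, (0, 1, 0), 16)
        p = m / m.sum()
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, p.T)
        nz = p[p > 0]
        entropy = -(nz * np.log(nz)).sum()
        assert 0 <= entropy <= 2 * np.log(16)
        assert 0 < (p**2).sum() <= 1

    def test_inplane_rotation_permutes_direction_features(self, rng):
        """A 90-degree in-plane rotation maps the four in-plane directions
        onto each other, so the in-plane feature multiset is preserved."""
        v = rng.random((4, 12, 12))
        vr = np.rot90(v, k=1, axes=(1, 2)).copy()
        params = GLCMParams(gray_levels=8, inplane_distances=(1, 2),
                            z_direction_distances=(1,))
        names = glcm_feature_names(params)
        inplane = [i for i, n in enumerate(names) if n.startswith("glcm_d0")]
        f1 = glcm3d_features(v, params)[inplane]
        f2 = glcm3d_features(vr, params)[inplane]
        np.testing.assert_allclose(np.sort(f1), np.sort(f2), atol=1e-10)

    def test_oversize_distance_warns_and_zeroes(self):
        v = np.random.default_rng(0).random((2, 12, 12))
        params = GLCMParams(gray_levels=4, z_direction_distances=(3,),
                            inplane_distances=(1,))
        with pytest.warns(UserWarning):
            feats = glcm3d_features(v, params)
        names = glcm_feature_names(params)
        zblock = [i for i, n in enumerate(names) if not n.startswith("glcm_d0")]
        np.testing.assert_array_equal(feats[zblock], 0.0)


class TestRadiomicsVector:
    def test_glcm_dimension_default_params(self, rng):
        """9 z-directions x 4 distances + 4 in-plane x 4 distances = 52
        matrices, 4 statistics each -> 208 features."""
        v = rng.random((8, 16, 16))
        assert glcm3d_features(v).size == 4 * (9 * 4 + 4 * 4) == 208

    def test_identical_volumes_identical_fr_and_stable_length(self, rng):
        hog = HOGParams(cell_shape=(4, 8, 8))
        a = rng.random((8, 16, 16))
        b = rng.random((8, 16, 16))
        fa1 = radiomics_vector(a, hog=hog).fr
        fa2 = radiomics_vector(a.copy(), hog=hog).fr
        fb = radiomics_vector(b, hog=hog).fr
        np.testing.assert_array_equal(fa1, fa2)
        assert fa1.size == fb.size
        assert np.isfinite(fa1).all()
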