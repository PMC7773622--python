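"""3D GLCM construction and Haralick descriptor computation."""

from itertools import product

import numpy as np
import pytest

import _oracles
from trabpipe.texture import (
    TEXTURE_FEATURE_NAMES,
    build_glcm,
    haralick_features,
    quantize,
    texture_features,
    unique_offsets_3d,
)


class TestQuantize:
    @pytest.mark.parametrize(
        "value, level",
        [(0, 1), (255, 16), (127, 8), (128, 9), (100, 7), (15, 1), (16, 2)],
    )
    def test_fixed_global_bins(self, value, level):
        q = quantize(np.full((2, 2, 2), value))
        assert set(np.unique(q.levels)) == {level}

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            quantize(np.full((2, 2, 2), 300))

    def test_every_voxel_mapped_in_range(self, random_volumes):
        q = quantize(random_volumes[0])
        assert q.levels.min() >= 1 and q.levels.max() <= 16


class TestOffsets:
    def test_thirteen_unique_directions(self):
        assert len(unique_offsets_3d()) == 13

    def test_antipodal_exclusivity(self):
        offsets = set(unique_offsets_3d())
        for v in offsets:
            anti = tuple(-c for c in v)
            assert anti not in offsets

    def test_enumeration_oracle(self):
        full = [v for v in product((-1, 0, 1), repeat=3) if v != (0, 0, 0)]
        assert len(full) == 26
        offsets = unique_offsets_3d()
        covered = set(offsets) | {tuple(-c for c in v) for v in offsets}
        assert covered == set(full)


class TestBuildGLCM:
    def test_constant_volume_concentrates_at_diagonal(self):
        q = quantize(np.full((6, 6, 4), 100))  # level 7
        glcm = build_glcm(q)
        for d in range(13):
            assert glcm[6, 6, d] == pytest.approx(1.0)
            assert glcm[:, :, d].sum() == pytest.approx(1.0)

    def test_hand_enumerated_plane(self):
        # 2x2x1 plane with levels [[1,2],[1,2]]; direction (0,1,0) pairs
        # (1,2) twice -> symmetrized p[0,1]=p[1,0]=0.5
        levels = np.array([[1, 2], [1, 2]])[:, :, None]
        from trabpipe.texture import QuantizedVOI

        glcm = build_glcm(QuantizedVOI(levels, 2), offsets=[(0, 1, 0)])
        np.testing.assert_allclose(glcm[:, :, 0], [[0.0, 0.5], [0.5, 0.0]])

    def test_matches_bruteforce_pair_enumeration(self, rng):
        vol = rng.integers(0, 256, (6, 5, 4)).astype(np.uint8)
        q = quantize(vol)
        offsets = unique_offsets_3d()
        glcm = build_glcm(q, offsets)
        for d, off in enumerate(offsets):
            expected = _oracles.glcm_bruteforce(q.levels, off, 16)
            np.testing.assert_allclose(glcm[:, :, d], expected, atol=1e-12)

    def test_symmetry_and_normalization_invariants(self, sample_voi):
        glcm = build_glcm(quantize(sample_voi))
        assert glcm.shape == (16, 16, 13)
        assert (glcm >= 0).all()
        for d in range(13):
            np.testing.assert_allclose(glcm[:, :, d], glcm[:, :, d].T, atol=1e-15)
            assert glcm[:, :, d].sum() == pytest.approx(1.0)

    def test_empty_direction_rejected(self):
        from trabpipe.texture import QuantizedVOI

        levels = np.ones((2, 2, 1), dtype=int)
        with pytest.raises(ValueError, match="no valid voxel pairs"):
            build_glcm(QuantizedVOI(levels, 2), offsets=[(0, 0, 1)])


class TestHaralick:
    def test_degenerate_single_cell_glcm(self):
        p = np.zeros((16, 16, 1))
        p[4, 4, 0] = 1.0
        f = haralick_features(p)
        assert f.contrast == 0.0
        assert f.homogeneity == 1.0
        assert f.entropy == 0.0
        assert f.maximum_probability == 1.0
        assert f.difference_variance == 0.0
        assert np.isnan(f.correlation)  # zero marginal variance

    def test_uniform_matrix_closed_forms(self):
        p = np.full((16, 16, 1), 1 / 256)
        f = haralick_features(p)
        assert f.entropy == pytest.approx(np.log(256))
        # E[(I-J)^2] for independent uniforms on 1..16 = 2*Var = 2*255/12
        assert f.contrast == pytest.approx(2 * 255 / 12)
        assert f.correlation == pytest.approx(0.0, abs=1e-12)
        assert f.maximum_probability == pytest.approx(1 / 256)
        assert f.imc == pytest.approx(0.0, abs=1e-12)  # independent marginals

    def test_matches_formula_transcription_oracle(self, rng):
        for _ in range(5):
            counts = rng.random((16, 16))
            counts = counts + counts.T
            p = (counts / counts.sum())[:, :, None]
            ours = haralick_features(p).as_series()
            oracle = _oracles.haralick_transcription(p[:, :, 0])
            for name in TEXTURE_FEATURE_NAMES:
                assert ours[name] == pytest.approx(oracle[name], abs=1e-10), name

    def test_unnormalized_glcm_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_features(np.full((16, 16, 2), 1.0))


class TestInvariances:
    def test_flip_invariance_along_each_axis(self, sample_voi):
        base = texture_features(sample_voi).as_series()
        for axis in range(3):
            flipped = np.flip(sample_voi.values, axis=axis)
            np.testing.assert_allclose(
                texture_features(flipped).as_series(), base, atol=1e-12
            )

    def test_relabeling_permutes_glcm_and_preserves_entropy(self, rng):
        vol = rng.integers(0, 256, (8, 8, 4)).astype(np.uint8)
        q = quantize(vol)
        perm = rng.permutation(16)
        from trabpipe.texture import QuantizedVOI

        q_perm = QuantizedVOI(perm[q.levels - 1] + 1, 16)
        g1 = build_glcm(q)
        g2 = build_glcm(q_perm)
        np.testing.assert_allclose(g2[perm][:, perm], g1, atol=1e-15)
        f1, f2 = haralick_features(g1), haralick_features(g2)
        assert f2.entropy == pytest.approx(f1.entropy)
        assert f2.maximum_probability == pytest.approx(f1.maximum_probability)

    def test_feature_vector_has_nine_entries(self, sample_voi):
        assert len(texture_features(sample_voi).as_series()) == 9

    def test_imc_nonpositive_for_nondegenerate(self, random_volumes):
        for vol in random_volumes[:5]:
            assert texture_features(vol).imc <= 1e-12

    def test_contrast_decreases_with_correlation_length(self):
        from trabpipe.synth import VOIRecipe, gen_voi

        means = []
        for cl in (0.8, 1.6, 3.2):
            vals = [
                texture_features(gen_voi(VOIRecipe(corr_length=(cl, cl, cl), seed=s))).contrast
                for s in range(8)
            ]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
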