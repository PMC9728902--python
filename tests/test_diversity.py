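import math

import numpy as np
import pytest
from scipy import stats

from songseg import (
    SyllableShapeMatrix,
    extract_shape_matrix,
    featurize_syllable,
    hull_volume_oracle,
    pca_retain,
    pseudo_hypervolume,
    relative_normalize,
    resampled_hypervolumes,
)
from oracle_utils import shoelace_hull_area


class TestFeaturizeSyllable:
    def test_output_length_500(self, rng):
        assert featurize_syllable(rng.normal(size=(37, 113))).shape == (500,)

    def test_constant_patch_degenerates_to_zeros(self):
        assert not featurize_syllable(np.full((10, 10), 3.3)).any()

    def test_identity_on_native_grid(self, rng):
        patch = rng.normal(size=(20, 25))  # freq x time, already on grid
        vec = featurize_syllable(patch)
        expected = patch.T  # time-major flatten
        expected = (expected - expected.min()) / (expected.max() - expected.min())
        np.testing.assert_allclose(vec, expected.ravel(), atol=1e-12)

    def test_scaled_to_unit_interval(self, rng):
        vec = featurize_syllable(rng.normal(size=(8, 30)))
        assert vec.min() == 0.0 and vec.max() == 1.0

    def test_degenerate_patch_rejected(self):
        with pytest.raises(ValueError):
            featurize_syllable(np.zeros((1, 30)))


class TestPcaRetain:
    def _data_with_ratios(self, rng, sds, n=400):
        # independent axes with chosen sds -> explained variance ~ sds^2
        return rng.normal(size=(n, len(sds))) * np.array(sds)

    def test_dominant_axis_needs_one_pc(self, rng):
        X = self._data_with_ratios(rng, [4.0, 1.0, 0.5])
        _, k = pca_retain(X, 0.5)
        assert k == 1

    def test_split_variance_needs_two_pcs(self, rng):
        # ratios near (0.45, 0.35, 0.20)
        X = self._data_with_ratios(rng, [math.sqrt(0.45), math.sqrt(0.35), math.sqrt(0.20)])
        _, k = pca_retain(X, 0.5)
        assert k == 2

    def test_rank_one_data_recovers_latent_axis(self, rng):
        z = rng.normal(size=200)
        X = np.column_stack([z, z])
        scores, k = pca_retain(X, 0.5)
        assert k == 1
        # eigendecomposition oracle on the 2x2 covariance: score = +-(z - mean)*sqrt(2)
        expected = (z - z.mean()) * math.sqrt(2)
        sign = np.sign(np.dot(scores[:, 0], expected))
        np.testing.assert_allclose(scores[:, 0], sign * expected, atol=1e-9)

    def test_k_monotone_in_threshold(self, rng):
        X = rng.normal(size=(100, 6)) * np.array([3, 2, 1.5, 1, 0.5, 0.2])
        ks = [pca_retain(X, th)[1] for th in (0.3, 0.5, 0.7, 0.9, 0.999)]
        assert ks == sorted(ks)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pca_retain(np.ones((10, 4)))


class TestPseudoHypervolume:
    def test_single_axis_is_its_sd(self, rng):
        z = rng.normal(size=500)
        z = (z - z.mean()) / z.std(ddof=1) * 0.5
        assert pseudo_hypervolume(z[:, None]) == pytest.approx(0.5)

    def test_product_across_axes(self, rng):
        n = 2000
        S = rng.normal(size=(n, 3))
        S = (S - S.mean(0)) / S.std(0, ddof=1) * np.array([1.0, 2.0, 0.5])
        assert pseudo_hypervolume(S, k=3) == pytest.approx(1.0)

    def test_scaling_points_scales_by_c_to_the_k(self, rng):
        S = rng.normal(size=(50, 4))
        base = pseudo_hypervolume(S)
        assert pseudo_hypervolume(3.0 * S) == pytest.approx(base * 3.0**4)

    def test_fewer_than_two_points_undefined(self):
        assert math.isnan(pseudo_hypervolume(np.zeros((1, 3))))


class TestRelativeNormalize:
    def test_divides_by_maximum(self):
        assert relative_normalize({"a": 2.0, "b": 1.0, "c": 0.5}) == {
            "a": 1.0, "b": 0.5, "c": 0.25,
        }

    def test_single_species_is_one(self):
        assert relative_normalize({"x": 0.123}) == {"x": 1.0}

    def test_ties_all_reach_one(self):
        out = relative_normalize({"a": 2.0, "b": 2.0})
        assert out["a"] == out["b"] == 1.0

    def test_non_positive_maximum_rejected(self):
        with pytest.raises(ValueError):
            relative_normalize({"a": 0.0})


def _gaussian_shapes(rng, scales, n=80):
    feats, species = [], []
    base = rng.normal(size=(n, 500))
    for i, c in enumerate(scales):
        feats.append(base * c + rng.normal(0, 0.01, size=(n, 500)))
        species += [f"sp{i}"] * n
    return SyllableShapeMatrix(np.vstack(feats), np.array(species), np.arange(n * len(scales)))


class TestResampledHypervolumes:
    def test_deterministic_under_seed(self, rng):
        shapes = _gaussian_shapes(rng, [1.0, 1.5])
        a = resampled_hypervolumes(shapes, reps=5, seed=7)
        b = resampled_hypervolumes(shapes, reps=5, seed=7)
        assert a.mean == b.mean and a.sd == b.sd

    def test_input_order_irrelevant(self, rng):
        shapes = _gaussian_shapes(rng, [1.0, 1.5])
        perm = rng.permutation(len(shapes.features))
        shuffled = SyllableShapeMatrix(
            shapes.features[perm], shapes.species[perm], shapes.syllable_ids[perm]
        )
        a = resampled_hypervolumes(shapes, reps=5, seed=3)
        b = resampled_hypervolumes(shuffled, reps=5, seed=3)
        assert a.mean == pytest.approx(b.mean)

    def test_one_species_attains_unity_every_rep(self, rng):
        shapes = _gaussian_shapes(rng, [0.7, 1.0, 1.4])
        res = resampled_hypervolumes(shapes, reps=8, seed=1)
        assert max(res.mean.values()) <= 1.0
        assert res.mean["sp2"] == pytest.approx(1.0)  # largest-scale species wins every rep

    def test_identical_distributions_agree_within_error(self, rng):
        # two species drawn from one distribution: means within 3 combined SEs
        n = 120
        feats = rng.normal(size=(2 * n, 500))
        species = np.array(["a"] * n + ["b"] * n)
        shapes = SyllableShapeMatrix(feats, species, np.arange(2 * n))
        res = resampled_hypervolumes(shapes, reps=200, n_per_species=50, seed=11)
        se = math.hypot(res.sd["a"], res.sd["b"]) / math.sqrt(200)
        assert abs(res.mean["a"] - res.mean["b"]) <= 3 * se

    def test_doubled_species_dominates_with_scale_equivariance(self, rng):
        # n == n_per_species: every rep uses all points, so species a
        # (= species b scaled by 1/2) scores exactly (1/2)^k per rep
        n = 50
        base = rng.normal(size=(n, 500))
        feats = np.vstack([base, base * 2.0])
        species = np.array(["a"] * n + ["b"] * n)
        shapes = SyllableShapeMatrix(feats, species, np.arange(2 * n))
        res = resampled_hypervolumes(shapes, reps=10, n_per_species=50, seed=5)
        assert res.mean["b"] == pytest.approx(1.0)
        ks = np.array(res.retained_pcs_per_rep, float)
        expected_a = np.mean(0.5**ks)
        assert res.mean["a"] == pytest.approx(expected_a, rel=1e-6)

    def test_species_with_one_syllable_rejected_by_name(self):
        feats = np.zeros((3, 500))
        feats[0, 0] = 1.0
        shapes = SyllableShapeMatrix(
            feats, np.array(["a", "a", "lonely"]), np.arange(3)
        )
        with pytest.raises(ValueError, match="lonely"):
            resampled_hypervolumes(shapes, reps=2)


class TestExtractShapeMatrix:
    def test_synthetic_songs_featurize_end_to_end(self):
        from songseg import SpectrogramConfig, compute_spectrogram, make_toy_clade, synth_song

        _, specs = make_toy_clade(2, seed=21)
        pairs = []
        for spec in specs:
            wave, track = synth_song(spec, 10.0, snr_db=25.0, seed=31)
            spect = compute_spectrogram(wave * 5000, SpectrogramConfig(min_power_log=None))
            pairs.append((spect, track))
        shapes = extract_shape_matrix(pairs)
        assert shapes.features.shape[1] == 500
        assert set(shapes.species) == {s.species_id for s in specs}
        assert shapes.features.min() >= 0 and shapes.features.max() <= 1

    def test_no_featurizable_syllables_rejected(self):
        from songseg import SegmentationTrack, SpectrogramConfig, compute_spectrogram

        spect = compute_spectrogram(np.zeros(4800), SpectrogramConfig())
        empty = SegmentationTrack("r", 48_000, 0.1, [])
        with pytest.raises(ValueError):
            extract_shape_matrix([(spect, empty)])


class TestHullVolumeOracle:
    def test_unit_square(self):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert hull_volume_oracle(corners) == pytest.approx(1.0)

    def test_unit_simplex_3d(self):
        simplex = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert hull_volume_oracle(simplex) == pytest.approx(1 / 6)

    def test_matches_shoelace_in_2d(self, rng):
        pts = rng.normal(size=(40, 2))
        assert hull_volume_oracle(pts) == pytest.approx(shoelace_hull_area(pts))

    def test_degenerate_set_signals_zero(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert hull_volume_oracle(line) == 0.0

    def test_dimension_cap(self, rng):
        with pytest.raises(ValueError):
            hull_volume_oracle(rng.normal(size=(20, 8)))


class TestProxyAgreement:
    @pytest.mark.parametrize("d", [2, 3, 4, 5])
    def test_rank_agreement_scaled_clusters(self, rng, d):
        base = rng.normal(size=(30, d))
        scales = [0.5, 0.9, 1.3, 2.0, 3.1]
        pseudo = [pseudo_hypervolume(base * c) for c in scales]
        hull = [hull_volume_oracle(base * c) for c in scales]
        rho = stats.spearmanr(pseudo, hull).statistic
        assert rho == pytest.approx(1.0)
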