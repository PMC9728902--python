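import math

import numpy as np
import pandas as pd
import pytest

from songseg import (
    ChirpPrimitive,
    DegradationModel,
    GenerationError,
    SpectrogramConfig,
    SpeciesSpec,
    compute_spectrogram,
    corrupt_segmentation,
    expected_ser,
    generate_track,
    learning_curve_experiment,
    make_toy_clade,
    read_raven_selection_table,
    run_experiment_grid,
    slice_recording,
    synth_song,
    write_raven_selection_table,
)
from songseg.synth import DURATION_BOUNDS, RATE_BOUNDS


def _spec(rate=2.0, band=(2000.0, 6000.0)):
    logsd = 0.45
    return SpeciesSpec(
        species_id="test_sp",
        freq_band=band,
        syllable_rate=rate,
        duration_logmean=math.log(0.3 / rate) - logsd**2 / 2,
        duration_logsd=logsd,
        repertoire=(ChirpPrimitive(0.3, 0.7),),
    )


class TestToyClade:
    def test_deterministic_under_seed(self):
        p1, s1 = make_toy_clade(6, seed=9)
        p2, s2 = make_toy_clade(6, seed=9)
        assert s1 == s2
        pd.testing.assert_frame_equal(p1.divergences.frame, p2.divergences.frame)

    def test_divergences_span_and_bounds(self):
        phylo, _ = make_toy_clade(10, max_depth_mya=85.0, seed=3)
        m = phylo.divergences.frame.to_numpy()
        off_diag = m[~np.eye(10, dtype=bool)]
        assert off_diag.min() > 0 and off_diag.max() == pytest.approx(85.0)

    def test_ultrametric_three_point_condition(self):
        # for any triple, the two largest pairwise divergences are equal
        phylo, _ = make_toy_clade(8, seed=4)
        t = phylo.divergences
        names = phylo.species
        for _ in range(50):
            a, b, c = np.random.default_rng(_).choice(names, 3, replace=False)
            ds = sorted([t.divergence(a, b), t.divergence(a, c), t.divergence(b, c)])
            assert ds[1] == pytest.approx(ds[2])

    def test_trait_variance_scales_with_divergence(self):
        # Brownian clock: Var(trait difference) ~ 2 * rate * d per axis
        rate, depth = 0.05, 40.0
        diffs = []
        for seed in range(1000):
            phylo, specs = make_toy_clade(2, max_depth_mya=depth, trait_rate=rate, seed=seed)
            d = phylo.divergences.divergence(*phylo.species)
            assert d == pytest.approx(depth)
            diffs.append(np.array(specs[0].trait_vector) - np.array(specs[1].trait_vector))
        var = np.var(np.array(diffs).ravel(), ddof=1)
        expected = 2 * rate * depth
        se = expected * math.sqrt(2 / (4 * 1000))  # chi2 relative error
        assert abs(var - expected) <= 4 * se

    def test_species_specs_respect_observed_ranges(self):
        _, specs = make_toy_clade(10, seed=5)
        for s in specs:
            assert RATE_BOUNDS[0] <= s.syllable_rate <= RATE_BOUNDS[1]
            assert 500 <= s.freq_band[0] < s.freq_band[1] <= 15_000

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            make_toy_clade(1)


class TestSynthSong:
    def test_renewal_count_near_rate_times_duration(self):
        track = generate_track(_spec(rate=2.0), 100.0, seed=0)
        assert abs(len(track) - 200) <= 3 * math.sqrt(200)

    def test_durations_within_truncation_bounds(self):
        track = generate_track(_spec(rate=6.0), 200.0, seed=1)
        durs = [s.duration_s for s in track.segments]
        assert min(durs) >= DURATION_BOUNDS[0] and max(durs) <= DURATION_BOUNDS[1]

    def test_deterministic_under_seed(self):
        w1, t1 = synth_song(_spec(), 5.0, seed=7)
        w2, t2 = synth_song(_spec(), 5.0, seed=7)
        np.testing.assert_array_equal(w1, w2)
        assert [(s.onset_s, s.offset_s) for s in t1.segments] == [
            (s.onset_s, s.offset_s) for s in t2.segments
        ]

    def test_syllable_energy_sits_in_species_band(self):
        band = (2500.0, 4500.0)
        wave, track = synth_song(_spec(band=band), 10.0, snr_db=40.0, seed=2)
        spect = compute_spectrogram(
            wave * 5000, SpectrogramConfig(min_power_log=None)
        )
        seg = max(track.segments, key=lambda s: s.duration_s)
        mid = (seg.onset_s + seg.offset_s) / 2
        frame = int(np.argmin(np.abs(spect.frame_times_s - mid)))
        peak = spect.freqs_hz[np.argmax(spect.logpower[:, frame])]
        assert band[0] - 200 <= peak <= band[1] + 200

    def test_infeasible_packing_raises(self):
        bad = SpeciesSpec(
            species_id="bad",
            freq_band=(2000.0, 6000.0),
            syllable_rate=9.0,
            duration_logmean=math.log(0.5),
            duration_logsd=0.3,
            repertoire=(ChirpPrimitive(0.5, 0.5),),
        )
        with pytest.raises(GenerationError):
            generate_track(bad, 10.0, seed=0)


class TestCorruptSegmentation:
    def test_zero_model_is_identity(self):
        track = generate_track(_spec(), 30.0, seed=3)
        pred = corrupt_segmentation(track, DegradationModel.zero(), d=50.0, seed=4)
        assert [(s.onset_s, s.offset_s) for s in pred.segments] == pytest.approx(
            [(s.onset_s, s.offset_s) for s in track.segments]
        )

    def test_total_miss_gives_empty_prediction(self):
        track = generate_track(_spec(), 30.0, seed=3)
        model = DegradationModel(miss_intercept=1.0, miss_slope=0.0,
                                 fp_intercept=0.0, fp_slope=0.0, gain_max=0.0)
        pred = corrupt_segmentation(track, model, d=0.0, seed=5)
        assert len(pred) == 0

    def test_deterministic_under_seed(self):
        track = generate_track(_spec(), 30.0, seed=3)
        model = DegradationModel()
        a = corrupt_segmentation(track, model, d=30.0, training_s=100, seed=6)
        b = corrupt_segmentation(track, model, d=30.0, training_s=100, seed=6)
        assert [(s.onset_s, s.offset_s) for s in a.segments] == [
            (s.onset_s, s.offset_s) for s in b.segments
        ]

    def test_prediction_is_sorted_and_disjoint(self):
        track = generate_track(_spec(rate=5.0), 60.0, seed=8)
        model = DegradationModel(jitter_intercept_s=0.01)
        pred = corrupt_segmentation(track, model, d=60.0, seed=9)
        assert pred.is_disjoint


class TestExpectedSer:
    def test_zero_corruption_zero_ser(self):
        assert expected_ser(DegradationModel.zero(), 10.0, 50, 20.0) == pytest.approx(0.0)

    def test_miss_and_split_arithmetic(self):
        model = DegradationModel(
            miss_intercept=0.2, miss_slope=0.0, split_intercept=0.1, split_slope=0.0,
            fp_intercept=0.0, fp_slope=0.0, gain_max=0.0,
        )
        assert expected_ser(model, 0.0, 10, 5.0) == pytest.approx(-0.12)

    def test_requires_observed_syllables(self):
        with pytest.raises(ValueError):
            expected_ser(DegradationModel(), 0.0, 0, 1.0)


class TestExperimentGrid:
    def test_grid_shape_and_determinism(self):
        phylo, specs = make_toy_clade(4, seed=10)
        seconds = {s: 200.0 for s in phylo.species}
        g1 = run_experiment_grid(phylo, specs, DegradationModel(), seconds,
                                 seed=11, test_duration_s=10.0, n_recordings=2)
        g2 = run_experiment_grid(phylo, specs, DegradationModel(), seconds,
                                 seed=11, test_duration_s=10.0, n_recordings=2)
        assert len(g1) == 5 * 4  # 4 single + multi, each tested on 4
        pd.testing.assert_frame_equal(g1, g2)

    def test_multi_model_not_worse_than_best_cross_species(self):
        # the multi model corrupts at the minimum divergence to the test
        # species, so it tracks the closest-trained single model
        phylo, specs = make_toy_clade(5, seed=12)
        seconds = {s: 200.0 for s in phylo.species}
        grid = run_experiment_grid(phylo, specs, DegradationModel(), seconds,
                                   seed=13, test_duration_s=60.0, n_recordings=3)
        for tested in phylo.species:
            sub = grid[grid.tested == tested]
            multi_acc = sub[sub.trained == "multi"].accuracy.iloc[0]
            cross = sub[(sub.trained != "multi") & (sub.trained != tested)]
            assert multi_acc >= cross.accuracy.max() - 0.02


class TestLearningCurve:
    def test_constant_gain_gives_flat_curve(self):
        model = DegradationModel(gain_max=0.0)
        table = learning_curve_experiment(_spec(), model, sizes=(10, 100, 1000),
                                          replicates=3, seed=14, test_duration_s=15.0)
        for _, rep in table.groupby("replicate"):
            assert rep.accuracy.nunique() == 1

    def test_saturating_gain_curve_monotone(self):
        table = learning_curve_experiment(_spec(), DegradationModel(), replicates=5,
                                          seed=15, test_duration_s=15.0)
        means = table.groupby("training_s").accuracy.mean()
        assert (np.diff(means.to_numpy()) >= -1e-12).all()

    def test_deterministic_under_seed(self):
        a = learning_curve_experiment(_spec(), DegradationModel(), sizes=(10, 50),
                                      replicates=2, seed=16, test_duration_s=10.0)
        b = learning_curve_experiment(_spec(), DegradationModel(), sizes=(10, 50),
                                      replicates=2, seed=16, test_duration_s=10.0)
        pd.testing.assert_frame_equal(a, b)


class TestPipelineIntegration:
    def test_generated_annotations_round_trip_and_slice(self):
        track = generate_track(_spec(rate=1.0), 60.0, seed=17)
        text = write_raven_selection_table(track)
        back = read_raven_selection_table(text, 60.0, 48_000, track.recording_id)
        assert [(s.onset_s, s.offset_s) for s in back.segments] == [
            (s.onset_s, s.offset_s) for s in track.segments
        ]
        slices = slice_recording(back)
        total = sum(loc.annotated_seconds for _, loc in slices)
        assert total == pytest.approx(track.annotated_seconds, abs=1e-9)
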