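"""The three-stage classifier and its post-processing rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_hypnogram, optimal_split_assignment
from somnograph import (
    DegenerateInputError,
    EpochSeries,
    Hypnogram,
    InvalidInputError,
    Stage,
    StagingConfig,
    cole_kripke,
    kmeans_1d,
    light_deep_score,
    rem_from_deep,
    rem_postprocess,
    stage_night,
)

P = 0.01076
WEIGHT_SUM = 50 + 30 + 14 + 28 + 121 + 8 + 50  # = 301


def _series(g, hr=None):
    g = np.asarray(g, dtype=float)
    return EpochSeries(g_value=g, heart_rate_bpm=hr)


class TestColeKripke:
    def test_zero_activity_scores_all_sleep(self):
        res = cole_kripke(_series(np.zeros(50)))
        assert np.all(res.d == 0.0)
        assert not res.wake.any()

    def test_constant_unit_activity_interior_score(self):
        res = cole_kripke(_series(np.ones(20)))
        assert res.d[10] == pytest.approx(P * WEIGHT_SUM)  # 3.23876
        assert res.d[10] == pytest.approx(3.23876)
        assert res.wake[10]

    def test_boundary_activity_scores_exactly_one(self):
        a0 = 1.0 / (P * 121)
        g = np.zeros(11)
        g[5] = a0
        res = cole_kripke(_series(g))
        assert res.d[5] == pytest.approx(1.0)
        # the wake rule is a half-open threshold at D = 1
        assert res.wake[5] == (res.d[5] >= 1.0)
        g[5] = a0 * (1 + 1e-9)
        assert cole_kripke(_series(g)).wake[5]

    def test_out_of_range_neighbours_contribute_zero(self):
        # a single-epoch record sees only the W0 term
        res = cole_kripke(_series([1.0]))
        assert res.d[0] == pytest.approx(P * 121)

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_monotone_in_activity(self, data):
        n = data.draw(st.integers(6, 24))
        g = np.array(data.draw(
            st.lists(st.floats(0, 50), min_size=n, max_size=n)
        ))
        idx = data.draw(st.integers(0, n - 1))
        bump = data.draw(st.floats(0.1, 100))
        before = cole_kripke(_series(g)).wake
        g2 = g.copy()
        g2[idx] += bump
        after = cole_kripke(_series(g2)).wake
        # increasing one epoch's activity can only create wake, never sleep
        assert np.all(after[before])


class TestLightDeepScore:
    def test_quiet_epochs_accumulate_toward_deep(self):
        es = _series([10.0, 10.0, 10.0])
        res = light_deep_score(es, np.ones(3, bool))
        np.testing.assert_allclose(res.score, [1, 2, 3])
        assert res.deep.all()

    def test_big_movement_clamps_score_to_light(self):
        es = _series([10.0, 450.0])
        res = light_deep_score(es, np.ones(2, bool))
        np.testing.assert_allclose(res.score, [1.0, 0.0])
        assert res.deep.tolist() == [True, False]

    def test_empty_sleep_mask_is_a_no_op(self):
        es = _series([10.0, 10.0])
        res = light_deep_score(es, np.zeros(2, bool))
        assert np.all(np.isnan(res.score))
        assert not res.deep.any()

    def test_wake_epochs_do_not_move_the_score(self):
        es = _series([10.0, 5000.0, 10.0])
        mask = np.array([True, False, True])
        res = light_deep_score(es, mask)
        np.testing.assert_allclose(res.score[mask], [1.0, 2.0])

    def test_mask_length_mismatch_errors(self):
        with pytest.raises(InvalidInputError):
            light_deep_score(_series([1.0]), np.ones(2, bool))


class TestKmeans1D:
    def test_two_point_masses_split_perfectly(self):
        model = kmeans_1d([50.0, 50.0, 90.0, 90.0])
        assert model.centroids == (50.0, 90.0)
        assert model.assignment.tolist() == [0, 0, 1, 1]
        assert model.converged

    def test_known_five_point_split(self):
        model = kmeans_1d([55.0, 58.0, 60.0, 72.0, 75.0])
        assert model.assignment.tolist() == [0, 0, 0, 1, 1]

    def test_degenerate_and_tiny_inputs_error(self):
        with pytest.raises(DegenerateInputError):
            kmeans_1d([60.0, 60.0, 60.0])
        with pytest.raises(InvalidInputError):
            kmeans_1d([60.0])

    def test_matches_contiguous_split_oracle_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 13))
            values = rng.uniform(45, 95, n)
            model = kmeans_1d(values, rng=np.random.default_rng(rng.integers(2**31)))
            np.testing.assert_array_equal(
                model.assignment, optimal_split_assignment(values)
            )

    def test_assignment_respects_nearest_centroid(self, rng):
        values = rng.uniform(40, 100, 30)
        model = kmeans_1d(values)
        c = np.asarray(model.centroids)
        nearest = (np.abs(values - c[1]) < np.abs(values - c[0])).astype(int)
        np.testing.assert_array_equal(model.assignment, nearest)


class TestRemFromDeep:
    def test_high_heart_rate_deep_epochs_become_rem(self):
        hr = np.array([55.0, 56.0, 54.0, 80.0, 82.0])
        es = _series(np.zeros(5), hr)
        hyp = Hypnogram(np.full(5, int(Stage.DEEP)))
        out, model = rem_from_deep(es, hyp)
        assert out.stages.tolist() == [2, 2, 2, 3, 3]
        assert model is not None and model.converged

    def test_no_deep_epochs_is_a_no_op(self):
        es = _series(np.zeros(4), np.full(4, 60.0))
        hyp = Hypnogram(np.full(4, int(Stage.LIGHT)))
        out, model = rem_from_deep(es, hyp)
        assert model is None
        np.testing.assert_array_equal(out.stages, hyp.stages)

    def test_constant_heart_rate_flags_and_keeps_deep(self):
        es = _series(np.zeros(6), np.full(6, 60.0))
        hyp = Hypnogram(np.full(6, int(Stage.DEEP)))
        with pytest.warns(UserWarning, match="degenerate"):
            out, model = rem_from_deep(es, hyp)
        assert model is None
        assert "degenerate_hr" in out.flags
        assert np.all(out.stages == int(Stage.DEEP))

    def test_relabelled_epochs_have_the_highest_heart_rates(self, rng):
        hr = rng.uniform(50, 85, 200)
        es = _series(np.zeros(200), hr)
        hyp = Hypnogram(np.full(200, int(Stage.DEEP)))
        out, _ = rem_from_deep(es, hyp)
        rem_hr = hr[out.stages == int(Stage.REM)]
        deep_hr = hr[out.stages == int(Stage.DEEP)]
        assert rem_hr.min() >= deep_hr.max()


class TestRemPostprocess:
    def test_short_rem_segment_demoted(self):
        # 4-min REM at minute 100, onset at 0: rule 2 demotes it to DEEP
        hyp = make_hypnogram("L*200 R*8 L*92")
        out = rem_postprocess(hyp)
        assert np.all(out.stages[200:208] == int(Stage.DEEP))

    def test_rem_inside_onset_lockout_demoted(self):
        # REM during minutes 10-20 falls inside the 45-min lockout
        hyp = make_hypnogram("L*20 R*20 L*260")
        out = rem_postprocess(hyp)
        assert np.all(out.stages[20:40] == int(Stage.DEEP))
        assert not (out.stages == int(Stage.REM)).any()

    def test_lockout_counts_from_sleep_onset_not_record_start(self):
        # 30 min of wake first; REM at minute 80 is 50 min past onset -> kept
        hyp = make_hypnogram("W*60 L*100 R*20 L*100")
        out = rem_postprocess(hyp)
        assert np.all(out.stages[160:180] == int(Stage.REM))

    def test_brief_gap_between_rem_runs_merged(self):
        # REM(10) + DEEP(2 min) + REM(10) after lockout: gap becomes REM
        hyp = make_hypnogram("L*100 R*20 D*4 R*20 L*100")
        out = rem_postprocess(hyp)
        assert np.all(out.stages[100:144] == int(Stage.REM))

    def test_wake_gap_is_preserved(self):
        hyp = make_hypnogram("L*100 R*20 W*2 R*20 L*100")
        out = rem_postprocess(hyp)
        assert np.all(out.stages[120:122] == int(Stage.WAKE))

    def test_gap_longer_than_three_minutes_not_merged(self):
        hyp = make_hypnogram("L*100 R*20 D*7 R*20 L*100")
        out = rem_postprocess(hyp)
        assert np.all(out.stages[120:127] == int(Stage.DEEP))

    def test_idempotent_on_random_hypnograms(self, rng):
        for _ in range(1000):
            stages = rng.integers(0, 4, int(rng.integers(20, 300)))
            hyp = Hypnogram(stages)
            once = rem_postprocess(hyp)
            twice = rem_postprocess(once)
            np.testing.assert_array_equal(once.stages, twice.stages)


class TestStageNight:
    def test_all_zero_activity_bimodal_hr(self):
        # no wake epochs; REM is exactly the high-HR cluster (after the
        # 45-min onset lockout and segment rules)
        hr = np.concatenate((
            np.full(120, 55.0), np.full(40, 80.0), np.full(80, 55.0),
            np.full(40, 80.0),
        ))
        hr = hr + np.linspace(0, 1, hr.size)  # break exact degeneracy
        es = _series(np.zeros(hr.size), hr)
        hyp = stage_night(es)
        assert not (hyp.stages == int(Stage.WAKE)).any()
        rem = hyp.stages == int(Stage.REM)
        expected = np.zeros(hr.size, bool)
        expected[120:160] = True
        expected[240:280] = True
        np.testing.assert_array_equal(rem, expected)

    def test_constant_high_activity_scores_all_wake(self):
        es = _series(np.full(30, 1000.0), np.full(30, 60.0))
        hyp = stage_night(es)
        assert np.all(hyp.stages == int(Stage.WAKE))

    def test_deterministic_given_seed(self, rng):
        es = _series(rng.uniform(0, 0.4, 200), rng.uniform(50, 90, 200))
        cfg = StagingConfig(rng_seed=7)
        a = stage_night(es, cfg)
        b = stage_night(es, cfg)
        np.testing.assert_array_equal(a.stages, b.stages)

    def test_labels_and_length_are_well_formed(self, rng):
        es = _series(rng.uniform(0, 30, 150), rng.uniform(50, 90, 150))
        hyp = stage_night(es)
        assert len(hyp) == 150
        assert set(np.unique(hyp.stages)) <= {0, 1, 2, 3}


class TestStagingConfig:
    def test_overlapping_bins_rejected(self):
        with pytest.raises(InvalidInputError):
            StagingConfig(score_bins=((0.0, 50.0, 1.0), (40.0, float("inf"), -2.0)))

    def test_bins_must_cover_zero_to_infinity(self):
        with pytest.raises(InvalidInputError):
            StagingConfig(score_bins=((0.0, 40.0, 1.0), (40.0, 600.0, -2.0)))

    def test_loadable_from_flat_toml(self, tmp_path):
        path = tmp_path / "staging.toml"
        path.write_text("ck_scale_p = 0.02\nrem_gap_merge_min = 2.0\nrng_seed = 9\n")
        cfg = StagingConfig.from_file(path)
        assert cfg.ck_scale_p == 0.02
        assert cfg.rem_gap_merge_min == 2.0
        assert cfg.rng_seed == 9
        assert cfg.ck_weights == (50, 30, 14, 28, 121, 8, 50)
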