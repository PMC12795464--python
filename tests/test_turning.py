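import numpy as np
import pytest

from shapespace import synthetic
from shapespace.turning import (
    DEPOLARISED,
    DEPOLARISING,
    POLARISED,
    REPOLARISING,
    TurnModel,
    angle_checks,
    decode_states,
    evaluate_predictions,
    locate_true_turn,
    predict_turns,
    straightness_check,
    train_hmm,
)


def _toy_model(means=None, self_prob=0.9):
    means = np.asarray(
        means if means is not None else [[3, 0], [1.5, 0.8], [0, 0], [1.5, -0.8]],
        float,
    )
    n = means.shape[0]
    covars = np.tile(0.05 * np.eye(2), (n, 1, 1))
    trans = np.full((n, n), (1 - self_prob) / (n - 1))
    np.fill_diagonal(trans, self_prob)
    return TurnModel(
        means=means, covars=covars, transmat=trans, startprob=np.full(n, 1 / n)
    )


class TestTraining:
    def test_recovers_emission_means(self, rng):
        model_true = _toy_model()
        sigma = np.sqrt(0.05)
        seqs = []
        for s in range(4):
            coords = model_true.means[s] + sigma * rng.normal(size=(500, 2))
            seqs.append((coords, np.full(500, s)))
        model = train_hmm(seqs)
        err = np.abs(model.means - model_true.means).max()
        assert err < 0.2 * sigma

    def test_transition_rows_sum_to_one(self, rng):
        tracks = synthetic.make_migration_tracks(
            synthetic.TrackParams(seed=0), n_tracks=5
        )
        model = train_hmm([(t.emissions, t.states) for t in tracks])
        np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(model.startprob.sum(), 1.0, atol=1e-12)

    def test_absorbing_state_dominates_its_row(self, rng):
        coords = rng.normal(size=(300, 2))
        labels = np.zeros(300, int)
        others = [
            (np.array([[9.0, 9.0], [9.1, 9.0]]) + s, np.full(2, s)) for s in range(1, 4)
        ]
        model = train_hmm([(coords, labels)] + others)
        row = model.transmat[POLARISED]
        assert row[POLARISED] > 0.98
        assert np.all(row[1:] > 0)  # smoothing keeps tiny mass everywhere

    def test_underpopulated_state_rejected(self, rng):
        coords = rng.normal(size=(10, 2))
        labels = np.array([0] * 9 + [1])  # states 1..3 nearly/fully absent
        with pytest.raises(ValueError, match="at least 2"):
            train_hmm([(coords, labels)])


class TestDecoding:
    def test_emissions_at_state_means_decode_exactly(self):
        model = _toy_model()
        states = np.array([0, 0, 1, 1, 2, 2, 3, 3, 0, 0])
        coords = model.means[states]
        decoded = decode_states(model, coords)
        np.testing.assert_array_equal(decoded, states)

    def test_synthetic_cycles_decode_accurately(self):
        tracks = synthetic.make_migration_tracks(
            synthetic.TrackParams(seed=21), n_tracks=30
        )
        model = train_hmm([(t.emissions, t.states) for t in tracks[:10]])
        correct = total = 0
        for t in tracks[10:]:
            decoded = decode_states(model, t.emissions)
            correct += (decoded == t.states).sum()
            total += t.states.size
        assert correct / total >= 0.95

    def test_single_frame_picks_most_likely_state(self):
        model = _toy_model()
        decoded = decode_states(model, np.array([[2.9, 0.05]]))
        assert decoded.tolist() == [POLARISED]

    def test_viterbi_agrees_with_exhaustive_search(self, rng):
        """Cross-check the decoder against brute-force path enumeration."""
        from itertools import product
        from scipy.stats import multivariate_normal

        model = _toy_model(self_prob=0.6)
        for _ in range(5):
            coords = rng.normal(1.5, 1.5, size=(5, 2))
            logp = np.array(
                [
                    multivariate_normal.logpdf(coords, model.means[s], model.covars[s])
                    for s in range(4)
                ]
            )
            best, best_path = -np.inf, None
            for path in product(range(4), repeat=5):
                lp = np.log(model.startprob[path[0]]) + logp[path[0], 0]
                for t in range(1, 5):
                    lp += np.log(model.transmat[path[t - 1], path[t]]) + logp[path[t], t]
                if lp > best:
                    best, best_path = lp, path
            decoded = decode_states(model, coords)
            assert tuple(decoded) == best_path


class TestPredictTurns:
    def test_canonical_pattern(self):
        turns, segments = predict_turns(
            [DEPOLARISED, DEPOLARISED, REPOLARISING, REPOLARISING, POLARISED, POLARISED]
        )
        assert turns == [4]
        assert segments == [(0, 4), (4, 5)]

    def test_all_polarised_gives_no_turns_one_segment(self):
        turns, segments = predict_turns([POLARISED] * 10)
        assert turns == [] and segments == [(0, 9)]

    def test_two_cycles_give_two_turns_three_segments(self):
        cycle = (
            [POLARISED] * 3
            + [DEPOLARISING] * 2
            + [DEPOLARISED] * 2
            + [REPOLARISING] * 2
        )
        seq = cycle + [POLARISED] * 3 + cycle[3:] + [POLARISED] * 3
        turns, segments = predict_turns(seq)
        assert len(turns) == 2 and len(segments) == 3

    def test_incomplete_pattern_predicts_nothing(self):
        # repolarising directly to depolarised, never reaching polarised
        turns, _ = predict_turns(
            [DEPOLARISED, REPOLARISING, DEPOLARISED, REPOLARISING]
        )
        assert turns == []

    def test_invariant_under_state_relabelling(self):
        """Decoding with a permuted model then inverting the permutation
        yields the same turn frames."""
        model = _toy_model()
        perm = np.array([2, 0, 3, 1])  # permuted state j is original perm[j]
        permuted = TurnModel(
            means=model.means[perm],
            covars=model.covars[perm],
            transmat=model.transmat[np.ix_(perm, perm)],
            startprob=model.startprob[perm],
        )
        states = np.array([0, 0, 1, 2, 2, 3, 3, 0, 0])
        coords = model.means[states]
        d1 = decode_states(model, coords)
        d2 = perm[decode_states(permuted, coords)]
        np.testing.assert_array_equal(d1, d2)
        assert predict_turns(d1)[0] == predict_turns(d2)[0]


class TestGeometricChecks:
    def test_straight_path_fails_both_angle_checks(self):
        path = np.column_stack([np.arange(20.0), np.zeros(20)])
        res = angle_checks(path, 10)
        assert res["local_angle"] == pytest.approx(0.0, abs=1e-9)
        assert res["local_pass"] is False and res["distant_pass"] is False
        assert res["confirmed"] is False

    def test_right_angle_corner_passes_local(self):
        path = np.array(
            [[i, 0.0] for i in range(8)] + [[7.0, i] for i in range(1, 8)]
        )
        res = angle_checks(path, 7)
        assert res["local_angle"] == pytest.approx(90.0, abs=1e-9)
        assert res["confirmed"] is True

    def test_gradual_arc_caught_only_by_distant_check(self):
        # a gradual 35-degree bend spread over 4 frames: the short local
        # windows straddle only part of it, the distant chords see it all
        bend = np.radians(np.array([8.75, 17.5, 26.25, 35.0]))
        angles = np.concatenate([np.zeros(6), bend, np.full(6, bend[-1])])
        steps = np.column_stack([np.cos(angles), np.sin(angles)])
        path = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        res = angle_checks(path, 8)  # centre of the bend
        assert res["local_angle"] < 40 and res["local_pass"] is False
        assert res["distant_angle"] >= 25 and res["distant_pass"] is True

    def test_insufficient_frames_not_evaluable(self):
        path = np.column_stack([np.arange(6.0), np.zeros(6)])
        res = angle_checks(path, 2)
        assert res["distant_pass"] is None  # needs 6 frames either side
        assert res["local_pass"] is False
        res_edge = angle_checks(path, 1)
        assert res_edge["local_pass"] is None  # needs 2 frames before

    def test_rigid_motion_invariance(self, rng):
        path = np.cumsum(rng.normal(size=(20, 2)), axis=0)
        R = np.array([[np.cos(1.1), -np.sin(1.1)], [np.sin(1.1), np.cos(1.1)]])
        moved = path @ R.T + [50, -3]
        r1, r2 = angle_checks(path, 10), angle_checks(moved, 10)
        assert r1["local_angle"] == pytest.approx(r2["local_angle"], abs=1e-9)
        assert r1["distant_angle"] == pytest.approx(r2["distant_angle"], abs=1e-9)
        s1 = straightness_check(path)
        s2 = straightness_check(moved)
        assert s1["max_deviation"] == pytest.approx(s2["max_deviation"], abs=1e-9)


class TestStraightness:
    def test_collinear_points_pass(self):
        path = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        res = straightness_check(path)
        assert res["straight"] is True and res["max_deviation"] == 0.0

    def test_right_angle_path_fails(self):
        path = np.array([[i, 0.0] for i in range(6)] + [[5.0, i] for i in range(1, 6)])
        assert straightness_check(path)["straight"] is False

    def test_noisy_straight_path_passes(self, rng):
        n_pass = 0
        for _ in range(200):
            x = np.linspace(0, 100, 15)
            y = rng.normal(0, 1.0, 15)  # 1% of length
            if straightness_check(np.column_stack([x, y]))["straight"]:
                n_pass += 1
        assert n_pass >= 198

    def test_short_segments_not_evaluable(self):
        assert straightness_check(np.zeros((2, 2)))["straight"] is None


class TestLocateTrueTurn:
    def test_l_shaped_path_corner_found(self):
        path = np.array([[i, 0.0] for i in range(6)] + [[5.0, i] for i in range(1, 6)])
        res = locate_true_turn(path)
        assert res["frame"] == 5 and res["clear"]

    def test_straight_path_flagged_unclear(self):
        path = np.column_stack([np.arange(10.0), np.zeros(10)])
        res = locate_true_turn(path)
        assert not res["clear"]

    def test_degenerate_chord_rejected(self):
        loop = np.array([[0, 0], [1, 0], [1, 1], [0, 0]], float)
        with pytest.raises(ValueError, match="chord"):
            locate_true_turn(loop)

    def test_noisy_corner_localised_within_one_frame(self, rng):
        hits = 0
        for _ in range(500):
            arm = 10
            path = np.array(
                [[i, 0.0] for i in range(arm)] + [[arm - 1.0, i] for i in range(1, arm)]
            )
            noisy = path + rng.normal(0, 0.02 * arm, path.shape)
            res = locate_true_turn(noisy)
            hits += abs(res["frame"] - (arm - 1)) <= 1
        assert hits / 500 >= 0.95


class TestEvaluation:
    def test_exact_prediction_has_zero_delay(self):
        rep = evaluate_predictions([[10]], [[10]], track_lengths=[30])
        assert rep["delays_frames"].tolist() == [0.0]
        assert rep["fraction_within_window"] == 1.0
        assert rep["delays_minutes"].tolist() == [0.0]

    def test_midpoint_of_long_straight_segment_is_outside_window(self):
        # a 20-frame straight run before the turn: its midpoint is 10 frames out
        rep = evaluate_predictions([[20]], [[20]], track_lengths=[40])
        assert np.all(rep["control_delays_frames"] >= 5)
        assert rep["control_fraction_within_window"] == 0.0

    def test_synthetic_turns_fully_recovered(self):
        tracks = synthetic.make_migration_tracks(
            synthetic.TrackParams(seed=33), n_tracks=40
        )
        model = train_hmm([(t.emissions, t.states) for t in tracks[:10]])
        preds, trues, lengths = [], [], []
        for t in tracks[10:]:
            turns, _ = predict_turns(decode_states(model, t.emissions))
            preds.append(turns)
            trues.append(t.true_turns)
            lengths.append(t.states.size)
        rep = evaluate_predictions(preds, trues, lengths, window_frames=1)
        assert rep["recall"] >= 0.9
        assert rep["false_positive_rate"] <= 0.1

    def test_model_json_round_trip(self, tmp_path):
        model = _toy_model()
        model.save(tmp_path / "m.json")
        back = TurnModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.means, model.means)
        np.testing.assert_allclose(back.transmat, model.transmat)
        assert back.state_names == model.state_names
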