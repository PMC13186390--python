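"""Tests for the foraging path statistics and accuracy metrics."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from fomo.metrics import (
    best_r,
    chance_baseline,
    count_runs,
    intersection_rate,
    levy_exponent,
    max_run_length,
    pao,
    path_statistics,
    path_statistics_table,
    prediction_accuracy,
    shortest_hamiltonian_path,
    statistic_error_summary,
    switch_confusion,
)
from fomo.model import DataValidationError, InvalidParameterError


def brute_force_shortest_path(points):
    pts = np.asarray(points, dtype=float)
    best = np.inf
    for perm in permutations(range(len(pts))):
        length = np.hypot(*np.diff(pts[list(perm)], axis=0).T).sum()
        best = min(best, length)
    return best


def segments_cross_oracle(p1, p2, p3, p4):
    """Orientation-test oracle for proper crossing of two segments."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return np.sign(v)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def naive_intersection_count(points):
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    count = 0
    for i in range(n - 1):
        for j in range(i + 2, n - 1):
            if segments_cross_oracle(pts[i], pts[i + 1], pts[j], pts[j + 1]):
                count += 1
    return count


class TestChanceBaseline:
    def test_single_item(self):
        assert chance_baseline(1) == 1.0

    @pytest.mark.parametrize("n, expected", [(40, 0.11), (20, 0.18)])
    def test_printed_values(self, n, expected):
        assert round(chance_baseline(n), 2) == expected

    def test_harmonic_form(self):
        n = 13
        assert chance_baseline(n) == pytest.approx(
            sum(1.0 / k for k in range(1, n + 1)) / n
        )

    def test_invalid_n(self):
        with pytest.raises(InvalidParameterError):
            chance_baseline(0)


class TestRuns:
    @pytest.mark.parametrize(
        "seq, n_runs, max_run",
        [
            (list("AABBBA"), 3, 3),
            (["A"] * 40, 1, 40),
            (list("ABABAB"), 6, 1),
            (["B"], 1, 1),
        ],
    )
    def test_examples(self, seq, n_runs, max_run):
        assert count_runs(seq) == n_runs
        assert max_run_length(seq) == max_run

    def test_empty_rejected(self):
        with pytest.raises(DataValidationError):
            count_runs([])


class TestPao:
    def test_optimal_path_scores_zero(self):
        pts = [(x, 0.0) for x in range(5)]
        assert pao(pts) == pytest.approx(0.0)

    def test_double_length_scores_hundred(self):
        # visiting x = 3, 0, 2, 1 travels 3+2+1 = 6; optimal is 3
        pts = [(3.0, 0.0), (0.0, 0.0), (2.0, 0.0), (1.0, 0.0)]
        assert pao(pts) == pytest.approx(100.0)

    def test_exact_solver_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 9))
            pts = rng.uniform(0, 100, size=(n, 2))
            assert shortest_hamiltonian_path(pts) == pytest.approx(
                brute_force_shortest_path(pts), rel=1e-9
            )

    def test_nonnegative_even_in_heuristic_regime(self, rng):
        for _ in range(5):
            pts = rng.uniform(0, 100, size=(20, 2))
            assert pao(pts[rng.permutation(20)]) >= 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(DataValidationError):
            pao([(0.0, 0.0)])


class TestBestR:
    def test_left_to_right_sweep(self, rng):
        xs = np.arange(10.0)
        ys = rng.normal(0, 1, 10)
        assert best_r(np.column_stack([xs, ys])) == pytest.approx(1.0)

    def test_random_order_near_zero(self, rng):
        rs = []
        for _ in range(200):
            pts = rng.uniform(0, 1, size=(60, 2))
            rs.append(best_r(pts))
        # max of two |r| values, each ~N(0, 1/sqrt(58)) under independence
        assert np.mean(rs) < 0.3

    def test_axis_exchange_invariance(self, rng):
        pts = rng.uniform(0, 1, size=(15, 2))
        assert best_r(pts) == pytest.approx(best_r(pts[:, ::-1]))

    def test_degenerate_coordinates_flagged(self):
        pts = np.tile([2.0, 3.0], (5, 1))
        assert np.isnan(best_r(pts))


class TestIntersectionRate:
    def test_convex_perimeter_path_has_none(self):
        angles = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.column_stack([np.cos(angles), np.sin(angles)])
        assert intersection_rate(pts) == 0

    def test_bow_tie_crosses_once(self):
        assert intersection_rate([(0, 0), (1, 1), (1, 0), (0, 1)]) == 1

    def test_rotation_invariance(self, rng):
        pts = rng.uniform(0, 10, size=(12, 2))
        a = np.deg2rad(37.0)
        rot = pts @ np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])
        assert intersection_rate(pts) == intersection_rate(rot)

    def test_matches_orientation_oracle(self, rng):
        for _ in range(50):
            pts = rng.uniform(0, 1, size=(10, 2))
            assert intersection_rate(pts) == naive_intersection_count(pts)

    def test_short_paths_cannot_cross(self):
        assert intersection_rate([(0, 0), (1, 1), (2, 0)]) == 0


class TestLevyExponent:
    @staticmethod
    def power_law_sample(rng, n, mu=2.0, xmin=1.0):
        u = rng.uniform(size=n)
        return xmin * (1 - u) ** (-1.0 / (mu - 1.0))

    def test_recovers_known_exponent(self, rng):
        x = self.power_law_sample(rng, 10_000, mu=2.0)
        fit = levy_exponent(x)
        assert fit.mu == pytest.approx(2.0, abs=0.1)
        assert not fit.degenerate

    def test_scale_invariance(self, rng):
        x = self.power_law_sample(rng, 5_000, mu=2.5)
        a = levy_exponent(x)
        b = levy_exponent(10.0 * x)
        assert a.mu == pytest.approx(b.mu, abs=1e-6)

    def test_constant_distances_degenerate(self):
        fit = levy_exponent(np.full(100, 3.0))
        assert fit.degenerate and np.isnan(fit.mu)

    def test_low_n_flagged(self, rng):
        fit = levy_exponent(self.power_law_sample(rng, 30))
        assert fit.low_n


class TestPathStatisticsBundle:
    def test_bundle_consistency(self, rng):
        pts = rng.uniform(0, 100, size=(12, 2))
        classes = list("AABBABABABAB")
        stats = path_statistics(pts, classes)
        assert stats.n_runs == count_runs(classes)
        assert stats.pao == pytest.approx(pao(pts))
        assert 0.0 <= stats.best_r <= 1.0

    def test_tidy_table_shape(self, small_dataset):
        tbl = path_statistics_table(small_dataset.trials)
        assert set(tbl["statistic"]) == {
            "n_runs", "max_run_length", "pao", "best_r",
            "intersection_rate", "levy_mu",
        }
        # 6 observers x 2 conditions x 6 statistics
        assert len(tbl) == 6 * 2 * 6
        assert (tbl["source"] == "observed").all()


def _oracle_predictions(observed):
    sel = observed[observed["order"] > 0]
    preds = sel[["observer", "condition", "trial", "order", "item_id"]].copy()
    preds = preds.rename(columns={"item_id": "predicted_id"})
    preds["draw"] = 0
    return preds


class TestPredictionAccuracy:
    def test_oracle_predictor_is_perfect(self, small_dataset):
        preds = _oracle_predictions(small_dataset.trials)
        report = prediction_accuracy(preds, small_dataset.trials)
        assert report.overall == 1.0
        assert (report.per_position["accuracy"] == 1.0).all()

    def test_final_position_always_correct_for_valid_predictor(self, rng):
        """Any predictor restricted to the remaining set is right when one
        item remains."""
        from fomo.model import CoreParams, ModelConfig, SelectionState
        from fomo.simulate import generate_stimulus, predict_next

        cfg = ModelConfig(version="v1.0")
        cp = CoreParams(*rng.normal(0, 1, 4))
        stim = generate_stimulus(n_items=12, n_cols=4, n_rows=3, seed=rng)
        order = rng.permutation(stim.ids).tolist()
        state = SelectionState.from_selected(stim, order[:-1])
        assert predict_next(cp, None, cfg, state, stim, rng) == order[-1]

    def test_uniform_predictor_matches_chance(self, rng):
        """A uniform-over-remaining guesser scores the harmonic chance rate
        on uniformly generated trials."""
        n_items, n_trials = 20, 400
        hits = 0
        total = 0
        for _ in range(n_trials):
            order = rng.permutation(n_items)
            remaining = list(range(n_items))
            for k, true_pick in enumerate(order):
                guess = remaining[rng.integers(len(remaining))]
                if k >= 1:  # accuracy is scored after the first selection
                    hits += guess == true_pick
                    total += 1
                remaining.remove(true_pick)
        chance_after_first = np.mean(
            [1.0 / (n_items - i) for i in range(1, n_items)]
        )
        se = np.sqrt(chance_after_first * (1 - chance_after_first) / total)
        assert hits / total == pytest.approx(chance_after_first, abs=4 * se)


class TestSwitchConfusion:
    def test_oracle_predictor_perfect(self, small_dataset):
        preds = _oracle_predictions(small_dataset.trials)
        tbl = switch_confusion(preds, small_dataset.trials)
        assert (tbl["accuracy"] == 1.0).all()

    def test_always_stick_predictor(self, small_dataset):
        obs = small_dataset.trials
        sel = obs[obs["order"] > 0].sort_values(
            ["observer", "condition", "trial", "order"]
        )
        # predict, at every position, an item of the same class as the
        # previous selection (the previous item itself is a valid stand-in
        # for class purposes here: it always "sticks")
        preds = sel.copy()
        preds["predicted_id"] = preds.groupby(
            ["observer", "condition", "trial"]
        )["item_id"].shift(1)
        preds = preds.dropna(subset=["predicted_id"])
        preds["predicted_id"] = preds["predicted_id"].astype(int)
        preds["draw"] = 0
        tbl = switch_confusion(
            preds[["draw", "observer", "condition", "trial", "order", "predicted_id"]],
            obs,
        )
        stick = tbl[tbl["transition"] == "stick"]["accuracy"]
        switch = tbl[tbl["transition"] == "switch"]["accuracy"]
        assert (stick == 1.0).all()
        assert (switch == 0.0).all()

    def test_sticky_generator_sticks_more_than_switches(self, small_dataset):
        """Data simulated with b_s >> 0 contain more sticks than switches."""
        obs = small_dataset.trials
        sel = obs[obs["order"] > 0].sort_values(
            ["observer", "condition", "trial", "order"]
        )
        prev = sel.groupby(["observer", "condition", "trial"])["item_class"].shift(1)
        sticks = (sel["item_class"] == prev).sum()
        switches = (sel["item_class"] != prev).sum() - prev.isna().sum()
        assert sticks > switches


class TestStatisticErrorSummary:
    @staticmethod
    def _tables(rng, offset=0.0):
        rows = []
        for obs in range(8):
            for cond in ("a", "b"):
                for stat in ("pao", "best_r"):
                    rows.append(
                        {
                            "observer": obs,
                            "condition": cond,
                            "statistic": stat,
                            "value": rng.normal(10, 2),
                            "source": "observed",
                        }
                    )
        observed = pd.DataFrame(rows)
        predicted = observed.copy()
        predicted["value"] = predicted["value"] + offset
        predicted["source"] = "predicted"
        return observed, predicted

    def test_perfect_predictions_zero_error(self, rng):
        observed, predicted = self._tables(rng)
        err = statistic_error_summary(observed, predicted)
        assert (err["scaled_error"] == 0.0).all()

    def test_one_sd_offset_scores_one(self, rng):
        observed, predicted = self._tables(rng)
        for stat, g in observed.groupby("statistic"):
            sd = g["value"].std(ddof=1)
            mask = predicted["statistic"] == stat
            predicted.loc[mask, "value"] = observed.loc[mask, "value"] + sd
        err = statistic_error_summary(observed, predicted)
        assert np.allclose(err["scaled_error"], 1.0)

    def test_affine_invariance(self, rng):
        observed, predicted = self._tables(rng, offset=1.3)
        base = statistic_error_summary(observed, predicted)
        scaled_obs = observed.copy()
        scaled_pred = predicted.copy()
        scaled_obs["value"] = 7.0 * scaled_obs["value"] - 2.0
        scaled_pred["value"] = 7.0 * scaled_pred["value"] - 2.0
        scaled = statistic_error_summary(scaled_obs, scaled_pred)
        assert np.allclose(base["scaled_error"], scaled["scaled_error"])
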