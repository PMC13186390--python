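"""Unit and property tests for the core selection model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0

from fomo.model import (
    CoreParams,
    DirectionParams,
    InvalidParameterError,
    InvalidStateError,
    ModelConfig,
    SelectionState,
    Stimulus,
    UnsupportedVersionError,
    absolute_angle,
    build_model,
    class_weight,
    direction_gain,
    item_weight,
    relative_direction,
    scaled_distance,
    selection_distribution,
    selection_log_weights,
    selection_probabilities,
    stick_weight,
)

from conftest import random_state, random_stimulus


class TestClassAndStickWeights:
    @pytest.mark.parametrize(
        "b, cls, expected",
        [
            (0.0, "A", 0.5),
            (0.0, "B", 0.5),
            # logistic(1.5) = 1/(1+e^-1.5), evaluated independently
            (1.5, "A", 1.0 / (1.0 + np.exp(-1.5))),
            (1.5, "B", 1.0 - 1.0 / (1.0 + np.exp(-1.5))),
        ],
    )
    def test_class_weight_values(self, b, cls, expected):
        assert class_weight(b, cls) == pytest.approx(expected, abs=1e-12)

    def test_class_weights_sum_to_one(self):
        for b in (-2.0, 0.0, 0.7, 3.5):
            assert class_weight(b, "A") + class_weight(b, "B") == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "b, prev, cand, expected",
        [
            (0.0, "A", "A", 0.5),
            (2.0, "A", "B", 1.0 - 1.0 / (1.0 + np.exp(-2.0))),
        ],
    )
    def test_stick_weight_values(self, b, prev, cand, expected):
        assert stick_weight(b, prev, cand) == pytest.approx(expected, abs=1e-12)

    def test_positive_stick_bias_favours_repeats(self):
        for b in (0.1, 1.0, 4.0):
            assert stick_weight(b, "A", "A") > stick_weight(b, "A", "B")

    def test_nonfinite_bias_rejected(self):
        with pytest.raises(InvalidParameterError):
            class_weight(np.nan, "A")
        with pytest.raises(InvalidParameterError):
            stick_weight(np.inf, "A", "B")


class TestGeometry:
    @pytest.mark.parametrize(
        "p, q, d0, expected",
        [
            ((0, 0), (0, 0), 20.0, 0.0),
            ((0, 0), (3, 4), 1.0, 5.0),
            ((0, 0), (60, 80), 20.0, 5.0),
        ],
    )
    def test_scaled_distance(self, p, q, d0, expected):
        assert scaled_distance(p, q, d0) == pytest.approx(expected)
        assert scaled_distance(q, p, d0) == pytest.approx(expected)

    def test_scaled_distance_rejects_bad_delta0(self):
        with pytest.raises(InvalidParameterError):
            scaled_distance((0, 0), (1, 1), 0.0)

    @pytest.mark.parametrize(
        "q, expected",
        [((1, 0), 0.0), ((0, 1), np.pi / 2), ((-1, -1), -3 * np.pi / 4)],
    )
    def test_absolute_angle(self, q, expected):
        assert absolute_angle((0, 0), q) == pytest.approx(expected)

    def test_absolute_angle_coincident_points(self):
        with pytest.raises(InvalidStateError):
            absolute_angle((2, 3), (2, 3))

    @pytest.mark.parametrize(
        "cand, expected",
        [((2, 0), 1.0), ((1, 1), 0.5), ((0, 0), 0.0)],
    )
    def test_relative_direction_anchors(self, cand, expected):
        # straight ahead = 1, perpendicular = 0.5, reversal = 0
        assert relative_direction((0, 0), (1, 0), cand) == pytest.approx(expected)

    @given(st.floats(-np.pi, np.pi))
    @settings(max_examples=50, deadline=None)
    def test_relative_direction_bounded(self, angle):
        cand = (1 + np.cos(angle), np.sin(angle))
        if np.hypot(cand[0] - 1, cand[1]) < 1e-9:
            return
        psi = relative_direction((0, 0), (1, 0), cand)
        assert 0.0 <= psi <= 1.0


class TestDirectionGain:
    def test_zero_weights_give_unit_gain(self, neutral_direction):
        for phi in (-3.0, 0.0, 1.2):
            assert direction_gain(neutral_direction, phi) == pytest.approx(1.0)

    def test_gain_at_component_peak(self):
        # exp(vM(0; 0, 20)) with vM density e^kappa/(2 pi I0(kappa))
        dp = DirectionParams(theta=(1.0, 0.0, 0.0, 0.0), kappa=20.0)
        expected = np.exp(np.exp(20.0) / (2 * np.pi * i0(20.0)))
        assert direction_gain(dp, 0.0) == pytest.approx(expected, rel=1e-9)
        assert direction_gain(dp, 0.0) == pytest.approx(5.89, rel=1e-2)

    def test_gain_periodic(self):
        dp = DirectionParams(theta=(0.5, -0.2, 0.8, 0.1), kappa=20.0)
        for phi in np.linspace(-np.pi, np.pi, 7):
            assert direction_gain(dp, phi) == pytest.approx(
                direction_gain(dp, phi + 2 * np.pi)
            )

    def test_positive_theta_attracts(self):
        dp = DirectionParams(theta=(1.0, 0.0, 0.0, 0.0), kappa=20.0)
        assert direction_gain(dp, 0.0) > direction_gain(dp, np.pi / 2)

    def test_invalid_kappa(self):
        with pytest.raises(InvalidParameterError):
            DirectionParams(theta=(0.0,) * 4, kappa=0.0)


class TestItemWeight:
    def test_neutral_model_equal_weights(self, square_stimulus, neutral_params):
        cfg = ModelConfig(version="v1.0")
        state = SelectionState.from_selected(square_stimulus, [0])
        ws = [
            item_weight(neutral_params, None, cfg, state, square_stimulus, j)
            for j in (1, 2, 3)
        ]
        assert np.allclose(ws, ws[0])

    def test_proximity_prefers_near(self):
        stim = Stimulus.from_arrays([0, 20, 40], [0, 0, 0], ["A", "A", "A"])
        cp = CoreParams(0.0, 0.0, 1.0, 0.0)
        cfg = ModelConfig(version="v1.0")
        state = SelectionState.from_selected(stim, [0])
        near = item_weight(cp, None, cfg, state, stim, 1)
        far = item_weight(cp, None, cfg, state, stim, 2)
        assert near > far
        # hand-derived ratio: exp(-1)/exp(-2) = e at delta0 = 20
        assert near / far == pytest.approx(np.e)

    def test_already_selected_rejected(self, square_stimulus, neutral_params):
        cfg = ModelConfig(version="v1.0")
        state = SelectionState.from_selected(square_stimulus, [0, 1])
        with pytest.raises(InvalidStateError):
            item_weight(neutral_params, None, cfg, state, square_stimulus, 1)


class TestSelectionDistribution:
    def test_single_remaining_item_is_certain(self, square_stimulus):
        state = SelectionState.from_selected(square_stimulus, [0, 1, 2])
        probs = selection_distribution(np.ones(4), state)
        assert probs[3] == pytest.approx(1.0)

    def test_equal_weights_split_evenly(self, square_stimulus):
        state = SelectionState.from_selected(square_stimulus, [0, 1])
        probs = selection_distribution(np.ones(4), state)
        assert probs[2] == probs[3] == pytest.approx(0.5)

    def test_selected_items_have_zero_mass(self, square_stimulus, rng):
        state = SelectionState.from_selected(square_stimulus, [1, 3])
        probs = selection_distribution(rng.uniform(0.1, 1, 4), state)
        assert probs[1] == 0.0 and probs[3] == 0.0
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_weights_degenerate(self, square_stimulus):
        from fomo.model import DegenerateWeightsError

        state = SelectionState.from_selected(square_stimulus, [0])
        with pytest.raises(DegenerateWeightsError):
            selection_distribution(np.zeros(4), state)


class TestInvariants:
    """Structural properties of the selection distribution."""

    def test_normalisation_and_shift_invariance(self, rng):
        cfg = ModelConfig(version="v1.3")
        for _ in range(50):
            stim = random_stimulus(rng)
            state = random_state(rng, stim)
            cp = CoreParams(*rng.normal(0, 1, 4))
            dp = DirectionParams(theta=tuple(rng.normal(0, 1, 4)), kappa=20.0)
            probs = selection_probabilities(cp, dp, cfg, state, stim)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)
            # multiplying all weights by a constant changes nothing
            log_w = selection_log_weights(cp, dp, cfg, state, stim)
            shifted = np.exp(log_w - np.nanmax(log_w) + 3.0)
            shifted[np.isnan(shifted)] = 0.0
            renorm = selection_distribution(np.nan_to_num(shifted), state)
            assert np.allclose(renorm, probs, atol=1e-12)

    def test_direction_free_versions_nest(self, rng):
        """v1.3 with theta = 0 must reproduce v1.0 exactly."""
        cp = CoreParams(0.3, 0.8, 1.2, 0.4)
        dp0 = DirectionParams(theta=(0.0,) * 4, kappa=20.0)
        for _ in range(25):
            stim = random_stimulus(rng)
            state = random_state(rng, stim)
            p13 = selection_probabilities(cp, dp0, ModelConfig("v1.3"), state, stim)
            p10 = selection_probabilities(cp, None, ModelConfig("v1.0"), state, stim)
            assert np.allclose(p13, p10, atol=1e-12)

    def test_psi_convention_equivalence(self, rng):
        """psi = 1 - D/pi with +rho exponent equals psi' = D/pi with -rho:
        the constant factor cancels in the normalisation."""
        cfg = ModelConfig(version="v1.0")
        for _ in range(25):
            stim = random_stimulus(rng)
            state = random_state(rng, stim, n_selected=3)
            rho_psi = float(rng.normal(0, 1))
            cp = CoreParams(0.0, 0.0, 0.0, rho_psi)
            probs = selection_probabilities(cp, None, cfg, state, stim)
            # recompute with the alternative convention by hand
            cur = stim.xy[stim.index_of(state.selected[-1])]
            prev = stim.xy[stim.index_of(state.selected[-2])]
            heading = np.arctan2(*(cur - prev)[::-1])
            log_w = np.full(stim.n_items, -np.inf)
            for j in sorted(state.remaining):
                idx = stim.index_of(j)
                phi = np.arctan2(*(stim.xy[idx] - cur)[::-1])
                delta = abs((phi - heading + np.pi) % (2 * np.pi) - np.pi)
                log_w[idx] = -rho_psi * (delta / np.pi)
            alt = np.exp(log_w - np.logaddexp.reduce(log_w))
            assert np.allclose(alt, probs, atol=1e-10)

    def test_quarter_turn_rotation_permutes_theta(self, rng):
        """Rotating the display by 90 degrees and rotating theta with it
        leaves the selection probabilities unchanged (K = 4)."""
        cfg = ModelConfig(version="v1.3")
        cp = CoreParams(0.2, 0.5, 1.0, 0.3)
        for _ in range(10):
            stim = random_stimulus(rng)
            state = random_state(rng, stim)
            theta = rng.normal(0, 1, 4)
            dp = DirectionParams(theta=tuple(theta), kappa=20.0)
            probs = selection_probabilities(cp, dp, cfg, state, stim)
            # rotate coordinates by +90 deg: (x, y) -> (-y, x)
            rot = Stimulus.from_arrays(
                -stim.xy[:, 1], stim.xy[:, 0], stim.classes, ids=stim.ids
            )
            rot_state = SelectionState.from_selected(rot, state.selected)
            dp_rot = DirectionParams(theta=tuple(np.roll(theta, 1)), kappa=20.0)
            probs_rot = selection_probabilities(cp, dp_rot, cfg, rot_state, rot)
            assert np.allclose(probs_rot, probs, atol=1e-10)


class TestVersions:
    @pytest.mark.parametrize(
        "vid, rel, nabs",
        [
            ("v1.0", True, 0),
            ("v1.2", False, 0),
            ("v1.3", True, 4),
            ("v1.4", True, 8),
            ("v1.5", False, 4),
        ],
    )
    def test_version_flags(self, vid, rel, nabs):
        v = build_model(vid)
        assert v.include_rel_dir is rel
        assert v.n_abs_directions == nabs

    @pytest.mark.parametrize("vid", ["v1.1", "v9.9", "nonsense"])
    def test_unknown_versions_rejected(self, vid):
        with pytest.raises(UnsupportedVersionError):
            build_model(vid)
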