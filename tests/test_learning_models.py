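"""Update equations, choice rules and the one-trial dispatcher."""

import math

import numpy as np
import pytest

from conftest import random_params, random_trial_table
from cpelearn.models import (
    LearnerState,
    ParameterSet,
    TrialContext,
    TrialObservation,
    choice_probability,
    perseveration_choice_prob,
    softmax_choice_prob,
    step_trial,
    transfer_confidence_to_value,
    update_expected_confidence,
    update_value_choice,
    update_value_deval,
    update_value_reward,
)


class TestParameterSet:
    def test_parameter_counts(self):
        counts = {"Static": 2, "Deval": 3, "Choice": 3, "Perseveration": 3,
                  "ConfSpec": 4, "ConfUnspec": 4}
        rng = np.random.default_rng(0)
        for kind, k in counts.items():
            assert random_params(kind, rng).k == k

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ParameterSet("Static", alpha_r=1.2, beta=0.5)
        with pytest.raises(ValueError):
            ParameterSet("Static", alpha_r=0.5, beta=2.5)
        with pytest.raises(ValueError):
            ParameterSet("Perseveration", alpha_r=0.5, beta=0.5, eta=-6.0)

    def test_inactive_parameters_dropped(self):
        p = ParameterSet("Static", alpha_r=0.5, beta=0.5, gamma=3.0)
        assert p.gamma is None

    def test_missing_active_parameter_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet("ConfUnspec", alpha_r=0.5, beta=0.5, alpha_c=0.1)

    def test_vector_roundtrip(self):
        p = ParameterSet("ConfSpec", alpha_r=0.3, beta=0.4, alpha_c=0.2, gamma=5.0)
        assert ParameterSet.from_vector("ConfSpec", p.to_vector()) == p


class TestChoiceRules:
    def test_softmax_symmetry_and_random_limits(self):
        assert softmax_choice_prob(1.3, 5.0, 5.0) == 0.5
        assert softmax_choice_prob(0.0, 40.0, 2.0) == 0.5

    def test_softmax_direct_evaluation(self):
        # beta 0.2, value difference 6 -> 1 / (1 + e^-1.2)
        expected = 1.0 / (1.0 + math.exp(-1.2))
        assert softmax_choice_prob(0.2, 10.0, 4.0) == pytest.approx(expected, abs=1e-12)

    def test_softmax_numerically_stable(self):
        assert softmax_choice_prob(2.0, 1000.0, -1000.0) == pytest.approx(1.0)
        assert softmax_choice_prob(2.0, -1000.0, 1000.0) == pytest.approx(0.0)

    def test_softmax_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            softmax_choice_prob(0.5, np.inf, 0.0)

    def test_perseveration_reduces_to_softmax_when_eta_zero(self):
        for dv in (-4.0, 0.0, 3.0):
            assert perseveration_choice_prob(0.4, 0.0, dv, 0.0, 1, 0) == \
                softmax_choice_prob(0.4, dv, 0.0)

    def test_perseveration_direct_evaluation(self):
        # beta 0.2, equal values, eta 0.73, previous choice right
        expected = 1.0 / (1.0 + math.exp(-0.146))
        assert perseveration_choice_prob(0.2, 0.73, 3.0, 3.0, 1, 0) == \
            pytest.approx(expected, abs=1e-12)

    def test_perseveration_no_previous_encounter_symmetric(self):
        assert perseveration_choice_prob(0.9, 2.0, 4.0, 4.0, 0, 0) == 0.5

    def test_perseveration_rejects_double_indicator(self):
        with pytest.raises(ValueError):
            perseveration_choice_prob(0.5, 1.0, 1.0, 1.0, 1, 1)


class TestUpdateRules:
    def setup_method(self):
        self.state = LearnerState.initial(5)

    def test_reward_update_direct(self):
        new = update_value_reward(self.state, 2, reward=20.0, alpha_r=0.25)
        assert new.v[2] == pytest.approx(5.0)
        assert np.all(new.v[[0, 1, 3, 4]] == 0.0)
        assert self.state.v[2] == 0.0  # input untouched

    def test_reward_update_identities(self):
        s = update_value_reward(self.state, 0, reward=12.0, alpha_r=0.0)
        assert np.array_equal(s.v, self.state.v)
        s2 = update_value_reward(self.state, 0, reward=0.0, alpha_r=0.7)
        assert np.array_equal(s2.v, self.state.v)  # reward equals current value

    def test_reward_update_unknown_cs(self):
        with pytest.raises(ValueError):
            update_value_reward(self.state, 9, 5.0, 0.5)

    def test_confidence_update_direct(self):
        s = self.state.copy()
        s.c_global = 0.5
        new, dc = update_expected_confidence(s, 0, confidence=0.8, alpha_c=0.14)
        assert dc == pytest.approx(0.3)
        assert new.c_global == pytest.approx(0.542)

    def test_confidence_update_zero_rate(self):
        new, dc = update_expected_confidence(self.state, 0, 0.9, alpha_c=0.0)
        assert dc == pytest.approx(0.9)
        assert new.c_global == 0.0

    def test_confidence_update_per_cs_mode(self):
        new, dc = update_expected_confidence(self.state, 3, 0.6, 0.5,
                                             specificity="per-cs")
        assert dc == pytest.approx(0.6)
        assert new.c_cs[3] == pytest.approx(0.3)
        assert new.c_cs[0] == 0.0 and new.c_global == 0.0

    def test_confidence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            update_expected_confidence(self.state, 0, 1.2, 0.5)

    def test_confidence_transfer_direct(self):
        s = self.state.copy()
        s.v[1] = 3.0
        new = transfer_confidence_to_value(s, 1, delta_c=0.3, gamma=8.0)
        assert new.v[1] == pytest.approx(5.4)

    def test_transfer_identities(self):
        s = transfer_confidence_to_value(self.state, 0, 0.0, 100.0)
        assert np.array_equal(s.v, self.state.v)
        s = transfer_confidence_to_value(self.state, 0, 0.4, 0.0)
        assert np.array_equal(s.v, self.state.v)

    def test_no_feedback_rules_reject_feedback_phase(self):
        for fn, args in [
            (transfer_confidence_to_value, (0, 0.2, 5.0)),
            (update_value_choice, (0, 1.0)),
            (update_value_deval, (0, 0.5)),
        ]:
            with pytest.raises(ValueError):
                fn(self.state, *args, no_feedback=False)

    def test_choice_update_additivity(self):
        s = self.state.copy()
        s.v[0] = 3.0
        s = update_value_choice(s, 0, 0.97)
        assert s.v[0] == pytest.approx(3.97)
        s = update_value_choice(s, 0, 0.97)
        assert s.v[0] == pytest.approx(3.0 + 2 * 0.97)

    def test_deval_update(self):
        s = self.state.copy()
        s.v[4] = 10.0
        assert update_value_deval(s, 4, 0.1).v[4] == pytest.approx(9.0)
        assert update_value_deval(s, 4, 0.0).v[4] == pytest.approx(10.0)
        assert update_value_deval(self.state, 4, 0.9).v[4] == 0.0  # fixed point


class TestStepTrial:
    def test_static_phase2_leaves_values_unchanged(self):
        p = ParameterSet("Static", alpha_r=0.5, beta=0.5)
        s = LearnerState.initial(5)
        s.v[:] = [1, 2, 3, 4, 5]
        ctx = TrialContext(phase=2, left_cs=0, right_cs=1, mode="fitting")
        new, info = step_trial("Static", p, s, ctx,
                               TrialObservation(chosen_cs=1))
        assert np.array_equal(new.v, s.v)

    def test_confunspec_phase2_composition(self):
        """CPE update then transfer: c=0.8, c_bar=0.5, gamma=8 moves v by 2.4."""
        p = ParameterSet("ConfUnspec", alpha_r=0.5, beta=0.5, alpha_c=0.14, gamma=8.0)
        s = LearnerState.initial(5)
        s.c_global = 0.5
        s.v[1] = 3.0
        s.v[0] = -10.0  # predicted choice is CS 1
        ctx = TrialContext(phase=2, left_cs=0, right_cs=1, mode="fitting")
        new, info = step_trial("ConfUnspec", p, s, ctx,
                               TrialObservation(chosen_cs=1, confidence=0.8))
        assert info.delta_c == pytest.approx(0.3)
        assert new.v[1] == pytest.approx(3.0 + 8.0 * 0.3)
        assert new.c_global == pytest.approx(0.542)

    def test_generative_mode_targets_sampled_choice(self):
        p = ParameterSet("ConfUnspec", alpha_r=0.5, beta=0.5, alpha_c=0.0, gamma=5.0)
        s = LearnerState.initial(5)
        s.v[0] = 10.0  # model strongly prefers CS 0 ...
        ctx = TrialContext(phase=2, left_cs=0, right_cs=1, mode="generative")
        new, info = step_trial("ConfUnspec", p, s, ctx,
                               TrialObservation(chosen_cs=1, confidence=0.2))
        assert info.phase2_target == 1  # ... but the sampled choice is updated
        assert new.v[1] == pytest.approx(5.0 * 0.2)

    def test_phase2_observed_reward_rejected(self):
        p = ParameterSet("Static", alpha_r=0.5, beta=0.5)
        ctx = TrialContext(phase=2, left_cs=0, right_cs=1)
        with pytest.raises(ValueError):
            step_trial("Static", p, LearnerState.initial(5), ctx,
                       TrialObservation(chosen_cs=0, reward=5.0,
                                        reward_observed=True))

    def test_feedback_phase_requires_reward(self):
        p = ParameterSet("Static", alpha_r=0.5, beta=0.5)
        ctx = TrialContext(phase=1, left_cs=0, right_cs=1)
        with pytest.raises(ValueError):
            step_trial("Static", p, LearnerState.initial(5), ctx,
                       TrialObservation(chosen_cs=0))


def _trial_probs(model_kind, params, df):
    """Per-trial choice probabilities chained through the pure ops."""
    from cpelearn.models import LearnerState

    probs = []
    for _, bdf in df.groupby("block", sort=False):
        state = LearnerState.initial(5)
        for row in bdf.itertuples(index=False):
            ctx = TrialContext(phase=int(row.phase), left_cs=int(row.left_cs),
                               right_cs=int(row.right_cs), mode="fitting")
            observed = row.phase != 2
            obs = TrialObservation(
                chosen_cs=int(row.chosen_cs),
                reward=float(row.reward) if observed else None,
                reward_observed=observed,
                confidence=float(row.confidence),
            )
            state, info = step_trial(model_kind, params, state, ctx, obs)
            probs.append(info.p_right)
    return np.array(probs)


@pytest.mark.parametrize("kind,null_param", [
    ("Deval", {"alpha_d": 0.0}),
    ("Choice", {"lambda_": 0.0}),
    ("ConfSpec", {"alpha_c": 0.3, "gamma": 0.0}),
    ("ConfUnspec", {"alpha_c": 0.3, "gamma": 0.0}),
    ("Perseveration", {"eta": 0.0}),
])
def test_nesting_identities(kind, null_param):
    """With the extra parameter nulled every model is trial-wise identical
    to Static, to machine precision, on random trial sequences."""
    rng = np.random.default_rng(99)
    for rep in range(10):
        df = random_trial_table(rng)
        alpha_r, beta = rng.uniform(0.1, 0.9), rng.uniform(0.1, 1.5)
        static = ParameterSet("Static", alpha_r=alpha_r, beta=beta)
        nested = ParameterSet(kind, alpha_r=alpha_r, beta=beta, **null_param)
        np.testing.assert_array_equal(
            _trial_probs(kind, nested, df), _trial_probs("Static", static, df)
        )


def test_confspec_equals_confunspec_when_one_cs_chosen():
    """With a single ever-chosen CS the specific and unspecific confidence
    references coincide, so the trajectories are identical."""
    rng = np.random.default_rng(5)
    rows = []
    for t in range(12):
        phase = 1 if t < 6 else 2
        conf = float(np.round(rng.random(), 3))
        rows.append({
            "subject": "s0", "block": 0, "trial": t, "phase": phase,
            "left_cs": 0, "right_cs": 1, "left_value": 20.0, "right_value": 25.0,
            "chosen_side": "right", "chosen_cs": 1,
            "reward": float(rng.integers(0, 51)) if phase != 2 else np.nan,
            "confidence_raw": conf * 10, "confidence": conf, "correct": np.nan,
        })
    import pandas as pd

    df = pd.DataFrame(rows)
    common = dict(alpha_r=0.4, beta=1.2, alpha_c=0.3, gamma=4.0)
    # beta high enough that CS 1 stays the predicted (and chosen) target
    ps = _trial_probs("ConfSpec", ParameterSet("ConfSpec", **common), df)
    pu = _trial_probs("ConfUnspec", ParameterSet("ConfUnspec", **common), df)
    np.testing.assert_allclose(ps, pu, rtol=0, atol=1e-15)


def test_probabilities_and_confidence_bounds():
    """c_bar stays in [0, 1]; values stay finite; p_left + p_right = 1."""
    rng = np.random.default_rng(123)
    for kind in ("ConfSpec", "ConfUnspec", "Perseveration"):
        df = random_trial_table(rng, n_blocks=2)
        params = random_params(kind, rng)
        from cpelearn.models import LearnerState

        for _, bdf in df.groupby("block"):
            state = LearnerState.initial(5)
            for row in bdf.itertuples(index=False):
                ctx = TrialContext(phase=int(row.phase), left_cs=int(row.left_cs),
                                   right_cs=int(row.right_cs))
                observed = row.phase != 2
                obs = TrialObservation(
                    chosen_cs=int(row.chosen_cs),
                    reward=float(row.reward) if observed else None,
                    reward_observed=observed,
                    confidence=float(row.confidence),
                )
                p_right = choice_probability(kind, params, state, ctx)
                assert 0.0 < p_right < 1.0 or p_right in (0.0, 1.0)
                state, _ = step_trial(kind, params, state, ctx, obs)
                assert 0.0 <= state.c_global <= 1.0
                assert np.all((state.c_cs >= 0.0) & (state.c_cs <= 1.0))
                assert np.all(np.isfinite(state.v))
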