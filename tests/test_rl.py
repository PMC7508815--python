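"""Reinforcement-learning kernels: updates, choice rule, likelihoods."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cwcst._engine import compile_trials, loglik_batch
from cwcst.inference import PARAM_SPECS, make_params
from cwcst.rl import (
    RLParams,
    RLState,
    init_rl_state,
    mb_response_values,
    rl_response_probs,
    rl_sequence_loglik,
    rl_update,
    softmax,
)
from cwcst.task import StimulusCard


def mbrl(**kw):
    base = dict(alpha_mb_pos=0.5, alpha_mb_neg=0.5, gamma_mb=0.5, tau=1.0, variant="mbrl")
    base.update(kw)
    return RLParams(**base)


class TestInitAndValues:
    def test_initial_state_is_zero(self):
        s = init_rl_state()
        assert np.all(s.q_c == 0) and np.all(s.q_mf == 0)
        t = init_rl_state()
        assert s is not t and np.all(s.q_c == t.q_c)

    def test_initial_probs_uniform_over_matched_keys(self):
        """At the zero state only the unmatched key (MB value -1) deviates."""
        card = StimulusCard(2, 3, 4)
        probs = rl_response_probs(init_rl_state(), card, mbrl())
        assert probs[1] == probs[2] == probs[3]
        assert probs[0] < probs[1]

    def test_mb_values_read_q_c_through_the_card(self):
        state = RLState(np.array([0.5, -0.2, 0.1]), np.zeros(4))
        vals = mb_response_values(state, StimulusCard(2, 3, 4))
        assert np.allclose(vals, [-1.0, 0.5, -0.2, 0.1])

    def test_mb_values_permute_with_card(self):
        state = RLState(np.array([0.5, -0.2, 0.1]), np.zeros(4))
        vals = mb_response_values(state, StimulusCard(3, 2, 4))
        assert np.allclose(vals, [-1.0, -0.2, 0.5, 0.1])


class TestChoiceRule:
    def test_softmax_of_constant_is_uniform(self):
        assert np.allclose(softmax(np.full(4, 0.3), 0.7), 0.25)

    def test_softmax_matches_closed_form(self):
        q = np.array([1.0, 0.0, 0.0, -1.0])
        expected = np.exp(q) / np.exp(q).sum()
        assert np.allclose(softmax(q, 1.0), expected, atol=1e-12)

    def test_lower_temperature_sharpens(self):
        q = np.array([0.5, 0.1, -0.2, -0.6])
        p_hot = softmax(q, 1.0).max()
        p_cold = softmax(q, 0.2).max()
        assert p_cold > p_hot

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            softmax(np.zeros(4), 0.0)


class TestUpdate:
    def test_full_learning_from_zero(self):
        params = mbrl(alpha_mb_pos=1.0, gamma_mb=1.0)
        card = StimulusCard(2, 3, 4)
        new = rl_update(init_rl_state(), card, 2, +1, params)  # applies color
        assert np.allclose(new.q_c, [1.0, 0.0, 0.0])

    def test_hand_computed_negative_update(self):
        """0.8 decays to 0.4; delta = -1.4; new value 0.4 + 0.6*(-1.4) = -0.44."""
        params = mbrl(gamma_mb=0.5, alpha_mb_neg=0.6)
        state = RLState(np.array([0.8, 0.0, 0.0]), np.zeros(4))
        new = rl_update(state, StimulusCard(2, 3, 4), 2, -1, params)
        assert abs(new.q_c[0] - (-0.44)) < 1e-10

    def test_zero_mf_learning_rate_keeps_value(self):
        params = RLParams(
            alpha_mb_pos=0.5, alpha_mb_neg=0.5, gamma_mb=0.5, tau=1.0,
            variant="prl", alpha_mf_pos=0.0, alpha_mf_neg=0.3, gamma_mf=1.0,
        )
        state = RLState(np.zeros(3), np.array([0.0, 0.5, 0.0, 0.0]))
        new = rl_update(state, StimulusCard(2, 3, 4), 2, +1, params)
        assert new.q_mf[1] == 0.5

    def test_unmatched_key_decays_mb_only(self):
        params = RLParams(
            alpha_mb_pos=0.9, alpha_mb_neg=0.9, gamma_mb=0.5, tau=1.0,
            variant="prl", alpha_mf_pos=0.2, alpha_mf_neg=0.4, gamma_mf=0.8,
        )
        state = RLState(np.array([0.6, 0.2, -0.2]), np.full(4, 0.1))
        new = rl_update(state, StimulusCard(2, 3, 4), 1, -1, params)  # key 1 unmatched
        assert np.allclose(new.q_c, 0.5 * state.q_c)  # decay, no delta update
        assert new.q_mf[0] == pytest.approx(0.8 * 0.1 + 0.4 * (-1 - 0.08))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            mbrl(alpha_mb_pos=1.2)
        with pytest.raises(ValueError):
            mbrl(tau=0.0)


class TestSequenceLoglik:
    def test_single_trial_matches_softmax_entry(self):
        params = RLParams(
            alpha_mb_pos=0.5, alpha_mb_neg=0.5, gamma_mb=0.5, tau=1.0,
            variant="prl", alpha_mf_pos=0.1, alpha_mf_neg=0.1, gamma_mf=0.5,
        )
        from cwcst.task import TrialRecord

        card = StimulusCard(2, 3, 4)
        trial = TrialRecord("s", 1, card, 2, 0, 1, 0)
        total, per = rl_sequence_loglik([trial], params)
        expected = np.log(softmax(np.array([-1.0, 0.0, 0.0, 0.0]), 1.0)[1])
        assert total == pytest.approx(expected, abs=1e-12)
        assert per.shape == (1,)

    def test_per_trial_values_sum_to_total(self, wprl_session, wprl_params):
        total, per = rl_sequence_loglik(wprl_session, wprl_params)
        assert total == pytest.approx(per.sum(), abs=1e-10)
        assert np.all(np.isfinite(per))

    def test_rejects_mixed_subjects(self, wprl_session):
        from dataclasses import replace

        bad = [wprl_session[0], replace(wprl_session[1], subject_id="other")]
        with pytest.raises(ValueError, match="mixes subjects"):
            rl_sequence_loglik(bad, mbrl())

    def test_weight_one_reduces_to_pure_model_based(self, random_sessions):
        rng = np.random.default_rng(3)
        for trials in random_sessions[:6]:
            shared = dict(
                alpha_mb_pos=rng.uniform(0.1, 0.9),
                alpha_mb_neg=rng.uniform(0.1, 0.9),
                gamma_mb=rng.uniform(0.1, 0.9),
                tau=rng.uniform(0.1, 1.0),
            )
            wp = RLParams(variant="wprl", w=1.0, alpha_mf_pos=0.3,
                          alpha_mf_neg=0.3, gamma_mf=0.5, **shared)
            mb = RLParams(variant="mbrl", **shared)
            assert rl_sequence_loglik(trials, wp)[0] == pytest.approx(
                rl_sequence_loglik(trials, mb)[0], abs=1e-10
            )

    def test_half_weight_halved_temperature_reduces_to_parallel(self, random_sessions):
        rng = np.random.default_rng(4)
        for trials in random_sessions[:6]:
            shared = dict(
                alpha_mb_pos=rng.uniform(0.1, 0.9),
                alpha_mb_neg=rng.uniform(0.1, 0.9),
                gamma_mb=rng.uniform(0.1, 0.9),
                alpha_mf_pos=rng.uniform(0.0, 0.5),
                alpha_mf_neg=rng.uniform(0.0, 0.5),
                gamma_mf=rng.uniform(0.1, 0.9),
            )
            tau = rng.uniform(0.1, 1.0)
            prl = RLParams(variant="prl", tau=tau, **shared)
            wp = RLParams(variant="wprl", w=0.5, tau=tau / 2, **shared)
            assert rl_sequence_loglik(trials, prl)[0] == pytest.approx(
                rl_sequence_loglik(trials, wp)[0], abs=1e-10
            )

    def test_loglik_invariant_to_key_relabeling(self, wprl_session, wprl_params):
        """Relabeling key cards consistently leaves the likelihood unchanged."""
        from dataclasses import replace

        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        relabeled = []
        for t in wprl_session:
            card = StimulusCard(perm[t.card.color], perm[t.card.shape], perm[t.card.number])
            relabeled.append(
                replace(t, card=card, response=perm[t.response])
            )
        assert rl_sequence_loglik(relabeled, wprl_params)[0] == pytest.approx(
            rl_sequence_loglik(wprl_session, wprl_params)[0], abs=1e-10
        )


class TestStateInvariants:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_expectations_stay_in_unit_interval(self, seed):
        """From zero init with valid parameters, |Q| never exceeds 1."""
        rng = np.random.default_rng(seed)
        params = RLParams(
            variant="wprl",
            alpha_mb_pos=rng.uniform(0, 1), alpha_mb_neg=rng.uniform(0, 1),
            gamma_mb=rng.uniform(0, 1), alpha_mf_pos=rng.uniform(0, 1),
            alpha_mf_neg=rng.uniform(0, 1), gamma_mf=rng.uniform(0, 1),
            tau=rng.uniform(0.05, 5), w=rng.uniform(0, 1),
        )
        from cwcst.task import build_deck

        deck = build_deck()
        state = init_rl_state()
        for _ in range(60):
            card = deck[rng.integers(24)]
            resp = int(rng.integers(1, 5))
            fb = int(rng.choice([-1, 1]))
            state = rl_update(state, card, resp, fb, params)
            assert np.all(np.abs(state.q_c) <= 1 + 1e-12)
            assert np.all(np.abs(state.q_mf) <= 1 + 1e-12)

    def test_probability_simplex_on_every_trial(self, random_sessions, wprl_params):
        from cwcst.rl import rl_response_probs, rl_update

        for trials in random_sessions[:4]:
            state = init_rl_state()
            for t in trials:
                probs = rl_response_probs(state, t.card, wprl_params)
                assert abs(probs.sum() - 1.0) < 1e-12
                assert np.all(probs > 0)
                state = rl_update(state, t.card, t.response, t.feedback, wprl_params)


class TestBatchEngineAgreement:
    @pytest.mark.parametrize("variant", ["wprl", "prl", "mbrl"])
    def test_batch_matches_scalar_path(self, variant, random_sessions):
        rng = np.random.default_rng(11)
        sessions = random_sessions[:5]
        ct = compile_trials(sessions)
        values = {}
        for name, kind in PARAM_SPECS[variant]:
            hi = 5.0 if kind == "scale5" else 1.0
            values[name] = rng.uniform(0.05 * hi, 0.9 * hi, size=len(sessions))
        batch = loglik_batch(ct, values, variant)
        for i, trials in enumerate(sessions):
            params = make_params(variant, {k: v[i] for k, v in values.items()})
            scalar = rl_sequence_loglik(trials, params)[0]
            assert batch[i] == pytest.approx(scalar, abs=1e-9)

    def test_fast_sequence_kernel_matches_scalar_path(self, random_sessions):
        from cwcst._fastseq import VARIANT_CODES, rl_loglik_seq

        trials = random_sessions[0]
        ct = compile_trials([trials])
        rng = np.random.default_rng(5)
        for variant in ("wprl", "prl", "mbrl"):
            vals = {}
            for name, kind in PARAM_SPECS[variant]:
                hi = 5.0 if kind == "scale5" else 1.0
                vals[name] = rng.uniform(0.05 * hi, 0.9 * hi)
            full = np.full(8, 0.5)
            slots = {"wprl": range(8), "prl": range(7), "mbrl": (0, 1, 2, 6)}[variant]
            full[list(slots)] = [vals[n] for n, _ in PARAM_SPECS[variant]]
            fast = rl_loglik_seq(
                ct.resp[0], ct.cat_of_resp[0], ct.applied[0], ct.fb[0],
                full, VARIANT_CODES[variant],
            )
            scalar = rl_sequence_loglik(trials, make_params(variant, vals))[0]
            assert fast == pytest.approx(scalar, abs=1e-9)
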