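"""Error scoring, demand stratification, screening, and recovery R²."""

import numpy as np
import pandas as pd
import pytest

from cwcst.behavior import (
    category_application_counts,
    classify_trial,
    conditional_error_table,
    group_error_summary,
    recovery_r2,
    remove_invalid_trials,
    screen_participants,
)
from cwcst.task import StimulusCard, TrialRecord, infer_applied_category


def make_trial(idx, card, response, target, subject="s"):
    applied = infer_applied_category(StimulusCard(*card), response)
    feedback = 1 if applied == target else -1
    return TrialRecord(subject, idx, StimulusCard(*card), response, applied,
                       feedback, target)


class TestClassifyTrial:
    def test_perseveration_under_demanded_alternation(self):
        """Prev key 2 applied color and got -1; on the new card key 2 still
        maps to color, so committing the perseveration repeats the key."""
        prev = make_trial(1, (2, 3, 4), 2, target=1)  # applied color, negative
        curr = make_trial(2, (2, 1, 3), 2, target=1)  # key 2 maps to color again
        c = classify_trial(prev, curr)
        assert c.error_possible == "perseveration"
        assert c.demand == "alternation"
        assert c.error_type == "perseveration"  # color repeated

    def test_perseveration_under_demanded_repetition(self):
        prev = make_trial(1, (2, 3, 4), 2, target=1)  # applied color, negative
        curr = make_trial(2, (1, 2, 4), 4, target=2)  # key 2 now maps to shape
        c = classify_trial(prev, curr)
        assert c.error_possible == "perseveration"
        assert c.demand == "repetition"
        assert c.error_type == "none"  # applied number, a switch

    def test_setloss_under_demanded_repetition(self):
        prev = make_trial(1, (2, 3, 4), 2, target=0)  # applied color, positive
        curr = make_trial(2, (2, 1, 3), 3, target=0)  # key 2 maps to color
        c = classify_trial(prev, curr)
        assert c.error_possible == "set_loss"
        assert c.demand == "repetition"
        assert c.error_type == "set_loss"  # switched to shape

    def test_setloss_under_demanded_alternation(self):
        prev = make_trial(1, (2, 3, 4), 2, target=0)  # applied color, positive
        curr = make_trial(2, (1, 2, 4), 1, target=0)  # key 2 maps to shape now
        c = classify_trial(prev, curr)
        assert c.error_possible == "set_loss"
        assert c.demand == "alternation"
        assert c.error_type == "none"  # key 1 applies color: repetition

    def test_unmatched_previous_key_is_unclassified(self):
        prev = make_trial(1, (2, 3, 4), 2, target=1)  # applied color, negative
        curr = make_trial(2, (1, 3, 4), 3, target=1)  # key 2 unmatched here
        c = classify_trial(prev, curr)
        assert c.demand == "unclassified"

    def test_demand_invariant_to_key_relabeling(self):
        perm = {1: 4, 2: 3, 3: 1, 4: 2}
        prev = make_trial(1, (2, 3, 4), 2, target=1)
        curr = make_trial(2, (2, 1, 3), 2, target=1)
        prev_r = make_trial(1, tuple(perm[a] for a in (2, 3, 4)), perm[2], target=1)
        curr_r = make_trial(2, tuple(perm[a] for a in (2, 1, 3)), perm[2], target=1)
        assert classify_trial(prev, curr).demand == classify_trial(prev_r, curr_r).demand

    def test_rejects_disordered_trials(self):
        a = make_trial(2, (2, 3, 4), 2, 0)
        b = make_trial(1, (2, 1, 3), 2, 0)
        with pytest.raises(ValueError):
            classify_trial(a, b)


class TestConditionalErrorTable:
    def test_probability_is_simple_ratio(self):
        """Independent brute-force rescan agrees with the table cell-wise."""
        from cwcst.inference import make_params
        from cwcst.simulate import default_group_means, simulate_generative

        params = make_params("wprl", default_group_means("wprl"))
        trials = remove_invalid_trials(
            list(simulate_generative(params, seed=31).trials)
        )[0]
        table = conditional_error_table(trials)

        # brute-force oracle: re-scan pairs with an independent derivation
        counts = {}
        for prev, curr in zip(trials, trials[1:]):
            if curr.trial_index != prev.trial_index + 1:
                continue
            prev_cat_on_curr = infer_applied_category(curr.card, prev.response)
            if prev_cat_on_curr is None:
                continue
            same_cat = prev_cat_on_curr == prev.applied_category
            if prev.feedback == -1:
                etype = "perseveration"
                demand = "alternation" if same_cat else "repetition"
                err = curr.applied_category == prev.applied_category
            else:
                etype = "set_loss"
                demand = "repetition" if same_cat else "alternation"
                err = curr.applied_category != prev.applied_category
            key = (etype, demand)
            opp, nerr = counts.get(key, (0, 0))
            counts[key] = (opp + 1, nerr + int(err))
        for key, (opp, nerr) in counts.items():
            assert table.loc[key, "opportunities"] == opp
            assert table.loc[key, "errors"] == nerr
            assert table.loc[key, "probability"] == pytest.approx(nerr / opp)

    def test_perfect_performer_has_zero_probabilities(self):
        # alternate targets so both feedback signs occur; always obey feedback
        trials = [
            make_trial(1, (2, 3, 4), 2, target=0),  # color correct (+)
            make_trial(2, (3, 2, 4), 3, target=0),  # repeat color (+)
            make_trial(3, (4, 2, 3), 4, target=1),  # color again, now wrong (-)
            make_trial(4, (3, 4, 2), 4, target=1),  # switch to shape (+)
        ]
        table = conditional_error_table(trials)
        scored = table.dropna(subset=["probability"])
        assert (scored["probability"] == 0).all()

    def test_errors_never_exceed_opportunities(self, wprl_session):
        table = conditional_error_table(wprl_session)
        assert (table["errors"] <= table["opportunities"]).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            conditional_error_table([])


class TestRemoveInvalidTrials:
    def test_reports_fraction_and_is_idempotent(self):
        trials = [make_trial(i + 1, (2, 3, 4), 2, target=0) for i in range(99)]
        trials.insert(50, make_trial(51, (2, 3, 4), 1, target=0))  # unmatched key
        # keep indices unique/ordered
        trials = [
            TrialRecord(t.subject_id, i + 1, t.card, t.response,
                        t.applied_category, t.feedback, t.target_category)
            for i, t in enumerate(trials)
        ]
        kept, report = remove_invalid_trials(trials)
        assert len(kept) == 99
        assert report["fraction_removed"] == pytest.approx(0.01)
        again, report2 = remove_invalid_trials(kept)
        assert again == kept and report2["n_removed"] == 0


class TestScreening:
    def test_extreme_subject_excluded_others_kept(self):
        # The screen uses full-cohort moments, so the cohort must be large
        # enough that the outlier does not dominate the SD itself (in a
        # cohort of n the largest possible standardized deviation from the
        # full-sample mean is (n-1)/sqrt(n), below 3 for n <= 10).
        rng = np.random.default_rng(0)
        n = 60
        counts = pd.DataFrame(
            {
                "color": rng.integers(50, 60, n).astype(float),
                "shape": rng.integers(50, 60, n).astype(float),
                "number": rng.integers(50, 60, n).astype(float),
            },
            index=[f"s{i}" for i in range(n)],
        )
        base_sd = counts["color"].std(ddof=1)
        counts.loc["s0", "color"] = counts["color"].mean() + 8 * base_sd
        keep = screen_participants(counts)
        assert not keep["s0"]
        assert keep.drop("s0").all()

    def test_subject_at_mean_kept(self):
        counts = pd.DataFrame(
            {"color": [50, 52, 48, 50], "shape": [40, 42, 38, 40],
             "number": [60, 58, 62, 60]},
            index=list("abcd"),
        )
        keep = screen_participants(counts)
        assert keep["a"] and keep["d"]

    def test_counts_derived_from_trials(self):
        trials = [make_trial(i + 1, (2, 3, 4), 2, target=0) for i in range(5)]
        counts = category_application_counts({"s": trials})
        assert counts.loc["s", "color"] == 5
        assert counts.loc["s", "shape"] == 0


class TestRecoveryR2:
    @staticmethod
    def _frame(values):
        rows = []
        for sid, v in values.items():
            for e in ("perseveration", "set_loss"):
                for d in ("repetition", "alternation"):
                    rows.append(
                        {"subject_id": sid, "error_type": e, "demand": d,
                         "probability": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_data_gives_unit_r2(self):
        obs = self._frame({"a": 0.1, "b": 0.2, "c": 0.3})
        r2 = recovery_r2(obs, obs.copy())
        assert np.allclose(r2["r2"], 1.0)

    def test_constant_prediction_gives_zero(self):
        obs = self._frame({"a": 0.1, "b": 0.2, "c": 0.3})
        sim = self._frame({"a": 0.2, "b": 0.2, "c": 0.2})
        r2 = recovery_r2(obs, sim)
        assert np.allclose(r2["r2"], 0.0)

    def test_three_point_example_matches_hand_ols(self):
        """{(0.1,0.2),(0.2,0.2),(0.3,0.5)}: r = cov/sd product, R2 = r^2 = 0.75."""
        sim = self._frame({"a": 0.1, "b": 0.2, "c": 0.3})
        obs = self._frame({"a": 0.2, "b": 0.2, "c": 0.5})
        x = np.array([0.1, 0.2, 0.3])
        y = np.array([0.2, 0.2, 0.5])
        r = np.corrcoef(x, y)[0, 1]
        r2 = recovery_r2(obs, sim)
        assert np.allclose(r2["r2"], r ** 2)

    def test_too_few_pairs_rejected(self):
        obs = self._frame({"a": 0.1, "b": 0.2})
        with pytest.raises(ValueError):
            recovery_r2(obs, obs.copy())


class TestGroupSummary:
    def test_contains_all_cells_per_subject(self, wprl_session):
        other = [
            TrialRecord("t2", t.trial_index, t.card, t.response,
                        t.applied_category, t.feedback, t.target_category)
            for t in wprl_session
        ]
        g = group_error_summary({"t1": wprl_session, "t2": other})
        assert len(g) == 8
        assert set(g.subject_id) == {"t1", "t2"}
        assert set(g.attrs["contrasts"]) == {"t1", "t2"}
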