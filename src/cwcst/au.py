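"""Attentional-updating (AU) model of card sorting performance.

The AU model tracks a 3-vector ``a`` of attentional category prioritizations
on the unit simplex, initialized at 1/3 each.  Feedback produces a signal
``s``: after positive feedback attention concentrates on the applied
category; after negative feedback it is redistributed over the non-applied
categories, in both cases weighted by the current attention raised to the
focus parameter ``f``.  Attention then moves a fraction ``p`` (``p_pos`` or
``p_neg`` by feedback sign) of the way toward the signal.  Response
probabilities are proportional to the attention (raised to the decision
consistency ``d``) of the category each response would apply; the unmatched
key receives probability exactly zero, which is why unmatched-key trials
must be removed before computing AU likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .task import StimulusCard, TrialRecord, match_categories
from .rl import _check_sequence

__all__ = [
    "AUParams",
    "AUState",
    "init_au_state",
    "au_feedback_signal",
    "au_update",
    "au_response_probs",
    "au_sequence_loglik",
]

#: Attention entries are floored at this value before exponentiation by f or
#: d, purely to avoid 0**0 and underflow; an implementation tolerance, not
#: model content.
ATTENTION_FLOOR = 1e-12


@dataclass(frozen=True)
class AUParams:
    """AU parameter vector.

    ``p_pos``/``p_neg`` are the updating ratios after positive/negative
    feedback, in (0,1).  ``f`` (attentional focus) and ``d`` (decision
    consistency) are positive, capped at 5 by the estimation transform.
    ``reduced=True`` selects the robustness configuration with ``f`` fixed at
    1 and ``p_pos`` at 0.9999.
    """

    p_pos: float
    p_neg: float
    f: float
    d: float
    reduced: bool = False

    def __post_init__(self) -> None:
        if self.reduced:
            object.__setattr__(self, "f", 1.0)
            object.__setattr__(self, "p_pos", 0.9999)
        for name in ("p_pos", "p_neg"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1): {v}")
        for name in ("f", "d"):
            v = getattr(self, name)
            if not 0 < v <= 5:
                raise ValueError(f"{name} must lie in (0, 5]: {v}")


@dataclass(frozen=True)
class AUState:
    """Attentional category prioritizations on the 3-simplex."""

    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        if a.shape != (3,):
            raise ValueError("attention vector must have shape (3,)")
        if (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError(f"attention must lie on the simplex: {a}")


def init_au_state() -> AUState:
    """Uniform initial attention, 1/3 per category."""
    return AUState(np.full(3, 1.0 / 3.0))


def _match_vector(card: StimulusCard, response: int) -> np.ndarray:
    """One-hot category match vector m_v of a response on a card (or zeros)."""
    cats = match_categories(card)
    m = np.zeros(3)
    if cats[response - 1] >= 0:
        m[cats[response - 1]] = 1.0
    return m


def au_feedback_signal(
    state: AUState, card: StimulusCard, response: int, feedback: int, f: float
) -> np.ndarray:
    """The normalized attention signal produced by one feedback event.

    Positive feedback: signal mass proportional to ``m_u * a_u**f`` (one-hot
    at the applied category for deck-valid cards).  Negative feedback:
    proportional to ``(1 - m_u) * a_u**f`` over the non-applied categories.
    """
    if feedback not in (-1, 1):
        raise ValueError(f"feedback must be +1 or -1: {feedback}")
    m = _match_vector(card, response)
    if m.sum() == 0 and feedback == 1:
        raise ValueError(
            "positive feedback for an unmatched-key response: such trials "
            "must be removed before applying the AU model"
        )
    a_f = np.maximum(state.a, ATTENTION_FLOOR) ** f
    weights = m * a_f if feedback == 1 else (1.0 - m) * a_f
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate feedback signal (all-zero numerator)")
    return weights / total


def au_update(
    state: AUState, signal: np.ndarray, feedback: int, params: AUParams
) -> AUState:
    """Move attention a fraction ``p`` of the way toward the signal."""
    p = params.p_pos if feedback == 1 else params.p_neg
    return AUState((1.0 - p) * state.a + p * np.asarray(signal, dtype=float))


def au_response_probs(state: AUState, card: StimulusCard, d: float) -> np.ndarray:
    """Choice probabilities proportional to attention**d of the applied category.

    The unmatched key receives probability exactly 0.
    """
    cats = match_categories(card)
    a_d = np.maximum(state.a, ATTENTION_FLOOR) ** d
    weights = np.where(cats >= 0, a_d[np.clip(cats, 0, 2)], 0.0)
    return weights / weights.sum()


def au_sequence_loglik(
    trials: Sequence[TrialRecord], params: AUParams
) -> Tuple[float, np.ndarray]:
    """Log-likelihood of a subject's preprocessed sequence under the AU model.

    Raises if any trial carries an unmatched-key response, since the AU model
    assigns such responses probability zero.
    """
    _check_sequence(trials)
    state = init_au_state()
    per_trial = np.empty(len(trials))
    for i, trial in enumerate(trials):
        if trial.applied_category is None:
            raise ValueError(
                f"trial {trial.trial_index} of subject {trial.subject_id} has an "
                "unmatched-key response; remove such trials before AU fitting"
            )
        probs = au_response_probs(state, trial.card, params.d)
        p = probs[trial.response - 1]
        if p <= 0:
            raise ValueError(
                f"trial {trial.trial_index}: executed response has probability 0"
            )
        per_trial[i] = np.log(p)
        signal = au_feedback_signal(
            state, trial.card, trial.response, trial.feedback, params.f
        )
        state = au_update(state, signal, trial.feedback, params)
    return float(per_trial.sum()), per_trial
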