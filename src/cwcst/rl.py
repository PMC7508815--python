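"""Parallel reinforcement-learning models of card sorting performance.

Three model variants share one machinery:

* ``mbrl`` -- model-based (MB) learning only: a 3-vector ``Q_C`` of feedback
  expectations for applying each category, decayed each trial by the inertia
  ``gamma_mb`` and updated by a delta rule with feedback-sign-specific
  learning rates ``alpha_mb_pos`` / ``alpha_mb_neg``.
* ``prl`` -- parallel MB and model-free (MF) learning: in addition a
  4-vector ``Q_MF`` of feedback expectations for the motor responses,
  updated analogously with ``gamma_mf`` and ``alpha_mf_pos/neg``; the two
  expectation vectors are summed before choice.
* ``wprl`` -- as ``prl`` but with a convex weight ``w`` on the MB term:
  ``Q_sum = w*Q_MB + (1-w)*Q_MF``.

MB expectations are projected onto responses through the stimulus card: the
response that applies category ``u`` inherits ``Q_C[u]``; the unmatched key,
which certainly yields negative feedback, is assigned -1.  Choice follows a
softmax on ``Q_sum / tau``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .task import StimulusCard, TrialRecord, match_categories

__all__ = [
    "RL_VARIANTS",
    "RLParams",
    "RLState",
    "init_rl_state",
    "mb_response_values",
    "integrate_expectations",
    "rl_response_probs",
    "rl_update",
    "rl_sequence_loglik",
    "softmax",
]

RL_VARIANTS = ("wprl", "prl", "mbrl")

SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class RLParams:
    """Parameter vector of the (weighted) parallel RL models.

    Learning rates and inertias live in [0,1]; the softmax temperature
    ``tau`` in (0,5]; the MB weight ``w`` in [0,1] (wprl only).  MF fields
    are ignored for the ``mbrl`` variant and ``w`` for ``prl``.
    """

    alpha_mb_pos: float
    alpha_mb_neg: float
    gamma_mb: float
    tau: float
    variant: str = "mbrl"
    alpha_mf_pos: float = 0.0
    alpha_mf_neg: float = 0.0
    gamma_mf: float = 1.0
    w: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in RL_VARIANTS:
            raise ValueError(f"unknown RL variant {self.variant!r}")
        if not 0 < self.tau <= 5:
            raise ValueError(f"tau must lie in (0, 5]: {self.tau}")
        unit = {
            "alpha_mb_pos": self.alpha_mb_pos,
            "alpha_mb_neg": self.alpha_mb_neg,
            "gamma_mb": self.gamma_mb,
        }
        if self.variant in ("wprl", "prl"):
            unit.update(
                alpha_mf_pos=self.alpha_mf_pos,
                alpha_mf_neg=self.alpha_mf_neg,
                gamma_mf=self.gamma_mf,
            )
        if self.variant == "wprl":
            unit["w"] = self.w
        for name, value in unit.items():
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1]: {value}")

    @property
    def uses_mf(self) -> bool:
        return self.variant in ("wprl", "prl")


@dataclass(frozen=True)
class RLState:
    """Latent feedback expectations: ``q_c`` per category, ``q_mf`` per response."""

    q_c: np.ndarray
    q_mf: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q_c", np.asarray(self.q_c, dtype=float))
        object.__setattr__(self, "q_mf", np.asarray(self.q_mf, dtype=float))
        if self.q_c.shape != (3,) or self.q_mf.shape != (4,):
            raise ValueError("q_c must have shape (3,) and q_mf shape (4,)")


def init_rl_state() -> RLState:
    """All feedback expectations start at zero."""
    return RLState(np.zeros(3), np.zeros(4))


def softmax(values: np.ndarray, tau: float) -> np.ndarray:
    """Temperature-scaled softmax with max-subtraction for stability."""
    if tau <= 0:
        raise ValueError(f"tau must be positive: {tau}")
    x = np.asarray(values, dtype=float) / tau
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def mb_response_values(state: RLState, card: StimulusCard) -> np.ndarray:
    """Project category expectations onto the four responses for ``card``.

    Response ``v`` inherits ``q_c`` of the category it applies; the
    unmatched key is assigned the certain-negative expectation -1.
    """
    cats = match_categories(card)
    q_mb = np.where(cats >= 0, state.q_c[np.clip(cats, 0, 2)], -1.0)
    return q_mb


def integrate_expectations(
    q_mb: np.ndarray, q_mf: np.ndarray, params: RLParams
) -> np.ndarray:
    """Combine MB and MF response expectations per model variant."""
    if params.variant == "mbrl":
        return np.asarray(q_mb, dtype=float)
    if params.variant == "prl":
        return q_mb + q_mf
    return params.w * q_mb + (1.0 - params.w) * q_mf


def rl_response_probs(
    state: RLState, card: StimulusCard, params: RLParams
) -> np.ndarray:
    """Softmax choice probabilities over the four responses."""
    q_sum = integrate_expectations(mb_response_values(state, card), state.q_mf, params)
    return softmax(q_sum, params.tau)


def rl_update(
    state: RLState,
    card: StimulusCard,
    response: int,
    feedback: int,
    params: RLParams,
    none_category_rule: str = "decay",
) -> RLState:
    """Advance the latent state given one (card, response, feedback) event.

    Both kernels first decay their expectations by the inertia, then apply a
    delta-rule update on the applied category (MB) / executed response (MF),
    with the learning rate selected by the feedback sign.  When the response
    applied no category there is no MB prediction error; by default the MB
    expectations only decay (``none_category_rule='decay'``), while MF
    updates the executed key as usual.
    """
    if feedback not in (-1, 1):
        raise ValueError(f"feedback must be +1 or -1: {feedback}")
    if none_category_rule not in ("decay",):
        raise ValueError(f"unknown none_category_rule {none_category_rule!r}")

    cats = match_categories(card)
    applied = int(cats[response - 1])

    q_c = params.gamma_mb * state.q_c
    if applied >= 0:
        alpha_mb = params.alpha_mb_pos if feedback == 1 else params.alpha_mb_neg
        delta_mb = feedback - q_c[applied]
        q_c = q_c.copy()
        q_c[applied] += alpha_mb * delta_mb

    q_mf = state.q_mf
    if params.uses_mf:
        q_mf = params.gamma_mf * state.q_mf
        alpha_mf = params.alpha_mf_pos if feedback == 1 else params.alpha_mf_neg
        delta_mf = feedback - q_mf[response - 1]
        q_mf = q_mf.copy()
        q_mf[response - 1] += alpha_mf * delta_mf

    return RLState(q_c, q_mf)


def _check_sequence(trials: Sequence[TrialRecord]) -> None:
    if not trials:
        raise ValueError("empty trial sequence")
    subject = trials[0].subject_id
    last = -np.inf
    for t in trials:
        if t.subject_id != subject:
            raise ValueError("trial sequence mixes subjects")
        if t.trial_index <= last:
            raise ValueError("trial sequence is not in chronological order")
        last = t.trial_index


def rl_sequence_loglik(
    trials: Sequence[TrialRecord], params: RLParams
) -> Tuple[float, np.ndarray]:
    """Log-likelihood of one subject's response sequence under an RL model.

    Trials must be a single subject's preprocessed sequence (chronological,
    unmatched-key responses removed).  Returns the total log-probability and
    the per-trial log-probabilities of the executed responses.
    """
    _check_sequence(trials)
    state = init_rl_state()
    per_trial = np.empty(len(trials))
    for i, trial in enumerate(trials):
        probs = rl_response_probs(state, trial.card, params)
        per_trial[i] = np.log(probs[trial.response - 1])
        state = rl_update(state, trial.card, trial.response, trial.feedback, params)
    return float(per_trial.sum()), per_trial
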