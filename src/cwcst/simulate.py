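"""Generative agents, synthetic cohorts, and one-trial-ahead simulation.

Three simulation modes:

* *Generative*: an agent plays full cWCST sessions, sampling responses from
  its own model probabilities and learning from its own choices and the
  feedback it receives.  Used for cohort generation and recovery studies.
* *Cohorts*: N agents with individual parameters drawn around group-level
  means (normal on the unconstrained scale), each playing an independent
  schedule.  Default group means follow the hierarchical group-location
  estimates of the weighted parallel RL model on the reference cohort
  (N = 375 undergraduates).
* *One-trial-ahead* (post-hoc absolute fit): per iteration, a parameter
  vector is drawn from a subject's individual posterior and the response on
  every trial t is sampled from the model's probabilities given the
  *observed* history 1..t-1.  Simulated responses therefore never feed back
  into the latent state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._engine import compile_trials, probs_sequence_batch
from .au import AUParams, AUState, au_feedback_signal, au_response_probs, au_update, init_au_state
from .inference import (
    PARAM_SPECS,
    PosteriorDraws,
    constrain_matrix,
    make_params,
    params_to_vector,
    theta_dict,
    unconstrain,
)
from .rl import RLParams, RLState, init_rl_state, rl_response_probs, rl_update
from .task import (
    CategorySchedule,
    StimulusCard,
    TrialRecord,
    generate_schedule,
    run_session,
)

__all__ = [
    "REFERENCE_GROUP_MEANS",
    "default_group_means",
    "CohortSpec",
    "SimulatedSession",
    "ModelAgent",
    "simulate_generative",
    "generate_cohort",
    "simulate_one_step_ahead",
    "one_step_ahead_error_probs",
]

#: Default generative group means (constrained scale) per model variant.
#: The wprl values are the posterior group-location estimates of the
#: weighted parallel RL model on the reference cohort; the boundary
#: estimates ">0.99" and "<0.01" are taken as 0.995 and 0.005.  prl and
#: mbrl reuse the shared parameters.  The AU values are a plausible
#: mid-range configuration used only for model-recovery exercises.
REFERENCE_GROUP_MEANS: Dict[str, Dict[str, float]] = {
    "wprl": {
        "alpha_mb_pos": 0.995,
        "alpha_mb_neg": 0.60,
        "gamma_mb": 0.31,
        "alpha_mf_pos": 0.005,
        "alpha_mf_neg": 0.02,
        "gamma_mf": 0.35,
        "tau": 0.09,
        "w": 0.33,
    },
    "au": {"p_pos": 0.7, "p_neg": 0.3, "f": 1.0, "d": 1.5},
}


def default_group_means(variant: str) -> Dict[str, float]:
    """Generative group means for a variant (subset of the wprl defaults)."""
    if variant == "au":
        return dict(REFERENCE_GROUP_MEANS["au"])
    base = REFERENCE_GROUP_MEANS["wprl"]
    return {name: base[name] for name, _ in PARAM_SPECS[variant]}


@dataclass(frozen=True)
class SimulatedSession:
    """A generative session with its hidden truth, replayable from (spec, seed)."""

    trials: Tuple[TrialRecord, ...]
    variant: str
    params: Union[RLParams, AUParams]
    schedule: CategorySchedule
    seed: Optional[int]

    @property
    def completed_switches(self) -> int:
        if not self.trials:
            return 0
        last = self.trials[-1]
        done = last.switch_number
        # run_session records switch_number before the trial resolves.
        if last.feedback == 1:
            done = min(done + 1, self.schedule.switch_count_required)
        return done

    @property
    def truncated(self) -> bool:
        """True when the session hit max_trials before completing all switches."""
        return (
            len(self.trials) >= self.schedule.max_trials
            and self.trials[-1].switch_number + 1 < self.schedule.switch_count_required
        )


class ModelAgent:
    """A response policy that samples from its own model and learns as it goes.

    Compatible with :func:`cwcst.task.run_session`: on each call it first
    digests any history entries it has not yet processed (updating its
    latent state from its own past choice and the feedback received), then
    samples a response for the current card.
    """

    def __init__(
        self,
        params: Union[RLParams, AUParams],
        rng: np.random.Generator,
        variant: Optional[str] = None,
    ) -> None:
        self.params = params
        self.rng = rng
        if isinstance(params, AUParams):
            self.variant = "au"
            self._state: Union[RLState, AUState] = init_au_state()
        else:
            self.variant = variant or params.variant
            self._state = init_rl_state()
        self._processed = 0

    def _digest(self, history: Sequence[TrialRecord]) -> None:
        for trial in history[self._processed:]:
            if self.variant == "au":
                signal = au_feedback_signal(
                    self._state, trial.card, trial.response, trial.feedback,
                    self.params.f,
                )
                self._state = au_update(self._state, signal, trial.feedback, self.params)
            else:
                self._state = rl_update(
                    self._state, trial.card, trial.response, trial.feedback, self.params
                )
            self._processed += 1

    def response_probs(self, card: StimulusCard) -> np.ndarray:
        if self.variant == "au":
            return au_response_probs(self._state, card, self.params.d)
        return rl_response_probs(self._state, card, self.params)

    def __call__(self, card: StimulusCard, history: Sequence[TrialRecord]) -> int:
        self._digest(history)
        probs = self.response_probs(card)
        return int(self.rng.choice(4, p=probs)) + 1


def simulate_generative(
    params: Union[RLParams, AUParams],
    seed: int,
    variant: Optional[str] = None,
    schedule: Optional[CategorySchedule] = None,
    switch_count: int = 41,
    max_trials: int = 250,
    subject_id: str = "sim",
) -> SimulatedSession:
    """Play one full session with a model agent.  Same (params, seed), same session."""
    if schedule is None:
        schedule = generate_schedule(
            rng=np.random.default_rng([seed, 0]),
            switch_count=switch_count,
            max_trials=max_trials,
        )
    agent = ModelAgent(params, np.random.default_rng([seed, 1]), variant)
    trials = run_session(
        agent,
        schedule,
        rng=np.random.default_rng([seed, 2]),
        subject_id=subject_id,
    )
    return SimulatedSession(
        tuple(trials), agent.variant, params, schedule, seed
    )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    Individual parameters are drawn per subject as
    ``transform(unconstrain(mean) + dispersion * z)`` with ``z ~ N(0,1)`` on
    the unconstrained scale, so they respect the parameter bounds by
    construction.  ``dispersion`` may be a scalar or a per-parameter map;
    the default 0.5 produces visible between-subject heterogeneity.
    """

    n_subjects: int
    variant: str = "wprl"
    group_means: Optional[Mapping[str, float]] = None
    dispersion: Union[float, Mapping[str, float]] = 0.5
    switch_count: int = 41
    max_trials: int = 250
    seed: int = 0
    subject_prefix: str = "sim"

    def resolved_means(self) -> Dict[str, float]:
        means = dict(self.group_means or default_group_means(self.variant))
        missing = [n for n, _ in PARAM_SPECS[self.variant] if n not in means]
        if missing:
            raise ValueError(f"group_means missing parameters: {missing}")
        return means

    def resolved_dispersion(self) -> np.ndarray:
        names = [n for n, _ in PARAM_SPECS[self.variant]]
        if isinstance(self.dispersion, Mapping):
            disp = np.asarray([self.dispersion[n] for n in names], dtype=float)
        else:
            disp = np.full(len(names), float(self.dispersion))
        if (disp < 0).any():
            raise ValueError("dispersion must be non-negative")
        return disp


def generate_cohort(
    spec: CohortSpec,
) -> Tuple[Dict[str, List[TrialRecord]], pd.DataFrame]:
    """Simulate an independent session for each of N agents.

    Returns the dataset (subject id -> trial list) and a truth table with
    one row per subject holding the generating parameters and session
    metadata.
    """
    if spec.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    param_spec = PARAM_SPECS[spec.variant]
    names = [n for n, _ in param_spec]
    kinds = [k for _, k in param_spec]
    means = spec.resolved_means()
    mu_u = np.asarray([unconstrain(means[n], k) for n, k in param_spec])
    disp = spec.resolved_dispersion()

    width = max(3, len(str(spec.n_subjects)))
    dataset: Dict[str, List[TrialRecord]] = {}
    truth_rows = []
    rng_params = np.random.default_rng([spec.seed, 10_000])
    for i in range(spec.n_subjects):
        sid = f"{spec.subject_prefix}{i + 1:0{width}d}"
        z = rng_params.standard_normal(len(names))
        theta = constrain_matrix((mu_u + disp * z)[None, :], kinds)[0]
        params = make_params(spec.variant, dict(zip(names, theta)))
        schedule = generate_schedule(
            rng=np.random.default_rng([spec.seed, i, 0]),
            switch_count=spec.switch_count,
            max_trials=spec.max_trials,
        )
        agent = ModelAgent(params, np.random.default_rng([spec.seed, i, 1]))
        trials = run_session(
            agent,
            schedule,
            rng=np.random.default_rng([spec.seed, i, 2]),
            subject_id=sid,
        )
        dataset[sid] = trials
        row = {"subject_id": sid, "variant": spec.variant, **dict(zip(names, theta))}
        row["n_trials"] = len(trials)
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    return dataset, truth


def _param_draw_matrix(
    source: Union[PosteriorDraws, RLParams, AUParams, Mapping[str, float], np.ndarray],
    variant: str,
    n_iter: int,
    rng: np.random.Generator,
    subject_id: Optional[str] = None,
) -> np.ndarray:
    """Resolve a (n_iter, K) constrained parameter matrix from any source."""
    K = len(PARAM_SPECS[variant])
    if isinstance(source, PosteriorDraws):
        if subject_id is None:
            raise ValueError("subject_id is required with posterior draws")
        i = source.subject_ids.index(subject_id)
        theta = source.individual_constrained()[:, :, i, :].reshape(-1, K)
        idx = rng.integers(theta.shape[0], size=n_iter)
        return theta[idx]
    if isinstance(source, (RLParams, AUParams)):
        vec = params_to_vector(source, variant)
        return np.tile(vec, (n_iter, 1))
    if isinstance(source, Mapping):
        vec = np.asarray([source[n] for n, _ in PARAM_SPECS[variant]], dtype=float)
        return np.tile(vec, (n_iter, 1))
    arr = np.asarray(source, dtype=float)
    if arr.ndim == 1:
        return np.tile(arr, (n_iter, 1))
    idx = rng.integers(arr.shape[0], size=n_iter)
    return arr[idx]


def simulate_one_step_ahead(
    subject_trials: Sequence[TrialRecord],
    draws: Union[PosteriorDraws, RLParams, AUParams, Mapping[str, float], np.ndarray],
    variant: str,
    n_iter: int = 1000,
    seed: int = 0,
    subject_id: Optional[str] = None,
) -> np.ndarray:
    """Post-hoc absolute-fit simulation of one subject.

    For each of ``n_iter`` iterations a parameter vector is drawn from
    ``draws`` (posterior draws, a fixed parameter object/map, or an
    (n, K) constrained matrix); then on every trial t a response is sampled
    from the model's probabilities with the latent state rebuilt from the
    observed history 1..t-1.  Returns an (n_iter, T) array of simulated
    responses in 1..4.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not subject_trials:
        raise ValueError("empty trial sequence")
    rng = np.random.default_rng(seed)
    sid = subject_id or subject_trials[0].subject_id
    theta = _param_draw_matrix(draws, variant, n_iter, rng, sid)
    ct = compile_trials([list(subject_trials)]).repeat(n_iter)
    probs = probs_sequence_batch(ct, theta_dict(variant, theta), variant)
    T = len(subject_trials)
    probs = probs[:, :T, :]
    # Vectorized categorical sampling per (iteration, trial) cell.
    cdf = probs.cumsum(axis=2)
    cdf[:, :, -1] = np.maximum(cdf[:, :, -1], 1.0)
    u = rng.random((n_iter, T, 1))
    responses = (u > cdf).sum(axis=2) + 1
    return responses.astype(np.int64)


def one_step_ahead_error_probs(
    subject_trials: Sequence[TrialRecord], simulated_responses: np.ndarray
) -> pd.DataFrame:
    """Score one-trial-ahead simulations into conditional error probabilities.

    The error and demand context of trial t (feedback and applied category
    on t-1, where the previous key maps on the current card) comes from the
    *observed* history; only the response on trial t is simulated.  Returns
    a frame indexed by (error_type, demand) with the per-iteration error
    probabilities averaged across iterations.
    """
    from .behavior import DEMANDS, ERROR_TYPES
    from .task import match_categories

    trials = list(subject_trials)
    n_iter, T = simulated_responses.shape
    if T != len(trials):
        raise ValueError("simulated responses do not match the trial sequence")

    # Per scored trial: cell index (error type x demand) and, per response,
    # whether choosing it commits the cell's error.
    cell_of_trial = np.full(T, -1, dtype=np.int64)
    error_by_resp = np.zeros((T, 4), dtype=bool)
    for t in range(1, T):
        prev, curr = trials[t - 1], trials[t]
        if curr.trial_index != prev.trial_index + 1 or prev.applied_category is None:
            continue
        cats = match_categories(curr.card)  # (4,) applied category per response
        prev_key_cat = cats[prev.response - 1]
        if prev_key_cat < 0:
            continue
        if prev.feedback == -1:
            e = 0  # perseveration possible
            demand = 1 if prev_key_cat == prev.applied_category else 0
            error_by_resp[t] = cats == prev.applied_category
        else:
            e = 1  # set-loss possible
            demand = 0 if prev_key_cat == prev.applied_category else 1
            error_by_resp[t] = (cats >= 0) & (cats != prev.applied_category)
        cell_of_trial[t] = 2 * e + demand

    sim_errors = np.take_along_axis(
        error_by_resp, (simulated_responses - 1).T, axis=1
    ).T  # (n_iter, T)
    rows = []
    for e_idx, e in enumerate(ERROR_TYPES):
        for d_idx, d in enumerate(DEMANDS):
            sel = cell_of_trial == 2 * e_idx + d_idx
            n_opp = int(sel.sum())
            if n_opp == 0:
                prob = np.nan
            else:
                prob = float(sim_errors[:, sel].sum(axis=1).mean() / n_opp)
            rows.append(
                {
                    "error_type": e,
                    "demand": d,
                    "opportunities": n_opp,
                    "probability": prob,
                }
            )
    return pd.DataFrame(rows).set_index(["error_type", "demand"])
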