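"""Computerized Wisconsin Card Sorting Test (cWCST) task engine.

The task presents a stimulus card on every trial, which the participant sorts
to one of four key cards (responses 1-4) by pressing the spatially mapped
key.  Key card ``k`` shows ``k`` items of the ``k``-th color and the ``k``-th
shape, so the key cards are fully diagnostic: a stimulus card that shares a
dimension with a key card shares exactly that one dimension.  Sorting can
follow one of three categories (color, shape, number); the correct category
switches unpredictably after runs of two or more consecutive correct sorts.

This module builds the 24-card deck, generates category-switch schedules,
infers which category a key press applied, evaluates feedback, and runs
complete sessions for arbitrary response policies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CATEGORIES",
    "COLOR",
    "SHAPE",
    "NUMBER",
    "StimulusCard",
    "CategorySchedule",
    "TrialRecord",
    "build_deck",
    "generate_schedule",
    "infer_applied_category",
    "evaluate_feedback",
    "match_categories",
    "unmatched_key",
    "run_session",
    "oracle_policy",
    "unmatched_key_policy",
    "random_policy",
]

#: Category indices. The order (color, shape, number) is fixed everywhere.
COLOR, SHAPE, NUMBER = 0, 1, 2
CATEGORIES = ("color", "shape", "number")

#: Default distribution of switch criteria: uniform on {2,3,4,5}, mean 3.5.
DEFAULT_CRITERIA = (2, 3, 4, 5)


@dataclass(frozen=True)
class StimulusCard:
    """A stimulus card given by its color, shape and number attribute.

    Each attribute indexes the key card (1-4) it matches on that dimension.
    Deck-valid cards have pairwise-distinct attributes, so a card matches
    exactly three key cards on exactly one dimension each, and exactly one
    key card on no dimension.
    """

    color: int
    shape: int
    number: int

    def __post_init__(self) -> None:
        for a in self.attributes:
            if a not in (1, 2, 3, 4):
                raise ValueError(f"card attribute out of range 1-4: {self}")

    @property
    def attributes(self) -> Tuple[int, int, int]:
        return (self.color, self.shape, self.number)

    @property
    def is_deck_valid(self) -> bool:
        return len(set(self.attributes)) == 3


def build_deck() -> List[StimulusCard]:
    """Enumerate the 24-card deck in canonical (lexicographic) order.

    A card is in the deck iff it shares at most one dimension with every key
    card, which for this key-card set is equivalent to its three attributes
    being pairwise distinct.
    """
    return [
        StimulusCard(c, s, n)
        for c, s, n in itertools.product(range(1, 5), repeat=3)
        if len({c, s, n}) == 3
    ]


def match_categories(card: StimulusCard) -> np.ndarray:
    """Map each response 1-4 to the category it would apply on ``card``.

    Returns a length-4 int array indexed by response-1; entries are category
    indices (0=color, 1=shape, 2=number) or -1 for the unmatched key card.
    """
    if not card.is_deck_valid:
        raise ValueError(f"card is not deck-valid: {card}")
    cats = np.full(4, -1, dtype=np.int64)
    for dim, attr in enumerate(card.attributes):
        cats[attr - 1] = dim
    return cats


def infer_applied_category(card: StimulusCard, response: int) -> Optional[int]:
    """The unique category on which ``card`` matches key card ``response``.

    Returns ``None`` when the response selects the card's unmatched key,
    i.e. no viable sorting category was applied.
    """
    cat = int(match_categories(card)[response - 1])
    return None if cat < 0 else cat


def unmatched_key(card: StimulusCard) -> int:
    """The single response that matches ``card`` on no dimension."""
    return ({1, 2, 3, 4} - set(card.attributes)).pop()


def evaluate_feedback(applied: Optional[int], target: int) -> int:
    """+1 iff the applied category equals the scheduled target, else -1.

    Selecting the unmatched key (``applied is None``) always yields -1.
    """
    return 1 if applied == target else -1


@dataclass(frozen=True)
class CategorySchedule:
    """Sequence of target-category episodes with per-episode switch criteria.

    ``episodes[k]`` holds ``(target, criterion)``: the scheduled category and
    the number of consecutive correct sorts that triggers the next switch.
    The list holds one episode per required switch plus the episode entered
    after the final switch (whose criterion is never reached because the
    session ends at the final switch).
    """

    episodes: Tuple[Tuple[int, int], ...]
    switch_count_required: int = 41
    max_trials: int = 250

    def __post_init__(self) -> None:
        if self.switch_count_required < 1:
            raise ValueError("switch_count_required must be >= 1")
        if len(self.episodes) < self.switch_count_required:
            raise ValueError("schedule has fewer episodes than required switches")
        for target, criterion in self.episodes:
            if target not in (COLOR, SHAPE, NUMBER):
                raise ValueError(f"invalid target category {target}")
            if criterion < 2:
                raise ValueError("every switch criterion must be >= 2")
        for (a, _), (b, _) in zip(self.episodes, self.episodes[1:]):
            if a == b:
                raise ValueError("consecutive episode targets must differ")

    @property
    def criteria(self) -> Tuple[int, ...]:
        return tuple(c for _, c in self.episodes)


def generate_schedule(
    rng_seed: Optional[int] = None,
    switch_count: int = 41,
    max_trials: int = 250,
    criterion_choices: Sequence[int] = DEFAULT_CRITERIA,
    rng: Optional[np.random.Generator] = None,
) -> CategorySchedule:
    """Draw a random category-switch schedule.

    The first target is uniform over the three categories; each subsequent
    target is uniform over the two categories differing from the current one.
    Criteria are drawn i.i.d. from ``criterion_choices`` (default uniform on
    {2,3,4,5}, mean 3.5).  Same seed, same schedule.
    """
    if switch_count < 1:
        raise ValueError("switch_count must be >= 1")
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    if any(c < 2 for c in criterion_choices):
        raise ValueError("all switch criteria must be >= 2")
    if rng is None:
        rng = np.random.default_rng(rng_seed)

    choices = np.asarray(list(criterion_choices), dtype=np.int64)
    episodes = []
    target = int(rng.integers(3))
    for _ in range(switch_count + 1):
        criterion = int(choices[rng.integers(len(choices))])
        episodes.append((target, criterion))
        target = int((target + 1 + rng.integers(2)) % 3)
    return CategorySchedule(tuple(episodes), switch_count, max_trials)


@dataclass(frozen=True)
class TrialRecord:
    """One administered cWCST trial.

    ``applied_category`` is the category implied by (card, response), or
    ``None`` for unmatched-key responses.  ``switch_number`` counts completed
    category switches before this trial.
    """

    subject_id: str
    trial_index: int
    card: StimulusCard
    response: int
    applied_category: Optional[int]
    feedback: int
    target_category: int
    switch_number: int = 0

    def __post_init__(self) -> None:
        if self.response not in (1, 2, 3, 4):
            raise ValueError(f"response out of range: {self.response}")
        if self.feedback not in (-1, 1):
            raise ValueError(f"feedback must be +1 or -1: {self.feedback}")


Policy = Callable[[StimulusCard, List[TrialRecord]], int]


def run_session(
    policy: Policy,
    schedule: CategorySchedule,
    rng_seed: Optional[int] = None,
    subject_id: str = "sim",
    rng: Optional[np.random.Generator] = None,
    forbid_immediate_repeat: bool = True,
) -> List[TrialRecord]:
    """Administer a full session of the cWCST to ``policy``.

    Cards are drawn uniformly from the 24-card deck, without immediate
    repetition of the previous card.  The target advances when the current
    episode's criterion of consecutive correct sorts is met; the session ends
    once ``schedule.switch_count_required`` switches are completed or
    ``schedule.max_trials`` trials were administered.
    """
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    deck = build_deck()

    history: List[TrialRecord] = []
    episode = 0
    streak = 0
    switches = 0
    prev_card_idx = -1

    for trial_index in range(1, schedule.max_trials + 1):
        while True:
            card_idx = int(rng.integers(len(deck)))
            if not forbid_immediate_repeat or card_idx != prev_card_idx:
                break
        prev_card_idx = card_idx
        card = deck[card_idx]

        response = policy(card, history)
        if response not in (1, 2, 3, 4):
            raise ValueError(
                f"policy returned invalid response {response!r} on trial {trial_index}"
            )
        target, criterion = schedule.episodes[episode]
        applied = infer_applied_category(card, response)
        feedback = evaluate_feedback(applied, target)
        history.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=trial_index,
                card=card,
                response=response,
                applied_category=applied,
                feedback=feedback,
                target_category=target,
                switch_number=switches,
            )
        )

        if feedback == 1:
            streak += 1
            if streak >= criterion:
                switches += 1
                streak = 0
                episode += 1
                if switches >= schedule.switch_count_required:
                    break
        else:
            streak = 0
    return history


# ---------------------------------------------------------------------------
# Reference policies


def oracle_policy(schedule: CategorySchedule) -> Policy:
    """A stateful policy that always sorts by the scheduled target category.

    Because it is always correct, it can track episode progress on its own:
    each episode lasts exactly its criterion in trials.
    """
    state = {"episode": 0, "streak": 0}

    def policy(card: StimulusCard, history: List[TrialRecord]) -> int:
        target, criterion = schedule.episodes[state["episode"]]
        state["streak"] += 1
        if state["streak"] >= criterion:
            state["episode"] += 1
            state["streak"] = 0
        return card.attributes[target]

    return policy


def unmatched_key_policy(card: StimulusCard, history: List[TrialRecord]) -> int:
    """Always press the card's unmatched key (never correct)."""
    return unmatched_key(card)


def random_policy(rng: np.random.Generator) -> Policy:
    """Uniform random key presses."""

    def policy(card: StimulusCard, history: List[TrialRecord]) -> int:
        return int(rng.integers(1, 5))

    return policy
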