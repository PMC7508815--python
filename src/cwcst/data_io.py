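"""Reading and writing cWCST trial logs and result tables.

Trial logs are comma-delimited UTF-8 text with one row per trial and the
canonical column order

    subject_id, trial_index, card_color, card_shape, card_number,
    response, feedback, target_category, applied_category

Card attributes and responses are key-card indices 1-4, feedback is +1/-1,
categories are the lowercase strings ``color``/``shape``/``number`` (plus
``none`` for unmatched-key responses).  Reading validates every row; strict
mode rejects any inconsistency, lenient mode recomputes the derived fields
(applied category, feedback) from the raw ones and warns on mismatch.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Union

import pandas as pd

from .task import (
    CATEGORIES,
    StimulusCard,
    TrialRecord,
    evaluate_feedback,
    infer_applied_category,
)

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "load_config",
    "save_config",
]

TRIAL_LOG_COLUMNS = (
    "subject_id",
    "trial_index",
    "card_color",
    "card_shape",
    "card_number",
    "response",
    "feedback",
    "target_category",
    "applied_category",
)

_CAT_TO_NAME = dict(enumerate(CATEGORIES))
_NAME_TO_CAT = {name: i for i, name in _CAT_TO_NAME.items()}


def _category_name(cat) -> str:
    return "none" if cat is None else _CAT_TO_NAME[cat]


def write_trial_log(
    dataset: Mapping[str, Sequence[TrialRecord]], path: Union[str, Path]
) -> None:
    """Write a dataset as a canonical trial log (deterministic ordering)."""
    rows = []
    for sid in sorted(dataset):
        for t in sorted(dataset[sid], key=lambda t: t.trial_index):
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "trial_index": t.trial_index,
                    "card_color": t.card.color,
                    "card_shape": t.card.shape,
                    "card_number": t.card.number,
                    "response": t.response,
                    "feedback": t.feedback,
                    "target_category": _category_name(t.target_category),
                    "applied_category": _category_name(t.applied_category),
                }
            )
    frame = pd.DataFrame(rows, columns=list(TRIAL_LOG_COLUMNS))
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_trial_log(
    path: Union[str, Path], strict: bool = True
) -> Dict[str, List[TrialRecord]]:
    """Read and validate a trial log, grouped by subject, sorted by trial.

    Strict mode raises (with the offending 1-based data row number) on any
    invariant violation; lenient mode recomputes ``applied_category`` and
    ``feedback`` from the raw fields and warns when they disagree with the
    file.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")

    dataset: Dict[str, List[TrialRecord]] = {}
    for pos, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            card = StimulusCard(
                int(row.card_color), int(row.card_shape), int(row.card_number)
            )
            if not card.is_deck_valid:
                raise ValueError(f"card attributes are not pairwise distinct: {card}")
            response = int(row.response)
            if response not in (1, 2, 3, 4):
                raise ValueError(f"response out of range: {response}")
            target = _NAME_TO_CAT[str(row.target_category)]
            applied_file = str(row.applied_category)
            if applied_file not in {"none", *CATEGORIES}:
                raise ValueError(f"unknown applied_category {applied_file!r}")
            feedback_file = int(row.feedback)
            if feedback_file not in (-1, 1):
                raise ValueError(f"feedback must be +1 or -1: {feedback_file}")

            applied = infer_applied_category(card, response)
            feedback = evaluate_feedback(applied, target)
            if _category_name(applied) != applied_file or feedback != feedback_file:
                msg = (
                    f"row {pos}: derived fields disagree with the file "
                    f"(applied {_category_name(applied)!r} vs {applied_file!r}, "
                    f"feedback {feedback} vs {feedback_file})"
                )
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg + "; using recomputed values", RuntimeWarning)
            record = TrialRecord(
                subject_id=str(row.subject_id),
                trial_index=int(row.trial_index),
                card=card,
                response=response,
                applied_category=applied,
                feedback=feedback,
                target_category=target,
            )
        except (ValueError, KeyError) as err:
            raise ValueError(f"invalid trial log row {pos}: {err}") from err
        dataset.setdefault(record.subject_id, []).append(record)

    for sid in dataset:
        dataset[sid].sort(key=lambda t: t.trial_index)
    return dict(sorted(dataset.items()))


def save_config(config: Mapping, path: Union[str, Path]) -> None:
    """Write a task/model/sampler/cohort configuration as YAML."""
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=True)


def load_config(path: Union[str, Path]) -> dict:
    """Read a YAML configuration written by :func:`save_config`."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise ValueError(f"configuration file {path} does not hold a mapping")
    return out
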