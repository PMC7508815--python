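"""Scoring of perseveration and set-loss errors stratified by response demand.

After negative feedback the applied category should switch; repeating it is
a perseveration error.  After positive feedback the applied category should
repeat; switching it is a set-loss error.  Each scored trial is additionally
classified by its *response demand*: whether the correct course of action on
trial t would repeat the key pressed on trial t-1.  The classification
follows from where the previously executed key maps on the current card:

* previous key applies the *same* category on the current card -- after
  negative feedback committing the perseveration would repeat the key
  (demanded response alternation); after positive feedback the correct
  category repetition repeats the key (demanded response repetition);
* previous key applies a *different* category -- the roles flip;
* previous key matches the current card on no dimension -- the trial cannot
  be assigned to either demand stratum and is left unclassified.

Conditional error probabilities divide committed errors by the number of
trials on which the error type was possible, per (error type x demand)
cell.  The module also implements the 3-SD participant screen on category
application counts and the simulated-vs-observed R-squared recovery
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .task import TrialRecord, infer_applied_category

__all__ = [
    "TrialClassification",
    "classify_trial",
    "conditional_error_table",
    "group_error_summary",
    "remove_invalid_trials",
    "screen_participants",
    "category_application_counts",
    "recovery_r2",
]

ERROR_TYPES = ("perseveration", "set_loss")
DEMANDS = ("repetition", "alternation")


@dataclass(frozen=True)
class TrialClassification:
    """Error scoring of one trial relative to its predecessor."""

    error_type: str  # 'perseveration' | 'set_loss' | 'none' | 'unscored'
    error_possible: Optional[str]  # which error type was possible, or None
    demand: str  # 'repetition' | 'alternation' | 'unclassified'


def classify_trial(prev: TrialRecord, curr: TrialRecord) -> TrialClassification:
    """Score one trial given its immediate predecessor.

    Both trials must be consecutive rows of the same preprocessed sequence
    (no unmatched-key responses).  The trial after a removed trial has no
    valid predecessor and must not be passed here.
    """
    if prev.subject_id != curr.subject_id:
        raise ValueError("classify_trial requires trials of the same subject")
    if curr.trial_index <= prev.trial_index:
        raise ValueError("trials must be passed in chronological order")
    if prev.applied_category is None or curr.applied_category is None:
        return TrialClassification("unscored", None, "unclassified")

    repeated = curr.applied_category == prev.applied_category
    if prev.feedback == -1:
        possible = "perseveration"
        committed = repeated
    else:
        possible = "set_loss"
        committed = not repeated

    prev_key_cat = infer_applied_category(curr.card, prev.response)
    if prev_key_cat is None:
        demand = "unclassified"
    elif prev_key_cat == prev.applied_category:
        # Sticking with the previous category on this card repeats the key.
        demand = "alternation" if prev.feedback == -1 else "repetition"
    else:
        demand = "repetition" if prev.feedback == -1 else "alternation"

    return TrialClassification(possible if committed else "none", possible, demand)


def conditional_error_table(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Per-cell error counts, opportunities and conditional probabilities.

    Returns a frame indexed by (error_type, demand) with columns ``errors``,
    ``opportunities`` and ``probability`` (NaN where a cell has no
    opportunities).  Trials whose predecessor was removed (non-consecutive
    ``trial_index``) are left unscored.  The perseveration-demand modulation
    contrast P(perseveration | repetition) - P(perseveration | alternation)
    is stored in ``frame.attrs['perseveration_demand_contrast']``.
    """
    if not trials:
        raise ValueError("empty trial sequence")
    errors = {(e, d): 0 for e in ERROR_TYPES for d in DEMANDS}
    opps = {(e, d): 0 for e in ERROR_TYPES for d in DEMANDS}
    for prev, curr in zip(trials, trials[1:]):
        if curr.trial_index != prev.trial_index + 1:
            continue  # a removed trial broke the sequence here
        c = classify_trial(prev, curr)
        if c.error_possible is None or c.demand == "unclassified":
            continue
        opps[(c.error_possible, c.demand)] += 1
        if c.error_type == c.error_possible:
            errors[(c.error_possible, c.demand)] += 1

    rows = []
    for e in ERROR_TYPES:
        for d in DEMANDS:
            n_err, n_opp = errors[(e, d)], opps[(e, d)]
            rows.append(
                {
                    "error_type": e,
                    "demand": d,
                    "errors": n_err,
                    "opportunities": n_opp,
                    "probability": n_err / n_opp if n_opp else np.nan,
                }
            )
    table = pd.DataFrame(rows).set_index(["error_type", "demand"])
    p = table["probability"]
    table.attrs["perseveration_demand_contrast"] = float(
        p[("perseveration", "repetition")] - p[("perseveration", "alternation")]
    )
    return table


def group_error_summary(
    dataset: Mapping[str, Sequence[TrialRecord]],
) -> pd.DataFrame:
    """Stack per-subject conditional error probabilities into one frame.

    One row per subject and (error type x demand) cell, plus the per-subject
    perseveration-demand contrast in ``attrs['contrasts']``.
    """
    rows = []
    contrasts = {}
    for sid in sorted(dataset):
        table = conditional_error_table(dataset[sid])
        contrasts[sid] = table.attrs["perseveration_demand_contrast"]
        for (e, d), row in table.iterrows():
            rows.append(
                {
                    "subject_id": sid,
                    "error_type": e,
                    "demand": d,
                    "errors": int(row["errors"]),
                    "opportunities": int(row["opportunities"]),
                    "probability": row["probability"],
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["contrasts"] = contrasts
    return out


def remove_invalid_trials(
    trials: Sequence[TrialRecord],
) -> Tuple[List[TrialRecord], Dict[str, object]]:
    """Delete unmatched-key trials from a sequence.

    Returns the filtered sequence and a report with the removed trial
    indices and the removal fraction.  Idempotent.
    """
    kept = [t for t in trials if t.applied_category is not None]
    removed = [t.trial_index for t in trials if t.applied_category is None]
    report = {
        "removed_indices": removed,
        "n_removed": len(removed),
        "fraction_removed": len(removed) / len(trials) if trials else 0.0,
    }
    return kept, report


def category_application_counts(
    dataset: Mapping[str, Sequence[TrialRecord]],
) -> pd.DataFrame:
    """Applications of each category per subject (unmatched keys ignored)."""
    rows = {}
    for sid, trials in dataset.items():
        counts = np.zeros(3, dtype=int)
        for t in trials:
            if t.applied_category is not None:
                counts[t.applied_category] += 1
        rows[sid] = counts
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["color", "shape", "number"]
    ).sort_index()


def screen_participants(counts: pd.DataFrame) -> pd.Series:
    """Flag subjects whose category usage is extreme relative to the cohort.

    A subject is excluded iff, for any category, their application count
    lies strictly outside the cohort mean +/- 3 standard deviations of that
    category; counts exactly on the boundary are kept.  Returns a boolean
    Series (True = keep) indexed like ``counts``.
    """
    if len(counts) < 2:
        raise ValueError("screening requires at least 2 subjects")
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    lo, hi = mean - 3 * sd, mean + 3 * sd
    outside = (counts.lt(lo, axis=1) | counts.gt(hi, axis=1)).any(axis=1)
    keep = ~outside
    keep.name = "keep"
    return keep


def recovery_r2(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    value_col: str = "probability",
) -> pd.DataFrame:
    """R-squared of observed vs simulated conditional error probabilities.

    ``observed`` and ``simulated`` are group frames as produced by
    :func:`group_error_summary` for the same subjects.  For every
    (error type x demand) cell, the observed per-subject probabilities are
    regressed on the simulated ones by ordinary least squares; cells drop
    subject pairs with a missing value and require at least 3 pairs.
    """
    rows = []
    for e in ERROR_TYPES:
        for d in DEMANDS:
            obs = observed[(observed.error_type == e) & (observed.demand == d)]
            sim = simulated[(simulated.error_type == e) & (simulated.demand == d)]
            merged = obs.merge(
                sim, on="subject_id", suffixes=("_obs", "_sim")
            ).dropna(subset=[f"{value_col}_obs", f"{value_col}_sim"])
            if len(merged) < 3:
                raise ValueError(
                    f"cell ({e}, {d}) has fewer than 3 paired observations"
                )
            x = merged[f"{value_col}_sim"].to_numpy()
            y = merged[f"{value_col}_obs"].to_numpy()
            if np.allclose(x, x[0]):
                r2 = 0.0  # a constant predictor explains no variance
            else:
                r2 = float(stats.linregress(x, y).rvalue ** 2)
            rows.append({"error_type": e, "demand": d, "r2": r2, "n": len(merged)})
    return pd.DataFrame(rows).set_index(["error_type", "demand"])
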