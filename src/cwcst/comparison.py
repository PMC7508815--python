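"""K-fold cross-validated model comparison via expected log predictive density.

Subjects are randomly partitioned into K folds (default 5).  For each fold,
the hierarchical model is fitted to the remaining subjects; a held-out
subject's elpd is the log of the across-draw average of the product of the
predicted probabilities of their observed responses.  Because a held-out
subject has no individual-level effects in the training fit, their
parameter vector is constructed per posterior draw from the group level:
either by sampling a fresh standardized effect ``z ~ N(0,1)`` (default,
"new-subject" construction) or by plugging in the group location (``z = 0``).

Group-level elpd is the sum over subjects; relative performance is the
difference to the best model (delta-elpd) with a standard error of
``sqrt(N) * sd`` of the per-subject elpd differences.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._engine import compile_trials, loglik_batch
from .inference import (
    PARAM_SPECS,
    PosteriorDraws,
    constrain_matrix,
    fit_hierarchical,
    theta_dict,
)
from .task import TrialRecord

__all__ = [
    "MODEL_N_PARAMS",
    "kfold_partition",
    "heldout_elpd",
    "elpd_from_draw_likelihoods",
    "compare_models",
    "kfold_elpd",
]

#: Free individual parameters per model, used to break winner ties toward
#: the simpler model.
MODEL_N_PARAMS = {name: len(spec) for name, spec in PARAM_SPECS.items()}


def kfold_partition(
    subject_ids: Sequence[str], k: int = 5, seed: int = 0
) -> Dict[str, int]:
    """Seeded uniform random partition of subjects into K near-equal folds.

    Fold sizes differ by at most one.  Returns subject id -> fold index in
    1..K.
    """
    ids = list(subject_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError("k exceeds the number of subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment: Dict[str, int] = {}
    for fold, chunk in enumerate(np.array_split(order, k), start=1):
        for i in chunk:
            assignment[ids[i]] = fold
    return assignment


def elpd_from_draw_likelihoods(likelihoods: Sequence[float]) -> float:
    """elpd from per-draw predicted sequence likelihoods: log of their mean."""
    lik = np.asarray(likelihoods, dtype=float)
    if lik.size == 0 or (lik < 0).any():
        raise ValueError("likelihoods must be a non-empty non-negative sequence")
    return float(np.log(lik.mean()))


def heldout_elpd(
    training_draws: PosteriorDraws,
    heldout_trials: Sequence[TrialRecord],
    variant: Optional[str] = None,
    seed: int = 0,
    method: str = "new-subject",
) -> float:
    """elpd of one held-out subject under a training-set posterior.

    For each posterior draw s, an individual parameter vector is built from
    the draw's group level (mu_s, sigma_s): with ``method='new-subject'``
    (default) a standardized effect vector is sampled per draw; with
    ``method='plugin'`` the group location is used directly.  The per-draw
    predicted probability of the subject's full observed sequence is then
    averaged across draws and logarithmized.
    """
    variant = variant or training_draws.variant
    if variant != training_draws.variant:
        raise ValueError("variant does not match the training draws")
    mu, sigma = training_draws.flat_group()  # (S, K)
    S, K = mu.shape
    if method == "new-subject":
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((S, K))
    elif method == "plugin":
        z = np.zeros((S, K))
    else:
        raise ValueError(f"unknown held-out construction {method!r}")
    theta = constrain_matrix(mu + sigma * z, training_draws.kinds)
    ct = compile_trials([list(heldout_trials)]).repeat(S)
    ll = loglik_batch(ct, theta_dict(variant, theta), variant)
    if not np.all(np.isfinite(ll)):
        raise ValueError(
            "zero-probability observed response in the held-out sequence; "
            "preprocess the data before computing elpd"
        )
    return float(logsumexp(ll) - np.log(S))


@dataclass(frozen=True)
class ComparisonResult:
    """Group and per-subject results of a multi-model comparison."""

    per_subject: pd.DataFrame  # subjects x models, individual elpd
    summary: pd.DataFrame  # per model: elpd, delta_elpd, se, winner share
    best_model: str


def compare_models(
    elpd_by_model: Mapping[str, Mapping[str, float]],
    n_params: Optional[Mapping[str, int]] = None,
) -> ComparisonResult:
    """Group-level delta-elpd with SEs and per-subject winner tallies.

    ``elpd_by_model`` maps model name -> (subject id -> elpd); all models
    must cover the identical subject set.  The best model has the highest
    total elpd (equivalently the lowest absolute value, elpd being
    negative); delta-elpd of any other model is its total minus the best
    model's, with SE = sqrt(N) * sd of the per-subject differences.
    Per-subject winner ties go to the model with fewer parameters.
    """
    models = list(elpd_by_model)
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    n_params = dict(n_params or MODEL_N_PARAMS)
    subject_sets = [frozenset(elpd_by_model[m]) for m in models]
    if len(set(subject_sets)) != 1:
        raise ValueError("models were evaluated on different subject sets")
    subjects = sorted(subject_sets[0])
    table = pd.DataFrame(
        {m: [elpd_by_model[m][s] for s in subjects] for m in models}, index=subjects
    )
    totals = table.sum(axis=0)
    best = str(totals.idxmax())

    # Winner per subject; ties broken toward the simpler model.
    def winner(row: pd.Series) -> str:
        top = row.max()
        tied = [m for m in models if row[m] == top]
        return min(tied, key=lambda m: (n_params.get(m, np.inf), models.index(m)))

    winners = table.apply(winner, axis=1)
    n = len(subjects)
    rows = []
    for m in models:
        if m == best:
            delta, se = 0.0, 0.0
        else:
            diffs = (table[m] - table[best]).to_numpy()
            delta = float(diffs.sum())
            se = float(np.sqrt(n) * diffs.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "model": m,
                "n_params": n_params.get(m, np.nan),
                "elpd": float(totals[m]),
                "delta_elpd": delta,
                "se": se,
                "best_for": int((winners == m).sum()),
                "best_share": float((winners == m).mean()),
            }
        )
    summary = pd.DataFrame(rows).set_index("model")
    return ComparisonResult(per_subject=table, summary=summary, best_model=best)


def kfold_elpd(
    dataset: Mapping[str, Sequence[TrialRecord]],
    variant: str,
    k: int = 5,
    seed: int = 0,
    method: str = "new-subject",
    **sampler_kwargs,
) -> Dict[str, float]:
    """Full K-fold cross-validation of one model over a dataset.

    Fits the hierarchical model K times, each time excluding one fold, and
    returns per-subject held-out elpd values.  ``sampler_kwargs`` are passed
    to :func:`cwcst.inference.fit_hierarchical` (reduce them for tests).
    """
    assignment = kfold_partition(sorted(dataset), k, seed)
    elpd: Dict[str, float] = {}
    for fold in range(1, k + 1):
        train = {s: dataset[s] for s, f in assignment.items() if f != fold}
        held = [s for s, f in assignment.items() if f == fold]
        draws = fit_hierarchical(train, variant, seed=seed + fold, **sampler_kwargs)
        for s in held:
            sub_seed = (seed + zlib.crc32(s.encode())) % (2**31)
            elpd[s] = heldout_elpd(
                draws, dataset[s], variant, seed=sub_seed, method=method
            )
    return elpd
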