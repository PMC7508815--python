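"""Vectorized trial-sequence likelihood kernels.

The public model modules (:mod:`cwcst.rl`, :mod:`cwcst.au`) expose the
per-trial recursions in readable scalar form.  Hierarchical sampling,
cross-validation and post-hoc simulation need the same recursions evaluated
for many parameter vectors and/or many subjects at once; this module
compiles trial sequences to padded integer arrays and runs the recursions
vectorized over the batch dimension with numpy.

Conventions: responses and categories are 0-based here; ``cat_of_resp``
holds, per trial and response, the applied category (0..2) or 3 for the
unmatched key; ``applied`` is -1 for unmatched-key trials (allowed only in
RL batches, where the model-based kernel then only decays).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np

from .task import TrialRecord, match_categories

_FLOOR = 1e-12
_TAU_FLOOR = 1e-10


@dataclass(frozen=True)
class CompiledTrials:
    """Padded array view of a batch of trial sequences."""

    resp: np.ndarray  # (S, T) int, 0-based executed response
    cat_of_resp: np.ndarray  # (S, T, 4) int, category per response, 3 = unmatched
    applied: np.ndarray  # (S, T) int, applied category or -1
    fb: np.ndarray  # (S, T) float, +1 / -1
    mask: np.ndarray  # (S, T) bool, True for real trials
    n_trials: np.ndarray  # (S,) int

    @property
    def n_sequences(self) -> int:
        return self.resp.shape[0]

    def repeat(self, n: int) -> "CompiledTrials":
        """Tile a batch ``n`` times along the sequence axis."""
        return CompiledTrials(
            np.repeat(self.resp, n, axis=0),
            np.repeat(self.cat_of_resp, n, axis=0),
            np.repeat(self.applied, n, axis=0),
            np.repeat(self.fb, n, axis=0),
            np.repeat(self.mask, n, axis=0),
            np.repeat(self.n_trials, n, axis=0),
        )


def compile_trials(sequences: Sequence[Sequence[TrialRecord]]) -> CompiledTrials:
    """Pack trial sequences into padded arrays for batch evaluation."""
    if not sequences:
        raise ValueError("no trial sequences to compile")
    n = [len(seq) for seq in sequences]
    if min(n) == 0:
        raise ValueError("empty trial sequence in batch")
    S, T = len(sequences), max(n)
    resp = np.zeros((S, T), dtype=np.int64)
    cat_of_resp = np.full((S, T, 4), 3, dtype=np.int64)
    applied = np.full((S, T), -1, dtype=np.int64)
    fb = np.ones((S, T))
    mask = np.zeros((S, T), dtype=bool)
    for i, seq in enumerate(sequences):
        for t, trial in enumerate(seq):
            cats = match_categories(trial.card)
            cat_of_resp[i, t] = np.where(cats >= 0, cats, 3)
            resp[i, t] = trial.response - 1
            applied[i, t] = -1 if trial.applied_category is None else trial.applied_category
            fb[i, t] = trial.feedback
            mask[i, t] = True
    return CompiledTrials(resp, cat_of_resp, applied, fb, mask, np.asarray(n))


def _log_softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=1, keepdims=True)
    return x - np.log(np.exp(x).sum(axis=1, keepdims=True))


def rl_scan_batch(
    ct: CompiledTrials,
    theta: Dict[str, np.ndarray],
    variant: str,
    collect_probs: bool = False,
) -> "tuple[np.ndarray, np.ndarray | None]":
    """Run the RL recursion over a batch of sequences.

    ``theta`` maps parameter names to (S,) arrays paired with the S compiled
    sequences.  Returns per-sequence total log-likelihoods and, when
    ``collect_probs`` is set, the (S, T, 4) response-probability array on
    every trial given the observed history.  Unmatched-key trials contribute
    their softmax probability and trigger a decay-only MB update, matching
    :func:`cwcst.rl.rl_update`.
    """
    S, T = ct.resp.shape
    rows = np.arange(S)
    a_mb_pos = np.asarray(theta["alpha_mb_pos"], dtype=float)
    a_mb_neg = np.asarray(theta["alpha_mb_neg"], dtype=float)
    g_mb = np.asarray(theta["gamma_mb"], dtype=float)
    tau = np.maximum(np.asarray(theta["tau"], dtype=float), _TAU_FLOOR)
    uses_mf = variant in ("wprl", "prl")
    if uses_mf:
        a_mf_pos = np.asarray(theta["alpha_mf_pos"], dtype=float)
        a_mf_neg = np.asarray(theta["alpha_mf_neg"], dtype=float)
        g_mf = np.asarray(theta["gamma_mf"], dtype=float)
    if variant == "wprl":
        w = np.asarray(theta["w"], dtype=float)

    q_c = np.zeros((S, 3))
    q_mf = np.zeros((S, 4))
    minus_one = np.full((S, 1), -1.0)
    ll = np.zeros(S)
    probs = np.zeros((S, T, 4)) if collect_probs else None
    for t in range(T):
        m = ct.mask[:, t]
        if not m.any():
            break
        q_c_ext = np.concatenate([q_c, minus_one], axis=1)
        q_mb = np.take_along_axis(q_c_ext, ct.cat_of_resp[:, t, :], axis=1)
        if variant == "mbrl":
            q_sum = q_mb
        elif variant == "prl":
            q_sum = q_mb + q_mf
        else:
            q_sum = w[:, None] * q_mb + (1.0 - w[:, None]) * q_mf
        logp = _log_softmax(q_sum / tau[:, None])
        if collect_probs:
            probs[:, t, :] = np.exp(logp)
        ll += np.where(m, logp[rows, ct.resp[:, t]], 0.0)

        fb = ct.fb[:, t]
        u = ct.applied[:, t]
        valid_u = u >= 0
        u_safe = np.where(valid_u, u, 0)
        q_c_dec = g_mb[:, None] * q_c
        alpha = np.where(fb > 0, a_mb_pos, a_mb_neg)
        delta = fb - q_c_dec[rows, u_safe]
        q_c_new = q_c_dec.copy()
        q_c_new[rows, u_safe] += np.where(valid_u, alpha * delta, 0.0)
        q_c = np.where(m[:, None], q_c_new, q_c)
        if uses_mf:
            q_mf_dec = g_mf[:, None] * q_mf
            alpha_f = np.where(fb > 0, a_mf_pos, a_mf_neg)
            delta_f = fb - q_mf_dec[rows, ct.resp[:, t]]
            q_mf_new = q_mf_dec.copy()
            q_mf_new[rows, ct.resp[:, t]] += alpha_f * delta_f
            q_mf = np.where(m[:, None], q_mf_new, q_mf)
    return ll, probs


def au_scan_batch(
    ct: CompiledTrials,
    theta: Dict[str, np.ndarray],
    collect_probs: bool = False,
) -> "tuple[np.ndarray, np.ndarray | None]":
    """Run the AU recursion over a batch of sequences.

    Sequences must be preprocessed: any unmatched-key response has
    probability zero under the AU model and is rejected.
    """
    if (ct.applied[ct.mask] < 0).any():
        bad = int(np.argmax((ct.applied < 0).any(axis=1)))
        raise ValueError(
            f"sequence {bad} contains an unmatched-key response; "
            "remove such trials before AU evaluation"
        )
    S, T = ct.resp.shape
    rows = np.arange(S)
    p_pos = np.asarray(theta["p_pos"], dtype=float)
    p_neg = np.asarray(theta["p_neg"], dtype=float)
    f = np.asarray(theta["f"], dtype=float)
    d = np.asarray(theta["d"], dtype=float)

    a = np.full((S, 3), 1.0 / 3.0)
    zeros = np.zeros((S, 1))
    ll = np.zeros(S)
    probs_out = np.zeros((S, T, 4)) if collect_probs else None
    eye3 = np.eye(3)
    # Padded trials produce 0/0 and log(0) in lanes that the mask discards.
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in range(T):
            m = ct.mask[:, t]
            if not m.any():
                break
            a_d = np.maximum(a, _FLOOR) ** d[:, None]
            w4 = np.take_along_axis(np.concatenate([a_d, zeros], axis=1),
                                    ct.cat_of_resp[:, t, :], axis=1)
            probs = w4 / w4.sum(axis=1, keepdims=True)
            if collect_probs:
                probs_out[:, t, :] = np.where(m[:, None], probs, 0.0)
            p_exec = probs[rows, ct.resp[:, t]]
            ll += np.where(m, np.log(p_exec), 0.0)

            fb = ct.fb[:, t]
            u_safe = np.maximum(ct.applied[:, t], 0)
            one_hot = eye3[u_safe]
            a_f = np.maximum(a, _FLOOR) ** f[:, None]
            wts = np.where((fb > 0)[:, None], one_hot * a_f, (1.0 - one_hot) * a_f)
            s = wts / wts.sum(axis=1, keepdims=True)
            p = np.where(fb > 0, p_pos, p_neg)[:, None]
            a_new = (1.0 - p) * a + p * s
            a = np.where(m[:, None], a_new, a)
    return ll, probs_out


def loglik_batch(
    ct: CompiledTrials, theta: Dict[str, np.ndarray], variant: str
) -> np.ndarray:
    """Total log-likelihood per sequence under a model variant."""
    if variant == "au":
        return au_scan_batch(ct, theta)[0]
    if variant in ("wprl", "prl", "mbrl"):
        return rl_scan_batch(ct, theta, variant)[0]
    raise ValueError(f"unknown model variant {variant!r}")


def probs_sequence_batch(
    ct: CompiledTrials, theta: Dict[str, np.ndarray], variant: str
) -> np.ndarray:
    """Per-trial response probabilities (S, T, 4) given the observed history.

    The latent state on trial t is rebuilt from the compiled (observed)
    responses and feedback on trials 1..t-1; this is the quantity the
    one-trial-ahead simulation samples from.
    """
    if variant == "au":
        return au_scan_batch(ct, theta, collect_probs=True)[1]
    if variant in ("wprl", "prl", "mbrl"):
        return rl_scan_batch(ct, theta, variant, collect_probs=True)[1]
    raise ValueError(f"unknown model variant {variant!r}")
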