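"""Numba-compiled single-sequence likelihood kernels.

The numpy batch kernels in :mod:`cwcst._engine` amortize per-trial overhead
across many sequences and are the right tool for hierarchical sampling; a
single-sequence likelihood inside an optimizer loop, however, is dominated
by that overhead.  These jitted kernels evaluate one sequence in tens of
microseconds and are used by the per-subject point-estimation path.  They
implement exactly the same recursions as the batch kernels (cross-checked
in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit

VARIANT_CODES = {"mbrl": 0, "prl": 1, "wprl": 2}

_FLOOR = 1e-12
_TAU_FLOOR = 1e-10


@njit(cache=False)
def rl_loglik_seq(
    resp: np.ndarray,  # (T,) int64, 0-based responses
    cats: np.ndarray,  # (T, 4) int64, category per response, 3 = unmatched
    applied: np.ndarray,  # (T,) int64, applied category or -1
    fb: np.ndarray,  # (T,) float64
    params: np.ndarray,  # (8,): a_mb+, a_mb-, g_mb, a_mf+, a_mf-, g_mf, tau, w
    variant_code: int,  # 0 = mbrl, 1 = prl, 2 = wprl
) -> float:
    a_mb_p, a_mb_n, g_mb = params[0], params[1], params[2]
    a_mf_p, a_mf_n, g_mf = params[3], params[4], params[5]
    tau = max(params[6], _TAU_FLOOR)
    w = params[7]
    q_c = np.zeros(3)
    q_mf = np.zeros(4)
    q_sum = np.empty(4)
    ll = 0.0
    for t in range(resp.shape[0]):
        for v in range(4):
            c = cats[t, v]
            q_mb_v = -1.0 if c == 3 else q_c[c]
            if variant_code == 0:
                q_sum[v] = q_mb_v
            elif variant_code == 1:
                q_sum[v] = q_mb_v + q_mf[v]
            else:
                q_sum[v] = w * q_mb_v + (1.0 - w) * q_mf[v]
        mx = q_sum[0]
        for v in range(1, 4):
            if q_sum[v] > mx:
                mx = q_sum[v]
        denom = 0.0
        for v in range(4):
            denom += np.exp((q_sum[v] - mx) / tau)
        ll += (q_sum[resp[t]] - mx) / tau - np.log(denom)

        r = fb[t]
        for c in range(3):
            q_c[c] *= g_mb
        u = applied[t]
        if u >= 0:
            alpha = a_mb_p if r > 0 else a_mb_n
            q_c[u] += alpha * (r - q_c[u])
        if variant_code != 0:
            for v in range(4):
                q_mf[v] *= g_mf
            alpha_f = a_mf_p if r > 0 else a_mf_n
            q_mf[resp[t]] += alpha_f * (r - q_mf[resp[t]])
    return ll


@njit(cache=False)
def au_loglik_seq(
    resp: np.ndarray,
    cats: np.ndarray,
    applied: np.ndarray,
    fb: np.ndarray,
    params: np.ndarray,  # (4,): p_pos, p_neg, f, d
) -> float:
    p_pos, p_neg, f, d = params[0], params[1], params[2], params[3]
    a = np.full(3, 1.0 / 3.0)
    wts = np.empty(3)
    ll = 0.0
    for t in range(resp.shape[0]):
        u = applied[t]
        if u < 0:
            return -np.inf  # unmatched-key response: probability zero
        denom = 0.0
        num = 0.0
        for v in range(4):
            c = cats[t, v]
            if c != 3:
                a_d = max(a[c], _FLOOR) ** d
                denom += a_d
                if v == resp[t]:
                    num = a_d
        if num <= 0.0:
            return -np.inf
        ll += np.log(num / denom)

        r = fb[t]
        s_denom = 0.0
        for c in range(3):
            a_f = max(a[c], _FLOOR) ** f
            if r > 0:
                wts[c] = a_f if c == u else 0.0
            else:
                wts[c] = 0.0 if c == u else a_f
            s_denom += wts[c]
        p = p_pos if r > 0 else p_neg
        for c in range(3):
            a[c] = (1.0 - p) * a[c] + p * wts[c] / s_denom
    return ll
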