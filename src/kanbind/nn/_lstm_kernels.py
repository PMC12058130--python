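"""Numba kernel for LSTM backpropagation through time.

The backward gate arithmetic is pure elementwise algebra (no
transcendentals — those were evaluated and cached in the forward pass), so
a JIT-compiled loop removes the per-step numpy temporary overhead.  The
large weight-gradient GEMMs stay outside in BLAS.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def lstm_backward_loop(g_seq, w_h_t, peep, use_peep,
                       i_s, f_s, g_s, o_s, c_s, tc_s):
    """Backpropagation through time for the recursion above.

    g_seq: (T, N, H) upstream gradient on the hidden states; w_h_t is the
    transposed recurrent weight (4H, H), contiguous.  Returns the packed
    pre-activation gradients da (T, N, 4H) and the peephole gradient (3, H).
    """
    T, n, H = g_seq.shape
    dt = g_seq.dtype
    da_all = np.empty((T, n, 4 * H), dtype=dt)
    dp = np.zeros((3, H), dtype=dt)
    dh_next = np.zeros((n, H), dtype=dt)
    dc_next = np.zeros((n, H), dtype=dt)
    for t in range(T - 1, -1, -1):
        for b in range(n):
            for j in range(H):
                cp = c_s[t - 1, b, j] if t > 0 else 0.0
                dh = g_seq[t, b, j] + dh_next[b, j]
                ot = o_s[t, b, j]
                tc = tc_s[t, b, j]
                da_o = dh * tc * ot * (1.0 - ot)
                dc = dh * ot * (1.0 - tc * tc) + dc_next[b, j]
                if use_peep:
                    dc += da_o * peep[2, j]
                it = i_s[t, b, j]
                ft = f_s[t, b, j]
                gt = g_s[t, b, j]
                da_i = dc * gt * it * (1.0 - it)
                da_g = dc * it * (1.0 - gt * gt)
                da_f = dc * cp * ft * (1.0 - ft)
                dcn = dc * ft
                if use_peep:
                    dcn += da_i * peep[0, j] + da_f * peep[1, j]
                    dp[0, j] += da_i * cp
                    dp[1, j] += da_f * cp
                    dp[2, j] += da_o * c_s[t, b, j]
                dc_next[b, j] = dcn
                da_all[t, b, j] = da_i
                da_all[t, b, H + j] = da_f
                da_all[t, b, 2 * H + j] = da_g
                da_all[t, b, 3 * H + j] = da_o
        dh_next = np.dot(da_all[t], w_h_t)
    return da_all, dp
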