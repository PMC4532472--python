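"""Numba-compiled direct-method SSA kernel with online time-fraction tallies.

The kernel exists for the long-horizon experiments (1e6 time units of the
multisite switch) where storing every jump is impossible and Python-level
propensity evaluation is too slow.  It understands three propensity forms:

* ``kind 0`` — mass action: rate * prod of falling factorials of reactant counts
* ``kind 1`` — mass action times a linear form w.x (state-dependent rate
  constants such as a degradation propensity proportional to a weighted
  population sum)
* ``kind 2`` — tabulated unary: the full propensity is ``table[x[s]]`` for a
  single species s (used for quasi-steady-state reduced rates)

Randomness is an embedded PCG32 stream so trajectories are bit-reproducible
for a given integer seed, independent of NumPy/Numba RNG internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
ERR_NEGATIVE_PROPENSITY = 1
ERR_TABLE_OVERFLOW = 2
ERR_HIST_OVERFLOW = 3

_MULT = np.uint64(6364136223846793005)


@njit(cache=True, inline="always")
def _pcg32_next(state, inc):
    """One PCG32-XSH-RR step; returns (new_state, uint32 output)."""
    old = state
    state = old * _MULT + inc
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    out = np.uint32(
        (xorshifted >> rot) | (xorshifted << ((np.uint32(32) - rot) & np.uint32(31)))
    )
    return state, out


@njit(cache=True, inline="always")
def _uniform(state, inc):
    state, out = _pcg32_next(state, inc)
    # (out + 0.5) / 2^32 lies strictly inside (0, 1): log() is always finite
    return state, (np.float64(out) + 0.5) / 4294967296.0


def pcg_init(seed: int) -> tuple[np.uint64, np.uint64]:
    """Seed a PCG32 stream (splitmix64 scrambling of one integer seed)."""
    mask = (1 << 64) - 1
    s = int(seed) & mask
    outs = []
    for _ in range(2):
        s = (s + 0x9E3779B97F4A7C15) & mask
        z = s
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        z = z ^ (z >> 31)
        outs.append(z)
    state = outs[0]
    inc = ((outs[1] << 1) | 1) & mask
    # pcg32_srandom: advance once so state depends on both words
    state = (state * 6364136223846793005 + inc) & mask
    return np.uint64(state), np.uint64(inc)


@njit(cache=True)
def ssa_time_fraction(
    x,
    nu,
    kind,
    rate,
    react_sp,
    react_ord,
    lin_w,
    tab_idx,
    tables,
    t_end,
    burn_in,
    hist_sp,
    hist,
    state,
    inc,
):
    """Run the direct method to t_end, tallying dwell time per copy number.

    ``x`` (int64) and ``hist`` (float64, raw dwell times of species
    ``hist_sp`` after ``burn_in``) are updated in place.  Returns
    (t, n_steps, status, rng_state).
    """
    t = 0.0
    m = nu.shape[0]
    n = x.shape[0]
    a = np.empty(m, dtype=np.float64)
    n_steps = np.int64(0)
    status = OK
    bad_reaction = -1

    while True:
        # propensities
        a0 = 0.0
        for j in range(m):
            if kind[j] == 2:
                xv = x[react_sp[j, 0]]
                if xv < 0 or xv >= tables.shape[1]:
                    return t, n_steps, ERR_TABLE_OVERFLOW, state
                aj = tables[tab_idx[j], xv]
            else:
                aj = rate[j]
                for q in range(react_sp.shape[1]):
                    s = react_sp[j, q]
                    if s < 0:
                        break
                    for r in range(react_ord[j, q]):
                        aj *= x[s] - r
                if kind[j] == 1:
                    lw = 0.0
                    for s in range(n):
                        lw += lin_w[j, s] * x[s]
                    aj *= lw
            if aj < 0.0:
                return t, n_steps, ERR_NEGATIVE_PROPENSITY, state
            a[j] = aj
            a0 += aj

        if a0 <= 0.0:
            # absorbed: dwell at the current state until t_end
            seg0 = max(t, burn_in)
            if t_end > seg0:
                xv = x[hist_sp]
                if xv < 0 or xv >= hist.shape[0]:
                    return t, n_steps, ERR_HIST_OVERFLOW, state
                hist[xv] += t_end - seg0
            t = t_end
            break

        state, r1 = _uniform(state, inc)
        tau = np.log(1.0 / r1) / a0
        t_next = t + tau

        seg0 = max(t, burn_in)
        seg1 = min(t_next, t_end)
        if seg1 > seg0:
            xv = x[hist_sp]
            if xv < 0 or xv >= hist.shape[0]:
                return t, n_steps, ERR_HIST_OVERFLOW, state
            hist[xv] += seg1 - seg0

        if t_next >= t_end:
            t = t_end
            break

        state, r2 = _uniform(state, inc)
        target = r2 * a0
        cum = 0.0
        fired = m - 1
        for j in range(m):
            cum += a[j]
            if cum > target:
                fired = j
                break
        for s in range(n):
            x[s] += nu[fired, s]
        t = t_next
        n_steps += 1

    return t, n_steps, status, state
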