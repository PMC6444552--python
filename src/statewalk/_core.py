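"""JIT-compiled stepping loop.

The arithmetic here is mirrored line-for-line by the pure-Python reference
engine in :mod:`statewalk.sim`; both consume the same RNG stream (one
uniform for the state draw, one for the heading draw, per step) so that the
two engines produce bit-identical trajectories.  Keep any change in sync.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _resistance_at(values, x0, y0, cell, nrow, ncol, x, y):
    col = int(np.floor((x - x0) / cell))
    row_b = int(np.floor((y - y0) / cell))
    if col < 0 or col >= ncol or row_b < 0 or row_b >= nrow:
        return 1.0
    return values[nrow - 1 - row_b, col]


@njit(cache=False)
def _simulate_loop(
    n_steps,
    start_x,
    start_y,
    start_state,
    start_heading_idx,
    trans,          # (S, S) row-stochastic
    kernels,        # (S, K) normalized wrapped-normal weights centered at index 0
    max_steps,      # (S,)
    perc_ranges,    # (S,)
    n_samples,      # (S,) int64
    cos_t,          # (K,)
    sin_t,          # (K,)
    has_raster,
    values,         # (nrow, ncol) resistance, dummy when has_raster is False
    rx0,
    ry0,
    rcell,
    rng,
):
    K = cos_t.shape[0]
    S = trans.shape[0]
    nrow, ncol = values.shape

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    states = np.empty(n_steps + 1, dtype=np.int64)
    xs[0] = start_x
    ys[0] = start_y
    states[0] = start_state

    x = start_x
    y = start_y
    state = start_state
    heading_idx = start_heading_idx
    n_trapped = 0

    perc = np.empty(K)
    combined = np.empty(K)

    for t in range(1, n_steps + 1):
        # 1. draw new behavioral state from the transition-matrix row
        u1 = rng.random()
        acc = 0.0
        s = S - 1
        for j in range(S - 1):
            acc += trans[state, j]
            if u1 < acc:
                s = j
                break
        state = s

        # 2-3. perceive: sum conductance along K radial lines
        if has_raster:
            R = perc_ranges[s]
            n = n_samples[s]
            for k in range(K):
                w = 0.0
                for j in range(1, n + 1):
                    d = R * j / n
                    r = _resistance_at(
                        values, rx0, ry0, rcell, nrow, ncol, x + d * cos_t[k], y + d * sin_t[k]
                    )
                    w += 1.0 - r
                perc[k] = w
        else:
            for k in range(K):
                perc[k] = 1.0

        # 4-5. multiply by the turning kernel centered on the previous heading
        total = 0.0
        for k in range(K):
            combined[k] = perc[k] * kernels[s, (k - heading_idx) % K]
            total += combined[k]
        if total <= 0.0:
            # walker boxed in: fall back to the kernel alone ("trapped" event)
            n_trapped += 1
            total = 0.0
            for k in range(K):
                combined[k] = kernels[s, (k - heading_idx) % K]
                total += combined[k]

        # 6. draw the heading
        u2 = rng.random()
        target = u2 * total
        acc = 0.0
        h = K - 1
        for k in range(K):
            acc += combined[k]
            if target < acc:
                h = k
                break

        # 7. attenuate the step by mean endpoint resistance
        L = max_steps[s]
        dx = L * cos_t[h]
        dy = L * sin_t[h]
        if has_raster:
            rf = _resistance_at(values, rx0, ry0, rcell, nrow, ncol, x, y)
            rt = _resistance_at(values, rx0, ry0, rcell, nrow, ncol, x + dx, y + dy)
            frac = 1.0 - (rf + rt) / 2.0
        else:
            frac = 1.0
        d = frac * L

        # 8. move, with the impassability guard: never land on resistance 1
        if has_raster and d > 0.0:
            if (
                _resistance_at(
                    values, rx0, ry0, rcell, nrow, ncol, x + d * cos_t[h], y + d * sin_t[h]
                )
                >= 1.0
            ):
                dd = d - rcell * 0.25
                found = False
                while dd > 0.0:
                    if (
                        _resistance_at(
                            values, rx0, ry0, rcell, nrow, ncol,
                            x + dd * cos_t[h], y + dd * sin_t[h],
                        )
                        < 1.0
                    ):
                        found = True
                        break
                    dd -= rcell * 0.25
                d = dd if found else 0.0

        if d > 0.0:
            x = x + d * cos_t[h]
            y = y + d * sin_t[h]
            heading_idx = h  # zero-length steps keep the previous heading

        xs[t] = x
        ys[t] = y
        states[t] = state

    return xs, ys, states, n_trapped, heading_idx
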