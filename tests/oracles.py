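"""Independent reference computations used to validate the HMM observer.

These oracles deliberately avoid the forward recursion they check: the exact
posterior is obtained by enumerating every change-point configuration of a
short sequence, and the no-volatility limit by conjugate Beta counting on the
same grid.
"""

from itertools import product

import numpy as np


def midpoint_grid(grid_n: int) -> np.ndarray:
    return (np.arange(grid_n) + 0.5) / grid_n


def _segment_likelihood(tones, a, b, grid_n):
    """Likelihood over the theta grid of trials a..b (inclusive) forming one
    segment; the first tone of the sequence is uninformative."""
    g = midpoint_grid(grid_n)
    L = np.ones((grid_n, grid_n))
    for t in range(max(a, 1), b + 1):
        prev, new = tones[t - 1], tones[t]
        if prev == 0:
            col = g if new == 0 else 1.0 - g
            L = L * col[:, None]
        else:
            col = g if new == 1 else 1.0 - g
            L = L * col[None, :]
    return L

def enumerate_posterior(tones, p_change, grid_n):
    """Exact joint posterior over theta at the final trial.

    Sums over all 2^(n-1) change-point configurations: each configuration
    splits the sequence into segments with independent flat-prior thetas;
    earlier segments contribute their marginal evidence (grid average of the
    segment likelihood), the last segment the unnormalized posterior of the
    current theta.
    """
    tones = np.asarray(tones, dtype=int)
    n = len(tones)
    ncells = grid_n**2
    post = np.zeros((grid_n, grid_n))
    for cps in product([0, 1], repeat=n - 1):
        w = 1.0
        for c in cps:
            w *= p_change if c else 1.0 - p_change
        if w == 0.0:
            continue
        bounds = [0] + [t for t in range(1, n) if cps[t - 1]] + [n]
        for k in range(len(bounds) - 2):
            w *= _segment_likelihood(tones, bounds[k], bounds[k + 1] - 1, grid_n).mean()
        last = _segment_likelihood(tones, bounds[-2], bounds[-1] - 1, grid_n)
        post += w * last / ncells
    return post / post.sum()


def conjugate_marginal_moments(n_same: int, n_other: int, grid_n: int):
    """Mean and variance of a Beta(n_same+1, n_other+1) posterior restricted
    to the midpoint grid (flat prior, counting likelihood)."""
    g = midpoint_grid(grid_n)
    w = g**n_same * (1.0 - g) ** n_other
    w = w / w.sum()
    mean = float(w @ g)
    var = float(w @ (g - mean) ** 2)
    return mean, var
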