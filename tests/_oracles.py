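"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (exhaustive enumeration, direct
formula evaluation) kept separate from the package implementation so that
agreement between the two routes is informative.
"""

import math

import numpy as np


def two_means_brute_force(values):
    """Exhaustive optimal 1-D 2-means split.

    Tries every threshold split of the sorted values (between distinct
    neighbours, so tied values stay together), computing within-cluster sum
    of squares directly.  Returns ``(best_ss, down_sets)`` where down_sets
    is the list of low-cluster value tuples achieving the minimum.
    """
    xs = np.sort(np.asarray(values, dtype=float))
    best_ss, downs = math.inf, []
    for i in range(1, xs.size):
        if xs[i - 1] == xs[i]:
            continue
        lo, hi = xs[:i], xs[i:]
        ss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if ss < best_ss - 1e-12:
            best_ss, downs = ss, [tuple(lo)]
        elif abs(ss - best_ss) <= 1e-12:
            downs.append(tuple(lo))
    return best_ss, downs


def exponential_lrt(times_up, events_up, times_down, events_down):
    """Direct evaluation of the two-rate vs pooled exponential LRT."""

    def loglik(times, events):
        d, T = sum(events), sum(times)
        if d == 0:
            return 0.0
        lam = d / T
        return d * math.log(lam) - lam * T

    ll_split = loglik(times_up, events_up) + loglik(times_down, events_down)
    ll_pool = loglik(list(times_up) + list(times_down), list(events_up) + list(events_down))
    return 2.0 * (ll_split - ll_pool)
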