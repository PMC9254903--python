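"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the signed-rank
oracle enumerates all 2^n sign assignments; the G-score null oracle
enumerates the factorized pooled permutation null exactly.
"""

import itertools

import numpy as np
from scipy import stats


def enumeration_signed_rank_p(d):
    """Exhaustive two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array([ranks[np.array(signs, bool)].sum()
                   for signs in itertools.product([0, 1], repeat=n)])
    cdf = (ws <= w_obs + 1e-9).mean()
    sf = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(cdf, sf))


def exact_pooled_gscore_null(x, theta=0.1):
    """Exact pooled permutation null of the per-gene G-score.

    Independently permuting each sample's gene-value column makes a gene's
    null G-score a sum of one uniform draw per sample from that sample's
    above-threshold contributions, so the pooled null enumerates the
    g^n_samples combinations exactly.
    """
    contrib = np.maximum(0.0, np.asarray(x, float) - theta)
    n_samples = contrib.shape[1]
    return np.array([
        sum(combo) / n_samples
        for combo in itertools.product(*[contrib[:, s]
                                         for s in range(n_samples)])
    ])
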