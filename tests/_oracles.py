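"""Independent brute-force oracles used by the statistical tests."""

import itertools

import numpy as np
from scipy.stats import hypergeom, rankdata


def ranksum_enumeration_p(x, y):
    """Full-enumeration two-sided rank-sum p-value (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = np.array(
        [
            ranks[list(idx)].sum() - n * (n + 1) / 2
            for idx in itertools.combinations(range(len(pooled)), n)
        ]
    )
    return min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))


def fisher_enumeration_p(table):
    """Hypergeometric-enumeration two-sided Fisher p-value."""
    (a, b), (c, d) = table
    r1, c1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (total - r1)), min(r1, c1)
    pmf = {x: hypergeom.pmf(x, total, r1, c1) for x in range(lo, hi + 1)}
    p0 = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p0 * (1 + 1e-10)))
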