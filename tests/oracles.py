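"""Independent reference computations used by the test suite only."""

from itertools import combinations

import numpy as np
from scipy import stats
from scipy.special import logsumexp


def exact_mixture_enumeration(y, K, a, B):
    """Exact outlier-mixture marginal by summing over all 2^N outlier sets.

    Returns (log total, log |S|<=1 partial sum, log neglected |S|>=2 sum,
    log_v1, log_v2) where each subset S contributes
    a^{N-|S|} b^{|S|} B^{|S|} N(y_{-S}; 0, K_{-S}).
    """
    N = len(y)
    b = 1.0 - a
    terms, orders = [], []
    log_v1 = None
    v2_terms = []
    for k in range(N + 1):
        for S in combinations(range(N), k):
            keep = [i for i in range(N) if i not in S]
            if keep:
                dens = stats.multivariate_normal.logpdf(
                    y[keep], mean=np.zeros(len(keep)),
                    cov=K[np.ix_(keep, keep)],
                )
            else:
                dens = 0.0
            if k == 0:
                log_v1 = dens
            elif k == 1:
                v2_terms.append(np.log(B) + dens)
            term = (N - k) * np.log(a) + k * (np.log(b) + np.log(B)) + dens \
                if b > 0 else (-np.inf if k else N * np.log(a) + dens)
            terms.append(term)
            orders.append(k)
    terms = np.asarray(terms)
    orders = np.asarray(orders)
    log_total = logsumexp(terms)
    log_first = logsumexp(terms[orders <= 1])
    neglected = terms[orders >= 2]
    log_neglected = logsumexp(neglected) if neglected.size else -np.inf
    return log_total, log_first, log_neglected, log_v1, logsumexp(v2_terms)
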