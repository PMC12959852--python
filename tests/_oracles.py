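"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's own code paths: the Wilcoxon nulls are
enumerated pattern by pattern, and spike detection is a sample-by-sample scan.
"""

from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata


def brute_signed_rank_p(a, b):
    """Two-tailed p by enumerating all 2^n sign assignments of the mid-ranks."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [float(ranks[np.array(s, bool)].sum()) for s in product([0, 1], repeat=n)]
    le = np.mean([w <= w_obs + 1e-9 for w in ws])
    ge = np.mean([w >= w_obs - 1e-9 for w in ws])
    return min(1.0, 2 * min(le, ge))


def brute_rank_sum_p(a, b):
    """Two-tailed p by enumerating all C(n1+n2, n1) group labelings."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1 = len(a)
    ranks = rankdata(np.concatenate([a, b]))
    w_obs = ranks[:n1].sum()
    ws = [ranks[list(c)].sum() for c in combinations(range(len(ranks)), n1)]
    le = np.mean([w <= w_obs + 1e-9 for w in ws])
    ge = np.mean([w >= w_obs - 1e-9 for w in ws])
    return min(1.0, 2 * min(le, ge))


def brute_force_detect(x, params, noise_sd):
    """Sample-by-sample reference scan: negative crossing, lockout, re-centre
    on the minimum within the search span, drop edge events."""
    thr = -params.threshold_multiplier * noise_sd
    lock = int(round(params.lockout * params.fs))
    span = int(round(params.search_span * params.fs))
    pre = params.waveform_len // 2
    post = params.waveform_len - pre - 1
    peaks = []
    last = None
    for i in range(1, len(x)):
        if x[i] < thr and x[i - 1] >= thr:
            if last is not None and i - last <= lock:
                continue
            last = i
            lo, hi = max(0, i - span), min(len(x), i + span + 1)
            peak = lo + int(np.argmin(x[lo:hi]))
            if peak - pre < 0 or peak + post >= len(x):
                continue
            if peaks and peak <= peaks[-1]:
                continue
            peaks.append(peak)
    return peaks
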