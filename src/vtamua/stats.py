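"""Nonparametric tests used throughout: Wilcoxon signed-rank (paired) and
Wilcoxon rank-sum / Mann-Whitney (independent), two-tailed at alpha = 0.05.

Exact null distributions are computed in-package so that tied data are
handled correctly in exact mode (mid-ranks throughout): the signed-rank null
by dynamic-programming convolution over sign assignments (default for
effective n <= 25), the rank-sum null by enumeration over group labelings
(default for n1 + n2 <= 16). Larger samples use the normal approximation
with tie (and zero) variance corrections and no continuity correction. The
two-tailed p is 2 * min(P(W <= w), P(W >= w)), capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import DataError

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "holm_correction",
    "epoch_contrast_table",
    "phase_comparison_table",
]

ALPHA = 0.05

SIGNED_RANK_EXACT_N = 25
RANK_SUM_EXACT_N = 16
_EPS = 1e-9


@dataclass(frozen=True)
class TestResult:
    method: str  # "signed_rank" | "rank_sum"
    statistic: float
    p_value: float
    n1: int
    n2: Optional[int]
    mode: str  # "exact" | "normal_approx" | "undefined"
    significant: bool
    undefined: bool = False

    @property
    def n(self) -> int:
        return self.n1


def _two_sided(cdf_le: float, cdf_ge: float) -> float:
    return min(1.0, 2.0 * min(cdf_le, cdf_ge))


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-tailed p of W+ over the 2^n equiprobable sign assignments,
    by convolution on twice the mid-ranks (integers)."""
    r2 = np.rint(2 * ranks).astype(int)
    if not np.allclose(2 * ranks, r2):
        raise ValueError("mid-ranks are not half-integers")
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = 2 * w_plus
    support = np.arange(total + 1)
    cdf_le = dist[support <= w2 + _EPS].sum()
    cdf_ge = dist[support >= w2 - _EPS].sum()
    return _two_sided(cdf_le, cdf_ge)


def wilcoxon_signed_rank(paired_a, paired_b, alpha: float = ALPHA,
                         exact_threshold: int = SIGNED_RANK_EXACT_N) -> TestResult:
    """Paired Wilcoxon signed-rank test, two-tailed.

    Zero differences are dropped (Wilcoxon's original treatment); tied
    absolute differences receive mid-ranks. All-zero differences make the
    test undefined: reported non-significant with ``undefined=True``.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise DataError("paired samples must be equal-length 1-D arrays")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult("signed_rank", np.nan, np.nan, 0, None,
                          "undefined", False, undefined=True)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        p = _signed_rank_exact_p(ranks, w_plus)
        mode = "exact"
    else:
        mu = n * (n + 1) / 4
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(counts**3 - counts) / 48
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
        mode = "normal_approx"
    return TestResult("signed_rank", w_plus, p, n, None, mode, p < alpha)


def _rank_sum_exact_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Exact two-tailed p of the group-1 rank sum over all C(n, n1) labelings."""
    n = len(ranks)
    idx = np.fromiter((i for c in combinations(range(n), n1) for i in c),
                      dtype=np.intp).reshape(-1, n1)
    sums = ranks[idx].sum(axis=1)
    cdf_le = np.mean(sums <= w_obs + _EPS)
    cdf_ge = np.mean(sums >= w_obs - _EPS)
    return _two_sided(float(cdf_le), float(cdf_ge))


def wilcoxon_rank_sum(sample_a, sample_b, alpha: float = ALPHA,
                      exact_threshold: int = RANK_SUM_EXACT_N) -> TestResult:
    """Independent-samples Wilcoxon rank-sum test, two-tailed.

    The statistic is the rank sum of ``sample_a`` in the combined mid-ranked
    data; exact enumeration when n1 + n2 <= ``exact_threshold``, otherwise
    the tie-corrected normal approximation.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([a, b]))
    w = float(ranks[:n1].sum())
    if n <= exact_threshold:
        p = _rank_sum_exact_p(ranks, n1, w)
        mode = "exact"
    else:
        mu = n1 * (n + 1) / 2
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var = n1 * n2 / 12 * ((n + 1) - tie_term)
        z = (w - mu) / np.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
        mode = "normal_approx"
    return TestResult("rank_sum", w, p, n1, n2, mode, p < alpha)


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs pass through unadjusted)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="holm")[1]
    return out


_CONTRASTS = {
    "pre_vs_cue": ("p_pre", "p_cue"),
    "pre_vs_rew": ("p_pre", "p_rew"),
    "cue_vs_rew": ("p_cue", "p_rew"),
}


def epoch_contrast_table(props, alpha: float = ALPHA):
    """Within-session paired epoch contrasts on trial-level proportions.

    For each (pigeon, session): pre-vs-cue always; pre-vs-reward and
    cue-vs-reward on 3-way (rewarded) trials. Pairs epochs within trials.
    Returns a tidy frame with Holm-adjusted p-values per family
    (pigeon x session), and '*' / 'n.s.' markers at ``alpha``.
    """
    import pandas as pd

    rows = []
    for (pid, s), df in props.groupby(["pigeon_id", "session"], sort=True):
        df = df[df["defined"]]
        family = []
        for name, (ca, cb) in _CONTRASTS.items():
            sub = df[[ca, cb]].dropna()
            if len(sub) == 0:
                continue
            res = wilcoxon_signed_rank(sub[ca], sub[cb], alpha=alpha)
            family.append({"pigeon_id": pid, "session": s, "contrast": name,
                           "method": res.method, "mode": res.mode, "n": res.n1,
                           "statistic": res.statistic, "p": res.p_value,
                           "significant": res.significant,
                           "undefined": res.undefined})
        if family:
            fam = pd.DataFrame(family)
            fam["p_holm"] = holm_correction(fam["p"])
            rows.append(fam)
    if not rows:
        return pd.DataFrame(columns=["pigeon_id", "session", "contrast", "method",
                                     "mode", "n", "statistic", "p", "significant",
                                     "undefined", "p_holm", "marker"])
    out = pd.concat(rows, ignore_index=True)
    out["marker"] = np.where(out["significant"], "*", "n.s.")
    return out


def phase_comparison_table(props, phases, alpha: float = ALPHA):
    """Learning vs consolidation rank-sum comparisons of trial proportions.

    ``phases`` maps (pigeon_id, session) -> phase label. Trials from learning
    sessions and consolidation sessions are treated as independent samples,
    per epoch proportion.
    """
    import pandas as pd

    rows = []
    for pid, df in props.groupby("pigeon_id", sort=True):
        df = df[df["defined"]].copy()
        df["phase"] = [phases[(pid, s)] for s in df["session"]]
        for col in ("p_pre", "p_cue", "p_rew"):
            a = df.loc[df["phase"] == "learning", col].dropna()
            b = df.loc[df["phase"] == "consolidation", col].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            res = wilcoxon_rank_sum(a, b, alpha=alpha)
            rows.append({"pigeon_id": pid, "measure": col, "method": res.method,
                         "mode": res.mode, "n_learning": res.n1,
                         "n_consolidation": res.n2, "statistic": res.statistic,
                         "p": res.p_value, "significant": res.significant})
    out = pd.DataFrame(rows, columns=["pigeon_id", "measure", "method", "mode",
                                      "n_learning", "n_consolidation",
                                      "statistic", "p", "significant"])
    if len(out):
        out["marker"] = np.where(out["significant"], "*", "n.s.")
    return out
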