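"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive (bitmaps, exhaustive enumeration, grid
search) and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pandas as pd


def bitmap_merge(manifest: pd.DataFrame, half_width: int):
    """Enhancer-region construction by per-base coverage bitmap.

    Marks every covered base of [pos-hw, pos+hw) per chromosome in a boolean
    array and reads off maximal runs of covered bases; each probe belongs to
    the run containing its window. Touching-but-disjoint windows remain
    separate runs because their shared boundary base is covered by neither.
    Returns a set of (chrom, start, end, frozenset(probe_ids)).
    """
    out = set()
    enh = manifest.loc[manifest["is_enhancer"]]
    for chrom, sub in enh.groupby("chrom"):
        positions = sub["pos"].to_numpy()
        pids = sub["probe_id"].to_numpy()
        hi = int(positions.max()) + half_width
        # half-base resolution: interval [s, e) covers doubled bases
        # [2s, 2e-1), so bookended intervals leave a gap while any true
        # overlap stays contiguous
        cover = np.zeros(2 * hi + 2, dtype=bool)
        for pos in positions:
            s = max(pos - half_width, 0)
            e = pos + half_width
            cover[2 * s: 2 * e - 1] = True
        trans = np.diff(np.concatenate([[0], cover.astype(np.int8), [0]]))
        run_starts = np.flatnonzero(trans == 1)
        run_ends = np.flatnonzero(trans == -1)
        for s2, e2 in zip(run_starts, run_ends):
            s, e = int(s2 // 2), int((e2 + 1) // 2)
            inside = (positions >= s) & (positions < e)
            out.add((chrom, s, e, frozenset(pids[inside])))
    return out


def hypergeom_tail_enum(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact combinatorial sums."""
    total = comb(N, n)
    hits = 0
    for j in range(k, min(K, n) + 1):
        hits += comb(K, j) * comb(N - K, n - j)
    return hits / total


def hypergeom_tail_draws(N: int, K: int, n: int, k: int) -> float:
    """Same tail by brute enumeration of every size-n draw (small N only)."""
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


def hypergeom_tail_table(N: int, K: int, n: int) -> np.ndarray:
    """tails[k] = P(X >= k) by enumerating every size-n draw once."""
    successes = set(range(K))
    counts = np.zeros(min(K, n) + 2)
    total = 0
    for draw in itertools.combinations(range(N), n):
        counts[len(successes.intersection(draw))] += 1
        total += 1
    probs = counts / total
    return probs[::-1].cumsum()[::-1]


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up rule."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return adj


def pooled_two_sample_t(x, y) -> float:
    """Ordinary pooled-variance two-sample t statistic."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def brute_force_bicliques(edges: set[tuple], min_left: int, min_right: int):
    """All maximal bicliques by enumerating every left-subset x right-subset."""
    lefts = sorted({l for l, _ in edges})
    rights = sorted({r for _, r in edges})
    complete = []
    for lsub in _subsets(lefts):
        for rsub in _subsets(rights):
            if lsub and rsub and all((l, r) in edges for l in lsub for r in rsub):
                complete.append((frozenset(lsub), frozenset(rsub)))
    complete_set = set(complete)
    maximal = set()
    for A, B in complete_set:
        extendable = False
        for l in set(lefts) - A:
            if (A | {l}, B) in complete_set:
                extendable = True
                break
        if not extendable:
            for r in set(rights) - B:
                if (A, B | {r}) in complete_set:
                    extendable = True
                    break
        if not extendable and len(A) >= min_left and len(B) >= min_right:
            maximal.add((A, B))
    return maximal


def _subsets(items):
    for r in range(len(items) + 1):
        yield from itertools.combinations(items, r)


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Breslow partial log-likelihood for a single covariate."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events]):
        dead = events & (times == t)
        at_risk = times >= t
        ll += beta * x[dead].sum()
        ll -= dead.sum() * np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def cox_grid_mle(times, events, x, lo=-5.0, hi=5.0, tol=1e-6) -> float:
    """Golden-section maximization of the single-covariate partial likelihood."""
    gr = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc = cox_partial_loglik(c, times, events, x)
    fd = cox_partial_loglik(d, times, events, x)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = cox_partial_loglik(c, times, events, x)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = cox_partial_loglik(d, times, events, x)
    return (a + b) / 2


def cox_score(beta, times, events, X) -> np.ndarray:
    """Gradient of the multivariate Breslow partial log-likelihood."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    score = np.zeros(X.shape[1])
    eta = X @ beta
    for t in np.unique(times[events]):
        dead = events & (times == t)
        at_risk = times >= t
        w = np.exp(eta[at_risk])
        xbar = (w[:, None] * X[at_risk]).sum(axis=0) / w.sum()
        score += X[dead].sum(axis=0) - dead.sum() * xbar
    return score


def logrank_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from O-E and hypergeometric variance."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    all_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    O = E = V = 0.0
    for t in all_times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        n = na + nb
        da = (ea & (ta == t)).sum()
        db = (eb & (tb == t)).sum()
        d = da + db
        if n <= 1:
            continue
        O += da
        E += d * na / n
        V += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return chi2, O, E, V


def auc_rank(scores, labels) -> float:
    """AUC via the rank-based Mann-Whitney U statistic."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, float)
    pos = np.asarray(labels, bool)
    ranks = rankdata(scores)
    n1 = pos.sum()
    n2 = (~pos).sum()
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n2)
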