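"""Independent brute-force oracles used by the test suite.

Everything here evaluates defining formulas directly (loops, exhaustive
enumeration, exact integer arithmetic) and never calls the implementation
under test.
"""

from itertools import combinations
from math import comb

import numpy as np


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact hypergeometric tail in the direction of the observed association.

    Enumerates every table with the observed margins using exact integer
    binomials; the float division at the end is the only rounding step.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    denom = comb(n, c1)
    if a * d >= b * c:
        num = sum(comb(r1, x) * comb(n - r1, c1 - x) for x in range(a, hi + 1))
    else:
        num = sum(comb(r1, x) * comb(n - r1, c1 - x) for x in range(lo, a + 1))
    return num / denom


def bh_step_up(pvalues) -> np.ndarray:
    """q_(i) = min_{j >= i} m p_(j) / j, capped at 1, by direct evaluation."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def pam_exhaustive(d: np.ndarray, k: int) -> tuple[float, tuple[int, ...]]:
    """Globally optimal medoid set by exhaustive search (tiny n only)."""
    n = d.shape[0]
    best = (np.inf, None)
    for medoids in combinations(range(n), k):
        obj = d[:, medoids].min(axis=1).sum()
        if obj < best[0] - 1e-15:
            best = (obj, medoids)
    return best


def validation_indices(d: np.ndarray, labels: np.ndarray) -> dict:
    """The four cluster validation indices from their defining formulas."""
    n = d.shape[0]
    labels = np.asarray(labels)
    clusters = sorted(set(labels.tolist()))
    k = len(clusters)

    # average silhouette width; singletons contribute s(i) = 0
    s_vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            s_vals.append(0.0)
            continue
        a_i = np.mean([d[i, j] for j in own])
        b_i = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in clusters
            if c != labels[i]
        )
        s_vals.append((b_i - a_i) / max(a_i, b_i) if max(a_i, b_i) > 0 else 0.0)
    asw = float(np.mean(s_vals))

    dist_vec, ind_vec = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dist_vec.append(d[i, j])
            ind_vec.append(1.0 if labels[i] != labels[j] else 0.0)
    dist_vec, ind_vec = np.array(dist_vec), np.array(ind_vec)
    if np.std(dist_vec) > 0 and np.std(ind_vec) > 0:
        pg = float(np.corrcoef(dist_vec, ind_vec)[0, 1])
    else:
        pg = np.nan

    within_means = []
    for c in clusters:
        members = np.flatnonzero(labels == c)
        if len(members) > 1:
            pairs = [(i, j) for i in members for j in members if i < j]
            within_means.append(np.mean([d[i, j] for i, j in pairs]))
    between_means = []
    for ci, cj in combinations(clusters, 2):
        mi, mj = np.flatnonzero(labels == ci), np.flatnonzero(labels == cj)
        between_means.append(np.mean([d[i, j] for i in mi for j in mj]))
    dunn2 = min(between_means) / max(within_means) if within_means else np.nan

    w = 0.0
    for c in clusters:
        members = np.flatnonzero(labels == c)
        w += sum(d[i, j] ** 2 for i, j in combinations(members, 2)) / len(members)
    t = sum(d[i, j] ** 2 for i, j in combinations(range(n), 2)) / n
    b = t - w
    ch = (b / (k - 1)) / (w / (n - k)) if w > 0 and n > k else np.nan
    return {"asw": asw, "pearson_gamma": pg, "dunn2": dunn2, "ch": ch}


def chi2_statistic(table: np.ndarray) -> float:
    """Pearson chi-square sum (O-E)^2/E without continuity correction."""
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


def wp_wn(ors, ps) -> tuple[float, float]:
    """Volcano half-plane sums by direct loop evaluation."""
    wp = wn = 0.0
    for o, p in zip(ors, ps):
        w = abs(np.log(o)) * (-np.log10(p))
        if o > 1:
            wp += w
        elif o < 1:
            wn += w
    return wp, wn


def all_bipartitions(n: int):
    """Every split of range(n) into two non-empty labeled groups (up to swap)."""
    for r in range(1, n // 2 + 1):
        for group in combinations(range(1, n), r):
            labels = np.zeros(n, dtype=int)
            labels[list(group)] = 1
            yield labels
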