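"""Community state types: PAM clustering on JSD and longitudinal stability.

Vaginal microbiome profiles fall into a small number of community state
types (CSTs), most of them dominated by a single Lactobacillus ASV plus a
more diverse, Gardnerella-rich type.  Samples are clustered by partitioning
around medoids (PAM) directly on the Jensen-Shannon divergence matrix; the
number of clusters is chosen from four internal validation indices; each
cluster is named by its dominant ASV; and stability between the two
pregnancy sampling weeks is quantified with per-CST chi-square tests and a
paired-distance permutation test.

The PAM here is deliberately deterministic (greedy BUILD seeding, steepest
descent SWAP, ties broken by the lowest sample index) so that the same
distance matrix always yields the same CSTs without a random seed.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from sklearn.metrics import silhouette_score

from .errors import ValidationError
from .diversity import CompositionTable
from .transfer_tests import bh_fdr


@dataclass
class Clustering:
    k: int
    sample_ids: list[str]
    labels: np.ndarray  # cluster index per sample, 0..k-1
    medoid_ids: list[str]
    objective: float  # sum of distances to own medoid

    def members(self, cluster: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == cluster]


@dataclass
class ValidationIndices:
    """Internal cluster validation indices (NaN where undefined)."""

    asw: float  # average silhouette width, in [-1, 1]
    pearson_gamma: float  # corr(distance, different-cluster indicator)
    dunn2: float  # min between-cluster mean / max within-cluster mean
    ch: float  # Calinski-Harabasz from the distance-based SS identity


@dataclass
class CSTAssignment:
    """Cluster labels named by each cluster's dominant ASV."""

    sample_ids: list[str]
    labels: list[str]  # per-sample CST label (= dominant asv_id)
    dominant: dict[int, str]  # cluster index -> dominant asv_id
    dominant_mean_abundance: dict[int, float]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cst")


def _build(d: np.ndarray, k: int) -> list[int]:
    """Greedy PAM BUILD: repeatedly add the medoid that most lowers cost."""
    n = d.shape[0]
    first = int(np.argmin(d.sum(axis=1)))  # argmin takes the lowest index on ties
    medoids = [first]
    nearest = d[:, first].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of max(nearest - d[:, c], 0)
        gain = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, d[:, c])
    return medoids


def _swap(d: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest-descent SWAP to a local optimum; deterministic tie-breaks."""
    n = d.shape[0]
    medoids = sorted(medoids)
    while True:
        dm = d[:, medoids]  # n x k
        order = np.argsort(dm, axis=1, kind="stable")
        d1 = dm[np.arange(n), order[:, 0]]
        idx1 = order[:, 0]
        d2 = dm[np.arange(n), order[:, 1]] if len(medoids) > 1 else np.full(n, np.inf)
        objective = float(d1.sum())
        cand = np.array([i for i in range(n) if i not in set(medoids)])
        if len(cand) == 0:
            return medoids, objective
        best = (0.0, None, None)  # (improvement, medoid position, candidate)
        for j in range(len(medoids)):
            excl = np.where(idx1 == j, d2, d1)  # nearest medoid excluding j
            newobj = np.minimum(excl[:, None], d[:, cand]).sum(axis=0)
            pos = int(np.argmin(newobj))  # lowest candidate index on ties
            improvement = objective - float(newobj[pos])
            if improvement > best[0] + 1e-12:
                best = (improvement, j, int(cand[pos]))
        if best[1] is None:
            return medoids, objective
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)


def pam(dist: DistanceMatrix, k: int) -> Clustering:
    """Partitioning around medoids on a precomputed dissimilarity matrix."""
    n = len(dist.ids)
    if not 2 <= k < n:
        raise ValidationError(f"k must satisfy 2 <= k < n (= {n}); got {k}")
    d = dist.data
    medoids, objective = _swap(d, _build(d, k))
    labels = np.argmin(d[:, medoids], axis=1)
    labels[medoids] = np.arange(k)  # a medoid belongs to its own cluster
    ids = list(dist.ids)
    return Clustering(k, ids, labels, [ids[m] for m in medoids], objective)


def cluster_validation(dist: DistanceMatrix, clustering: Clustering | np.ndarray) -> ValidationIndices:
    """The four internal validation indices used to pick the number of CSTs.

    asw: mean silhouette width.  pearson_gamma: Pearson correlation between
    the pairwise-distance vector and the same(0)/different(1)-cluster
    indicator.  dunn2: minimum mean between-cluster distance over maximum
    mean within-cluster distance.  ch: Calinski-Harabasz, with the within
    and total sums of squares obtained from pairwise distances via
    W_c = (1/n_c) sum_{i<j in c} d_ij^2 (exact for Euclidean distances and
    well-defined for any dissimilarity).
    """
    labels = clustering.labels if isinstance(clustering, Clustering) else np.asarray(clustering)
    d = dist.data
    n = d.shape[0]
    clusters = np.unique(labels)
    k = len(clusters)
    if k < 2:
        raise ValidationError("need at least two non-empty clusters")
    iu = np.triu_indices(n, 1)
    dv = d[iu]
    diff = (labels[iu[0]] != labels[iu[1]]).astype(float)

    sizes = {c: int(np.sum(labels == c)) for c in clusters}
    try:
        asw = float(silhouette_score(d, labels, metric="precomputed")) if max(sizes.values()) > 1 else np.nan
    except ValueError:
        asw = np.nan
    if diff.std() == 0 or dv.std() == 0:
        pg = np.nan
    else:
        pg = float(stats.pearsonr(dv, diff)[0])

    within_means = []
    w_c = []
    for c in clusters:
        mask = labels == c
        sub = d[np.ix_(mask, mask)]
        m = int(mask.sum())
        if m > 1:
            within_means.append(sub.sum() / (m * (m - 1)))
        w_c.append((sub[np.triu_indices(m, 1)] ** 2).sum() / m)
    between_means = []
    for i, ci in enumerate(clusters):
        for cj in clusters[i + 1 :]:
            between_means.append(d[np.ix_(labels == ci, labels == cj)].mean())
    if not within_means:
        dunn2 = np.nan
    elif max(within_means) == 0:
        dunn2 = np.inf
    else:
        dunn2 = float(min(between_means) / max(within_means))

    t = float((dv**2).sum()) / n
    w = float(sum(w_c))
    b = t - w
    ch = float((b / (k - 1)) / (w / (n - k))) if w > 0 and n > k else np.nan
    return ValidationIndices(asw=asw, pearson_gamma=pg, dunn2=dunn2, ch=ch)


def select_k(dist: DistanceMatrix, k_range=range(2, 11)) -> tuple[int, pd.DataFrame]:
    """Cluster for each k and tabulate all four indices.

    The chosen k maximizes the average silhouette width (smaller k wins
    ties); the full index table is returned so the choice can be overridden
    by inspection.
    """
    rows = []
    for k in k_range:
        cl = pam(dist, k)
        v = cluster_validation(dist, cl)
        rows.append({"k": k, "asw": v.asw, "pearson_gamma": v.pearson_gamma,
                     "dunn2": v.dunn2, "ch": v.ch, "objective": cl.objective})
    table = pd.DataFrame(rows)
    best = table.loc[table["asw"].idxmax(), "k"]  # idxmax returns first (smallest k) on ties
    return int(best), table


def assign_cst(clustering: Clustering, comp: CompositionTable) -> CSTAssignment:
    """Name each cluster by its dominant ASV (highest mean relative abundance).

    Exact ties are broken lexicographically on the ASV id, with a warning;
    mapping the resulting ids onto conventional roman-numeral CST names is
    left to the caller.
    """
    cdf = comp.to_dataframe()
    missing = [s for s in clustering.sample_ids if s not in cdf.index]
    if missing:
        raise ValidationError(f"composition table missing clustered samples: {missing[:5]}")
    dominant: dict[int, str] = {}
    dom_mean: dict[int, float] = {}
    for c in range(clustering.k):
        means = cdf.loc[clustering.members(c)].mean(axis=0)
        top = means.max()
        winners = sorted(means.index[means == top])
        if len(winners) > 1:
            _warnings.warn(
                f"cluster {c}: dominant-ASV tie between {winners}; using {winners[0]}"
            )
        dominant[c] = winners[0]
        dom_mean[c] = float(top)
    labels = [dominant[int(l)] for l in clustering.labels]
    return CSTAssignment(list(clustering.sample_ids), labels, dominant, dom_mean)


def cst_stability(
    cst_w24: pd.Series, cst_w36: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per-CST stability between gestational weeks 24 and 36.

    Both inputs are CST labels indexed by subject; only subjects present in
    both are used.  A subject is stable when her CST is unchanged.  For each
    week-24 CST a 2x2 table (this CST vs all others x stable vs not) is
    tested with the chi-square test without continuity correction, and the
    p-values are Benjamini-Hochberg adjusted across CSTs.  Returns the
    per-CST table and the overall stable fraction.
    """
    subjects = cst_w24.index.intersection(cst_w36.index)
    if len(subjects) == 0:
        raise ValidationError("no subjects with both assignments")
    w24 = cst_w24.loc[subjects]
    stable = (w24 == cst_w36.loc[subjects]).astype(int)
    overall = float(stable.mean())
    rows = []
    for cst in sorted(w24.unique()):
        in_cst = w24 == cst
        a = int((stable[in_cst] == 1).sum())
        b = int((stable[in_cst] == 0).sum())
        c = int((stable[~in_cst] == 1).sum())
        d = int((stable[~in_cst] == 0).sum())
        table = np.array([[a, b], [c, d]])
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2, p = 0.0, 1.0  # degenerate margin: no evidence of difference
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"cst": cst, "n": a + b, "n_stable": a, "stable_fraction": a / (a + b),
                     "chi2": float(chi2), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out, overall


def paired_distance_test(
    dist: DistanceMatrix,
    pairs: list[tuple[str, str]],
    n_perm: int = 2500,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Permutation test that paired samples are closer than unpaired ones.

    The statistic is the median distance between each subject's week-24 and
    week-36 samples.  The null scrambles the week-36 side among subjects
    (2500 permutations by default) and the one-sided p counts null medians
    at least as small as the observed one: small distances mean stability.

    Returns (median paired distance, median unpaired distance, p).
    """
    if len(pairs) < 2:
        raise ValidationError("need at least two pairs")
    idx = {s: i for i, s in enumerate(dist.ids)}
    a = np.array([idx[m] for m, _ in pairs])
    b = np.array([idx[c] for _, c in pairs])
    d = dist.data
    observed = float(np.median(d[a, b]))
    cross = d[np.ix_(a, b)]
    off_diag = ~np.eye(len(pairs), dtype=bool)
    unpaired_median = float(np.median(cross[off_diag]))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pairs))
        if np.median(d[a, b[perm]]) <= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, unpaired_median, p
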