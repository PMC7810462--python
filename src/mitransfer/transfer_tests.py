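"""Per-ASV transfer odds between mother-child dyads.

For every ASV in a stratum (child compartment x timepoint x delivery mode)
the dyads are cross-tabulated by maternal (vaginal week 36) and child
presence/absence into a 2x2 table; Fisher's exact test gives a one-sided p
in the direction of the observed association, and the cross-product odds
ratio (Haldane-corrected when a cell is zero) quantifies transfer.  Only
"testable" ASVs - those varying in both mothers and children, i.e. with no
zero margin - enter the analysis.  q-values are Benjamini-Hochberg within
the stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings as _warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_core import AbundanceTable, DyadSet, TaxonomyTable


@dataclass
class PresenceTable:
    """Boolean presence/absence matrix, same shape as its source counts."""

    sample_ids: list[str]
    asv_ids: list[str]
    present: np.ndarray

    def select_samples(self, ids) -> "PresenceTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [pos[str(s)] for s in ids]
        return PresenceTable(list(ids), list(self.asv_ids), self.present[rows])


@dataclass
class TransferResult:
    """One ASV's dyad 2x2 counts and Fisher transfer statistics.

    a = mother+child+, b = mother+child-, c = mother-child+, d = mother-child-.
    """

    asv_id: str
    a: int
    b: int
    c: int
    d: int
    or_point: float
    p_one_sided: float
    q: float = np.nan


def presence_matrix(table: AbundanceTable, threshold: int = 1) -> PresenceTable:
    """Presence = count >= threshold, computed on the unrarefied table."""
    if threshold < 1:
        raise ValidationError("presence threshold must be >= 1")
    return PresenceTable(
        list(table.sample_ids), list(table.asv_ids), table.counts >= threshold
    )


def _dyad_presence(
    mothers: PresenceTable, children: PresenceTable, dyads: DyadSet
) -> tuple[np.ndarray, np.ndarray]:
    """Presence matrices (n_dyads x n_asvs) aligned on the dyad pairing."""
    if mothers.asv_ids != children.asv_ids:
        raise ValidationError("mother and child tables must share the ASV axis")
    m = mothers.select_samples(dyads.mother_samples).present
    c = children.select_samples(dyads.child_samples).present
    return m, c


def _testable_mask(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """ASVs present and absent in >=1 mother AND >=1 child (no zero margin)."""
    n = m.shape[0]
    ms, cs = m.sum(axis=0), c.sum(axis=0)
    return (ms > 0) & (ms < n) & (cs > 0) & (cs < n)


def testable_asvs(
    mothers: PresenceTable, children: PresenceTable, dyads: DyadSet
) -> list[str]:
    """ASVs whose stratum 2x2 table has no zero margin."""
    m, c = _dyad_presence(mothers, children, dyads)
    mask = _testable_mask(m, c)
    return [a for a, t in zip(mothers.asv_ids, mask) if t]


def _fisher_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized odds ratios and one-sided exact p for many 2x2 tables.

    p is the exact hypergeometric tail in the direction of the observed
    association (upper tail P(X >= a) when ad >= bc, else lower tail),
    conditioning on both margins.  The odds ratio is ad/bc, with 0.5 added
    to every cell when any cell is zero (Haldane-Anscombe); the correction
    never touches p.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    if min(a.min(initial=0), b.min(initial=0), c.min(initial=0), d.min(initial=0)) < 0:
        raise ValidationError("2x2 cell counts must be non-negative")
    n = a + b + c + d
    zero = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plain = (a * d) / (b * c)
    corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    or_point = np.where(zero, corrected, plain)
    upper = a * d >= b * c
    p_up = stats.hypergeom.sf(a - 1, n, a + b, a + c)
    p_lo = stats.hypergeom.cdf(a, n, a + b, a + c)
    p = np.where(upper, p_up, p_lo)
    return or_point, np.clip(p, 0.0, 1.0)


def fisher_transfer(a: int, b: int, c: int, d: int) -> TransferResult:
    """Fisher's exact transfer test for one ASV's dyad 2x2 table."""
    if min(a, b, c, d) < 0:
        raise ValidationError("2x2 cell counts must be non-negative")
    if a + b + c + d < 1:
        raise ValidationError("empty 2x2 table")
    ors, ps = _fisher_arrays(
        np.array([a]), np.array([b]), np.array([c]), np.array([d])
    )
    return TransferResult("", a, b, c, d, float(ors[0]), float(ps[0]))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def transfer_scan(
    mother_table: AbundanceTable,
    child_table: AbundanceTable,
    dyads: DyadSet,
    taxonomy: TaxonomyTable | None = None,
    presence_threshold: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Fisher transfer scan over all testable ASVs of one stratum.

    Returns the per-ASV result table (2x2 counts, OR, one-sided p, BH q
    within the stratum, and the order rank when a taxonomy is given) and a
    stratum summary with the testable count, the share of maternal/child
    reads covered by testable ASVs, and significance tallies.
    """
    mothers = presence_matrix(mother_table, presence_threshold)
    children = presence_matrix(child_table, presence_threshold)
    m, c = _dyad_presence(mothers, children, dyads)
    mask = _testable_mask(m, c)
    asv_ids = np.array(mother_table.asv_ids)

    n = m.shape[0]
    a = (m & c).sum(axis=0)[mask]
    ms = m.sum(axis=0)[mask]
    cs = c.sum(axis=0)[mask]
    b = ms - a
    cc = cs - a
    d = n - a - b - cc
    or_point, p = _fisher_arrays(a, b, cc, d)
    q = bh_fdr(p) if mask.any() else np.array([])

    out = pd.DataFrame(
        {
            "asv_id": asv_ids[mask],
            "a": a,
            "b": b,
            "c": cc,
            "d": d,
            "or_point": or_point,
            "p_one_sided": p,
            "q": q,
        }
    )
    if taxonomy is not None:
        out["order"] = taxonomy.orders(list(out["asv_id"])).to_numpy()

    mother_counts = mother_table.select_samples(dyads.mother_samples).counts
    child_counts = child_table.select_samples(dyads.child_samples).counts
    def _coverage(counts: np.ndarray) -> float:
        total = counts.sum()
        return float(100.0 * counts[:, mask].sum() / total) if total else 0.0

    summary = {
        "compartment": dyads.compartment,
        "timepoint_days": dyads.timepoint_days,
        "modes": "+".join(sorted(dyads.modes)),
        "n_dyads": n,
        "n_testable": int(mask.sum()),
        "maternal_abundance_pct": _coverage(mother_counts),
        "child_abundance_pct": _coverage(child_counts),
        "n_p_lt_0.01": int((p < 0.01).sum()),
        "n_p_lt_0.05": int((p < 0.05).sum()),
        "n_q_lt_0.05": int((q < 0.05).sum()) if mask.any() else 0,
        "n_q_lt_0.10": int((q < 0.10).sum()) if mask.any() else 0,
    }
    return out, summary


def abundance_or_correlation(
    results: pd.DataFrame,
    maternal_mean_abundance: pd.Series,
    method: str = "spearman",
) -> tuple[float, float]:
    """Correlation of per-ASV log transfer OR with maternal mean abundance.

    ``maternal_mean_abundance`` is the mean relative abundance of each ASV
    across the stratum's mothers.  Spearman by default (Pearson available),
    two-sided p.
    """
    if len(results) < 3:
        raise ValidationError("need at least three ASVs")
    x = np.log(results["or_point"].to_numpy(dtype=float))
    y = maternal_mean_abundance.reindex(results["asv_id"]).to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0 or np.any(~np.isfinite(y)):
        _warnings.warn("degenerate inputs for OR-abundance correlation")
        return np.nan, np.nan
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(rho), float(p)


def dominant_asv_transfer(
    vaginal_w36: AbundanceTable,
    child_presence: PresenceTable,
    dyads: DyadSet,
    n_perm: int = 2500,
    seed: int | None = None,
) -> tuple[float, float]:
    """Transfer of each mother's most dominant vaginal ASV.

    Per dyad, the maternal ASV with the highest week-36 count (ties broken
    by higher total abundance across all mothers, then lexicographically) is
    checked for presence in the child.  The statistic is the fraction of
    dyads whose child carries it; the null scrambles the child side and the
    one-sided p counts permutations reaching at least the observed fraction.
    """
    if len(dyads) < 2:
        raise ValidationError("need at least two dyads")
    mothers = vaginal_w36.select_samples(dyads.mother_samples)
    if np.any(mothers.counts.sum(axis=1) == 0):
        raise ValidationError("a dyad's mother sample has no reads")
    totals = vaginal_w36.counts.sum(axis=0)
    asv_arr = np.array(mothers.asv_ids)
    dom_idx = []
    for row in mothers.counts:
        tied = np.flatnonzero(row == row.max())
        if len(tied) > 1:  # higher population-wide abundance wins
            tied = tied[totals[tied] == totals[tied].max()]
        if len(tied) > 1:  # then lexicographic on the ASV id
            tied = tied[np.argsort(asv_arr[tied], kind="stable")][:1]
        dom_idx.append(int(tied[0]))
    dom_idx = np.array(dom_idx)
    children = child_presence.select_samples(dyads.child_samples).present
    hits = children[np.arange(len(dyads)), dom_idx]
    observed = float(hits.mean())
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(dyads))
        if children[perm, dom_idx].mean() >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, p
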