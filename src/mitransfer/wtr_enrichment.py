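"""The weighted transfer ratio (WTR) and its scrambled-dyad permutation null.

Individual-ASV transfer tests are underpowered in sparse mother-child data,
so evidence is pooled over ASVs through the geometry of the volcano plot
(log odds ratio vs -log10 p).  The weighted positive and negative sums

    WP = sum over ASVs with OR > 1 of |ln OR| * (-log10 p)
    WN = sum over ASVs with OR < 1 of |ln OR| * (-log10 p)

give each ASV weight proportional to both effect size and inference
strength; their ratio WP/WN is the raw WTR.  Because sparsity skews the
ratio even without transfer, the dyad pairing is scrambled to build a null
distribution, and the reported WTR is the raw ratio divided by the null
median, with a one-sided permutation p.  The same machinery runs per
bacterial order for the order-level analysis, with bootstrap standard
errors over ASVs.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_core import AbundanceTable, DyadSet, TaxonomyTable
from .transfer_tests import (
    _dyad_presence,
    _fisher_arrays,
    _testable_mask,
    presence_matrix,
)

#: Fig-style export clamp for order-level WTR values.
PLOT_CLAMP = (0.625, 16.0)


@dataclass
class WTRRecord:
    """One stratum's (or one order-within-stratum's) WTR analysis."""

    compartment: str
    timepoint_days: int
    modes: str
    order: str  # bacterial order, or "all"
    n_testable: int
    n_pos: int  # ASVs with OR > 1
    n_neg: int  # ASVs with OR < 1
    wp: float
    wn: float
    raw_wtr: float
    null_median: float
    wtr: float  # raw_wtr / null_median: the reported value
    p_perm: float
    se: float  # bootstrap SE of ln(raw WTR) over ASVs
    n_inf_boot: int  # bootstrap replicates dropped as infinite/undefined
    n_perm: int
    n_boot: int
    seed: int | None
    low_support: bool = False
    usable: bool = True


def wtr_raw(results: pd.DataFrame) -> tuple[float, float, float]:
    """WP, WN and their ratio from a per-ASV transfer result table.

    ``results`` needs columns ``or_point`` and ``p_one_sided``.  ASVs with
    OR exactly 1 contribute to neither sum; p = 1 contributes zero weight.
    The ratio is +inf when WN = 0 < WP and NaN (with a warning) when both
    sums are zero.
    """
    if len(results) == 0:
        raise ValidationError("empty transfer result table")
    ors = np.asarray(results["or_point"], dtype=float)
    ps = np.asarray(results["p_one_sided"], dtype=float)
    wp, wn, raw = _wtr_from_arrays(ors, ps)
    if np.isnan(raw):
        _warnings.warn("both WP and WN are zero; raw WTR undefined")
    return wp, wn, raw


def _wtr_from_arrays(ors: np.ndarray, ps: np.ndarray) -> tuple[float, float, float]:
    weight = np.abs(np.log(ors)) * (-np.log10(np.clip(ps, 1e-300, 1.0)))
    wp = float(weight[ors > 1].sum())
    wn = float(weight[ors < 1].sum())
    if wn > 0:
        return wp, wn, wp / wn
    return wp, wn, (np.inf if wp > 0 else np.nan)


def _stratum_raw(m: np.ndarray, c: np.ndarray) -> tuple[float, float, float, np.ndarray, np.ndarray]:
    """Full per-ASV pipeline on aligned presence matrices -> raw WTR."""
    mask = _testable_mask(m, c)
    if not mask.any():
        return 0.0, 0.0, np.nan, np.array([]), np.array([])
    n = m.shape[0]
    a = (m & c).sum(axis=0)[mask]
    b = m.sum(axis=0)[mask] - a
    cc = c.sum(axis=0)[mask] - a
    d = n - a - b - cc
    ors, ps = _fisher_arrays(a, b, cc, d)
    wp, wn, raw = _wtr_from_arrays(ors, ps)
    return wp, wn, raw, ors, ps


def wtr_null(
    mother_table: AbundanceTable,
    child_table: AbundanceTable,
    dyads: DyadSet,
    taxonomy: TaxonomyTable | None = None,
    order: str | None = None,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int | None = None,
    presence_threshold: int = 1,
) -> WTRRecord:
    """Observed WTR for one stratum with its scrambled-dyad null.

    Each permutation scrambles the child side of the dyad pairing and
    re-runs the whole downstream pipeline (testable-ASV selection, Fisher
    tests, WP/WN).  The reported ``wtr`` is the observed raw ratio divided
    by the null median (infinities participate in the median by ordering);
    ``p_perm`` is one-sided, counting null raw ratios at least as large as
    the observed one.  With ``order`` set, only that order's ASVs enter.
    """
    if len(dyads) < 2:
        raise ValidationError("need at least two dyads")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    mothers = presence_matrix(mother_table, presence_threshold)
    children = presence_matrix(child_table, presence_threshold)
    m, c = _dyad_presence(mothers, children, dyads)
    if order is not None:
        if taxonomy is None:
            raise ValidationError("order filtering requires a taxonomy")
        keep = taxonomy.orders(mothers.asv_ids).to_numpy() == order
        m, c = m[:, keep], c[:, keep]

    wp, wn, raw, ors, ps = _stratum_raw(m, c)
    n_testable = len(ors)

    ss = np.random.SeedSequence(seed)
    rng_perm, rng_boot = (np.random.default_rng(s) for s in ss.spawn(2))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng_perm.permutation(m.shape[0])
        null[i] = _stratum_raw(m, c[perm])[2]
    valid = null[~np.isnan(null)]
    usable = len(valid) > 0 and not np.isnan(raw)
    null_median = float(np.median(valid)) if len(valid) else np.nan
    with np.errstate(invalid="ignore"):
        wtr = raw / null_median if usable else np.nan
    hits = int(np.sum(valid >= raw)) if usable else 0
    p_perm = (1 + hits) / (n_perm + 1)

    if n_testable >= 2 and usable:
        se, n_inf = wtr_se(pd.DataFrame({"or_point": ors, "p_one_sided": ps}),
                           n_boot=n_boot, rng=rng_boot)
    else:
        se, n_inf = np.nan, 0

    return WTRRecord(
        compartment=dyads.compartment,
        timepoint_days=dyads.timepoint_days,
        modes="+".join(sorted(dyads.modes)),
        order=order if order is not None else "all",
        n_testable=n_testable,
        n_pos=int(np.sum(ors > 1)),
        n_neg=int(np.sum(ors < 1)),
        wp=wp,
        wn=wn,
        raw_wtr=raw,
        null_median=null_median,
        wtr=float(wtr) if usable else np.nan,
        p_perm=p_perm if usable else np.nan,
        se=se,
        n_inf_boot=n_inf,
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
        usable=usable,
    )


def wtr_se(
    results: pd.DataFrame,
    n_boot: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, int]:
    """Bootstrap standard error of ln(raw WTR), resampling ASVs.

    Replicates whose raw ratio is infinite or undefined are dropped from
    the standard deviation; their count is returned alongside.
    """
    if len(results) < 2:
        raise ValidationError("need at least two testable ASVs")
    ors = np.asarray(results["or_point"], dtype=float)
    ps = np.asarray(results["p_one_sided"], dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(ors)
    raws = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        raws[i] = _wtr_from_arrays(ors[idx], ps[idx])[2]
    finite = raws[np.isfinite(raws) & (raws > 0)]
    n_dropped = n_boot - len(finite)
    if len(finite) < 2:
        return np.nan, n_dropped
    return float(np.std(np.log(finite), ddof=1)), n_dropped


def order_testable_counts(
    mother_table: AbundanceTable,
    child_tables: dict[tuple[str, int], AbundanceTable],
    dyadsets: list[DyadSet],
    taxonomy: TaxonomyTable,
    presence_threshold: int = 1,
) -> pd.DataFrame:
    """Testable-ASV counts per (order, stratum); basis for the inclusion rule."""
    orders = taxonomy.orders(mother_table.asv_ids).to_numpy()
    rows = []
    for dy in dyadsets:
        child = child_tables[(dy.compartment, dy.timepoint_days)]
        m, c = _dyad_presence(
            presence_matrix(mother_table, presence_threshold),
            presence_matrix(child, presence_threshold),
            dy,
        )
        mask = _testable_mask(m, c)
        for o in sorted(set(orders) - {""}):
            rows.append({
                "order": o,
                "compartment": dy.compartment,
                "timepoint_days": dy.timepoint_days,
                "modes": "+".join(sorted(dy.modes)),
                "n_testable": int(mask[orders == o].sum()),
            })
    return pd.DataFrame(rows)


def wtr_by_order(
    mother_table: AbundanceTable,
    child_tables: dict[tuple[str, int], AbundanceTable],
    dyadsets: list[DyadSet],
    taxonomy: TaxonomyTable,
    n_perm: int = 1000,
    n_boot: int = 500,
    seed: int | None = None,
    min_per_stratum: int = 2,
    min_peak: int = 10,
    low_support_mean: float = 15.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Order-stratified WTR across all strata.

    An order is included when it has at least ``min_per_stratum`` testable
    ASVs in every stratum and more than ``min_peak`` in at least one; for
    each included (order, stratum) the full scrambled-dyad analysis runs on
    that order's ASVs alone.  Records where the mean testable count across
    strata is below ``low_support_mean`` carry a low-support flag.  ASVs
    without an order rank are skipped (they are counted in the taxonomy's
    ``unassigned`` list).  Returns the record table and the excluded orders.
    """
    counts = order_testable_counts(mother_table, child_tables, dyadsets, taxonomy)
    by_order = counts.groupby("order")["n_testable"]
    included = sorted(
        o for o, g in by_order
        if g.min() >= min_per_stratum and g.max() > min_peak
    )
    excluded = sorted(set(counts["order"]) - set(included))
    ss = np.random.SeedSequence(seed)
    records = []
    for o in included:
        low = bool(by_order.get_group(o).mean() < low_support_mean)
        for dy in dyadsets:
            child = child_tables[(dy.compartment, dy.timepoint_days)]
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            rec = wtr_null(
                mother_table, child, dy, taxonomy=taxonomy, order=o,
                n_perm=n_perm, n_boot=n_boot, seed=sub_seed,
            )
            rec.low_support = low
            records.append(rec)
    import dataclasses

    columns = [f.name for f in dataclasses.fields(WTRRecord)]
    return pd.DataFrame([r.__dict__ for r in records], columns=columns), excluded


def truncate_for_plot(records: pd.DataFrame, clamp: tuple[float, float] = PLOT_CLAMP) -> pd.DataFrame:
    """Plot-ready copy with WTR clamped into ``clamp`` (display convention only)."""
    out = records.copy()
    out["wtr_plot"] = out["wtr"].clip(lower=clamp[0], upper=clamp[1])
    return out


def wtr_mode_contrast(
    mother_table: AbundanceTable,
    child_table: AbundanceTable,
    dyads_a: DyadSet,
    dyads_b: DyadSet,
    n_perm: int = 1000,
    seed: int | None = None,
    taxonomy: TaxonomyTable | None = None,
    order: str | None = None,
) -> tuple[float, float]:
    """Delivery-mode contrast of raw WTRs between two strata.

    The strata must share compartment and timepoint and differ only in the
    delivery-mode set.  The statistic is ln(raw WTR_A) - ln(raw WTR_B); the
    null permutes the mode labels over the union of dyads (preserving group
    sizes) and recomputes both raw ratios; one-sided p toward A > B.
    """
    if (dyads_a.compartment, dyads_a.timepoint_days) != (
        dyads_b.compartment,
        dyads_b.timepoint_days,
    ):
        raise ValidationError("strata must differ only by delivery mode")
    mothers = presence_matrix(mother_table)
    children = presence_matrix(child_table)
    ma, ca = _dyad_presence(mothers, children, dyads_a)
    mb, cb = _dyad_presence(mothers, children, dyads_b)
    if order is not None:
        if taxonomy is None:
            raise ValidationError("order filtering requires a taxonomy")
        keep = taxonomy.orders(mothers.asv_ids).to_numpy() == order
        ma, ca, mb, cb = ma[:, keep], ca[:, keep], mb[:, keep], cb[:, keep]
    m_all = np.vstack([ma, mb])
    c_all = np.vstack([ca, cb])
    na = ma.shape[0]

    def _stat(assignment: np.ndarray) -> float:
        ra = _stratum_raw(m_all[assignment], c_all[assignment])[2]
        rb = _stratum_raw(m_all[~assignment], c_all[~assignment])[2]
        with np.errstate(divide="ignore", invalid="ignore"):
            return float(np.log(ra) - np.log(rb))

    base = np.zeros(m_all.shape[0], dtype=bool)
    base[:na] = True
    observed = _stat(base)
    if not np.isfinite(observed):
        _warnings.warn("raw WTR undefined or infinite in one stratum; contrast unavailable")
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(m_all.shape[0])
        assignment = np.zeros(m_all.shape[0], dtype=bool)
        assignment[perm[:na]] = True
        s = _stat(assignment)
        if not np.isnan(s) and s >= observed:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return observed, p
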