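import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mitransfer as mt
from mitransfer.errors import ValidationError
from oracles import wp_wn


def _results(ors, ps):
    return pd.DataFrame({"or_point": ors, "p_one_sided": ps})


class TestWTRRaw:
    def test_symmetric_pair_gives_unit_ratio(self):
        wp, wn, raw = mt.wtr_raw(_results([2.0, 0.5], [0.1, 0.1]))
        assert wp == pytest.approx(np.log(2))
        assert wn == pytest.approx(np.log(2))
        assert raw == pytest.approx(1.0)

    def test_three_asv_worked_example(self):
        wp, wn, raw = mt.wtr_raw(_results([10.0, 4.0, 0.5], [1e-3, 1e-2, 1e-1]))
        assert wp == pytest.approx(3 * np.log(10) + 2 * np.log(4), abs=1e-9)
        assert wn == pytest.approx(np.log(2), abs=1e-9)
        assert raw == pytest.approx((3 * np.log(10) + 2 * np.log(4)) / np.log(2), abs=1e-9)
        assert raw == pytest.approx(13.966, abs=1e-3)

    def test_p_one_contributes_nothing(self):
        wp, wn, raw = mt.wtr_raw(_results([5.0, 2.0], [1.0, 0.1]))
        assert wp == pytest.approx(np.log(2))  # only the p=0.1 ASV counts

    def test_or_exactly_one_contributes_to_neither(self):
        wp, wn, _ = mt.wtr_raw(_results([1.0, 2.0, 0.5], [1e-5, 0.1, 0.1]))
        assert wp == pytest.approx(np.log(2)) and wn == pytest.approx(np.log(2))

    def test_infinite_when_no_negative_side(self):
        _, _, raw = mt.wtr_raw(_results([3.0], [0.01]))
        assert raw == np.inf

    def test_undefined_when_both_sides_zero(self):
        with pytest.warns(UserWarning):
            _, _, raw = mt.wtr_raw(_results([1.0], [0.5]))
        assert np.isnan(raw)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mt.wtr_raw(_results([], []))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 15)
        ors = np.exp(rng.normal(0, 1, n))
        ps = rng.uniform(1e-6, 1, n)
        wp, wn, _ = mt.wtr_raw(_results(ors, ps))
        owp, own = wp_wn(ors, ps)
        assert wp == pytest.approx(owp, rel=1e-12)
        assert wn == pytest.approx(own, rel=1e-12)


class TestAlgebraicIdentities:
    def test_log_base_invariance(self):
        # replacing ln OR by log_b OR rescales WP and WN equally
        ors, ps = [10.0, 4.0, 0.5, 0.2], [1e-3, 1e-2, 1e-1, 0.3]
        _, _, raw = mt.wtr_raw(_results(ors, ps))
        for base in (2.0, 10.0, np.e):
            w = np.abs(np.log(ors) / np.log(base)) * (-np.log10(ps))
            alt = w[np.array(ors) > 1].sum() / w[np.array(ors) < 1].sum()
            assert raw == pytest.approx(alt, rel=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_reciprocal_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        ors = np.exp(rng.normal(0, 1.5, n))
        ors = ors[np.abs(np.log(ors)) > 1e-6]
        if (ors > 1).sum() == 0 or (ors < 1).sum() == 0:
            return
        ps = rng.uniform(1e-4, 0.99, len(ors))
        _, _, raw = mt.wtr_raw(_results(ors, ps))
        _, _, inv = mt.wtr_raw(_results(1 / ors, ps))
        assert inv == pytest.approx(1 / raw, rel=1e-9)

    def test_monotone_in_positive_side_significance(self):
        ors = [4.0, 0.5]
        base = mt.wtr_raw(_results(ors, [0.2, 0.1]))[2]
        better = mt.wtr_raw(_results(ors, [0.02, 0.1]))[2]
        assert better >= base


class TestWTRNull:
    def test_reported_wtr_is_raw_over_null_median(self, planted_cohort):
        dy = mt.build_dyads(planted_cohort.metadata, "fecal", 7, "VAG")
        rec = mt.wtr_null(planted_cohort.vaginal_w36,
                          planted_cohort.child_tables[("fecal", 7)], dy,
                          n_perm=99, seed=3)
        assert rec.wtr == pytest.approx(rec.raw_wtr / rec.null_median)
        assert 0 < rec.p_perm <= 1
        assert rec.n_testable == rec.n_pos + rec.n_neg + int(rec.n_testable - rec.n_pos - rec.n_neg)

    def test_planted_transfer_detected(self, planted_cohort):
        dy = mt.build_dyads(planted_cohort.metadata, "fecal", 7, "VAG")
        rec = mt.wtr_null(planted_cohort.vaginal_w36,
                          planted_cohort.child_tables[("fecal", 7)], dy,
                          n_perm=199, seed=5)
        assert rec.wtr > 1.5
        assert rec.p_perm == pytest.approx(1 / 200)

    def test_order_restriction_reduces_testable_set(self, planted_cohort):
        dy = mt.build_dyads(planted_cohort.metadata, "fecal", 7, "VAG")
        rec_all = mt.wtr_null(planted_cohort.vaginal_w36,
                              planted_cohort.child_tables[("fecal", 7)], dy,
                              n_perm=19, seed=1)
        rec_lac = mt.wtr_null(planted_cohort.vaginal_w36,
                              planted_cohort.child_tables[("fecal", 7)], dy,
                              taxonomy=planted_cohort.taxonomy, order="Lactobacillales",
                              n_perm=19, seed=1)
        assert 0 < rec_lac.n_testable < rec_all.n_testable
        assert rec_lac.order == "Lactobacillales"

    def test_seed_determinism(self, small_cohort):
        dy = mt.build_dyads(small_cohort.metadata, "fecal", 30, "VAG")
        a = mt.wtr_null(small_cohort.vaginal_w36, small_cohort.child_tables[("fecal", 30)],
                        dy, n_perm=49, seed=11)
        b = mt.wtr_null(small_cohort.vaginal_w36, small_cohort.child_tables[("fecal", 30)],
                        dy, n_perm=49, seed=11)
        assert a.null_median == b.null_median and a.p_perm == b.p_perm and a.se == b.se

    def test_too_few_dyads(self, small_cohort):
        dy = mt.DyadSet("fecal", 7, frozenset({"VAG"}), ())
        with pytest.raises(ValidationError):
            mt.wtr_null(small_cohort.vaginal_w36, small_cohort.child_tables[("fecal", 7)], dy)


class TestWTRSE:
    def test_identical_asvs_give_zero_se(self):
        res = _results([2.0] * 6, [0.05] * 6)
        se, dropped = mt.wtr_se(res, n_boot=50, seed=0)
        assert np.isnan(se) or se == 0.0  # every resample has WN=0 -> dropped
        res = _results([2.0, 0.5] * 3, [0.05] * 6)
        # still heterogeneous resamples, but weights all equal ln2: ratio = n_pos/n_neg
        se2, _ = mt.wtr_se(res, n_boot=200, seed=0)
        assert se2 > 0

    def test_two_asv_exhaustive_enumeration(self):
        # resamples of {x, y}: (x,x) w.p. 1/4 -> +inf; (y,y) w.p. 1/4 -> 0 (dropped);
        # (x,y) w.p. 1/2 -> finite ratio. All finite replicates share one value -> sd 0.
        res = _results([4.0, 0.25], [0.01, 0.1])
        se, dropped = mt.wtr_se(res, n_boot=400, seed=2)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert 100 < dropped < 300  # about half the replicates are degenerate

    def test_seed_determinism(self):
        res = _results([3.0, 0.5, 2.0, 0.2], [0.01, 0.2, 0.05, 0.5])
        a = mt.wtr_se(res, n_boot=100, seed=9)
        b = mt.wtr_se(res, n_boot=100, seed=9)
        assert a == b


class TestByOrderAndContrast:
    def test_inclusion_rule(self):
        # 20 ASVs per order so the "more than 10 in some stratum" rule can bind
        bundle = mt.simulate_cohort(
            mt.SimulationParams(n_dyads=120, n_asvs=200, seed=23, compartments=("fecal",))
        )
        dyadsets = [
            mt.build_dyads(bundle.metadata, "fecal", tp, modes)
            for tp in (7, 30, 300)
            for modes in ("VAG", "CS")
        ]
        # shrink one order to a single ASV so the inclusion rule must drop it
        tax = bundle.taxonomy.frame.copy()
        bacillales = tax.index[tax["order"] == "Bacillales"]
        tax.loc[bacillales[1:], "order"] = "Clostridiales"
        taxonomy = mt.TaxonomyTable(tax.reset_index(names="asv_id"))
        counts = mt.order_testable_counts(
            bundle.vaginal_w36, bundle.child_tables, dyadsets, taxonomy
        )
        records, excluded = mt.wtr_by_order(
            bundle.vaginal_w36, bundle.child_tables, dyadsets, taxonomy,
            n_perm=19, seed=0,
        )
        assert "Bacillales" in excluded
        included = set(records["order"].unique())
        assert included  # the remaining orders stay analyzable
        by_order = counts.groupby("order")["n_testable"]
        for o in included:
            assert by_order.get_group(o).min() >= 2
            assert by_order.get_group(o).max() > 10
        for o in excluded:
            g = by_order.get_group(o)
            assert g.min() < 2 or g.max() <= 10
        # every included (order, stratum) ran the full scrambled-dyad analysis
        assert len(records) == len(included) * len(dyadsets)
        assert records["p_perm"].between(0, 1).all()

    def test_truncation_is_export_only(self):
        df = pd.DataFrame({"wtr": [0.1, 1.0, 50.0]})
        out = mt.truncate_for_plot(df)
        assert out["wtr_plot"].tolist() == [0.625, 1.0, 16.0]
        assert out["wtr"].tolist() == [0.1, 1.0, 50.0]  # raw column untouched

    def test_mode_contrast_identical_strata_zero_statistic(self, planted_cohort):
        dy = mt.build_dyads(planted_cohort.metadata, "fecal", 7, "VAG")
        stat, p = mt.wtr_mode_contrast(
            planted_cohort.vaginal_w36, planted_cohort.child_tables[("fecal", 7)],
            dy, dy, n_perm=19, seed=0,
        )
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_mode_contrast_detects_vag_only_transfer(self, planted_cohort):
        meta = planted_cohort.metadata
        a = mt.build_dyads(meta, "fecal", 7, "VAG")
        b = mt.build_dyads(meta, "fecal", 7, "CS")
        stat, p = mt.wtr_mode_contrast(
            planted_cohort.vaginal_w36, planted_cohort.child_tables[("fecal", 7)],
            a, b, n_perm=99, seed=4,
        )
        assert stat > 0
        assert p < 0.05
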