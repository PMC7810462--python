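import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mitransfer as mt
from mitransfer.errors import ValidationError
from oracles import bh_step_up, fisher_one_sided


def _presence(rows, ids=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=bool))
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    return mt.PresenceTable(ids, [f"A{j}" for j in range(rows.shape[1])], rows)


class TestPresenceMatrix:
    def test_threshold_semantics(self):
        t = mt.AbundanceTable(["s"], ["A", "B", "C"], np.array([[0, 1, 4]]))
        assert mt.presence_matrix(t).present.tolist() == [[False, True, True]]
        assert mt.presence_matrix(t, threshold=5).present.tolist() == [[False, False, False]]

    def test_threshold_must_be_positive(self):
        t = mt.AbundanceTable(["s"], ["A"], np.array([[1]]))
        with pytest.raises(ValidationError):
            mt.presence_matrix(t, threshold=0)


class TestTestableASVs:
    def _dyads(self, n):
        return mt.DyadSet("fecal", 7, frozenset({"VAG"}),
                          tuple((f"m{i}", f"c{i}") for i in range(n)))

    def test_zero_margin_exclusions(self):
        mothers = _presence([[1, 1, 1], [1, 0, 1], [1, 1, 0]], ["m0", "m1", "m2"])
        children = _presence([[1, 1, 0], [0, 1, 0], [1, 0, 0]], ["c0", "c1", "c2"])
        got = mt.testable_asvs(mothers, children, self._dyads(3))
        # A0 present in every mother; A2 absent in every child
        assert got == ["A1"]

    def test_all_margins_positive_included(self):
        mothers = _presence([[1]] * 5 + [[0]] * 5, [f"m{i}" for i in range(10)])
        children = _presence([[1], [0]] * 5, [f"c{i}" for i in range(10)])
        assert mt.testable_asvs(mothers, children, self._dyads(10)) == ["A0"]


class TestFisherTransfer:
    def test_balanced_table_matches_enumeration(self):
        r = mt.fisher_transfer(1, 1, 1, 1)
        assert r.or_point == pytest.approx(1.0)
        assert r.p_one_sided == pytest.approx(fisher_one_sided(1, 1, 1, 1), abs=1e-12)
        assert r.p_one_sided == pytest.approx(5 / 6, abs=1e-12)

    def test_perfect_association(self):
        r = mt.fisher_transfer(5, 0, 0, 5)
        assert r.p_one_sided == pytest.approx(1 / 252, abs=1e-12)
        assert r.or_point == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))  # Haldane

    def test_strong_association(self):
        r = mt.fisher_transfer(4, 1, 1, 4)
        assert r.or_point == pytest.approx(16.0)
        assert r.p_one_sided == pytest.approx(26 / 252, abs=1e-12)

    def test_exhaustive_small_tables_match_enumeration(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        r = mt.fisher_transfer(a, b, c, d)
                        assert r.p_one_sided == pytest.approx(
                            fisher_one_sided(a, b, c, d), abs=1e-12
                        ), (a, b, c, d)

    def test_mother_child_axis_swap_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            r1 = mt.fisher_transfer(a, b, c, d)
            r2 = mt.fisher_transfer(a, c, b, d)  # transpose the 2x2
            assert r1.p_one_sided == pytest.approx(r2.p_one_sided, abs=1e-12)
            assert r1.or_point == pytest.approx(r2.or_point)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            mt.fisher_transfer(-1, 1, 1, 1)


class TestBHFDR:
    def test_hand_worked_step_up(self):
        assert mt.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_is_itself(self):
        assert mt.bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert mt.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            mt.bh_fdr([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_step_up_definition_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 40))
        q = mt.bh_fdr(p)
        assert np.allclose(q, bh_step_up(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()  # q monotone in p


class TestTransferScan:
    def test_planted_hits_concentrate_in_planted_order(self, planted_cohort):
        bundle = planted_cohort
        dy = mt.build_dyads(bundle.metadata, "fecal", 7, "VAG")
        scan, summary = mt.transfer_scan(
            bundle.vaginal_w36, bundle.child_tables[("fecal", 7)], dy, bundle.taxonomy
        )
        hits = scan[scan["q"] < 0.05]
        assert len(hits) >= 3
        assert (hits["order"] == "Lactobacillales").mean() > 0.8

    def test_null_rejection_rate_calibrated(self, small_cohort):
        ps = []
        for tp in (7, 30, 300):
            dy = mt.build_dyads(small_cohort.metadata, "fecal", tp, ["VAG", "CS-L", "CS-S"])
            scan, _ = mt.transfer_scan(
                small_cohort.vaginal_w36, small_cohort.child_tables[("fecal", tp)], dy
            )
            ps.extend(scan["p_one_sided"])
        rate = float(np.mean(np.array(ps) < 0.05))
        se = np.sqrt(0.05 * 0.95 / len(ps))
        assert rate < 0.05 + 3 * se  # exact test: at or below nominal

    def test_summary_fields_in_range(self, small_cohort):
        dy = mt.build_dyads(small_cohort.metadata, "airway", 7, "CS")
        scan, summary = mt.transfer_scan(
            small_cohort.vaginal_w36, small_cohort.child_tables[("airway", 7)], dy
        )
        assert summary["n_testable"] == len(scan)
        assert 0 <= summary["maternal_abundance_pct"] <= 100
        assert 0 <= summary["child_abundance_pct"] <= 100
        assert summary["n_p_lt_0.01"] <= summary["n_p_lt_0.05"]
        assert summary["n_q_lt_0.05"] <= summary["n_q_lt_0.10"]


class TestAbundanceORCorrelation:
    def test_perfect_monotone_decreasing(self):
        results = pd.DataFrame(
            {"asv_id": ["A", "B", "C", "D"], "or_point": [8.0, 4.0, 2.0, 1.1],
             "p_one_sided": [0.01] * 4}
        )
        abund = pd.Series([0.01, 0.05, 0.2, 0.5], index=["A", "B", "C", "D"])
        rho, p = mt.abundance_or_correlation(results, abund)
        assert rho == pytest.approx(-1.0)

    def test_too_few_asvs(self):
        results = pd.DataFrame({"asv_id": ["A", "B"], "or_point": [2.0, 0.5],
                                "p_one_sided": [0.1, 0.1]})
        with pytest.raises(ValidationError):
            mt.abundance_or_correlation(results, pd.Series([0.1, 0.2], index=["A", "B"]))

    def test_degenerate_variance_warns_and_returns_nan(self):
        results = pd.DataFrame({"asv_id": list("ABC"), "or_point": [2.0, 2.0, 2.0],
                                "p_one_sided": [0.1] * 3})
        abund = pd.Series([0.1, 0.2, 0.3], index=list("ABC"))
        with pytest.warns(UserWarning):
            rho, p = mt.abundance_or_correlation(results, abund)
        assert np.isnan(rho) and np.isnan(p)


class TestDominantASVTransfer:
    def _setup(self, child_rows):
        mothers = mt.AbundanceTable(
            ["m0", "m1", "m2"], ["A", "B", "C"],
            np.array([[10, 1, 0], [0, 9, 1], [1, 0, 7]]),
        )
        children = _presence(child_rows, ["c0", "c1", "c2"])
        dyads = mt.DyadSet("fecal", 7, frozenset({"VAG"}),
                           (("m0", "c0"), ("m1", "c1"), ("m2", "c2")))
        return mothers, children, dyads

    def test_dominant_everywhere_gives_p_one(self):
        mothers, children, dyads = self._setup(np.ones((3, 3)))
        prop, p = mt.dominant_asv_transfer(mothers, children, dyads, n_perm=99, seed=0)
        assert prop == 1.0
        assert p == 1.0  # statistic invariant under scrambling

    def test_forced_transfer_attains_minimal_p(self):
        # each child carries exactly its own mother's dominant ASV; a random
        # scramble essentially never aligns all 8 dyads
        n = 8
        mothers = mt.AbundanceTable(
            [f"m{i}" for i in range(n)], [f"A{j}" for j in range(n)],
            np.eye(n, dtype=np.int64) * 10 + 1,
        )
        children = _presence(np.eye(n, dtype=bool), [f"c{i}" for i in range(n)])
        dyads = mt.DyadSet("fecal", 7, frozenset({"VAG"}),
                           tuple((f"m{i}", f"c{i}") for i in range(n)))
        prop, p = mt.dominant_asv_transfer(mothers, children, dyads, n_perm=199, seed=1)
        assert prop == 1.0
        assert p == pytest.approx(1 / 200)

    def test_too_few_dyads(self):
        mothers = mt.AbundanceTable(["m0"], ["A"], np.array([[3]]))
        children = _presence([[1]], ["c0"])
        dyads = mt.DyadSet("fecal", 7, frozenset({"VAG"}), (("m0", "c0"),))
        with pytest.raises(ValidationError):
            mt.dominant_asv_transfer(mothers, children, dyads)
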