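"""Unit and property tests of the sliding-window DMR caller."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import fisher_exact

import methylite as ml
from methylite.dmr import fisher_p_batch
from conftest import make_sample
from oracles import bh_step_up, fisher_two_sided_exact


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((0, 10, 0, 10), 1.0),            # identical rows
            ((5, 0, 0, 5), 2 / 252),          # doubled extreme tail
            ((0, 0, 0, 0), 1.0),              # empty table convention
            ((3, 0, 0, 0), 1.0),              # zero column margin
        ],
    )
    def test_known_tables(self, table, expected):
        assert ml.fisher_p(*table) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        assert ml.fisher_p(3, 7, 9, 1) == pytest.approx(
            fisher_two_sided_exact(3, 7, 9, 1), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ml.fisher_p(-1, 2, 3, 4)

    @given(
        st.tuples(
            st.integers(0, 60), st.integers(0, 60),
            st.integers(0, 60), st.integers(0, 60),
        )
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_scipy(self, table):
        ours = ml.fisher_p(*table)
        ref = fisher_exact([[table[0], table[1]], [table[2], table[3]]])[1]
        assert ours == pytest.approx(ref, abs=1e-9)
        assert 0.0 < ours <= 1.0

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(5)
        tabs = rng.integers(0, 200, size=(200, 4))
        batch = fisher_p_batch(*tabs.T)
        scalars = [ml.fisher_p(*t) for t in tabs]
        np.testing.assert_allclose(batch, scalars, atol=1e-12)


class TestBH:
    def test_single_p_unchanged(self):
        assert ml.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        np.testing.assert_allclose(
            ml.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(ml.bh_adjust([1.0] * 5), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ml.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_sort_based_oracle(self, p_values):
        adjusted = ml.bh_adjust(p_values)
        np.testing.assert_allclose(adjusted, bh_step_up(p_values), atol=1e-12)
        # adjusted values are monotone non-decreasing in raw-p rank
        order = np.argsort(p_values, kind="mergesort")
        assert (np.diff(adjusted[order]) >= -1e-12).all()


def _pair_from_positions(positions, cov_a=10, cov_b=10, meth_a=0, meth_b=0):
    """Two single-context samples over the same CG positions."""
    rows_a = [("Chr1", p, "+", meth_a, cov_a - meth_a, "CG", "CGT") for p in positions]
    rows_b = [("Chr1", p, "+", meth_b, cov_b - meth_b, "CG", "CGT") for p in positions]
    return make_sample(rows_a, "a"), make_sample(rows_b, "b")


class TestWindows:
    def test_seven_sites_give_three_windows(self):
        a, b = _pair_from_positions(range(10, 80, 10))
        windows, _ = ml.build_windows(a, b, "CG")
        assert len(windows) == 3
        assert windows.loc[0, ["start", "end"]].tolist() == [10, 50]

    def test_too_few_sites_give_zero_windows(self):
        a, b = _pair_from_positions([10, 20, 30, 40])
        windows, _ = ml.build_windows(a, b, "CG")
        assert len(windows) == 0

    def test_covered_fraction_requires_coverage_in_both_samples(self):
        a, b = _pair_from_positions([10, 20, 30, 40, 50])
        # site 30 drops below 4x in sample B only -> not qualifying
        b.data.loc[b.data["pos"] == 30, ["n_meth", "n_unmeth"]] = [1, 2]
        windows, _ = ml.build_windows(a, b, "CG")
        assert windows.loc[0, "covered_fraction"] == pytest.approx(0.8)
        # pooled counts exclude the non-qualifying member in BOTH samples
        assert windows.loc[0, "u_a"] == 40

    def test_windows_on_union_inventory(self):
        a, b = _pair_from_positions([10, 20, 30, 40, 50])
        b_extra = pd.concat(
            [b.data, make_sample([("Chr1", 60, "+", 0, 10, "CG", "CGT")]).data],
            ignore_index=True,
        )
        b2 = ml.MethylomeSample(sample_id="b", data=b_extra)
        windows, sites = ml.build_windows(a, b2, "CG")
        assert len(windows) == 2          # 6 union sites -> 2 windows
        assert len(sites) == 6
        # site 60 is uncovered in sample A -> non-qualifying member
        assert windows.loc[1, "covered_fraction"] == pytest.approx(0.8)


class TestEvaluate:
    def _one_window(self, m_a, u_a, m_b, u_b, frac=1.0):
        return pd.DataFrame(
            {
                "chrom": ["Chr1"], "start": [10], "end": [50], "context": ["CG"],
                "first_site": [0], "n_qual": [int(frac * 5)],
                "covered_fraction": [frac],
                "m_a": [m_a], "u_a": [u_a], "m_b": [m_b], "u_b": [u_b],
            }
        )

    def test_fold_change_and_direction(self):
        tests = ml.evaluate_windows(self._one_window(20, 80, 50, 50))
        row = tests.iloc[0]
        assert row["level_a"] == pytest.approx(0.2)
        assert row["level_b"] == pytest.approx(0.5)
        assert row["fold_change"] == pytest.approx(2.5)
        assert row["direction"] == "hyper"
        assert bool(row["passed"])

    def test_small_fold_change_fails(self):
        tests = ml.evaluate_windows(self._one_window(20, 80, 30, 70))
        assert tests.iloc[0]["fold_change"] == pytest.approx(1.5)
        assert not tests.iloc[0]["passed"]

    def test_zero_level_gives_infinite_fold_change(self):
        tests = ml.evaluate_windows(self._one_window(0, 100, 40, 60))
        assert np.isinf(tests.iloc[0]["fold_change"])
        assert bool(tests.iloc[0]["passed"])

    def test_both_zero_levels_fail(self):
        tests = ml.evaluate_windows(self._one_window(0, 100, 0, 100))
        assert not tests.iloc[0]["passed"]

    def test_zero_pooled_total_fails(self):
        tests = ml.evaluate_windows(self._one_window(0, 0, 40, 60))
        assert not tests.iloc[0]["passed"]

    def test_fraction_at_cutoff_is_excluded(self):
        # coverage > 0.6 is strict: 3 of 5 qualifying is not eligible
        tests = ml.evaluate_windows(self._one_window(0, 100, 50, 50, frac=0.6))
        assert not tests.iloc[0]["passed"]
        assert np.isnan(tests.iloc[0]["p_adj"])
        tests = ml.evaluate_windows(self._one_window(0, 100, 50, 50, frac=0.8))
        assert bool(tests.iloc[0]["passed"])


def _tests_frame(rows):
    """(start, end, first_site, p_adj, direction, passed) window-test rows."""
    return pd.DataFrame(
        [
            {
                "chrom": "Chr1", "start": s, "end": e, "context": "CG",
                "first_site": f, "n_qual": 5, "covered_fraction": 1.0,
                "m_a": 10, "u_a": 40, "m_b": 40, "u_b": 10,
                "level_a": 0.2, "level_b": 0.8, "fold_change": 4.0,
                "p": p, "p_adj": p, "direction": d, "passed": ok,
            }
            for s, e, f, p, d, ok in rows
        ]
    )


def _sites_frame(n):
    return pd.DataFrame(
        {
            "chrom": "Chr1", "pos": np.arange(10, 10 + 10 * n, 10),
            "strand": "+",
            "n_meth_a": 2, "n_unmeth_a": 8, "n_meth_b": 8, "n_unmeth_b": 2,
            "qual": True,
        }
    )


class TestMerge:
    def test_overlapping_same_direction_windows_merge(self):
        tests = _tests_frame(
            [(100, 250, 0, 1e-6, "hyper", True), (200, 350, 2, 1e-4, "hyper", True)]
        )
        dmrs = ml.merge_to_dmrs(tests, _sites_frame(10))
        assert len(dmrs) == 1
        assert dmrs.loc[0, ["start", "end", "length"]].tolist() == [100, 350, 251]
        assert dmrs.loc[0, "n_windows"] == 2
        assert dmrs.loc[0, "best_p_adj"] == pytest.approx(1e-6)

    def test_short_region_dropped(self):
        tests = _tests_frame([(100, 180, 0, 1e-6, "hyper", True)])
        dmrs = ml.merge_to_dmrs(tests, _sites_frame(6))
        assert len(dmrs) == 0

    def test_opposite_directions_not_merged(self):
        tests = _tests_frame(
            [(100, 340, 0, 1e-6, "hyper", True), (400, 640, 10, 1e-6, "hypo", True)]
        )
        dmrs = ml.merge_to_dmrs(tests, _sites_frame(40))
        assert sorted(dmrs["direction"]) == ["hyper", "hypo"]

    def test_failing_windows_ignored(self):
        tests = _tests_frame([(100, 340, 0, 0.5, "hyper", False)])
        assert len(ml.merge_to_dmrs(tests, _sites_frame(30))) == 0


class TestCallDmrs:
    def test_identical_samples_give_no_dmrs(self, planted_pair):
        _, _, sample_a, _ = planted_pair
        result = ml.call_dmrs(sample_a, sample_a)
        assert len(result.dmrs) == 0

    def test_planted_cg_dmrs_recovered(self, planted_pair):
        truth_a, _, sample_a, sample_b = planted_pair
        result = ml.call_dmrs(sample_a, sample_b, contexts=("CG",))
        for planted in truth_a.planted:
            hit = result.dmrs[
                (result.dmrs["start"] <= planted.end)
                & (result.dmrs["end"] >= planted.start)
            ]
            assert len(hit) >= 1
            assert (hit["direction"] == "hyper").all()  # B more methylated

    def test_swapping_samples_flips_directions(self, planted_pair):
        _, _, sample_a, sample_b = planted_pair
        fwd = ml.call_dmrs(sample_a, sample_b, contexts=("CG",)).dmrs
        rev = ml.call_dmrs(sample_b, sample_a, contexts=("CG",)).dmrs
        assert fwd[["chrom", "start", "end"]].equals(rev[["chrom", "start", "end"]])
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert rev["direction"].tolist() == [flip[d] for d in fwd["direction"]]

    def test_emitted_dmrs_satisfy_all_criteria(self, planted_pair):
        _, _, sample_a, sample_b = planted_pair
        result = ml.call_dmrs(sample_a, sample_b)
        for context, tests in result.windows.items():
            dmrs = result.dmrs[result.dmrs["context"] == context]
            assert (dmrs["length"] >= 200).all()
            intervals = sorted(zip(dmrs["start"], dmrs["end"]))
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                assert s2 > e1  # same-context DMRs never overlap
            passing = tests[tests["passed"]]
            for row in dmrs.itertuples(index=False):
                inside = passing[
                    (passing["start"] >= row.start)
                    & (passing["end"] <= row.end)
                    & (passing["direction"] == row.direction)
                ]
                assert len(inside) >= 1
                assert (inside["p_adj"] <= 0.05).all()
                assert (inside["fold_change"] > 2).all()
                assert (inside["covered_fraction"] > 0.6).all()
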