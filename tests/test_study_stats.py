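"""Accuracy-table arithmetic and the matched-pairs signed-rank test."""

from itertools import product

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from periodx.study_stats import (
    PairedStudyRecord,
    compare_conditions,
    pool_row,
    score_accuracy,
    summarize_likert,
    wilcoxon_signed_rank,
)


class TestPoolRow:
    @pytest.mark.parametrize(
        "cells,decimals,expected",
        [
            ([(10, 15), (2, 2), (5, 8)], 1, (17, 25, 68.0)),
            ([(2, 89), (2, 10), (1, 30)], 2, (5, 129, 3.88)),
            ([(18, 36), (3, 4), (9, 12)], 1, (30, 52, 57.7)),
        ],
    )
    def test_pooled_cells(self, cells, decimals, expected):
        cell = pool_row(cells, decimals)
        assert (cell.correct, cell.total, cell.percent) == expected

    def test_empty_denominator_renders_dash(self):
        cell = pool_row([(0, 0), (0, 0)])
        assert cell.percent is None
        assert cell.render() == "0/0 (–)"

    def test_render_matches_table_syntax(self):
        assert pool_row([(10, 15), (2, 2), (5, 8)], 1).render(1) == "17/25 (68.0)"

    @given(
        st_h.lists(
            st_h.tuples(st_h.integers(0, 20), st_h.integers(0, 20)).map(
                lambda ct: (min(ct), max(ct))
            ),
            min_size=2, max_size=8,
        ),
        st_h.integers(1, 5),
    )
    @settings(max_examples=60, deadline=None)
    def test_pooling_is_associative(self, cells, split):
        split = min(split, len(cells) - 1)
        whole = pool_row(cells)
        left = pool_row(cells[:split])
        right = pool_row(cells[split:])
        regrouped = pool_row([(left.correct, left.total), (right.correct, right.total)])
        assert (whole.correct, whole.total) == (regrouped.correct, regrouped.total)
        assert whole.percent == regrouped.percent

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            pool_row([(3, 2)])


def brute_force_two_sided_p(diffs):
    """Enumerate all sign assignments of the ranked |d|; independent oracle."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = st.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([False, True], repeat=n)
    ]
    stats = np.array(stats)
    p_low = np.mean(stats <= w_obs)
    p_high = np.mean(stats >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_one_through_five(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.exact
        assert res.pvalue == pytest.approx(0.0625)

    def test_symmetric_pair_gives_p_one(self):
        assert wilcoxon_signed_rank([1, -1]).pvalue == pytest.approx(1.0)

    def test_all_zero_is_degenerate(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.degenerate and res.pvalue == 1.0

    @given(
        st_h.lists(
            st_h.integers(-30, 30).filter(lambda x: x != 0), min_size=1, max_size=10
        ),
    )
    @settings(max_examples=250, deadline=None)
    def test_matches_brute_force_enumeration(self, diffs):
        # perturb to break ties so the exact path is exercised
        rng = np.random.default_rng(abs(hash(tuple(diffs))) % 2**31)
        d = np.array(diffs, dtype=float) + rng.uniform(-0.3, 0.3, len(diffs))
        d = d[d != 0]
        if len(d) == 0:
            return
        assert wilcoxon_signed_rank(d).pvalue == pytest.approx(brute_force_two_sided_p(d))

    @given(st_h.lists(st_h.floats(-9, 9).filter(lambda x: abs(x) > 1e-6),
                      min_size=2, max_size=12))
    @settings(max_examples=80, deadline=None)
    def test_two_sided_symmetry_under_negation(self, diffs):
        assert wilcoxon_signed_rank(diffs).pvalue == pytest.approx(
            wilcoxon_signed_rank([-d for d in diffs]).pvalue
        )

    def test_tied_inputs_fall_back_to_approximation_matching_scipy(self):
        d = [1.0, 1.0, 2.0, -2.0, 3.0, 3.0, 3.0, -4.0, 5.0]
        ours = wilcoxon_signed_rank(d)
        ref = st.wilcoxon(d, alternative="two-sided", method="approx", correction=False)
        assert not ours.exact
        assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_exact_path_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            d = rng.normal(0.5, 1.0, int(rng.integers(3, 20)))
            ours = wilcoxon_signed_rank(d)
            ref = st.wilcoxon(d, alternative="two-sided", method="exact")
            assert ours.pvalue == pytest.approx(ref.pvalue)


def _records_from_counts(counts):
    """Expand {(label, group): (correct, total)} into individual records."""
    records = []
    i = 0
    for (label, group), (correct, total) in counts.items():
        for j in range(total):
            records.append(
                PairedStudyRecord(
                    case_id=f"c{i}-{j}", group=group, gold_label=label,
                    control_primary_correct=j < correct, test_primary_correct=True,
                )
            )
        i += 1
    return records


class TestScoreAccuracy:
    def test_row_and_margin_pooling(self):
        counts = {
            ("localized periodontitis stage III grade B", "DS3"): (10, 15),
            ("localized periodontitis stage III grade B", "DS4"): (2, 2),
            ("localized periodontitis stage III grade B", "ISP2"): (5, 8),
            ("generalized periodontitis stage IV grade B", "DS3"): (8, 22),
        }
        primary, _ = score_accuracy(_records_from_counts(counts))
        row = primary.rows["localized periodontitis stage III grade B"]
        assert (row["Total"].correct, row["Total"].total, row["Total"].percent) == (17, 25, 68.0)
        assert primary.pooled["Total"].correct == 25
        assert primary.pooled["Total"].total == 47

    def test_all_correct_gives_100_percent(self):
        counts = {("gingivitis", "DS3"): (4, 4)}
        primary, _ = score_accuracy(_records_from_counts(counts))
        assert primary.pooled["Total"].percent == 100.0

    def test_single_group_margins_consistent(self):
        counts = {("gingivitis", "ISP2"): (3, 5)}
        primary, _ = score_accuracy(_records_from_counts(counts))
        assert set(primary.pooled) == {"ISP2", "Total"}
        assert primary.pooled["ISP2"] == primary.pooled["Total"]

    def test_secondary_scored_per_incident(self):
        records = [
            PairedStudyRecord(
                case_id="a", group="DS3", gold_label="gingivitis",
                control_primary_correct=False, test_primary_correct=True,
                secondary_gold=frozenset({"occlusal_trauma", "mucogingival_deformity"}),
                secondary_found_control=frozenset({"occlusal_trauma"}),
                secondary_found_test=frozenset({"occlusal_trauma", "mucogingival_deformity"}),
            ),
            PairedStudyRecord(
                case_id="b", group="DS3", gold_label="gingivitis",
                control_primary_correct=False, test_primary_correct=True,
                secondary_gold=frozenset({"occlusal_trauma"}),
                secondary_found_control=frozenset(),
                secondary_found_test=frozenset({"occlusal_trauma"}),
            ),
        ]
        _, secondary = score_accuracy(records)
        # 3 incidents over 2 patients; control found 1
        assert secondary.pooled["Total"].total == 3
        assert secondary.pooled["Total"].correct == 1
        _, secondary_test = score_accuracy(records, condition="test")
        assert secondary_test.pooled["Total"].percent == 100.0

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            PairedStudyRecord(case_id="x", group="DS9", gold_label="g",
                              control_primary_correct=True, test_primary_correct=True)


class TestCompareConditions:
    def test_clear_improvement_rejected_at_alpha_001(self, rng):
        control = rng.normal(20, 10, 22)
        test = control + rng.normal(40, 5, 22)
        report = compare_conditions(control, test)
        assert report.reject and report.pvalue < 0.01
        assert report.test_mean > report.control_mean

    def test_identical_vectors_degenerate_not_rejected(self):
        v = [10.0, 20.0, 30.0]
        report = compare_conditions(v, v)
        assert report.degenerate and not report.reject

    def test_unpaired_input_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            compare_conditions([1.0, 2.0], [1.0])


def test_likert_summary_mean_and_range():
    out = summarize_likert([5, 4, 4, 5, 4, 4, 4])
    assert out["mean"] == 4.29
    assert out["range"] == (4, 5)
    with pytest.raises(ValueError):
        summarize_likert([0, 3])
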