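"""Positivity calls, tail-cut thresholds, exclusion filters and the
eight-state truth table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_quantile
from promoterpoise.state_classification import (
    MARKS,
    NA,
    NEGATIVE,
    POSITIVE,
    apply_exclusion_filters,
    call_positive,
    classify_all,
    classify_state,
    count_reads_in_window,
    positivity_threshold,
)

STATUSES = (POSITIVE, NEGATIVE)


class TestTruthTable:
    def test_eight_states_partition_the_combinations(self):
        seen = {}
        for triple in itertools.product(STATUSES, repeat=3):
            seen[triple] = classify_state(*triple)
        assert len(set(seen.values())) == 8

    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((POSITIVE, POSITIVE, NEGATIVE), "PRC_S5p"),
            ((POSITIVE, POSITIVE, POSITIVE), "PRC_Active"),
            ((POSITIVE, NEGATIVE, NEGATIVE), "PRC_Only"),
            ((POSITIVE, NEGATIVE, POSITIVE), "PRC_S7p"),
            ((NEGATIVE, POSITIVE, POSITIVE), "Active"),
            ((NEGATIVE, NEGATIVE, NEGATIVE), "Inactive"),
            ((NEGATIVE, POSITIVE, NEGATIVE), "S5p_Only"),
            ((NEGATIVE, NEGATIVE, POSITIVE), "S7p_Only"),
        ],
    )
    def test_state_logic(self, triple, expected):
        assert classify_state(*triple) == expected

    def test_na_propagates_from_any_mark(self):
        for i in range(3):
            triple = [POSITIVE, POSITIVE, POSITIVE]
            triple[i] = NA
            assert classify_state(*triple) == NA

    def test_invalid_status_rejected(self):
        with pytest.raises(ValueError):
            classify_state("yes", NEGATIVE, NEGATIVE)


class TestThreshold:
    def test_degenerate_distribution(self):
        assert positivity_threshold([7, 7, 7]) == 7

    def test_single_count(self):
        assert positivity_threshold([42]) == 42

    def test_matches_sort_based_oracle(self):
        counts = list(range(1, 101))
        assert positivity_threshold(counts) == pytest.approx(
            brute_force_quantile(counts, 0.05)
        )

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError, match="no overlapping genes"):
            positivity_threshold([])

    @given(st.lists(st.integers(0, 500), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=200)
    def test_oracle_agreement_on_random_vectors(self, counts):
        assert positivity_threshold(counts) == pytest.approx(
            brute_force_quantile(counts, 0.05)
        )


class TestCallPositive:
    def test_two_condition_rule(self):
        overlapped = np.array([True, False, True])
        counts = np.array([10.0, 10.0, 1.0])
        got = call_positive(overlapped, counts, threshold=5.0)
        assert got.tolist() == [True, False, False]

    def test_strict_vs_inclusive_at_the_threshold(self):
        overlapped = np.array([True])
        counts = np.array([5.0])
        assert not call_positive(overlapped, counts, 5.0)[0]
        assert call_positive(overlapped, counts, 5.0, inclusive=True)[0]

    @given(
        st.lists(st.integers(0, 100), min_size=1, max_size=30),
        st.integers(0, 100),
        st.integers(0, 100),
    )
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_threshold(self, counts, t1, t2):
        lo, hi = sorted((t1, t2))
        overlapped = np.ones(len(counts), dtype=bool)
        at_lo = call_positive(overlapped, np.array(counts, float), lo)
        at_hi = call_positive(overlapped, np.array(counts, float), hi)
        assert not (at_hi & ~at_lo).any()


def _calls(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "win_start", "win_end", "body_start", "body_end",
                 "count", "status"],
    )


class TestExclusionFilters:
    def test_large_window_overlap_removes_both(self):
        calls = _calls([
            ("a", "chr1", 0, 2000, 0, 8000, 50, POSITIVE),
            ("b", "chr1", 1500, 3500, 8001, 16000, 60, POSITIVE),  # 500 bp overlap
        ])
        out = apply_exclusion_filters(calls)
        assert set(out["status"]) == {NA}

    def test_150bp_overlap_is_tolerated_but_250_is_not(self):
        ok = _calls([
            ("a", "chr1", 0, 2000, 0, 5000, 50, POSITIVE),
            ("b", "chr1", 1850, 3850, 6000, 9000, 60, POSITIVE),
        ])
        assert (apply_exclusion_filters(ok)["status"] == POSITIVE).all()
        bad = _calls([
            ("a", "chr1", 0, 2000, 0, 5000, 50, POSITIVE),
            ("b", "chr1", 1750, 3750, 6000, 9000, 60, POSITIVE),
        ])
        assert (apply_exclusion_filters(bad)["status"] == NA).all()

    def test_exactly_200bp_overlap_is_tolerated(self):
        calls = _calls([
            ("a", "chr1", 0, 2000, 0, 5000, 50, POSITIVE),
            ("b", "chr1", 1800, 3800, 6000, 9000, 60, POSITIVE),
        ])
        assert (apply_exclusion_filters(calls)["status"] == POSITIVE).all()

    def test_internal_gene_removed_outer_kept(self):
        calls = _calls([
            ("outer", "chr1", 0, 2000, 0, 20_000, 50, POSITIVE),
            ("inner", "chr1", 7000, 9000, 8000, 12_000, 60, POSITIVE),
        ])
        out = apply_exclusion_filters(calls).set_index("gene")["status"]
        assert out["inner"] == NA
        assert out["outer"] == POSITIVE

    def test_negative_genes_are_untouched(self):
        calls = _calls([
            ("a", "chr1", 0, 2000, 0, 20_000, 50, NEGATIVE),
            ("b", "chr1", 0, 2000, 8000, 12_000, 60, POSITIVE),
        ])
        out = apply_exclusion_filters(calls).set_index("gene")["status"]
        assert out["a"] == NEGATIVE  # inner but not positive
        assert out["b"] == POSITIVE  # overlap partner not positive

    def test_lower_count_policy_keeps_the_stronger_gene(self):
        calls = _calls([
            ("weak", "chr1", 0, 2000, 0, 5000, 10, POSITIVE),
            ("strong", "chr1", 500, 2500, 6000, 9000, 99, POSITIVE),
        ])
        out = apply_exclusion_filters(calls, overlap_policy="lower_count")
        got = out.set_index("gene")["status"]
        assert got["weak"] == NA and got["strong"] == POSITIVE

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        n = 80
        starts = rng.integers(0, 50_000, n)
        calls = _calls([
            (f"g{i}", "chr1", s, s + 2000, s - 500, s + rng.integers(3000, 20_000),
             rng.integers(1, 100), POSITIVE if rng.random() < 0.7 else NEGATIVE)
            for i, s in enumerate(starts)
        ])
        once = apply_exclusion_filters(calls)
        twice = apply_exclusion_filters(once)
        pd.testing.assert_frame_equal(once, twice)


class TestClassifyAll:
    def _calls_long(self, statuses_by_gene, timepoints=("t1", "t2")):
        rows = []
        for gene, per_tp in statuses_by_gene.items():
            for tp, (k, f, s) in per_tp.items():
                rows += [
                    {"gene": gene, "mark": "H3K27me3", "timepoint": tp, "status": k},
                    {"gene": gene, "mark": "S5p", "timepoint": tp, "status": f},
                    {"gene": gene, "mark": "S7p", "timepoint": tp, "status": s},
                ]
        return pd.DataFrame(rows)

    def test_single_na_excludes_gene_from_analysis_set(self):
        calls = self._calls_long({
            "a": {"t1": (POSITIVE, POSITIVE, NEGATIVE), "t2": (NEGATIVE, NEGATIVE, NA)},
            "b": {"t1": (NEGATIVE,) * 3, "t2": (NEGATIVE,) * 3},
        })
        states, analysis = classify_all(calls, ("t1", "t2"))
        assert analysis == ["b"]
        assert set(states[states["gene"] == "b"]["state"]) == {"Inactive"}

    def test_missing_combination_is_an_error(self):
        calls = self._calls_long({"a": {"t1": (NEGATIVE,) * 3}})
        with pytest.raises(ValueError, match="missing"):
            classify_all(calls, ("t1", "t2"))


def test_count_reads_unknown_chromosome_warns_and_returns_zero(caplog):
    with caplog.at_level("WARNING"):
        got = count_reads_in_window({"chr1": np.array([1, 2, 3])}, "chrX", 0, 10)
    assert got == 0
    assert any("unknown chromosome" in r.message for r in caplog.records)
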