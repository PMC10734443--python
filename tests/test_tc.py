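"""Transcriptional-cluster calling: candidate filters, strand-aware
chaining against an exhaustive oracle, the rescue rule, summaries."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_de_frame, random_candidate_layout, tc_bruteforce
from redoxreg.models import GeneModel, GenomeAnnotation
from redoxreg.tc import (
    apply_rescue,
    call_tcs,
    select_candidates,
    summarize_affected,
    summarize_counts,
)


def annotation_of(*genes: tuple[str, int, int, str]) -> GenomeAnnotation:
    return GenomeAnnotation(GeneModel(g, "c1", s, e, st_) for g, s, e, st_ in genes)


def candidates_of(**fc: float) -> pd.DataFrame:
    df = pd.DataFrame({"fc": list(fc.values())}, index=pd.Index(fc.keys(), name="gene_id"))
    df["direction"] = np.where(df["fc"] < 0, "down", "up")
    return df


class TestSelectCandidates:
    @pytest.mark.parametrize(
        "fc,p,included",
        [
            (2.0, 0.049, True),   # fc threshold inclusive
            (-1.9, 0.001, False),  # below magnitude threshold
            (5.0, 0.05, False),   # p threshold strict
            (-2.0, 0.0499, True),
        ],
    )
    def test_threshold_edges(self, fc, p, included):
        de = make_de_frame({"g1": {"fc": fc, "pvalue": p}})
        out = select_candidates(de)
        assert ("g1" in out.index) is included

    def test_direction_assignment(self):
        de = make_de_frame({"a": {"fc": -3.0, "pvalue": 0.01}, "b": {"fc": 3.0, "pvalue": 0.01}})
        out = select_candidates(de)
        assert out.loc["a", "direction"] == "down" and out.loc["b", "direction"] == "up"


class TestCallTcs:
    def test_gap_partition_example(self):
        ann = annotation_of(("g1", 100, 500, "+"), ("g2", 600, 900, "+"), ("g3", 1300, 1500, "+"))
        tcs, isolated = call_tcs(candidates_of(g1=-3, g2=-4, g3=-5), ann)
        assert [t.members for t in tcs] == [("g1", "g2")]
        assert tcs[0].max_internal_gap == 99
        assert isolated == ["g3"]

    def test_strand_partition(self):
        ann = annotation_of(("g1", 100, 500, "+"), ("g2", 550, 800, "-"))
        tcs, isolated = call_tcs(candidates_of(g1=-3, g2=-4), ann)
        assert tcs == [] and sorted(isolated) == ["g1", "g2"]

    def test_direction_discordance(self):
        ann = annotation_of(("g1", 100, 500, "+"), ("g2", 600, 900, "+"))
        tcs, isolated = call_tcs(candidates_of(g1=3, g2=-4), ann)
        assert tcs == [] and sorted(isolated) == ["g1", "g2"]

    def test_gap_threshold_strict(self):
        # gap exactly 250 does not join; 249 does
        ann = annotation_of(("g1", 100, 500, "+"), ("g2", 751, 900, "+"))
        assert call_tcs(candidates_of(g1=-3, g2=-4), ann)[0] == []
        ann = annotation_of(("g1", 100, 500, "+"), ("g2", 750, 900, "+"))
        assert call_tcs(candidates_of(g1=-3, g2=-4), ann)[0][0].members == ("g1", "g2")

    def test_intervening_noncandidate_does_not_break_chain(self):
        # g_mid sits between the candidates but only the candidate-to-
        # candidate distance matters (here 199 < 250)
        ann = annotation_of(
            ("g1", 100, 500, "+"), ("g_mid", 520, 620, "+"), ("g2", 700, 900, "+")
        )
        tcs, _ = call_tcs(candidates_of(g1=-3, g2=-4), ann)
        assert tcs[0].members == ("g1", "g2")

    def test_missing_candidate_raises(self):
        ann = annotation_of(("g1", 100, 500, "+"))
        with pytest.raises(KeyError, match="ghost"):
            call_tcs(candidates_of(ghost=-3), ann)

    def test_avg_fc_and_span(self):
        ann = annotation_of(("g1", 100, 500, "-"), ("g2", 600, 900, "-"))
        tcs, _ = call_tcs(candidates_of(g1=-44, g2=-20), ann)
        tc = tcs[0]
        assert tc.avg_fc == pytest.approx(-32.0)
        assert tc.direction == "down"
        assert tc.span == (100, 900)

    @settings(max_examples=200)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        annotation, candidates, rows = random_candidate_layout(rng)
        tcs, isolated = call_tcs(candidates, annotation)
        oracle_tcs, oracle_iso = tc_bruteforce(rows)
        assert {t.members for t in tcs} == oracle_tcs
        assert set(isolated) == oracle_iso
        # partition: every candidate in exactly one TC or isolated
        covered = [m for t in tcs for m in t.members] + list(isolated)
        assert sorted(covered) == sorted(candidates.index)

    @settings(max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_gap_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        annotation, candidates, _ = random_candidate_layout(rng)
        n_prev = -1
        for gap in (50, 250, 600):
            tcs, _ = call_tcs(candidates, annotation, max_gap=gap)
            n_in = sum(t.size for t in tcs)
            assert n_in >= n_prev
            n_prev = n_in


class TestRescue:
    ann = annotation_of(("a", 100, 500, "+"), ("b", 600, 900, "+"), ("c", 5000, 5400, "+"))

    def de(self, padj_a, padj_b, padj_c=0.3):
        return make_de_frame(
            {
                "a": {"fc": -4.0, "pvalue": 0.01, "padj": padj_a},
                "b": {"fc": -3.0, "pvalue": 0.02, "padj": padj_b},
                "c": {"fc": -5.0, "pvalue": 0.03, "padj": padj_c},
            }
        )

    def test_rescued_member_included(self):
        de = self.de(0.01, 0.30)
        cand = select_candidates(de)
        tcs, _ = call_tcs(cand, self.ann)
        affected = apply_rescue(de, cand, tcs)
        assert affected.reasons == {"a": "bh_significant", "b": "tc_rescued"}
        assert affected.n_rescued == 1

    def test_isolated_failing_bh_excluded(self):
        de = self.de(0.01, 0.30, padj_c=0.30)
        cand = select_candidates(de)
        tcs, _ = call_tcs(cand, self.ann)
        affected = apply_rescue(de, cand, tcs)
        assert "c" not in affected.reasons

    def test_tc_without_significant_member_dropped(self):
        de = self.de(0.30, 0.40)
        cand = select_candidates(de)
        tcs, _ = call_tcs(cand, self.ann)
        affected = apply_rescue(de, cand, tcs)
        assert affected.n_affected == 0
        assert summarize_affected(affected, tcs, de)["n_tcs"] == 0

    def test_bh_threshold_monotonicity(self):
        de = self.de(0.04, 0.30, padj_c=0.06)
        cand = select_candidates(de)
        tcs, _ = call_tcs(cand, self.ann)
        n = [apply_rescue(de, cand, tcs, bh_threshold=t).n_affected for t in (0.01, 0.05, 0.1)]
        assert n == sorted(n)

    def test_rescued_genes_pass_raw_filters(self, recovery_result):
        # every rescue on the benchmark comes out of the candidate set
        assert recovery_result["n_rescued"] >= 1


class TestSummaries:
    def test_percentages_round_half_away(self):
        s = summarize_counts(273, 227, 47, 153, n_tcs=52, n_rescued=18)
        assert (s["pct_down"], s["pct_up"], s["pct_in_tcs"]) == (83, 17, 56)

    def test_empty_set_all_zero(self):
        s = summarize_counts(0, 0, 0, 0)
        assert all(s[k] == 0 for k in ("n_affected", "pct_down", "pct_up", "pct_in_tcs"))

    def test_largest_tcs_ordering(self):
        ann = annotation_of(
            ("a", 100, 500, "+"), ("b", 600, 900, "+"),
            ("c", 2000, 2400, "-"), ("d", 2500, 2900, "-"), ("e", 3000, 3400, "-"),
        )
        de = make_de_frame({g: {"fc": -4.0, "pvalue": 0.01, "padj": 0.01} for g in "abcde"})
        cand = select_candidates(de)
        tcs, _ = call_tcs(cand, ann)
        s = summarize_affected(apply_rescue(de, cand, tcs), tcs, de)
        assert [t["size"] for t in s["largest_tcs"]] == [3, 2]
        assert s["n_tcs"] == 2 and s["n_genes_in_tcs"] == 5
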