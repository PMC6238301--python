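"""Promoter definition: isolation filtering, CAGE TSS clustering,
tiered activity calling and matrix reduction."""

import numpy as np
import pandas as pd
import pytest

from promclust import promoters as pm
from promclust.signal import SignalMatrix


def tss_df(positions, strands=None, genes=None, chrom="chr1"):
    n = len(positions)
    return pd.DataFrame({
        "chrom": [chrom] * n,
        "pos": list(positions),
        "strand": strands or ["+"] * n,
        "gene_id": genes or [f"g{i}" for i in range(n)],
        "name": [f"t{i}" for i in range(n)],
    })


def cage_df(positions, strand="+", chrom="chr1", width=20):
    return pd.DataFrame({
        "chrom": [chrom] * len(positions),
        "start": list(positions),
        "end": [p + width for p in positions],
        "strand": [strand] * len(positions),
    })


EMPTY_CAGE = cage_df([])


class TestFilterIsolatedTSS:
    def test_close_pair_both_removed(self):
        out = pm.filter_isolated_tss(tss_df([1000, 1800]))
        assert len(out) == 0

    def test_single_tss_retained(self):
        out = pm.filter_isolated_tss(tss_df([1000]))
        assert len(out) == 1

    def test_spacing_above_threshold_retained(self):
        # pairwise distances 1500: all pass the <= 1000 rule
        out = pm.filter_isolated_tss(tss_df([0, 1500, 3000]))
        assert len(out) == 3

    def test_boundary_distance_exactly_1000_removed(self):
        out = pm.filter_isolated_tss(tss_df([0, 1000]))
        assert len(out) == 0

    def test_cross_strand_and_cross_gene(self):
        out = pm.filter_isolated_tss(
            tss_df([0, 500], strands=["+", "-"], genes=["a", "b"]))
        assert len(out) == 0

    def test_idempotent(self):
        t = tss_df([0, 800, 5000, 9000])
        once = pm.filter_isolated_tss(t)
        twice = pm.filter_isolated_tss(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_different_chromosomes_independent(self):
        t = pd.concat([tss_df([1000]), tss_df([1200], chrom="chr2")],
                      ignore_index=True)
        assert len(pm.filter_isolated_tss(t)) == 2


class TestCallActivity:
    def test_robust_peak_gives_active(self):
        assert pm.call_activity(5000, "chr1", cage_df([5100]),
                                cage_df([5100])) == "active"

    def test_permissive_only_gives_low(self):
        assert pm.call_activity(5000, "chr1", EMPTY_CAGE,
                                cage_df([4950])) == "low"

    def test_empty_window_gives_inactive(self):
        assert pm.call_activity(5000, "chr1", EMPTY_CAGE,
                                EMPTY_CAGE) == "inactive"

    def test_peak_outside_window_ignored(self):
        assert pm.call_activity(5000, "chr1", cage_df([5600]),
                                cage_df([5600])) == "inactive"

    def test_strand_specific_filtering(self):
        rob = cage_df([5100], strand="-")
        assert pm.call_activity(5000, "chr1", rob, rob,
                                strand="+") == "inactive"
        assert pm.call_activity(5000, "chr1", rob, rob,
                                strand="-") == "active"

    def test_robust_without_permissive_is_error(self):
        with pytest.raises(ValueError, match="permissive"):
            pm.call_activity(5000, "chr1", cage_df([5100]), EMPTY_CAGE)


class TestClusterCageTSS:
    def test_chain_same_gene_retained(self):
        cl = pm.cluster_cage_tss(tss_df([100, 250, 400],
                                        genes=["g", "g", "g"]))
        assert len(cl) == 1 and cl[0].retained and cl[0].span == 300

    def test_mixed_strand_excluded(self):
        cl = pm.cluster_cage_tss(tss_df([100, 250], strands=["+", "-"],
                                        genes=["g", "g"]))
        assert cl[0].status == "excluded"
        assert cl[0].exclusion_reason == "mixed_strand"

    def test_long_chain_excluded_by_span(self):
        # 7 TSSs at 190 bp gaps chain transitively: span 1140 > 1000
        pos = [i * 190 for i in range(7)]
        cl = pm.cluster_cage_tss(tss_df(pos, genes=["g"] * 7))
        assert len(cl) == 1
        assert cl[0].exclusion_reason == "span>1000"

    def test_multi_gene_excluded(self):
        cl = pm.cluster_cage_tss(tss_df([100, 250], genes=["a", "b"]))
        assert cl[0].exclusion_reason == "multi_gene"

    def test_missing_gene_excluded_not_error(self):
        cl = pm.cluster_cage_tss(tss_df([100, 250], genes=["a", None]))
        assert cl[0].exclusion_reason == "multi_gene_unresolvable"

    def test_gap_of_exactly_merge_gap_splits(self):
        cl = pm.cluster_cage_tss(tss_df([0, 200], genes=["a", "b"]))
        assert len(cl) == 2  # distance must be *shorter* than 200 bp

    def test_activity_on_extended_region_strand_specific(self):
        rob = cage_df([900], strand="+")
        cl = pm.cluster_cage_tss(tss_df([100, 250], genes=["g", "g"]),
                                 robust=rob, permissive=rob)
        # region [100,250] extends to [-400, 750]; robust peak at 900
        # overlaps? peak [900,920] vs window hi=750 -> no: inactive
        assert cl[0].status == "inactive"
        rob2 = cage_df([700], strand="+")
        cl2 = pm.cluster_cage_tss(tss_df([100, 250], genes=["g", "g"]),
                                  robust=rob2, permissive=rob2)
        assert cl2[0].status == "active"

    def test_retained_clusters_satisfy_invariants(self, toy_genome):
        cls = pm.cluster_cage_tss(toy_genome.tss, toy_genome.robust,
                                  toy_genome.permissive)
        for c in cls:
            if c.retained:
                assert c.span <= 1000
                assert len(set(c.members["strand"])) == 1
                assert len(set(c.members["gene_id"])) == 1


class TestReduceInactive:
    @staticmethod
    def matrix():
        vals = np.array([[0.0, 0.4, 0.4, 0.0],
                         [0.0, 0.2, 0.2, 0.0]])
        return SignalMatrix(vals, ["e1", "e2"], ["a", "b", "c", "d"])

    def test_inactive_all_zero_dropped(self):
        out = pm.reduce_inactive(self.matrix(),
                                 {"a": "inactive", "b": "active",
                                  "c": "active", "d": "active"})
        assert out.col_ids == ["b", "c", "d"]

    def test_active_all_zero_retained(self):
        out = pm.reduce_inactive(self.matrix(), {"a": "active"})
        assert "a" in out.col_ids

    def test_duplicate_columns_in_cluster_collapse(self):
        out = pm.reduce_inactive(self.matrix(), {},
                                 cluster_of={"b": "cl1", "c": "cl1"})
        assert out.col_ids == ["a", "b", "d"]

    def test_identical_columns_in_different_clusters_kept(self):
        out = pm.reduce_inactive(self.matrix(), {},
                                 cluster_of={"b": "cl1", "c": "cl2"})
        assert out.col_ids == ["a", "b", "c", "d"]


class TestToyGenomeAgreement:
    def test_refseq_isolation_matches_truth(self, toy_genome):
        retained = pm.filter_isolated_tss(toy_genome.tss)
        got = set(retained["name"])
        for name, expect in toy_genome.truth["refseq_retained"].items():
            assert (name in got) == expect, name

    def test_tss_activity_matches_truth(self, toy_genome):
        for _, row in toy_genome.tss.iterrows():
            status = pm.call_activity(row["pos"], row["chrom"],
                                      toy_genome.robust,
                                      toy_genome.permissive)
            assert status == toy_genome.truth["activity"][row["name"]]

    def test_cluster_statuses_match_truth(self, toy_genome):
        cls = pm.cluster_cage_tss(toy_genome.tss, toy_genome.robust,
                                  toy_genome.permissive)
        truth = toy_genome.truth["clusters"]
        for c in cls:
            gene = c.members["gene_id"].iloc[0]
            expect = truth[gene]
            assert c.status == expect["status"], gene
            if expect["reason"]:
                assert c.exclusion_reason == expect["reason"], gene

    def test_every_exclusion_rule_fires(self, toy_genome):
        cls = pm.cluster_cage_tss(toy_genome.tss, toy_genome.robust,
                                  toy_genome.permissive)
        reasons = {c.exclusion_reason for c in cls if not c.retained}
        assert {"span>1000", "mixed_strand", "multi_gene"} <= reasons
        statuses = {c.status for c in cls if c.retained}
        assert {"active", "inactive", "low"} <= statuses
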