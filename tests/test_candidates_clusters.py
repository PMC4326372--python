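import numpy as np
import pandas as pd
import pytest

from cosreg.candidates_clusters import (
    CandidateList,
    build_candidates,
    build_clusters,
    clusters_to_frame,
    support_distribution,
)
from cosreg.cosine_engine import SimilarityTable


def table_from_tails(tails: dict, comparison_id="E7fe_vs_E9se") -> SimilarityTable:
    """Hand-built SimilarityTable: tails maps seed -> (co tuple, recip tuple)."""
    probes = sorted(
        set(tails) | {p for co, recip in tails.values() for p in (*co, *recip)}
    )
    probe_ids = pd.Index(probes)
    return SimilarityTable(
        comparison_id=comparison_id,
        seed_ids=sorted(tails),
        probe_ids=probe_ids,
        cosines=np.zeros((len(tails), len(probes))),
        tails={s: (tuple(co), tuple(recip)) for s, (co, recip) in tails.items()},
        tail_fraction=0.005,
    )


def candidate_list_of(probes, comparison_id="E7fe_vs_E9se") -> CandidateList:
    table = pd.DataFrame(
        {
            "probe_id": sorted(probes),
            "n_co_seeds": 0,
            "n_recip_seeds": 0,
            "support": 0,
            "polarity": "mixed",
        }
    )
    return CandidateList(comparison_id=comparison_id, table=table, min_seed_support=0)


class TestBuildCandidates:
    def make_support_table(self, n_co, n_recip, probe="x"):
        tails = {}
        for i in range(n_co):
            tails[f"co_seed{i}"] = ((probe,), ())
        for i in range(n_recip):
            tails[f"re_seed{i}"] = ((), (probe,))
        return table_from_tails(tails)

    @pytest.mark.parametrize(
        "n_co,n_recip,retained", [(12, 0, True), (9, 0, False), (6, 4, True), (5, 4, False)]
    )
    def test_support_threshold_inclusive_at_ten(self, n_co, n_recip, retained):
        table = self.make_support_table(n_co, n_recip)
        candidates = build_candidates(table, min_seed_support=10)
        if retained:
            row = candidates.table.set_index("probe_id").loc["x"]
            assert row.support == n_co + n_recip
            assert row.n_co_seeds == n_co and row.n_recip_seeds == n_recip
        else:
            assert "x" not in candidates.probe_ids

    @pytest.mark.parametrize(
        "n_co,n_recip,polarity",
        [(8, 3, "co_dominant"), (3, 8, "recip_dominant"), (5, 5, "mixed")],
    )
    def test_polarity_by_majority(self, n_co, n_recip, polarity):
        table = self.make_support_table(n_co, n_recip)
        candidates = build_candidates(table, min_seed_support=1)
        assert candidates.table.set_index("probe_id").loc["x", "polarity"] == polarity

    def test_min_support_below_one_is_error(self):
        with pytest.raises(ValueError, match="min_seed_support"):
            build_candidates(self.make_support_table(2, 0), min_seed_support=0)

    def test_raising_support_never_grows_list(self, default_run):
        for table in default_run["tables"].values():
            sizes = [
                len(build_candidates(table, min_seed_support=k)) for k in (1, 5, 10, 20)
            ]
            assert sizes == sorted(sizes, reverse=True)

    def test_exclusive_convention_via_threshold_eleven(self):
        table = self.make_support_table(10, 0)
        assert len(build_candidates(table, min_seed_support=10)) == 1
        assert len(build_candidates(table, min_seed_support=11)) == 0


class TestBuildClusters:
    def test_mutual_co_tails_merge_with_gene_union(self):
        tails = {
            "s1": (("s2", "g1", "g2"), ()),
            "s2": (("s1", "g3"), ()),
        }
        table = table_from_tails(tails)
        clusters = build_clusters(table, candidate_list_of(["g1", "g2", "g3"]))
        assert len(clusters) == 1
        cluster = clusters[0]
        assert set(cluster.seed_ids) == {"s1", "s2"}
        assert set(cluster.gene_ids) == {"g1", "g2", "g3"}
        assert cluster.seed_signs == {"s1": 1, "s2": 1}
        assert cluster.sign_consistent

    def test_reciprocal_pair_records_negative_sign(self):
        tails = {
            "s1": ((), ("s2", "g1")),
            "s2": ((), ("s1",)),
        }
        clusters = build_clusters(table_from_tails(tails), candidate_list_of(["g1"]))
        assert len(clusters) == 1
        assert clusters[0].seed_signs == {"s1": 1, "s2": -1}
        assert clusters[0].sign_consistent

    def test_no_seed_relations_one_cluster_per_overlapping_seed(self):
        tails = {
            "s1": (("g1",), ()),
            "s2": (("g2",), ()),
            "s3": (("g_not_candidate",), ()),
        }
        clusters = build_clusters(table_from_tails(tails), candidate_list_of(["g1", "g2"]))
        assert len(clusters) == 2
        assert all(len(c.seed_ids) == 1 for c in clusters)

    def test_transitive_merge_over_seed_chain(self):
        tails = {
            "s1": (("s2", "g1"), ()),
            "s2": (("s3",), ()),
            "s3": ((), ("g2",)),
        }
        clusters = build_clusters(table_from_tails(tails), candidate_list_of(["g1", "g2"]))
        assert len(clusters) == 1
        assert set(clusters[0].seed_ids) == {"s1", "s2", "s3"}

    def test_odd_negative_cycle_reported_mixed_not_resolved(self):
        # s1~s2 and s2~s3 co (+1), s1~s3 reciprocal (-1): no consistent signs
        tails = {
            "s1": (("s2", "g1"), ("s3",)),
            "s2": (("s3",), ()),
            "s3": ((), ()),
        }
        clusters = build_clusters(table_from_tails(tails), candidate_list_of(["g1"]))
        assert len(clusters) == 1
        assert not clusters[0].sign_consistent

    def test_empty_candidates_gives_no_clusters(self):
        tails = {"s1": (("g1",), ())}
        assert build_clusters(table_from_tails(tails), candidate_list_of([])) == []

    def test_genes_never_appear_from_nowhere(self, default_run):
        for comparison_id, table in default_run["tables"].items():
            candidates = default_run["candidates"][comparison_id]
            candidate_set = set(candidates.probe_ids)
            for cluster in build_clusters(table, candidates):
                allowed = set()
                for seed in cluster.seed_ids:
                    co, recip = table.tails[seed]
                    allowed |= (set(co) | set(recip)) & candidate_set
                assert set(cluster.gene_ids) <= allowed

    def test_gene_may_belong_to_multiple_clusters(self):
        tails = {
            "s1": (("shared",), ()),
            "s2": ((), ("shared",)),
        }
        clusters = build_clusters(table_from_tails(tails), candidate_list_of(["shared"]))
        assert len(clusters) == 2
        assert all("shared" in c.gene_ids for c in clusters)

    def test_flat_frame_lists_seeds_and_genes(self):
        tails = {"s1": (("g1",), ())}
        clusters = build_clusters(table_from_tails(tails), candidate_list_of(["g1"]))
        frame = clusters_to_frame(clusters)
        assert set(frame["role"]) == {"seed", "gene"}
        assert set(frame["member_id"]) == {"s1", "g1"}


class TestSupportDistribution:
    def test_all_single_support(self):
        tails = {"s1": (("a",), ()), "s2": (("b",), ("c",))}
        dist = support_distribution(table_from_tails(tails))
        assert dist.set_index("n_seeds")["n_probes"].to_dict() == {1: 3}

    def test_counts_sum_to_probes_in_any_tail(self, default_run):
        for comparison_id, table in default_run["tables"].items():
            dist = support_distribution(table)
            assert dist["n_probes"].sum() == len(table.tail_members())

    def test_planted_modules_produce_heavy_support_tail(self, default_run):
        """Module members share many seeds, so support extends beyond 10."""
        heavy = 0
        for table in default_run["tables"].values():
            dist = support_distribution(table)
            heavy += dist.loc[dist["n_seeds"] > 10, "n_probes"].sum()
        assert heavy > 100
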