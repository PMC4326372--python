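"""Shortlisting and exploratory grouping of tail probes.

A probe becomes a candidate when it sits in the co- or reciprocal tail of at
least ``min_seed_support`` distinct seeds (default 10, inclusive — the
shared-seed filter that suppresses one-off correlations). Seeds are then
grouped with the candidate genes in their tails, and groups merge when their
seeds appear in each other's tails, carrying a polarity sign (+1 co, -1
reciprocal); sign conflicts within a merged cluster are recorded as mixed
rather than resolved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .cosine_engine import SimilarityTable

POLARITY_CO = "co_dominant"
POLARITY_RECIP = "recip_dominant"
POLARITY_MIXED = "mixed"


@dataclass
class CandidateList:
    """Probes supported by >= min_seed_support seeds for one comparison.

    ``table`` columns: probe_id, n_co_seeds, n_recip_seeds, support,
    polarity; sorted by probe_id.
    """

    comparison_id: str
    table: pd.DataFrame
    min_seed_support: int

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class Cluster:
    """A connected group of seeds plus the candidate genes in their tails."""

    cluster_id: str
    comparison_id: str
    seed_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    seed_signs: dict[str, int] = field(default_factory=dict)
    sign_consistent: bool = True


def _support_counts(table: SimilarityTable) -> pd.DataFrame:
    """Distinct-seed co/reciprocal support per probe (probes with support >= 1)."""
    co_counter: Counter[str] = Counter()
    recip_counter: Counter[str] = Counter()
    for co, recip in table.tails.values():
        co_counter.update(co)
        recip_counter.update(recip)
    probes = sorted(set(co_counter) | set(recip_counter))
    return pd.DataFrame(
        {
            "probe_id": probes,
            "n_co_seeds": [co_counter.get(p, 0) for p in probes],
            "n_recip_seeds": [recip_counter.get(p, 0) for p in probes],
        }
    )


def build_candidates(table: SimilarityTable, min_seed_support: int = 10) -> CandidateList:
    """Retain probes present in the tails of >= min_seed_support distinct seeds.

    Co and reciprocal tails both count toward support. Polarity is
    co_dominant / recip_dominant by majority, mixed on a tie.
    """
    if min_seed_support < 1:
        raise ValueError("min_seed_support must be a positive integer")
    counts = _support_counts(table)
    counts["support"] = counts["n_co_seeds"] + counts["n_recip_seeds"]
    retained = counts[counts["support"] >= min_seed_support].reset_index(drop=True)

    def polarity(row) -> str:
        if row.n_co_seeds > row.n_recip_seeds:
            return POLARITY_CO
        if row.n_co_seeds < row.n_recip_seeds:
            return POLARITY_RECIP
        return POLARITY_MIXED

    retained["polarity"] = [polarity(r) for r in retained.itertuples()]
    return CandidateList(
        comparison_id=table.comparison_id,
        table=retained,
        min_seed_support=min_seed_support,
    )


def build_clusters(table: SimilarityTable, candidates: CandidateList) -> list[Cluster]:
    """Group seeds with their candidate tail genes; merge linked seed groups.

    Each seed forms a group of itself plus its tail genes restricted to the
    candidate list. Two groups merge when either seed appears in the other's
    tail (symmetrized), with edge sign +1 for a co tail and -1 for a
    reciprocal tail (-1 wins if the two directions disagree, flagging the
    pair as conflicting). Merging is transitive over the seed-seed relation;
    per-seed polarity signs are propagated from an arbitrary anchor seed and
    any inconsistency is reported via ``sign_consistent=False`` ("mixed"),
    not resolved. A gene may belong to several clusters. Seeds with no
    candidate overlap and no seed-seed link form no cluster.
    """
    if len(candidates) == 0:
        return []
    candidate_set = set(candidates.probe_ids)
    seed_set = set(table.seed_ids)

    groups = {
        seed: (set(co) | set(recip)) & candidate_set
        for seed, (co, recip) in table.tails.items()
    }

    graph = nx.Graph()
    graph.add_nodes_from(table.seed_ids)
    for seed, (co, recip) in table.tails.items():
        for other in set(co) & seed_set:
            _add_signed_edge(graph, seed, other, +1)
        for other in set(recip) & seed_set:
            _add_signed_edge(graph, seed, other, -1)

    clusters: list[Cluster] = []
    counter = 0
    for component in sorted(nx.connected_components(graph), key=lambda c: min(c)):
        members = sorted(component)
        genes = set().union(*(groups[s] for s in members))
        if len(members) == 1 and not genes:
            continue
        signs, consistent = _propagate_signs(graph, members)
        counter += 1
        clusters.append(
            Cluster(
                cluster_id=f"{table.comparison_id}:C{counter:03d}",
                comparison_id=table.comparison_id,
                seed_ids=tuple(members),
                gene_ids=tuple(sorted(genes)),
                seed_signs=signs,
                sign_consistent=consistent,
            )
        )
    return clusters


def _add_signed_edge(graph: nx.Graph, u: str, v: str, sign: int) -> None:
    if u == v:
        return
    if graph.has_edge(u, v):
        if graph.edges[u, v]["sign"] != sign:
            graph.edges[u, v]["sign"] = -1
            graph.edges[u, v]["conflict"] = True
    else:
        graph.add_edge(u, v, sign=sign, conflict=False)


def _propagate_signs(graph: nx.Graph, members: list[str]) -> tuple[dict[str, int], bool]:
    """BFS sign assignment relative to the lexicographically first seed."""
    anchor = members[0]
    signs = {anchor: +1}
    consistent = True
    for u, v in nx.bfs_edges(graph, anchor):
        signs[v] = signs[u] * graph.edges[u, v]["sign"]
    for u, v, data in graph.subgraph(members).edges(data=True):
        if data.get("conflict") or signs[u] * signs[v] != data["sign"]:
            consistent = False
    return signs, consistent


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Flatten clusters into (comparison, cluster_id, role, member_id, sign...)."""
    records = []
    for cluster in clusters:
        for seed in cluster.seed_ids:
            records.append(
                {
                    "comparison": cluster.comparison_id,
                    "cluster_id": cluster.cluster_id,
                    "role": "seed",
                    "member_id": seed,
                    "sign": cluster.seed_signs.get(seed, 1),
                    "sign_consistent": cluster.sign_consistent,
                }
            )
        for gene in cluster.gene_ids:
            records.append(
                {
                    "comparison": cluster.comparison_id,
                    "cluster_id": cluster.cluster_id,
                    "role": "gene",
                    "member_id": gene,
                    "sign": 0,
                    "sign_consistent": cluster.sign_consistent,
                }
            )
    columns = ["comparison", "cluster_id", "role", "member_id", "sign", "sign_consistent"]
    return pd.DataFrame.from_records(records, columns=columns)


def support_distribution(table: SimilarityTable) -> pd.DataFrame:
    """Histogram of probes by exact number of supporting seeds (k = 1...max).

    Counts sum to the number of probes appearing in at least one tail.
    """
    counts = _support_counts(table)
    support = counts["n_co_seeds"] + counts["n_recip_seeds"]
    hist = support.value_counts().sort_index()
    return pd.DataFrame(
        {
            "comparison": table.comparison_id,
            "n_seeds": hist.index.astype(int),
            "n_probes": hist.to_numpy(),
        }
    )
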