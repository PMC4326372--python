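"""Hypergeometric gene-set enrichment and cross-comparison pathway ranking.

For a query list of n genes drawn from a universe of N genes, K of which
carry a set's annotation, the upper-tail hypergeometric probability of
observing at least k annotated genes is

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n).

Raw p-values drive the cross-comparison ranking (pathways ordered by how
many comparisons reach p < alpha, ties by smallest p); Benjamini-Hochberg
q-values are reported alongside.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "comparison", "set_name", "N", "K", "n", "k", "p_value", "q_value",
]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Delegates to scipy's survival function, which works in log space and is
    stable for genome-scale N. Validates 0 <= k <= min(K, n) <= N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid urn: N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    comparison_id: str = "",
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of a query gene list against every set.

    ``universe``, when given, is the explicit identifier universe: query and
    set members outside it are dropped (with a logged count) and N becomes
    its size; otherwise N is ``sets.universe_size`` and the query is used as
    supplied. Returns one row per set with BH-adjusted q-values, sorted by
    p ascending (ties by set name). Raises on an empty query.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query gene list")
    if universe is not None:
        universe_set = set(universe)
        dropped = len(query_set - universe_set)
        if dropped:
            logger.info("%d query genes outside the universe dropped", dropped)
        query_set &= universe_set
        if not query_set:
            raise ValueError("no query genes remain inside the universe")
        N = len(universe_set)
    else:
        universe_set = None
        N = sets.universe_size

    records = []
    for name in sorted(sets.sets):
        members = sets.sets[name]
        if universe_set is not None:
            members = members & universe_set
        K = min(len(members), N)
        k = len(query_set & members)
        n = len(query_set)
        records.append(
            {
                "comparison": comparison_id,
                "set_name": name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p_value": hypergeom_upper(N, K, n, k),
            }
        )
    frame = pd.DataFrame.from_records(records, columns=ENRICHMENT_COLUMNS[:-1])
    if len(frame):
        frame["q_value"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["q_value"] = []
    return frame.sort_values(
        ["p_value", "set_name"], kind="mergesort", ignore_index=True
    )


def rank_pathways(
    results: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank gene sets by the number of comparisons significant at raw p < alpha.

    ``results`` maps comparison id to an enrichment table (or is a sequence
    of tables carrying a ``comparison`` column). Sets are ordered by
    n_significant_comparisons descending, ties by the minimum p-value across
    comparisons ascending, then set name. Per-comparison p-values are
    returned in columns ``p_<comparison>``.
    """
    if isinstance(results, Mapping):
        frames = []
        for comparison_id, frame in results.items():
            frame = frame.copy()
            frame["comparison"] = comparison_id
            frames.append(frame)
    else:
        frames = [f.copy() for f in results]
    if not 1 <= len(frames) <= 4:
        raise ValueError("rank_pathways expects 1-4 comparison result tables")
    combined = pd.concat(frames, ignore_index=True)
    pivot = combined.pivot_table(
        index="set_name", columns="comparison", values="p_value", aggfunc="min"
    )
    n_significant = (pivot < alpha).sum(axis=1)
    min_p = pivot.min(axis=1)
    ranking = pd.DataFrame(
        {
            "set_name": pivot.index,
            "n_significant_comparisons": n_significant.to_numpy(dtype=int),
            "min_p": min_p.to_numpy(),
        }
    )
    for comparison_id in pivot.columns:
        ranking[f"p_{comparison_id}"] = pivot[comparison_id].to_numpy()
    ranking = ranking.sort_values(
        ["n_significant_comparisons", "min_p", "set_name"],
        ascending=[False, True, True],
        kind="mergesort",
        ignore_index=True,
    )
    ranking.insert(0, "rank", range(1, len(ranking) + 1))
    return ranking
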