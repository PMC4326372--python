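"""Cosine-similarity screen: score every probe against every seed.

Each probe is a point in sample space (20 dimensions under the canonical
design). The similarity of two probes a and b is

    cos(theta) = a . b / (|a| |b|) = sum_k a_k b_k / sqrt(sum_k a_k^2 sum_k b_k^2)

so +1 marks co-regulation, -1 reciprocal regulation, 0 no concordance.
Cosines are variance-stabilized with the Fisher transform z = arctanh(r)
and, per seed, the ceil(0.005 * P) largest / smallest values form the co- /
reciprocal tails ("top 0.5% and bottom 0.5%", 1% of the probe set per seed).

By default probe vectors are mean-centered across samples first. Raw log2
intensities are strictly positive, which confines the cosine to [0, 1] and
makes the reciprocal tail vacuous; after centering the cosine equals the
Pearson correlation of the raw rows and both tails are realizable. The
uncentered mode is retained behind a flag for convention comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix
from .seeds import SeedSet

logger = logging.getLogger(__name__)

TAIL_CO = "co"
TAIL_RECIPROCAL = "reciprocal"

#: magnitude at which cosines are clipped before arctanh, keeping z finite
FISHER_CLIP = 1.0 - 1e-7

#: histogram convention: 16 even bins from -1 to 1 (width 0.125)
HISTOGRAM_EDGES = np.linspace(-1.0, 1.0, 17)


def cosine(a, b) -> float:
    """Cosine similarity of two equal-length vectors, clipped to [-1, 1].

    Raises ``ValueError`` on length mismatch or a zero-norm vector (zero-norm
    probes must be excluded upstream).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    norm_a = np.linalg.norm(a)
    norm_b = np.linalg.norm(b)
    if norm_a == 0.0 or norm_b == 0.0:
        raise ValueError("cosine undefined for a zero-norm vector")
    return float(np.clip(np.dot(a, b) / (norm_a * norm_b), -1.0, 1.0))


def center_probes(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Subtract each probe row's across-sample mean.

    Returns the centered matrix and the probe_ids whose rows have zero
    variance (zero norm after centering); those must be excluded from
    similarity scoring.
    """
    values = matrix.values()
    centered = values - values.mean(axis=1, keepdims=True)
    flagged_mask = np.all(centered == 0.0, axis=1)
    flagged = list(matrix.probe_ids[flagged_mask].astype(str))
    if flagged:
        logger.warning("%d zero-variance probes flagged for exclusion", len(flagged))
    frame = pd.DataFrame(centered, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, matrix.design), flagged


def fisher_z(r):
    """Fisher transform z = arctanh(r) = 0.5 * ln((1+r)/(1-r)).

    Magnitudes at or beyond 1 - 1e-7 are clipped to 1 - 1e-7, which keeps z
    finite while preserving order. Accepts scalars or arrays.
    """
    arr = np.clip(np.asarray(r, dtype=float), -FISHER_CLIP, FISHER_CLIP)
    out = np.arctanh(arr)
    if np.isscalar(r) or np.ndim(r) == 0:
        return float(out)
    return out


@dataclass
class SimilarityTable:
    """Per-(seed, probe) cosine screen results for one comparison.

    ``cosines`` is the dense seed x probe matrix (probes in ``probe_ids``
    order, zero-variance probes already removed). ``tails`` maps each seed to
    its (co, reciprocal) probe-id tuples; self-comparisons are excluded.
    """

    comparison_id: str
    seed_ids: list[str]
    probe_ids: pd.Index
    cosines: np.ndarray
    tails: dict[str, tuple[tuple[str, ...], tuple[str, ...]]]
    tail_fraction: float
    excluded_probes: list[str] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def z_values(self) -> np.ndarray:
        return fisher_z(self.cosines)

    def tail_members(self) -> set[str]:
        """Distinct probes appearing in at least one seed's tail."""
        members: set[str] = set()
        for co, recip in self.tails.values():
            members.update(co)
            members.update(recip)
        return members

    def to_tail_frame(self) -> pd.DataFrame:
        """Tail entries as a flat table (the on-disk representation)."""
        probe_pos = {p: i for i, p in enumerate(self.probe_ids)}
        seed_pos = {s: i for i, s in enumerate(self.seed_ids)}
        records = []
        for seed_id in self.seed_ids:
            co, recip = self.tails[seed_id]
            for tail, ids in ((TAIL_CO, co), (TAIL_RECIPROCAL, recip)):
                for probe_id in ids:
                    c = self.cosines[seed_pos[seed_id], probe_pos[probe_id]]
                    records.append(
                        {
                            "comparison": self.comparison_id,
                            "seed_id": seed_id,
                            "probe_id": probe_id,
                            "cosine": c,
                            "z": fisher_z(c),
                            "tail": tail,
                        }
                    )
        columns = ["comparison", "seed_id", "probe_id", "cosine", "z", "tail"]
        return pd.DataFrame.from_records(records, columns=columns)


@dataclass
class CosineHistogram:
    """Counts of pooled (seed, probe) cosines in 16 even bins over [-1, 1]."""

    comparison_id: str
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "comparison": self.comparison_id,
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def _tail_indices(scores: np.ndarray, probe_rank: np.ndarray, n_tail: int,
                  exclude: int | None) -> np.ndarray:
    """Indices of the ``n_tail`` largest scores, ties broken by probe rank."""
    order = np.lexsort((probe_rank, -scores))
    if exclude is not None:
        order = order[order != exclude]
    return order[:n_tail]


def similarity_table(
    matrix: ExpressionMatrix,
    seed_set: SeedSet,
    tail_fraction: float = 0.005,
    center: bool = True,
    pooled_tails: bool = False,
) -> SimilarityTable:
    """Score all probes against each seed and mark the co/reciprocal tails.

    Per seed, the ``ceil(tail_fraction * P)`` probes with the largest Fisher z
    are the co tail and the same number with the smallest z the reciprocal
    tail (P = number of scored probes; arctanh is monotone, so ranking on z
    and on cosine agree). The seed's self-comparison is excluded; ties at the
    cut break by lexicographic probe_id. With ``pooled_tails`` the cutoffs
    come instead from the pooled cosine distribution over all (seed, probe)
    pairs of the seed group.
    """
    if not (0.0 < tail_fraction < 0.5):
        raise ValueError("tail_fraction must lie in (0, 0.5)")
    work = matrix
    if center:
        work, flagged = center_probes(matrix)
    else:
        values = work.values()
        flagged = list(work.probe_ids[np.linalg.norm(values, axis=1) == 0.0].astype(str))
    if flagged:
        keep = ~work.probe_ids.isin(flagged)
        work = ExpressionMatrix(work.data.loc[keep], work.design)

    probe_ids = work.probe_ids.astype(str)
    missing = [s for s in seed_set.probe_ids if s not in set(probe_ids)]
    if missing:
        raise ValueError(
            f"seed probes absent from matrix (or zero-variance): {missing[:5]}"
        )

    values = work.values()
    norms = np.linalg.norm(values, axis=1, keepdims=True)
    unit = values / norms
    probe_index = pd.Index(probe_ids)
    seed_ids = list(seed_set.probe_ids)
    seed_rows = probe_index.get_indexer(seed_ids)
    cosines = np.clip(unit[seed_rows] @ unit.T, -1.0, 1.0)

    n_probes = len(probe_index)
    n_tail = math.ceil(tail_fraction * n_probes)
    # lexicographic rank of each probe id, for deterministic tie-breaking
    probe_rank = np.argsort(np.argsort(probe_index.to_numpy()))

    tails: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {}
    if pooled_tails and seed_ids:
        pooled = cosines.flatten()
        hi = np.sort(pooled)[-math.ceil(tail_fraction * pooled.size)]
        lo = np.sort(pooled)[math.ceil(tail_fraction * pooled.size) - 1]
    for row, seed_id in enumerate(seed_ids):
        scores = cosines[row]
        self_idx = int(seed_rows[row])
        if pooled_tails:
            co_mask = scores >= hi
            recip_mask = scores <= lo
            co_mask[self_idx] = recip_mask[self_idx] = False
            co_idx = np.nonzero(co_mask)[0]
            recip_idx = np.nonzero(recip_mask)[0]
        else:
            co_idx = _tail_indices(scores, probe_rank, n_tail, self_idx)
            recip_idx = _tail_indices(-scores, probe_rank, n_tail, self_idx)
        tails[seed_id] = (
            tuple(probe_index[co_idx]),
            tuple(probe_index[recip_idx]),
        )

    return SimilarityTable(
        comparison_id=seed_set.comparison.id,
        seed_ids=seed_ids,
        probe_ids=probe_index,
        cosines=cosines,
        tails=tails,
        tail_fraction=tail_fraction,
        excluded_probes=flagged,
    )


def cosine_histogram(table: SimilarityTable) -> CosineHistogram:
    """Tally pooled (seed, probe) cosines into 16 even bins from -1 to 1.

    Bins are half-open [edge_k, edge_{k+1}) with the last bin closed at 1
    (numpy's histogram convention); counts sum to the number of pairs.
    """
    counts, _ = np.histogram(table.cosines.flatten(), bins=HISTOGRAM_EDGES)
    return CosineHistogram(
        comparison_id=table.comparison_id,
        bin_edges=HISTOGRAM_EDGES.copy(),
        counts=counts,
    )
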