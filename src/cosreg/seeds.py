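"""Seed selection: probes differentially expressed between matched groups.

A probe is a "seed" for a comparison when its group-mean log2 expression
difference exceeds log2(fold_threshold) in magnitude (strictly greater than,
default 5-fold). The four canonical comparisons pair feather- and
scale-forming skin of matched developmental plasticity, within compartment:
E7fe vs E9se, E7fm vs E9sm, E9fe vs E11se, E9fm vs E11sm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .preprocess import GroupMeans

UP_IN_A = "up_in_a"
UP_IN_B = "up_in_b"


@dataclass(frozen=True)
class Comparison:
    id: str
    group_a: str
    group_b: str


CANONICAL_COMPARISONS: tuple[Comparison, ...] = (
    Comparison("E7fe_vs_E9se", "E7fe", "E9se"),
    Comparison("E7fm_vs_E9sm", "E7fm", "E9sm"),
    Comparison("E9fe_vs_E11se", "E9fe", "E11se"),
    Comparison("E9fm_vs_E11sm", "E9fm", "E11sm"),
)

COMPARISON_BY_ID = {c.id: c for c in CANONICAL_COMPARISONS}


@dataclass
class SeedSet:
    """Differentially expressed probes for one comparison.

    ``table`` has columns probe_id, log2_difference (mean_a - mean_b) and
    direction (up_in_a / up_in_b), sorted by probe_id.
    """

    comparison: Comparison
    table: pd.DataFrame
    fold_threshold: float

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)


def select_seeds(
    means: GroupMeans, comparison: Comparison, fold_threshold: float = 5.0
) -> SeedSet:
    """Select probes with |group-mean difference| strictly above log2(fold_threshold).

    Fold change is computed from log2 group means, i.e. ``2**(mean_a - mean_b)``
    on the linear scale; a probe exactly at the threshold is not a seed.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be greater than 1")
    for group in (comparison.group_a, comparison.group_b):
        if group not in means.groups:
            raise ValueError(f"group {group!r} absent from group means")
    cutoff = math.log2(fold_threshold)
    diff = means.means[comparison.group_a] - means.means[comparison.group_b]
    selected = diff[diff.abs() > cutoff]
    table = pd.DataFrame(
        {
            "probe_id": selected.index.astype(str),
            "log2_difference": selected.to_numpy(),
            "direction": [UP_IN_A if d > 0 else UP_IN_B for d in selected.to_numpy()],
        }
    ).sort_values("probe_id", kind="mergesort", ignore_index=True)
    return SeedSet(comparison=comparison, table=table, fold_threshold=fold_threshold)


def seeds_to_frame(seed_sets: dict[str, SeedSet]) -> pd.DataFrame:
    """Flatten per-comparison seed sets into one table (for write_table)."""
    frames = []
    for comparison_id, seed_set in seed_sets.items():
        frame = seed_set.table.copy()
        frame.insert(0, "comparison", comparison_id)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(columns=["comparison", "probe_id", "log2_difference", "direction"])
    return pd.concat(frames, ignore_index=True)
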