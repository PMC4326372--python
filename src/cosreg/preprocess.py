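"""Across-array normalization and group summaries.

Quantile normalization forces every array column onto the common reference
distribution (the rank-wise mean of order statistics), removing array-specific
intensity bias while preserving within-array rank order. Group means collapse
replicate columns into the eight canonical (day, region, compartment) groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleDesign


@dataclass
class GroupMeans:
    """Probe x group matrix of mean log2 expression."""

    means: pd.DataFrame  # index probe_id, columns group labels
    design: SampleDesign

    @property
    def probe_ids(self) -> pd.Index:
        return self.means.index

    @property
    def groups(self) -> list[str]:
        return list(self.means.columns)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the mean-of-order-statistics reference.

    After normalization every column's sorted value vector equals the
    reference vector: the across-column mean of each rank's order statistic.
    Tied values within a column all receive the mean of the reference values
    spanning their tied ranks, so the map is rank-preserving and idempotent.

    Raises ``ValueError`` for a single-column matrix (the reference would be
    the column itself, leaving nothing to normalize against).
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 columns")
    values = matrix.values()
    order = np.argsort(values, axis=0, kind="stable")
    sorted_values = np.take_along_axis(values, order, axis=0)
    reference = sorted_values.mean(axis=1)

    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col_sorted = sorted_values[:, j]
        # runs of tied values all receive the mean reference value of their ranks
        is_run_start = np.empty(n, dtype=bool)
        is_run_start[0] = True
        np.not_equal(col_sorted[1:], col_sorted[:-1], out=is_run_start[1:])
        starts = np.nonzero(is_run_start)[0]
        run_means = np.add.reduceat(reference, starts) / np.diff(np.append(starts, n))
        out[order[:, j], j] = run_means[np.cumsum(is_run_start) - 1]
    frame = pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    return ExpressionMatrix(frame, matrix.design)


def group_means(matrix: ExpressionMatrix) -> GroupMeans:
    """Arithmetic mean of log2 values within each (day, region, compartment) group.

    On the linear scale this is the geometric-mean convention, matching the
    downstream interpretation of a fold change as ``2**(mean_a - mean_b)``.
    """
    design = matrix.design
    columns = {}
    for group in design.groups:
        ids = design.samples_in_group(group)
        columns[group] = matrix.data[ids].mean(axis=1)
    means = pd.DataFrame(columns, index=matrix.data.index)
    means.index.name = "probe_id"
    return GroupMeans(means=means, design=design)
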