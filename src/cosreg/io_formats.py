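"""Readers and writers for every external representation the screen touches.

The pipeline's exchange formats are deliberately plain: tab-delimited
expression matrices and sample designs, GMT gene-set collections, and
header-carrying TSV result tables. Each result type has a documented,
deterministic sort key so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS = ("E7", "E9", "E11")
REGIONS = ("feather", "scale")
COMPARTMENTS = ("epithelium", "mesenchyme")

#: Canonical group order used for all grouped outputs: embryonic day E7->E11,
#: feather before scale, epithelium before mesenchyme (E7fe ... E11sm).
CANONICAL_GROUP_ORDER = (
    "E7fe", "E7fm", "E9fe", "E9fm", "E9se", "E9sm", "E11se", "E11sm",
)


def group_label(day: str, region: str, compartment: str) -> str:
    """Short group label, e.g. ('E9', 'scale', 'epithelium') -> 'E9se'."""
    return f"{day}{region[0]}{compartment[0]}"


@dataclass(frozen=True)
class SampleInfo:
    """Design annotation for a single array column."""

    sample_id: str
    day: str
    region: str
    compartment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.day not in DAYS:
            raise ValueError(f"unknown day {self.day!r}; expected one of {DAYS}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be a positive integer")

    @property
    def group(self) -> str:
        return group_label(self.day, self.region, self.compartment)


@dataclass(frozen=True)
class SampleDesign:
    """Ordered collection of sample annotations (one per matrix column)."""

    samples: tuple[SampleInfo, ...]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids in design: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def group_of_sample(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}

    @property
    def groups(self) -> list[str]:
        """Distinct groups in canonical order (unknown groups appended sorted)."""
        present = {s.group for s in self.samples}
        ordered = [g for g in CANONICAL_GROUP_ORDER if g in present]
        ordered += sorted(present - set(ordered))
        return ordered

    def samples_in_group(self, group: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.group == group]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "day": [s.day for s in self.samples],
                "region": [s.region for s in self.samples],
                "compartment": [s.compartment for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of log2-scale intensities with its design.

    ``data`` is a DataFrame indexed by probe_id with one column per sample,
    ordered exactly as the design. Values must be finite; probe_ids unique.
    """

    data: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.design.sample_ids:
            raise ValueError(
                "matrix columns do not match design sample order: "
                f"{list(self.data.columns)} vs {self.design.sample_ids}"
            )
        if self.data.index.has_duplicates:
            dupes = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate probe_ids: {dupes[:10]}")
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            bad = int(np.size(values) - np.isfinite(values).sum())
            raise ValueError(f"expression matrix contains {bad} non-finite values")

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the size N of the annotation universe."""

    sets: dict[str, frozenset[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError("universe_size must be a positive integer")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_design_tsv(path) -> SampleDesign:
    """Read a design TSV with columns sample_id, day, region, compartment, replicate."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "day", "region", "compartment", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"design file {path} missing columns: {sorted(missing)}")
    samples = tuple(
        SampleInfo(
            sample_id=row.sample_id,
            day=row.day,
            region=row.region,
            compartment=row.compartment,
            replicate=int(row.replicate),
        )
        for row in frame.itertuples()
    )
    return SampleDesign(samples)


#: shortest float representation that parses back to the identical float64
def _REPR_FLOAT(value) -> str:
    return repr(float(value))


def _coerce_numeric(frame: pd.DataFrame, path) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any():
        rows, cols = np.nonzero(out.isna().to_numpy())
        probe = frame.index[rows[0]]
        sample = frame.columns[cols[0]]
        raise ValueError(
            f"non-numeric expression value in {path} at probe {probe!r}, sample {sample!r}"
        )
    return out.astype(float)


def read_expression_tsv(path, design_path) -> ExpressionMatrix:
    """Read a probes x samples TSV (first column probe_id) with its design file.

    Columns are reordered to follow the design; a header sample absent from
    the design (or vice versa) is a hard error naming the sample_id.
    """
    design = read_design_tsv(design_path)
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    header = list(frame.columns)
    missing_in_design = [s for s in header if s not in design.sample_ids]
    if missing_in_design:
        raise ValueError(
            f"sample_id {missing_in_design[0]!r} in {path} is absent from the design"
        )
    missing_in_matrix = [s for s in design.sample_ids if s not in header]
    if missing_in_matrix:
        raise ValueError(
            f"sample_id {missing_in_matrix[0]!r} in the design is absent from {path}"
        )
    if frame.index.has_duplicates:
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValueError(f"duplicate probe_id rows in {path}: {dupes[:10]}")
    frame = _coerce_numeric(frame[design.sample_ids], path)
    frame.index = frame.index.astype(str)
    frame.index.name = "probe_id"
    return ExpressionMatrix(frame, design)


SERIES_MATRIX_BEGIN = "!series_matrix_table_begin"
SERIES_MATRIX_END = "!series_matrix_table_end"


def read_series_matrix(path, design: SampleDesign | None = None) -> pd.DataFrame | ExpressionMatrix:
    """Parse the table block of a GEO series-matrix file.

    Only the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is read; quoted identifiers are unquoted.
    Metadata lines are ignored — the design must be supplied separately.
    Returns a probes x samples DataFrame, or an ExpressionMatrix when a
    design covering the table's columns is given.
    """
    with open(path) as handle:
        lines = handle.read().splitlines()
    try:
        begin = next(i for i, l in enumerate(lines) if l.strip() == SERIES_MATRIX_BEGIN)
        end = next(i for i, l in enumerate(lines) if l.strip() == SERIES_MATRIX_END)
    except StopIteration:
        raise ValueError(
            f"{path} lacks the {SERIES_MATRIX_BEGIN}/{SERIES_MATRIX_END} delimiters"
        ) from None
    if end <= begin + 1:
        raise ValueError(f"series-matrix table block in {path} is empty")

    def unquote(tok: str) -> str:
        tok = tok.strip()
        if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
            tok = tok[1:-1]
        return tok

    header = [unquote(t) for t in lines[begin + 1].split("\t")][1:]
    records, index = [], []
    for line in lines[begin + 2 : end]:
        tokens = line.split("\t")
        index.append(unquote(tokens[0]))
        records.append([unquote(t) for t in tokens[1:]])
    frame = pd.DataFrame(records, index=pd.Index(index, name="probe_id"), columns=header)
    frame = _coerce_numeric(frame, path)
    if design is None:
        return frame
    return ExpressionMatrix(frame[design.sample_ids], design)


def read_gmt(path, universe_size: int) -> GeneSetCollection:
    """Read a standard GMT file: name <tab> description <tab> members...

    The description field is discarded; duplicate members within a line are
    deduplicated with a logged warning. Lines with fewer than three fields
    are an error naming the line number. An empty file is a valid, empty
    collection.
    """
    sets: dict[str, frozenset[str]] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno} in {path} has {len(fields)} fields; "
                    "expected name, description, and at least one member"
                )
            name = fields[0]
            members = [m for m in fields[2:] if m]
            unique = frozenset(members)
            if len(unique) < len(members):
                logger.warning(
                    "GMT line %d (%s): %d duplicate members removed",
                    lineno, name, len(members) - len(unique),
                )
            sets[name] = unique
    return GeneSetCollection(sets=sets, universe_size=universe_size)


def read_probe_gene_map(path) -> dict[str, str]:
    """Optional two-column probe -> gene mapping; identity where absent."""
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"mapping file {path} needs two tab-separated columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path, design_path=None) -> None:
    """Write a matrix (and optionally its design) back to TSV."""
    frame = matrix.data.copy()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", lineterminator="\n", float_format=_REPR_FLOAT)
    if design_path is not None:
        matrix.design.to_frame().to_csv(design_path, sep="\t", index=False, lineterminator="\n")


#: sort key per result table, applied before writing (determinism contract)
_SORT_KEYS: dict[str, list[str]] = {
    "seeds": ["comparison", "probe_id"],
    "similarity_tails": ["comparison", "seed_id", "tail", "probe_id"],
    "candidates": ["comparison", "probe_id"],
    "clusters": ["comparison", "cluster_id", "role", "member_id"],
    "enrichment": ["comparison", "p_value", "set_name"],
    "ranking": ["rank", "set_name"],
    "support_distribution": ["comparison", "n_seeds"],
    "recovery": ["metric", "module_id"],
    "summary": ["comparison"],
    "truth": ["kind", "group_id", "probe_id"],
}


def write_table(frame: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a result table as TSV with a header and a deterministic row order.

    ``kind`` selects the documented sort key (see ``_SORT_KEYS``); if omitted
    or unknown, rows are sorted by all columns. Writing the same frame twice
    yields byte-identical files; an empty frame yields a header-only file.
    """
    frame = pd.DataFrame(frame)
    key = _SORT_KEYS.get(kind or "", None)
    if key is not None:
        key = [k for k in key if k in frame.columns]
    if not key:
        key = list(frame.columns)
    if key and len(frame):
        frame = frame.sort_values(key, kind="mergesort")
    frame.to_csv(
        path, sep="\t", index=False, lineterminator="\n", float_format=_REPR_FLOAT
    )


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
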