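"""Synthetic expression matrices with planted co-regulation structure.

The generator emulates the statistical skeleton of the 20-array embryonic
chicken skin design: eight (day, region, compartment) groups — E7 and E9
feather, E9 and E11 scale, each split into epithelium (2 replicates) and
mesenchyme (3 replicates) — measured on a log2 intensity scale.

Background probe g in sample s is  b_g + eps,  with probe baseline
b_g ~ Normal(baseline_mean, baseline_sd^2) and array noise
eps ~ Normal(0, noise_sd^2). Each co-regulated module m carries a latent
group-level trajectory t_m(group) ~ Normal(0, 1), drawn once per group so
replicates share it (replicates are the same tissue); a member gene adds
lambda_g * t_m(group) with loading lambda_g ~ Normal(1, module_loading_sd^2).
Differential "seeds" are planted as module members: each canonical
comparison's seeds are drawn from one module (module index = comparison
index mod n_modules) and receive +log2(seed_fold) on one side of the
comparison, the side chosen by fair coin. Concentrating a comparison's
seeds in one module mirrors the biology the screen presumes — differential
genes arise within co-regulated programs, so seeds are mutually correlated
and the shared-seed support filter has true positives. With n_modules = 0
there are no modules and hence no planted seeds: a pure-noise null matrix.

Everything is reproducible bit-for-bit from ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .candidates_clusters import CandidateList
from .io_formats import ExpressionMatrix, SampleDesign, SampleInfo
from .seeds import CANONICAL_COMPARISONS

#: canonical replicate counts: 2 epithelial + 3 mesenchymal per (day, region)
_CANONICAL_GROUPS = (
    ("E7", "feather", "epithelium", 2),
    ("E7", "feather", "mesenchyme", 3),
    ("E9", "feather", "epithelium", 2),
    ("E9", "feather", "mesenchyme", 3),
    ("E9", "scale", "epithelium", 2),
    ("E9", "scale", "mesenchyme", 3),
    ("E11", "scale", "epithelium", 2),
    ("E11", "scale", "mesenchyme", 3),
)


def canonical_design() -> SampleDesign:
    """The 20-sample design: 8 groups, 2 epithelial + 3 mesenchymal replicates."""
    samples = []
    for day, region, compartment, n_rep in _CANONICAL_GROUPS:
        for rep in range(1, n_rep + 1):
            label = f"{day}{region[0]}{compartment[0]}"
            samples.append(
                SampleInfo(
                    sample_id=f"{label}_r{rep}",
                    day=day,
                    region=region,
                    compartment=compartment,
                    replicate=rep,
                )
            )
    return SampleDesign(tuple(samples))


@dataclass
class SimulationConfig:
    """Parameters of the planted-module simulation (log2 units throughout)."""

    n_probes: int = 20000
    n_modules: int = 5
    module_size: int = 50
    n_seed_probes_per_comparison: int = 30
    seed_fold: float = 8.0  # linear-scale fold planted on seeds; must exceed 5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    module_loading_sd: float = 0.15
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1 or self.module_size < 1 or self.n_seed_probes_per_comparison < 1:
            raise ValueError("n_probes, module_size and seed counts must be positive")
        if self.n_modules < 0:
            raise ValueError("n_modules must be non-negative")
        if self.seed_fold <= 5:
            raise ValueError("seed_fold must exceed 5 (the differential threshold)")
        if self.baseline_sd <= 0 or self.noise_sd <= 0 or self.module_loading_sd <= 0:
            raise ValueError("baseline_sd, noise_sd and module_loading_sd must be positive")
        budget = self.n_modules * self.module_size + 4 * self.n_seed_probes_per_comparison
        if budget > self.n_probes:
            raise ValueError(
                f"planted structure ({budget} probes) exceeds n_probes={self.n_probes}"
            )
        if self.n_modules > 0 and self.n_seed_probes_per_comparison > self.module_size:
            raise ValueError(
                "n_seed_probes_per_comparison cannot exceed module_size "
                "(planted seeds are drawn as members of one module)"
            )


@dataclass
class GroundTruth:
    """Planted structure labels for recovery scoring."""

    module_members: dict[str, tuple[str, ...]]
    planted_seeds: dict[str, tuple[str, ...]]
    module_of_seed: dict[str, str]
    seed_side: dict[tuple[str, str], str] = field(default_factory=dict)

    def all_planted_probes(self) -> set[str]:
        planted: set[str] = set()
        for members in self.module_members.values():
            planted.update(members)
        for seeds in self.planted_seeds.values():
            planted.update(seeds)
        return planted

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"kind": "module_member", "group_id": module, "probe_id": probe}
            for module, members in self.module_members.items()
            for probe in members
        ] + [
            {"kind": "planted_seed", "group_id": comparison, "probe_id": probe}
            for comparison, seeds in self.planted_seeds.items()
            for probe in seeds
        ]
        return pd.DataFrame.from_records(
            records, columns=["kind", "group_id", "probe_id"]
        )


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw an expression matrix with planted modules and differential seeds.

    See the module docstring for the generative model. Deterministic given
    ``config.rng_seed``; raises ``ValueError`` on an invalid configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    design = canonical_design()
    groups = design.groups
    group_index = {g: i for i, g in enumerate(groups)}
    sample_group_idx = np.array(
        [group_index[s.group] for s in design.samples], dtype=int
    )
    n_samples = len(design)

    width = max(6, len(str(config.n_probes)))
    probe_ids = np.array([f"P{i:0{width}d}" for i in range(1, config.n_probes + 1)])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_probes)
    values = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, (config.n_probes, n_samples)
    )

    # module membership: disjoint random chunks of a permutation
    perm = rng.permutation(config.n_probes)
    module_members: dict[str, tuple[str, ...]] = {}
    member_rows: dict[str, np.ndarray] = {}
    for m in range(config.n_modules):
        rows = np.sort(perm[m * config.module_size : (m + 1) * config.module_size])
        module_id = f"M{m + 1}"
        member_rows[module_id] = rows
        module_members[module_id] = tuple(probe_ids[rows])
        trajectory = rng.normal(0.0, 1.0, len(groups))
        loadings = rng.normal(1.0, config.module_loading_sd, len(rows))
        values[rows, :] += loadings[:, None] * trajectory[sample_group_idx][None, :]

    planted_seeds: dict[str, tuple[str, ...]] = {}
    module_of_seed: dict[str, str] = {}
    seed_side: dict[tuple[str, str], str] = {}
    shift = math.log2(config.seed_fold)
    for c, comparison in enumerate(CANONICAL_COMPARISONS):
        if config.n_modules == 0:
            planted_seeds[comparison.id] = ()
            continue
        module_id = f"M{(c % config.n_modules) + 1}"
        pool = member_rows[module_id]
        chosen = np.sort(rng.choice(pool, size=config.n_seed_probes_per_comparison, replace=False))
        sides = rng.integers(0, 2, size=len(chosen))
        seed_list = []
        for row, side in zip(chosen, sides):
            group = comparison.group_a if side == 0 else comparison.group_b
            cols = [i for i, s in enumerate(design.samples) if s.group == group]
            values[row, cols] += shift
            probe = str(probe_ids[row])
            seed_list.append(probe)
            module_of_seed[probe] = module_id
            seed_side[(comparison.id, probe)] = group
        planted_seeds[comparison.id] = tuple(seed_list)

    frame = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=design.sample_ids
    )
    truth = GroundTruth(
        module_members=module_members,
        planted_seeds=planted_seeds,
        module_of_seed=module_of_seed,
        seed_side=seed_side,
    )
    return ExpressionMatrix(frame, design), truth


@dataclass
class RecoveryMetrics:
    """Precision/recall of a candidate list against planted structure."""

    precision: float
    recall_per_module: dict[str, float]
    mean_recall: float
    n_candidates: int
    empty_candidates: bool

    def to_frame(self) -> pd.DataFrame:
        records = [
            {"metric": "recall", "module_id": m, "value": r}
            for m, r in self.recall_per_module.items()
        ]
        records.append({"metric": "mean_recall", "module_id": "", "value": self.mean_recall})
        records.append({"metric": "precision", "module_id": "", "value": self.precision})
        records.append(
            {"metric": "n_candidates", "module_id": "", "value": float(self.n_candidates)}
        )
        return pd.DataFrame.from_records(records, columns=["metric", "module_id", "value"])


def score_recovery(
    candidates: CandidateList | Iterable[CandidateList] | Mapping[str, CandidateList],
    truth: GroundTruth,
) -> RecoveryMetrics:
    """Score candidate probes against the planted modules and seeds.

    ``candidates`` may be a single per-comparison list, several, or a mapping
    by comparison id; the union of their probes is scored. recall(m) is the
    fraction of module m's members among the candidates; precision is the
    fraction of candidates belonging to any module or planted seed set. An
    empty candidate list has undefined precision, reported as 1.0 with
    ``empty_candidates=True`` (and recall 0 for every module).
    """
    if isinstance(candidates, CandidateList):
        lists = [candidates]
    elif isinstance(candidates, Mapping):
        lists = list(candidates.values())
    else:
        lists = list(candidates)
    found: set[str] = set()
    for candidate_list in lists:
        found.update(candidate_list.probe_ids)

    planted = truth.all_planted_probes()
    empty = len(found) == 0
    precision = 1.0 if empty else len(found & planted) / len(found)
    recall_per_module = {
        module: (len(set(members) & found) / len(members)) if members else 0.0
        for module, members in truth.module_members.items()
    }
    mean_recall = (
        float(np.mean(list(recall_per_module.values()))) if recall_per_module else 0.0
    )
    return RecoveryMetrics(
        precision=precision,
        recall_per_module=recall_per_module,
        mean_recall=mean_recall,
        n_candidates=len(found),
        empty_candidates=empty,
    )
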