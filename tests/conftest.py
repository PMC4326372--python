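import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cosreg
from cosreg.io_formats import ExpressionMatrix, SampleDesign, SampleInfo

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_design(n_samples: int = 2) -> SampleDesign:
    """Minimal valid design: n replicates of one group."""
    return SampleDesign(
        tuple(
            SampleInfo(f"s{i}", "E7", "feather", "epithelium", i)
            for i in range(1, n_samples + 1)
        )
    )


def make_matrix(values, probe_ids=None, design=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"p{i}" for i in range(1, values.shape[0] + 1)]
    if design is None:
        design = make_design(values.shape[1])
    frame = pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                         columns=design.sample_ids)
    return ExpressionMatrix(frame, design)


@pytest.fixture(scope="session")
def small_config() -> cosreg.SimulationConfig:
    """Reduced-size simulation for fast structural tests."""
    return cosreg.SimulationConfig(
        n_probes=3000, n_modules=4, module_size=40,
        n_seed_probes_per_comparison=20, rng_seed=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return cosreg.simulate(small_config)


@pytest.fixture(scope="session")
def default_run():
    """Full screen on the default-size simulation, rng_seed=1 (shared)."""
    matrix, truth = cosreg.simulate(cosreg.SimulationConfig(rng_seed=1))
    normalized = cosreg.quantile_normalize(matrix)
    means = cosreg.group_means(normalized)
    tables, candidates = {}, {}
    for comparison in cosreg.CANONICAL_COMPARISONS:
        seed_set = cosreg.select_seeds(means, comparison)
        tables[comparison.id] = cosreg.similarity_table(normalized, seed_set)
        candidates[comparison.id] = cosreg.build_candidates(tables[comparison.id])
    return {
        "matrix": matrix,
        "normalized": normalized,
        "truth": truth,
        "tables": tables,
        "candidates": candidates,
    }
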