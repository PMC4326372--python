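import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cosreg.cosine_engine import (
    FISHER_CLIP,
    HISTOGRAM_EDGES,
    center_probes,
    cosine,
    cosine_histogram,
    fisher_z,
    similarity_table,
)
from cosreg.seeds import COMPARISON_BY_ID, SeedSet

from conftest import make_design, make_matrix

finite_vectors = st.lists(
    st.floats(-100, 100, allow_nan=False, width=64), min_size=2, max_size=20
)


def seed_set_for(probe_ids, comparison_id="E7fe_vs_E9se"):
    table = pd.DataFrame(
        {
            "probe_id": list(probe_ids),
            "log2_difference": [3.0] * len(probe_ids),
            "direction": ["up_in_a"] * len(probe_ids),
        }
    )
    return SeedSet(
        comparison=COMPARISON_BY_ID[comparison_id], table=table, fold_threshold=5.0
    )


class TestCosine:
    def test_parallel_vectors(self):
        assert cosine([1, 2, 2], [2, 4, 4]) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        assert cosine([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        assert cosine([1, 2, 3], [3, 2, 1]) == pytest.approx(10 / 14, abs=1e-12)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length mismatch"):
            cosine([1, 2], [1, 2, 3])

    def test_zero_norm_is_error(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine([0, 0, 0], [1, 2, 3])

    @given(finite_vectors, finite_vectors)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        if not (np.linalg.norm(a) and np.linalg.norm(b)):
            return
        assert cosine(a, b) == pytest.approx(cosine(b, a), abs=1e-12)

    @given(finite_vectors, st.floats(0.01, 50), st.booleans())
    def test_scaled_copies_and_scale_invariance(self, a, c, negate):
        if not np.linalg.norm(a):
            return
        scale = -c if negate else c
        assert cosine(a, np.multiply(scale, a)) == pytest.approx(
            -1.0 if negate else 1.0, abs=1e-9
        )
        b = np.arange(1.0, len(a) + 1.0)
        assert cosine(np.multiply(c, a), b) == pytest.approx(cosine(a, b), abs=1e-9)


class TestCenterProbes:
    def test_constant_row_flagged(self):
        matrix = make_matrix([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]],
                             design=make_design(3))
        centered, flagged = center_probes(matrix)
        assert flagged == ["p1"]
        np.testing.assert_allclose(centered.values()[0], 0.0)

    def test_two_sample_row(self):
        matrix = make_matrix([[1.0, 3.0]])
        centered, flagged = center_probes(matrix)
        np.testing.assert_allclose(centered.values()[0], [-1.0, 1.0])
        assert flagged == []

    def test_centered_cosine_equals_pearson(self):
        rng = np.random.default_rng(42)
        pairs = rng.normal(size=(1000, 2, 20))
        for a, b in pairs:
            expected = np.corrcoef(a, b)[0, 1]
            got = cosine(a - a.mean(), b - b.mean())
            assert got == pytest.approx(expected, abs=1e-10)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_pole_is_clipped(self):
        expected = math.atanh(FISHER_CLIP)
        assert fisher_z(1.0) == pytest.approx(expected, abs=1e-12)
        assert fisher_z(1.0) == pytest.approx(8.406, abs=1e-3)
        assert fisher_z(-1.0) == -fisher_z(1.0)

    @given(st.floats(-0.999, 0.999), st.floats(-0.999, 0.999))
    def test_odd_and_strictly_increasing(self, r1, r2):
        assert fisher_z(-r1) == pytest.approx(-fisher_z(r1), abs=1e-12)
        if r1 < r2:
            assert fisher_z(r1) < fisher_z(r2)


class TestSimilarityTable:
    def make_random_table(self, n_probes=1000, n_seeds=3, tail_fraction=0.005):
        rng = np.random.default_rng(0)
        design = make_design(8)
        matrix = make_matrix(rng.normal(size=(n_probes, 8)), design=design)
        seed_ids = [f"p{i}" for i in (1, 2, 3)][:n_seeds]
        return similarity_table(
            matrix, seed_set_for(seed_ids), tail_fraction=tail_fraction
        )

    def test_tail_sizes_exactly_half_percent_each(self):
        table = self.make_random_table()
        for seed_id in table.seed_ids:
            co, recip = table.tails[seed_id]
            assert len(co) == 5 and len(recip) == 5  # ceil(0.005 * 1000)

    def test_self_comparison_excluded(self):
        table = self.make_random_table()
        for seed_id in table.seed_ids:
            co, recip = table.tails[seed_id]
            assert seed_id not in co and seed_id not in recip

    def test_tails_disjoint_within_seed_but_may_overlap_across_seeds(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(1, 6))
        # two seeds nearly parallel: their co tails should overlap
        values = np.vstack(
            [base + rng.normal(0, 0.01, size=(2, 6)), rng.normal(size=(200, 6))]
        )
        matrix = make_matrix(values, design=make_design(6))
        table = similarity_table(matrix, seed_set_for(["p1", "p2"]), tail_fraction=0.02)
        co1, recip1 = table.tails["p1"]
        co2, _ = table.tails["p2"]
        assert not (set(co1) & set(recip1))
        assert set(co1) & set(co2)

    def test_ties_at_cut_break_lexicographically(self):
        # probes c..f are exact copies: all tie at cosine 1 with the seed
        values = np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [4.0, 3.0, 2.0, 1.0],
            ]
        )
        matrix = make_matrix(
            values, probe_ids=["s", "d", "b", "c", "z", "y"], design=make_design(4)
        )
        table = similarity_table(
            matrix, seed_set_for(["s"]), tail_fraction=0.3  # ceil(0.3*6)=2 per tail
        )
        co, recip = table.tails["s"]
        assert list(co) == ["b", "c"]  # lexicographic among tied b, c, d
        assert list(recip) == ["y", "z"]

    def test_zero_variance_probe_excluded_with_warning(self):
        values = np.vstack([np.arange(6.0), np.full(6, 3.0),
                            np.random.default_rng(0).normal(size=(50, 6))])
        matrix = make_matrix(values, design=make_design(6))
        table = similarity_table(matrix, seed_set_for(["p1"]), tail_fraction=0.1)
        assert table.excluded_probes == ["p2"]
        assert "p2" not in table.probe_ids

    def test_invalid_tail_fraction_is_error(self):
        matrix = make_matrix(np.random.default_rng(0).normal(size=(10, 4)),
                             design=make_design(4))
        for bad in (0.0, 0.5, 0.7):
            with pytest.raises(ValueError, match="tail_fraction"):
                similarity_table(matrix, seed_set_for(["p1"]), tail_fraction=bad)

    def test_planted_module_members_fill_seed_co_tails(self, default_run):
        """On the default simulation, a planted seed's co tail is rich in
        members of its own module (the guilt-by-association signal)."""
        truth = default_run["truth"]
        found_rich_tail = False
        for comparison_id, table in default_run["tables"].items():
            planted = set(truth.planted_seeds[comparison_id]) & set(table.seed_ids)
            for seed_id in planted:
                module = truth.module_of_seed[seed_id]
                members = set(truth.module_members[module])
                co, _ = table.tails[seed_id]
                if len(set(co) & members) >= 10:
                    found_rich_tail = True
        assert found_rich_tail


class TestCosineHistogram:
    def test_sixteen_even_bins(self):
        assert len(HISTOGRAM_EDGES) == 17
        np.testing.assert_allclose(np.diff(HISTOGRAM_EDGES), 0.125)
        assert HISTOGRAM_EDGES[0] == -1.0 and HISTOGRAM_EDGES[-1] == 1.0

    def test_concentration_and_conservation(self):
        rng = np.random.default_rng(3)
        matrix = make_matrix(rng.normal(size=(100, 6)), design=make_design(6))
        table = similarity_table(matrix, seed_set_for(["p1", "p2"]), tail_fraction=0.01)
        hist = cosine_histogram(table)
        assert hist.counts.sum() == 2 * 100  # every (seed, probe) pair tallied
        # self-pairs (cosine 1.0) land in the final closed bin
        assert hist.counts[-1] >= 2
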