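"""Generator and pseudo-bulk construction: conservation, markers, scaling."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from atacsep.synthesize import (
    SimulationSpec,
    build_training_set,
    generate_synthetic_snatac,
    normalize_pairs,
    sample_pseudobulk_pair,
)


class TestGenerator:
    def test_deterministic_under_seed(self, small_spec):
        a = generate_synthetic_snatac(small_spec)
        b = generate_synthetic_snatac(small_spec)
        assert (a.matrix != b.matrix).nnz == 0
        assert a.cell_meta.equals(b.cell_meta)

    def test_marker_blocks_separate_cell_types(self, small_spec, small_counts):
        """Own-marker mean counts exceed other types' marker means, and a
        one-sided rank test rejects at alpha=0.01 (fixture sanity)."""
        meta = small_counts.cell_meta
        mat = small_counts.matrix
        S = len(small_spec.cell_types)
        for i, ct in enumerate(small_spec.cell_types):
            rows = np.flatnonzero(meta["cell_type"] == ct)
            prof = np.asarray(mat[rows].mean(axis=0)).ravel()
            own = prof[small_spec.marker_block(i)]
            others = np.concatenate(
                [prof[small_spec.marker_block(j)] for j in range(S) if j != i]
            )
            assert own.mean() > others.mean()
            p = mannwhitneyu(own, others, alternative="greater").pvalue
            assert p < 0.01

    def test_null_effect_gives_no_marker_contrast(self):
        spec = SimulationSpec(
            n_subjects=2,
            cell_types=("A", "B"),
            cells_per_subject_per_type=(100, 100),
            P=400,
            markers_per_type=50,
            marker_effect=1.0 + 1e-12,  # exactly-null multiplier
            seed=11,
        )
        counts = generate_synthetic_snatac(spec)
        prof = np.asarray(
            counts.matrix[
                np.flatnonzero(counts.cell_meta["cell_type"] == "A")
            ].mean(axis=0)
        ).ravel()
        own = prof[spec.marker_block(0)]
        other = prof[spec.marker_block(1)]
        # ratio of marker to non-marker means stays ~1 within sampling error
        assert own.mean() / other.mean() == pytest.approx(1.0, abs=0.3)

    def test_marker_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceeds P"):
            SimulationSpec(P=100, markers_per_type=30, cell_types=("A", "B", "C", "D"))


class TestPseudoBulk:
    def test_bulk_is_exact_column_sum_of_sources(self, small_counts):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pair = sample_pseudobulk_pair(
                small_counts, "S01", "R1", rng, n_cells_range=(20, 100)
            )
            assert np.array_equal(pair.bulk, pair.sources.sum(axis=0))

    def test_single_present_type_means_bulk_equals_that_source(self, small_counts):
        rng = np.random.default_rng(1)
        pair = sample_pseudobulk_pair(
            small_counts,
            "S01",
            "R1",
            rng,
            n_cells_range=(20, 50),
            allow_absent=("EXC", "MIC"),
        )
        i = list(sorted(("AST", "EXC", "MIC"))).index("AST")
        assert np.array_equal(pair.bulk, pair.sources[i])
        assert pair.n_cells_per_type.sum() == pair.n_cells_per_type[i]

    def test_per_type_cell_numbers_within_range(self, small_counts):
        rng = np.random.default_rng(2)
        pair = sample_pseudobulk_pair(
            small_counts, "S02", "R1", rng, n_cells_range=(30, 60)
        )
        assert np.all(pair.n_cells_per_type >= 30)
        assert np.all(pair.n_cells_per_type <= 60)

    def test_default_cell_range_is_100_to_800(self, small_counts):
        import inspect

        sig = inspect.signature(sample_pseudobulk_pair)
        assert sig.parameters["n_cells_range"].default == (100, 800)

    def test_absent_type_without_permission_errors(self, small_counts):
        import pandas as pd
        sub = small_counts.cell_meta["cell_type"] != "MIC"
        from atacsep.io import AnnotatedCounts

        counts = AnnotatedCounts(
            matrix=small_counts.matrix[np.flatnonzero(sub)],
            cell_meta=small_counts.cell_meta.loc[sub].reset_index(drop=True),
            peaks=small_counts.peaks,
        )
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="absent"):
            sample_pseudobulk_pair(
                counts, "S01", "R1", rng, cell_types=("AST", "EXC", "MIC")
            )

    def test_rare_fraction_cap_respected(self, small_counts):
        rng = np.random.default_rng(4)
        for _ in range(10):
            pair = sample_pseudobulk_pair(
                small_counts,
                "S01",
                "R1",
                rng,
                n_cells_range=(50, 200),
                rare_fraction_caps={"MIC": 0.05},
            )
            i = sorted(("AST", "EXC", "MIC")).index("MIC")
            share = pair.n_cells_per_type[i] / pair.n_cells_per_type.sum()
            assert share < 0.05


class TestTrainingSet:
    def test_pair_counting(self, small_counts):
        ts = build_training_set(
            small_counts, pairs_per_subject=10, n_cells_range=(20, 60), seed=0
        )
        assert len(ts) == 30  # 3 subjects x 1 region x 10 pairs
        assert all((ts.subject == s).sum() == 10 for s in ("S01", "S02", "S03"))

    def test_deterministic_under_seed(self, small_counts):
        a = build_training_set(small_counts, 5, n_cells_range=(20, 60), seed=9)
        b = build_training_set(small_counts, 5, n_cells_range=(20, 60), seed=9)
        assert np.array_equal(a.bulk, b.bulk)
        assert np.array_equal(a.sources, b.sources)

    def test_invalid_pairs_per_subject(self, small_counts):
        with pytest.raises(ValueError, match="pairs_per_subject"):
            build_training_set(small_counts, 0)

    def test_default_pairs_per_subject_is_3000(self):
        import inspect

        sig = inspect.signature(build_training_set)
        assert sig.parameters["pairs_per_subject"].default == 3000


class TestNormalization:
    def test_hand_example(self):
        # one pair, one type with 2 cells and counts [2, 4]; per-cell [1, 2];
        # global max 2 -> [0.5, 1.0]
        bulk = np.array([[2, 4]])
        sources = np.array([[[2, 4]], [[0, 0]]]).transpose(1, 0, 2)  # (1, 2, 2)
        sources = np.array([[[2, 4], [0, 0]]])
        n_cells = np.array([[2, 0]])
        bulk_n, src_n, c = normalize_pairs(bulk, sources, n_cells)
        assert np.allclose(src_n[0, 0], [0.5, 1.0])
        assert c == 2.0
        # bulk: 2 total cells -> [1, 2] -> /2 -> [0.5, 1.0]
        assert np.allclose(bulk_n[0], [0.5, 1.0])

    def test_all_zero_counts_degenerate(self):
        bulk = np.zeros((2, 3))
        sources = np.zeros((2, 2, 3))
        n_cells = np.ones((2, 2), dtype=int)
        bulk_n, src_n, c = normalize_pairs(bulk, sources, n_cells)
        assert c == 1.0
        assert not bulk_n.any() and not src_n.any()

    def test_global_max_is_one(self, small_training_set):
        m = max(small_training_set.bulk.max(), small_training_set.sources.max())
        assert m == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_common_count_scaling(self, small_counts):
        ts = build_training_set(small_counts, 5, n_cells_range=(20, 60), seed=2)
        # rebuild the raw pairs and scale counts by c=7: max-scaling cancels it
        raw_src = ts.sources * ts.normalization_constant
        raw_bulk = ts.bulk * ts.normalization_constant
        bulk_n, src_n, c = normalize_pairs(
            7 * raw_bulk * ts.n_cells.sum(1)[:, None],
            7 * raw_src * np.where(ts.n_cells, ts.n_cells, 1)[:, :, None],
            ts.n_cells,
        )
        assert np.allclose(bulk_n, ts.bulk, atol=1e-6)
        assert np.allclose(src_n, ts.sources, atol=1e-6)

    def test_zero_cells_with_nonzero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero cells"):
            normalize_pairs(
                np.array([[1.0, 1.0]]),
                np.array([[[1.0, 1.0]]]),
                np.array([[0]]),
            )
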