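"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from atacsep.synthesize import (
    SimulationSpec,
    TrainingSet,
    build_training_set,
    generate_synthetic_snatac,
)


@pytest.fixture(scope="session")
def small_spec() -> SimulationSpec:
    """A fast 3-type simulation used by unit tests."""
    return SimulationSpec(
        n_subjects=3,
        n_regions=1,
        cell_types=("AST", "EXC", "MIC"),
        cells_per_subject_per_type=(40, 80),
        P=300,
        markers_per_type=30,
        marker_effect=8.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_counts(small_spec):
    return generate_synthetic_snatac(small_spec)


@pytest.fixture(scope="session")
def small_training_set(small_counts) -> TrainingSet:
    return build_training_set(
        small_counts, pairs_per_subject=30, n_cells_range=(50, 200), seed=3
    )


def make_disjoint_support_set(
    n_pairs: int = 240,
    S: int = 3,
    width: int = 64,
    n_subjects: int = 4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TrainingSet:
    """Pairs where each OCR belongs to exactly one cell type.

    Source i is nonzero only on its own block of ``width`` OCRs, so the
    bulk restricted to that block *is* the ground truth — a deconvolution
    task that is learnable by construction.
    """
    rng = np.random.default_rng(seed)
    P = S * width
    sources = np.zeros((n_pairs, S, P), dtype=np.float32)
    for i in range(S):
        block = slice(i * width, (i + 1) * width)
        vals = rng.lognormal(mean=0.0, sigma=1.0, size=(n_pairs, width))
        sources[:, i, block] = vals
    if noise_sd > 0:
        sources += rng.normal(0, noise_sd, size=sources.shape).astype(np.float32)
        sources = np.clip(sources, 0, None)
    bulk = sources.sum(axis=1)
    c = float(max(bulk.max(), sources.max()))
    subjects = np.array(
        [f"S{1 + n % n_subjects:02d}" for n in range(n_pairs)], dtype=object
    )
    return TrainingSet(
        bulk=bulk / c,
        sources=sources / c,
        n_cells=np.ones((n_pairs, S), dtype=np.int64),
        subject=subjects,
        region=np.array(["R1"] * n_pairs, dtype=object),
        cell_types=tuple(f"T{i}" for i in range(S)),
        normalization_constant=c,
    )


@pytest.fixture(scope="session")
def disjoint_support_set() -> TrainingSet:
    return make_disjoint_support_set()
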