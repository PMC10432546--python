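"""Standard scaled-down benchmark protocols.

These functions assemble the full pipeline — synthetic snATAC generation,
pseudo-bulk pair construction, leave-one-subject-out separator training
with NMEA/tau filtering, and metric computation — at sizes a single CPU
can handle: 8 subjects x 200 pairs for the brain-like fixture and 18
pseudo-subjects x 100 pairs for the blood-like fixture, with the benchmark
averaged over a seeded subset of folds and step budgets sized to a single
CPU. The published protocol's per-pair numbers (100-800
cells per type, chunk 250, one dual-path block, 256-unit feed-forward
layers, lr 1e-3, batch 32, 20% validation split) are kept as they are.
"""

from __future__ import annotations


import numpy as np

from .evaluation import FoldResult, mean_spearman, run_loso, summarize_loso
from .separator import SeparatorConfig, separate
from .synthesize import SimulationSpec, build_training_set, generate_synthetic_snatac

#: blood-like label set: B cells, CD4+/CD8+ T cells, myeloid cells, NK cells
PBMC_CELL_TYPES: tuple[str, ...] = ("B", "CD4", "CD8", "MYELOID", "NK")


def brain_spec(seed: int) -> SimulationSpec:
    """The standard 6-cell-type brain-like fixture (P=2000, 100 markers per
    type at 8x effect, 8 subjects)."""
    return SimulationSpec(seed=seed)


def pbmc_spec(seed: int) -> SimulationSpec:
    """An independent 5-cell-type blood-like fixture over 18 pseudo-subjects."""
    return SimulationSpec(
        n_subjects=18,
        cell_types=PBMC_CELL_TYPES,
        seed=seed,
    )


def small_separator_config(
    n_sources: int,
    seed: int = 0,
    max_epochs: int = 18,
    snapshot_epochs: tuple[int, ...] = (13, 15, 17),
) -> SeparatorConfig:
    """The small configuration used for scaled-down benchmarks.

    Keeps the published chunk size (250), one dual-path block, 256-unit
    feed-forward layers, lr 1e-3 and batch 32; uses a 16-dim embedding
    with a single attention head, no chunk overlap, a step budget sized to
    the reduced number of training pairs, and weight snapshots for
    selection on the validation deconvolution objective.
    """
    return SeparatorConfig(
        n_sources=n_sources,
        chunk_size=250,
        embed_dim=16,
        n_heads=1,
        ff_dim=256,
        chunk_overlap=0.0,
        warmup_steps=50,
        max_epochs=max_epochs,
        patience=max_epochs,  # selection over snapshots replaces MSE early stopping
        snapshot_epochs=snapshot_epochs,
        seed=seed,
    )


def run_scaled_benchmark(
    spec: SimulationSpec,
    pairs_per_subject: int,
    seed: int,
    methods: tuple[str, ...] = ("dualpath",),
    max_folds: int | None = 1,
    max_train_pairs: int | None = None,
    max_epochs: int = 18,
    snapshot_epochs: tuple[int, ...] = (13, 15, 17),
) -> dict:
    """Generate data, build pairs and run the LOSO benchmark.

    Returns a dict with the generated counts, the training set, the long
    metric report, its fold-mean summary and the per-fold details (models
    kept for follow-up evaluations).
    """
    counts = generate_synthetic_snatac(spec)
    ts = build_training_set(counts, pairs_per_subject=pairs_per_subject, seed=seed)
    sep_cfg = small_separator_config(
        ts.S, seed=seed, max_epochs=max_epochs, snapshot_epochs=snapshot_epochs
    )
    report, folds = run_loso(
        ts,
        sep_cfg,
        methods=methods,
        max_folds=max_folds,
        max_train_pairs=max_train_pairs,
        seed=seed,
        keep_models=True,
    )
    return {
        "counts": counts,
        "training_set": ts,
        "report": report,
        "summary": summarize_loso(report),
        "folds": folds,
    }


def benchmark_value(summary, method: str, metric: str, cell_type: str = "overall",
                    masked: bool = True) -> float:
    row = summary[
        (summary["method"] == method)
        & (summary["masked"] == masked)
        & (summary["metric"] == metric)
        & (summary["cell_type"] == cell_type)
    ]
    return float(row["mean_value"].iloc[0])


def rare_type_spearman(
    benchmark: dict,
    cell_type: str,
    cap: float,
    seed: int,
    pairs_per_subject: int = 50,
) -> tuple[float, int]:
    """Mean Spearman for one cell type on pairs where its share of cells
    is capped below ``cap``, evaluated with each fold's trained model and
    mask on its own held-out subject. Returns (mean, n_pairs_scored)."""
    counts = benchmark["counts"]
    ts = benchmark["training_set"]
    folds: list[FoldResult] = benchmark["folds"]
    i_type = ts.cell_types.index(cell_type)
    values = []
    n_pairs = 0
    for k, fold in enumerate(folds):
        eval_set = build_training_set(
            counts,
            pairs_per_subject=pairs_per_subject,
            seed=seed + 97 * k,
            rare_fraction_caps={cell_type: cap},
            normalization_constant=ts.normalization_constant,
            subjects=(fold.held_out_subject,),
        )
        pred = separate(fold.trained, eval_set.bulk)
        sp = mean_spearman(pred, eval_set.sources, fold.mask)
        values.append(sp["per_type"][i_type])
        n_pairs += len(eval_set)
    return float(np.nanmean(values)), n_pairs


def classifier_macro_auroc(
    benchmark: dict, n_per_class: int = 120, cv_folds: int = 5, seed: int = 0
) -> tuple[float, int]:
    """Macro one-vs-rest AUROC of the boosted-tree signature classifier on
    unmixed cell type-specific pseudo-bulk rows from the fixture."""
    from .evaluation import train_cell_classifier

    ts = benchmark["training_set"]
    rng = np.random.default_rng(seed)
    pick = rng.permutation(len(ts))[:n_per_class]
    profiles = []
    labels = []
    for i, ct in enumerate(ts.cell_types):
        profiles.append(ts.sources[pick, i, :])
        labels.extend([ct] * len(pick))
    X = np.concatenate(profiles)
    _, report = train_cell_classifier(
        X, np.array(labels), cv_folds=cv_folds, seed=seed
    )
    return float(report.auroc), X.shape[0]
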