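"""Synthetic snATAC-seq generation and pseudo-bulk pair construction.

The generator emulates an annotated single-nucleus ATAC-seq experiment:
each cell type owns a disjoint block of marker OCRs with elevated
accessibility, every cell type is accessible at a random subset of the
remaining OCRs, and counts are negative-binomially distributed around
cell type-specific rates modulated by log-normal subject and region
random effects. Pseudo-bulk training pairs are built by aggregating a
random number of each subject's nuclei per cell type into ground-truth
source rows whose sum is the paired synthetic bulk sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.sparse

from .io import DEFAULT_CELL_TYPES, AnnotatedCounts, PeakSet


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of the synthetic snATAC-seq generator.

    ``baseline_rate`` is the mean count per accessible OCR per nucleus;
    markers multiply it by ``marker_effect``; OCRs closed in a cell type
    keep a tiny ``background_rate`` of sporadic insertions. ``dispersion``
    is the negative-binomial size parameter (variance = mu + mu^2 /
    dispersion). Subject and region effects are multiplicative log-normal
    with the given log-scale standard deviations.
    """

    n_subjects: int = 8
    n_regions: int = 1
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    cells_per_subject_per_type: tuple[int, int] = (200, 500)
    P: int = 2000
    markers_per_type: int = 100
    marker_effect: float = 8.0
    baseline_rate: float = 0.1
    background_rate: float = 0.005
    accessible_fraction: float = 0.7
    dispersion: float = 2.0
    subject_sd: float = 0.3
    region_sd: float = 0.2
    rare_fraction_overrides: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_type * len(self.cell_types) > self.P:
            raise ValueError(
                f"markers_per_type x n_cell_types "
                f"({self.markers_per_type} x {len(self.cell_types)}) exceeds P={self.P}"
            )
        for name in ("marker_effect", "baseline_rate", "background_rate", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.accessible_fraction < 1.0):
            raise ValueError("accessible_fraction must be in (0, 1)")
        if self.rare_fraction_overrides:
            for ct, f in self.rare_fraction_overrides.items():
                if not (0.0 < f < 1.0):
                    raise ValueError(f"fraction cap for {ct} must be in (0, 1)")
                if ct not in self.cell_types:
                    raise ValueError(f"unknown cell type in rare_fraction_overrides: {ct}")

    @property
    def S(self) -> int:
        return len(self.cell_types)

    def marker_block(self, type_index: int) -> slice:
        """OCR index block of the given cell type's markers."""
        w = self.markers_per_type
        return slice(type_index * w, (type_index + 1) * w)


def expected_rates(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Per (cell type, OCR) mean accessibility rate before random effects."""
    S, P = spec.S, spec.P
    rates = np.full((S, P), spec.background_rate)
    for i in range(S):
        accessible = rng.random(P) < spec.accessible_fraction
        rates[i, accessible] = spec.baseline_rate
        rates[i, spec.marker_block(i)] = spec.marker_effect * spec.baseline_rate
    return rates


def _negative_binomial(
    rng: np.random.Generator, mu: np.ndarray, theta: float, size: tuple[int, ...]
) -> np.ndarray:
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, np.broadcast_to(p, size))


def generate_synthetic_snatac(spec: SimulationSpec) -> AnnotatedCounts:
    """Draw an annotated cells x OCRs count matrix from the generative model."""
    rng = np.random.default_rng(spec.seed)
    S, P = spec.S, spec.P
    rates = expected_rates(spec, rng)

    subj_eff = np.exp(rng.normal(0.0, spec.subject_sd, size=(spec.n_subjects, P)))
    reg_eff = np.exp(rng.normal(0.0, spec.region_sd, size=(spec.n_regions, P)))

    lo, hi = spec.cells_per_subject_per_type
    blocks: list[scipy.sparse.csr_matrix] = []
    meta_rows: list[dict] = []
    for s in range(spec.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for r in range(spec.n_regions):
            region = f"R{r + 1}"
            for i, ct in enumerate(spec.cell_types):
                n_cells = int(rng.integers(lo, hi + 1))
                mu = rates[i] * subj_eff[s] * reg_eff[r]
                counts = _negative_binomial(rng, mu, spec.dispersion, (n_cells, P))
                blocks.append(scipy.sparse.csr_matrix(counts))
                meta_rows.extend(
                    {
                        "cell_type": ct,
                        "subject_id": subject_id,
                        "region": region,
                        "replicate_id": "rep1",
                    }
                    for _ in range(n_cells)
                )
    matrix = scipy.sparse.vstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows)
    peaks = PeakSet.from_intervals(
        [("chrS", 1000 * p, 1000 * p + 500, f"ocr_{p:05d}") for p in range(P)]
    )
    return AnnotatedCounts(matrix=matrix, cell_meta=meta, peaks=peaks)


# -- pseudo-bulk pairs -------------------------------------------------------


@dataclasses.dataclass
class PseudoBulkPair:
    """One synthetic bulk vector with its S x P ground-truth source matrix."""

    bulk: np.ndarray  # (P,)
    sources: np.ndarray  # (S, P)
    n_cells_per_type: np.ndarray  # (S,)
    subject_id: str
    region: str


def _extract_pools(
    counts: AnnotatedCounts, subject_id: str, region: str, cell_types
) -> dict[str, np.ndarray]:
    """Dense per-type cell pools (n_cells x P) for one (subject, region)."""
    meta = counts.cell_meta
    sel = (meta["subject_id"] == subject_id) & (meta["region"] == region)
    if not sel.any():
        raise ValueError(f"no cells for subject {subject_id!r} region {region!r}")
    pools = {}
    for ct in cell_types:
        idx = np.flatnonzero(sel & (meta["cell_type"] == ct))
        pools[ct] = np.asarray(counts.matrix[idx].todense(), dtype=np.int64)
    return pools


def sample_pseudobulk_pair(
    counts: AnnotatedCounts,
    subject_id: str,
    region: str,
    rng: np.random.Generator,
    n_cells_range: tuple[int, int] = (100, 800),
    cell_types: tuple[str, ...] | None = None,
    allow_absent: tuple[str, ...] = (),
    rare_fraction_caps: dict | None = None,
    _pools: dict[str, np.ndarray] | None = None,
) -> PseudoBulkPair:
    """Aggregate a random number of one subject's nuclei per cell type.

    For each cell type a random number of cells in ``n_cells_range``
    (default 100-800, the published protocol) is drawn from the subject's
    nuclei of that type — with replacement when the subject has fewer
    cells than requested — and summed into a ground-truth source row; the
    paired bulk sample is the exact column sum of the source rows. Types
    listed in ``allow_absent`` are drawn with zero cells, emulating bulk
    samples from which a cell type is missing. ``rare_fraction_caps``
    (cell type -> fraction) re-draws the capped type's cell count so its
    share of the pair's total cells stays below the cap.
    """
    if cell_types is None:
        cell_types = tuple(sorted(counts.cell_meta["cell_type"].unique()))
    S, P = len(cell_types), counts.P
    pools = _pools if _pools is not None else _extract_pools(
        counts, subject_id, region, cell_types
    )
    for ct in cell_types:
        if pools[ct].shape[0] == 0 and ct not in allow_absent:
            raise ValueError(
                f"cell type {ct!r} absent for subject {subject_id!r} and absence "
                f"not allowed"
            )
    lo, hi = n_cells_range
    n_per_type = rng.integers(lo, hi + 1, size=S)
    for i, ct in enumerate(cell_types):
        if ct in allow_absent or pools[ct].shape[0] == 0:
            n_per_type[i] = 0
    if rare_fraction_caps:
        for ct, cap in rare_fraction_caps.items():
            i = cell_types.index(ct)
            others = int(n_per_type.sum() - n_per_type[i])
            # share n_i / (n_i + others) < cap  <=>  n_i < cap/(1-cap) * others
            n_max = min(int(np.ceil(cap / (1.0 - cap) * others)) - 1, hi)
            if n_max < 1:
                raise ValueError(f"fraction cap {cap} for {ct!r} is infeasible")
            # draw from the upper half of the feasible range: a capped type
            # is rare but present near its (capped) abundance, not vanishing
            n_lo = max(1, (n_max + 1) // 2)
            n_per_type[i] = int(rng.integers(n_lo, n_max + 1))

    sources = np.zeros((S, P), dtype=np.int64)
    for i, ct in enumerate(cell_types):
        n_i = int(n_per_type[i])
        if n_i == 0:
            continue
        pool = pools[ct]
        n_pool = pool.shape[0]
        weights = np.zeros(n_pool, dtype=np.int64)
        if n_i <= n_pool:
            picked = rng.choice(n_pool, size=n_i, replace=False)
            np.add.at(weights, picked, 1)
        else:
            weights = rng.multinomial(n_i, np.full(n_pool, 1.0 / n_pool))
        sources[i] = weights @ pool
    bulk = sources.sum(axis=0)
    return PseudoBulkPair(
        bulk=bulk,
        sources=sources,
        n_cells_per_type=np.asarray(n_per_type, dtype=np.int64),
        subject_id=subject_id,
        region=region,
    )


@dataclasses.dataclass
class TrainingSet:
    """Stacked, normalized pseudo-bulk pairs ready for training/evaluation."""

    bulk: np.ndarray  # (N, P) float32, normalized
    sources: np.ndarray  # (N, S, P) float32, normalized
    n_cells: np.ndarray  # (N, S) int
    subject: np.ndarray  # (N,) str
    region: np.ndarray  # (N,) str
    cell_types: tuple[str, ...]
    normalization_constant: float
    provenance: object = None

    def __post_init__(self):
        if self.normalization_constant <= 0:
            raise ValueError("normalization_constant must be > 0")
        if self.sources.shape[1] != len(self.cell_types):
            raise ValueError("cell_types length does not match sources")

    def __len__(self) -> int:
        return self.bulk.shape[0]

    @property
    def P(self) -> int:
        return self.bulk.shape[1]

    @property
    def S(self) -> int:
        return len(self.cell_types)

    @property
    def pairs(self) -> list[PseudoBulkPair]:
        return [
            PseudoBulkPair(
                bulk=self.bulk[n],
                sources=self.sources[n],
                n_cells_per_type=self.n_cells[n],
                subject_id=str(self.subject[n]),
                region=str(self.region[n]),
            )
            for n in range(len(self))
        ]

    def subset(self, idx) -> "TrainingSet":
        idx = np.asarray(idx)
        return TrainingSet(
            bulk=self.bulk[idx],
            sources=self.sources[idx],
            n_cells=self.n_cells[idx],
            subject=self.subject[idx],
            region=self.region[idx],
            cell_types=self.cell_types,
            normalization_constant=self.normalization_constant,
            provenance=self.provenance,
        )


def normalize_pairs(
    bulk: np.ndarray,
    sources: np.ndarray,
    n_cells: np.ndarray,
    normalization_constant: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalize by cell counts, then by the global maximum OCR value.

    Each source row is divided by its own cell count and the bulk by the
    total cell count; all values are then divided by one global maximum
    taken over the whole set, which is returned for reuse at inference.
    Output values lie in [0, 1]. Evaluation sets built after training pass
    the training set's ``normalization_constant`` so they live on the
    scale the model was fitted on.
    """
    bulk = np.asarray(bulk, dtype=np.float64)
    sources = np.asarray(sources, dtype=np.float64)
    n_cells = np.asarray(n_cells)
    zero_cell = n_cells == 0
    if np.any((sources.sum(axis=2) > 0) & zero_cell):
        raise ValueError("pair has nonzero counts for a cell type with zero cells drawn")
    denom = np.where(zero_cell, 1, n_cells)[:, :, None]
    src_n = sources / denom
    total = n_cells.sum(axis=1).astype(np.float64)
    if np.any(total == 0):
        raise ValueError("pair with zero total cells")
    bulk_n = bulk / total[:, None]
    if normalization_constant is not None:
        c = float(normalization_constant)
        if c <= 0:
            raise ValueError("normalization_constant must be > 0")
    else:
        c = max(float(src_n.max()), float(bulk_n.max()))
        if c <= 0:
            c = 1.0
    return (bulk_n / c).astype(np.float32), (src_n / c).astype(np.float32), c


def build_training_set(
    counts: AnnotatedCounts,
    pairs_per_subject: int = 3000,
    n_cells_range: tuple[int, int] = (100, 800),
    seed: int = 0,
    cell_types: tuple[str, ...] | None = None,
    allow_absent: tuple[str, ...] = (),
    rare_fraction_caps: dict | None = None,
    normalization_constant: float | None = None,
    subjects: tuple[str, ...] | None = None,
) -> TrainingSet:
    """Build ``pairs_per_subject`` normalized pairs per (subject, region).

    The published protocol generates 3000 pairs per subject of 100-800
    cells each; scale ``pairs_per_subject`` down for small experiments.
    """
    if pairs_per_subject <= 0:
        raise ValueError("pairs_per_subject must be > 0")
    if cell_types is None:
        cell_types = tuple(sorted(counts.cell_meta["cell_type"].unique()))
    rng = np.random.default_rng(seed)
    groups = (
        counts.cell_meta[["subject_id", "region"]]
        .drop_duplicates()
        .sort_values(["subject_id", "region"])
        .itertuples(index=False)
    )
    if subjects is not None:
        groups = [g for g in groups if g.subject_id in subjects]
    bulks, sources, n_cells, subjects, regions = [], [], [], [], []
    for subject_id, region in groups:
        pools = _extract_pools(counts, subject_id, region, cell_types)
        for _ in range(pairs_per_subject):
            pair = sample_pseudobulk_pair(
                counts,
                subject_id,
                region,
                rng,
                n_cells_range=n_cells_range,
                cell_types=cell_types,
                allow_absent=allow_absent,
                rare_fraction_caps=rare_fraction_caps,
                _pools=pools,
            )
            bulks.append(pair.bulk)
            sources.append(pair.sources)
            n_cells.append(pair.n_cells_per_type)
            subjects.append(subject_id)
            regions.append(region)
    bulk = np.stack(bulks)
    src = np.stack(sources)
    ncl = np.stack(n_cells)
    bulk_n, src_n, c = normalize_pairs(
        bulk, src, ncl, normalization_constant=normalization_constant
    )
    return TrainingSet(
        bulk=bulk_n,
        sources=src_n,
        n_cells=ncl,
        subject=np.asarray(subjects, dtype=object),
        region=np.asarray(regions, dtype=object),
        cell_types=cell_types,
        normalization_constant=c,
        provenance=getattr(counts, "provenance", None),
    )


def save_training_set(ts: TrainingSet, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("bulk", data=ts.bulk)
        f.create_dataset("sources", data=ts.sources)
        f.create_dataset("n_cells", data=ts.n_cells)
        f.create_dataset("subject", data=ts.subject.astype("S"))
        f.create_dataset("region", data=ts.region.astype("S"))
        f.attrs["cell_types"] = list(ts.cell_types)
        f.attrs["normalization_constant"] = ts.normalization_constant


def load_training_set(path) -> TrainingSet:
    import h5py

    with h5py.File(path, "r") as f:
        return TrainingSet(
            bulk=f["bulk"][...],
            sources=f["sources"][...],
            n_cells=f["n_cells"][...],
            subject=np.array([s.decode() for s in f["subject"][...]], dtype=object),
            region=np.array([s.decode() for s in f["region"][...]], dtype=object),
            cell_types=tuple(f.attrs["cell_types"]),
            normalization_constant=float(f.attrs["normalization_constant"]),
        )
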