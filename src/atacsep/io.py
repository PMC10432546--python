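"""Readers/writers for the standard formats the pipeline touches.

Conventions shared by every module:

* peaks (OCRs) are BED intervals, 0-based half-open; their file order is
  fixed and defines the OCR column index ``p`` in every matrix;
* count matrices are cells x OCRs, stored sparse (Matrix Market on disk);
* per-cell metadata is a tab-separated table with a header;
* source tensors (samples x cell types x OCRs) and model checkpoints are
  HDF5 containers.
"""

from __future__ import annotations

import dataclasses
import logging

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: Default cell-type label set: astrocytes, microglia, oligodendrocytes,
#: oligodendrocyte progenitors, excitatory and inhibitory neurons.
DEFAULT_CELL_TYPES: tuple[str, ...] = ("AST", "MIC", "OLD", "OPC", "EXC", "INH")

META_COLUMNS = ("cell_type", "subject_id", "region", "replicate_id")


@dataclasses.dataclass(frozen=True)
class PeakSet:
    """An ordered universe of open chromatin regions.

    The order defines the OCR column index p in {0..P-1} for every matrix
    in the pipeline; peaks are never re-sorted after reading.
    """

    chrom: np.ndarray  # (P,) str
    start: np.ndarray  # (P,) int
    end: np.ndarray  # (P,) int
    peak_id: np.ndarray  # (P,) str

    def __post_init__(self):
        if not (len(self.chrom) == len(self.start) == len(self.end) == len(self.peak_id)):
            raise ValueError("PeakSet field lengths differ")
        if np.any(self.start < 0):
            raise ValueError("peak start must be >= 0")
        if np.any(self.end <= self.start):
            raise ValueError("peak end must be > start")
        if len(np.unique(self.peak_id)) != len(self.peak_id):
            raise ValueError("duplicate peak_id")

    def __len__(self) -> int:
        return len(self.peak_id)

    @property
    def P(self) -> int:
        return len(self.peak_id)

    @classmethod
    def from_intervals(cls, intervals) -> "PeakSet":
        """Build from (chrom, start, end[, peak_id]) tuples."""
        chrom, start, end, pid = [], [], [], []
        for row in intervals:
            chrom.append(str(row[0]))
            start.append(int(row[1]))
            end.append(int(row[2]))
            pid.append(str(row[3]) if len(row) > 3 else f"{row[0]}:{row[1]}-{row[2]}")
        return cls(
            chrom=np.asarray(chrom, dtype=object),
            start=np.asarray(start, dtype=np.int64),
            end=np.asarray(end, dtype=np.int64),
            peak_id=np.asarray(pid, dtype=object),
        )


@dataclasses.dataclass
class AnnotatedCounts:
    """Cells x OCRs sparse counts with per-cell annotations."""

    matrix: scipy.sparse.csr_matrix
    cell_meta: pd.DataFrame
    peaks: PeakSet

    def __post_init__(self):
        self.matrix = scipy.sparse.csr_matrix(self.matrix)
        if self.matrix.shape[1] != self.peaks.P:
            raise ValueError(
                f"count matrix has {self.matrix.shape[1]} columns but the peak "
                f"set has {self.peaks.P} peaks"
            )
        if self.matrix.shape[0] != len(self.cell_meta):
            raise ValueError(
                f"count matrix has {self.matrix.shape[0]} rows but metadata has "
                f"{len(self.cell_meta)} cells"
            )
        missing = [c for c in META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell metadata missing columns: {missing}")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def P(self) -> int:
        return self.peaks.P

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.cell_meta["cell_type"].unique())

    @property
    def subjects(self) -> list[str]:
        return sorted(self.cell_meta["subject_id"].unique())


def read_peaks_bed(path) -> PeakSet:
    """Read a 3+ column BED file (0-based half-open) into a :class:`PeakSet`."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: end ({end}) <= start ({start})"
                )
            if start < 0:
                raise ValueError(f"{path}: line {lineno}: negative start")
            row = (fields[0], start, end)
            if len(fields) >= 4 and fields[3]:
                row = row + (fields[3],)
            intervals.append(row)
    if not intervals:
        raise ValueError(f"{path}: no peaks")
    return PeakSet.from_intervals(intervals)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for c, s, e, pid in zip(peaks.chrom, peaks.start, peaks.end, peaks.peak_id):
            fh.write(f"{c}\t{s}\t{e}\t{pid}\n")


def read_count_matrix(
    matrix_path,
    peaks_path,
    meta_path,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
) -> AnnotatedCounts:
    """Read Matrix Market counts + BED peaks + TSV metadata.

    Cells whose ``cell_type`` is outside ``cell_types`` (doublets,
    unassigned nuclei, ...) are dropped; the number dropped is logged.
    """
    peaks = read_peaks_bed(peaks_path)
    matrix = scipy.sparse.csr_matrix(scipy.io.mmread(matrix_path))
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if len(meta) == 0:
        raise ValueError(f"{meta_path}: no cells")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{meta_path}: missing columns {missing}")
    if matrix.shape[1] != peaks.P:
        raise ValueError(
            f"{matrix_path}: {matrix.shape[1]} columns but {peaks_path} has "
            f"{peaks.P} peaks"
        )
    if matrix.shape[0] != len(meta):
        raise ValueError(
            f"{matrix_path}: {matrix.shape[0]} rows but {meta_path} has "
            f"{len(meta)} cells"
        )
    if matrix.nnz:
        data = matrix.data
        if np.any(data < 0) or np.any(data != np.round(data)):
            raise ValueError(f"{matrix_path}: counts must be non-negative integers")
    keep = meta["cell_type"].isin(cell_types).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d cells with cell_type outside the configured label set",
            n_dropped,
        )
        matrix = matrix[keep]
        meta = meta.loc[keep].reset_index(drop=True)
    if len(meta) == 0:
        raise ValueError("no cells left after cell-type filtering")
    return AnnotatedCounts(matrix=matrix, cell_meta=meta, peaks=peaks)


def write_count_matrix(counts: AnnotatedCounts, matrix_path, peaks_path, meta_path) -> None:
    """Inverse of :func:`read_count_matrix` (integer Matrix Market output)."""
    scipy.io.mmwrite(matrix_path, counts.matrix.astype(np.int64), field="integer")
    write_peaks_bed(counts.peaks, peaks_path)
    counts.cell_meta.to_csv(meta_path, sep="\t", index=False)


def write_source_tensor(tensor: np.ndarray, peaks: PeakSet, labels, path) -> None:
    """Write a samples x S x P source tensor to an HDF5 container."""
    tensor = np.asarray(tensor)
    if tensor.ndim != 3:
        raise ValueError("source tensor must be 3-D (samples x cell types x OCRs)")
    if not np.all(np.isfinite(tensor)):
        raise ValueError("source tensor contains non-finite values")
    labels = list(labels)
    if tensor.shape[1] != len(labels):
        raise ValueError(
            f"tensor has {tensor.shape[1]} sources but {len(labels)} labels given"
        )
    if tensor.shape[2] != peaks.P:
        raise ValueError(f"tensor has {tensor.shape[2]} OCRs but peak set has {peaks.P}")
    with h5py.File(path, "w") as f:
        f.create_dataset("sources", data=tensor)
        f.create_dataset("cell_types", data=np.array(labels, dtype="S"))
        f.create_dataset("peak_id", data=peaks.peak_id.astype("S"))


def read_source_tensor(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read back (tensor, labels, peak_ids) written by :func:`write_source_tensor`."""
    with h5py.File(path, "r") as f:
        tensor = f["sources"][...]
        labels = [s.decode() for s in f["cell_types"][...]]
        peak_ids = np.array([s.decode() for s in f["peak_id"][...]], dtype=object)
    return tensor, labels, peak_ids
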