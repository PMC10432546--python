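"""Normalized mean-absolute-error (NMEA) predictability filtering.

After training, each (cell type, OCR) position is scored by the mean
absolute prediction error over N held-out training samples, normalized by
the mean absolute ground-truth signal at that position:

    NMEA_p(i) = mean_n |pred[n,i,p] - truth[n,i,p]| / mean_n |truth[n,i,p]|

Positions with NMEA below a per-cell-type threshold M + tau * sigma (mean
and population standard deviation of the finite NMEA values over OCRs) are
retained; tau is chosen on validation pairs to maximise the mean
per-cell-type Spearman correlation between predicted and true profiles
over the retained OCRs.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.stats import rankdata

#: the threshold range is prescribed; the 0.05 step is this package's
#: choice — NMEA distributions are long-tailed, so the retained-set size
#: is a sharp function of tau and a coarser grid skips usable thresholds
DEFAULT_TAU_GRID: tuple[float, ...] = tuple(np.round(np.arange(-0.5, 1.001, 0.05), 10))


@dataclasses.dataclass
class PredictabilityScores:
    """Per (cell type, OCR) NMEA values; +inf marks zero-denominator OCRs."""

    nmea: np.ndarray  # (S, P), >= 0, +inf where undefined
    n_samples: int
    zero_denominator: np.ndarray  # (S, P) bool

    def __post_init__(self):
        if np.any(self.nmea[np.isfinite(self.nmea)] < 0):
            raise ValueError("NMEA must be non-negative")


@dataclasses.dataclass
class FilterParams:
    tau: float
    m_nmea: np.ndarray  # (S,) per-cell-type mean over finite NMEA
    sigma_nmea: np.ndarray  # (S,) per-cell-type population std

    def __post_init__(self):
        if not (-0.5 <= self.tau <= 1.0):
            raise ValueError("tau must be in [-0.5, 1]")
        if np.any(self.sigma_nmea < 0):
            raise ValueError("sigma_nmea must be >= 0")


@dataclasses.dataclass
class PredictabilityMask:
    mask: np.ndarray  # (S, P) bool
    params: FilterParams


def compute_nmea(pred: np.ndarray, truth: np.ndarray) -> PredictabilityScores:
    """Score each (cell type, OCR) by normalized mean absolute error.

    ``pred`` and ``truth`` are samples x S x P. Positions where the mean
    absolute truth is zero (the OCR is never accessible for that cell type
    in the scoring samples) get NMEA = +inf and are flagged.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if pred.ndim != 3 or pred.shape[0] < 1:
        raise ValueError("pred/truth must be (samples, S, P) with >= 1 sample")
    mea = np.abs(pred - truth).mean(axis=0)  # (S, P)
    denom = np.abs(truth).mean(axis=0)
    zero = denom == 0
    nmea = np.where(zero, np.inf, mea / np.where(zero, 1.0, denom))
    return PredictabilityScores(
        nmea=nmea, n_samples=pred.shape[0], zero_denominator=zero
    )


def select_predictable_ocrs(scores: PredictabilityScores, tau: float) -> PredictabilityMask:
    """Retain OCRs with NMEA strictly below M_NMEA + tau * sigma_NMEA.

    The mean and (population) standard deviation are computed per cell
    type over the finite NMEA values; zero-denominator OCRs are always
    excluded.
    """
    if not (-0.5 <= tau <= 1.0):
        raise ValueError("tau must be in [-0.5, 1]")
    S, P = scores.nmea.shape
    m = np.empty(S)
    sd = np.empty(S)
    mask = np.zeros((S, P), dtype=bool)
    for i in range(S):
        finite = np.isfinite(scores.nmea[i])
        if not finite.any():
            raise ValueError(f"all NMEA values are infinite for cell type index {i}")
        vals = scores.nmea[i, finite]
        m[i] = vals.mean()
        sd[i] = vals.std()  # population standard deviation
        mask[i] = finite & (scores.nmea[i] < m[i] + tau * sd[i])
        if not mask[i].any():
            warnings.warn(
                f"no OCR retained for cell type index {i} at tau={tau}",
                stacklevel=2,
            )
    return PredictabilityMask(
        mask=mask, params=FilterParams(tau=tau, m_nmea=m, sigma_nmea=sd)
    )


def rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman correlation of each row pair (tie-aware, vectorized).

    Equivalent to ``scipy.stats.spearmanr`` per row but ranks whole
    matrices at once; rows where either side has zero rank variance give
    NaN.
    """
    ra = rankdata(a, axis=1).astype(np.float64)
    rb = rankdata(b, axis=1).astype(np.float64)
    ra -= ra.mean(axis=1, keepdims=True)
    rb -= rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den2 = (ra * ra).sum(axis=1) * (rb * rb).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den2 > 0, num / np.sqrt(den2), np.nan)


def masked_mean_spearman(
    pred: np.ndarray, truth: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Mean per-cell-type Spearman over masked OCRs (used as tau objective)."""
    N, S, _ = pred.shape
    out = np.full(S, np.nan)
    for i in range(S):
        cols = np.flatnonzero(mask[i])
        if len(cols) < 3:
            continue
        rs = rowwise_spearman(pred[:, i, cols], truth[:, i, cols])
        if np.any(np.isfinite(rs)):
            out[i] = np.nanmean(rs)
    return out


def optimize_tau(
    pred_val: np.ndarray,
    truth_val: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_TAU_GRID,
    scores: PredictabilityScores | None = None,
    max_pairs: int | None = 100,
    min_retained: int = 10,
) -> tuple[float, PredictabilityMask, list[dict]]:
    """Pick the tau maximising mean per-cell-type Spearman on validation pairs.

    ``pred_val``/``truth_val`` are predictions and ground truth for
    validation pairs held out from weight fitting. NMEA scores default to
    being computed on the same validation pairs. Grid points that leave
    any cell type with fewer than ``min_retained`` OCRs are rejected (a
    filter that discards nearly everything for a cell type trivially
    maximises the mean over the survivors but is useless downstream).
    Ties are broken toward the smaller (stricter) tau. Returns
    (tau*, mask at tau*, objective curve).
    """
    grid = tuple(grid)
    if len(grid) == 0:
        raise ValueError("empty tau grid")
    if scores is None:
        scores = compute_nmea(pred_val, truth_val)
    if max_pairs is not None and pred_val.shape[0] > max_pairs:
        pred_val = pred_val[:max_pairs]
        truth_val = truth_val[:max_pairs]
    curve: list[dict] = []
    best_tau, best_obj, best_mask = None, -np.inf, None
    for tau in sorted(grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = select_predictable_ocrs(scores, tau)
        per_type = masked_mean_spearman(pred_val, truth_val, mask.mask)
        if np.any(mask.mask.sum(axis=1) < min_retained) or not np.all(
            np.isfinite(per_type)
        ):
            obj = -np.inf
        else:
            obj = float(np.mean(per_type))
        curve.append(
            {
                "tau": float(tau),
                "objective": float(obj),
                "n_retained": int(mask.mask.sum()),
            }
        )
        if obj > best_obj:  # strict: ties keep the smaller tau
            best_tau, best_obj, best_mask = float(tau), obj, mask
    if best_mask is None:
        # every grid point starved some cell type: fall back to the most
        # inclusive tau rather than failing the whole pipeline
        best_tau = float(max(grid))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            best_mask = select_predictable_ocrs(scores, best_tau)
    return best_tau, best_mask, curve


def save_mask_tsv(mask: PredictabilityMask, peak_ids, cell_types, path) -> None:
    """Write the OCR x cell-type 0/1 mask as TSV."""
    import pandas as pd

    df = pd.DataFrame(
        mask.mask.T.astype(int), index=list(peak_ids), columns=list(cell_types)
    )
    df.index.name = "peak_id"
    df.to_csv(path, sep="\t")
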