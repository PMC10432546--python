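"""Cell type-resolved differential accessibility and enrichment statistics.

Differential OCRs between two phenotype groups are called per (cell type,
region) stratum with a two-sided Wilcoxon rank-sum test, Benjamini-
Hochberg correction at FDR 5%, and an absolute log2 fold-change threshold
of 0.5. Significant OCRs are categorized by the exact set of cell types
in which they reach significance, and gene-set enrichment of OCR-linked
genes is assessed by two-sided Fisher's exact tests with BH correction
across gene sets.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EPSILON = 1e-6  # pseudocount in log2 fold changes, small vs the [0, 1] scale


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p value; exact when both groups are
    small and tie-free, normal approximation otherwise."""
    small = min(len(a), len(b)) <= 8
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def differential_ocr(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = 0.05,
    fc_min: float = 0.5,
    peak_ids=None,
    sample_ids_a=None,
    sample_ids_b=None,
) -> pd.DataFrame:
    """Differentially accessible OCRs between two sample groups.

    ``group_a``/``group_b`` are samples x P matrices of (deconvolved,
    normalized) accessibility for one cell type and region. An OCR is
    significant when its BH-adjusted two-sided Wilcoxon rank-sum p value
    is below ``alpha`` and |log2 fold change| exceeds ``fc_min``.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups have different numbers of OCRs")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("need at least 3 samples per group")
    if sample_ids_a is not None and sample_ids_b is not None:
        overlap = set(sample_ids_a) & set(sample_ids_b)
        if overlap:
            raise ValueError(f"groups share sample ids: {sorted(overlap)}")
    P = A.shape[1]
    if peak_ids is None:
        peak_ids = [f"ocr_{p:05d}" for p in range(P)]
    peak_ids = list(peak_ids)
    if len(peak_ids) != P:
        raise ValueError("peak_ids length does not match the OCR count")

    pvals = np.ones(P)
    for p in range(P):
        a, b = A[:, p], B[:, p]
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[p] = 1.0
        else:
            pvals[p] = _rank_sum_p(a, b)
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    log_fc = np.log2((mean_a + EPSILON) / (mean_b + EPSILON))
    significant = (p_adj < alpha) & (np.abs(log_fc) > fc_min)
    return pd.DataFrame(
        {
            "peak_id": peak_ids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": log_fc,
            "p_value": pvals,
            "p_adj": p_adj,
            "significant": significant,
            "direction": np.where(log_fc > 0, "up", "down"),
        }
    )


@dataclasses.dataclass
class SharingSummary:
    """How differential OCRs distribute across cell types."""

    categories: dict  # frozenset of cell types -> count of significant OCRs
    per_ocr: dict  # peak_id -> frozenset of cell types
    up_down: pd.DataFrame  # per cell type: up / down counts

    @property
    def n_significant(self) -> int:
        return len(self.per_ocr)


def categorize_sharing(tables: dict[str, pd.DataFrame]) -> SharingSummary:
    """Label each significant OCR with the exact set of cell types in
    which it is significant and count the categories."""
    universes = {ct: tuple(df["peak_id"]) for ct, df in tables.items()}
    ref = next(iter(universes.values()))
    for ct, uni in universes.items():
        if uni != ref:
            raise ValueError(f"OCR universe for {ct!r} differs from the others")
    per_ocr: dict[str, set] = {}
    rows = []
    for ct, df in tables.items():
        sig = df.loc[df["significant"]]
        for pid in sig["peak_id"]:
            per_ocr.setdefault(pid, set()).add(ct)
        rows.append(
            {
                "cell_type": ct,
                "up": int((sig["direction"] == "up").sum()),
                "down": int((sig["direction"] == "down").sum()),
            }
        )
    per_ocr_frozen = {pid: frozenset(cts) for pid, cts in per_ocr.items()}
    categories: dict = {}
    for cts in per_ocr_frozen.values():
        categories[cts] = categories.get(cts, 0) + 1
    return SharingSummary(
        categories=categories,
        per_ocr=per_ocr_frozen,
        up_down=pd.DataFrame(rows),
    )


def fisher_enrichment(
    hit_genes: set,
    trait_gene_sets: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """Two-sided Fisher's exact enrichment of ``hit_genes`` in each trait
    gene set, BH-corrected across sets.

    The 2x2 table per set is (hit n trait, hit \\ trait, trait \\ hit,
    neither), all within ``universe``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    hits = set(hit_genes) & universe
    if set(hit_genes) - universe:
        raise ValueError("hit genes outside the universe")
    rows = []
    for name, traits in trait_gene_sets.items():
        traits = set(traits)
        if traits - universe:
            raise ValueError(f"trait set {name!r} contains genes outside the universe")
        a = len(hits & traits)
        b = len(hits - traits)
        c = len(traits - hits)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "gene_set": name,
                "n_overlap": a,
                "n_hits": len(hits),
                "n_set": len(traits),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


def planted_signal_groups(
    n_per_group: int = 10,
    n_ocr: int = 200,
    n_shifted: int = 20,
    shift_factor: float = 4.0,
    noise_sd: float = 0.05,
    base_mean: float = 1.0,
    shifted_start: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two sample groups with a planted fold-change in a block of OCRs.

    Returns (group_a, group_b, shifted_index); used to check that the
    dual-threshold differential test recovers exactly the planted OCRs.
    """
    rng = np.random.default_rng(seed)
    base = base_mean * np.exp(rng.normal(0, 0.1, size=n_ocr))
    A = base * np.exp(rng.normal(0, noise_sd, size=(n_per_group, n_ocr)))
    B = base * np.exp(rng.normal(0, noise_sd, size=(n_per_group, n_ocr)))
    shifted = np.arange(shifted_start, shifted_start + n_shifted)
    A[:, shifted] *= shift_factor
    return A, B, shifted
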