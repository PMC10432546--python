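"""Leave-one-subject-out benchmarking, deconvolution metrics and
statistical model comparison.

Deconvolution quality is scored per held-out pair and cell type: Spearman
correlation between predicted and ground-truth OCR profiles, and AUROC /
AUPRC between the binarized ground truth (accessible = value > 0) and the
continuous predictions. Metrics are macro-averaged over pairs, then cell
types (pairs with degenerate truth are skipped and counted). Model
comparison uses fold-paired two-sided Wilcoxon signed-rank tests with
Bonferroni correction; replicate consistency uses a permutation null of
random partner samples.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .synthesize import TrainingSet

logger = logging.getLogger(__name__)


# -- LOSO folds --------------------------------------------------------------


def loso_folds(ts: TrainingSet) -> list[tuple[TrainingSet, TrainingSet, str]]:
    """One (train, test, held_out_subject) split per subject.

    All pairs from one subject (every region) form the test side; the test
    sides of the folds partition the pairs exactly.
    """
    subjects = sorted(set(ts.subject.tolist()))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for subj in subjects:
        test_idx = np.flatnonzero(ts.subject == subj)
        train_idx = np.flatnonzero(ts.subject != subj)
        folds.append((ts.subset(train_idx), ts.subset(test_idx), subj))
    return folds


# -- metrics -----------------------------------------------------------------


def _mask_cols(mask: np.ndarray | None, S: int, P: int) -> list[np.ndarray]:
    if mask is None:
        return [np.arange(P)] * S
    if mask.shape != (S, P):
        raise ValueError(f"mask shape {mask.shape} does not match (S={S}, P={P})")
    return [np.flatnonzero(mask[i]) for i in range(S)]


def mean_spearman(
    pred: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> dict:
    """Per-cell-type and overall mean Spearman across held-out pairs.

    For each pair and cell type the Spearman correlation is computed over
    the masked OCRs; correlations are averaged over pairs per cell type,
    and the overall value is the mean of the per-type means. Pairs whose
    truth has zero variance over the masked OCRs are skipped and counted.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 3:
        raise ValueError("pred and truth must both be (samples, S, P)")
    N, S, P = pred.shape
    cols = _mask_cols(mask, S, P)
    for i in range(S):
        if len(cols[i]) < 3:
            raise ValueError(
                f"cell type index {i}: fewer than 3 OCRs retained by the mask"
            )
    from .predictability import rowwise_spearman

    per_type = np.full(S, np.nan)
    n_skipped = 0
    for i in range(S):
        t = truth[:, i, cols[i]]
        degenerate = np.ptp(t, axis=1) == 0
        n_skipped += int(degenerate.sum())
        rs = rowwise_spearman(pred[:, i, cols[i]][~degenerate], t[~degenerate])
        if np.any(np.isfinite(rs)):
            per_type[i] = np.nanmean(rs)
    return {
        "per_type": per_type,
        "overall": float(np.nanmean(per_type)),
        "n_skipped": n_skipped,
    }


def binarized_classification_metrics(
    pred: np.ndarray, truth: np.ndarray, mask: np.ndarray | None = None
) -> dict:
    """AUROC / AUPRC of predicting binarized accessibility (truth > 0).

    Predictions are used as continuous scores; metrics are computed per
    (pair, cell type) over the masked OCRs and macro-averaged. Pairs whose
    truth is single-class over the masked OCRs are skipped and counted.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 3:
        raise ValueError("pred and truth must both be (samples, S, P)")
    N, S, P = pred.shape
    cols = _mask_cols(mask, S, P)
    auroc = np.full(S, np.nan)
    auprc = np.full(S, np.nan)
    n_skipped = 0
    any_scored = False
    for i in range(S):
        rocs, prcs = [], []
        for n in range(N):
            y = (truth[n, i, cols[i]] > 0).astype(int)
            if y.min() == y.max():
                n_skipped += 1
                continue
            s = pred[n, i, cols[i]]
            rocs.append(roc_auc_score(y, s))
            prcs.append(average_precision_score(y, s))
        if rocs:
            auroc[i] = np.mean(rocs)
            auprc[i] = np.mean(prcs)
            any_scored = True
    if not any_scored:
        raise ValueError("all (pair, cell type) combinations were single-class")
    return {
        "auroc_per_type": auroc,
        "auprc_per_type": auprc,
        "auroc": float(np.nanmean(auroc)),
        "auprc": float(np.nanmean(auprc)),
        "n_skipped": n_skipped,
    }


# -- LOSO harness ------------------------------------------------------------


@dataclasses.dataclass
class FoldResult:
    """Everything one leave-one-subject-out fold produced."""

    held_out_subject: str
    tau: float
    mask: np.ndarray  # (S, P) predictability mask at tau
    metrics: pd.DataFrame  # long format: method, masked, metric, cell_type, value
    trained: object | None = None  # TrainedSeparator when keep_models=True


def _metric_rows(method, masked, sp, bi, cell_types):
    rows = [
        {"method": method, "masked": masked, "metric": "spearman",
         "cell_type": "overall", "value": sp["overall"]},
        {"method": method, "masked": masked, "metric": "auroc",
         "cell_type": "overall", "value": bi["auroc"]},
        {"method": method, "masked": masked, "metric": "auprc",
         "cell_type": "overall", "value": bi["auprc"]},
    ]
    for i, ct in enumerate(cell_types):
        rows.append({"method": method, "masked": masked, "metric": "spearman",
                     "cell_type": ct, "value": sp["per_type"][i]})
        rows.append({"method": method, "masked": masked, "metric": "auroc",
                     "cell_type": ct, "value": bi["auroc_per_type"][i]})
        rows.append({"method": method, "masked": masked, "metric": "auprc",
                     "cell_type": ct, "value": bi["auprc_per_type"][i]})
    return rows


def run_loso(
    ts: TrainingSet,
    separator_config,
    methods: tuple[str, ...] = ("dualpath", "linear", "knn", "nmf"),
    tau: float | None = None,
    tau_grid: tuple[float, ...] | None = None,
    max_folds: int | None = None,
    max_train_pairs: int | None = None,
    baseline_train_pairs: int = 100,
    knn_k: int = 5,
    seed: int = 0,
    keep_models: bool = False,
) -> tuple[pd.DataFrame, list[FoldResult]]:
    """Run the leave-one-subject-out benchmark over the requested methods.

    Per fold: the separator is trained on the remaining subjects (its
    internal 20% validation split calibrates the NMEA filter, with tau
    optimized on the grid unless fixed), every method predicts the
    held-out subject's pairs, and Spearman/AUROC/AUPRC are computed over
    the mask-retained OCRs. ``max_folds`` evaluates a seeded subset of
    folds and ``max_train_pairs`` caps each fold's training pairs — both
    scale the benchmark down without changing the protocol. Returns a long
    metric table (one row per fold x method x metric x cell type) and the
    per-fold details.
    """
    import dataclasses as _dc

    from .baselines import fit_predict_knn, fit_predict_linear, fit_predict_nmf
    from .predictability import (
        DEFAULT_TAU_GRID,
        compute_nmea,
        optimize_tau,
        select_predictable_ocrs,
    )
    from .separator import build_separator, separate, train_separator

    if tau_grid is None:
        tau_grid = DEFAULT_TAU_GRID
    folds = loso_folds(ts)
    rng = np.random.default_rng(seed)
    if max_folds is not None and max_folds < len(folds):
        pick = sorted(rng.permutation(len(folds))[:max_folds].tolist())
        folds = [folds[i] for i in pick]

    all_rows = []
    outputs: list[FoldResult] = []
    for fold_i, (train, test, subject) in enumerate(folds):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        if max_train_pairs is not None and len(train) > max_train_pairs:
            sub = np.random.default_rng(fold_seed).permutation(len(train))
            train = train.subset(np.sort(sub[:max_train_pairs]))
        cfg = _dc.replace(separator_config, seed=fold_seed)
        model = build_separator(cfg)
        trained = train_separator(model, train, cfg)

        # NMEA filter calibrated on the validation split of the training
        # fold; when weight snapshots exist, the candidate (snapshot or
        # best-MSE weights) with the best validation deconvolution
        # objective is kept — the masked rank metric is not monotone in
        # the training MSE
        val = train.subset(trained.val_indices)

        def calibrate():
            pred_val = separate(trained, val.bulk)
            scores = compute_nmea(pred_val, val.sources)
            if tau is None:
                t_star, msk, curve = optimize_tau(
                    pred_val, val.sources, grid=tau_grid, scores=scores, max_pairs=60
                )
                obj = max(r["objective"] for r in curve)
            else:
                t_star, msk = tau, select_predictable_ocrs(scores, tau)
                sp = mean_spearman(pred_val[:60], val.sources[:60], msk.mask)
                obj = sp["overall"]
            return t_star, msk, obj

        candidates = {"best_mse": [p.data.copy() for p in trained.model.parameters()]}
        if trained.snapshots:
            candidates.update(trained.snapshots)
        best = None
        for key, weights in candidates.items():
            trained.load_weights(weights)
            t_star, msk, obj = calibrate()
            if best is None or obj > best[3]:
                best = (key, t_star, msk, obj)
        best_key, tau_star, mask, _ = best
        trained.load_weights(candidates[best_key])
        logger.info("fold %s: selected weights %r (tau=%.2f)", subject, best_key, tau_star)

        preds: dict[str, np.ndarray] = {}
        if "dualpath" in methods:
            preds["dualpath"] = separate(trained, test.bulk)
        if "linear" in methods or "knn" in methods or "nmf" in methods:
            n_base = min(baseline_train_pairs, len(train))
            bsub = np.sort(
                np.random.default_rng(fold_seed + 1).permutation(len(train))[:n_base]
            )
            base_train = train.subset(bsub)
            if "linear" in methods:
                preds["linear"] = fit_predict_linear(base_train, test.bulk)
            if "knn" in methods:
                preds["knn"] = fit_predict_knn(base_train, test.bulk, k=knn_k)
            if "nmf" in methods:
                preds["nmf"] = fit_predict_nmf(base_train, test.bulk, seed=fold_seed)

        fold_rows = []
        for method, pred in preds.items():
            sp = mean_spearman(pred, test.sources, mask.mask)
            bi = binarized_classification_metrics(pred, test.sources, mask.mask)
            fold_rows.extend(_metric_rows(method, True, sp, bi, ts.cell_types))
            if method == "dualpath":
                sp_u = mean_spearman(pred, test.sources, None)
                bi_u = binarized_classification_metrics(pred, test.sources, None)
                fold_rows.extend(_metric_rows(method, False, sp_u, bi_u, ts.cell_types))
        for r in fold_rows:
            r["fold"] = subject
        all_rows.extend(fold_rows)
        outputs.append(
            FoldResult(
                held_out_subject=subject,
                tau=float(tau_star),
                mask=mask.mask,
                metrics=pd.DataFrame(fold_rows),
                trained=trained if keep_models else None,
            )
        )
        logger.info("LOSO fold %s done (tau=%.2f)", subject, tau_star)
    report = pd.DataFrame(all_rows)
    return report, outputs


def summarize_loso(report: pd.DataFrame) -> pd.DataFrame:
    """Mean metric value over folds, per method x masked x metric x cell type."""
    return (
        report.groupby(["method", "masked", "metric", "cell_type"], as_index=False)[
            "value"
        ]
        .mean()
        .rename(columns={"value": "mean_value"})
    )


# -- statistical comparison --------------------------------------------------


def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d, 0):
        return 1.0
    return float(stats.wilcoxon(d, alternative="two-sided").pvalue)


def compare_score_groups(scores: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise fold-paired Wilcoxon signed-rank tests between methods.

    ``scores`` maps method name to a per-fold score vector; vectors are
    paired by fold so all must have equal length. P values are Bonferroni
    corrected over method pairs. For three or more groups an (unpaired)
    Kruskal-Wallis row is appended.
    """
    names = list(scores)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    lengths = {len(v) for v in scores.values()}
    if len(lengths) != 1:
        raise ValueError("groups must have equal per-fold lengths (paired by fold)")
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    for a, b in pairs:
        p = _paired_wilcoxon(scores[a], scores[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "test": "wilcoxon_signed_rank",
                "p_value": p,
                "p_bonferroni": min(1.0, p * len(pairs)),
                "median_diff": float(np.median(np.asarray(scores[a]) - np.asarray(scores[b]))),
            }
        )
    if len(names) > 2:
        groups = [np.asarray(v, dtype=float) for v in scores.values()]
        if all(np.allclose(g, groups[0]) for g in groups[1:]):
            kw_p = 1.0
        else:
            kw_p = float(stats.kruskal(*groups).pvalue)
        rows.append(
            {
                "group_a": "all",
                "group_b": "all",
                "test": "kruskal_wallis",
                "p_value": kw_p,
                "p_bonferroni": kw_p,
                "median_diff": np.nan,
            }
        )
    return pd.DataFrame(rows)


# -- replicate consistency ---------------------------------------------------


@dataclasses.dataclass
class ReplicateTestResult:
    grouping: str
    true_pair_correlations: np.ndarray
    random_pair_correlations: np.ndarray
    p_value: float  # Bonferroni-corrected two-sided Wilcoxon rank-sum
    n_random: int
    seed: int


def replicate_consistency_test(
    sources: np.ndarray,
    replicate_pairs: list[tuple[int, int]],
    strata: dict[str, np.ndarray],
    n_random: int = 100,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> list[ReplicateTestResult]:
    """Compare deconvolved profiles of true technical replicates against
    random partners drawn from the same stratum.

    ``sources`` is samples x S x P; ``replicate_pairs`` lists index pairs
    of true technical replicates; ``strata`` maps each grouping name (e.g.
    region, phenotype, both) to a per-sample stratum label array. For each
    sample the Spearman correlation with its true replicate (per cell
    type) is compared with correlations against ``n_random`` random
    partners from the same stratum, using a two-sided Wilcoxon rank-sum
    test Bonferroni-corrected over the groupings tested.
    """
    if n_random <= 0:
        raise ValueError("empty null: n_random must be positive")
    if len(replicate_pairs) < 2:
        raise ValueError("need at least 2 true replicate pairs")
    sources = np.asarray(sources)
    n_samples, S, P = sources.shape
    cols = _mask_cols(mask, S, P)
    rng = np.random.default_rng(seed)

    def pair_corr(a: int, b: int) -> list[float]:
        out = []
        for i in range(S):
            x = sources[a, i, cols[i]]
            y = sources[b, i, cols[i]]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            out.append(stats.spearmanr(x, y).statistic)
        return out

    true_corrs = []
    for a, b in replicate_pairs:
        true_corrs.extend(pair_corr(a, b))

    results = []
    for name, labels in strata.items():
        labels = np.asarray(labels)
        if len(labels) != n_samples:
            raise ValueError(f"stratum labels for {name!r} do not match sample count")
        random_corrs = []
        for a, b in replicate_pairs:
            for anchor, partner_true in ((a, b), (b, a)):
                pool = np.flatnonzero(
                    (labels == labels[anchor])
                    & (np.arange(n_samples) != anchor)
                    & (np.arange(n_samples) != partner_true)
                )
                if len(pool) == 0:
                    logger.warning(
                        "stratum %r has no random partners for sample %d; skipped",
                        name,
                        anchor,
                    )
                    continue
                partners = rng.choice(pool, size=n_random, replace=True)
                for q in partners:
                    random_corrs.extend(pair_corr(anchor, int(q)))
        p = float(
            stats.mannwhitneyu(
                true_corrs, random_corrs, alternative="two-sided"
            ).pvalue
        )
        results.append(
            ReplicateTestResult(
                grouping=name,
                true_pair_correlations=np.asarray(true_corrs),
                random_pair_correlations=np.asarray(random_corrs),
                p_value=min(1.0, p * len(strata)),
                n_random=n_random,
                seed=seed,
            )
        )
    return results


# -- cell-signature classifier ----------------------------------------------


@dataclasses.dataclass
class ClassifierReport:
    auroc: float  # macro one-vs-rest
    precision: float  # macro
    recall: float  # macro
    confusion: np.ndarray  # (S, S), rows = true class
    classes: tuple[str, ...]


def train_cell_classifier(
    profiles: np.ndarray,
    labels: np.ndarray,
    cv_folds: int = 5,
    learning_rate: float = 0.1,
    max_depth: int = 10,
    n_estimators: int = 100,
    seed: int = 0,
):
    """Gradient-boosted cell-type signature classifier with stratified CV.

    Trains an XGBoost multiclass (softmax-loss) classifier on cell
    type-specific pseudo-bulk profiles and evaluates macro AUROC /
    precision / recall by stratified K-fold cross-validation; the returned
    classifier is refit on all samples.
    """
    from xgboost import XGBClassifier

    profiles = np.asarray(profiles, dtype=np.float32)
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y)
    if counts.min() < max(5, cv_folds):
        raise ValueError(
            f"each class needs >= {max(5, cv_folds)} samples "
            f"(smallest has {counts.min()})"
        )

    def make_clf():
        return XGBClassifier(
            learning_rate=learning_rate,
            max_depth=max_depth,
            n_estimators=n_estimators,
            objective="multi:softprob",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    aurocs, precs, recs = [], [], []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for tr, te in skf.split(profiles, y):
        clf = make_clf()
        clf.fit(profiles[tr], y[tr])
        prob = clf.predict_proba(profiles[te])
        pred = prob.argmax(axis=1)
        aurocs.append(
            roc_auc_score(y[te], prob, multi_class="ovr", average="macro")
        )
        precs.append(precision_score(y[te], pred, average="macro", zero_division=0))
        recs.append(recall_score(y[te], pred, average="macro", zero_division=0))
        confusion += confusion_matrix(y[te], pred, labels=np.arange(len(classes)))
    report = ClassifierReport(
        auroc=float(np.mean(aurocs)),
        precision=float(np.mean(precs)),
        recall=float(np.mean(recs)),
        confusion=confusion,
        classes=tuple(str(c) for c in classes),
    )
    final = make_clf()
    final.fit(profiles, y)
    final._atacsep_classes = tuple(str(c) for c in classes)
    return final, report


def classify_deconvoluted(
    classifier, sources: np.ndarray, cell_types: tuple[str, ...]
) -> ClassifierReport:
    """Classify each deconvolved source row; confusion is against the
    source index the row came from."""
    sources = np.asarray(sources, dtype=np.float32)
    n, S, P = sources.shape
    classes = getattr(classifier, "_atacsep_classes", None)
    if classes is None:
        raise ValueError("classifier was not produced by train_cell_classifier")
    if classifier.n_features_in_ != P:
        raise ValueError(
            f"classifier expects {classifier.n_features_in_} OCRs, got {P}"
        )
    if tuple(cell_types) != tuple(classes):
        order = [list(classes).index(ct) for ct in cell_types]
    else:
        order = list(range(S))
    X = sources.reshape(n * S, P)
    y_true = np.repeat(np.arange(S), 1)[None, :].repeat(n, axis=0).ravel()
    y_true = np.array([order[i] for i in y_true])
    prob = classifier.predict_proba(X)
    y_pred = prob.argmax(axis=1)
    auroc = roc_auc_score(y_true, prob, multi_class="ovr", average="macro")
    report = ClassifierReport(
        auroc=float(auroc),
        precision=float(precision_score(y_true, y_pred, average="macro", zero_division=0)),
        recall=float(recall_score(y_true, y_pred, average="macro", zero_division=0)),
        confusion=confusion_matrix(y_true, y_pred, labels=np.arange(len(classes))),
        classes=tuple(classes),
    )
    return report
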