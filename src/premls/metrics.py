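"""Multi-label evaluation and the cross-validation experiment harness.

Chou's five set-based multi-label metrics compare, per sample, the true
label set Y with the predicted set Y* over the M = 4 modification types::

    Aiming         mean |Y ∩ Y*| / |Y*|     (precision-like)
    Coverage       mean |Y ∩ Y*| / |Y|      (recall-like)
    Accuracy       mean |Y ∩ Y*| / |Y ∪ Y*| (Jaccard)
    Absolute-True  mean [Y == Y*]           (exact-match rate)
    Absolute-False mean (|Y ∪ Y*| - |Y ∩ Y*|) / M

A sample whose predicted set is empty contributes 0 to Aiming and Accuracy
(its denominators would otherwise be 0 or undefined); such samples are
counted and reported.  The harness runs category-stratified k-fold
cross-validation of the full pipeline: propensity fitting, encoding, and
majority-class undersampling happen inside each training fold only, so no
information from the held-out fold leaks into the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import encoding, network, sampling
from .sampling import SampleSet
from .windowing import CATEGORY_LABELS, N_CATEGORIES, PeptideWindow, onehot_label

logger = logging.getLogger("premls")

M_LABELS = 4


@dataclass
class MetricsReport:
    aiming: float
    coverage: float
    accuracy: float
    absolute_true: float
    absolute_false: float
    n: int
    n_empty_predictions: int = 0
    per_category_absolute_true: dict[int, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # exact match implies every per-sample Jaccard term is 1
        if self.absolute_true > self.accuracy + 1e-12:
            raise ValueError("Absolute-True cannot exceed Accuracy")

    def as_dict(self) -> dict:
        return {
            "aiming": self.aiming,
            "coverage": self.coverage,
            "accuracy": self.accuracy,
            "absolute_true": self.absolute_true,
            "absolute_false": self.absolute_false,
            "n": self.n,
            "n_empty_predictions": self.n_empty_predictions,
            "per_category_absolute_true": {
                CATEGORY_LABELS[c]: v
                for c, v in sorted(self.per_category_absolute_true.items())
            },
        }


def multilabel_metrics(
    true_labels: np.ndarray,
    predicted: np.ndarray,
    categories: Sequence[int] | None = None,
) -> MetricsReport:
    """Compute the five metrics from (n, 4) binary arrays.

    ``categories`` optionally provides per-sample category ids for the
    per-category Absolute-True breakdown.
    """
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape or y.ndim != 2 or y.shape[1] != M_LABELS:
        raise ValueError(f"expected matching (n, {M_LABELS}) arrays")
    if len(y) == 0:
        raise ValueError("empty evaluation set")
    if (y.sum(axis=1) == 0).any():
        raise ValueError("every sample must have at least one true label")

    inter = (y & p).sum(axis=1)
    union = (y | p).sum(axis=1)
    size_y = y.sum(axis=1)
    size_p = p.sum(axis=1)

    empty = size_p == 0
    aiming_terms = np.where(empty, 0.0, inter / np.where(empty, 1, size_p))
    accuracy_terms = np.where(empty, 0.0, inter / np.where(union == 0, 1, union))
    exact = (inter == union).astype(float)  # Y == Y* iff |Y ∩ Y*| == |Y ∪ Y*|

    n_empty = int(empty.sum())
    if n_empty:
        logger.info("multilabel_metrics: %d empty prediction(s)", n_empty)

    per_cat: dict[int, float | None] = {}
    if categories is not None:
        per_cat = per_category_absolute_true(categories, y, p)

    return MetricsReport(
        aiming=float(aiming_terms.mean()),
        coverage=float((inter / size_y).mean()),
        accuracy=float(accuracy_terms.mean()),
        absolute_true=float(exact.mean()),
        absolute_false=float(((union - inter) / M_LABELS).mean()),
        n=len(y),
        n_empty_predictions=n_empty,
        per_category_absolute_true=per_cat,
    )


def per_category_absolute_true(
    categories: Sequence[int], true_labels: np.ndarray, predicted: np.ndarray
) -> dict[int, float | None]:
    """Exact-match fraction per category; ``None`` for absent categories."""
    cats = np.asarray(categories, dtype=int)
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    exact = (y == p).all(axis=1)
    out: dict[int, float | None] = {}
    for c in range(1, N_CATEGORIES + 1):
        mask = cats == c
        out[c] = float(exact[mask].mean()) if mask.any() else None
    return out


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

def stratified_folds(
    categories: Sequence[int], folds: int, seed: int
) -> list[np.ndarray]:
    """Category-stratified fold assignment; returns index arrays per fold.

    Categories with fewer members than folds are spread best-effort (some
    folds simply receive none of them), with a log message.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    cats = np.asarray(categories, dtype=int)
    rng = np.random.default_rng(seed)
    fold_indices: list[list[int]] = [[] for _ in range(folds)]
    for c in np.unique(cats):
        idx = np.flatnonzero(cats == c)
        if len(idx) < folds:
            logger.info(
                "stratified_folds: category %d has %d < %d members; best-effort",
                int(c), len(idx), folds,
            )
        idx = rng.permutation(idx)
        for i, j in enumerate(idx):
            fold_indices[i % folds].append(int(j))
    return [np.sort(np.array(f, dtype=int)) for f in fold_indices]


def _pipeline_fit(
    train_windows: Sequence[PeptideWindow],
    ratio: float,
    classifier_config: network.ClassifierConfig,
    sampler_seed: int,
    batch_size: int = sampling.DEFAULT_BATCH_SIZE,
    max_iter: int = sampling.DEFAULT_MAX_ITER,
    undersample_category: int = 1,
):
    """Fit propensity + undersample + train on a window collection."""
    model = encoding.fit_propensity(encoding.group_contexts_by_category(train_windows))
    feats = encoding.encode_windows(train_windows, model)
    labels = np.array([onehot_label(w.category) for w in train_windows])
    cats = np.array([w.category for w in train_windows])
    data = SampleSet(feats, labels, cats)
    if undersample_category in cats:
        data = sampling.cluster_centroids_undersample(
            data, undersample_category, ratio, seed=sampler_seed,
            batch_size=batch_size, max_iter=max_iter,
        )
    clf = network.train(data, classifier_config)
    return model, clf


def cross_validate(
    windows: Sequence[PeptideWindow],
    folds: int = 5,
    ratio: float = 0.1,
    classifier_config: network.ClassifierConfig | None = None,
    seed: int = 0,
    undersample_category: int = 1,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold cross-validation of the full pipeline.

    Per fold: fit the propensity model on the training folds, encode both
    sides, undersample the majority category of the training folds only,
    train the classifier, and evaluate on the held-out fold.  Returns the
    sample-weighted mean report and the per-fold reports.
    """
    if classifier_config is None:
        classifier_config = network.ClassifierConfig(seed=seed)
    cats = [w.category for w in windows]
    fold_idx = stratified_folds(cats, folds, seed)
    reports: list[MetricsReport] = []
    all_true, all_pred, all_cats = [], [], []
    for f, test_idx in enumerate(fold_idx):
        test_set = set(test_idx.tolist())
        train_windows = [w for i, w in enumerate(windows) if i not in test_set]
        test_windows = [windows[i] for i in test_idx]
        cfg = network.ClassifierConfig(
            **{**classifier_config.__dict__, "seed": classifier_config.seed + f}
        )
        model, clf = _pipeline_fit(
            train_windows, ratio, cfg, sampler_seed=seed + 100 + f,
            undersample_category=undersample_category,
        )
        feats = encoding.encode_windows(test_windows, model)
        pred = clf.predict(feats)
        true = np.array([onehot_label(w.category) for w in test_windows])
        tcats = [w.category for w in test_windows]
        reports.append(multilabel_metrics(true, pred, tcats))
        all_true.append(true)
        all_pred.append(pred)
        all_cats.extend(tcats)
    pooled = multilabel_metrics(
        np.vstack(all_true), np.vstack(all_pred), all_cats
    )
    return pooled, reports


def ratio_sweep(
    windows: Sequence[PeptideWindow],
    ratios: Sequence[float],
    folds: int = 5,
    classifier_config: network.ClassifierConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-category Absolute-True (in %) under cross-validation per ratio.

    Rows are undersampling ratios; columns the 11 category labels.
    """
    for r in ratios:
        if not 0 < r <= 1:
            raise ValueError(f"ratio must be in (0, 1], got {r}")
    rows = []
    for r in ratios:
        pooled, _ = cross_validate(
            windows, folds=folds, ratio=r,
            classifier_config=classifier_config, seed=seed,
        )
        rows.append(
            {
                "ratio": r,
                **{
                    CATEGORY_LABELS[c]: (
                        float("nan") if v is None else round(100.0 * v, 2)
                    )
                    for c, v in pooled.per_category_absolute_true.items()
                },
            }
        )
    return pd.DataFrame(rows).set_index("ratio")
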