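"""Cross-validation folds, stratified train/test splits and per-class
classification quality parameters.

Per-class "accuracy" follows the chemometric convention
(sensitivity + specificity) / 2, which differs from the overall fraction of
correct predictions; both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ftirprint.spectra_io import SpectralDataset


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic fold index per sample, values in 0..k-1."""

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        fi = np.asarray(self.fold_index)
        if fi.min() < 0 or fi.max() >= self.k:
            raise ValueError("fold indices out of range")
        object.__setattr__(self, "fold_index", fi)


def venetian_blinds(n: int, k: int) -> FoldAssignment:
    """Assign sample i (0-based, dataset order) to fold i mod k."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot build {k} folds from {n} samples")
    return FoldAssignment(fold_index=np.arange(n) % k, k=k)


def split_70_30(
    ds: SpectralDataset,
    frac: float = 0.7,
    seed: int = 0,
    stratify_by: str | None = "region",
    group_by_leaf: bool = False,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Random stratified train/test split at the spectrum level.

    Per-stratum sizes are rounded so the total training size equals
    round(frac * n). With ``group_by_leaf`` whole leaves (site, cane,
    leaf_position) are assigned to one side, avoiding pseudo-replicate
    leakage at the cost of exact size control.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    n = ds.n_spectra
    rng = np.random.default_rng(seed)
    if group_by_leaf:
        leaves = np.array([f"{m.site}|{m.cane}|{m.leaf_position}" for m in ds.meta])
        uniq = np.unique(leaves)
        shuffled = rng.permutation(uniq)
        n_train_leaves = int(round(frac * uniq.size))
        train_leaves = set(shuffled[:n_train_leaves])
        train_idx = np.where(np.isin(leaves, list(train_leaves)))[0]
        test_idx = np.where(~np.isin(leaves, list(train_leaves)))[0]
        return ds.subset(train_idx), ds.subset(test_idx)

    strata = (
        ds.labels(stratify_by) if stratify_by else np.zeros(n, dtype=int)
    )
    target_train = int(round(frac * n))
    train_mask = np.zeros(n, dtype=bool)
    # largest-remainder apportionment of the training quota across strata
    uniq, counts = np.unique(strata, return_counts=True)
    exact = counts * frac
    base = np.floor(exact).astype(int)
    remainder = target_train - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    take = base.copy()
    for j in order[:remainder]:
        take[j] += 1
    for label, n_take, count in zip(uniq, take, counts):
        if count < 2:
            raise ValueError(f"stratum {label!r} has fewer than 2 samples")
        idx = np.where(strata == label)[0]
        chosen = rng.choice(idx, size=n_take, replace=False)
        train_mask[chosen] = True
    train_idx = np.where(train_mask)[0]
    test_idx = np.where(~train_mask)[0]
    return ds.subset(train_idx), ds.subset(test_idx)


@dataclass
class ClassMetrics:
    """One-vs-all confusion summaries per class, on the percent scale."""

    classes: list[str]
    confusion_matrix: np.ndarray  # rows = true, cols = predicted
    per_class: pd.DataFrame  # accuracy, sensitivity, specificity, precision
    overall_accuracy: float

    def to_frame(self, algorithm: str = "") -> pd.DataFrame:
        """Rows of (algorithm, class, accuracy, sensitivity, specificity,
        precision), percentages unrounded."""
        df = self.per_class.copy()
        df.insert(0, "class", self.classes)
        if algorithm:
            df.insert(0, "algorithm", algorithm)
        return df.reset_index(drop=True)


def quality_parameters(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> ClassMetrics:
    """Per-class sensitivity, specificity, precision and accuracy.

    accuracy_c = (sensitivity_c + specificity_c) / 2. Precision for a class
    never predicted is NaN. All values are percentages.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.size == 0:
        raise ValueError("empty input")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors differ in length")
    classes = sorted(set(true_labels) | set(predicted_labels))
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        cm[idx[t], idx[p]] += 1
    n = cm.sum()
    rows = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        prec = 100.0 * tp / (tp + fp) if tp + fp else np.nan
        rows.append(
            {
                "accuracy": (sens + spec) / 2.0,
                "sensitivity": sens,
                "specificity": spec,
                "precision": prec,
            }
        )
    overall = 100.0 * np.trace(cm) / n
    return ClassMetrics(
        classes=[str(c) for c in classes],
        confusion_matrix=cm,
        per_class=pd.DataFrame(rows),
        overall_accuracy=float(overall),
    )


def display_round(x: float) -> int:
    """Half-up rounding to integer percent, as printed in report tables."""
    import math

    return int(math.floor(x + 0.5))
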