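"""SVM feature-combination search for group discrimination.

A Gaussian-RBF support vector machine is evaluated by repeated Monte-Carlo
cross-validation: each repeat draws a stratified random 75/25 train/test
split, standardises on the training subset only, selects the RBF
hyperparameters by an inner grid search on the training subset, and records
sensitivity (patient recall) and specificity (control recall) on the test
subset.  :func:`search_combinations` evaluates every feature subset up to a
size cap and ranks them by the mean of sensitivity and specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["CvConfig", "CombinationResult", "evaluate_combination", "search_combinations"]


@dataclass(frozen=True)
class CvConfig:
    """Repeated random-split cross-validation configuration."""

    train_fraction: float = 0.75
    repeats: int = 20
    seed: int = 0
    max_subset_size: int = 4
    standardize: bool = True
    c_grid: tuple[float, ...] = (1.0, 10.0, 100.0)
    gamma_grid: tuple[float, ...] = (0.3, 1.0, 3.0)  # multiples of 1/n_features
    inner_folds: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass
class CombinationResult:
    """Cross-validated performance of one feature subset."""

    features: tuple[str, ...]
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float

    @property
    def score(self) -> float:
        return 0.5 * (self.sensitivity_mean + self.specificity_mean)


def _fit_best_svm(
    xtr: np.ndarray, ytr: np.ndarray, cfg: CvConfig, rng: np.random.Generator
) -> SVC:
    """Inner grid search over (C, gamma) by stratified k-fold on the train set."""
    n_feat = xtr.shape[1]
    best, best_acc = None, -1.0
    n_splits = min(cfg.inner_folds, int(np.bincount(ytr).min()))
    for c in cfg.c_grid:
        for gmul in cfg.gamma_grid:
            gamma = gmul / n_feat
            if n_splits >= 2:
                accs = []
                skf = StratifiedKFold(
                    n_splits=n_splits,
                    shuffle=True,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                for itr, ival in skf.split(xtr, ytr):
                    clf = SVC(kernel="rbf", C=c, gamma=gamma)
                    clf.fit(xtr[itr], ytr[itr])
                    pred = clf.predict(xtr[ival])
                    recalls = [
                        (pred[ytr[ival] == cls] == cls).mean()
                        for cls in (0, 1)
                        if (ytr[ival] == cls).any()
                    ]
                    accs.append(np.mean(recalls))
                acc = float(np.mean(accs))
            else:
                acc = 0.0
            if acc > best_acc:
                best_acc = acc
                best = (c, gamma)
    clf = SVC(kernel="rbf", C=best[0], gamma=best[1])
    clf.fit(xtr, ytr)
    return clf


def evaluate_combination(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    subset: tuple[str, ...] | list[str],
    cfg: CvConfig | None = None,
    patient_label: str | int | None = None,
) -> CombinationResult:
    """Cross-validate an RBF-SVM on one feature subset.

    ``labels`` must contain exactly two classes; ``patient_label`` names
    the positive (patient) class, defaulting to the lexicographically
    larger label.  Deterministic for a fixed ``cfg.seed``.
    """
    if cfg is None:
        cfg = CvConfig()
    subset = tuple(subset)
    if not subset:
        raise ValueError("feature subset must be non-empty")
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if patient_label is None:
        patient_label = classes[-1]
    y = (labels == patient_label).astype(int)
    x = table.loc[:, list(subset)].to_numpy(dtype=float)
    ok = np.all(np.isfinite(x), axis=1)
    x, y, raw = x[ok], y[ok], labels[ok]
    if np.unique(y).size != 2:
        raise ValueError("one class has no complete observations")

    rng = np.random.default_rng(cfg.seed)
    sens, spec = [], []
    for _ in range(cfg.repeats):
        # stratified random split drawn per class of the *original* labels,
        # so the split is identical whichever class is declared positive
        # (label swap then exchanges sensitivity and specificity exactly)
        tr_idx, te_idx = [], []
        for cls in classes:
            idx = np.flatnonzero(raw == cls)
            idx = idx[rng.permutation(idx.size)]
            n_train = int(np.clip(round(cfg.train_fraction * idx.size), 1, idx.size - 1))
            tr_idx.extend(idx[:n_train])
            te_idx.extend(idx[n_train:])
        xtr, ytr = x[tr_idx], y[tr_idx]
        xte, yte = x[te_idx], y[te_idx]
        if cfg.standardize:
            scaler = StandardScaler().fit(xtr)
            xtr, xte = scaler.transform(xtr), scaler.transform(xte)
        clf = _fit_best_svm(xtr, ytr, cfg, rng)
        pred = clf.predict(xte)
        sens.append(float((pred[yte == 1] == 1).mean()) * 100.0)
        spec.append(float((pred[yte == 0] == 0).mean()) * 100.0)
    return CombinationResult(
        features=subset,
        sensitivity_mean=float(np.mean(sens)),
        sensitivity_sd=float(np.std(sens)),
        specificity_mean=float(np.mean(spec)),
        specificity_sd=float(np.std(spec)),
    )


def search_combinations(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    candidate_features: list[str],
    cfg: CvConfig | None = None,
    patient_label: str | int | None = None,
) -> list[CombinationResult]:
    """Exhaustively rank feature subsets up to ``cfg.max_subset_size``.

    Ranked by the mean of sensitivity and specificity; ties broken by
    smaller subset, then lexicographic feature order.
    """
    if cfg is None:
        cfg = CvConfig()
    if not candidate_features:
        raise ValueError("candidate feature list is empty")
    results = []
    for size in range(1, cfg.max_subset_size + 1):
        for subset in combinations(sorted(candidate_features), size):
            results.append(
                evaluate_combination(table, labels, subset, cfg, patient_label)
            )
    results.sort(key=lambda r: (-r.score, len(r.features), r.features))
    return results
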