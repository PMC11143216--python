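"""Stratified cross-validated AUROC, predictor importance, and baselines.

Evaluation follows the study protocol: stratified 10-fold cross-validation
with, per rotation, 80% training / 10% validation / 10% test (the validation
fold is the next fold cyclically), AUROC per test fold, and the mean with its
standard error over folds.  Predictor importance is measured *without
refitting*: withholding a predictor group at evaluation time makes the model
marginalize it out, and the resulting AUROC drop ranks the group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .schema import Cohort, TabularSchema
from .training import FitResult, TrainConfig, fit_model

__all__ = [
    "FoldAssignment",
    "FoldResult",
    "CVResult",
    "stratified_cv_split",
    "auroc",
    "cross_validate",
    "predictor_importance",
    "baseline_logistic",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per observation plus the train/val/test rotation rule."""

    fold: np.ndarray
    k: int
    seed: int

    def roles(self, f: int):
        """(train_idx, val_idx, test_idx) for rotation ``f``."""
        test = np.where(self.fold == f)[0]
        val = np.where(self.fold == (f + 1) % self.k)[0]
        train = np.where((self.fold != f) & (self.fold != (f + 1) % self.k))[0]
        return train, val, test


def stratified_cv_split(labels: np.ndarray, k: int = 10,
                        seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment; class proportions per fold within one
    observation of the global ones.  Both classes must have >= k members."""
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members; needs >= k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(labels.size, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        fold[test_idx] = f
    return FoldAssignment(fold=fold, k=k, seed=seed)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


@dataclass
class FoldResult:
    """Per-fold scores, labels and the resulting AUROC."""

    fold: int
    auroc: float
    n_test: int
    scores: np.ndarray
    labels: np.ndarray


@dataclass
class CVResult:
    """k fold results with mean AUROC and its standard error."""

    folds: list
    assignment: FoldAssignment
    fits: list = field(default_factory=list)

    @property
    def aurocs(self) -> np.ndarray:
        return np.array([f.auroc for f in self.folds])

    @property
    def mean_auroc(self) -> float:
        return float(self.aurocs.mean())

    @property
    def sem(self) -> float:
        a = self.aurocs
        if a.size < 2:
            return 0.0
        return float(a.std(ddof=1) / np.sqrt(a.size))


def cross_validate(cohort: Cohort, config: TrainConfig, k: int = 10,
                   seed: int = 0, d_f: Optional[int] = None,
                   keep_fits: bool = True) -> CVResult:
    """Full stratified-CV protocol: one fit per rotation, scored on its test
    fold.  Scalers, priors and parameters only ever see training rows."""
    assignment = stratified_cv_split(cohort.y, k=k, seed=seed)
    folds, fits = [], []
    for f in range(k):
        tr, va, te = assignment.roles(f)
        fit = fit_model(cohort.subset(tr), cohort.subset(va), config, d_f=d_f)
        scores = fit.predict(cohort.subset(te))
        folds.append(FoldResult(fold=f, auroc=auroc(scores, cohort.y[te]),
                                n_test=te.size, scores=scores,
                                labels=cohort.y[te]))
        if keep_fits:
            fits.append(fit)
    return CVResult(folds=folds, assignment=assignment, fits=fits)


# ---------------------------------------------------------------------------
# predictor importance by evaluation-time marginalization
# ---------------------------------------------------------------------------

def _withhold(cohort: Cohort, members: Sequence[str],
              schema: TabularSchema) -> Cohort:
    out = cohort.copy()
    cov, jdims, image = [], [], False
    for m in members:
        if m == "image":
            image = True
        elif m.startswith("J:"):
            jdims.append(int(m.split(":", 1)[1]))
        elif m in schema.names:
            cov.append(m)
        else:
            raise KeyError(f"unknown predictor-group member {m!r}")
    if cov:
        out = out.with_masked_covariates(cov)
    if jdims:
        out = out.with_masked_measurements(jdims)
    if image:
        out = out.without_images()
    return out


def predictor_importance(cv: CVResult, cohort: Cohort,
                         groups: Dict[str, Sequence[str]]) -> pd.DataFrame:
    """Mean AUROC drop (+/- SEM) when each predictor group is withheld.

    Group members are covariate names, ``"J:<dim>"`` measurement dimensions,
    or ``"image"``.  No refitting: each fold's fitted model re-scores its own
    test fold with the group's variables masked, so the model marginalizes
    them out.  Returns a DataFrame sorted by mean drop, descending.
    """
    if not cv.fits:
        raise ValueError("CVResult carries no fitted models (keep_fits=False?)")
    base = cv.aurocs
    records = []
    for label, members in groups.items():
        masked = _withhold(cohort, members, cohort.schema)
        drops = []
        for f, fit in enumerate(cv.fits):
            _, _, te = cv.assignment.roles(f)
            scores = fit.predict(masked.subset(te))
            drops.append(base[f] - auroc(scores, cohort.y[te]))
        drops = np.array(drops)
        records.append({
            "group": label,
            "mean_drop": drops.mean(),
            "sem": drops.std(ddof=1) / np.sqrt(drops.size) if drops.size > 1 else 0.0,
        })
    df = pd.DataFrame.from_records(records).sort_values(
        "mean_drop", ascending=False, ignore_index=True)
    return df


# ---------------------------------------------------------------------------
# logistic-regression baselines
# ---------------------------------------------------------------------------

def _design(cohort: Cohort, use_j: bool):
    X = cohort.A.copy()
    M = cohort.A_mask.copy()
    if use_j:
        X = np.concatenate([X, cohort.J], axis=1)
        M = np.concatenate([M, cohort.J_mask], axis=1)
    return X, M


def baseline_logistic(cohort: Cohort, assignment: FoldAssignment,
                      use_j: bool = False,
                      missing_mode: str = "mean_imputation") -> list:
    """Per-fold logistic-regression baseline on the tabular predictors.

    ``missing_mode``:
      * ``mean_imputation`` — missing entries replaced by the training-fold
        mean of the column;
      * ``complete_case``  — fit on fully observed training rows only
        (test rows are still scored with training-mean imputation, the only
        way a deleted-row model can score incomplete patients).

    Uses the same fold rotation as the probabilistic model.
    """
    if missing_mode not in ("mean_imputation", "complete_case"):
        raise ValueError(f"unknown missing_mode {missing_mode!r}")
    X, M = _design(cohort, use_j)
    y = cohort.y
    folds = []
    for f in range(assignment.k):
        tr, va, te = assignment.roles(f)
        tr_fit = np.concatenate([tr, va])  # baseline has no early stopping
        means = np.array([
            X[tr_fit][M[tr_fit][:, c], c].mean() if M[tr_fit][:, c].any() else 0.0
            for c in range(X.shape[1])])
        Xtr = np.where(M[tr_fit], X[tr_fit], means)
        ytr = y[tr_fit]
        if missing_mode == "complete_case":
            keep = M[tr_fit].all(axis=1)
            if keep.sum() < 2 or len(np.unique(ytr[keep])) < 2:
                raise ValueError("too few complete training rows for deletion")
            Xtr, ytr = Xtr[keep], ytr[keep]
        clf = LogisticRegression(C=1e6, max_iter=5000)
        clf.fit(Xtr, ytr)
        Xte = np.where(M[te], X[te], means)
        scores = clf.predict_proba(Xte)[:, 1]
        folds.append(FoldResult(fold=f, auroc=auroc(scores, y[te]),
                                n_test=te.size, scores=scores, labels=y[te]))
    return folds
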