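"""Linear discriminant analysis with leave-one-out cross-validation and
stepwise variable selection under an absolute cross-validation
improvement stopping rule.

The classifier is the standard pooled-within-covariance linear
discriminant: class k scores x via  x' S⁻¹ μ_k − ½ μ_k' S⁻¹ μ_k + log π_k,
with equal priors by default and deterministic first-label tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled within-class covariance is singular."""


@dataclass
class DfaModel:
    classes: np.ndarray            # sorted class labels
    predictors: list[str]
    means: np.ndarray              # (K, p) class means
    pooled_cov: np.ndarray         # (p, p)
    coef: np.ndarray               # (K, p) linear score weights
    intercept: np.ndarray          # (K,)
    priors: np.ndarray             # (K,)
    scalings: np.ndarray           # (p, m) discriminant axes, m = min(K-1, p)
    eigenvalues: np.ndarray        # (m,) between/within eigenvalues


@dataclass
class CvResult:
    classes: np.ndarray
    predicted: np.ndarray          # per-observation leave-one-out label
    actual: np.ndarray
    confusion: pd.DataFrame        # actual rows x predicted columns
    cv_percent: float              # 100 * correct / n

    @property
    def n(self) -> int:
        return len(self.actual)


@dataclass
class StepwiseStep:
    move: str                      # e.g. "+q50_mean", "-onset", "start"
    predictors: tuple[str, ...]
    cv_proportion: float
    accepted: bool


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep]
    selected: list[str]
    cv_result: CvResult


def _encode(table: pd.DataFrame, class_column: str,
            predictors: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = table[list(predictors)].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = [p for p in predictors if table[p].isna().any()]
        raise ValueError(f"predictors contain NaN: {bad}")
    labels = table[class_column].to_numpy()
    classes, y = np.unique(labels, return_inverse=True)
    return X, y, classes


def _pooled_stats(X: np.ndarray, y: np.ndarray,
                  n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    """Class means and pooled (unbiased) within-class covariance."""
    n, p = X.shape
    means = np.empty((n_classes, p))
    scatter = np.zeros((p, p))
    for k in range(n_classes):
        xk = X[y == k]
        means[k] = xk.mean(axis=0)
        d = xk - means[k]
        scatter += d.T @ d
    return means, scatter / (n - n_classes)


def _linear_scores(means: np.ndarray, cov: np.ndarray,
                   priors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        c, low = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError(str(exc)) from exc
    diag = np.abs(np.diag(c))
    if diag.min() <= diag.max() * 1e-7:
        raise SingularCovarianceError("ill-conditioned pooled covariance")
    coef = linalg.cho_solve((c, low), means.T).T
    intercept = -0.5 * np.sum(coef * means, axis=1) + np.log(priors)
    return coef, intercept


def fit_dfa(table: pd.DataFrame, class_column: str, predictors: list[str],
            priors: np.ndarray | None = None) -> DfaModel:
    """Fit a linear discriminant model (equal priors by default)."""
    X, y, classes = _encode(table, class_column, predictors)
    n, p = X.shape
    K = len(classes)
    if K < 2:
        raise ValueError("need at least two classes")
    counts = np.bincount(y, minlength=K)
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"every class needs n >= 2; too small: {list(small)}")
    if p >= n:
        raise ValueError(f"{p} predictors for only {n} observations")

    priors = (np.full(K, 1.0 / K) if priors is None
              else np.asarray(priors, dtype=float) / np.sum(priors))
    means, cov = _pooled_stats(X, y, K)
    try:
        coef, intercept = _linear_scores(means, cov, priors)
    except SingularCovarianceError as exc:
        raise SingularCovarianceError(
            f"singular pooled covariance for predictors {list(predictors)}"
        ) from exc

    # discriminant axes: generalized eigenproblem Sb v = lambda Sw v
    grand = X.mean(axis=0)
    d = means - grand
    Sb = (d.T * counts) @ d / (n - K)
    eigvals, eigvecs = linalg.eigh(Sb, cov)
    order = np.argsort(eigvals)[::-1][:min(K - 1, p)]
    return DfaModel(classes=classes, predictors=list(predictors), means=means,
                    pooled_cov=cov, coef=coef, intercept=intercept,
                    priors=priors, scalings=eigvecs[:, order],
                    eigenvalues=eigvals[order])


def classify(model: DfaModel, observations) -> np.ndarray:
    """Class labels with maximal discriminant score; ties break to the
    first label in sorted class order."""
    if isinstance(observations, pd.DataFrame):
        missing = set(model.predictors) - set(observations.columns)
        if missing:
            raise ValueError(f"observation missing predictors {sorted(missing)}")
        X = observations[model.predictors].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(observations, dtype=float))
        if X.shape[1] != len(model.predictors):
            raise ValueError(f"expected {len(model.predictors)} predictors, "
                             f"got {X.shape[1]}")
    scores = X @ model.coef.T + model.intercept
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# fast label-encoded internals used by LOOCV / bootstrap / pDFA loops

def _fit_raw(X: np.ndarray, y: np.ndarray,
             n_classes: int) -> tuple[np.ndarray, np.ndarray]:
    means, cov = _pooled_stats(X, y, n_classes)
    priors = np.full(n_classes, 1.0 / n_classes)
    return _linear_scores(means, cov, priors)


def _predict_raw(coef: np.ndarray, intercept: np.ndarray,
                 X: np.ndarray) -> np.ndarray:
    return np.argmax(X @ coef.T + intercept, axis=1)


def _loocv_raw(X: np.ndarray, y: np.ndarray, n_classes: int,
               warn_singular: bool = True) -> np.ndarray:
    """Leave-one-out predictions; degenerate folds predict class -1."""
    n = len(y)
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            coef, intercept = _fit_raw(X[mask], y[mask], n_classes)
            pred[i] = _predict_raw(coef, intercept, X[i:i + 1])[0]
        except SingularCovarianceError:
            if warn_singular:
                warnings.warn(f"singular covariance leaving out row {i}; "
                              "scored as misclassified")
            pred[i] = -1
        mask[i] = True
    return pred


def loocv(table: pd.DataFrame, class_column: str,
          predictors: list[str]) -> CvResult:
    """Leave-one-out cross-validation of the discriminant classifier."""
    X, y, classes = _encode(table, class_column, predictors)
    K = len(classes)
    counts = np.bincount(y, minlength=K)
    if counts.min() < 2:
        small = classes[counts < 2]
        raise ValueError(f"cannot leave out from class(es) with n = 1: "
                         f"{list(small)}")
    pred_idx = _loocv_raw(X, y, K)
    valid = pred_idx >= 0
    predicted = np.where(valid, classes[np.clip(pred_idx, 0, None)], None)
    correct = np.count_nonzero(valid & (pred_idx == y))
    confusion = pd.crosstab(pd.Series(classes[y], name="actual"),
                            pd.Series(predicted, name="predicted"),
                            dropna=False)
    extra = [c for c in confusion.columns if c not in set(classes)]
    confusion = confusion.reindex(index=classes,
                                  columns=[*classes, *extra], fill_value=0)
    return CvResult(classes=classes, predicted=predicted, actual=classes[y],
                    confusion=confusion,
                    cv_percent=100.0 * correct / len(y))


def _loocv_proportion(X: np.ndarray, y: np.ndarray, K: int,
                      cols: list[int]) -> float:
    sub = X[:, cols]
    pred = _loocv_raw(sub, y, K, warn_singular=False)
    return float(np.mean(pred == y))


def stepwise_select(table: pd.DataFrame, class_column: str,
                    candidate_predictors: list[str],
                    improvement: float = 0.05,
                    max_predictors: int | None = None,
                    forced: tuple[str, ...] = ()) -> StepwiseTrace:
    """Best-first stepwise selection scored by LOOCV proportion correct.

    Starts from the best single predictor (plus any ``forced``
    predictors, which are never removed); each round evaluates every
    single-variable inclusion and exclusion and accepts the best move
    only if it improves the LOOCV proportion by at least
    ``improvement`` (absolute). ``max_predictors`` caps the selected
    set (default: number of distinct ``individual_id`` minus one when
    that column is present, otherwise the number of candidates).
    """
    candidates = list(candidate_predictors)
    if not candidates:
        raise ValueError("no candidate predictors")
    for f in forced:
        if f not in candidates:
            candidates.append(f)
    if max_predictors is None:
        if "individual_id" in table.columns:
            max_predictors = max(1, table["individual_id"].nunique() - 1)
        else:
            max_predictors = len(candidates)
    max_predictors = max(max_predictors, len(forced), 1)

    X, y, classes = _encode(table, class_column, candidates)
    K = len(classes)
    col_of = {p: j for j, p in enumerate(candidates)}
    forced_cols = [col_of[f] for f in forced]

    steps: list[StepwiseStep] = []
    if forced_cols:
        current = list(forced_cols)
        best_score = _loocv_proportion(X, y, K, current)
    else:
        best_start, best_score = None, -1.0
        for p in candidates:
            score = _loocv_proportion(X, y, K, [col_of[p]])
            if score > best_score:
                best_start, best_score = col_of[p], score
        current = [best_start]
    steps.append(StepwiseStep(
        move="start", predictors=tuple(candidates[j] for j in current),
        cv_proportion=best_score, accepted=True))

    while True:
        moves: list[tuple[str, list[int]]] = []
        if len(current) < max_predictors:
            moves += [(f"+{p}", current + [col_of[p]])
                      for p in candidates if col_of[p] not in current]
        if len(current) > 1:
            moves += [(f"-{candidates[j]}", [c for c in current if c != j])
                      for j in current if j not in forced_cols]
        if not moves:
            break
        best_move, best_set, move_score = None, None, -1.0
        for name, cols in moves:
            score = _loocv_proportion(X, y, K, cols)
            if score > move_score:
                best_move, best_set, move_score = name, cols, score
        accepted = move_score >= best_score + improvement
        steps.append(StepwiseStep(
            move=best_move, predictors=tuple(candidates[j] for j in best_set),
            cv_proportion=move_score, accepted=accepted))
        if not accepted:
            break
        current, best_score = best_set, move_score

    selected = [candidates[j] for j in sorted(current)]
    final_cv = loocv(table, class_column, selected)
    return StepwiseTrace(steps=steps, selected=selected, cv_result=final_cv)
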