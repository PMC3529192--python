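"""Significance testing for cross-validated classification.

Two procedures:

* :func:`bootstrap_chance` — permutes class labels over calls and
  recomputes the leave-one-out CV-value to estimate the probability
  that the observed correct-assignment rate arose by chance.

* :func:`crossed_pdfa` — a permuted discriminant function analysis for
  designs where a test factor is crossed with (or constant within) a
  control subject factor. The test statistic, ncce, is the number of
  correctly cross-classified elements, averaged over random balanced
  training/cross-set selections and expressed as a percentage of
  cross-set elements. Permutations shuffle test-factor labels within
  each subject (crossed case) or whole-subject labels across subjects
  (between-subject case), so that repeated sampling of the same
  individual never inflates significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfa import (SingularCovarianceError, _fit_raw, _loocv_raw,
                  _predict_raw, loocv)


def chance_level(n_classes: int) -> float:
    """Expected percent correct under uniform random assignment."""
    if n_classes < 1:
        raise ValueError("need at least one class")
    return 100.0 / n_classes


@dataclass
class BootstrapResult:
    observed_cv_percent: float
    null_cv_percents: np.ndarray
    p_value: float
    n_randomizations: int
    seed: int | None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_cv_percents))


@dataclass
class PdfaResult:
    observed_ncce: float
    null_ncce: np.ndarray
    p_value: float
    n_permutations: int
    n_selections: int
    test_factor: str
    control_factor: str
    n_subjects: int
    n_cross_elements: int
    crossed: bool
    seed: int | None


def bootstrap_chance(table: pd.DataFrame, class_column: str,
                     predictors: list[str], n_randomizations: int = 1000,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> BootstrapResult:
    """Permutation (label-shuffling) null for the LOOCV CV-value.

    P = (1 + #{null >= observed}) / (1 + n_randomizations).
    """
    if n_randomizations < 100:
        warnings.warn(f"n_randomizations = {n_randomizations} < 100; "
                      "P-value will be unstable")
    rng = rng if rng is not None else np.random.default_rng(seed)
    observed = loocv(table, class_column, predictors)
    X = table[list(predictors)].to_numpy(dtype=float)
    _, y = np.unique(table[class_column].to_numpy(), return_inverse=True)
    K = int(y.max()) + 1
    n = len(y)
    nulls = np.empty(n_randomizations)
    for b in range(n_randomizations):
        perm = rng.permutation(y)
        pred = _loocv_raw(X, perm, K, warn_singular=False)
        nulls[b] = 100.0 * np.count_nonzero(pred == perm) / n
    p = (1 + np.count_nonzero(nulls >= observed.cv_percent)) / (
        1 + n_randomizations)
    return BootstrapResult(observed_cv_percent=observed.cv_percent,
                           null_cv_percents=nulls, p_value=float(p),
                           n_randomizations=n_randomizations, seed=seed)


# ---------------------------------------------------------------------------
# ncce engine

class _NcceEngine:
    """Precomputed design for repeated ncce evaluation under permutation."""

    def __init__(self, table: pd.DataFrame, test_factor: str,
                 control_factor: str, predictors: list[str],
                 train_fraction: float = 2.0 / 3.0):
        self.test_factor = test_factor
        self.control_factor = control_factor
        self.predictors = list(predictors)
        self.train_fraction = train_fraction
        self._warned_singular = False

        X = table[self.predictors].to_numpy(dtype=float)
        if np.isnan(X).any():
            bad = [p for p in self.predictors if table[p].isna().any()]
            raise ValueError(f"predictors contain NaN: {bad}")
        labels = table[test_factor].to_numpy()
        self.levels, y = np.unique(labels, return_inverse=True)
        subjects_all = table[control_factor].to_numpy()

        # per-subject level counts decide crossed vs between-subject design
        per_subject_levels = (pd.Series(labels).groupby(pd.Series(subjects_all))
                              .nunique())
        self.crossed = bool((per_subject_levels > 1).any())

        if self.crossed:
            keep_subjects = set(per_subject_levels[per_subject_levels >= 2].index)
            excluded = sorted(set(per_subject_levels.index) - keep_subjects)
            if excluded:
                warnings.warn(f"excluding subject(s) with a single "
                              f"{test_factor} level: {excluded}")
        else:
            keep_subjects = set(per_subject_levels.index)
        keep = np.isin(subjects_all, list(keep_subjects))
        if not keep.any():
            raise ValueError("no subject contributes calls to two or more "
                             f"levels of {test_factor}")
        self.X = X[keep]
        self.y = y[keep]
        self.subjects = subjects_all[keep]
        self.subject_ids = np.unique(self.subjects)
        self.n_levels = len(self.levels)
        self._subject_rows = {s: np.nonzero(self.subjects == s)[0]
                              for s in self.subject_ids}

    # -- balanced selections ------------------------------------------------

    def _crossed_cells(self, y: np.ndarray) -> list[np.ndarray]:
        """Row indices of each (subject, level) cell with >= 2 calls."""
        cells = []
        for s in self.subject_ids:
            rows = self._subject_rows[s]
            for lev in range(self.n_levels):
                cell = rows[y[rows] == lev]
                if len(cell) >= 2:
                    cells.append(cell)
        return cells

    def compute(self, rng: np.random.Generator, n_selections: int,
                y: np.ndarray | None = None) -> tuple[float, int]:
        """(ncce as % of cross elements, number of cross elements)."""
        y = self.y if y is None else y
        if self.crossed:
            return self._compute_crossed(rng, n_selections, y)
        return self._compute_between(rng, n_selections, y)

    def _compute_crossed(self, rng, n_selections, y) -> tuple[float, int]:
        cells = self._crossed_cells(y)
        if not cells:
            raise ValueError("no (subject x level) cell with >= 2 calls")
        m = min(len(c) for c in cells)
        n_train = max(1, int(np.floor(self.train_fraction * m)))
        n_train = min(n_train, m - 1)
        n_cross = m - n_train
        totals = np.empty(n_selections)
        n_cross_total = n_cross * len(cells)
        for sel in range(n_selections):
            train_idx, cross_idx = [], []
            for cell in cells:
                chosen = rng.choice(cell, size=m, replace=False)
                train_idx.append(chosen[:n_train])
                cross_idx.append(chosen[n_train:])
            totals[sel] = self._score(np.concatenate(train_idx),
                                      np.concatenate(cross_idx), y)
        return float(100.0 * totals.mean() / n_cross_total), n_cross_total

    def _compute_between(self, rng, n_selections, y) -> tuple[float, int]:
        # y is constant within subjects; split at subject level
        subj_level = {s: int(y[self._subject_rows[s]][0])
                      for s in self.subject_ids}
        by_level = {lev: [s for s in self.subject_ids if subj_level[s] == lev]
                    for lev in range(self.n_levels)}
        m_subj = min(len(v) for v in by_level.values())
        if m_subj < 2:
            raise ValueError("need >= 2 subjects per level of "
                             f"{self.test_factor}")
        n_train = max(1, int(np.floor(self.train_fraction * m_subj)))
        n_train = min(n_train, m_subj - 1)
        n_cross_subj = m_subj - n_train
        m_calls = min(len(rows) for rows in self._subject_rows.values())
        totals = np.empty(n_selections)
        n_cross_total = n_cross_subj * self.n_levels * m_calls
        for sel in range(n_selections):
            train_idx, cross_idx = [], []
            for lev in range(self.n_levels):
                subs = rng.choice(np.asarray(by_level[lev], dtype=object),
                                  size=m_subj, replace=False)
                for s in subs[:n_train]:
                    rows = self._subject_rows[s]
                    train_idx.append(rng.choice(rows, size=m_calls,
                                                replace=False))
                for s in subs[n_train:]:
                    rows = self._subject_rows[s]
                    cross_idx.append(rng.choice(rows, size=m_calls,
                                                replace=False))
            totals[sel] = self._score(np.concatenate(train_idx),
                                      np.concatenate(cross_idx), y)
        return float(100.0 * totals.mean() / n_cross_total), n_cross_total

    def _score(self, train: np.ndarray, cross: np.ndarray,
               y: np.ndarray) -> int:
        try:
            coef, intercept = _fit_raw(self.X[train], y[train], self.n_levels)
        except SingularCovarianceError:
            if not self._warned_singular:
                self._warned_singular = True
                warnings.warn("singular covariance in a training selection; "
                              "its cross-set scores as misclassified — "
                              "consider screening predictors for "
                              "collinearity first")
            return 0
        pred = _predict_raw(coef, intercept, self.X[cross])
        return int(np.count_nonzero(pred == y[cross]))

    # -- permutations -------------------------------------------------------

    def permute(self, rng: np.random.Generator) -> np.ndarray:
        """One null relabelling; conserves per-subject level counts in the
        crossed case (asserted per draw)."""
        if self.crossed:
            perm = self.y.copy()
            for s in self.subject_ids:
                rows = self._subject_rows[s]
                perm[rows] = rng.permutation(perm[rows])
                assert np.array_equal(np.bincount(perm[rows],
                                                  minlength=self.n_levels),
                                      np.bincount(self.y[rows],
                                                  minlength=self.n_levels)), \
                    "within-subject label counts not conserved"
            return perm
        # between-subject: shuffle subject-level labels across subjects
        subj_level = np.array([int(self.y[self._subject_rows[s]][0])
                               for s in self.subject_ids])
        shuffled = rng.permutation(subj_level)
        perm = np.empty_like(self.y)
        for s, lev in zip(self.subject_ids, shuffled):
            perm[self._subject_rows[s]] = lev
        return perm


def ncce_statistic(table: pd.DataFrame, test_factor: str, control_factor: str,
                   predictors: list[str], n_selections: int = 100,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> float:
    """Observed ncce: mean correctly cross-classified elements over
    balanced selections, as a percentage of cross-set elements."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    engine = _NcceEngine(table, test_factor, control_factor, predictors)
    ncce, _ = engine.compute(rng, n_selections)
    return ncce


def crossed_pdfa(table: pd.DataFrame, test_factor: str, control_factor: str,
                 predictors: list[str], n_permutations: int = 1000,
                 n_selections: int = 100, seed: int | None = None,
                 rng: np.random.Generator | None = None) -> PdfaResult:
    """Permuted DFA controlling for repeated sampling of subjects.

    P = (1 + #{null ncce >= observed ncce}) / (1 + n_permutations).
    Because test-factor labels are permuted within subjects (or across
    whole subjects for a between-subject factor), any factor constant
    within subjects — group, sex — is automatically held constant.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    engine = _NcceEngine(table, test_factor, control_factor, predictors)
    observed, n_cross = engine.compute(rng, n_selections)
    nulls = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = engine.permute(rng)
        nulls[b], _ = engine.compute(rng, n_selections, y=perm)
    p = (1 + np.count_nonzero(nulls >= observed)) / (1 + n_permutations)
    return PdfaResult(observed_ncce=observed, null_ncce=nulls,
                      p_value=float(p), n_permutations=n_permutations,
                      n_selections=n_selections, test_factor=test_factor,
                      control_factor=control_factor,
                      n_subjects=len(engine.subject_ids),
                      n_cross_elements=n_cross, crossed=engine.crossed,
                      seed=seed)
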