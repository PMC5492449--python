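"""Fisher LDA training and cumulative-posterior symbol selection.

The two-class discriminant assumes Gaussian classes with a shared
covariance.  With class means mu1 (target), mu0 (non-target), pooled
covariance S and priors pi1, pi0, the discriminant weight vector is
w = S^-1 (mu1 - mu0) and the posterior probability of the target class is
the logistic of the discriminant score:

    P(target | x) = sigmoid( w . x - w . (mu0 + mu1)/2 + log(pi1/pi0) ).

Symbol selection emulates the on-line system: for each spelled symbol the
per-flash target posteriors are accumulated (cumulative sum) per flashed
unit, and the row (units 0-5) and column (units 6-11) with the highest
cumulative weight identify the selected cell.  Because posteriors are
non-negative, every cumulative weight series is monotone nondecreasing.

The pooled covariance may be shrunk (Ledoit-Wolf by default): 120 features
from 900 training rows is workable but near-singular once channels are
ablated.  Shrinkage 0 reproduces the classical Fisher solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf

from .exceptions import (ConditioningError, CoverageError, DomainError,
                         LabelError)
from .preprocess import FeatureMatrix

N_UNITS = 12


@dataclass
class LdaModel:
    """A trained two-class shared-covariance discriminant."""

    weights: np.ndarray
    bias: float
    class_means: np.ndarray          # (2, n_features): [non-target, target]
    pooled_covariance: np.ndarray
    priors: np.ndarray               # [non-target, target]
    shrinkage: float

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise DomainError(
                f"feature length {X.shape[1]} does not match model "
                f"({self.n_features})")
        return X @ self.weights + self.bias

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """P(target | x) for one row or a batch; values in (0, 1)."""
        scores = self.decision_scores(X)
        # Numerically stable logistic.
        out = np.empty_like(scores)
        pos = scores >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-scores[pos]))
        e = np.exp(scores[~pos])
        out[~pos] = e / (1.0 + e)
        return out


def train_lda(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    shrinkage: float | str | None = "lw",
    priors: tuple[float, float] | None = None,
) -> LdaModel:
    """Fit the discriminant on a feature matrix with binary target labels.

    ``shrinkage`` is ``'lw'`` (Ledoit-Wolf, default), a float in [0, 1]
    toward the scaled identity, or ``None``/0 for the classical pooled
    covariance.  ``priors`` default to the class frequencies (1/6 target,
    5/6 non-target under the standard row/column design).
    """
    if isinstance(features, FeatureMatrix):
        X = features.X
        y = features.labels if labels is None else np.asarray(labels, dtype=bool)
    else:
        X = np.asarray(features, dtype=float)
        if labels is None:
            raise LabelError("labels are required when passing a bare array")
        y = np.asarray(labels, dtype=bool)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise LabelError("labels length must equal the number of feature rows")
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise LabelError("both target and non-target examples are required")

    mu0 = X[~y].mean(axis=0)
    mu1 = X[y].mean(axis=0)
    centered = X.copy()
    centered[~y] -= mu0
    centered[y] -= mu1
    p = X.shape[1]

    if shrinkage == "lw":
        cov, lam = ledoit_wolf(centered, assume_centered=True)
    elif shrinkage in (None, 0, 0.0):
        cov = centered.T @ centered / max(1, len(y) - 2)
        lam = 0.0
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            raise ConditioningError(
                "pooled covariance is numerically singular; enable shrinkage")
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise DomainError("shrinkage must be in [0, 1]")
        emp = centered.T @ centered / max(1, len(y) - 2)
        cov = (1.0 - lam) * emp + lam * (np.trace(emp) / p) * np.eye(p)

    weights = np.linalg.solve(cov, mu1 - mu0)
    if priors is None:
        priors = (n0 / len(y), n1 / len(y))
    pi0, pi1 = priors
    if not (0 < pi0 < 1 and 0 < pi1 < 1):
        raise DomainError("priors must lie strictly inside (0, 1)")
    bias = float(-weights @ (mu0 + mu1) / 2.0 + np.log(pi1 / pi0))
    return LdaModel(weights=weights, bias=bias,
                    class_means=np.stack([mu0, mu1]), pooled_covariance=cov,
                    priors=np.array([pi0, pi1]), shrinkage=float(lam))


def score_flash(model: LdaModel, feature_row: np.ndarray) -> float:
    """Posterior probability of the target class for a single flash."""
    return float(model.posterior(np.atleast_2d(feature_row))[0])


@dataclass
class SelectionResult:
    """Outcome of cumulative-posterior selection for one spelled symbol."""

    cumulative: list[np.ndarray]          # per unit, nondecreasing series
    chosen: tuple[int, int]               # (row, col) indices
    truth: tuple[int, int] | None = None
    symbol_index: int = 0
    tie_row: bool = False
    tie_col: bool = False

    @property
    def correct(self) -> bool | None:
        if self.truth is None:
            return None
        return self.chosen == self.truth

    @property
    def final_weights(self) -> np.ndarray:
        return np.array([series[-1] for series in self.cumulative])


def accumulate_unit_weights(posteriors: np.ndarray, units: np.ndarray,
                            n_units: int = N_UNITS) -> list[np.ndarray]:
    """Cumulative posterior sum per flashed unit, in flash order."""
    posteriors = np.asarray(posteriors, dtype=float)
    units = np.asarray(units, dtype=int)
    if posteriors.shape != units.shape:
        raise DomainError("posteriors and units must have equal length")
    series = []
    for u in range(n_units):
        vals = posteriors[units == u]
        if vals.size == 0:
            raise CoverageError(f"unit {u} never flashed in this symbol")
        series.append(np.cumsum(vals))
    return series


def select_from_weights(
    cumulative: list[np.ndarray],
    truth: tuple[int, int] | None = None,
    symbol_index: int = 0,
    n_rows: int = 6,
) -> SelectionResult:
    """Argmax the final cumulative weights over rows and over columns.

    Ties break toward the lowest unit index and are flagged on the result.
    """
    finals = np.array([s[-1] for s in cumulative])
    rows, cols = finals[:n_rows], finals[n_rows:]
    r = int(np.argmax(rows))
    c = int(np.argmax(cols))
    tie_row = bool(np.sum(rows == rows[r]) > 1)
    tie_col = bool(np.sum(cols == cols[c]) > 1)
    return SelectionResult(cumulative=cumulative, chosen=(r, c), truth=truth,
                           symbol_index=symbol_index, tie_row=tie_row,
                           tie_col=tie_col)


def select_symbol(
    model: LdaModel,
    features: FeatureMatrix,
    truth: tuple[int, int] | None = None,
    symbol_index: int | None = None,
) -> SelectionResult:
    """Classify every flash of one symbol and select the (row, column) cell."""
    posteriors = model.posterior(features.X)
    units = features.row_labels["unit"].to_numpy(dtype=int)
    cumulative = accumulate_unit_weights(posteriors, units)
    if symbol_index is None:
        symbol_index = int(features.row_labels["symbol_index"].iloc[0])
    return select_from_weights(cumulative, truth=truth, symbol_index=symbol_index)


def _truth_from_labels(features: FeatureMatrix) -> tuple[int, int]:
    """Recover the target (row, col) of one symbol from its flash labels."""
    rl = features.row_labels
    target_units = sorted(rl.loc[rl["is_target"] == 1, "unit"].unique())
    rows = [u for u in target_units if u < 6]
    cols = [u - 6 for u in target_units if u >= 6]
    if len(rows) != 1 or len(cols) != 1:
        raise CoverageError("cannot recover a unique target cell from labels")
    return rows[0], cols[0]


def classify_phase(model: LdaModel, features: FeatureMatrix) -> list[SelectionResult]:
    """Select one symbol per spelled symbol in a performance-phase matrix."""
    results = []
    for sym in sorted(features.row_labels["symbol_index"].unique()):
        sub = features.for_symbol(int(sym))
        truth = _truth_from_labels(sub)
        results.append(select_symbol(model, sub, truth=truth,
                                     symbol_index=int(sym)))
    return results


def selection_accuracy(results: list[SelectionResult]) -> float:
    """Percent of correctly selected symbols."""
    if not results:
        raise DomainError("no selection results")
    correct = [r.correct for r in results]
    if any(c is None for c in correct):
        raise DomainError("selection results lack ground truth")
    return 100.0 * float(np.mean(correct))


@dataclass
class AblationResult:
    """Full-montage vs reduced-montage accuracy, Table-style 'acc (reduction)'."""

    full_accuracy: float
    reduced_accuracy: float
    dropped: tuple[str, ...] = field(default_factory=tuple)

    @property
    def reduction_pct(self) -> float:
        """Percent decrease relative to the full-montage accuracy."""
        if self.full_accuracy == 0:
            return 0.0
        return 100.0 * (self.full_accuracy - self.reduced_accuracy) / self.full_accuracy

    def __str__(self) -> str:
        return f"{self.reduced_accuracy:g} ({self.reduction_pct:.1f})"


def ablate_channels(
    train_features: FeatureMatrix,
    perf_features: FeatureMatrix,
    drop: tuple[str, ...] = ("Pz", "PO7", "PO8"),
    shrinkage: float | str | None = "lw",
) -> AblationResult:
    """Retrain and re-classify after removing the named electrodes.

    Feature columns of the dropped channels are removed from both phases,
    the classifier is retrained from scratch on the reduced training matrix
    and the performance phase is re-classified.
    """
    full_model = train_lda(train_features, shrinkage=shrinkage)
    full_acc = selection_accuracy(classify_phase(full_model, perf_features))
    if drop:
        red_train = train_features.drop_channels(list(drop))
        red_perf = perf_features.drop_channels(list(drop))
    else:
        red_train, red_perf = train_features, perf_features
    red_model = train_lda(red_train, shrinkage=shrinkage)
    red_acc = selection_accuracy(classify_phase(red_model, red_perf))
    return AblationResult(full_accuracy=full_acc, reduced_accuracy=red_acc,
                          dropped=tuple(drop))
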