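"""Redundancy removal by pairwise-correlation thresholding (20 -> ~15 features).

Features whose absolute pairwise Pearson correlation reaches the threshold
(default |r| >= 0.95) carry redundant information; iteratively, the
higher-canonical-index member of the currently most-correlated pair is
dropped and correlations are re-examined, until no pair reaches the
threshold.  The procedure is deterministic given the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, InsufficientDataError
from .features import FEATURE_NAMES


@dataclass
class ReductionReport:
    threshold: float
    removed: list = field(default_factory=list)  # (feature, partner, r) in removal order
    retained: list = field(default_factory=list)
    constant: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "removed": [
                {"feature": f, "partner": p, "r": r} for f, p, r in self.removed
            ],
            "retained": list(self.retained),
            "constant": list(self.constant),
        }


class CorrelationThresholdReducer(TransformerMixin, BaseEstimator):
    """Drop the redundant member of every feature pair with |r| >= threshold.

    Parameters
    ----------
    threshold : float, default 0.95
        Absolute Pearson correlation at or above which a pair is redundant.

    Attributes
    ----------
    retained_ : list of str
        Features kept, in canonical order.
    removed_ : list of (feature, partner, r)
        Dropped features with the pair that triggered each removal.
    report_ : ReductionReport
    """

    def __init__(self, threshold: float = 0.95):
        self.threshold = threshold

    def _validate_matrix(self, X) -> tuple[np.ndarray, list[str]]:
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError(f"threshold must be in (0, 1], got {self.threshold}")
        if isinstance(X, pd.DataFrame):
            names = [c for c in X.columns if c not in ("subject_id", "condition", "block_onset")]
            values = X[names].to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else f"f{i}" for i in range(values.shape[1])]
        if values.shape[0] < 3:
            raise InsufficientDataError("correlation-based reduction needs >= 3 rows")
        if np.isnan(values).any():
            raise InsufficientDataError("feature matrix contains missing values")
        return values, names

    def fit(self, X, y=None):
        values, names = self._validate_matrix(X)
        sds = values.std(axis=0)
        constant = [names[i] for i in np.flatnonzero(sds == 0)]
        if constant:
            warnings.warn(
                f"constant feature(s) {constant} have undefined correlations; retained as-is",
                UserWarning,
                stacklevel=2,
            )
        active = [i for i in range(len(names)) if sds[i] > 0]
        removed: list[tuple[str, str, float]] = []
        while len(active) >= 2:
            sub = values[:, active]
            corr = np.corrcoef(sub, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            absr = np.abs(corr)
            i, j = np.unravel_index(int(np.argmax(absr)), absr.shape)
            if absr[i, j] < self.threshold:
                break
            lo, hi = sorted((active[i], active[j]))
            removed.append((names[hi], names[lo], float(corr[i, j])))
            active.remove(hi)
        removed_names = {f for f, _, _ in removed}
        self.feature_names_in_ = list(names)
        self.removed_ = removed
        self.retained_ = [n for n in names if n not in removed_names]
        self.report_ = ReductionReport(
            threshold=self.threshold,
            removed=removed,
            retained=self.retained_,
            constant=constant,
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "retained_")
        if isinstance(X, pd.DataFrame):
            meta = [c for c in ("subject_id", "condition") if c in X.columns]
            out = X[meta + self.retained_].copy()
            out.attrs["provenance"] = "reduced"
            return out
        X = np.asarray(X, dtype=float)
        idx = [self.feature_names_in_.index(n) for n in self.retained_]
        return X[:, idx]


def reduce_by_correlation(matrix: pd.DataFrame, threshold: float = 0.95) -> ReductionReport:
    """Functional wrapper around :class:`CorrelationThresholdReducer`."""
    return CorrelationThresholdReducer(threshold=threshold).fit(matrix).report_
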