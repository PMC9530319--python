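"""Indicator weights from eigen-analysis of the cohort correlation matrix.

The weighting stage standardizes the nine indicators to z-scores, eigen-
decomposes their correlation matrix, keeps the leading components whose
eigenvalues exceed 1 and whose cumulative variance share exceeds 85%, and
blends the retained component score coefficients by their contribution
rates into a single weight vector A:

    raw_i = sum_j a_ij * c_j / sum_j c_j,      A = raw / sum(raw)

where a_ij is indicator i's score coefficient on component j and
c_j = lambda_j / p is component j's contribution rate.  The unit-sum
normalization makes A a proper set of averaging weights for the fuzzy
composition stage.

Score coefficients are the unit-norm eigenvector entries; factor loadings
are coefficients scaled by sqrt(lambda).  :func:`loadings_to_coefficients`
converts a published loading matrix back to score coefficients, and
:func:`eigenvalues_from_loading_ratio` recovers the eigenvalues from a
loading/coefficient pair when only those two tables are available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (
    ComponentSelectionError,
    ConversionError,
    DegenerateIndicatorError,
    ValidationError,
    WeightDegeneracyError,
)
from .rubric import INDICATOR_NAMES, IndicatorProfile
from .profiles import cohort_matrix

__all__ = [
    "StandardizedMatrix",
    "WeightModel",
    "PrincipalComponentWeights",
    "standardize",
    "eigen_components",
    "contribution_rates",
    "select_components",
    "loadings_to_coefficients",
    "coefficients_to_loadings",
    "eigenvalues_from_loading_ratio",
    "compute_weights",
]


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column-wise z-scores with the standardization parameters kept."""

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray


@dataclass
class WeightModel:
    """A fitted weighting model, serializable to JSON.

    ``coefficients`` holds the component score coefficients column per
    component (p x m); ``contributions`` the individual contribution rates
    c_j; ``weights`` the normalized indicator weight vector A.
    """

    eigenvalues: np.ndarray
    coefficients: np.ndarray
    contributions: np.ndarray
    cumulative: np.ndarray
    n_selected: int
    weights: np.ndarray
    n_subjects: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.contributions = np.asarray(self.contributions, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValidationError("eigenvalues must be sorted descending")
        if abs(self.contributions.sum() - 1.0) > 1e-9 and len(
            self.contributions
        ) == len(self.eigenvalues):
            raise ValidationError("contribution rates must sum to 1")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")
        if self.n_selected < 1:
            raise ValidationError("n_selected must be at least 1")

    def to_json(self) -> str:
        doc = {
            "eigenvalues": self.eigenvalues.tolist(),
            "coefficients": self.coefficients.tolist(),
            "contributions": self.contributions.tolist(),
            "cumulative": self.cumulative.tolist(),
            "n_selected": int(self.n_selected),
            "weights": self.weights.tolist(),
            "n_subjects": self.n_subjects,
            "metadata": self.metadata,
            "indicator_order": list(INDICATOR_NAMES),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "WeightModel":
        doc = json.loads(text)
        return cls(
            eigenvalues=doc["eigenvalues"],
            coefficients=doc["coefficients"],
            contributions=doc["contributions"],
            cumulative=doc["cumulative"],
            n_selected=doc["n_selected"],
            weights=doc["weights"],
            n_subjects=doc.get("n_subjects"),
            metadata=doc.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "WeightModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if all(name in X.columns for name in INDICATOR_NAMES):
            X = X[list(INDICATOR_NAMES)]
        X = X.to_numpy(dtype=float)
    elif len(X) and isinstance(next(iter(X)), IndicatorProfile):
        X = cohort_matrix(X)
    return check_array(X, dtype=float, ensure_min_samples=2, ensure_min_features=2)


def standardize(cohort) -> StandardizedMatrix:
    """Column-wise z-scores with the sample (n-1) standard deviation."""
    X = _as_matrix(cohort)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = [
            INDICATOR_NAMES[i] if X.shape[1] == len(INDICATOR_NAMES) else str(i)
            for i in np.flatnonzero(sds == 0)
        ]
        raise DegenerateIndicatorError(f"constant indicator column(s): {bad}")
    return StandardizedMatrix(values=(X - means) / sds, means=means, sds=sds)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector columns so the largest-magnitude entry is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


def eigen_components(z: StandardizedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose the correlation matrix of the standardized data.

    Returns (eigenvalues descending, coefficients p x m) where the
    coefficient columns are unit-norm eigenvectors with the sign fixed so
    each column's largest-magnitude entry is positive.
    """
    Z = z.values
    n = Z.shape[0]
    corr = Z.T @ Z / (n - 1)
    if not np.all(np.isfinite(corr)):
        raise ValidationError("non-finite values in correlation matrix")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    return eigvals, _fix_signs(eigvecs[:, order])


def contribution_rates(eigenvalues: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Individual and cumulative variance shares of the eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0):
        raise ValidationError("eigenvalues must be nonnegative")
    total = lam.sum()
    if total <= 0:
        raise DegenerateIndicatorError("all eigenvalues are zero")
    individual = lam / total
    return individual, np.cumsum(individual)


def select_components(
    eigenvalues: Sequence[float],
    eigen_min: float = 1.0,
    cum_min: float = 0.85,
    fallback: bool = False,
) -> int:
    """Smallest component count with all eigenvalues > eigen_min and
    cumulative contribution > cum_min.

    Raises :class:`ComponentSelectionError` when the rules cannot be met
    (unless ``fallback`` allows degrading to a single component).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    _, cumulative = contribution_rates(lam)
    for n in range(1, len(lam) + 1):
        if lam[n - 1] <= eigen_min:
            break
        if cumulative[n - 1] > cum_min:
            return n
    if fallback:
        return 1
    raise ComponentSelectionError(
        f"no component prefix has all eigenvalues > {eigen_min} and "
        f"cumulative contribution > {cum_min}"
    )


def loadings_to_coefficients(loadings, eigenvalues) -> np.ndarray:
    """Convert factor loadings to component score coefficients.

    coefficient_ij = loading_ij / sqrt(lambda_j).
    """
    L = np.asarray(loadings, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)[: L.shape[1]]
    if np.any(lam <= 0):
        raise ConversionError("loading conversion needs strictly positive eigenvalues")
    return L / np.sqrt(lam)


def coefficients_to_loadings(coefficients, eigenvalues) -> np.ndarray:
    """Inverse of :func:`loadings_to_coefficients`."""
    C = np.asarray(coefficients, dtype=float)
    lam = np.asarray(eigenvalues, dtype=float)[: C.shape[1]]
    if np.any(lam <= 0):
        raise ConversionError("loading conversion needs strictly positive eigenvalues")
    return C * np.sqrt(lam)


def eigenvalues_from_loading_ratio(
    loadings, coefficients, min_coefficient: float = 0.05
) -> np.ndarray:
    """Recover eigenvalues from a published loading/coefficient pair.

    Since loading = coefficient * sqrt(lambda), each component's eigenvalue
    is the squared ratio; averaging over indicators smooths the rounding of
    the printed tables.  Entries with |coefficient| < ``min_coefficient``
    are excluded because the ratio of two near-zero rounded numbers is
    dominated by rounding error.
    """
    L = np.asarray(loadings, dtype=float)
    C = np.asarray(coefficients, dtype=float)
    if L.shape != C.shape:
        raise ValidationError("loadings and coefficients must share a shape")
    lam = np.empty(L.shape[1])
    for j in range(L.shape[1]):
        keep = np.abs(C[:, j]) >= min_coefficient
        if not keep.any():
            raise ConversionError(f"component {j}: all coefficients negligible")
        lam[j] = np.mean((L[keep, j] / C[keep, j]) ** 2)
    return lam


def compute_weights(coefficients, rates) -> np.ndarray:
    """Blend score-coefficient columns by contribution rates into weights A.

    raw_i = sum_j a_ij c_j / sum_j c_j, then A = raw / sum(raw) so the
    weights are nonnegative-summing-to-one averaging weights.
    """
    C = np.asarray(coefficients, dtype=float)
    c = np.asarray(rates, dtype=float)
    if C.shape[1] != c.shape[0]:
        raise ValidationError(
            f"coefficient columns ({C.shape[1]}) != rates ({c.shape[0]})"
        )
    if c.sum() <= 0:
        raise WeightDegeneracyError("contribution rates sum to a non-positive value")
    raw = C @ c / c.sum()
    total = raw.sum()
    if total <= 0:
        raise WeightDegeneracyError(f"raw weights sum to {total}; cannot normalize")
    return raw / total


class PrincipalComponentWeights(TransformerMixin, BaseEstimator):
    """Derive the indicator weight vector A from a cohort matrix.

    Parameters
    ----------
    eigen_min : float, default 1.0
        Components must have eigenvalue strictly above this to be retained.
    cum_min : float, default 0.85
        Retained components must jointly explain more than this share of
        total variance.
    n_components : int or None
        Bypass the selection rule with a fixed component count.
    fallback : bool, default False
        Degrade to one component instead of raising when the selection
        rules cannot be satisfied.

    Attributes
    ----------
    weights_ : ndarray of shape (p,)
        Normalized indicator weights (sum to 1).
    eigenvalues_, coefficients_, contributions_, cumulative_, n_selected_
        Intermediate quantities of the derivation.

    Examples
    --------
    >>> est = PrincipalComponentWeights().fit(X)   # X: (n_subjects, 9)
    >>> est.weights_.sum()
    1.0
    """

    def __init__(
        self,
        eigen_min: float = 1.0,
        cum_min: float = 0.85,
        n_components: Optional[int] = None,
        fallback: bool = False,
    ):
        self.eigen_min = eigen_min
        self.cum_min = cum_min
        self.n_components = n_components
        self.fallback = fallback

    def fit(self, X, y=None):
        z = standardize(X)
        self.means_ = z.means
        self.sds_ = z.sds
        self.n_subjects_ = z.values.shape[0]
        self.n_features_in_ = z.values.shape[1]
        self.eigenvalues_, self.coefficients_ = eigen_components(z)
        self.contributions_, self.cumulative_ = contribution_rates(self.eigenvalues_)
        if self.n_components is not None:
            if not 1 <= self.n_components <= len(self.eigenvalues_):
                raise ComponentSelectionError(
                    f"n_components={self.n_components} out of range"
                )
            self.n_selected_ = int(self.n_components)
        else:
            self.n_selected_ = select_components(
                self.eigenvalues_, self.eigen_min, self.cum_min, self.fallback
            )
        m = self.n_selected_
        self.weights_ = compute_weights(
            self.coefficients_[:, :m], self.contributions_[:m]
        )
        return self

    def transform(self, X):
        """Project standardized measurements onto the retained components."""
        check_is_fitted(self, "weights_")
        X = _as_matrix(X)
        Z = (X - self.means_) / self.sds_
        return Z @ self.coefficients_[:, : self.n_selected_]

    def to_model(self) -> WeightModel:
        check_is_fitted(self, "weights_")
        return WeightModel(
            eigenvalues=self.eigenvalues_,
            coefficients=self.coefficients_,
            contributions=self.contributions_,
            cumulative=self.cumulative_,
            n_selected=self.n_selected_,
            weights=self.weights_,
            n_subjects=self.n_subjects_,
            metadata={
                "standardization": "sample-sd (ddof=1)",
                "matrix": "correlation",
                "sign_convention": "largest-magnitude entry positive",
                "eigen_min": self.eigen_min,
                "cum_min": self.cum_min,
            },
        )


def fit_weights(cohort: Iterable[IndicatorProfile], **kwargs) -> WeightModel:
    """One-call convenience: cohort -> fitted :class:`WeightModel`."""
    return PrincipalComponentWeights(**kwargs).fit(cohort_matrix(list(cohort))).to_model()
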