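"""Subject-level fuzzy assessment: relation matrix, composition, verdict.

For one subject the pipeline is

1. scale each raw indicator to an ability value r in [0, 1],
2. evaluate the four rubric membership functions at each r, giving the
   9 x 4 fuzzy relation matrix R,
3. compose R with the indicator weights A by the weighted-sum operator
   b_j = sum_i A_i R_ij, giving the level-evidence vector B,
4. defuzzify by the weighted average of rubric values,
   u* = sum_i V_i b_i / sum_i b_i,
5. assign the verdict level whose rubric value is nearest to u*
   (exact midpoints resolve to the more severe level).

The weighted-sum composition is used rather than max-min because the
defuzzification is an averaging principle: max-min would discard the
weight magnitudes that the eigen-analysis was run to obtain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .defaults import default_scalings, default_weights
from .exceptions import EmptyEvidenceError, ValidationError
from .profiles import cohort_matrix
from .rubric import (
    DEFAULT_FAMILY,
    DEFAULT_RUBRIC,
    INDICATOR_NAMES,
    N_INDICATORS,
    N_LEVELS,
    AbilityScaling,
    IndicatorProfile,
    MembershipFamily,
    RubricSet,
    ability_value,
    membership_matrix,
)
from .weighting import WeightModel

__all__ = [
    "FuzzyRelation",
    "EvaluationResult",
    "FuzzyAssessor",
    "relation_matrix",
    "compose",
    "defuzzify",
    "classify",
    "assess",
    "assess_cohort",
]


@dataclass(frozen=True)
class FuzzyRelation:
    """Indicators x levels membership matrix for one subject."""

    R: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.shape != (N_INDICATORS, N_LEVELS):
            raise ValidationError(f"relation matrix must be 9x4, got {R.shape}")
        if np.any(R < 0) or np.any(R > 1):
            raise ValidationError("relation matrix entries must lie in [0, 1]")
        object.__setattr__(self, "R", R)


@dataclass(frozen=True)
class EvaluationResult:
    """One subject's assessment: evidence vector, composite score, verdict."""

    subject_id: str
    B: np.ndarray
    u_star: float
    level_index: int
    level_label: str


def _ability_vector(
    profile: IndicatorProfile, scalings: Mapping[str, AbilityScaling]
) -> np.ndarray:
    missing = [n for n in INDICATOR_NAMES if n not in scalings]
    if missing:
        raise ValidationError(f"missing scaling for indicators: {missing}")
    return np.array(
        [ability_value(getattr(profile, n), scalings[n]) for n in INDICATOR_NAMES]
    )


def relation_matrix(
    profile: IndicatorProfile,
    scalings: Optional[Mapping[str, AbilityScaling]] = None,
    family: MembershipFamily = DEFAULT_FAMILY,
) -> FuzzyRelation:
    """Build the subject's 9 x 4 fuzzy relation matrix R."""
    if scalings is None:
        scalings = default_scalings()
    r = _ability_vector(profile, scalings)
    return FuzzyRelation(R=membership_matrix(r, family), subject_id=profile.subject_id)


def compose(A, R: Union[FuzzyRelation, np.ndarray]) -> np.ndarray:
    """Weighted-sum composition B = A . R, b_j = sum_i A_i R_ij."""
    A = np.asarray(A, dtype=float)
    M = R.R if isinstance(R, FuzzyRelation) else np.asarray(R, dtype=float)
    if A.ndim != 1 or M.ndim != 2 or A.shape[0] != M.shape[0]:
        raise ValidationError(
            f"shape mismatch: weights {A.shape} vs relation {M.shape}"
        )
    return A @ M


def defuzzify(B, rubric: RubricSet = DEFAULT_RUBRIC) -> float:
    """Weighted average of rubric values: u* = sum V_i b_i / sum b_i."""
    b = np.asarray(B, dtype=float)
    if np.any(b < 0):
        raise ValidationError("evidence vector must be nonnegative")
    total = b.sum()
    if total <= 0:
        raise EmptyEvidenceError("evidence vector sums to zero")
    return float(rubric.values_array @ b / total)


def classify(u_star: float, rubric: RubricSet = DEFAULT_RUBRIC) -> tuple[int, str]:
    """Nearest rubric value; midpoint ties go to the more severe level."""
    if not np.isfinite(u_star):
        raise ValidationError(f"composite score must be finite, got {u_star}")
    d = np.abs(u_star - rubric.values_array)
    idx = int(np.flatnonzero(d == d.min()).max())  # largest index = most severe
    return idx + 1, rubric.labels[idx]


def assess(
    profile: IndicatorProfile,
    weights=None,
    scalings: Optional[Mapping[str, AbilityScaling]] = None,
    family: MembershipFamily = DEFAULT_FAMILY,
    rubric: RubricSet = DEFAULT_RUBRIC,
) -> EvaluationResult:
    """Run the full chain for one subject."""
    A = default_weights() if weights is None else np.asarray(weights, dtype=float)
    rel = relation_matrix(profile, scalings, family)
    B = compose(A, rel)
    u = defuzzify(B, rubric)
    idx, label = classify(u, rubric)
    return EvaluationResult(
        subject_id=profile.subject_id, B=B, u_star=u, level_index=idx, level_label=label
    )


class FuzzyAssessor(ClassifierMixin, BaseEstimator):
    """Fuzzy comprehensive evaluator for the nine-indicator profile.

    Parameters
    ----------
    weights : "default", "fit", array-like of shape (9,), or WeightModel
        "default" uses the packaged published weight vector; "fit" derives
        weights from the training cohort at ``fit`` time via
        :class:`~fuzzycomm.weighting.PrincipalComponentWeights`.
    scalings : mapping of indicator name -> AbilityScaling, optional
    family : MembershipFamily, optional
    rubric : RubricSet, optional
    eigen_min, cum_min : component-selection thresholds when weights="fit".

    After ``fit``:

    - ``transform(X)`` returns the (n, 4) level-evidence matrix B,
    - ``score_samples(X)`` the composite scores u*,
    - ``predict(X)`` the verdict levels in {1, 2, 3, 4}.
    """

    def __init__(
        self,
        weights="default",
        scalings=None,
        family=None,
        rubric=None,
        eigen_min: float = 1.0,
        cum_min: float = 0.85,
    ):
        self.weights = weights
        self.scalings = scalings
        self.family = family
        self.rubric = rubric
        self.eigen_min = eigen_min
        self.cum_min = cum_min

    # -- fitting -----------------------------------------------------------
    def fit(self, X=None, y=None):
        from .weighting import PrincipalComponentWeights

        self.scalings_ = dict(self.scalings) if self.scalings else default_scalings()
        self.family_ = self.family or DEFAULT_FAMILY
        self.rubric_ = self.rubric or DEFAULT_RUBRIC
        if isinstance(self.weights, str) and self.weights == "default":
            self.weights_ = default_weights()
        elif isinstance(self.weights, str) and self.weights == "fit":
            if X is None:
                raise ValidationError("weights='fit' requires training data X")
            est = PrincipalComponentWeights(
                eigen_min=self.eigen_min, cum_min=self.cum_min
            ).fit(self._matrix(X))
            self.weights_ = est.weights_
            self.weight_model_ = est.to_model()
        elif isinstance(self.weights, WeightModel):
            self.weights_ = np.asarray(self.weights.weights, dtype=float)
            self.weight_model_ = self.weights
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (N_INDICATORS,) or np.any(w < 0):
                raise ValidationError(
                    "weights must be a nonnegative vector of length 9"
                )
            if abs(w.sum() - 1.0) > 1e-6:
                raise ValidationError("weights must sum to 1")
            self.weights_ = w
        self.classes_ = np.arange(1, N_LEVELS + 1)
        return self

    # -- application -------------------------------------------------------
    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[list(INDICATOR_NAMES)].to_numpy(dtype=float)
        if len(X) and isinstance(X[0], IndicatorProfile):
            return cohort_matrix(X)
        M = np.asarray(X, dtype=float)
        if M.ndim != 2 or M.shape[1] != N_INDICATORS:
            raise ValidationError(f"expected (n, 9) measurements, got {M.shape}")
        return M

    def _ability_matrix(self, X) -> np.ndarray:
        M = self._matrix(X)
        cols = [
            ability_value(M[:, i], self.scalings_[name])
            for i, name in enumerate(INDICATOR_NAMES)
        ]
        return np.column_stack(cols)

    def transform(self, X) -> np.ndarray:
        """Level-evidence matrix B, one row per subject."""
        check_is_fitted(self, "weights_")
        r = self._ability_matrix(X)
        out = np.empty((r.shape[0], N_LEVELS))
        for i in range(r.shape[0]):
            out[i] = self.weights_ @ membership_matrix(r[i], self.family_)
        return out

    def score_samples(self, X) -> np.ndarray:
        """Composite scores u* in [min(V), max(V)]."""
        B = self.transform(X)
        return np.array([defuzzify(b, self.rubric_) for b in B])

    def predict(self, X) -> np.ndarray:
        """Verdict levels 1 (intact) .. 4 (severe)."""
        return np.array(
            [classify(u, self.rubric_)[0] for u in self.score_samples(X)], dtype=int
        )

    def assess(self, cohort: Iterable[IndicatorProfile]) -> list[EvaluationResult]:
        """Full per-subject results for a cohort of profiles."""
        check_is_fitted(self, "weights_")
        return [
            assess(p, self.weights_, self.scalings_, self.family_, self.rubric_)
            for p in cohort
        ]


def assess_cohort(
    cohort: Iterable[IndicatorProfile],
    weights=None,
    scalings: Optional[Mapping[str, AbilityScaling]] = None,
    family: MembershipFamily = DEFAULT_FAMILY,
    rubric: RubricSet = DEFAULT_RUBRIC,
) -> pd.DataFrame:
    """Assess every subject and tabulate the results.

    Columns: subject_id, b1..b4, u_star, level_index, level_label.
    """
    results = [assess(p, weights, scalings, family, rubric) for p in cohort]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            **{
                f"b{j + 1}": [r.B[j] for r in results] for j in range(N_LEVELS)
            },
            "u_star": [r.u_star for r in results],
            "level_index": [r.level_index for r in results],
            "level_label": [r.level_label for r in results],
        }
    )
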