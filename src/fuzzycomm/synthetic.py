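"""Synthetic labeled cohorts and model-vs-reference agreement scoring.

Real cohorts pairing the nine indicators with clinician verdicts are not
publicly available, so this module generates them: each severity level
gets a truncated multivariate-normal indicator distribution (percentages
truncated to [0, 100], the two speech rates to positive values) and a
single equicorrelation parameter supplies the dominant shared factor that
the indicator loadings consistently show.  Level counts follow a
deterministic largest-remainder allocation so tests can assert exact
class sizes; all sampling is driven by one recorded seed.

The default per-level means are calibrated from the packaged six-subject
reference table (a fixture-derived choice, not population ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .defaults import default_scalings
from .exceptions import CohortSpecError, ValidationError
from .rubric import (
    INDICATOR_NAMES,
    N_INDICATORS,
    N_LEVELS,
    PERCENTAGE_INDICATORS,
    IndicatorProfile,
)

__all__ = ["CohortSpec", "AgreementReport", "generate", "agreement", "well_separated_spec"]

# Per-level indicator means (rows: intact..severe), calibrated from the
# packaged reference subjects: levels 1/2 average their two subjects,
# levels 3/4 take their single subject.
_DEFAULT_MEANS = np.array(
    [
        [96.5, 94.2, 70.5, 98.2, 88.8, 84.4, 90.1, 70.7, 48.2],  # intact
        [83.5, 84.3, 52.3, 86.1, 93.6, 77.6, 76.6, 58.6, 38.9],  # mild
        [61.4, 87.7, 29.2, 77.8, 90.0, 54.4, 64.0, 63.8, 54.8],  # moderate
        [23.8, 66.7, 11.5, 6.7, 36.7, 16.6, 27.2, 65.3, 13.5],  # severe
    ]
)

# Measurement noise: 10 percentage points, 5 dB, 8 events/min.
_DEFAULT_SDS = np.array([10.0] * 7 + [5.0, 8.0])

_LOWER = np.array([0.0] * 7 + [1e-9, 1e-9])
_UPPER = np.array([100.0] * 7 + [np.inf, np.inf])


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic labeled cohort."""

    n_subjects: int = 200
    #: Reference-table-style severity mix (close to 22:15:9:4 out of 50).
    level_proportions: tuple[float, ...] = (0.44, 0.30, 0.18, 0.08)
    level_means: np.ndarray = field(default_factory=lambda: _DEFAULT_MEANS.copy())
    level_sds: np.ndarray = field(default_factory=lambda: np.tile(_DEFAULT_SDS, (4, 1)))
    correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortSpecError("n_subjects must be positive")
        p = np.asarray(self.level_proportions, dtype=float)
        if p.shape != (N_LEVELS,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise CohortSpecError("level proportions must be 4 nonnegatives summing to 1")
        means = np.asarray(self.level_means, dtype=float)
        sds = np.asarray(self.level_sds, dtype=float)
        if means.shape != (N_LEVELS, N_INDICATORS) or sds.shape != means.shape:
            raise CohortSpecError("level means/sds must be 4 x 9 arrays")
        if np.any(sds <= 0):
            raise CohortSpecError("level sds must be strictly positive")
        if np.any(means < _LOWER) or np.any(means > _UPPER):
            raise CohortSpecError("a level mean lies outside the indicator support")
        corr = self.correlation_matrix()
        if np.any(np.linalg.eigvalsh(corr) <= 1e-12):
            raise CohortSpecError("correlation matrix is not positive definite")
        object.__setattr__(self, "level_means", means)
        object.__setattr__(self, "level_sds", sds)

    def correlation_matrix(self) -> np.ndarray:
        if np.isscalar(self.correlation):
            rho = float(self.correlation)
            if not 0.0 <= rho < 1.0:
                raise CohortSpecError(f"equicorrelation must lie in [0, 1), got {rho}")
            return np.full((N_INDICATORS, N_INDICATORS), rho) + (1 - rho) * np.eye(
                N_INDICATORS
            )
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (N_INDICATORS, N_INDICATORS):
            raise CohortSpecError("correlation matrix must be 9 x 9")
        return corr


def level_counts(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Deterministic largest-remainder allocation of n subjects to levels."""
    p = np.asarray(proportions, dtype=float)
    ideal = n * p
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    # Ties broken by level order (stable argsort on negated remainder).
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    return counts


def _sample_level(
    rng: np.random.Generator,
    n: int,
    mean: np.ndarray,
    sd: np.ndarray,
    corr: np.ndarray,
    max_rounds: int = 1000,
) -> np.ndarray:
    """Truncated MVN by rejection: redraw rows until inside the support."""
    cov = corr * np.outer(sd, sd)
    chol = np.linalg.cholesky(cov)
    out = np.empty((n, N_INDICATORS))
    pending = np.arange(n)
    for _ in range(max_rounds):
        draw = mean + rng.standard_normal((len(pending), N_INDICATORS)) @ chol.T
        ok = np.all((draw >= _LOWER) & (draw <= _UPPER), axis=1)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            return out
    raise CohortSpecError(
        "truncation rejection did not converge; a level mean is too close to "
        "the support boundary for the requested spread"
    )


def generate(spec: CohortSpec, rng: Optional[np.random.Generator] = None) -> list[IndicatorProfile]:
    """Draw a labeled cohort; deterministic for a fixed spec (and seed)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    counts = level_counts(spec.n_subjects, spec.level_proportions)
    corr = spec.correlation_matrix()
    cohort: list[IndicatorProfile] = []
    sid = 0
    for level in range(1, N_LEVELS + 1):
        n = int(counts[level - 1])
        if n == 0:
            continue
        draws = _sample_level(
            rng, n, spec.level_means[level - 1], spec.level_sds[level - 1], corr
        )
        for row in draws:
            sid += 1
            cohort.append(
                IndicatorProfile(
                    subject_id=f"S{sid:04d}",
                    clinician_level=level,
                    **dict(zip(INDICATOR_NAMES, row.tolist())),
                )
            )
    return cohort


def well_separated_spec(
    n_subjects: int = 200,
    r_sd: float = 0.05,
    correlation: float = 0.6,
    seed: int = 0,
    level_proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
) -> CohortSpec:
    """A cohort whose per-level mean ability values sit exactly on the
    rubric values (0.9, 0.75, 0.55, 0.25) under the default scalings.

    ``r_sd`` is the marginal standard deviation on the ability scale; it is
    converted back to raw units per indicator (sd_raw = 2 * r_sd * (H - M)).
    """
    scalings = default_scalings()
    targets = np.array([0.9, 0.75, 0.55, 0.25])
    means = np.empty((N_LEVELS, N_INDICATORS))
    sds = np.empty((N_LEVELS, N_INDICATORS))
    for i, name in enumerate(INDICATOR_NAMES):
        s = scalings[name]
        means[:, i] = s.M + (targets - 0.5) * 2.0 * (s.H - s.M)
        sds[:, i] = 2.0 * r_sd * (s.H - s.M)
    return CohortSpec(
        n_subjects=n_subjects,
        level_proportions=level_proportions,
        level_means=means,
        level_sds=sds,
        correlation=correlation,
        seed=seed,
    )


@dataclass(frozen=True)
class AgreementReport:
    """Confusion-matrix summary of model vs reference verdict levels."""

    confusion: np.ndarray  # (4, 4), reference rows x model columns
    per_class_accuracy: np.ndarray
    overall_accuracy: float
    reference_marginals: np.ndarray
    model_marginals: np.ndarray

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def adjacent_error_rate(self) -> float:
        """Share of subjects misclassified by exactly one level."""
        idx = np.arange(N_LEVELS)
        off = np.abs(idx[:, None] - idx[None, :]) == 1
        return float(self.confusion[off].sum() / max(self.n, 1))

    def nonadjacent_error_rate(self) -> float:
        """Share of subjects misclassified by two or more levels."""
        idx = np.arange(N_LEVELS)
        far = np.abs(idx[:, None] - idx[None, :]) >= 2
        return float(self.confusion[far].sum() / max(self.n, 1))


def agreement(reference: Sequence[int], predicted: Sequence[int]) -> AgreementReport:
    """Score predicted verdict levels against reference levels.

    Per-class accuracy is the confusion diagonal over the reference row
    sum; levels absent from the reference get a zero row and an accuracy
    of 0.0 rather than an error.
    """
    ref = np.asarray(reference, dtype=int)
    pred = np.asarray(predicted, dtype=int)
    if ref.shape != pred.shape or ref.ndim != 1:
        raise ValidationError("reference and predicted levels must be equal-length 1-d")
    if len(ref) and (
        ref.min() < 1 or ref.max() > N_LEVELS or pred.min() < 1 or pred.max() > N_LEVELS
    ):
        raise ValidationError("levels must lie in 1..4")
    confusion = np.zeros((N_LEVELS, N_LEVELS), dtype=int)
    for r, p in zip(ref, pred):
        confusion[r - 1, p - 1] += 1
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_class = np.where(row_sums > 0, np.diag(confusion) / np.maximum(row_sums, 1), 0.0)
    overall = float(np.trace(confusion) / len(ref)) if len(ref) else 0.0
    return AgreementReport(
        confusion=confusion,
        per_class_accuracy=per_class.astype(float),
        overall_accuracy=overall,
        reference_marginals=row_sums,
        model_marginals=confusion.sum(axis=0),
    )
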