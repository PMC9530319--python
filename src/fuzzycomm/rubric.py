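"""Fuzzy rubric mathematics: verdict levels, ability scaling, memberships.

The assessment rates each of nine communication indicators on a common
ability scale ``r`` in [0, 1] and converts ``r`` into degrees of membership
in four ordered verdict levels (intact, mild, moderate, severe).  Each
level's representative fuzzy value lives in the :class:`RubricSet`; the
piecewise power membership functions live in :class:`MembershipFamily`.

The membership family is trapezoid-like with exponent ``k`` (default 1.2):
the top level is an ascending shoulder, the bottom level a descending
shoulder, and the two middle levels rise, plateau and fall between their
breakpoints.  Rising segments evaluate ``((x - a)/(b - a))**k`` and falling
segments ``((b - x)/(b - a))**k``, so with ``k = 1`` every segment is the
straight line between its endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import DegenerateScalingError, DomainError, ValidationError

#: Canonical indicator order used for every matrix and CSV in the package.
INDICATOR_NAMES: tuple[str, ...] = (
    "auditory",
    "visual",
    "memory",
    "comprehension",
    "judgment",
    "expression",
    "attention",
    "speech_energy",
    "speech_speed",
)

#: The seven indicators recorded as percentages in [0, 100].
PERCENTAGE_INDICATORS: tuple[str, ...] = INDICATOR_NAMES[:7]

N_INDICATORS = len(INDICATOR_NAMES)
N_LEVELS = 4


@dataclass(frozen=True)
class IndicatorProfile:
    """One subject's raw nine-indicator measurement vector.

    Percentages are stored on the 0-100 scale; they are converted to [0, 1]
    ability values only inside :func:`ability_value`.  ``clinician_level``
    is the optional reference verdict (1 = intact ... 4 = severe).
    """

    subject_id: str
    auditory: float
    visual: float
    memory: float
    comprehension: float
    judgment: float
    expression: float
    attention: float
    speech_energy: float
    speech_speed: float
    clinician_level: Optional[int] = None

    def __post_init__(self) -> None:
        for name in PERCENTAGE_INDICATORS:
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={v} outside [0, 100]"
                )
        for name in ("speech_energy", "speech_speed"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ValidationError(
                    f"subject {self.subject_id!r}: {name}={v} must be positive"
                )
        if self.clinician_level is not None and self.clinician_level not in (1, 2, 3, 4):
            raise ValidationError(
                f"subject {self.subject_id!r}: clinician_level="
                f"{self.clinician_level} not in {{1, 2, 3, 4}}"
            )

    def values(self) -> np.ndarray:
        """The nine measurements in canonical indicator order."""
        return np.array([getattr(self, name) for name in INDICATOR_NAMES], dtype=float)


@dataclass(frozen=True)
class RubricSet:
    """The ordered verdict levels and their representative fuzzy values V."""

    labels: tuple[str, ...] = ("intact", "mild", "moderate", "severe")
    fuzzy_values: tuple[float, ...] = (0.90, 0.75, 0.55, 0.25)

    def __post_init__(self) -> None:
        if len(self.labels) != N_LEVELS or len(self.fuzzy_values) != N_LEVELS:
            raise ValidationError("rubric must define exactly four levels")
        v = np.asarray(self.fuzzy_values, dtype=float)
        if not np.all(np.diff(v) < 0):
            raise ValidationError("rubric fuzzy values must be strictly decreasing")
        if not np.all((v > 0) & (v < 1)):
            raise ValidationError("rubric fuzzy values must lie in (0, 1)")

    @property
    def values_array(self) -> np.ndarray:
        return np.asarray(self.fuzzy_values, dtype=float)


@dataclass(frozen=True)
class AbilityScaling:
    """Affine anchoring of one indicator onto the [0, 1] ability scale.

    ``M`` (reference normal midpoint) maps to 0.5 and ``H`` (reference best
    value) maps to 1.0; in between the map is linear with slope
    ``0.5 / (H - M)``.  ``direction='decreasing'`` reflects the measurement
    about ``M`` first, for indicators where smaller raw values mean better
    ability.  With ``clip`` (the default) the result is clamped to [0, 1]
    so it stays inside the membership domain.
    """

    H: float
    M: float
    direction: str = "increasing"
    clip: bool = True

    def __post_init__(self) -> None:
        if self.H == self.M:
            raise DegenerateScalingError(f"degenerate scaling: H == M == {self.H}")
        if self.H < self.M:
            raise ValidationError(f"require H > M, got H={self.H}, M={self.M}")
        if self.direction not in ("increasing", "decreasing"):
            raise ValidationError(f"unknown direction {self.direction!r}")


def ability_value(cur_val, scaling: AbilityScaling):
    """Map a raw indicator measurement to the fuzzy ability value r.

    r = 0.5 / (H - M) * (cur_val - M) + 0.5, so ``cur_val = M`` gives 0.5
    and ``cur_val = H`` gives 1.0.  Accepts scalars or arrays.
    """
    x = np.asarray(cur_val, dtype=float)
    if scaling.direction == "decreasing":
        x = 2.0 * scaling.M - x
    r = 0.5 / (scaling.H - scaling.M) * (x - scaling.M) + 0.5
    if scaling.clip:
        r = np.clip(r, 0.0, 1.0)
    return float(r) if np.isscalar(cur_val) else r


def _default_breakpoints() -> tuple[tuple[float, ...], ...]:
    # Level 1 ascending shoulder; levels 2-3 trapezoids; level 4 descending
    # shoulder.  Level 2's descending flank [0.775, 0.9] completes the
    # printed rubric by mirror symmetry with level 3's shape.
    return (
        (0.75, 0.9),
        (0.55, 0.725, 0.775, 0.9),
        (0.25, 0.455, 0.545, 0.75),
        (0.25, 0.55),
    )


@dataclass(frozen=True)
class MembershipFamily:
    """The four piecewise power membership functions of the rubric."""

    k: float = 1.2
    breakpoints: tuple[tuple[float, ...], ...] = field(
        default_factory=_default_breakpoints
    )

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValidationError(f"exponent k must be positive, got {self.k}")
        if len(self.breakpoints) != N_LEVELS:
            raise ValidationError("need breakpoints for exactly four levels")
        for lvl, pts in enumerate(self.breakpoints, start=1):
            expected = 2 if lvl in (1, N_LEVELS) else 4
            if len(pts) != expected:
                raise ValidationError(
                    f"level {lvl} needs {expected} breakpoints, got {len(pts)}"
                )
            arr = np.asarray(pts, dtype=float)
            if not np.all(np.diff(arr) > 0):
                raise ValidationError(f"level {lvl} breakpoints must strictly increase")
            if not np.all((arr >= 0) & (arr <= 1)):
                raise ValidationError(f"level {lvl} breakpoints must lie in [0, 1]")


DEFAULT_FAMILY = MembershipFamily()
DEFAULT_RUBRIC = RubricSet()


def _rise(x: np.ndarray, a: float, b: float, k: float) -> np.ndarray:
    return ((x - a) / (b - a)) ** k


def _fall(x: np.ndarray, a: float, b: float, k: float) -> np.ndarray:
    return ((b - x) / (b - a)) ** k


def _eval_level(x: np.ndarray, level: int, family: MembershipFamily) -> np.ndarray:
    pts = family.breakpoints[level - 1]
    k = family.k
    # Segment boundaries are left-closed; both sides agree there because
    # every rising/falling segment hits exactly 0 or 1 at its endpoints.
    if level == 1:  # ascending shoulder
        a, b = pts
        return np.select(
            [x < a, x <= b], [0.0, _rise(np.clip(x, a, b), a, b, k)], default=1.0
        )
    if level == N_LEVELS:  # descending shoulder
        a, b = pts
        return np.select(
            [x < a, x <= b], [1.0, _fall(np.clip(x, a, b), a, b, k)], default=0.0
        )
    a, b, c, d = pts  # trapezoid
    return np.select(
        [x < a, x <= b, x <= c, x <= d],
        [0.0, _rise(np.clip(x, a, b), a, b, k), 1.0, _fall(np.clip(x, c, d), c, d, k)],
        default=0.0,
    )


def membership(x, level: int, family: MembershipFamily = DEFAULT_FAMILY):
    """Degree of membership of ability value ``x`` in one verdict level.

    ``level`` is 1 (intact) through 4 (severe).  Accepts scalars or arrays;
    raises :class:`DomainError` if any x falls outside [0, 1].
    """
    if level not in range(1, N_LEVELS + 1):
        raise DomainError(f"unknown rubric level {level}; expected 1..{N_LEVELS}")
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise DomainError(f"ability value outside [0, 1]: {x!r}")
    out = _eval_level(arr, level, family)
    return float(out) if np.isscalar(x) else out


def membership_row(x: float, family: MembershipFamily = DEFAULT_FAMILY) -> np.ndarray:
    """Evaluate all four membership functions at one ability value."""
    return membership_matrix([x], family)[0]


def membership_matrix(
    x: Sequence[float], family: MembershipFamily = DEFAULT_FAMILY
) -> np.ndarray:
    """Vectorized membership evaluation: (n,) ability values -> (n, 4)."""
    arr = np.asarray(x, dtype=float)
    cols = [membership(arr, level, family) for level in range(1, N_LEVELS + 1)]
    return np.column_stack(cols)
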