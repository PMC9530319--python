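"""Exception hierarchy for fuzzycomm.

Every error the library raises deliberately derives from
:class:`FuzzycommError`, so callers (and the CLI) can catch one base class
and still distinguish validation problems from numerical degeneracies.
"""


class FuzzycommError(Exception):
    """Base class for all fuzzycomm errors."""


class ValidationError(FuzzycommError, ValueError):
    """Input data violates a documented precondition or range rule."""


class DomainError(FuzzycommError, ValueError):
    """An ability value or membership argument lies outside its domain."""


class DegenerateScalingError(FuzzycommError, ValueError):
    """Ability scaling with H == M: the affine map is undefined."""


class DegenerateIndicatorError(FuzzycommError, ValueError):
    """An indicator column is constant: z-scoring is undefined."""


class ComponentSelectionError(FuzzycommError, ValueError):
    """No prefix of components satisfies the eigenvalue/cumulative rules."""


class ConversionError(FuzzycommError, ValueError):
    """Loading-to-coefficient conversion with a non-positive eigenvalue."""


class WeightDegeneracyError(FuzzycommError, ValueError):
    """Raw weights sum to a non-positive value; normalization undefined."""


class EmptyEvidenceError(FuzzycommError, ValueError):
    """Level-evidence vector B sums to zero; defuzzification undefined."""


class CohortSpecError(FuzzycommError, ValueError):
    """Synthetic cohort specification is invalid or infeasible."""
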