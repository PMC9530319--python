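"""Cohort tables: reading, validating and writing subject profiles.

The on-disk format is a comma-delimited, UTF-8 CSV with a header row in
the canonical indicator order (auditory, visual, memory, comprehension,
judgment, expression, attention, speech_energy, speech_speed) plus an
optional leading ``subject_id`` and trailing ``label`` column holding the
clinician-assigned level 1-4.  The six-subject reference table ships as
package data and is returned by :func:`load_reference_cohort`.
"""

from __future__ import annotations

import logging
from importlib import resources
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .rubric import INDICATOR_NAMES, PERCENTAGE_INDICATORS, IndicatorProfile

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"
ID_COLUMN = "subject_id"


def cohort_to_frame(cohort: Iterable[IndicatorProfile]) -> pd.DataFrame:
    """Serialize profiles to a DataFrame in canonical column order."""
    rows = []
    for p in cohort:
        row = {ID_COLUMN: p.subject_id}
        row.update({name: getattr(p, name) for name in INDICATOR_NAMES})
        row[LABEL_COLUMN] = p.clinician_level
        rows.append(row)
    frame = pd.DataFrame(rows, columns=[ID_COLUMN, *INDICATOR_NAMES, LABEL_COLUMN])
    if frame[LABEL_COLUMN].isna().all():
        frame = frame.drop(columns=[LABEL_COLUMN])
    return frame


def frame_to_cohort(frame: pd.DataFrame, source: str = "<frame>") -> list[IndicatorProfile]:
    """Validate a cohort DataFrame cell by cell and build profiles.

    Validation failures report the offending row and column so a bad cell
    in a hand-edited CSV is easy to locate.
    """
    missing = [c for c in INDICATOR_NAMES if c not in frame.columns]
    if missing:
        raise ValidationError(f"{source}: missing indicator columns {missing}")
    has_label = LABEL_COLUMN in frame.columns
    has_id = ID_COLUMN in frame.columns
    cohort: list[IndicatorProfile] = []
    for pos, (idx, row) in enumerate(frame.iterrows()):
        values = {}
        for name in INDICATOR_NAMES:
            try:
                v = float(row[name])
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{source}: row {idx}, column {name!r}: "
                    f"non-numeric value {row[name]!r}"
                ) from exc
            if name in PERCENTAGE_INDICATORS and not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{source}: row {idx}, column {name!r}: "
                    f"value {v} outside [0, 100]"
                )
            values[name] = v
        level: Optional[int] = None
        if has_label and not pd.isna(row[LABEL_COLUMN]):
            level = int(row[LABEL_COLUMN])
            if level not in (1, 2, 3, 4):
                raise ValidationError(
                    f"{source}: row {idx}, column {LABEL_COLUMN!r}: "
                    f"level {level} not in {{1, 2, 3, 4}}"
                )
        if has_id:
            sid = row[ID_COLUMN]
            if isinstance(sid, float) and sid.is_integer():
                sid = int(sid)
            subject_id = str(sid)
        else:
            subject_id = str(pos + 1)
        try:
            cohort.append(
                IndicatorProfile(subject_id=subject_id, clinician_level=level, **values)
            )
        except ValidationError as exc:
            raise ValidationError(f"{source}: row {idx}: {exc}") from exc
    return cohort


def read_cohort(path) -> list[IndicatorProfile]:
    """Read and validate a cohort CSV; empty (header-only) files are allowed."""
    frame = pd.read_csv(path)
    if frame.empty:
        logger.warning("cohort file %s contains a header but no subjects", path)
        missing = [c for c in INDICATOR_NAMES if c not in frame.columns]
        if missing:
            raise ValidationError(f"{path}: missing indicator columns {missing}")
        return []
    return frame_to_cohort(frame, source=str(path))


def write_cohort(cohort: Iterable[IndicatorProfile], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def cohort_matrix(cohort: Iterable[IndicatorProfile]) -> np.ndarray:
    """Stack profiles into an (n_subjects, 9) measurement matrix."""
    return np.array([p.values() for p in cohort], dtype=float)


def cohort_labels(cohort: Iterable[IndicatorProfile]) -> Optional[np.ndarray]:
    """Clinician levels as an int array, or None when any are missing."""
    levels = [p.clinician_level for p in cohort]
    if any(lv is None for lv in levels):
        return None
    return np.asarray(levels, dtype=int)


def load_reference_cohort() -> list[IndicatorProfile]:
    """The six packaged reference subjects (labels 3, 2, 2, 1, 1, 4)."""
    ref = resources.files("fuzzycomm.data").joinpath("table5.csv")
    with resources.as_file(ref) as path:
        return read_cohort(path)
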