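"""Data model and I/O for tables of historical randomized-trial effects.

The unit of analysis is one trial comparison: a summary relative treatment
effect ``y`` on the log odds-ratio or log hazard-ratio scale together with
its standard error ``se``, labelled with a disease area and (optionally) the
comparison type.  Negative ``y`` favours the new/experimental treatment:
the package-wide sign convention is that a decrease in outcome is an
improvement.

The comparison-type covariate is coded ``X = 0`` for an active-vs-inactive
comparison (placebo or no treatment) and ``X = 1`` for active-vs-active.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ACTIVE_VS_INACTIVE = "active_vs_inactive"  # X = 0
ACTIVE_VS_ACTIVE = "active_vs_active"  # X = 1
COMPARISON_TYPES = (ACTIVE_VS_INACTIVE, ACTIVE_VS_ACTIVE)
OUTCOME_TYPES = ("binary", "survival", "continuous")

#: canonical CSV column order
COLUMNS = ("study_id", "y", "se", "disease_area", "comparison_type", "outcome_type", "year")

DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan", ".")


class DatasetFormatError(ValueError):
    """A file does not have the expected columns or cell types."""


class DatasetValidationError(ValueError):
    """Rows violate a record invariant (e.g. non-positive standard error)."""


@dataclass(frozen=True)
class EffectRecord:
    """One trial comparison: effect estimate and standard error on the log scale."""

    study_id: str
    y: float
    se: float
    disease_area: str | None = None
    comparison_type: str | None = None
    outcome_type: str | None = None
    year: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.y):
            raise DatasetValidationError(f"study {self.study_id!r}: y must be finite, got {self.y}")
        if not (np.isfinite(self.se) and self.se > 0):
            raise DatasetValidationError(f"study {self.study_id!r}: se must be > 0, got {self.se}")
        if self.comparison_type is not None and self.comparison_type not in COMPARISON_TYPES:
            raise DatasetValidationError(
                f"study {self.study_id!r}: unknown comparison_type {self.comparison_type!r} "
                f"(expected one of {COMPARISON_TYPES})"
            )
        if self.outcome_type is not None and self.outcome_type not in OUTCOME_TYPES:
            raise DatasetValidationError(
                f"study {self.study_id!r}: unknown outcome_type {self.outcome_type!r} "
                f"(expected one of {OUTCOME_TYPES})"
            )

    @property
    def x(self) -> float | None:
        """Covariate coding: 0 = active vs inactive, 1 = active vs active."""
        if self.comparison_type is None:
            return None
        return float(self.comparison_type == ACTIVE_VS_ACTIVE)


@dataclass
class TrialDataset:
    """Ordered collection of :class:`EffectRecord` with a disease-area index.

    ``area_index`` maps each distinct non-missing disease-area label to a
    contiguous integer code (alphabetical order), used to address the
    area-level parameters of the hierarchical model.
    """

    records: list[EffectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def area_index(self) -> dict[str, int]:
        labels = sorted({r.disease_area for r in self.records if r.disease_area is not None})
        return {label: i for i, label in enumerate(labels)}

    @property
    def n_areas(self) -> int:
        return len(self.area_index)

    def area_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {label: 0 for label in self.area_index}
        for r in self.records:
            if r.disease_area is not None:
                counts[r.disease_area] += 1
        return counts

    # -- array views used by the model ------------------------------------
    @property
    def y(self) -> np.ndarray:
        return np.array([r.y for r in self.records], dtype=float)

    @property
    def se(self) -> np.ndarray:
        return np.array([r.se for r in self.records], dtype=float)

    @property
    def area_codes(self) -> np.ndarray:
        """Per-record integer area code; -1 for a missing disease area."""
        idx = self.area_index
        return np.array(
            [idx[r.disease_area] if r.disease_area is not None else -1 for r in self.records],
            dtype=int,
        )

    @property
    def x(self) -> np.ndarray:
        """Per-record covariate X (NaN where comparison type is missing)."""
        return np.array(
            [r.x if r.x is not None else np.nan for r in self.records], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "study_id": r.study_id,
                "y": r.y,
                "se": r.se,
                "disease_area": r.disease_area,
                "comparison_type": r.comparison_type,
                "outcome_type": r.outcome_type,
                "year": r.year,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(COLUMNS))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrialDataset":
        records = []
        for _, row in frame.iterrows():
            year = row.get("year")
            records.append(
                EffectRecord(
                    study_id=str(row["study_id"]),
                    y=float(row["y"]),
                    se=float(row["se"]),
                    disease_area=_none_if_missing(row.get("disease_area")),
                    comparison_type=_none_if_missing(row.get("comparison_type")),
                    outcome_type=_none_if_missing(row.get("outcome_type")),
                    year=int(year) if year is not None and not _is_missing(year) else None,
                )
            )
        return cls(records)


@dataclass(frozen=True)
class FilterReport:
    """Accounting of the analysis-set filters applied to a dataset."""

    n_input: int
    n_missing_area_removed: int
    n_small_area_removed: int
    areas_removed: tuple[str, ...]
    n_output: int

    def __post_init__(self) -> None:
        if self.n_output != self.n_input - self.n_missing_area_removed - self.n_small_area_removed:
            raise ValueError("FilterReport counts do not reconcile")

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_missing_area_removed": self.n_missing_area_removed,
                "n_small_area_removed": self.n_small_area_removed,
                "areas_removed": list(self.areas_removed),
                "n_output": self.n_output,
            },
            indent=2,
        )


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() in DEFAULT_MISSING_TOKENS:
        return True
    return False


def _none_if_missing(value):
    return None if _is_missing(value) else value


def read_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    exclude_continuous: bool = False,
) -> TrialDataset:
    """Read a CSV of trial comparisons into a :class:`TrialDataset`.

    Parameters
    ----------
    path:
        CSV file with a mandatory header row.
    column_map:
        Optional mapping from canonical names (``study_id``, ``y``, ``se``,
        ``disease_area``, ``comparison_type``, ``outcome_type``, ``year``)
        to the headers actually present in the file.
    missing_tokens:
        Cell values treated as missing (empty field by default).
    exclude_continuous:
        Drop rows whose ``outcome_type`` is ``continuous`` (continuous
        outcomes carry mean differences, which do not pool with the log
        ratio scales used here); the number dropped is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(missing_tokens),
        skipinitialspace=True,
    )
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in COLUMNS if column_map.get(c, c) in frame.columns}
    frame = frame.rename(columns=rename)
    for required in ("study_id", "y", "se"):
        if required not in frame.columns:
            mapped = column_map.get(required, required)
            raise DatasetFormatError(f"missing required column {mapped!r} (for {required!r})")
    for optional in COLUMNS:
        if optional not in frame.columns:
            frame[optional] = None

    bad_numeric: list[str] = []
    bad_se: list[str] = []
    records: list[EffectRecord] = []
    n_continuous = 0
    for _, row in frame.iterrows():
        study_id = str(row["study_id"])
        try:
            y = float(row["y"])
            se = float(row["se"])
        except (TypeError, ValueError):
            bad_numeric.append(study_id)
            continue
        if not np.isfinite(y) or not np.isfinite(se):
            bad_numeric.append(study_id)
            continue
        if se <= 0:
            bad_se.append(study_id)
            continue
        outcome_type = _none_if_missing(row.get("outcome_type"))
        if exclude_continuous and outcome_type == "continuous":
            n_continuous += 1
            continue
        year_raw = _none_if_missing(row.get("year"))
        records.append(
            EffectRecord(
                study_id=study_id,
                y=y,
                se=se,
                disease_area=_none_if_missing(row.get("disease_area")),
                comparison_type=_none_if_missing(row.get("comparison_type")),
                outcome_type=outcome_type,
                year=int(float(year_raw)) if year_raw is not None else None,
            )
        )
    if bad_numeric:
        raise DatasetFormatError(
            f"non-numeric y/se in rows for studies: {', '.join(bad_numeric)}"
        )
    if bad_se:
        raise DatasetValidationError(
            f"standard error must be > 0; offending studies: {', '.join(bad_se)}"
        )
    if n_continuous:
        logger.info("read_dataset: dropped %d continuous-outcome rows", n_continuous)
    return TrialDataset(records)


def write_dataset(data: TrialDataset, path: str | Path) -> Path:
    """Write a dataset as canonical CSV (UTF-8, header row, empty = missing).

    Round-trips: ``read_dataset(write_dataset(d))`` reproduces ``d``
    field-for-field.
    """
    path = Path(path)
    frame = data.to_frame()
    frame["year"] = frame["year"].astype("Int64")
    frame.to_csv(path, index=False, na_rep="")
    return path


def filter_for_analysis(
    data: TrialDataset, min_per_area: int = 5
) -> tuple[TrialDataset, FilterReport]:
    """Apply the analysis-set inclusion filters.

    Removes records with a missing disease area, then removes every disease
    area with fewer than ``min_per_area`` records (five is a common rule of
    thumb for estimating between-trial heterogeneity, hence the default).
    Idempotent: applying the filter twice equals applying it once.
    """
    if min_per_area < 1:
        raise ValueError("min_per_area must be >= 1")
    n_input = len(data)
    with_area = [r for r in data if r.disease_area is not None]
    n_missing = n_input - len(with_area)
    counts: dict[str, int] = {}
    for r in with_area:
        counts[r.disease_area] = counts.get(r.disease_area, 0) + 1
    small = sorted(a for a, n in counts.items() if n < min_per_area)
    kept = [r for r in with_area if r.disease_area not in small]
    n_small = len(with_area) - len(kept)
    report = FilterReport(
        n_input=n_input,
        n_missing_area_removed=n_missing,
        n_small_area_removed=n_small,
        areas_removed=tuple(small),
        n_output=len(kept),
    )
    if n_input > 0 and not kept:
        logger.warning("filter_for_analysis: all %d records removed", n_input)
    logger.info(
        "filter_for_analysis: %d -> %d records (%d missing area, %d in small areas %s)",
        n_input,
        len(kept),
        n_missing,
        n_small,
        list(small),
    )
    return TrialDataset(kept), report


def summarize_composition(data: TrialDataset) -> pd.DataFrame:
    """Per-area and per-comparator counts with percentages of the total.

    Returns a tidy frame with columns ``section`` (``disease_area`` or
    ``comparison_type``), ``label``, ``n`` and ``pct``; percentages are of
    the total record count and sum to 100 within rounding.
    """
    total = len(data)
    rows = []
    for section, key in (
        ("disease_area", lambda r: r.disease_area),
        ("comparison_type", lambda r: r.comparison_type),
    ):
        counts: dict[str, int] = {}
        for r in data:
            label = key(r)
            if label is not None:
                counts[label] = counts.get(label, 0) + 1
        for label in sorted(counts):
            rows.append(
                {
                    "section": section,
                    "label": label,
                    "n": counts[label],
                    "pct": 100.0 * counts[label] / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["section", "label", "n", "pct"])
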