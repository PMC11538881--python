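"""Domain types, unit conventions, validation and tabular I/O for GIST patient records.

A patient record captures what is known about a gastrointestinal stromal tumor
(GIST) at biopsy time: anatomical site, tumor size, the tissue surface examined
on the biopsy, the mitotic count found on that surface, and whether the tumor
responded to neoadjuvant therapy.  For training data the mitotic count on the
surgical specimen (the ground truth, expressed per 5 mm²) is also present.

Canonical units
---------------
* tumor size: millimetres (risk tables convert internally to centimetres);
* biopsy surface: mm².  High-power fields (HPFs) are accepted at the I/O
  boundary only, using a configurable microscope calibration constant of
  23.5 HPF = 5 mm².
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "HPF_PER_5MM2",
    "Site",
    "PatientRecord",
    "Dataset",
    "ValidationError",
    "DatasetValidationError",
    "hpf_to_mm2",
    "mm2_to_hpf",
    "read_dataset",
    "write_dataset",
]

#: Number of microscope high-power fields covering 5 mm² of tissue
#: (stage-micrometer calibration used throughout the field's guidelines).
HPF_PER_5MM2 = 23.5


class ValidationError(ValueError):
    """A single field or record failed validation."""


class DatasetValidationError(ValidationError):
    """One or more rows of a tabular input failed validation.

    Attributes
    ----------
    row_errors : list of (row_number, message)
        1-based data row numbers (header excluded).
    """

    def __init__(self, row_errors: list[tuple[int, str]]):
        self.row_errors = row_errors
        lines = "; ".join(f"row {r}: {msg}" for r, msg in row_errors)
        super().__init__(f"invalid dataset ({len(row_errors)} bad row(s)): {lines}")


class Site(enum.Enum):
    """Anatomical location of the tumor, indexed 1..4.

    The integer index doubles as the site's position in hierarchical model
    coefficient vectors (1=colon-rectum, 2=duodenum, 3=small-intestine,
    4=stomach).
    """

    COLON_RECTUM = (1, "colon-rectum")
    DUODENUM = (2, "duodenum")
    SMALL_INTESTINE = (3, "small-intestine")
    STOMACH = (4, "stomach")

    def __init__(self, index: int, label: str):
        self.index = index
        self.label = label

    @classmethod
    def from_label(cls, label: str) -> "Site":
        key = str(label).strip().lower().replace("_", "-").replace(" ", "-")
        for site in cls:
            if site.label == key:
                return site
        raise ValidationError(f"unknown site label {label!r}")

    @classmethod
    def from_index(cls, index: int) -> "Site":
        for site in cls:
            if site.index == int(index):
                return site
        raise ValidationError(f"site index must be 1..4, got {index!r}")

    @classmethod
    def coerce(cls, value) -> "Site":
        """Accept a Site, a 1..4 index, or a textual label."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int,)) or (
            isinstance(value, float) and float(value).is_integer()
        ):
            return cls.from_index(int(value))
        text = str(value).strip()
        if text.isdigit():
            return cls.from_index(int(text))
        return cls.from_label(text)


def _check_count(value, name: str) -> int | None:
    if value is None:
        return None
    if isinstance(value, float):
        if math.isnan(value):
            return None
        if not value.is_integer():
            raise ValidationError(f"{name} must be an integer count, got {value}")
        value = int(value)
    if not isinstance(value, int):
        raise ValidationError(f"{name} must be an integer count, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be >= 0, got {value}")
    return value


def hpf_to_mm2(n_hpf: float, hpf_per_5mm2: float = HPF_PER_5MM2) -> float:
    """Convert a number of high-power fields to a tissue area in mm².

    With the default calibration, 23.5 HPF correspond to 5 mm², so
    ``hpf_to_mm2(14.3) ≈ 3.04``.
    """
    if n_hpf < 0:
        raise ValidationError(f"HPF count must be >= 0, got {n_hpf}")
    if hpf_per_5mm2 <= 0:
        raise ValidationError("calibration constant must be positive")
    return n_hpf / hpf_per_5mm2 * 5.0


def mm2_to_hpf(area_mm2: float, hpf_per_5mm2: float = HPF_PER_5MM2) -> float:
    """Inverse of :func:`hpf_to_mm2`; round-trips to floating tolerance."""
    if area_mm2 < 0:
        raise ValidationError(f"area must be >= 0, got {area_mm2}")
    if hpf_per_5mm2 <= 0:
        raise ValidationError("calibration constant must be positive")
    return area_mm2 / 5.0 * hpf_per_5mm2


@dataclass(frozen=True)
class PatientRecord:
    """One tumor at biopsy time (plus, for training, the specimen count).

    Parameters
    ----------
    site : Site
        Anatomical location.
    size_mm : float
        Largest tumor dimension, millimetres; must be positive.
    surface_mm2 : float
        Neoplastic tissue surface examined on the biopsy, mm²; must be
        positive (typically <= 5 mm², the reference counting area).
    biopsy_mitoses : int
        Raw mitotic count found within ``surface_mm2``.
    response : bool
        Operational response-to-therapy flag: the specimen count was lower
        than the biopsy count after neoadjuvant treatment.  May be True only
        for pre-treated tumors.
    specimen_mitoses : int or None
        Mitotic count on the surgical specimen, per 5 mm²; None when the
        tumor has not (yet) been resected.
    pretreated : bool
        Whether the patient received neoadjuvant therapy.  Defaults to the
        value of ``response``.
    """

    site: Site
    size_mm: float
    surface_mm2: float
    biopsy_mitoses: int
    response: bool = False
    specimen_mitoses: int | None = None
    pretreated: bool | None = None

    def __post_init__(self):
        object.__setattr__(self, "site", Site.coerce(self.site))
        if not (self.size_mm > 0) or not math.isfinite(self.size_mm):
            raise ValidationError(f"size_mm must be positive, got {self.size_mm}")
        if not (self.surface_mm2 > 0) or not math.isfinite(self.surface_mm2):
            raise ValidationError(
                f"surface_mm2 must be positive, got {self.surface_mm2}"
            )
        object.__setattr__(
            self, "biopsy_mitoses", _check_count(self.biopsy_mitoses, "biopsy_mitoses")
        )
        if self.biopsy_mitoses is None:
            raise ValidationError("biopsy_mitoses is required")
        object.__setattr__(
            self,
            "specimen_mitoses",
            _check_count(self.specimen_mitoses, "specimen_mitoses"),
        )
        object.__setattr__(self, "response", bool(self.response))
        pretreated = self.pretreated
        if pretreated is None:
            pretreated = self.response
        object.__setattr__(self, "pretreated", bool(pretreated))
        if self.response and not self.pretreated:
            raise ValidationError(
                "response may be True only for pre-treated tumors"
            )

    @property
    def size_cm(self) -> float:
        return self.size_mm / 10.0


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of validated patient records."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> PatientRecord:
        return self.records[i]

    def has_specimen_counts(self) -> bool:
        return all(r.specimen_mitoses is not None for r in self.records)

    def missing_specimen_rows(self) -> list[int]:
        """1-based row numbers of records without a specimen count."""
        return [i + 1 for i, r in enumerate(self.records) if r.specimen_mitoses is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": [r.site.label for r in self.records],
                "size_mm": [r.size_mm for r in self.records],
                "surface_mm2": [r.surface_mm2 for r in self.records],
                "biopsy_mitoses": [r.biopsy_mitoses for r in self.records],
                "response": [r.response for r in self.records],
                "specimen_mitoses": [r.specimen_mitoses for r in self.records],
            }
        )


#: Canonical CSV column names.
CANONICAL_COLUMNS = (
    "site",
    "size_mm",
    "surface_mm2",
    "surface_hpf",
    "biopsy_mitoses",
    "response",
    "specimen_mitoses",
    "pretreated",
)

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value, name: str) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValidationError(f"{name} must be boolean-like, got {value!r}")


def dataset_from_frame(
    frame: pd.DataFrame,
    dialect: Mapping[str, str] | None = None,
    hpf_per_5mm2: float = HPF_PER_5MM2,
    provenance: str = "",
) -> Dataset:
    """Build a validated :class:`Dataset` from a data frame.

    ``dialect`` maps canonical column names to the frame's actual column
    names.  A ``surface_hpf`` column (native or via dialect) is converted to
    mm² with :func:`hpf_to_mm2`.  Row errors are collected and reported
    together with their 1-based row numbers.
    """
    dialect = dict(dialect or {})
    cols = {name: dialect.get(name, name) for name in CANONICAL_COLUMNS}

    def get(row, name, default=None):
        col = cols[name]
        if col in frame.columns:
            value = row[col]
            if isinstance(value, float) and math.isnan(value):
                return default
            return value
        return default

    if cols["site"] not in frame.columns:
        raise ValidationError(f"missing required column {cols['site']!r}")
    for required in ("size_mm", "biopsy_mitoses"):
        if cols[required] not in frame.columns:
            raise ValidationError(f"missing required column {cols[required]!r}")
    has_mm2 = cols["surface_mm2"] in frame.columns
    has_hpf = cols["surface_hpf"] in frame.columns
    if not has_mm2 and not has_hpf:
        raise ValidationError(
            f"need a surface column: {cols['surface_mm2']!r} or {cols['surface_hpf']!r}"
        )

    records: list[PatientRecord] = []
    errors: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            if has_mm2 and get(row, "surface_mm2") is not None:
                surface = float(get(row, "surface_mm2"))
            else:
                surface = hpf_to_mm2(float(get(row, "surface_hpf")), hpf_per_5mm2)
            response = _parse_bool(get(row, "response", False), "response")
            pretreated_raw = get(row, "pretreated")
            pretreated = (
                _parse_bool(pretreated_raw, "pretreated")
                if pretreated_raw is not None
                else None
            )
            specimen = get(row, "specimen_mitoses")
            records.append(
                PatientRecord(
                    site=Site.coerce(get(row, "site")),
                    size_mm=float(get(row, "size_mm")),
                    surface_mm2=surface,
                    biopsy_mitoses=(
                        float(get(row, "biopsy_mitoses"))
                        if get(row, "biopsy_mitoses") is not None
                        else None
                    ),
                    response=response,
                    specimen_mitoses=(
                        float(specimen) if specimen is not None else None
                    ),
                    pretreated=pretreated,
                )
            )
        except (ValidationError, TypeError) as exc:
            errors.append((i, str(exc)))
    if errors:
        raise DatasetValidationError(errors)
    return Dataset(records=tuple(records), provenance=provenance)


def read_dataset(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    hpf_per_5mm2: float = HPF_PER_5MM2,
) -> Dataset:
    """Read a CSV of patient records; see :func:`dataset_from_frame`."""
    frame = pd.read_csv(path)
    return dataset_from_frame(
        frame, dialect=dialect, hpf_per_5mm2=hpf_per_5mm2, provenance=str(path)
    )


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a Dataset as canonical-column CSV (round-trips with read_dataset)."""
    frame = dataset.to_frame()
    # keep missing specimen counts as empty cells, not "nan"
    frame["specimen_mitoses"] = frame["specimen_mitoses"].astype("Int64")
    frame.to_csv(path, index=False)
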