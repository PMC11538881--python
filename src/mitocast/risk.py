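"""GIST risk stratification: deterministic, probabilistic and preoperative.

Three layers:

* :func:`miettinen_lasota` — the classical site / size / mitotic-count
  lookup (AFIP long-term follow-up data), loaded from an editable YAML
  configuration so other classifications can be swapped in;
* :func:`predictive_risk` — pushes a posterior predictive distribution of
  the specimen count through the lookup, turning the forecast into a
  probability for each risk class;
* :func:`preoperative_class` — the proposed clinical types 0–4 combining
  resectability, metastatic status, site, size and the forecast risk.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .data_model import Site, ValidationError
from .prediction import PredictiveDistribution

__all__ = [
    "RiskClass",
    "RiskTable",
    "Resectability",
    "PreopClass",
    "load_risk_table",
    "miettinen_lasota",
    "predictive_risk",
    "preoperative_class",
]


class RiskClass(enum.Enum):
    """Ordered risk of progressive disease; insufficient_data is incomparable."""

    NONE = "none"
    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    INSUFFICIENT_DATA = "insufficient_data"

    @property
    def order(self) -> int | None:
        ordering = {
            RiskClass.NONE: 0,
            RiskClass.VERY_LOW: 1,
            RiskClass.LOW: 2,
            RiskClass.MODERATE: 3,
            RiskClass.HIGH: 4,
        }
        return ordering.get(self)

    def __lt__(self, other: "RiskClass") -> bool:
        if self.order is None or other.order is None:
            raise TypeError("insufficient_data is not comparable")
        return self.order < other.order

    @classmethod
    def coerce(cls, value) -> "RiskClass":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())


_SIZE_BAND_LABELS = ("<=2", ">2-5", ">5-10", ">10")
_MITOTIC_LABELS = ("<=5", ">5")


@dataclass(frozen=True)
class RiskTable:
    """A (site-group, size-band, mitotic-band) -> RiskClass lookup."""

    name: str
    size_band_edges_cm: tuple[float, ...]
    mitotic_threshold: float
    site_groups: dict[str, str]
    cells: dict[tuple[str, str, str], RiskClass]

    def size_band(self, size_cm: float) -> str:
        for edge, label in zip(self.size_band_edges_cm, _SIZE_BAND_LABELS):
            if size_cm <= edge:
                return label
        return _SIZE_BAND_LABELS[-1]

    def mitotic_band(self, mitoses_per_5mm2: float) -> str:
        return "<=5" if mitoses_per_5mm2 <= self.mitotic_threshold else ">5"

    def lookup(self, site: Site, size_cm: float, mitoses_per_5mm2: float) -> RiskClass:
        group = self.site_groups[site.label]
        return self.cells[(group, self.size_band(size_cm), self.mitotic_band(mitoses_per_5mm2))]


@functools.lru_cache(maxsize=8)
def _load_yaml(path: str | None) -> dict:
    if path is None:
        text = (
            resources.files("mitocast").joinpath("data/miettinen_lasota.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def load_risk_table(path: str | Path | None = None) -> RiskTable:
    """Load a risk table configuration (the packaged Miettinen–Lasota one by
    default) and validate that all 32 cells are present."""
    raw = _load_yaml(str(path) if path is not None else None)
    cells: dict[tuple[str, str, str], RiskClass] = {}
    for group, bands in raw["classes"].items():
        for size_label, by_mitoses in bands.items():
            for mito_label, value in by_mitoses.items():
                cells[(group, size_label, mito_label)] = RiskClass.coerce(value)
    groups = set(raw["classes"])
    expected = {
        (g, s, m) for g in groups for s in _SIZE_BAND_LABELS for m in _MITOTIC_LABELS
    }
    missing = expected - set(cells)
    if missing:
        raise ValidationError(f"risk table incomplete; missing cells {sorted(missing)}")
    site_groups = dict(raw["site_groups"])
    for site in Site:
        if site.label not in site_groups:
            raise ValidationError(f"risk table does not map site {site.label!r}")
        if site_groups[site.label] not in groups:
            raise ValidationError(
                f"site {site.label!r} maps to unknown group {site_groups[site.label]!r}"
            )
    return RiskTable(
        name=raw.get("name", "custom"),
        size_band_edges_cm=tuple(raw["size_band_edges_cm"]),
        mitotic_threshold=float(raw["mitotic_threshold_per_5mm2"]),
        site_groups=site_groups,
        cells=cells,
    )


def miettinen_lasota(
    site: Site | str | int,
    size_mm: float,
    mitoses_per_5mm2: float,
    table: RiskTable | None = None,
) -> RiskClass:
    """Deterministic risk class for a tumor of given site, size and count.

    ``size_mm`` is in millimetres (converted internally to the table's
    centimetre bands); band edges are closed on the upper bound, so a 50 mm
    tumor falls in the >2–5 cm band.
    """
    site = Site.coerce(site)
    if size_mm <= 0:
        raise ValidationError(f"size_mm must be positive, got {size_mm}")
    if mitoses_per_5mm2 < 0:
        raise ValidationError(f"mitotic count must be >= 0, got {mitoses_per_5mm2}")
    table = table or load_risk_table()
    return table.lookup(site, size_mm / 10.0, mitoses_per_5mm2)


def predictive_risk(
    pred: PredictiveDistribution,
    site: Site | str | int,
    size_mm: float,
    table: RiskTable | None = None,
) -> dict[RiskClass, float]:
    """Probability of each risk class under a predictive count distribution.

    ``P(class c) = Σ_k pmf_k · 1[class(site, size, k) = c]``; the result sums
    to 1 because the pmf does.
    """
    site = Site.coerce(site)
    table = table or load_risk_table()
    out = {c: 0.0 for c in RiskClass}
    for k, p in zip(pred.support, pred.pmf):
        out[table.lookup(site, size_mm / 10.0, float(k))] += float(p)
    return out


class Resectability(enum.Enum):
    RESECTABLE = "resectable"
    UNRESECTABLE = "unresectable"

    @classmethod
    def coerce(cls, value) -> "Resectability":
        if isinstance(value, cls):
            return value
        return cls(str(value).strip().lower())


@dataclass(frozen=True)
class PreopClass:
    """Proposed preoperative clinical type 0..4 (None = unclassified)."""

    clinical_type: int | None
    label: str

    @property
    def classified(self) -> bool:
        return self.clinical_type is not None


_PREOP_LABELS = {
    0: "resectable gastric mini tumor (<2 cm), low forecast risk",
    1: "resectable gastric small tumor (2-10 cm), low forecast risk",
    2: "resectable locally advanced",
    3: "resectable synchronous metastatic disease",
    4: "unresectable nonmetastatic disease",
}


def preoperative_class(
    resectability: Resectability | str,
    metastatic: bool,
    site: Site | str | int,
    size_mm: float,
    forecast_risk: RiskClass | str,
    rupture_risk: bool = False,
    mutilating_resection: bool = False,
) -> PreopClass:
    """Assign the preoperative clinical type (0–4).

    Clinical judgment (resectability, metastatic status, rupture risk,
    mutilating-resection need) enters as input flags; precedence is
    highest-severity-first: unresectable (4), then resectable metastatic (3),
    then any locally-advanced trigger (2: large tumor — gastric >10 cm,
    nongastric >5 cm — nongastric site, rupture risk, mutilating resection,
    or a high forecast risk), then the low-risk gastric types (0: <2 cm,
    1: 2–10 cm).  Inputs matching no row yield an explicit unclassified
    outcome, never a silent default.
    """
    resectability = Resectability.coerce(resectability)
    site = Site.coerce(site)
    forecast_risk = RiskClass.coerce(forecast_risk)
    if size_mm <= 0:
        raise ValidationError(f"size_mm must be positive, got {size_mm}")
    size_cm = size_mm / 10.0
    gastric = site is Site.STOMACH

    if resectability is Resectability.UNRESECTABLE:
        return PreopClass(4, _PREOP_LABELS[4])
    if metastatic:
        return PreopClass(3, _PREOP_LABELS[3])
    large = size_cm > 10.0 if gastric else size_cm > 5.0
    if (
        large
        or not gastric
        or rupture_risk
        or mutilating_resection
        or forecast_risk is RiskClass.HIGH
    ):
        return PreopClass(2, _PREOP_LABELS[2])
    low_risk = forecast_risk in (RiskClass.NONE, RiskClass.VERY_LOW, RiskClass.LOW)
    if gastric and low_risk and size_cm < 2.0:
        return PreopClass(0, _PREOP_LABELS[0])
    if gastric and low_risk and 2.0 <= size_cm <= 10.0:
        return PreopClass(1, _PREOP_LABELS[1])
    return PreopClass(
        None,
        "unclassified: no row of the preoperative classification matches "
        f"(site={site.label}, size={size_mm} mm, risk={forecast_risk.value})",
    )
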