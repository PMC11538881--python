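"""Miettinen–Lasota lookup, probabilistic risk, preoperative classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocast.data_model import Site, ValidationError
from mitocast.prediction import PredictiveDistribution
from mitocast.risk import (
    PreopClass,
    Resectability,
    RiskClass,
    load_risk_table,
    miettinen_lasota,
    predictive_risk,
    preoperative_class,
)

TABLE = load_risk_table()

# the full classification: (group, size band, mitotic band) -> class.
# sizes chosen inside each band (cm -> mm); mitoses 3 (<=5) and 8 (>5)
CELLS = [
    ("stomach", 15, 3, RiskClass.NONE),
    ("stomach", 40, 3, RiskClass.VERY_LOW),
    ("stomach", 80, 3, RiskClass.LOW),
    ("stomach", 120, 3, RiskClass.MODERATE),
    ("stomach", 15, 8, RiskClass.NONE),
    ("stomach", 40, 8, RiskClass.MODERATE),
    ("stomach", 80, 8, RiskClass.HIGH),
    ("stomach", 120, 8, RiskClass.HIGH),
    ("duodenum", 15, 3, RiskClass.NONE),
    ("duodenum", 40, 3, RiskClass.LOW),
    ("duodenum", 80, 3, RiskClass.INSUFFICIENT_DATA),
    ("duodenum", 120, 3, RiskClass.HIGH),
    ("duodenum", 15, 8, RiskClass.INSUFFICIENT_DATA),
    ("duodenum", 40, 8, RiskClass.HIGH),
    ("duodenum", 80, 8, RiskClass.INSUFFICIENT_DATA),
    ("duodenum", 120, 8, RiskClass.HIGH),
    ("small-intestine", 15, 3, RiskClass.NONE),
    ("small-intestine", 40, 3, RiskClass.LOW),
    ("small-intestine", 80, 3, RiskClass.MODERATE),
    ("small-intestine", 120, 3, RiskClass.HIGH),
    ("small-intestine", 15, 8, RiskClass.HIGH),
    ("small-intestine", 40, 8, RiskClass.HIGH),
    ("small-intestine", 80, 8, RiskClass.HIGH),
    ("small-intestine", 120, 8, RiskClass.HIGH),
    ("colon-rectum", 15, 3, RiskClass.NONE),
    ("colon-rectum", 40, 3, RiskClass.LOW),
    ("colon-rectum", 80, 3, RiskClass.INSUFFICIENT_DATA),
    ("colon-rectum", 120, 3, RiskClass.HIGH),
    ("colon-rectum", 15, 8, RiskClass.HIGH),
    ("colon-rectum", 40, 8, RiskClass.HIGH),
    ("colon-rectum", 80, 8, RiskClass.HIGH),
    ("colon-rectum", 120, 8, RiskClass.HIGH),
]


def _point_mass(k: int, support_max: int = 60) -> PredictiveDistribution:
    pmf = np.zeros(support_max + 1)
    pmf[k] = 1.0
    return _dist(pmf)


def _dist(pmf) -> PredictiveDistribution:
    pmf = np.asarray(pmf, dtype=float)
    return PredictiveDistribution(
        support=np.arange(pmf.size),
        pmf=pmf / pmf.sum(),
        lambda_samples=np.array([1.0, 2.0]),
        truncated_mass=0.0,
        modal_band=(0, 0),
        modal_band_mass=1.0,
    )


class TestMiettinenLasota:
    @pytest.mark.parametrize("site, size_mm, mitoses, expected", CELLS)
    def test_all_32_cells(self, site, size_mm, mitoses, expected):
        assert miettinen_lasota(site, size_mm, mitoses, TABLE) is expected

    def test_72mm_gastric_low_count_is_low_risk(self):
        # the worked example: 72 mm gastric tumor with <=5 mitoses / 5 mm²
        assert miettinen_lasota("stomach", 72, 4, TABLE) is RiskClass.LOW

    def test_band_edges_closed_above(self):
        # 50 mm sits in the >2-5 cm band, 20 mm in <=2 cm
        assert miettinen_lasota("stomach", 50, 0, TABLE) is RiskClass.VERY_LOW
        assert miettinen_lasota("stomach", 20, 0, TABLE) is RiskClass.NONE
        # mitotic threshold: exactly 5 is the low band
        assert miettinen_lasota("stomach", 80, 5, TABLE) is RiskClass.LOW
        assert miettinen_lasota("stomach", 80, 5.1, TABLE) is RiskClass.HIGH

    def test_monotone_in_size_and_count_where_classifiable(self):
        sizes = [15, 40, 80, 120]
        for site in Site:
            for mitoses in (3, 8):
                classes = [
                    miettinen_lasota(site, s, mitoses, TABLE) for s in sizes
                ]
                ordered = [c for c in classes if c.order is not None]
                assert all(
                    a.order <= b.order for a, b in zip(ordered, ordered[1:])
                )
            for s in sizes:
                low = miettinen_lasota(site, s, 3, TABLE)
                high = miettinen_lasota(site, s, 8, TABLE)
                if low.order is not None and high.order is not None:
                    assert low.order <= high.order

    def test_unit_convention_is_mm(self):
        # 7.2 "mm" would be a <=2 cm tumor; 72 mm the >5-10 cm band
        assert miettinen_lasota("stomach", 7.2, 3, TABLE) is RiskClass.NONE
        assert miettinen_lasota("stomach", 72, 3, TABLE) is RiskClass.LOW

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            miettinen_lasota("stomach", 0, 3, TABLE)
        with pytest.raises(ValidationError):
            miettinen_lasota("stomach", 50, -1, TABLE)


class TestPredictiveRisk:
    def test_point_mass_is_deterministic_class(self):
        probs = predictive_risk(_point_mass(3), "stomach", 72, TABLE)
        assert probs[RiskClass.LOW] == pytest.approx(1.0)
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_split_mass_across_threshold(self):
        pmf = np.zeros(20)
        pmf[4] = 0.5
        pmf[7] = 0.5
        probs = predictive_risk(_dist(pmf), "stomach", 72, TABLE)
        assert probs[RiskClass.LOW] == pytest.approx(0.5)
        assert probs[RiskClass.HIGH] == pytest.approx(0.5)

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=40),
        st.sampled_from(["stomach", "duodenum", "small-intestine", "colon-rectum"]),
        st.floats(min_value=5.0, max_value=150.0),
    )
    def test_probabilities_sum_to_one(self, weights, site, size_mm):
        probs = predictive_risk(_dist(weights), site, size_mm, TABLE)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= p <= 1.0 + 1e-12 for p in probs.values())

    def test_upward_mass_shift_never_decreases_high(self):
        for site in Site:
            for size_mm in (15, 40, 80, 120):
                pmf = np.zeros(30)
                pmf[2] = 0.7
                pmf[10] = 0.3
                before = predictive_risk(_dist(pmf), site, size_mm, TABLE)
                shifted = np.zeros(30)
                shifted[2] = 0.4
                shifted[10] = 0.6  # mass moved from <=5 to >5 counts
                after = predictive_risk(_dist(shifted), site, size_mm, TABLE)
                assert after[RiskClass.HIGH] >= before[RiskClass.HIGH] - 1e-12


class TestRiskClassOrdering:
    def test_total_order_on_comparable_classes(self):
        assert (
            RiskClass.NONE
            < RiskClass.VERY_LOW
            < RiskClass.LOW
            < RiskClass.MODERATE
            < RiskClass.HIGH
        )

    def test_insufficient_data_incomparable(self):
        with pytest.raises(TypeError):
            RiskClass.INSUFFICIENT_DATA < RiskClass.HIGH


class TestPreoperativeClass:
    def test_unresectable_dominates(self):
        out = preoperative_class(
            "unresectable", metastatic=False, site="stomach", size_mm=15,
            forecast_risk=RiskClass.LOW,
        )
        assert out.clinical_type == 4

    def test_resectable_metastatic(self):
        out = preoperative_class(
            "resectable", metastatic=True, site="stomach", size_mm=15,
            forecast_risk=RiskClass.LOW,
        )
        assert out.clinical_type == 3

    def test_gastric_mini_low_risk(self):
        out = preoperative_class(
            "resectable", metastatic=False, site="stomach", size_mm=15,
            forecast_risk=RiskClass.LOW,
        )
        assert out.clinical_type == 0

    def test_gastric_small_low_risk(self):
        out = preoperative_class(
            "resectable", metastatic=False, site="stomach", size_mm=50,
            forecast_risk=RiskClass.VERY_LOW,
        )
        assert out.clinical_type == 1

    def test_nongastric_site_is_locally_advanced(self):
        out = preoperative_class(
            "resectable", metastatic=False, site="duodenum", size_mm=60,
            forecast_risk=RiskClass.LOW,
        )
        assert out.clinical_type == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"size_mm": 120},  # gastric > 10 cm
            {"forecast_risk": RiskClass.HIGH},
            {"rupture_risk": True},
            {"mutilating_resection": True},
        ],
    )
    def test_locally_advanced_triggers(self, kwargs):
        base = dict(
            resectability="resectable", metastatic=False, site="stomach",
            size_mm=50, forecast_risk=RiskClass.LOW,
        )
        base.update(kwargs)
        assert preoperative_class(**base).clinical_type == 2

    def test_unmatched_inputs_are_explicitly_unclassified(self):
        out = preoperative_class(
            "resectable", metastatic=False, site="stomach", size_mm=50,
            forecast_risk=RiskClass.MODERATE,
        )
        assert out.clinical_type is None
        assert not out.classified
        assert "unclassified" in out.label
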