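"""WAWQI and CWQI: ratings, factors, scores, classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riverwqi import (
    ParameterDef,
    QualityRating,
    SampleRecord,
    StandardsRegistry,
    classify_cwqi,
    classify_wawqi,
    cwqi_factors,
    cwqi_score,
    quality_rating,
    wawqi_score,
)
from riverwqi.indices import CwqiFactors


def _pdef(name="X", objective="ceiling", limit=10.0, ideal=0.0, **kw):
    return ParameterDef(
        name=name, unit="mg/L", objective=objective, standard_limit=limit,
        ideal=ideal, weight=kw.pop("weight", 1.0), **kw,
    )


class TestQualityRating:
    def test_value_at_limit_rates_100(self):
        assert quality_rating(10.0, _pdef()).qi == pytest.approx(100.0)
        do = _pdef("DO", "floor", 6.0, ideal=14.6)
        assert quality_rating(6.0, do).qi == pytest.approx(100.0)

    def test_value_at_ideal_rates_0(self):
        assert quality_rating(0.0, _pdef()).qi == 0.0
        do = _pdef("DO", "floor", 6.0, ideal=14.6)
        assert quality_rating(14.6, do).qi == 0.0

    def test_ph_near_upper_bound(self):
        ph = _pdef("pH", "range", (6.5, 8.5), ideal=7.0)
        assert quality_rating(7.98, ph).qi == pytest.approx(65.3333, abs=1e-3)
        # either bound rates exactly 100
        assert quality_rating(6.5, ph).qi == pytest.approx(100.0)
        assert quality_rating(8.5, ph).qi == pytest.approx(100.0)

    def test_low_summer_oxygen_exceeds_100(self):
        do = _pdef("DO", "floor", 6.0, ideal=14.6)
        assert quality_rating(3.82, do).qi == pytest.approx(125.349, abs=1e-3)

    def test_safe_side_of_ideal_clamps_to_zero(self):
        do = _pdef("DO", "floor", 6.0, ideal=14.6)
        r = quality_rating(15.0, do)
        assert r.qi == 0.0 and r.clamped


class TestWawqi:
    def test_single_parameter_is_its_rating(self):
        r = QualityRating("X", 37.5, 3.75)
        assert wawqi_score([r], {"X": 2.7}) == pytest.approx(37.5)

    def test_equal_weights_average(self):
        rs = [QualityRating("A", 100.0, 0), QualityRating("B", 0.0, 0)]
        assert wawqi_score(rs, {"A": 1, "B": 1}) == pytest.approx(50.0)

    def test_hand_weighted_mean(self):
        rs = [
            QualityRating("A", 120.0, 0),
            QualityRating("B", 30.0, 0),
            QualityRating("C", 60.0, 0),
        ]
        assert wawqi_score(rs, {"A": 3, "B": 1, "C": 2}) == pytest.approx(85.0)

    def test_empty_and_missing_weight_raise(self):
        with pytest.raises(ValueError):
            wawqi_score([], {})
        with pytest.raises(ValueError, match="weight"):
            wawqi_score([QualityRating("A", 1.0, 0)], {})

    @given(
        qis=st.lists(st.floats(0, 500), min_size=1, max_size=8),
        scale=st.floats(1e-3, 1e3),
        data=st.data(),
    )
    def test_weight_rescaling_invariance_and_bounds(self, qis, scale, data):
        weights = {
            f"p{i}": data.draw(st.floats(0.1, 10)) for i in range(len(qis))
        }
        rs = [QualityRating(f"p{i}", q, 0) for i, q in enumerate(qis)]
        s1 = wawqi_score(rs, weights)
        s2 = wawqi_score(rs, {k: v * scale for k, v in weights.items()})
        assert s1 == pytest.approx(s2, abs=1e-9, rel=1e-9)
        assert min(qis) - 1e-9 <= s1 <= max(qis) + 1e-9

    @given(
        qis=st.lists(st.floats(0, 500), min_size=1, max_size=6),
        bump=st.floats(0.1, 100),
        data=st.data(),
    )
    def test_monotone_in_every_rating(self, qis, bump, data):
        weights = {f"p{i}": 1.0 + i for i in range(len(qis))}
        rs = [QualityRating(f"p{i}", q, 0) for i, q in enumerate(qis)]
        base = wawqi_score(rs, weights)
        k = data.draw(st.integers(0, len(qis) - 1))
        rs[k] = QualityRating(f"p{k}", qis[k] + bump, 0)
        assert wawqi_score(rs, weights) >= base


class TestClassification:
    @pytest.mark.parametrize(
        "score,category",
        [
            (24.5, "excellent"),
            (52.6, "poor"),
            (127.4, "unsuitable"),
            (25.0, "excellent"),
            (25.5, "good"),
            (100.0, "very_poor"),
        ],
    )
    def test_wawqi_classes(self, score, category):
        assert classify_wawqi(score) == category

    @pytest.mark.parametrize(
        "score,category",
        [
            (93.69, "good"),
            (85.48, "good"),
            (74.2, "fair"),
            (68.3, "fair"),
            (100.0, "excellent"),
            (44.999, "poor"),
        ],
    )
    def test_cwqi_classes(self, score, category):
        assert classify_cwqi(score) == category

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            classify_wawqi(-0.1)
        with pytest.raises(ValueError):
            classify_cwqi(100.1)

    @given(st.floats(0, 300, allow_nan=False))
    def test_every_wawqi_score_has_exactly_one_class(self, score):
        bins = [(0, 25), (25, 50), (50, 75), (75, 100), (100, math.inf)]
        hits = [lo < score <= hi or (score == 0 and lo == 0) for lo, hi in bins]
        assert sum(hits) == 1
        assert classify_wawqi(score) in {
            "excellent", "good", "poor", "very_poor", "unsuitable"
        }

    @given(st.floats(0, 100, allow_nan=False))
    def test_every_cwqi_score_has_exactly_one_class(self, score):
        assert classify_cwqi(score) in {
            "excellent", "good", "fair", "marginal", "poor"
        }

    @pytest.mark.parametrize("edge", [45.0, 65.0, 80.0, 95.0])
    def test_cwqi_edges_belong_to_the_upper_class(self, edge):
        below = classify_cwqi(math.nextafter(edge, 0.0))
        assert classify_cwqi(edge) != below


def _registry_simple():
    return StandardsRegistry(
        [
            _pdef("COD", "ceiling", 10.0, weight=4),
            _pdef("TN", "ceiling", 3500.0, weight=4),
            _pdef("DO", "floor", 6.0, ideal=14.6, weight=3),
            ParameterDef("pH", "pH", "range", (6.5, 8.5), 7.0, 2.0),
        ]
    )


def _recs(values):
    return [
        SampleRecord("S1", "main", "summer", p, v, replicate=i)
        for p, vals in values.items()
        for i, v in enumerate(vals)
    ]


class TestCwqiFactors:
    def test_all_passing_gives_zero_factors(self):
        reg = _registry_simple()
        f = cwqi_factors(_recs({"COD": [5, 8], "DO": [7, 9], "pH": [7.2]}), reg)
        assert f.F1 == f.F2 == f.F3 == 0.0
        assert cwqi_score(f).score == 100.0
        assert cwqi_score(f).category == "excellent"

    def test_single_failure_hand_values(self):
        reg = _registry_simple()
        recs = _recs({"COD": [15, 8], "TN": [100, 200], "DO": [7, 8]})
        f = cwqi_factors(recs, reg)
        assert f.F1 == pytest.approx(100 / 3)
        assert f.F2 == pytest.approx(100 / 6)
        assert f.nse == pytest.approx(0.5 / 6)
        assert f.F3 == pytest.approx(7.6923, abs=1e-4)
        assert f.excursions == [("COD", 0, pytest.approx(0.5))]

    def test_nse_of_one_gives_f3_of_50(self):
        reg = _registry_simple()
        recs = _recs({"COD": [20, 20], "TN": [7000, 7000]})
        f = cwqi_factors(recs, reg)
        assert f.nse == pytest.approx(1.0)
        assert f.F3 == pytest.approx(50.0)

    def test_floor_zero_measurement_is_capped(self, caplog):
        reg = _registry_simple()
        with caplog.at_level("WARNING"):
            f = cwqi_factors(_recs({"DO": [0.0, 7.0]}), reg)
        assert f.excursions[0][2] == pytest.approx(100.0)
        assert any("capped" in m for m in caplog.messages)

    def test_agrees_with_brute_force_oracle(self):
        """Vectorized bookkeeping vs a naive loop on 500 random datasets."""
        reg = _registry_simple()
        rng = np.random.default_rng(42)
        params = ["COD", "TN", "DO", "pH"]
        for _ in range(500):
            k = rng.integers(1, 5)
            chosen = rng.choice(params, size=k, replace=False)
            values = {
                p: list(
                    rng.uniform(
                        *{
                            "COD": (0, 40), "TN": (0, 8000),
                            "DO": (0.5, 12), "pH": (5.5, 9.5),
                        }[p],
                        size=rng.integers(1, 4),
                    )
                )
                for p in chosen
            }
            f = cwqi_factors(_recs(values), reg)
            # independent oracle: recount failures/excursions from scratch
            n_tests = sum(len(v) for v in values.values())
            failed_params, n_failed, total_exc = set(), 0, 0.0
            for p, vals in values.items():
                for v in vals:
                    if p == "COD" and v > 10:
                        exc = v / 10 - 1
                    elif p == "TN" and v > 3500:
                        exc = v / 3500 - 1
                    elif p == "DO" and v < 6:
                        exc = 6 / v - 1
                    elif p == "pH" and v > 8.5:
                        exc = v / 8.5 - 1
                    elif p == "pH" and v < 6.5:
                        exc = 6.5 / v - 1
                    else:
                        continue
                    failed_params.add(p)
                    n_failed += 1
                    total_exc += exc
            nse = total_exc / n_tests
            assert f.F1 == pytest.approx(100 * len(failed_params) / len(values))
            assert f.F2 == pytest.approx(100 * n_failed / n_tests)
            assert f.F3 == pytest.approx(nse / (0.01 * nse + 0.01))


class TestCwqiScore:
    def test_hand_arithmetic(self):
        f = CwqiFactors(10, 10, 50, 0, 1, 1, 0, 0)
        res = cwqi_score(f)
        assert res.score == pytest.approx(100 - math.sqrt(2700) / 1.732, abs=1e-9)
        assert res.score == pytest.approx(69.999, abs=1e-3)
        assert res.category == "fair"

    def test_worst_case_clamps_to_zero(self):
        f = CwqiFactors(100, 100, 100, 0, 1, 1, 1, 1)
        raw = 100 - math.sqrt(3 * 100**2) / 1.732
        assert raw == pytest.approx(-0.0029, abs=1e-4)  # literal 1.732, not sqrt(3)
        res = cwqi_score(f)
        assert res.score == 0.0
        assert res.category == "poor"

    def test_monotone_nonincreasing_when_adding_failed_tests(self):
        """Exhaustive small-case enumeration: adding one failed COD test
        (value above the guideline) never raises the CWQI."""
        reg = _registry_simple()
        levels = {"COD": [5.0, 15.0, 30.0], "TN": [1000.0, 7000.0], "DO": [4.0, 8.0]}
        for combo in itertools.product(
            levels["COD"], levels["TN"], levels["DO"], repeat=1
        ):
            for n_tests in (1, 2, 3):
                values = {
                    "COD": [combo[0]] * n_tests,
                    "TN": [combo[1]] * n_tests,
                    "DO": [combo[2]] * n_tests,
                }
                base = cwqi_score(cwqi_factors(_recs(values), reg)).score
                worse = {k: list(v) for k, v in values.items()}
                worse["COD"] = worse["COD"] + [25.0]
                after = cwqi_score(cwqi_factors(_recs(worse), reg)).score
                assert after <= base + 1e-9
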