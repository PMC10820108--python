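"""NRF6.4 scoring, normalizations, and their structural invariants."""

import numpy as np
import pytest

from snackprofiler.gnpd_io import CodedValue
from snackprofiler.nrf_scoring import (
    DEFAULT_DAILY_VALUES,
    DEFAULT_RACC_G,
    DISQUALIFYING,
    QUALIFYING,
    NRFResult,
    ScoringExclusion,
    capped_percent_dv,
    per_100g,
    per_100kcal,
    per_racc,
    score_nrf64,
    score_table,
)
from conftest import make_record


class TestBasisConversions:
    def test_per_100kcal(self):
        assert per_100kcal(2.0, 200.0) == pytest.approx(1.0)
        assert per_100kcal(3.5, 100.0) == pytest.approx(3.5)

    def test_zero_energy_excluded_not_silently_zero(self):
        with pytest.raises(ScoringExclusion):
            per_100kcal(2.0, 0.0)

    def test_per_100g(self):
        assert per_100g(4.0, 40.0) == pytest.approx(10.0)
        assert per_100g(7.0, 100.0) == pytest.approx(7.0)
        with pytest.raises(ScoringExclusion):
            per_100g(4.0, 0.0)

    @pytest.mark.parametrize(
        "per100g,category,expected",
        [
            (323.8, "dried_fruit", 129.5),   # 40 g reference amount
            (68.5, "fruit_puree", 85.6),     # 125 g reference amount
        ],
    )
    def test_per_racc_published_examples(self, per100g, category, expected):
        assert per_racc(per100g, category) == pytest.approx(expected, abs=0.05)

    def test_per_racc_identity_at_100g(self):
        assert per_racc(7.7, "dried_fruit", {"dried_fruit": 100.0}) == pytest.approx(7.7)

    def test_unknown_category_hard_error(self):
        with pytest.raises(KeyError):
            per_racc(1.0, "frozen_fruit")


class TestCappedPercentDV:
    def test_at_dv_and_above_cap(self):
        assert capped_percent_dv(28.0, "fiber") == pytest.approx(100.0)
        assert capped_percent_dv(56.0, "fiber") == pytest.approx(100.0)
        assert capped_percent_dv(25.0, "added_sugar") == pytest.approx(50.0)

    def test_unknown_nutrient_hard_error(self):
        with pytest.raises(KeyError):
            capped_percent_dv(1.0, "trans_fat")


class TestScoreNRF64:
    def test_all_zero_panel(self):
        res = score_nrf64(make_record(energy=100.0, serving_g=50.0))
        assert res.nr == 0 and res.lim == 0 and res.nrf64 == 0
        assert res.energy_density_100g == pytest.approx(200.0)

    def test_each_nutrient_at_ten_percent_dv(self):
        # per 100 kcal: each qualifying and disqualifying term is exactly 10%
        r = make_record(
            energy=100.0, serving_g=40.0,
            protein=5.0, fiber=2.8, potassium=470.0, vitamin_d=2.0,
            calcium=130.0, iron=1.8,
            added_sugar=5.0, saturated_fat=2.0, sodium=230.0, cholesterol=30.0,
        )
        res = score_nrf64(r)
        assert res.nr == pytest.approx(60.0)
        assert res.lim == pytest.approx(40.0)
        assert res.nrf64 == pytest.approx(20.0)

    def test_cap_binds_per_nutrient(self):
        r = make_record(energy=100.0, fiber=100.0)
        res = score_nrf64(r)
        assert res.breakdown["fiber"] == pytest.approx(100.0)
        assert res.nrf64 == pytest.approx(100.0)

    def test_score_bounds(self, rng):
        for _ in range(50):
            r = _random_panel(rng)
            res = score_nrf64(r)
            assert 0 <= res.nr <= 600 and 0 <= res.lim <= 400
            assert -400 <= res.nrf64 <= 600
            assert res.nrf64 == res.nr - res.lim

    def test_missing_panel_value_is_hard_error(self):
        r = make_record()
        r.panel["iron"] = CodedValue.missing()
        with pytest.raises(ValueError, match="iron"):
            score_nrf64(r)

    def test_zero_energy_is_exclusion(self):
        with pytest.raises(ScoringExclusion):
            score_nrf64(make_record(energy=0.0))


def _random_panel(rng, energy=None, serving=None):
    return make_record(
        record_id=f"R{rng.integers(1e9)}",
        energy=float(energy if energy is not None else rng.uniform(20, 600)),
        serving_g=float(serving if serving is not None else rng.uniform(10, 150)),
        protein=float(rng.uniform(0, 10)),
        fiber=float(rng.uniform(0, 12)),
        potassium=float(rng.uniform(0, 1200)),
        vitamin_d=float(rng.uniform(0, 5)),
        calcium=float(rng.uniform(0, 400)),
        iron=float(rng.uniform(0, 5)),
        added_sugar=float(rng.uniform(0, 40)),
        saturated_fat=float(rng.uniform(0, 8)),
        sodium=float(rng.uniform(0, 500)),
        cholesterol=float(rng.uniform(0, 60)),
    )


class TestInvariants:
    def test_serving_rescaling_leaves_scores_unchanged(self, rng):
        """Multiplying serving mass and the whole panel by c>0 changes nothing."""
        for _ in range(200):
            r = _random_panel(rng)
            c = float(rng.uniform(0.2, 5.0))
            scaled = r.copy()
            scaled.serving_g = r.serving_g * c
            for nutrient, cv in r.panel.items():
                scaled.panel[nutrient] = CodedValue.numeric(cv.value * c)
            a, b = score_nrf64(r), score_nrf64(scaled)
            assert b.nrf64 == pytest.approx(a.nrf64, rel=1e-9)
            assert b.energy_density_100g == pytest.approx(a.energy_density_100g, rel=1e-9)

    def test_added_sugar_monotonicity_below_cap(self, rng):
        for _ in range(100):
            r = _random_panel(rng, energy=200.0)
            r.panel["added_sugar"] = CodedValue.numeric(float(rng.uniform(0, 40)))
            more = r.copy()
            more.panel["added_sugar"] = CodedValue.numeric(r.numeric("added_sugar") + 5.0)
            if per_100kcal(more.numeric("added_sugar"), 200.0) <= DEFAULT_DAILY_VALUES["added_sugar"]:
                assert score_nrf64(more).nrf64 < score_nrf64(r).nrf64

    def test_fiber_monotonicity_below_cap(self, rng):
        for _ in range(100):
            r = _random_panel(rng, energy=200.0)
            more = r.copy()
            more.panel["fiber"] = CodedValue.numeric(r.numeric("fiber") + 2.0)
            if per_100kcal(more.numeric("fiber"), 200.0) <= DEFAULT_DAILY_VALUES["fiber"]:
                assert score_nrf64(more).nrf64 > score_nrf64(r).nrf64

    def test_aggregation_linearity(self, rng):
        records = [_random_panel(rng) for _ in range(60)]
        for r in records:
            r.category = "dried_fruit"
        table, excluded = score_table(records)
        assert not excluded
        assert np.mean(table["nrf64"]) == pytest.approx(
            np.mean(table["nr"]) - np.mean(table["lim"]), rel=1e-12
        )
        ratio = DEFAULT_RACC_G["dried_fruit"] / 100.0
        assert np.mean(table["fiber_racc"]) == pytest.approx(
            np.mean(table["fiber_100g"]) * ratio, rel=1e-12
        )

    def test_oracle_equivalence_brute_force(self, rng):
        """Explicit spreadsheet-style loop over the ten nutrients agrees."""
        for _ in range(100):
            r = _random_panel(rng)
            energy = r.numeric("energy")
            nr = 0.0
            for nutrient in QUALIFYING:
                amount = r.numeric(nutrient) * 100.0 / energy
                pct = amount / DEFAULT_DAILY_VALUES[nutrient] * 100.0
                nr += min(pct, 100.0)
            lim = 0.0
            for nutrient in DISQUALIFYING:
                amount = r.numeric(nutrient) * 100.0 / energy
                pct = amount / DEFAULT_DAILY_VALUES[nutrient] * 100.0
                lim += min(pct, 100.0)
            res = score_nrf64(r)
            assert res.nr == pytest.approx(nr, rel=1e-12)
            assert res.lim == pytest.approx(lim, rel=1e-12)
            assert res.nrf64 == pytest.approx(nr - lim, rel=1e-9)


class TestNRFResult:
    def test_identity_enforced(self):
        with pytest.raises(AssertionError):
            NRFResult(nr=10.0, lim=2.0, nrf64=9.0, energy_density_100g=100.0, breakdown={})
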