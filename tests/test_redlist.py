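import numpy as np
import pytest
from shapely.geometry import box

from deforisk.exploitation import ExploitationEstimate
from deforisk.habitat import HabitatChange, SpeciesRecord
from deforisk.redlist import (
    CATEGORIES,
    Thresholds,
    assess,
    assessment_window,
    category_counts,
    classify_decline,
    classify_eoo,
    more_severe,
    percent_increase,
    project_decline,
    summarize,
    threatened_total,
)

SEVERITY = {cat: k for k, cat in enumerate(CATEGORIES)}


class TestAssessmentWindow:
    def test_short_generation_floors_at_ten(self):
        assert assessment_window(2.0) == 10.0

    def test_long_generation(self):
        assert assessment_window(7.0) == 21.0

    def test_absent_defaults_to_ten_with_warning(self):
        with pytest.warns(UserWarning, match="generation"):
            assert assessment_window(None) == 10.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            assessment_window(0.0)


class TestProjectDecline:
    def test_zero_loss(self):
        assert project_decline(0.0, 15, 25).decline_deforestation == 0.0

    def test_closed_form(self):
        proj = project_decline(0.15, 15.0, 10.0)
        assert proj.r_annual == pytest.approx(0.01)
        assert proj.decline_deforestation == pytest.approx(1 - 0.99**10)
        assert proj.decline_deforestation == pytest.approx(0.0956, abs=1e-4)

    def test_increase_floored(self):
        proj = project_decline(-0.1, 15.0, 10.0)
        assert proj.increase
        assert proj.r_annual == 0.0
        assert proj.decline_deforestation == 0.0

    def test_rate_ge_one_capped(self):
        proj = project_decline(30.0, 15.0, 10.0)
        assert proj.rate_capped
        assert proj.decline_deforestation == 1.0

    def test_invalid_observed_years(self):
        with pytest.raises(ValueError):
            project_decline(0.1, 0.0, 10.0)


class TestClassifyDecline:
    @pytest.mark.parametrize(
        "decline,expected",
        [
            (0.0, "LC"),
            (0.149999, "LC"),
            (0.15, "NT"),
            (0.299, "NT"),
            (0.30, "VU"),
            (0.50, "EN"),
            (0.54, "EN"),
            (0.80, "CR"),
            (1.20, "CR"),  # capped to 1.0 then CR
        ],
    )
    def test_thresholds_inclusive(self, decline, expected):
        assert classify_decline(decline) == expected

    def test_monotone_in_decline(self, rng):
        declines = np.sort(rng.uniform(0, 1.2, 100))
        cats = [SEVERITY[classify_decline(d)] for d in declines]
        assert all(a <= b for a, b in zip(cats, cats[1:]))

    def test_configurable_nt_threshold(self):
        t = Thresholds(nt=0.20)
        assert classify_decline(0.17, t) == "LC"
        assert classify_decline(0.20, t) == "NT"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_decline(-0.1)


class TestClassifyEoo:
    @pytest.mark.parametrize(
        "eoo,expected",
        [(499.0, "EN"), (1999.0, "VU"), (2000.0, None), (0.0, "EN"), (500.0, "VU")],
    )
    def test_strict_bounds(self, eoo, expected):
        assert classify_eoo(eoo) == expected


def _sp(sid, gen=5.0, persecution="none"):
    return SpeciesRecord(
        species_id=sid,
        range_geometry=box(0, 0, 1000, 1000),
        generation_length=gen,
        persecution=persecution,
    )


def _est(sid, point, lo=None, hi=None, category="high"):
    lo = point if lo is None else lo
    hi = point if hi is None else hi
    return ExploitationEstimate(sid, category, 1.0, 1.0, point, lo, hi)


class TestAssess:
    def test_all_benign_all_lc(self):
        species = [_sp(f"s{i}") for i in range(5)]
        changes = {s.species_id: HabitatChange(s.species_id, 100.0, 100.0) for s in species}
        out = assess(species, changes, {}, {s.species_id: 1.0 for s in species})
        assert all(a.final_category == "LC" for a in out)
        assert threatened_total(category_counts(a.final_category for a in out)) == 0

    def test_combined_en_with_exploitation_driver(self):
        sp = _sp("s0")
        # deforestation decline 0.10 + exploitation 0.45 -> 0.55 -> EN
        window = assessment_window(sp.generation_length)
        p_loss = (1 - (1 - 0.10) ** (1 / window)) * 15.0
        changes = {"s0": HabitatChange("s0", 100.0, 100.0 * (1 - p_loss))}
        out = assess([sp], changes, {"s0": _est("s0", 0.45)}, {"s0": 1.0})
        a = out[0]
        assert a.decline_deforestation == pytest.approx(0.10, abs=1e-9)
        assert a.decline_total == pytest.approx(0.55, abs=1e-9)
        assert a.final_category == "EN"
        assert a.primary_driver == "exploitation"

    def test_cohort_counts_match_brute_force(self, rng):
        # classification oracle: independently classify constructed declines
        species, changes, ests, fracs = [], {}, {}, {}
        expected = {cat: 0 for cat in CATEGORIES}
        for i in range(60):
            sid = f"s{i}"
            species.append(_sp(sid, gen=2.0))  # window = 10
            p_loss = float(rng.uniform(-0.1, 0.9))
            changes[sid] = HabitatChange(sid, 100.0, 100.0 * (1 - p_loss))
            exp_point = float(rng.uniform(0, 0.6)) if rng.uniform() < 0.5 else 0.0
            if exp_point > 0:
                ests[sid] = _est(sid, exp_point)
            fracs[sid] = 1.0
            r = max(p_loss, 0.0) / 15.0
            total = min((1 - (1 - r) ** 10) + exp_point, 1.0)
            if total >= 0.80:
                expected["CR"] += 1
            elif total >= 0.50:
                expected["EN"] += 1
            elif total >= 0.30:
                expected["VU"] += 1
            elif total >= 0.15:
                expected["NT"] += 1
            else:
                expected["LC"] += 1
        out = assess(species, changes, ests, fracs)
        assert category_counts(a.final_category for a in out) == expected

    def test_additivity_pre_cap(self, rng):
        species = [_sp(f"s{i}", gen=4.0) for i in range(20)]
        changes, ests, fracs = {}, {}, {}
        for s in species:
            changes[s.species_id] = HabitatChange(
                s.species_id, 100.0, float(rng.uniform(10, 100))
            )
            ests[s.species_id] = _est(s.species_id, float(rng.uniform(0, 0.9)))
            fracs[s.species_id] = 1.0
        for a in assess(species, changes, ests, fracs):
            assert a.decline_total_raw - a.decline_deforestation == pytest.approx(
                ests[a.species_id].decline_point
            )

    def test_uncertainty_ordering(self, rng):
        species = [_sp(f"s{i}") for i in range(30)]
        changes, ests, fracs = {}, {}, {}
        for s in species:
            changes[s.species_id] = HabitatChange(
                s.species_id, 100.0, float(rng.uniform(20, 100))
            )
            point = float(rng.uniform(0.1, 0.7))
            ests[s.species_id] = _est(
                s.species_id, point, lo=point * 0.5, hi=min(point * 1.5, 1.0)
            )
            fracs[s.species_id] = 1.0
        for a in assess(species, changes, ests, fracs):
            c_lo = SEVERITY[classify_decline(a.decline_lo)]
            c_pt = SEVERITY[classify_decline(a.decline_total)]
            c_hi = SEVERITY[classify_decline(a.decline_hi)]
            assert c_lo <= c_pt <= c_hi

    def test_monotone_in_components(self):
        sp = _sp("s0", gen=2.0)
        fracs = {"s0": 1.0}
        base = assess(
            [sp], {"s0": HabitatChange("s0", 100.0, 80.0)}, {"s0": _est("s0", 0.2)}, fracs
        )[0]
        worse_exp = assess(
            [sp], {"s0": HabitatChange("s0", 100.0, 80.0)}, {"s0": _est("s0", 0.5)}, fracs
        )[0]
        worse_hab = assess(
            [sp], {"s0": HabitatChange("s0", 100.0, 40.0)}, {"s0": _est("s0", 0.2)}, fracs
        )[0]
        assert SEVERITY[worse_exp.category_decline] >= SEVERITY[base.category_decline]
        assert SEVERITY[worse_hab.category_decline] >= SEVERITY[base.category_decline]

    def test_eoo_escalates_final_category(self):
        sp = _sp("s0")
        changes = {"s0": HabitatChange("s0", 100.0, 100.0)}
        out = assess([sp], changes, {}, {"s0": 1.0}, eoo_km2={"s0": 400.0})
        assert out[0].category_decline == "LC"
        assert out[0].category_eoo == "EN"
        assert out[0].final_category == "EN"

    def test_non_endemic_flagged(self):
        sp = _sp("s0")
        changes = {"s0": HabitatChange("s0", 100.0, 100.0)}
        out = assess([sp], changes, {}, {"s0": 0.5})
        assert not out[0].endemic

    def test_missing_inputs_skipped_with_warning(self):
        species = [_sp("s0"), _sp("s1")]
        changes = {"s0": HabitatChange("s0", 100.0, 90.0)}
        with pytest.warns(UserWarning, match="s1"):
            out = assess(species, changes, {}, {"s0": 1.0})
        assert [a.species_id for a in out] == ["s0"]

    def test_capped_total_flagged(self):
        sp = _sp("s0", gen=10.0)
        changes = {"s0": HabitatChange("s0", 100.0, 20.0)}
        out = assess([sp], changes, {"s0": _est("s0", 0.9)}, {"s0": 1.0})
        a = out[0]
        assert a.decline_total_raw > 1.0
        assert a.decline_total == 1.0
        assert "decline_capped" in a.flags
        assert a.final_category == "CR"


class TestAggregation:
    def test_more_severe(self):
        assert more_severe("LC", "EN") == "EN"
        assert more_severe("CR", "VU") == "CR"
        assert more_severe("NT", None) == "NT"

    def test_threatened_total(self):
        assert threatened_total({"CR": 9, "EN": 20, "VU": 22, "NT": 5, "LC": 100}) == 51

    def test_percent_increase(self):
        assert percent_increase(51, 27) == 89

    def test_category_counts_rejects_unknown(self):
        with pytest.raises(ValueError):
            category_counts(["LC", "XX"])

    def test_summarize_driver_counts(self):
        species = [_sp("s0", gen=2.0), _sp("s1", gen=2.0)]
        changes = {
            "s0": HabitatChange("s0", 100.0, 50.0),
            "s1": HabitatChange("s1", 100.0, 99.0),
        }
        ests = {"s1": _est("s1", 0.6)}
        out = assess(species, changes, ests, {"s0": 1.0, "s1": 1.0})
        summary = summarize(out)
        assert summary["n_exploited"] == 1
        assert summary["exploitation_dominant"] == 1
        assert summary["threatened_total"] == threatened_total(summary["category_counts"])
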