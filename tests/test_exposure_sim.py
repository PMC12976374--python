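"""Monte Carlo exposure engine: substitution, PAH4, unit conversion, coupling."""

import math

import numpy as np
import pytest

from pahburden.exposure_sim import (
    OPTIMISTIC,
    PESSIMISTIC,
    Scenario,
    SimConfig,
    UG_PER_KG_TO_MG,
    draw_concentration,
    draw_food_sample,
    pah4,
    person_day_exposure,
    simulate,
    substitute,
)
from pahburden.tds_data import (
    ANALYTES,
    AnalyteCode,
    ConcentrationRecord,
    ConsumptionEvent,
    PersonDay,
    ValidationError,
)


def _rec(fid, sid, analyte, detected, value=None, lod=0.15):
    return ConcentrationRecord(fid, sid, analyte, detected, value, lod)


def _full_sample(fid, sid, per_analyte_value=None, lod=0.15):
    """Four records for one composite sample; detected iff a value is given."""
    return [
        _rec(fid, sid, a, per_analyte_value is not None, per_analyte_value, lod)
        for a in ANALYTES
    ]


# --- substitution ----------------------------------------------------------

def test_substitute_nondetect_optimistic_is_zero():
    r = _rec("F1", "s0", AnalyteCode.BaP, False)
    assert substitute(r, OPTIMISTIC) == 0.0


def test_substitute_nondetect_pessimistic_is_lod():
    r = _rec("F1", "s0", AnalyteCode.BaP, False, lod=0.15)
    assert substitute(r, PESSIMISTIC) == 0.15


@pytest.mark.parametrize("scenario", [OPTIMISTIC, PESSIMISTIC])
def test_detection_overrides_substitution(scenario):
    r = _rec("F1", "s0", AnalyteCode.BaP, True, 2.06)
    assert substitute(r, scenario) == 2.06


def test_optimistic_scenario_must_substitute_zero():
    with pytest.raises(ValidationError):
        Scenario("optimistic", 0.1)


# --- PAH4 summation --------------------------------------------------------

def test_pah4_is_the_sum_of_four():
    vals = dict(zip(ANALYTES, (0.1, 0.2, 0.3, 0.4)))
    assert pah4(vals) == pytest.approx(1.0)


def test_pah4_four_nondetects_pessimistic():
    sample = _full_sample("F1", "s0")
    vals = {r.analyte: substitute(r, PESSIMISTIC) for r in sample}
    assert pah4(vals) == pytest.approx(0.6)


def test_pah4_four_nondetects_optimistic():
    sample = _full_sample("F1", "s0")
    vals = {r.analyte: substitute(r, OPTIMISTIC) for r in sample}
    assert pah4(vals) == 0.0


def test_pah4_missing_analyte_rejected():
    vals = {AnalyteCode.BaA: 0.1, AnalyteCode.BaP: 0.2}
    with pytest.raises(ValidationError, match="missing"):
        pah4(vals)


# --- sample draws ----------------------------------------------------------

def test_single_sample_food_always_drawn():
    records = _full_sample("F1", "s0", 0.5)
    rng = np.random.default_rng(0)
    for _ in range(5):
        assert draw_concentration("F1", records, AnalyteCode.BaP, rng, OPTIMISTIC) == 0.5


def test_two_samples_drawn_uniformly():
    records = _full_sample("F1", "s0", 1.0) + _full_sample("F1", "s1", 2.0)
    rng = np.random.default_rng(1)
    n = 10_000
    hits = sum(
        draw_food_sample("F1", records, rng, OPTIMISTIC)[AnalyteCode.BaP] == 1.0
        for _ in range(n)
    )
    assert abs(hits / n - 0.5) <= 3 * math.sqrt(0.25 / n)


def test_drawn_values_lie_in_substituted_support():
    records = _full_sample("F1", "s0", 1.0) + _full_sample("F1", "s1")
    rng = np.random.default_rng(2)
    support = {1.0, 0.15}
    for _ in range(50):
        assert draw_food_sample("F1", records, rng, PESSIMISTIC)[AnalyteCode.Ch] in support


def test_draw_unknown_food_rejected():
    with pytest.raises(ValidationError):
        draw_food_sample("F9", _full_sample("F1", "s0", 1.0), np.random.default_rng(0), OPTIMISTIC)


# --- person-day exposure ---------------------------------------------------

def test_empty_diet_gives_zero_exposure():
    day = PersonDay("r1", 30, ())
    assert person_day_exposure(day, {}) == 0.0


def test_unit_conversion_hand_oracle():
    # 10 g/kg bw at 1.0 ug/kg -> 10 * 1.0 * 1e-6 = 1e-5 mg/kg bw/d
    day = PersonDay("r1", 30, (ConsumptionEvent("F1", 10.0),))
    assert person_day_exposure(day, {"F1": 1.0}) == pytest.approx(1.0e-5)


def test_exposure_linear_in_amounts():
    events = tuple(ConsumptionEvent(f, a) for f, a in [("F1", 2.0), ("F2", 3.0)])
    doubled = tuple(ConsumptionEvent(e.food_id, 2 * e.amount) for e in events)
    conc = {"F1": 0.4, "F2": 1.1}
    e1 = person_day_exposure(PersonDay("r", 30, events), conc)
    e2 = person_day_exposure(PersonDay("r", 30, doubled), conc)
    assert e2 == pytest.approx(2 * e1)


# --- simulate --------------------------------------------------------------

def test_single_iteration_hand_computed():
    records = _full_sample("F1", "s0", 0.25) + _full_sample("F2", "s0", 0.5)
    survey = [
        PersonDay("r1", 30, (ConsumptionEvent("F1", 2.0), ConsumptionEvent("F2", 4.0)))
    ]
    dist = simulate(survey, records, OPTIMISTIC, SimConfig(iterations=1, seed=0))
    # PAH4 per sample: 4 analytes x value; exposure = (2*1.0 + 4*2.0) * 1e-6
    assert dist.values[0] == pytest.approx((2 * 1.0 + 4 * 2.0) * 1e-6)


def test_all_nondetect_optimistic_is_all_zero():
    records = _full_sample("F1", "s0") + _full_sample("F1", "s1")
    survey = [PersonDay("r1", 30, (ConsumptionEvent("F1", 5.0),))]
    dist = simulate(survey, records, OPTIMISTIC, SimConfig(iterations=200, seed=1))
    assert np.all(dist.values == 0.0)


def test_empty_survey_rejected():
    with pytest.raises(ValidationError):
        simulate([], _full_sample("F1", "s0", 1.0), OPTIMISTIC, SimConfig(iterations=1))


def test_simulation_deterministic_in_seed(small_dataset):
    _, records, survey = small_dataset
    cfg = SimConfig(iterations=2_000, seed=11)
    a = simulate(survey, records, PESSIMISTIC, cfg)
    b = simulate(survey, records, PESSIMISTIC, cfg)
    assert np.array_equal(a.values, b.values)


def test_pathwise_dominance_with_common_random_numbers(small_dataset):
    """Substitution is the only scenario difference, so under shared draws the
    pessimistic exposure dominates the optimistic at every iteration."""
    _, records, survey = small_dataset
    cfg = SimConfig(iterations=5_000, seed=13, common_random_numbers=True)
    opt = simulate(survey, records, OPTIMISTIC, cfg)
    pes = simulate(survey, records, PESSIMISTIC, cfg)
    assert np.all(pes.values >= opt.values)
    assert np.all(opt.values >= 0)


def test_median_dominance_without_common_random_numbers(small_dataset):
    _, records, survey = small_dataset
    cfg = SimConfig(iterations=20_000, seed=13, common_random_numbers=False)
    opt = simulate(survey, records, OPTIMISTIC, cfg)
    pes = simulate(survey, records, PESSIMISTIC, cfg)
    assert np.median(pes.values) >= np.median(opt.values)


def test_unmatched_survey_food_contributes_zero_with_warning(caplog):
    records = _full_sample("F1", "s0", 1.0)
    survey = [PersonDay("r1", 30, (ConsumptionEvent("F_missing", 100.0),))]
    with caplog.at_level("WARNING", logger="pahburden.exposure_sim"):
        dist = simulate(survey, records, PESSIMISTIC, SimConfig(iterations=50, seed=0))
    assert np.all(dist.values == 0.0)
    assert any("F_missing" in m for m in caplog.messages)


def test_degenerate_constant_input_recovered_exactly():
    """One sample per food, constant PAH4 c, fixed diet total a: every
    iteration equals a*c*1e-6 bit-exactly (dyadic inputs)."""
    c_analyte = 0.125  # PAH4 = 0.5 per sample
    records = _full_sample("F1", "s0", c_analyte) + _full_sample("F2", "s0", c_analyte)
    events = (ConsumptionEvent("F1", 2.0), ConsumptionEvent("F2", 4.0))
    survey = [PersonDay(f"r{i}", 30, events) for i in range(3)]
    dist = simulate(survey, records, OPTIMISTIC, SimConfig(iterations=1_000, seed=5))
    expected = (2.0 + 4.0) * 0.5 * UG_PER_KG_TO_MG
    assert np.all(dist.values == expected)
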