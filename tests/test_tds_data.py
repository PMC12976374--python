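"""Domain types, CSV round-trips, and total validation of TDS tables."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahburden.tds_data import (
    ANALYTES,
    AnalyteCode,
    Catalog,
    ConcentrationRecord,
    ConsumptionEvent,
    FoodItem,
    FormatError,
    PersonDay,
    ValidationError,
    read_catalog,
    read_concentration_table,
    read_survey,
    write_catalog,
    write_concentration_table,
    write_survey,
)

FOOD_IDS = ["F001", "F002", "F003"]


def _catalog():
    return Catalog(
        [FoodItem(fid, f"name {fid}", "fish and seafood", "boiled") for fid in FOOD_IDS]
    )


# --- record invariants -----------------------------------------------------

def test_detected_record_requires_value():
    with pytest.raises(ValidationError):
        ConcentrationRecord("F001", "s0", AnalyteCode.BaP, True, None, 0.15)


def test_nondetect_record_must_not_carry_value():
    with pytest.raises(ValidationError):
        ConcentrationRecord("F001", "s0", AnalyteCode.BaP, False, 0.2, 0.15)


@pytest.mark.parametrize("lod", [0.0, -0.1])
def test_lod_must_be_positive(lod):
    with pytest.raises(ValidationError):
        ConcentrationRecord("F001", "s0", AnalyteCode.BaP, False, None, lod)


def test_negative_amount_rejected():
    with pytest.raises(ValidationError):
        ConsumptionEvent("F001", -1.0)


def test_zero_amount_permitted():
    assert ConsumptionEvent("F001", 0.0).amount == 0.0


def test_underage_respondent_rejected():
    with pytest.raises(ValidationError):
        PersonDay("r1", 17, (ConsumptionEvent("F001", 1.0),))


def test_catalog_rejects_duplicate_ids():
    item = FoodItem("F001", "x", "fruits", "raw")
    with pytest.raises(ValidationError):
        Catalog([item, item])


# --- concentration table I/O ----------------------------------------------

def test_concentration_four_rows_one_sample(tmp_path):
    path = tmp_path / "conc.csv"
    path.write_text(
        "food_id,sample_id,analyte,detected,value,lod\n"
        "F001,s0,BaA,true,0.5,0.15\n"
        "F001,s0,BaP,true,1.5,0.15\n"
        "F001,s0,BbF,false,,0.15\n"
        "F001,s0,Ch,false,,0.15\n"
    )
    records = read_concentration_table(path, _catalog())
    assert len(records) == 4
    assert {r.analyte for r in records} == set(ANALYTES)
    nd = [r for r in records if not r.detected]
    assert all(r.value is None and r.lod == 0.15 for r in nd)


def test_unknown_analyte_rejected_with_row_number(tmp_path):
    path = tmp_path / "conc.csv"
    path.write_text(
        "food_id,sample_id,analyte,detected,value,lod\nF001,s0,PYR,true,0.5,0.15\n"
    )
    with pytest.raises(ValidationError, match=r"row 2.*analyte"):
        read_concentration_table(path, _catalog())


def test_detected_row_with_empty_value_rejected(tmp_path):
    path = tmp_path / "conc.csv"
    path.write_text(
        "food_id,sample_id,analyte,detected,value,lod\nF001,s0,BaP,true,,0.15\n"
    )
    with pytest.raises(ValidationError, match=r"row 2.*value"):
        read_concentration_table(path, _catalog())


def test_unknown_food_rejected_against_catalog(tmp_path):
    path = tmp_path / "conc.csv"
    path.write_text(
        "food_id,sample_id,analyte,detected,value,lod\nF999,s0,BaP,true,0.5,0.15\n"
    )
    with pytest.raises(ValidationError, match=r"row 2.*food_id"):
        read_concentration_table(path, _catalog())


def test_missing_column_is_format_error(tmp_path):
    path = tmp_path / "conc.csv"
    path.write_text("food_id,sample_id,analyte,detected,value\nF001,s0,BaP,true,0.5\n")
    with pytest.raises(FormatError, match="lod"):
        read_concentration_table(path, _catalog())


@st.composite
def concentration_records(draw):
    fid = draw(st.sampled_from(FOOD_IDS))
    sid = draw(st.sampled_from(["s0", "s1", "s2"]))
    analyte = draw(st.sampled_from(list(ANALYTES)))
    detected = draw(st.booleans())
    value = (
        draw(st.floats(0, 100, allow_nan=False, allow_infinity=False))
        if detected
        else None
    )
    lod = draw(st.floats(0.01, 1.0, allow_nan=False))
    return ConcentrationRecord(fid, sid, analyte, detected, value, lod)


@given(st.lists(concentration_records(), min_size=1, max_size=30))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_concentration_roundtrip_is_identity(tmp_path_factory, records):
    """Write-then-read reproduces every record field-for-field."""
    path = tmp_path_factory.mktemp("rt") / "conc.csv"
    write_concentration_table(records, path)
    assert read_concentration_table(path, _catalog()) == records


# --- survey I/O ------------------------------------------------------------

def test_survey_grouping(tmp_path):
    path = tmp_path / "survey.csv"
    rows = ["respondent_id,age,food_id,amount"]
    for rid, age in (("r1", 25), ("r2", 60)):
        for fid in FOOD_IDS:
            rows.append(f"{rid},{age},{fid},1.5")
    path.write_text("\n".join(rows) + "\n")
    days = read_survey(path, _catalog())
    assert [d.respondent_id for d in days] == ["r1", "r2"]
    assert all(len(d.events) == 3 for d in days)


def test_survey_zero_amount_rows_retained(tmp_path):
    path = tmp_path / "survey.csv"
    path.write_text("respondent_id,age,food_id,amount\nr1,30,F001,0.0\n")
    (day,) = read_survey(path, _catalog())
    assert day.events[0].amount == 0.0
    assert day.total_amount == 0.0


@pytest.mark.parametrize(
    "row,field",
    [("r1,17,F001,1.0", "age"), ("r1,30,F001,-2.0", "amount")],
)
def test_survey_validation_names_row_and_field(tmp_path, row, field):
    path = tmp_path / "survey.csv"
    path.write_text(f"respondent_id,age,food_id,amount\n{row}\n")
    with pytest.raises(ValidationError, match=rf"row 2.*{field}"):
        read_survey(path, _catalog())


@given(
    st.lists(
        st.tuples(
            st.integers(18, 90),
            st.lists(
                st.tuples(
                    st.sampled_from(FOOD_IDS),
                    st.floats(0, 50, allow_nan=False, allow_infinity=False),
                ),
                min_size=1,
                max_size=5,
            ),
        ),
        min_size=1,
        max_size=10,
    )
)
@settings(max_examples=30, derandomize=True, deadline=None)
def test_survey_roundtrip_is_identity(tmp_path_factory, spec_rows):
    days = [
        PersonDay(f"r{i}", age, tuple(ConsumptionEvent(f, a) for f, a in evs))
        for i, (age, evs) in enumerate(spec_rows)
    ]
    path = tmp_path_factory.mktemp("rt") / "survey.csv"
    write_survey(days, path)
    assert read_survey(path, _catalog()) == days


def test_catalog_roundtrip(tmp_path):
    catalog = _catalog()
    path = tmp_path / "catalog.csv"
    write_catalog(catalog, path)
    assert read_catalog(path) == catalog
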