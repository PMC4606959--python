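"""ICD classification and multiple-cause tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chdprev.icd import (DEFAULT_CODE_MAPS, DeathRecord, ICDCodeMap, classify,
                         normalize_code, rates_from_counts, records_from_frame,
                         tabulate)


@pytest.mark.parametrize("code,version,expected", [
    ("Q21.1", 10, True),       # ventricular septal defect: cardiac anomaly
    ("Q26.9", 10, True),       # great-vein anomaly, inside Q20-Q26
    ("Q27.0", 10, False),      # peripheral vascular anomaly, excluded
    ("I25.1", 10, False),      # ischaemic heart disease, outside all ranges
    ("745.4", 9, True),
    ("746.6", 9, True),        # interior of 745.0-747.49 despite short code
    ("747.49", 9, True),       # inclusive upper edge
    ("747.5", 9, False),       # peripheral range excluded
    ("390", 9, False),
    ("746.0", 8, True),
])
def test_classify_default_maps(code, version, expected):
    assert classify(code, version) is expected


def test_classify_unknown_version_is_configuration_error():
    with pytest.raises(KeyError):
        classify("Q21", 11)


def test_normalize_strips_dots_and_case():
    assert normalize_code(" q21.1 ") == "Q211"
    assert normalize_code(normalize_code("745.60")) == normalize_code("745.60")


def test_code_map_rejects_inverted_range():
    with pytest.raises(ValueError):
        ICDCodeMap(10, (("Q26", "Q20"),))


def _fixture_records():
    """10 condition deaths: 7 with CHD underlying, 3 with mention only."""
    recs = []
    for i in range(7):
        recs.append(DeathRecord(age=0, sex="male", year=2005, icd_version=10,
                                underlying_cause="Q21.0",
                                mentioned_causes=["Q21.0", "P22.0"]))
    for i in range(3):
        recs.append(DeathRecord(age=0, sex="male", year=2005, icd_version=10,
                                underlying_cause="P22.0",
                                mentioned_causes=["P22.0", "Q23.4"]))
    return recs


def test_tabulate_fixture_hand_count():
    out = tabulate(_fixture_records())
    row = out.iloc[0]
    assert (row["underlying"], row["any_mention"]) == (7, 10)
    from chdprev.summaries import share
    assert share(row["underlying"], row["any_mention"]) == 70.0


def test_mention_only_record_counts_in_any_mention_not_underlying():
    rec = DeathRecord(age=30, sex="female", year=1999, icd_version=10,
                      underlying_cause="I50.9", mentioned_causes=["I50.9", "Q20.3"])
    out = tabulate([rec])
    assert out.iloc[0]["any_mention"] == 1 and out.iloc[0]["underlying"] == 0


def test_empty_record_list_gives_empty_table():
    out = tabulate([])
    assert out.empty


def test_records_with_empty_causes_or_missing_age_dropped_with_warning(caplog):
    recs = _fixture_records()
    recs.append(DeathRecord(age=1, sex="male", year=2005, icd_version=10,
                            underlying_cause="", mentioned_causes=[]))
    recs.append(DeathRecord(age=None, sex="male", year=2005, icd_version=10,
                            underlying_cause="Q21.0", mentioned_causes=["Q21.0"]))
    with caplog.at_level("WARNING", logger="chdprev.icd"):
        out = tabulate(recs)
    assert out["any_mention"].sum() == 10
    assert "empty cause list" in caplog.text and "missing age or sex" in caplog.text


def test_underlying_cause_added_to_mentions_on_load():
    df = pd.DataFrame({"age": [4], "sex": ["female"], "year": [2001],
                       "icd_version": [10], "underlying_cause": ["Q24.9"],
                       "cause_2": [None], "cause_3": ["I50.9"]})
    rec = records_from_frame(df)[0]
    assert "Q249" in rec.mentioned_causes and "I509" in rec.mentioned_causes


@given(st.lists(
    st.tuples(st.integers(0, 90), st.sampled_from(["male", "female"]),
              st.integers(1990, 2010),
              st.sampled_from(["Q20", "Q24.5", "Q27.1", "I21.0", "P29.3"]),
              st.sampled_from(["Q21.1", "I50.9", "Q28.2", "J18.9"])),
    max_size=40))
def test_underlying_never_exceeds_any_mention(entries):
    recs = [DeathRecord(age=a, sex=s, year=y, icd_version=10,
                        underlying_cause=u, mentioned_causes=[u, m])
            for a, s, y, u, m in entries]
    out = tabulate(recs)
    if not out.empty:
        assert (out["underlying"] <= out["any_mention"]).all()
        # aggregation consistency: cells sum to the classified record count
        n_classified = sum(
            any(classify(code, 10) for code in r.mentioned_causes) for r in recs)
        assert out["any_mention"].sum() == n_classified


def test_rates_from_counts_scale_and_zero_handling():
    counts = pd.DataFrame({"age": [30, 31], "sex": ["male"] * 2,
                           "year": [2000] * 2, "deaths": [53, 0]})
    pop = pd.DataFrame({"age": [30, 31], "sex": ["male"] * 2,
                        "year": [2000] * 2, "population": [100_000] * 2})
    obs = rates_from_counts(counts, pop)
    assert obs.loc[0, "value"] == pytest.approx(53e-5)   # 53 per 100,000 PY
    assert obs.loc[1, "value"] == 0.0                    # zero retained
    assert (obs["effective_n"] == 100_000).all()
    assert (obs["measure"] == "csmr").all()


def test_rates_from_counts_missing_or_zero_population_is_hard_error():
    counts = pd.DataFrame({"age": [30], "sex": ["male"], "year": [2000],
                           "deaths": [5]})
    with pytest.raises(ValueError, match="age=30"):
        rates_from_counts(counts, counts.assign(population=0))
    other = pd.DataFrame({"age": [31], "sex": ["male"], "year": [2000],
                          "population": [1000]})
    with pytest.raises(ValueError, match="age=30"):
        rates_from_counts(counts, other)
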