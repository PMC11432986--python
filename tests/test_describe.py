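"""Descriptive logic: most-serious resolution, outcome classes, tables."""

import pytest

from sedror import (
    AdverseEvent,
    Dataset,
    OutcomeCode,
    SeriousnessCriterion as SC,
    Sex,
    classify_outcome,
    most_serious,
    pct,
    round_half_up,
    summarize,
)
from sedror.describe import OutcomeClass, atc_class, cell
from sedror.selection import primary_term_set
from tests.test_selection import _report


@pytest.mark.parametrize(
    "criteria, expected",
    [
        ({SC.HOSPITALIZATION, SC.DEATH}, SC.DEATH),
        ({SC.OTHER_MEDICALLY_IMPORTANT}, SC.OTHER_MEDICALLY_IMPORTANT),
        ({SC.LIFE_THREATENING, SC.HOSPITALIZATION}, SC.LIFE_THREATENING),
        ({SC.NOT_SERIOUS}, SC.NOT_SERIOUS),
        ({SC.CONGENITAL_ANOMALY, SC.OTHER_MEDICALLY_IMPORTANT, SC.DISABLING},
         SC.DISABLING),
    ],
)
def test_most_serious_order(criteria, expected):
    assert most_serious(criteria) is expected


def test_most_serious_rejects_empty():
    with pytest.raises(ValueError):
        most_serious(set())


@pytest.mark.parametrize(
    "outcome, cls",
    [
        (OutcomeCode.RECOVERED, OutcomeClass.FAVOURABLE),
        (OutcomeCode.RECOVERING, OutcomeClass.FAVOURABLE),
        (OutcomeCode.RECOVERED_WITH_SEQUELAE, OutcomeClass.UNFAVOURABLE),
        (OutcomeCode.NOT_RECOVERED, OutcomeClass.UNFAVOURABLE),
        (OutcomeCode.FATAL, OutcomeClass.UNFAVOURABLE),
        (OutcomeCode.UNKNOWN, OutcomeClass.UNKNOWN),
    ],
)
def test_classify_outcome(outcome, cls):
    assert classify_outcome(outcome) is cls


def test_percent_rounding_is_half_up():
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(67.85, 1) == 67.9
    assert pct(361, 364) == 99.2
    assert pct(1, 3) == 33.3
    assert pct(0, 0) == 0.0


@pytest.mark.parametrize(
    "atc, cls",
    [("N01AH01", "Anaesthetics"), ("N02BE01", "Analgesics"),
     ("N05AD01", "Psycholeptics"), ("C03CA01", "Other"), (None, "Unclassified")],
)
def test_atc_level2_classes(atc, cls):
    assert atc_class(atc) == cls


def test_summarize_single_female_report():
    ds = Dataset([_report("A", ["dexmedetomidine"], sex=Sex.FEMALE)])
    bundle = summarize(ds, primary_term_set())
    assert cell(bundle.demographics, "Sex: Female", "DEX") == (1, 100.0)
    assert cell(bundle.demographics, "Sex: Female", "Overall") == (1, 100.0)


def test_summarize_fatal_share():
    # 4 of 10 target events fatal -> Fatal 40.0%
    reports = [_report(f"R{i}", ["propofol"]) for i in range(6)]
    for i in range(4):
        r = _report(f"F{i}", ["propofol"])
        ev = r.events[0]
        r.events[0] = AdverseEvent(ev.pt, ev.criteria, OutcomeCode.FATAL)
        reports.append(r)
    bundle = summarize(Dataset(reports), primary_term_set())
    assert cell(bundle.outcome, "Fatal", "Overall") == (4, 40.0)


def test_block_counts_sum_to_denominators(fixture_ds):
    bundle = summarize(fixture_ds, primary_term_set())
    denoms = bundle.denominators.set_index("group")
    for block, denom_col in [
        ("seriousness", "target_events"),
        ("outcome", "target_events"),
        ("soc", "other_events"),
    ]:
        table = getattr(bundle, block)
        for grp in denoms.index:
            got = int(table[table["group"] == grp]["count"].sum())
            assert got == int(denoms.loc[grp, denom_col]), (block, grp)
    # demographics: each categorical sub-block sums to the report denominator
    demo = bundle.demographics
    for prefix in ("Age:", "Sex:", "Source:", "Country:"):
        sub = demo[demo["row"].str.startswith(prefix)]
        total = int(sub[sub["group"] == "Overall"]["count"].sum())
        assert total == len(fixture_ds)


def test_overall_equals_sum_across_groups(fixture_ds):
    bundle = summarize(fixture_ds, primary_term_set())
    demo = bundle.demographics
    for row in demo["row"].unique():
        sub = demo[demo["row"] == row]
        overall = int(sub[sub["group"] == "Overall"]["count"].iloc[0])
        groups = int(sub[sub["group"] != "Overall"]["count"].sum())
        assert overall == groups


def test_fixture_group_seriousness_leads(fixture_ds):
    """Per-group leading seriousness criteria match the published series."""
    bundle = summarize(fixture_ds, primary_term_set())
    assert cell(bundle.seriousness, "Caused/Prolonged Hospitalization", "PRO") == (82, 29.3)
    assert cell(bundle.seriousness, "Life Threatening", "DEX") == (8, 57.1)
    assert cell(bundle.seriousness, "Results in Death", "MID") == (12, 32.4)
    assert cell(bundle.seriousness, "Not Serious", "Overall") == (3, 0.8)


def test_fixture_soc_blocks_match_event_counts(fixture_ds):
    bundle = summarize(fixture_ds, primary_term_set())
    assert cell(bundle.soc, "Metabolism and nutrition disorders", "PRO") == (231, 22.1)
    assert cell(bundle.soc, "Nervous system disorders", "MID") == (38, 16.3)
    assert cell(bundle.soc, "General disorders and administration site conditions", "DEX") == (10, 19.2)
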