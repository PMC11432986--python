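"""Reporting odds ratio: oracle equivalence, Woolf CI properties, gating."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from sedror import ContingencyTable, count_events, ror, run_plan
from sedror.selection import ExposureGroup, primary_term_set
from sedror.simulate import GroupSpec, SimConfig, simulate

cells = st.integers(min_value=3, max_value=500)


def test_symmetric_table_is_null():
    est = ror(ContingencyTable(10, 10, 10, 10))
    assert est.ror == 1.0
    assert est.ci_low < 1.0 < est.ci_high
    assert not est.significant


def test_min_events_gate():
    est = ror(ContingencyTable(2, 50, 40, 500))
    assert est.gated
    assert est.ror is None and est.p_value is None
    assert not est.significant
    # gate applies to the comparator side too
    assert ror(ContingencyTable(40, 500, 2, 50)).gated


def test_hand_worked_woolf_example():
    """a=9,b=9,c=21,d=86: cross-product 4.095 and Woolf CI (1.45, 11.58)."""
    est = ror(ContingencyTable(9, 9, 21, 86))
    assert est.ror == pytest.approx(9 * 86 / (9 * 21), rel=1e-12)
    se = math.sqrt(1 / 9 + 1 / 9 + 1 / 21 + 1 / 86)
    assert est.ci_low == pytest.approx(math.exp(math.log(est.ror) - 1.96 * se))
    assert est.ci_high == pytest.approx(math.exp(math.log(est.ror) + 1.96 * se))
    assert round(est.ror, 2) == 4.10
    assert (round(est.ci_low, 2), round(est.ci_high, 2)) == (1.45, 11.58)
    assert est.significant and est.p_value < 0.05


def test_oracle_equivalence_small_tables():
    """ROR equals the brute-force cross-product a*d/(b*c) on all {1..6}^4."""
    for a, b, c, d in itertools.product(range(1, 7), repeat=4):
        est = ror(ContingencyTable(a, b, c, d), min_events=1)
        assert est.ror == pytest.approx(a * d / (b * c), rel=1e-12)


def test_statsmodels_cross_check():
    """Independent oracle: statsmodels Table2x2 odds ratio and log CI."""
    sm = pytest.importorskip("statsmodels.api")
    from scipy.stats import norm

    z_exact = float(norm.ppf(0.975))  # statsmodels uses the exact quantile
    for a, b, c, d in [(9, 9, 21, 86), (14, 52, 280, 1046), (5, 100, 7, 90)]:
        est = ror(ContingencyTable(a, b, c, d), z=z_exact)
        t22 = sm.stats.Table2x2([[a, b], [c, d]])
        assert est.ror == pytest.approx(t22.oddsratio, rel=1e-10)
        lo, hi = t22.oddsratio_confint(alpha=0.05)
        assert est.ci_low == pytest.approx(lo, rel=1e-6)
        assert est.ci_high == pytest.approx(hi, rel=1e-6)


def test_zero_cell_haldane_correction():
    est = ror(ContingencyTable(5, 0, 7, 90), min_events=3)
    assert est.corrected
    expected = (5.5 * 90.5) / (0.5 * 7.5)
    assert est.ror == pytest.approx(expected)
    assert est.ci_low <= est.ror <= est.ci_high


@given(a=cells, b=cells, c=cells, d=cells)
def test_reciprocity(a, b, c, d):
    t = ContingencyTable(a, b, c, d)
    fwd, rev = ror(t), ror(t.transposed())
    assert fwd.ror * rev.ror == pytest.approx(1.0, rel=1e-12)
    assert fwd.ci_low == pytest.approx(1.0 / rev.ci_high, rel=1e-12)
    assert fwd.ci_high == pytest.approx(1.0 / rev.ci_low, rel=1e-12)


@given(a=cells, b=cells, c=cells, d=cells)
def test_log_symmetry_of_woolf_ci(a, b, c, d):
    est = ror(ContingencyTable(a, b, c, d))
    assert math.sqrt(est.ci_low * est.ci_high) == pytest.approx(est.ror, rel=1e-9)


@given(a=st.integers(3, 100), b=cells, c=cells, d=cells)
def test_monotone_in_a(a, b, c, d):
    lo = ror(ContingencyTable(a, b, c, d)).ror
    hi = ror(ContingencyTable(a + 1, b, c, d)).ror
    assert hi > lo


@given(a=cells, b=cells, c=cells, d=cells)
def test_significance_iff_ci_excludes_one(a, b, c, d):
    est = ror(ContingencyTable(a, b, c, d))
    assert est.significant == (est.ci_low > 1.0 or est.ci_high < 1.0)
    # Wald p agrees with the CI decision at matching alpha
    assert (est.p_value <= 0.05) == est.significant


def test_count_events_on_constructed_group():
    from tests.test_selection import _report

    from sedror import Dataset

    reports = []
    for i in range(10):
        r = _report(f"R{i}", ["dexmedetomidine"],
                    pts=("Rhabdomyolysis", "Nausea", "Hypotension"))
        reports.append(r)
    a, b = count_events(Dataset(reports), ExposureGroup.DEX, primary_term_set())
    assert (a, b) == (10, 20)
    a, b = count_events(Dataset(reports), ExposureGroup.MID, primary_term_set())
    assert (a, b) == (0, 0)


def test_count_events_matches_ledger():
    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 400, 0.1, 2.0),
                GroupSpec(ExposureGroup.PRO, 600, 0.05, 2.0)],
        seed=11,
    )
    ds, ledger = simulate(cfg)
    ts = primary_term_set()
    for g in (ExposureGroup.DEX, ExposureGroup.PRO):
        a, b = count_events(ds, g, ts)
        assert (a, b) == (ledger.realized_a[g], ledger.realized_b[g])


def test_run_plan_reverse_is_reciprocal():
    from sedror.ror import PlanEntry

    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 800, 0.1, 2.0),
                GroupSpec(ExposureGroup.PRO, 800, 0.1, 2.0)],
        seed=5,
    )
    ds, _ = simulate(cfg)
    plan = [
        PlanEntry("fwd", "primary", ExposureGroup.DEX, ExposureGroup.PRO),
        PlanEntry("rev", "primary", ExposureGroup.PRO, ExposureGroup.DEX),
    ]
    res = run_plan(ds, plan, {"primary": primary_term_set()})
    fwd, rev = res.iloc[0], res.iloc[1]
    assert fwd["ror"] * rev["ror"] == pytest.approx(1.0, rel=1e-12)
    assert fwd["ci_low"] == pytest.approx(1.0 / rev["ci_high"], rel=1e-12)
    # null simulation: symmetric groups give ROR ~ 1 inside its own CI
    assert fwd["ci_low"] < 1.0 < fwd["ci_high"]


def test_run_plan_self_comparison_rejected():
    from sedror.ror import PlanEntry

    with pytest.raises(ValueError):
        PlanEntry("bad", "primary", ExposureGroup.DEX, ExposureGroup.DEX)


def test_sex_subgroup_restricts_to_stated_sex(fixture_ds):
    from sedror.ror import PlanEntry

    res = run_plan(
        fixture_ds,
        [PlanEntry("PRO: male vs female", "primary", ExposureGroup.PRO,
                   stratum="male vs female")],
        {"primary": primary_term_set()},
    )
    rec = res.iloc[0]
    # fixture PRO: 191 male and 77 female case reports, one target event each;
    # sex-unspecified reports are excluded entirely
    assert rec["a"] == 191 and rec["c"] == 77
    assert rec["a"] + rec["c"] < 280 + 1046


def test_default_plan_covers_both_term_sets_and_sex_subgroups():
    from sedror.ror import default_plan

    plan = default_plan()
    labels = [(e.label, e.term_set) for e in plan]
    assert ("DEX vs PRO", "primary") in labels
    assert ("DEX vs PRO", "indicative") in labels
    assert ("MID vs PRO", "primary") in labels
    assert ("MID/PRO vs DEX/MID/PRO", "indicative") in labels
    assert ("PRO: male vs female", "primary") in labels
    assert ("PRO: male vs female", "indicative") in labels
    assert len(plan) == 2 * (6 + 7) + 2 * 3
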