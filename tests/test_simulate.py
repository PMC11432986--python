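"""Generator: determinism, analytic ledger, duplicates, fixture margins."""

import math

import pytest

from sedror import (
    Categorical,
    GroupSpec,
    SimConfig,
    fixture_from_tables,
    inject_duplicates,
    simulate,
)
from sedror.selection import ExposureGroup, GROUP_ORDER, assign_group, group_counts
from sedror.simulate import (
    FIXTURE_GROUP_N,
    _SOC_MARGINS,
)
from sedror.vocab import TARGET_PT


def test_same_seed_bit_identical():
    cfg = SimConfig(groups=[GroupSpec(ExposureGroup.MID, 200, 0.1, 2.0)], seed=9)
    ds1, led1 = simulate(cfg)
    ds2, led2 = simulate(cfg)
    assert ds1.reports == ds2.reports
    assert led1.realized_a == led2.realized_a


def test_different_seed_differs():
    g = [GroupSpec(ExposureGroup.MID, 200, 0.1, 2.0)]
    ds1, _ = simulate(SimConfig(groups=g, seed=1))
    ds2, _ = simulate(SimConfig(groups=g, seed=2))
    assert ds1.reports != ds2.reports


def test_degenerate_probabilities():
    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 10, 1.0, 0.0)],
        co_suspect_rate=0.0, concomitant_rate=0.0, seed=0,
    )
    ds, ledger = simulate(cfg)
    assert len(ds) == 10
    assert all(len(r.events) == 1 for r in ds.reports)
    assert all(r.events[0].pt.key == TARGET_PT.key for r in ds.reports)
    assert ledger.realized_a[ExposureGroup.DEX] == 10
    assert ledger.realized_b[ExposureGroup.DEX] == 0


def test_identical_groups_have_true_ror_one():
    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 50, 0.2, 1.0),
                GroupSpec(ExposureGroup.PRO, 50, 0.2, 1.0)],
        seed=0,
    )
    _, ledger = simulate(cfg)
    assert ledger.true_ror(ExposureGroup.DEX, ExposureGroup.PRO) == pytest.approx(1.0)


def test_true_ror_reciprocity():
    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 50, 0.15, 3.0),
                GroupSpec(ExposureGroup.MID, 80, 0.05, 2.0)],
        seed=0,
    )
    _, ledger = simulate(cfg)
    fwd = ledger.true_ror(ExposureGroup.DEX, ExposureGroup.MID)
    rev = ledger.true_ror(ExposureGroup.MID, ExposureGroup.DEX)
    assert fwd * rev == pytest.approx(1.0, rel=1e-12)


def test_true_ror_closed_form():
    """Ledger odds match the direct binomial/Poisson expectation."""
    gs1 = GroupSpec(ExposureGroup.DEX, 100, 0.15, 3.0)
    gs2 = GroupSpec(ExposureGroup.PRO, 100, 0.05, 3.0)
    cfg = SimConfig(groups=[gs1, gs2], seed=0)
    _, ledger = simulate(cfg)
    want = (0.15 / ((1 - 0.15) + 3.0)) / (0.05 / ((1 - 0.05) + 3.0))
    assert ledger.true_ror(ExposureGroup.DEX, ExposureGroup.PRO) == pytest.approx(want)


def test_group_sizes_exact_and_law_of_large_numbers():
    """Realized event-level ROR lands within 3 MC standard errors of truth."""
    cfg = SimConfig(
        groups=[GroupSpec(ExposureGroup.DEX, 5000, 0.15, 3.0),
                GroupSpec(ExposureGroup.PRO, 5000, 0.05, 3.0)],
        seed=7,
    )
    ds, ledger = simulate(cfg)
    counts = group_counts(ds)
    assert counts[ExposureGroup.DEX] == 5000
    assert counts[ExposureGroup.PRO] == 5000
    realized = ledger.realized_ror(ExposureGroup.DEX, ExposureGroup.PRO)
    truth = ledger.true_ror(ExposureGroup.DEX, ExposureGroup.PRO)
    se = math.sqrt(
        sum(
            1.0 / ledger.__dict__[k][g]
            for k in ("realized_a", "realized_b")
            for g in (ExposureGroup.DEX, ExposureGroup.PRO)
        )
    )
    assert abs(math.log(realized) - math.log(truth)) <= 3 * se


def test_empty_groups_fatal():
    with pytest.raises(ValueError):
        SimConfig(groups=[])


def test_vocab_must_exclude_target():
    with pytest.raises(ValueError):
        SimConfig(vocab=[TARGET_PT])


def test_categorical_must_sum_to_one():
    with pytest.raises(ValueError):
        Categorical(("a", "b"), (0.5, 0.4))


def test_inject_duplicates_rate_zero_is_identity(small_sim):
    ds, _ = small_sim
    assert inject_duplicates(ds, 0.0, seed=1) is ds


def test_inject_duplicates_full_rate():
    cfg = SimConfig(groups=[GroupSpec(ExposureGroup.PRO, 3, 0.5, 1.0)], seed=2)
    ds, _ = simulate(cfg)
    noisy = inject_duplicates(ds, 1.0, seed=1)
    assert len(noisy) == 6
    ids = [r.case_id for r in noisy.reports]
    assert len(set(ids)) == 6  # fresh case ids


# --- fixture margins ---

def test_fixture_group_counts():
    ds = fixture_from_tables()
    counts = group_counts(ds)
    assert counts[ExposureGroup.DEX] == 14
    assert counts[ExposureGroup.MID_PRO] == 21
    assert sum(counts.values()) == 364 == sum(FIXTURE_GROUP_N.values())


def test_fixture_is_deterministic():
    a, b = fixture_from_tables(), fixture_from_tables()
    assert a.reports == b.reports


def test_fixture_event_totals_match_soc_margins():
    ds = fixture_from_tables()
    per_group_other = {g: 0 for g in GROUP_ORDER}
    for r in ds.reports:
        g = assign_group(r)
        per_group_other[g] += sum(
            1 for ev in r.events if ev.pt.key != TARGET_PT.key
        )
    expected = {
        g: sum(counts[i] for counts in _SOC_MARGINS.values())
        for i, g in enumerate(GROUP_ORDER)
    }
    assert per_group_other == expected
    assert sum(expected.values()) == 1446
    assert sum(len(r.events) for r in ds.reports) == 1810


def test_fixture_each_report_has_one_target_event():
    ds = fixture_from_tables()
    for r in ds.reports:
        n_target = sum(1 for ev in r.events if ev.pt.key == TARGET_PT.key)
        assert n_target == 1
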