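"""Reporting odds ratio (ROR) with Woolf confidence intervals.

The ROR is the classic case/non-case disproportionality statistic: for a
2x2 event-count table

    ==============  ============  ============
                    target event  other events
    ==============  ============  ============
    drug/group       a             b
    comparator       c             d
    ==============  ============  ============

ROR = (a/c)/(b/d) = ad/bc, with the Woolf (log-normal) 95% CI
exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).

Counting unit is *events over the full retained dataset*: a and c count
target-term events for the drug of interest and the comparator, b and d
count every other event reported with them.  A minimum-events gate (default
3 target events on each side) suppresses estimation on tiny counts, and a
Haldane-Anscombe +0.5 correction handles residual zero cells.  Significance
is CI-excludes-1, equivalent to a two-sided Wald test on log ROR at
alpha = 0.05 for z = 1.96; the Wald p-value is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm

from .model import Dataset, Sex
from .selection import ExposureGroup, TermSet, assign_group


@dataclass(frozen=True)
class ContingencyTable:
    """Event counts for one comparison (see module docstring)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    def transposed(self) -> "ContingencyTable":
        """Swap drug of interest and comparator."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass
class RorEstimate:
    """Point estimate, Woolf CI and flags for one comparison."""

    table: ContingencyTable
    ror: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    z: float = 1.96
    gated: bool = False
    corrected: bool = False

    @property
    def significant(self) -> bool:
        if self.gated or self.ror is None:
            return False
        return self.ci_low > 1.0 or self.ci_high < 1.0


def ror(t: ContingencyTable, min_events: int = 3, z: float = 1.96) -> RorEstimate:
    """Estimate the ROR for one 2x2 event table.

    Reports with fewer than ``min_events`` target events on either side are
    gated (no estimate); zero cells that survive the gate get the
    Haldane-Anscombe +0.5 on all four cells, flagged via ``corrected``.
    """
    if t.a < min_events or t.c < min_events:
        return RorEstimate(t, None, None, None, None, z=z, gated=True)

    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True

    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(estimate)
    ci_low = math.exp(log_ror - z * se)
    ci_high = math.exp(log_ror + z * se)
    p_value = 2.0 * float(norm.sf(abs(log_ror) / se))
    return RorEstimate(t, estimate, ci_low, ci_high, p_value, z=z, corrected=corrected)


def count_events(ds: Dataset, g: ExposureGroup, ts: TermSet) -> tuple[int, int]:
    """(a, b): target vs other event counts over all reports of group ``g``.

    The dataset should be the FULL deduplicated extract, not just the case
    reports: b counts every non-target event reported with the group.
    """
    if not isinstance(g, ExposureGroup):
        raise ValueError(f"unknown group: {g!r}")
    a = b = 0
    for r in ds.reports:
        if assign_group(r) is not g:
            continue
        for ev in r.events:
            if ev.pt.name in ts:
                a += 1
            else:
                b += 1
    return a, b


@dataclass(frozen=True)
class PlanEntry:
    """One planned comparison.

    ``stratum`` is None for group-vs-group comparisons; for the sex
    subgroup analysis it is "male vs female" and the contrast is male
    (a, b) vs female (c, d) within ``group`` (sex-unspecified excluded).
    """

    label: str
    term_set: str  # key into the term-set mapping handed to run_plan
    group: ExposureGroup
    comparator: ExposureGroup | None = None
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.stratum is None and self.comparator is self.group:
            raise ValueError("comparison pairs a group with itself")


#: Figure-style panel order of comparators for the lead drug.
PRIMARY_COMPARATORS = [
    ExposureGroup.MID,
    ExposureGroup.PRO,
    ExposureGroup.DEX_MID,
    ExposureGroup.DEX_PRO,
    ExposureGroup.MID_PRO,
    ExposureGroup.DEX_MID_PRO,
]

_SUBANALYSIS_PAIRS = [
    (ExposureGroup.MID, ExposureGroup.PRO),
    (ExposureGroup.DEX_MID, ExposureGroup.DEX_PRO),
    (ExposureGroup.DEX_MID, ExposureGroup.MID_PRO),
    (ExposureGroup.DEX_MID, ExposureGroup.DEX_MID_PRO),
    (ExposureGroup.DEX_PRO, ExposureGroup.MID_PRO),
    (ExposureGroup.DEX_PRO, ExposureGroup.DEX_MID_PRO),
    (ExposureGroup.MID_PRO, ExposureGroup.DEX_MID_PRO),
]

_SEX_SUBGROUPS = [ExposureGroup.DEX, ExposureGroup.MID, ExposureGroup.PRO]


def default_plan(term_sets: tuple[str, str] = ("primary", "indicative")) -> list[PlanEntry]:
    """The full comparison plan: lead-drug contrasts, sub-analysis pairs,
    both repeated under each term set, then male-vs-female subgroups."""
    plan: list[PlanEntry] = []
    for ts in term_sets:
        for comp in PRIMARY_COMPARATORS:
            plan.append(
                PlanEntry(f"DEX vs {comp.value}", ts, ExposureGroup.DEX, comp)
            )
        for g1, g2 in _SUBANALYSIS_PAIRS:
            plan.append(PlanEntry(f"{g1.value} vs {g2.value}", ts, g1, g2))
    for ts in term_sets:
        for g in _SEX_SUBGROUPS:
            plan.append(
                PlanEntry(
                    f"{g.value}: male vs female", ts, g, stratum="male vs female"
                )
            )
    return plan


def _restrict_sex(ds: Dataset, sex: Sex) -> Dataset:
    return Dataset([r for r in ds.reports if r.sex is sex], provenance=ds.provenance)


def run_plan(
    ds: Dataset,
    plan: list[PlanEntry] | None = None,
    term_sets: dict[str, TermSet] | None = None,
    min_events: int = 3,
    z: float = 1.96,
) -> pd.DataFrame:
    """Execute a comparison plan on a deduplicated dataset.

    Returns a tidy frame, one row per plan entry: label, term_set, stratum,
    the four cells, estimate, CI, p-value and flags.  Gated entries are
    emitted with empty estimates rather than dropped.
    """
    from .selection import default_indicative_terms, primary_term_set

    if term_sets is None:
        term_sets = {
            "primary": primary_term_set(),
            "indicative": default_indicative_terms(),
        }
    if plan is None:
        plan = default_plan(tuple(term_sets))

    rows = []
    for entry in plan:
        ts = term_sets[entry.term_set]
        if entry.stratum is None:
            a, b = count_events(ds, entry.group, ts)
            c, d = count_events(ds, entry.comparator, ts)
        else:
            a, b = count_events(_restrict_sex(ds, Sex.MALE), entry.group, ts)
            c, d = count_events(_restrict_sex(ds, Sex.FEMALE), entry.group, ts)
        est = ror(ContingencyTable(a, b, c, d), min_events=min_events, z=z)
        rows.append(
            {
                "label": entry.label,
                "term_set": entry.term_set,
                "stratum": entry.stratum or "",
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "ror": est.ror,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p_value": est.p_value,
                "gated": est.gated,
                "corrected": est.corrected,
                "significant": est.significant,
            }
        )
    return pd.DataFrame.from_records(rows)


def forest_table(results: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Plot-ready view of run_plan output: label, ROR and CI text column."""
    out = results.copy()

    def fmt(rec):
        if rec["gated"]:
            return "not estimated (<3 events)"
        return (
            f"{rec['ror']:.{ndigits}f} "
            f"({rec['ci_low']:.{ndigits}f}-{rec['ci_high']:.{ndigits}f})"
        )

    out["ror_ci"] = out.apply(fmt, axis=1)
    return out[["label", "term_set", "stratum", "ror", "ci_low", "ci_high", "ror_ci"]]
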