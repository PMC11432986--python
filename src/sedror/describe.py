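"""Descriptive summarisation of case reports.

Reproduces the descriptive logic of a spontaneous-report case series:
demographic margins per exposure group, seriousness of the target events
after resolving multiple ICH E2D criteria to the single most serious one,
favourable/unfavourable outcome classification, the SOC distribution of
the remaining (non-target) events, and ATC level-2 concomitant classes.

Percentages are rounded half-up to one decimal, the convention used in
regulatory-style tables; counts are kept alongside so nothing is lost to
rounding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .model import (
    AgeGroup,
    Dataset,
    OutcomeCode,
    Region,
    ReporterType,
    SeriousnessCriterion,
    Sex,
)
from .selection import ExposureGroup, GROUP_ORDER, TermSet, assign_group
from .vocab import ALL_SOCS


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), e.g. 0.05 -> 0.1."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denom: int, ndigits: int = 1) -> float:
    """Percentage with half-up rounding; 0.0 for an empty denominator."""
    if denom == 0:
        return 0.0
    return round_half_up(100.0 * count / denom, ndigits)


def most_serious(criteria: set[SeriousnessCriterion]) -> SeriousnessCriterion:
    """Resolve a set of seriousness criteria to the single most serious one.

    Order: death > life-threatening > disabling > hospitalization >
    congenital anomaly > other medically important > not serious.
    """
    if not criteria:
        raise ValueError("empty criteria set")
    return max(criteria, key=lambda c: c.severity)


class OutcomeClass(enum.Enum):
    FAVOURABLE = "Favourable"
    UNFAVOURABLE = "Unfavourable"
    UNKNOWN = "Unknown"


_OUTCOME_CLASS = {
    OutcomeCode.RECOVERED: OutcomeClass.FAVOURABLE,
    OutcomeCode.RECOVERING: OutcomeClass.FAVOURABLE,
    OutcomeCode.RECOVERED_WITH_SEQUELAE: OutcomeClass.UNFAVOURABLE,
    OutcomeCode.NOT_RECOVERED: OutcomeClass.UNFAVOURABLE,
    OutcomeCode.FATAL: OutcomeClass.UNFAVOURABLE,
    OutcomeCode.UNKNOWN: OutcomeClass.UNKNOWN,
}


def classify_outcome(o: OutcomeCode) -> OutcomeClass:
    """Favourable = recovered or recovering; unfavourable = sequelae,
    not recovered, or fatal; anything else stays unknown."""
    return _OUTCOME_CLASS[o]


# ATC level-2 concomitant classes of interest (anatomical level N).
_ATC_CLASSES = {
    "N01": "Anaesthetics",
    "N02": "Analgesics",
    "N05": "Psycholeptics",
}


def atc_class(atc: str | None) -> str:
    if atc is None:
        return "Unclassified"
    return _ATC_CLASSES.get(atc[:3], "Other")


@dataclass
class SummaryBundle:
    """Per-group descriptive tables; every table carries an Overall column.

    ``demographics``: report counts per categorical level (denominator =
    reports per group).  ``seriousness``/``outcome``/``outcome_class``:
    target-event counts (denominator = target events per group).  ``soc``:
    non-target event counts by SOC (denominator = non-target events).
    ``concomitant_atc``: concomitant drug entries by ATC level-2 class.
    """

    demographics: pd.DataFrame
    seriousness: pd.DataFrame
    outcome: pd.DataFrame
    outcome_class: pd.DataFrame
    soc: pd.DataFrame
    concomitant_atc: pd.DataFrame
    denominators: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demographics": self.demographics,
            "seriousness": self.seriousness,
            "outcome": self.outcome,
            "outcome_class": self.outcome_class,
            "soc": self.soc,
            "concomitant_atc": self.concomitant_atc,
            "denominators": self.denominators,
        }


def _block_frame(
    counts: dict[ExposureGroup, dict[str, int]],
    row_labels: list[str],
    denoms: dict[ExposureGroup, int],
    block: str,
) -> pd.DataFrame:
    """Tidy frame: one row per (block row, group) with count and pct."""
    records = []
    groups = GROUP_ORDER + ["Overall"]
    total_denom = sum(denoms.values())
    for label in row_labels:
        overall = 0
        for g in GROUP_ORDER:
            n = counts.get(g, {}).get(label, 0)
            overall += n
            records.append(
                {
                    "block": block,
                    "row": label,
                    "group": g.value,
                    "count": n,
                    "pct": pct(n, denoms.get(g, 0)),
                }
            )
        records.append(
            {
                "block": block,
                "row": label,
                "group": "Overall",
                "count": overall,
                "pct": pct(overall, total_denom),
            }
        )
    df = pd.DataFrame.from_records(records)
    df["group"] = pd.Categorical(
        df["group"], categories=[g.value for g in groups[:-1]] + ["Overall"]
    )
    return df


def summarize(ds: Dataset, target: TermSet) -> SummaryBundle:
    """Build the full descriptive table bundle for a case dataset.

    ``ds`` should already be deduplicated; reports are grouped on the fly.
    Target events are those whose PT is in ``target``; every other event
    contributes to the SOC block.
    """
    by_group: dict[ExposureGroup, list] = {g: [] for g in GROUP_ORDER}
    for r in ds.reports:
        g = assign_group(r)
        if g is not ExposureGroup.NONE:
            by_group[g].append(r)

    report_denoms = {g: len(rs) for g, rs in by_group.items()}

    demo_counts: dict[ExposureGroup, dict[str, int]] = {}
    ser_counts: dict[ExposureGroup, dict[str, int]] = {}
    out_counts: dict[ExposureGroup, dict[str, int]] = {}
    cls_counts: dict[ExposureGroup, dict[str, int]] = {}
    soc_counts: dict[ExposureGroup, dict[str, int]] = {}
    atc_counts: dict[ExposureGroup, dict[str, int]] = {}
    target_denoms: dict[ExposureGroup, int] = {}
    soc_denoms: dict[ExposureGroup, int] = {}
    conco_denoms: dict[ExposureGroup, int] = {}

    def bump(table, g, label):
        table.setdefault(g, {})
        table[g][label] = table[g].get(label, 0) + 1

    for g, reports in by_group.items():
        target_denoms[g] = 0
        soc_denoms[g] = 0
        conco_denoms[g] = 0
        for r in reports:
            bump(demo_counts, g, f"Age: {r.age_group.value}")
            bump(demo_counts, g, f"Sex: {r.sex.value}")
            bump(demo_counts, g, f"Source: {r.reporter.value}")
            bump(demo_counts, g, f"Country: {r.region.value}")
            for ev in r.events:
                if ev.pt.name in target:
                    target_denoms[g] += 1
                    bump(ser_counts, g, most_serious(ev.criteria).value)
                    bump(out_counts, g, ev.outcome.value)
                    bump(cls_counts, g, classify_outcome(ev.outcome).value)
                else:
                    soc_denoms[g] += 1
                    bump(soc_counts, g, ev.pt.soc or "Unspecified SOC")
            for d in r.concomitants():
                conco_denoms[g] += 1
                bump(atc_counts, g, atc_class(d.atc))

    demo_rows = (
        [f"Age: {a.value}" for a in AgeGroup]
        + [f"Sex: {s.value}" for s in Sex]
        + [f"Source: {t.value}" for t in ReporterType]
        + [f"Country: {c.value}" for c in Region]
    )
    ser_rows = [
        c.value
        for c in sorted(SeriousnessCriterion, key=lambda c: -c.severity)
    ]
    out_rows = [o.value for o in OutcomeCode]
    cls_rows = [c.value for c in OutcomeClass]
    soc_rows = sorted(
        set(ALL_SOCS) | {s for d in soc_counts.values() for s in d}
    )
    atc_rows = ["Anaesthetics", "Analgesics", "Psycholeptics", "Other", "Unclassified"]

    denominators = pd.DataFrame(
        {
            "group": [g.value for g in GROUP_ORDER] + ["Overall"],
            "reports": [report_denoms[g] for g in GROUP_ORDER]
            + [sum(report_denoms.values())],
            "target_events": [target_denoms[g] for g in GROUP_ORDER]
            + [sum(target_denoms.values())],
            "other_events": [soc_denoms[g] for g in GROUP_ORDER]
            + [sum(soc_denoms.values())],
            "concomitant_entries": [conco_denoms[g] for g in GROUP_ORDER]
            + [sum(conco_denoms.values())],
        }
    )

    return SummaryBundle(
        demographics=_block_frame(demo_counts, demo_rows, report_denoms, "demographics"),
        seriousness=_block_frame(ser_counts, ser_rows, target_denoms, "seriousness"),
        outcome=_block_frame(out_counts, out_rows, target_denoms, "outcome"),
        outcome_class=_block_frame(cls_counts, cls_rows, target_denoms, "outcome_class"),
        soc=_block_frame(soc_counts, soc_rows, soc_denoms, "soc"),
        concomitant_atc=_block_frame(atc_counts, atc_rows, conco_denoms, "concomitant_atc"),
        denominators=denominators,
    )


def cell(df: pd.DataFrame, row: str, group: str) -> tuple[int, float]:
    """Convenience accessor: (count, pct) for one table cell."""
    hit = df[(df["row"] == row) & (df["group"] == group)]
    if hit.empty:
        raise KeyError((row, group))
    rec = hit.iloc[0]
    return int(rec["count"]), float(rec["pct"])
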