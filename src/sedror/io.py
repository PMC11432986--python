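"""Reader/writer for the flat ICSR line-listing dialect.

The dialect emulates a public spontaneous-report line-listing export: one
CSV row per report, with list-valued cells (drugs, events) packed into
single fields using an intra-cell separator, and per-event multi-valued
seriousness criteria using a third separator.  Default separators:
field ``,`` / list ``|`` / within-event ``;``; missing categorical values
are written as the blank token.

Parsing is total: every row either becomes a valid :class:`~sedror.model.ICSR`
or is rejected with a logged reason; the attached :class:`~sedror.model.ParseLog`
reconciles ``rows = parsed + rejected``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path

from .model import (
    AdverseEvent,
    AgeGroup,
    Dataset,
    DrugEntry,
    DrugRole,
    ICSR,
    OutcomeCode,
    ParseLog,
    Region,
    ReporterType,
    SeriousnessCriterion,
    Sex,
    normalize_text,
)
from .vocab import lookup_pt

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dialect:
    delimiter: str = ","
    list_sep: str = "|"
    multi_sep: str = ";"
    blank: str = ""


DEFAULT_DIALECT = Dialect()

COLUMNS = [
    "case_id",
    "receipt_date",
    "age_group",
    "sex",
    "reporter",
    "region",
    "suspect_drugs",
    "suspect_atc",
    "concomitant_drugs",
    "concomitant_atc",
    "event_pts",
    "event_socs",
    "event_seriousness",
    "event_outcomes",
]

REQUIRED_COLUMNS = [
    "case_id",
    "age_group",
    "sex",
    "reporter",
    "region",
    "suspect_drugs",
    "concomitant_drugs",
    "event_pts",
    "event_socs",
    "event_seriousness",
    "event_outcomes",
]


def _enum_lookup(enum_cls):
    table = {}
    for member in enum_cls:
        table[normalize_text(member.value)] = member
        table[normalize_text(member.name)] = member
    return table


_AGE = _enum_lookup(AgeGroup)
_SEX = _enum_lookup(Sex)
_REPORTER = _enum_lookup(ReporterType)
_REGION = _enum_lookup(Region)
_REGION.update({"eea": Region.EEA, "non-eea": Region.NON_EEA, "non eea": Region.NON_EEA})
_CRIT = _enum_lookup(SeriousnessCriterion)
_OUTCOME = _enum_lookup(OutcomeCode)


def _parse_categorical(token: str, table, default, what: str):
    if not token.strip():
        return default
    member = table.get(normalize_text(token))
    if member is None:
        log.warning("unknown %s %r mapped to %s", what, token, default.name)
        return default
    return member


def _split_list(cell: str, dialect: Dialect) -> list[str]:
    if not cell.strip():
        return []
    return cell.split(dialect.list_sep)


class RowError(ValueError):
    pass


def _parse_row(row: dict[str, str], dialect: Dialect) -> ICSR:
    case_id = (row.get("case_id") or "").strip()
    if not case_id:
        raise RowError("missing case_id")

    date_cell = (row.get("receipt_date") or "").strip()
    if date_cell:
        try:
            receipt = date.fromisoformat(date_cell)
        except ValueError as exc:
            raise RowError(f"bad receipt_date {date_cell!r}") from exc
    else:
        receipt = None

    age = _parse_categorical(row["age_group"], _AGE, AgeGroup.NOT_SPECIFIED, "age group")
    sex = _parse_categorical(row["sex"], _SEX, Sex.NOT_SPECIFIED, "sex")
    reporter = _parse_categorical(
        row["reporter"], _REPORTER, ReporterType.NOT_SPECIFIED, "reporter type"
    )
    # Region has no NOT_SPECIFIED band in line listings: non-EEA is the
    # residual class when EEA origin is not confirmed.
    region = _parse_categorical(row["region"], _REGION, Region.NON_EEA, "region")

    drugs: list[DrugEntry] = []
    for role, name_col, atc_col in (
        (DrugRole.SUSPECT, "suspect_drugs", "suspect_atc"),
        (DrugRole.CONCOMITANT, "concomitant_drugs", "concomitant_atc"),
    ):
        names = _split_list(row[name_col], dialect)
        atcs = _split_list(row.get(atc_col) or "", dialect)
        if atcs and len(atcs) != len(names):
            raise RowError(f"ragged {atc_col}: {len(atcs)} codes for {len(names)} drugs")
        if not atcs:
            atcs = [""] * len(names)
        for name, atc in zip(names, atcs):
            try:
                drugs.append(DrugEntry(name, role, atc.strip() or None))
            except ValueError as exc:
                raise RowError(str(exc)) from exc

    pts = _split_list(row["event_pts"], dialect)
    socs = _split_list(row["event_socs"], dialect)
    crits = _split_list(row["event_seriousness"], dialect)
    outcomes = _split_list(row["event_outcomes"], dialect)
    lengths = {len(pts), len(socs), len(crits), len(outcomes)}
    if len(lengths) != 1:
        raise RowError(
            "ragged event sublists: "
            f"{len(pts)} PTs, {len(socs)} SOCs, {len(crits)} seriousness, "
            f"{len(outcomes)} outcomes"
        )

    events: list[AdverseEvent] = []
    for pt_name, soc, crit_cell, outcome_cell in zip(pts, socs, crits, outcomes):
        if not pt_name.strip():
            raise RowError("empty PT name in event list")
        criteria = set()
        for token in crit_cell.split(dialect.multi_sep):
            criteria.add(
                _parse_categorical(
                    token, _CRIT, SeriousnessCriterion.NOT_SERIOUS, "seriousness criterion"
                )
            )
        outcome = _parse_categorical(outcome_cell, _OUTCOME, OutcomeCode.UNKNOWN, "outcome")
        try:
            events.append(
                AdverseEvent(lookup_pt(pt_name.strip(), soc.strip()), frozenset(criteria), outcome)
            )
        except ValueError as exc:
            raise RowError(str(exc)) from exc

    try:
        return ICSR(case_id, age, sex, reporter, region, drugs, events, receipt)
    except ValueError as exc:
        raise RowError(str(exc)) from exc


def read_line_listing(path: str | Path, dialect: Dialect = DEFAULT_DIALECT) -> Dataset:
    """Read a line-listing CSV into a :class:`Dataset`.

    Missing required columns abort; malformed rows are rejected one by one
    and accounted for in ``Dataset.parse_log``.
    """
    path = Path(path)
    plog = ParseLog()
    reports: list[ICSR] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ValueError(f"missing required column: {col!r}")
        for i, row in enumerate(reader, start=2):
            plog.n_rows += 1
            try:
                reports.append(_parse_row(row, dialect))
                plog.n_parsed += 1
            except RowError as exc:
                plog.n_rejected += 1
                plog.rejections.append(f"line {i}: {exc}")
                log.warning("rejected line %d: %s", i, exc)
    if plog.n_rejected:
        log.warning(
            "%s: %d of %d rows rejected", path.name, plog.n_rejected, plog.n_rows
        )
    return Dataset(reports, provenance=str(path), parse_log=plog)


def _render_blank(member, not_specified, dialect: Dialect) -> str:
    return dialect.blank if member is not_specified else member.value


def _render_report(r: ICSR, dialect: Dialect) -> dict[str, str]:
    suspects = [d for d in r.drugs if d.role is DrugRole.SUSPECT]
    concos = [d for d in r.drugs if d.role is DrugRole.CONCOMITANT]
    sep, msep = dialect.list_sep, dialect.multi_sep

    def crit_cell(ev: AdverseEvent) -> str:
        ordered = sorted(ev.criteria, key=lambda c: -c.severity)
        return msep.join(c.value for c in ordered)

    return {
        "case_id": r.case_id,
        "receipt_date": r.receipt_date.isoformat() if r.receipt_date else dialect.blank,
        "age_group": _render_blank(r.age_group, AgeGroup.NOT_SPECIFIED, dialect),
        "sex": _render_blank(r.sex, Sex.NOT_SPECIFIED, dialect),
        "reporter": _render_blank(r.reporter, ReporterType.NOT_SPECIFIED, dialect),
        "region": r.region.value,
        "suspect_drugs": sep.join(d.name for d in suspects),
        "suspect_atc": sep.join(d.atc or "" for d in suspects)
        if any(d.atc for d in suspects)
        else dialect.blank,
        "concomitant_drugs": sep.join(d.name for d in concos),
        "concomitant_atc": sep.join(d.atc or "" for d in concos)
        if any(d.atc for d in concos)
        else dialect.blank,
        "event_pts": sep.join(ev.pt.name for ev in r.events),
        "event_socs": sep.join(ev.pt.soc for ev in r.events),
        "event_seriousness": sep.join(crit_cell(ev) for ev in r.events),
        "event_outcomes": sep.join(ev.outcome.value for ev in r.events),
    }


def write_line_listing(
    ds: Dataset, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> Path:
    """Write a dataset as a line-listing CSV; round-trips via ``read_line_listing``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, delimiter=dialect.delimiter)
        writer.writeheader()
        for r in ds.reports:
            writer.writerow(_render_report(r, dialect))
    return path
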