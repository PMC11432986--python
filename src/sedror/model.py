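"""Domain model for spontaneous adverse-event reports (ICSRs).

An Individual Case Safety Report (ICSR) is one spontaneous report of
suspected adverse drug reactions for one patient: demographics, the drugs
involved (with the reporter's suspect/concomitant attribution), and the
adverse events coded as MedDRA Preferred Terms (PTs) grouped under System
Organ Classes (SOCs).  Seriousness follows the ICH E2D regulatory criteria
and event outcome uses the standard spontaneous-reporting outcome codes.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from datetime import date


def normalize_text(s: str) -> str:
    """Lowercase, trim and collapse internal whitespace (matching key)."""
    return " ".join(s.split()).lower()


class AgeGroup(enum.Enum):
    """Patient age band, as reported in spontaneous-report line listings."""

    M0_1 = "0-1 Month"
    M2_Y2 = "2 Months-2 Years"
    Y3_11 = "3-11 Years"
    Y12_17 = "12-17 Years"
    Y18_64 = "18-64 Years"
    Y65_85 = "65-85 Years"
    OVER_85 = ">85 Years"
    NOT_SPECIFIED = "Not Specified"

    @classmethod
    def from_years(cls, years: float) -> "AgeGroup":
        """Bin a numeric age (in years) half-open on the lower bound."""
        if years < 0:
            raise ValueError(f"negative age: {years}")
        bounds = [
            (2 / 12, cls.M0_1),
            (3, cls.M2_Y2),
            (12, cls.Y3_11),
            (18, cls.Y12_17),
            (65, cls.Y18_64),
            (86, cls.Y65_85),
        ]
        for upper, band in bounds:
            if years < upper:
                return band
        return cls.OVER_85


class Sex(enum.Enum):
    FEMALE = "Female"
    MALE = "Male"
    NOT_SPECIFIED = "Not Specified"


class ReporterType(enum.Enum):
    HCP = "Healthcare Professional"
    NON_HCP = "Non-Healthcare Professional"
    NOT_SPECIFIED = "Not Specified"


class Region(enum.Enum):
    """Primary source country for regulatory purposes."""

    EEA = "European Economic Area"
    NON_EEA = "Non-European Economic Area"


class SeriousnessCriterion(enum.Enum):
    """ICH E2D seriousness criteria, plus the explicit non-serious class.

    ``severity`` gives a strict total ordering used to resolve the single
    "most serious" criterion when a report lists several.
    """

    NOT_SERIOUS = "Not Serious"
    OTHER_MEDICALLY_IMPORTANT = "Other Medically Important Condition"
    CONGENITAL_ANOMALY = "Congenital Anomaly"
    HOSPITALIZATION = "Caused/Prolonged Hospitalization"
    DISABLING = "Disabling"
    LIFE_THREATENING = "Life Threatening"
    DEATH = "Results in Death"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]


# DEATH > LIFE_THREATENING > DISABLING > HOSPITALIZATION > CONGENITAL_ANOMALY
# > OTHER_MEDICALLY_IMPORTANT > NOT_SERIOUS
_SEVERITY = {
    SeriousnessCriterion.DEATH: 6,
    SeriousnessCriterion.LIFE_THREATENING: 5,
    SeriousnessCriterion.DISABLING: 4,
    SeriousnessCriterion.HOSPITALIZATION: 3,
    SeriousnessCriterion.CONGENITAL_ANOMALY: 2,
    SeriousnessCriterion.OTHER_MEDICALLY_IMPORTANT: 1,
    SeriousnessCriterion.NOT_SERIOUS: 0,
}


class OutcomeCode(enum.Enum):
    RECOVERED = "Recovered/Resolved"
    RECOVERING = "Recovering/Resolving"
    RECOVERED_WITH_SEQUELAE = "Recovered/Resolved With Sequelae"
    NOT_RECOVERED = "Not Recovered/Not Resolved"
    FATAL = "Fatal"
    UNKNOWN = "Unknown"


class DrugRole(enum.Enum):
    SUSPECT = "Suspect"
    CONCOMITANT = "Concomitant"


_ATC_RE = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2})?)?)?$")


@dataclass(frozen=True, slots=True)
class PtTerm:
    """A MedDRA Preferred Term with its System Organ Class label.

    Matching is case-insensitive on the whitespace-normalized name.
    """

    name: str
    soc: str = ""
    code: int | None = None

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("PT name must be nonempty")

    @property
    def key(self) -> str:
        return normalize_text(self.name)


@dataclass(slots=True)
class AdverseEvent:
    """One coded adverse event: PT, seriousness criteria and outcome."""

    pt: PtTerm
    criteria: frozenset[SeriousnessCriterion]
    outcome: OutcomeCode

    def __post_init__(self) -> None:
        self.criteria = frozenset(self.criteria)
        if not self.criteria:
            raise ValueError("criteria must be nonempty")
        if (
            SeriousnessCriterion.NOT_SERIOUS in self.criteria
            and len(self.criteria) > 1
        ):
            raise ValueError("NOT_SERIOUS must be the only criterion when present")

    @property
    def serious(self) -> bool:
        return self.criteria != {SeriousnessCriterion.NOT_SERIOUS}


@dataclass(slots=True)
class DrugEntry:
    """A drug on a report with the reporter's causality attribution."""

    name: str
    role: DrugRole
    atc: str | None = None

    def __post_init__(self) -> None:
        self.name = normalize_text(self.name)
        if not self.name:
            raise ValueError("drug name must be nonempty")
        if self.atc is not None:
            self.atc = self.atc.strip().upper()
            if not _ATC_RE.match(self.atc):
                raise ValueError(f"invalid ATC code: {self.atc!r}")


@dataclass(slots=True)
class ICSR:
    """One Individual Case Safety Report."""

    case_id: str
    age_group: AgeGroup
    sex: Sex
    reporter: ReporterType
    region: Region
    drugs: list[DrugEntry]
    events: list[AdverseEvent]
    receipt_date: date | None = None

    def __post_init__(self) -> None:
        if not any(d.role is DrugRole.SUSPECT for d in self.drugs):
            raise ValueError(f"report {self.case_id}: needs >=1 suspect drug")
        if not self.events:
            raise ValueError(f"report {self.case_id}: needs >=1 event")

    def suspect_names(self) -> list[str]:
        return [d.name for d in self.drugs if d.role is DrugRole.SUSPECT]

    def concomitants(self) -> list[DrugEntry]:
        return [d for d in self.drugs if d.role is DrugRole.CONCOMITANT]


@dataclass(slots=True)
class ParseLog:
    """Row-level accounting for a line-listing read: rows = parsed + rejected."""

    n_rows: int = 0
    n_parsed: int = 0
    n_rejected: int = 0
    rejections: list[str] = field(default_factory=list)


@dataclass(slots=True)
class Dataset:
    """A collection of ICSRs with provenance."""

    reports: list[ICSR]
    provenance: str = ""
    parse_log: ParseLog | None = None

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)


def filter_date_window(
    ds: Dataset,
    start: date = date(2013, 1, 1),
    end: date = date(2023, 12, 31),
) -> Dataset:
    """Keep reports whose receipt date lies in [start, end] (closed).

    Reports without a receipt date are kept: the upstream extract is assumed
    already windowed and dates are optional in the line-listing dialect.
    """
    kept = [
        r
        for r in ds.reports
        if r.receipt_date is None or start <= r.receipt_date <= end
    ]
    return Dataset(kept, provenance=f"{ds.provenance}|window[{start}..{end}]")
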