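"""Deduplication, case definition by PT term sets, and exposure grouping.

The analysis contrasts three intensive-care sedatives — dexmedetomidine,
midazolam and propofol — so every report is assigned to exactly one of the
seven non-empty subsets of those drugs found among its *suspect* drugs
(co-suspects outside the trio do not move a report out of its group), or to
``NONE`` when no study sedative is suspect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from .model import Dataset, ICSR, normalize_text
from .vocab import INDICATIVE_PTS, TARGET_PT

DEXMEDETOMIDINE = "dexmedetomidine"
MIDAZOLAM = "midazolam"
PROPOFOL = "propofol"
SEDATIVES = (DEXMEDETOMIDINE, MIDAZOLAM, PROPOFOL)


class ExposureGroup(enum.Enum):
    DEX = "DEX"
    MID = "MID"
    PRO = "PRO"
    DEX_MID = "DEX/MID"
    DEX_PRO = "DEX/PRO"
    MID_PRO = "MID/PRO"
    DEX_MID_PRO = "DEX/MID/PRO"
    NONE = "NONE"


#: Column/plan order used throughout (single drugs, then combinations).
GROUP_ORDER = [
    ExposureGroup.DEX,
    ExposureGroup.MID,
    ExposureGroup.PRO,
    ExposureGroup.DEX_MID,
    ExposureGroup.DEX_PRO,
    ExposureGroup.MID_PRO,
    ExposureGroup.DEX_MID_PRO,
]

_SUBSET_TO_GROUP = {
    (True, False, False): ExposureGroup.DEX,
    (False, True, False): ExposureGroup.MID,
    (False, False, True): ExposureGroup.PRO,
    (True, True, False): ExposureGroup.DEX_MID,
    (True, False, True): ExposureGroup.DEX_PRO,
    (False, True, True): ExposureGroup.MID_PRO,
    (True, True, True): ExposureGroup.DEX_MID_PRO,
    (False, False, False): ExposureGroup.NONE,
}


def assign_group(r: ICSR) -> ExposureGroup:
    """Map a report to its exposure group from its suspect drugs alone."""
    suspects = set(r.suspect_names())
    return _SUBSET_TO_GROUP[tuple(s in suspects for s in SEDATIVES)]


def group_sedatives(g: ExposureGroup) -> list[str]:
    """The sedative subset a group denotes (empty for NONE)."""
    for subset, group in _SUBSET_TO_GROUP.items():
        if group is g:
            return [s for s, flag in zip(SEDATIVES, subset) if flag]
    raise KeyError(g)


@dataclass(frozen=True)
class TermSet:
    """A labelled set of MedDRA PT names with case-insensitive membership."""

    label: str
    pts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.pts:
            raise ValueError("TermSet must be nonempty")
        object.__setattr__(
            self, "pts", frozenset(normalize_text(p) for p in self.pts)
        )

    def __contains__(self, pt_name: str) -> bool:
        return normalize_text(pt_name) in self.pts

    def __le__(self, other: "TermSet") -> bool:
        return self.pts <= other.pts

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "TermSet":
        """Load a term set from a plain-text file, one PT per line."""
        path = Path(path)
        names = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
        return cls(label or path.stem, frozenset(names))


def primary_term_set() -> TermSet:
    """The primary case definition: the single target PT."""
    return TermSet("primary", frozenset({TARGET_PT.name}))


def default_indicative_terms() -> TermSet:
    """Default set of PTs indicative of rhabdomyolysis (secondary outcome).

    A superset of the primary set covering myoglobin markers, muscle-enzyme
    elevations, muscle signs/symptoms, dark urine and reduced urine output.
    Fully user-overridable via :meth:`TermSet.from_file`.
    """
    return TermSet("indicative", frozenset(pt.name for pt in INDICATIVE_PTS))


def dedup_key(r: ICSR) -> tuple:
    """Heuristic duplicate key for public line listings without stable IDs."""
    return (
        r.sex,
        r.age_group,
        r.region,
        tuple(sorted(r.suspect_names())),
        tuple(sorted(ev.pt.key for ev in r.events)),
    )


def deduplicate(ds: Dataset) -> tuple[Dataset, int]:
    """Drop duplicate reports, keeping the first occurrence per key.

    Reports sharing a case_id always collapse; otherwise the heuristic
    :func:`dedup_key` (demographics + suspects + PT multiset) is used.
    Idempotent.
    """
    seen_ids: set[str] = set()
    seen_keys: set[tuple] = set()
    kept = []
    for r in ds.reports:
        key = dedup_key(r)
        if r.case_id in seen_ids or key in seen_keys:
            continue
        seen_ids.add(r.case_id)
        seen_keys.add(key)
        kept.append(r)
    removed = len(ds.reports) - len(kept)
    return Dataset(kept, provenance=f"{ds.provenance}|dedup(-{removed})"), removed


def select_cases(ds: Dataset, ts: TermSet) -> Dataset:
    """Reports with at least one event whose PT belongs to the term set."""
    if not ts.pts:
        raise ValueError("empty TermSet")
    cases = [r for r in ds.reports if any(ev.pt.name in ts for ev in r.events)]
    return Dataset(cases, provenance=f"{ds.provenance}|cases[{ts.label}]")


def group_counts(ds: Dataset) -> dict[ExposureGroup, int]:
    """Report counts per exposure group (NONE included when present)."""
    counts: dict[ExposureGroup, int] = {}
    for r in ds.reports:
        g = assign_group(r)
        counts[g] = counts.get(g, 0) + 1
    return counts
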