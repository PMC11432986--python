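"""Synthetic ICSR generator with analytically known disproportionality.

Two sources of test data:

* :func:`simulate` draws spontaneous reports from a configurable generative
  process — seven mutually exclusive sedative exposure groups, a per-group
  probability that a report carries the target PT, Poisson background
  events, demographic/reporter/region margins, seriousness and outcome
  margins, optional co-suspects/concomitants and injected duplicates — and
  returns a :class:`TruthLedger` whose expected event counts (and hence the
  true ROR of every pairwise contrast) follow in closed form.

* :func:`fixture_from_tables` rebuilds, deterministically, the 364-report
  rhabdomyolysis case series whose per-group demographic, seriousness,
  outcome and SOC margins match the published descriptive tables cell for
  cell.  Only margins are published, so the joint assignment is a fixed
  round-robin; any joint satisfying the margins is equally valid.

Generative model per report in group g (parameters p = p_target,
lambda = extra_events_mean): one index event, which is the target PT with
probability p and a background PT otherwise, plus K ~ Poisson(lambda)
further background events.  Expected target events per report: p; expected
other events: (1 - p) + lambda.  The true ROR of g1 vs g2 is the ratio of
those per-report odds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    AdverseEvent,
    AgeGroup,
    Dataset,
    DrugEntry,
    DrugRole,
    ICSR,
    OutcomeCode,
    PtTerm,
    Region,
    ReporterType,
    SeriousnessCriterion,
    Sex,
)
from .selection import ExposureGroup, GROUP_ORDER, group_sedatives
from .vocab import (
    ALL_SOCS,
    BACKGROUND_PTS,
    CONCOMITANT_DRUGS,
    CO_SUSPECT_DRUGS,
    TARGET_PT,
    background_pts_for_soc,
)


@dataclass(frozen=True)
class Categorical:
    """A finite categorical distribution over arbitrary labels."""

    labels: tuple
    probs: tuple

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.probs):
            raise ValueError("labels/probs length mismatch")
        total = float(sum(self.probs))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(cls, labels, counts) -> "Categorical":
        total = sum(counts)
        return cls(tuple(labels), tuple(c / total for c in counts))

    def sample(self, rng: np.random.Generator, n: int) -> list:
        idx = rng.choice(len(self.labels), size=n, p=np.asarray(self.probs))
        return [self.labels[i] for i in idx]


@dataclass(frozen=True)
class GroupSpec:
    """Generating parameters for one exposure group."""

    group: ExposureGroup
    n_reports: int
    p_target: float
    extra_events_mean: float = 3.0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not 0.0 <= self.p_target <= 1.0:
            raise ValueError("p_target must lie in [0, 1]")
        if self.extra_events_mean < 0:
            raise ValueError("extra_events_mean must be nonnegative")

    @property
    def event_odds(self) -> float:
        """Expected target events per expected other event per report."""
        other = (1.0 - self.p_target) + self.extra_events_mean
        return self.p_target / other if other > 0 else float("inf")


# Default categorical margins: the published overall case-series margins.
_TABLE1_AGE = Categorical.from_counts(tuple(AgeGroup), (1, 7, 21, 22, 247, 52, 1, 13))
_TABLE1_SEX = Categorical.from_counts(tuple(Sex), (102, 245, 17))
_TABLE1_REPORTER = Categorical.from_counts(tuple(ReporterType), (355, 7, 2))
_TABLE1_REGION = Categorical.from_counts(tuple(Region), (113, 251))
_TABLE2_SERIOUSNESS = Categorical.from_counts(
    (
        SeriousnessCriterion.NOT_SERIOUS,
        SeriousnessCriterion.HOSPITALIZATION,
        SeriousnessCriterion.DISABLING,
        SeriousnessCriterion.LIFE_THREATENING,
        SeriousnessCriterion.DEATH,
        SeriousnessCriterion.OTHER_MEDICALLY_IMPORTANT,
    ),
    (3, 100, 6, 88, 74, 93),
)
_TABLE2_OUTCOME = Categorical.from_counts(tuple(OutcomeCode), (117, 75, 5, 21, 74, 72))


def default_groups() -> list[GroupSpec]:
    """Seven-group structure at full-extract scale (19,268 reports total).

    Per-group sizes emulate a sedative extract dominated by propofol and
    midazolam; p_target is set so each group's expected target-event count
    matches the published case series (e.g. 10000 x 0.028 = 280 for
    propofol).
    """
    sizes = {
        ExposureGroup.DEX: 2000,
        ExposureGroup.MID: 5000,
        ExposureGroup.PRO: 10000,
        ExposureGroup.DEX_MID: 300,
        ExposureGroup.DEX_PRO: 500,
        ExposureGroup.MID_PRO: 1400,
        ExposureGroup.DEX_MID_PRO: 68,
    }
    cases = {
        ExposureGroup.DEX: 14,
        ExposureGroup.MID: 37,
        ExposureGroup.PRO: 280,
        ExposureGroup.DEX_MID: 2,
        ExposureGroup.DEX_PRO: 9,
        ExposureGroup.MID_PRO: 21,
        ExposureGroup.DEX_MID_PRO: 1,
    }
    return [
        GroupSpec(g, sizes[g], cases[g] / sizes[g]) for g in GROUP_ORDER
    ]


@dataclass
class SimConfig:
    """Full configuration of the generative process."""

    groups: list[GroupSpec] = field(default_factory=default_groups)
    age_dist: Categorical = _TABLE1_AGE
    sex_dist: Categorical = _TABLE1_SEX
    reporter_dist: Categorical = _TABLE1_REPORTER
    region_dist: Categorical = _TABLE1_REGION
    seriousness_dist: Categorical = _TABLE2_SERIOUSNESS
    outcome_dist: Categorical = _TABLE2_OUTCOME
    vocab: list[PtTerm] = field(default_factory=lambda: list(BACKGROUND_PTS))
    co_suspect_rate: float = 0.62
    concomitant_rate: float = 0.544
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("groups must be nonempty")
        if len({gs.group for gs in self.groups}) != len(self.groups):
            raise ValueError("duplicate exposure group in config")
        if any(pt.key == TARGET_PT.key for pt in self.vocab):
            raise ValueError("background vocab must exclude the target PT")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1]")


@dataclass
class TruthLedger:
    """Analytic and realized event counts per group, and true RORs."""

    expected_a: dict[ExposureGroup, float]
    expected_b: dict[ExposureGroup, float]
    realized_a: dict[ExposureGroup, int]
    realized_b: dict[ExposureGroup, int]
    n_duplicates: int = 0

    def true_ror(self, g1: ExposureGroup, g2: ExposureGroup) -> float:
        """ROR implied by the generative process (expected counts)."""
        odds1 = self.expected_a[g1] / self.expected_b[g1]
        odds2 = self.expected_a[g2] / self.expected_b[g2]
        return odds1 / odds2

    def realized_ror(self, g1: ExposureGroup, g2: ExposureGroup) -> float:
        return (self.realized_a[g1] * self.realized_b[g2]) / (
            self.realized_b[g1] * self.realized_a[g2]
        )

    def to_dict(self) -> dict:
        return {
            "expected": {
                g.value: {"a": self.expected_a[g], "b": self.expected_b[g]}
                for g in self.expected_a
            },
            "realized": {
                g.value: {"a": self.realized_a[g], "b": self.realized_b[g]}
                for g in self.realized_a
            },
            "n_duplicates": self.n_duplicates,
        }


def simulate(cfg: SimConfig) -> tuple[Dataset, TruthLedger]:
    """Draw a synthetic dataset; reproducible for a fixed ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    reports: list[ICSR] = []
    expected_a, expected_b = {}, {}
    realized_a, realized_b = {}, {}
    vocab = cfg.vocab

    for gs in cfg.groups:
        n = gs.n_reports
        g = gs.group
        expected_a[g] = n * gs.p_target
        expected_b[g] = n * ((1.0 - gs.p_target) + gs.extra_events_mean)

        target_flags = rng.random(n) < gs.p_target
        n_extra = rng.poisson(gs.extra_events_mean, n)
        ages = cfg.age_dist.sample(rng, n)
        sexes = cfg.sex_dist.sample(rng, n)
        reporters = cfg.reporter_dist.sample(rng, n)
        regions = cfg.region_dist.sample(rng, n)
        co_flags = rng.random(n) < cfg.co_suspect_rate
        conco_flags = rng.random(n) < cfg.concomitant_rate

        # draw per-event attributes in bulk, then slice per report
        total_events = int(n + n_extra.sum())
        crit_all = cfg.seriousness_dist.sample(rng, total_events)
        out_all = cfg.outcome_dist.sample(rng, total_events)
        pt_idx_all = rng.integers(len(vocab), size=total_events)
        co_idx = rng.integers(len(CO_SUSPECT_DRUGS), size=n)
        conco_idx = rng.integers(len(CONCOMITANT_DRUGS), size=n)

        sedatives = group_sedatives(g)
        a_count = b_count = 0
        pos = 0
        for i in range(n):
            n_events = 1 + int(n_extra[i])
            crits = crit_all[pos : pos + n_events]
            outs = out_all[pos : pos + n_events]
            pt_idx = pt_idx_all[pos : pos + n_events]
            pos += n_events
            events = []
            if target_flags[i]:
                events.append(
                    AdverseEvent(TARGET_PT, frozenset({crits[0]}), outs[0])
                )
                a_count += 1
            else:
                pt = vocab[pt_idx[0]]
                events.append(AdverseEvent(pt, frozenset({crits[0]}), outs[0]))
                b_count += 1
            for j in range(1, n_events):
                pt = vocab[pt_idx[j]]
                events.append(AdverseEvent(pt, frozenset({crits[j]}), outs[j]))
                b_count += 1

            drugs = [DrugEntry(s, DrugRole.SUSPECT) for s in sedatives]
            if co_flags[i]:
                name, atc = CO_SUSPECT_DRUGS[co_idx[i]]
                drugs.append(DrugEntry(name, DrugRole.SUSPECT, atc))
            if conco_flags[i]:
                name, atc = CONCOMITANT_DRUGS[conco_idx[i]]
                drugs.append(DrugEntry(name, DrugRole.CONCOMITANT, atc))

            reports.append(
                ICSR(
                    case_id=f"SIM-{g.name}-{i:06d}",
                    age_group=ages[i],
                    sex=sexes[i],
                    reporter=reporters[i],
                    region=regions[i],
                    drugs=drugs,
                    events=events,
                )
            )
        realized_a[g] = a_count
        realized_b[g] = b_count

    ds = Dataset(reports, provenance=f"simulate(seed={cfg.seed})")
    ledger = TruthLedger(expected_a, expected_b, realized_a, realized_b)
    if cfg.duplicate_rate > 0:
        ds = inject_duplicates(ds, cfg.duplicate_rate, seed=cfg.seed + 1)
        ledger.n_duplicates = len(ds.reports) - len(reports)
    return ds, ledger


def inject_duplicates(ds: Dataset, rate: float, seed: int) -> Dataset:
    """Append copies of ``round(rate * n)`` randomly chosen reports.

    Copies receive fresh case_ids but identical deduplication keys, so a
    downstream duplicate pass should recover the original report count.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    n = len(ds.reports)
    n_dups = int(round(rate * n))
    if n_dups == 0:
        return ds
    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=n_dups, replace=False)
    copies = []
    for k, idx in enumerate(sorted(picks)):
        src = ds.reports[idx]
        copies.append(
            ICSR(
                case_id=f"DUP-{k:06d}",
                age_group=src.age_group,
                sex=src.sex,
                reporter=src.reporter,
                region=src.region,
                drugs=list(src.drugs),
                events=list(src.events),
                receipt_date=src.receipt_date,
            )
        )
    return Dataset(
        ds.reports + copies, provenance=f"{ds.provenance}|+{n_dups}dups"
    )


# --- published case-series margins (counts per group, group order:
# DEX, MID, PRO, DEX/MID, DEX/PRO, MID/PRO, DEX/MID/PRO) ---

FIXTURE_GROUP_N = {
    ExposureGroup.DEX: 14,
    ExposureGroup.MID: 37,
    ExposureGroup.PRO: 280,
    ExposureGroup.DEX_MID: 2,
    ExposureGroup.DEX_PRO: 9,
    ExposureGroup.MID_PRO: 21,
    ExposureGroup.DEX_MID_PRO: 1,
}

_AGE_MARGINS = {
    AgeGroup.M0_1: (0, 0, 1, 0, 0, 0, 0),
    AgeGroup.M2_Y2: (1, 2, 3, 1, 0, 0, 0),
    AgeGroup.Y3_11: (0, 0, 20, 0, 0, 1, 0),
    AgeGroup.Y12_17: (1, 5, 15, 0, 0, 1, 0),
    AgeGroup.Y18_64: (9, 21, 196, 1, 7, 13, 0),
    AgeGroup.Y65_85: (2, 9, 36, 0, 0, 5, 0),
    AgeGroup.OVER_85: (0, 0, 1, 0, 0, 0, 0),
    AgeGroup.NOT_SPECIFIED: (1, 0, 8, 0, 2, 1, 1),
}

_SEX_MARGINS = {
    Sex.FEMALE: (4, 12, 77, 1, 3, 5, 0),
    Sex.MALE: (9, 24, 191, 1, 4, 15, 1),
    Sex.NOT_SPECIFIED: (1, 1, 12, 0, 2, 1, 0),
}

_REPORTER_MARGINS = {
    ReporterType.HCP: (14, 31, 278, 2, 9, 20, 1),
    ReporterType.NON_HCP: (0, 6, 1, 0, 0, 0, 0),
    ReporterType.NOT_SPECIFIED: (0, 0, 1, 0, 0, 1, 0),
}

_REGION_MARGINS = {
    Region.EEA: (2, 15, 90, 0, 1, 5, 0),
    Region.NON_EEA: (12, 22, 190, 2, 8, 16, 1),
}

_SERIOUSNESS_MARGINS = {
    SeriousnessCriterion.NOT_SERIOUS: (0, 1, 1, 0, 0, 1, 0),
    SeriousnessCriterion.HOSPITALIZATION: (1, 10, 82, 2, 0, 5, 0),
    SeriousnessCriterion.DISABLING: (0, 0, 6, 0, 0, 0, 0),
    SeriousnessCriterion.LIFE_THREATENING: (8, 5, 68, 0, 0, 6, 1),
    SeriousnessCriterion.DEATH: (2, 12, 54, 0, 3, 3, 0),
    SeriousnessCriterion.OTHER_MEDICALLY_IMPORTANT: (3, 9, 69, 0, 6, 6, 0),
}

_OUTCOME_MARGINS = {
    OutcomeCode.RECOVERED: (5, 11, 94, 0, 0, 7, 0),
    OutcomeCode.RECOVERING: (4, 5, 63, 0, 0, 3, 0),
    OutcomeCode.RECOVERED_WITH_SEQUELAE: (0, 1, 3, 0, 0, 0, 1),
    OutcomeCode.NOT_RECOVERED: (0, 1, 19, 1, 0, 0, 0),
    OutcomeCode.FATAL: (2, 12, 54, 0, 3, 3, 0),
    OutcomeCode.UNKNOWN: (3, 7, 47, 1, 6, 8, 0),
}

# Non-target (other-ADR) event counts per SOC and group; column totals
# 52, 233, 1046, 18, 9, 86, 2 (1446 events overall).
_SOC_MARGINS: dict[str, tuple[int, ...]] = dict(
    zip(
        ALL_SOCS,
        [
            (2, 9, 22, 0, 0, 2, 0),      # Blood and lymphatic system
            (1, 10, 97, 6, 1, 6, 0),     # Cardiac
            (0, 0, 1, 0, 0, 0, 0),       # Congenital, familial and genetic
            (0, 0, 1, 0, 0, 0, 0),       # Ear and labyrinth
            (0, 1, 2, 0, 0, 0, 0),       # Endocrine
            (0, 6, 1, 0, 0, 0, 0),       # Eye
            (2, 5, 22, 0, 0, 0, 0),      # Gastrointestinal
            (10, 31, 109, 1, 5, 14, 1),  # General disorders
            (0, 4, 38, 0, 0, 2, 0),      # Hepatobiliary
            (1, 8, 13, 0, 0, 2, 0),      # Infections
            (9, 17, 42, 1, 0, 3, 0),     # Injury, poisoning, procedural
            (8, 30, 121, 2, 1, 17, 0),   # Investigations
            (1, 11, 231, 1, 0, 8, 0),    # Metabolism and nutrition
            (0, 5, 57, 0, 0, 6, 0),      # Musculoskeletal
            (0, 0, 0, 0, 0, 1, 0),       # Neoplasms
            (7, 38, 50, 2, 1, 5, 0),     # Nervous system
            (2, 23, 14, 0, 0, 0, 0),     # Psychiatric
            (8, 12, 125, 1, 0, 10, 1),   # Renal and urinary
            (0, 0, 1, 0, 0, 0, 0),       # Reproductive system
            (1, 10, 30, 3, 0, 5, 0),     # Respiratory
            (0, 7, 7, 0, 0, 3, 0),       # Skin
            (0, 1, 2, 0, 0, 0, 0),       # Social circumstances
            (0, 0, 9, 0, 0, 0, 0),       # Surgical and medical procedures
            (0, 5, 51, 1, 1, 2, 0),      # Vascular
        ],
    )
)


def _expand(margins: dict, col: int) -> list:
    """Expand {label: per-group counts} into a label sequence for one group."""
    seq = []
    for label, counts in margins.items():
        seq.extend([label] * counts[col])
    return seq


def fixture_from_tables() -> Dataset:
    """Deterministic 364-report case series matching the published margins.

    Every per-group margin of the demographic, seriousness, outcome and SOC
    tables is reproduced exactly; the joint assignment within a group is a
    fixed round-robin over the margin expansions (the publication prints
    margins only, so any margin-consistent joint is valid).  Each report
    carries exactly one target (rhabdomyolysis) event; the group's
    non-target events are dealt to its reports in rotation.
    """
    reports: list[ICSR] = []
    for col, g in enumerate(GROUP_ORDER):
        n = FIXTURE_GROUP_N[g]
        ages = _expand(_AGE_MARGINS, col)
        sexes = _expand(_SEX_MARGINS, col)
        reporters = _expand(_REPORTER_MARGINS, col)
        regions = _expand(_REGION_MARGINS, col)
        crits = _expand(_SERIOUSNESS_MARGINS, col)
        outs = _expand(_OUTCOME_MARGINS, col)
        assert len(ages) == len(sexes) == len(crits) == len(outs) == n

        # deal the group's non-target events round-robin over its reports,
        # rotating within each SOC's PT pool so neighbouring reports do not
        # end up with identical event sets
        extra_events: list[list[AdverseEvent]] = [[] for _ in range(n)]
        pos = 0
        for soc, counts in _SOC_MARGINS.items():
            pts = background_pts_for_soc(soc)
            for _ in range(counts[col]):
                pt = pts[pos % len(pts)]
                extra_events[pos % n].append(
                    AdverseEvent(
                        pt,
                        frozenset({SeriousnessCriterion.NOT_SERIOUS}),
                        OutcomeCode.UNKNOWN,
                    )
                )
                pos += 1

        sedatives = group_sedatives(g)
        for i in range(n):
            events = [
                AdverseEvent(TARGET_PT, frozenset({crits[i]}), outs[i])
            ] + extra_events[i]
            reports.append(
                ICSR(
                    case_id=f"FIX-{g.name}-{i:03d}",
                    age_group=ages[i],
                    sex=sexes[i],
                    reporter=reporters[i],
                    region=regions[i],
                    drugs=[DrugEntry(s, DrugRole.SUSPECT) for s in sedatives],
                    events=events,
                )
            )
    return Dataset(reports, provenance="fixture_from_tables")
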