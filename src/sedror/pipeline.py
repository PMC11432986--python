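"""End-to-end pipeline: load/simulate -> window -> dedup -> select ->
describe -> disproportionality, with stage-count reconciliation and a
machine-readable run summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

from . import io as llio
from .describe import SummaryBundle, summarize
from .model import Dataset, filter_date_window
from .ror import default_plan, forest_table, run_plan
from .selection import (
    TermSet,
    deduplicate,
    default_indicative_terms,
    group_counts,
    primary_term_set,
    select_cases,
)
from .simulate import GroupSpec, SimConfig, simulate
from .selection import ExposureGroup

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Exactly one of ``input_path`` / ``sim`` must be set."""

    input_path: Path | None = None
    sim: SimConfig | None = None
    outdir: Path = Path("sedror_out")
    term_set: str | Path = "primary"  # case definition for descriptives
    window_start: date = date(2013, 1, 1)
    window_end: date = date(2023, 12, 31)
    min_events: int = 3
    z: float = 1.96
    seed: int = 0
    round_digits: int = 2
    dedup: bool = True  # disable for inputs known to be duplicate-free

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ConfigError("exactly one of input_path / sim must be given")


def _resolve_term_set(choice: str | Path) -> TermSet:
    if choice == "primary":
        return primary_term_set()
    if choice == "indicative":
        return default_indicative_terms()
    return TermSet.from_file(Path(choice))


def sim_config_from_dict(d: dict, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a plain (YAML/JSON) mapping."""
    groups = [
        GroupSpec(
            ExposureGroup(g["group"]),
            int(g["n_reports"]),
            float(g["p_target"]),
            float(g.get("extra_events_mean", 3.0)),
        )
        for g in d.get("groups", [])
    ]
    kwargs = {}
    if groups:
        kwargs["groups"] = groups
    for key in ("co_suspect_rate", "concomitant_rate", "duplicate_rate"):
        if key in d:
            kwargs[key] = float(d[key])
    kwargs["seed"] = int(d.get("seed", seed if seed is not None else 0))
    return SimConfig(**kwargs)


def config_from_yaml(path: str | Path, **overrides) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "input" in raw and "simulate" in raw:
        raise ConfigError("config sets both 'input' and 'simulate'")
    kwargs: dict = {}
    if "input" in raw:
        kwargs["input_path"] = Path(raw["input"])
    if "simulate" in raw:
        kwargs["sim"] = sim_config_from_dict(raw["simulate"], raw.get("seed"))
    for key in ("term_set", "min_events", "z", "seed", "round_digits", "dedup"):
        if key in raw:
            kwargs[key] = raw[key]
    if "outdir" in raw:
        kwargs["outdir"] = Path(raw["outdir"])
    if "window_start" in raw:
        kwargs["window_start"] = date.fromisoformat(str(raw["window_start"]))
    if "window_end" in raw:
        kwargs["window_end"] = date.fromisoformat(str(raw["window_end"]))
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@dataclass
class RunResult:
    dataset: Dataset
    cases: Dataset
    summary: SummaryBundle
    ror_results: "object"
    stages: list[dict] = field(default_factory=list)


def run_all(cfg: PipelineConfig) -> RunResult:
    """Execute every stage and write the report bundle to ``cfg.outdir``.

    Stage counts reconcile: at every stage reports_in = reports_out +
    removed, asserted and recorded in the run log.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name, n_in, n_out, removed):
        assert n_in == n_out + removed, f"{name}: {n_in} != {n_out} + {removed}"
        stages.append(
            {"stage": name, "in": n_in, "out": n_out, "removed": removed}
        )
        log.info("%s: %d -> %d (-%d)", name, n_in, n_out, removed)

    if cfg.input_path is not None:
        ds = llio.read_line_listing(cfg.input_path)
        plog = ds.parse_log
        stage("read", plog.n_rows, plog.n_parsed, plog.n_rejected)
    else:
        ds, ledger = simulate(cfg.sim)
        stage("simulate", len(ds), len(ds), 0)
        (outdir / "truth_ledger.json").write_text(
            json.dumps(ledger.to_dict(), indent=2)
        )

    n = len(ds)
    ds = filter_date_window(ds, cfg.window_start, cfg.window_end)
    stage("date_window", n, len(ds), n - len(ds))

    if cfg.dedup:
        ds, n_removed = deduplicate(ds)
        stage("deduplicate", len(ds) + n_removed, len(ds), n_removed)
    else:
        stage("deduplicate", len(ds), len(ds), 0)

    case_ts = _resolve_term_set(cfg.term_set)
    cases = select_cases(ds, case_ts)
    stage("select_cases", len(ds), len(cases), len(ds) - len(cases))

    summary = summarize(cases, case_ts)
    for name, table in summary.tables().items():
        table.to_csv(outdir / f"table_{name}.csv", index=False)

    term_sets = {
        "primary": primary_term_set(),
        "indicative": default_indicative_terms(),
    }
    results = run_plan(
        ds, default_plan(tuple(term_sets)), term_sets, cfg.min_events, cfg.z
    )
    results.to_csv(outdir / "ror.csv", index=False)
    forest_table(results, cfg.round_digits).to_csv(
        outdir / "forest.csv", index=False
    )

    counts = {g.value: n for g, n in group_counts(cases).items()}
    run_summary = {
        "stages": stages,
        "case_group_counts": counts,
        "n_cases": len(cases),
        "n_reports_retained": len(ds),
        "seed": cfg.seed,
        "term_set": case_ts.label,
    }
    (outdir / "run_log.json").write_text(json.dumps(run_summary, indent=2))

    llio.write_line_listing(cases, outdir / "cases.csv")
    return RunResult(ds, cases, summary, results, stages)
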