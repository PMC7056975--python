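"""End-to-end orchestration: simulate -> scan -> filter -> screen -> classify.

Each stage writes its table under the configured output directory, and the
run ends with a JSON + plain-text report carrying the per-arm interval
summary, the candidate count and the per-category gene tallies.  A fixed
seed makes the whole bundle byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .candidates import FilterParams, annotate_min_snp_p, select_candidates
from .classify import classify_all, screen_tallies
from .io import (
    write_annotations,
    write_intervals,
    write_intervals_bed,
    write_lifespan,
    write_productivity,
    write_qpcr,
    write_variants,
)
from .scan import ScanParams, assign_genes, scan_intervals, scan_summary
from .screen import call_knockdown, call_lifespan_effects, call_productivity_effects
from .simulate import CONTROL_LABEL, PlantedSweep, SimConfig, simulate_annotations, simulate_frequencies, simulate_screen

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "default_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "senescan_out"
    sim: SimConfig = field(default_factory=SimConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    filter: FilterParams = field(default_factory=FilterParams)
    alpha: float = 0.05
    early_weeks: tuple[int, ...] = (1, 2)
    late_weeks: tuple[int, ...] | None = None
    flank_bp: int = 0

    def validate(self) -> None:
        self.sim.validate()
        self.scan.validate()
        self.filter.validate()
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sweeps = [PlantedSweep(**sw) for sw in sim_raw.pop("sweeps", [])]
        if "lifespan_effects" in sim_raw:
            sim_raw["lifespan_effects"] = {
                g: tuple(v) for g, v in sim_raw["lifespan_effects"].items()
            }
        if "productivity_effects" in sim_raw:
            sim_raw["productivity_effects"] = {
                g: {int(w): x for w, x in v.items()}
                for g, v in sim_raw["productivity_effects"].items()
            }
        if "arms" in sim_raw:
            sim_raw["arms"] = [tuple(a) for a in sim_raw["arms"]]
        if "weekly_means" in sim_raw:
            sim_raw["weekly_means"] = tuple(sim_raw["weekly_means"])
        sim = SimConfig(sweeps=sweeps, **sim_raw)
        scan = ScanParams(**raw.pop("scan", {}))
        filt = FilterParams(**raw.pop("filter", {}))
        if "early_weeks" in raw:
            raw["early_weeks"] = tuple(raw["early_weeks"])
        if raw.get("late_weeks") is not None:
            raw["late_weeks"] = tuple(raw["late_weeks"])
        cfg = cls(sim=sim, scan=scan, filter=filt, **raw)
        cfg.sim.seed = cfg.seed
        return cfg


def default_config(seed: int = 0, outdir: str = "senescan_out") -> PipelineConfig:
    """A small self-contained demonstration configuration: two arms, two
    planted sweeps, four screen genes covering the main effect classes."""
    sim = SimConfig(
        seed=seed,
        arms=[("X", 23_500_000, 2500), ("3R", 32_100_000, 2500)],
        sweeps=[
            PlantedSweep("X", 5_000_000, 5_400_000, 0.95),
            PlantedSweep("3R", 12_000_000, 12_300_000, 0.92),
        ],
        gene_length=25_000,
        lifespan_effects={
            "ap-1": (-8.0, 8.0),   # sexually antagonistic
            "ben-1": (9.0, 9.0),   # concordant benefit
            "del-1": (-9.0, -9.0),  # concordant cost
            "null-1": (0.0, 0.0),
        },
        productivity_effects={
            "ap-1": {1: 8.0, 2: 6.0, 4: -5.0, 5: -2.5},
            "ben-1": {1: 6.0, 2: 6.0, 3: 6.0, 4: 6.0, 5: 6.0},
            "del-1": {1: -6.0, 2: -6.0, 3: -6.0, 4: -4.0, 5: -2.0},
            "null-1": {},
        },
        qpcr_knockdown={"ap-1": 0.25, "ben-1": 0.4},
    )
    return PipelineConfig(seed=seed, outdir=outdir, sim=sim)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - report stage and abort
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write the output bundle, return the report dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("senescan %s, seed=%d", __version__, config.seed)

    variants, annotations, tables = _simulate(config, out)
    lifespan, weekly, qpcr = tables
    intervals = _scan(config, out, variants, annotations)
    cands = _filter(config, out, variants, annotations, intervals)
    calls = _screen(config, out, lifespan, weekly, qpcr)
    profiles, tallies = _classify(config, out, calls)

    report = {
        "version": __version__,
        "seed": config.seed,
        "params": {
            "scan": dataclasses.asdict(config.scan),
            "filter": dataclasses.asdict(config.filter),
            "alpha": config.alpha,
            "early_weeks": list(config.early_weeks),
            "late_weeks": list(config.late_weeks) if config.late_weeks else None,
        },
        "intervals_per_arm": scan_summary(intervals).to_dict(orient="records"),
        "n_intervals": len(intervals),
        "n_candidates": int(cands["selected"].sum()),
        "tallies": tallies,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(out / "report.txt", "w") as fh:
        fh.write(_format_report(report))
    return report


@_stage("simulate")
def _simulate(config: PipelineConfig, out: Path):
    variants = simulate_frequencies(config.sim)
    annotations = simulate_annotations(config.sim)
    tables = simulate_screen(config.sim)
    write_variants(variants, out / "variants.tsv")
    write_annotations(annotations, out / "annotations.tsv")
    write_lifespan(tables[0], out / "lifespan.csv")
    write_productivity(tables[1], out / "productivity.csv")
    write_qpcr(tables[2], out / "qpcr.csv")
    return variants, annotations, tables


@_stage("scan")
def _scan(config: PipelineConfig, out: Path, variants, annotations):
    intervals = scan_intervals(variants, config.scan)
    assign_genes(intervals, annotations, flank_bp=config.flank_bp, known_arms=set(variants["arm"]))
    write_intervals(intervals, out / "intervals.tsv")
    write_intervals_bed(intervals, out / "intervals.bed")
    return intervals


@_stage("filter")
def _filter(config: PipelineConfig, out: Path, variants, annotations, intervals):
    annotated = annotate_min_snp_p(annotations, variants)
    cands = select_candidates(annotated, intervals, config.filter)
    cands.to_csv(out / "candidates.tsv", sep="\t", index=False)
    return cands


@_stage("screen")
def _screen(config: PipelineConfig, out: Path, lifespan, weekly, qpcr):
    import pandas as pd

    calls = [call_lifespan_effects(lifespan, alpha=config.alpha)]
    pairing = {g: CONTROL_LABEL for g in config.sim.screen_genotypes()}
    calls.append(call_productivity_effects(weekly, pairing, alpha=config.alpha))
    if len(qpcr):
        kd, _ = call_knockdown(qpcr, alpha=config.alpha)
        calls.append(kd)
    all_calls = pd.concat(calls, ignore_index=True)
    all_calls.to_csv(out / "effect_calls.csv", index=False)
    return all_calls


@_stage("classify")
def _classify(config: PipelineConfig, out: Path, calls):
    pheno = calls[~calls["trait"].str.startswith("expression")]
    profiles = classify_all(
        pheno, early_weeks=set(config.early_weeks),
        late_weeks=set(config.late_weeks) if config.late_weeks else None,
    )
    profiles.to_csv(out / "profiles.csv", index=False)
    tallies = screen_tallies(pheno, profiles)
    return profiles, tallies


def _format_report(report: dict) -> str:
    lines = [
        f"senescan {report['version']} report (seed={report['seed']})",
        "",
        "Intervals per arm:",
    ]
    for rec in report["intervals_per_arm"]:
        lines.append(
            f"  {rec['arm']}: {rec['n_intervals']} interval(s), "
            f"{rec['n_variants']} variants, {rec['bp_covered']:.0f} bp covered"
        )
    t = report["tallies"]
    lines += [
        "",
        f"Candidate genes selected: {report['n_candidates']}",
        f"Screened genes: {t['n_genes']}",
        f"  affecting lifespan:          {t['lifespan_affected']}",
        f"  increased in at least 1 sex: {t['lifespan_increased_any_sex']}",
        f"  decreased in at least 1 sex: {t['lifespan_decreased_any_sex']}",
        f"  sexually antagonistic:       {t['lifespan_sex_antagonistic']}",
        "",
        "Pleiotropy categories:",
    ]
    for cat, n in t["categories"].items():
        lines.append(f"  {cat}: {n}")
    return "\n".join(lines) + "\n"
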