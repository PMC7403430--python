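"""End-to-end orchestration: simulate/ingest -> screen -> annotate -> call ->
assemble -> tally/CI -> exclusivity, from a single YAML configuration.

Each stage's record accounting (input = retained + removed + skipped) is
kept in the run report, which is written as JSON next to the landscape TSV
and the filter-audit TSV. One top-level seed deterministically derives the
per-stage seeds, so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exclusivity import bootstrap_exclusivity, exclusivity_from_landscape
from .fusion_screen import (
    annotate_fusion,
    filter_candidates,
    fusion_patient_summary,
    load_mgmt_domains,
    load_normal_blacklist,
    load_paralog_pairs,
    read_fusion_candidates,
)
from .gene_model import read_gtf, select_canonical
from .landscape import assemble_landscape, binomial_ci, tally_frequencies
from .synthetic import SyntheticCohortSpec, write_simulation
from .variant_status import call_cohort_hotspots, ingest_upstream_calls, read_pileup

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "load_config"]

EXCLUSIVITY_ALTERATIONS = ["hypomethylation", "hypermutation", "fusion"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    simulate: dict | None = None
    resources: dict = field(default_factory=dict)
    min_depth: int = 5
    min_alt_reads: int = 2
    min_vaf: float = 0.1
    ci_level: float = 0.95
    n_reps: int = 10_000
    exclusivity_scope: str = "assayed"

    def validate(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.min_depth < 1 or self.min_alt_reads < 0 or not 0 <= self.min_vaf <= 1:
            raise ValueError("hotspot thresholds out of range")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    thresholds = raw.pop("thresholds", {})
    cfg = PipelineConfig(
        outdir=raw.get("outdir", "fusionscape_out"),
        seed=int(raw.get("seed", 0)),
        inputs=raw.get("inputs", {}) or {},
        simulate=raw.get("simulate"),
        resources=raw.get("resources", {}) or {},
        **{k: v for k, v in thresholds.items() if k in {
            "min_depth", "min_alt_reads", "min_vaf", "ci_level", "n_reps",
            "exclusivity_scope",
        }},
    )
    cfg.validate()
    return cfg


def _stage_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the report dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in {"inputs", "simulate", "resources"}
        },
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    # ------------------------------------------------------------- simulate
    inputs = dict(config.inputs)
    if config.simulate is not None:
        logger.info("stage simulate: generating synthetic inputs")
        spec = SyntheticCohortSpec(**{**config.simulate, "seed": seeds[0]})
        sim = write_simulation(outdir / "inputs", spec=spec, seed=seeds[0])
        inputs.update(sim["paths"])
        report["stages"]["simulate"] = {"n_patients": spec.n_patients}

    for key in ("cohort_csv", "fusion_tsv", "gtf", "pileup_tsv"):
        if key not in inputs:
            stage = "gene_model" if key == "gtf" else "ingest"
            raise StageError(stage, f"required input {key!r} not configured")
        if not Path(inputs[key]).exists():
            stage = "gene_model" if key == "gtf" else "ingest"
            raise StageError(stage, f"input file not found: {inputs[key]}")

    # --------------------------------------------------------------- ingest
    try:
        cohort = pd.read_csv(inputs["cohort_csv"], dtype=str, keep_default_na=False)
    except Exception as exc:
        raise StageError("ingest", f"cannot read cohort CSV: {exc}") from exc
    report["stages"]["ingest"] = {"patients": len(cohort)}

    try:
        models = select_canonical(read_gtf(inputs["gtf"]))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("gene_model", str(exc)) from exc

    # --------------------------------------------------------------- screen
    try:
        candidates = read_fusion_candidates(inputs["fusion_tsv"])
        retained, audit = filter_candidates(
            candidates,
            normal_blacklist=load_normal_blacklist(config.resources.get("blacklist")),
            paralog_pairs=load_paralog_pairs(config.resources.get("paralogs")),
        )
    except Exception as exc:
        raise StageError("fusion_screen", str(exc)) from exc
    removed = len(candidates) - len(retained)
    report["stages"]["screen"] = {
        "input": len(candidates),
        "retained": len(retained),
        "removed": removed,
        "skipped": 0,
        "removal_reasons": audit.counts(),
    }
    audit_frame = pd.DataFrame(
        {
            "FusionName": [c.name for c in candidates],
            "SampleID": [c.sample_id for c in candidates],
            "reason": audit.reasons,
        }
    )
    audit_frame.to_csv(outdir / "audit.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- annotate
    domains = load_mgmt_domains(config.resources.get("domains"))
    annotations, skipped = [], 0
    for cand in retained:
        left = models.get(cand.left_gene)
        right = models.get(cand.right_gene)
        if left is None or right is None:
            logger.warning("no gene model for %s; candidate skipped", cand.name)
            skipped += 1
            continue
        annotations.append(annotate_fusion(cand, left, right, domains))
    report["stages"]["annotate"] = {
        "input": len(retained),
        "retained": len(annotations),
        "removed": 0,
        "skipped": skipped,
        "categories": {
            cat: sum(a.category == cat for a in annotations)
            for cat in sorted({a.category for a in annotations})
        },
    }

    # ----------------------------------------------------------------- call
    try:
        sites = read_pileup(inputs["pileup_tsv"])
        idh_calls = call_cohort_hotspots(
            sites,
            min_depth=config.min_depth,
            min_alt_reads=config.min_alt_reads,
            min_vaf=config.min_vaf,
        )
    except Exception as exc:
        raise StageError("variant_status", str(exc)) from exc
    report["stages"]["call"] = {
        "sites": len(sites),
        "calls": len(idh_calls),
        "na_calls": int((idh_calls["status"] == "NA").sum()) if len(idh_calls) else 0,
    }

    upstream = None
    if inputs.get("upstream_csv") and Path(inputs["upstream_csv"]).exists():
        upstream = ingest_upstream_calls(
            pd.read_csv(inputs["upstream_csv"], dtype=str, keep_default_na=False),
            known_patients=set(cohort["patient_id"]),
        )

    expression = None
    if inputs.get("expression_csv") and Path(inputs["expression_csv"]).exists():
        expr_frame = pd.read_csv(inputs["expression_csv"])
        expression = pd.Series(
            expr_frame.iloc[:, 1].to_numpy(dtype=float),
            index=expr_frame.iloc[:, 0].astype(str).to_numpy(),
        )

    # ------------------------------------------------------------- assemble
    n_fusions, n_fusion_patients, fusion_summary = fusion_patient_summary(
        annotations, cohort
    )
    try:
        landscape = assemble_landscape(
            cohort,
            idh_calls=idh_calls,
            upstream_calls=upstream,
            fusion_summary=fusion_summary,
            expression=expression,
        )
    except Exception as exc:
        raise StageError("cohort_landscape", str(exc)) from exc
    landscape.to_csv(outdir / "landscape.tsv", sep="\t", index=False)
    report["stages"]["assemble"] = {
        "patients": len(landscape),
        "distinct_fusions": n_fusions,
        "fusion_patients": n_fusion_patients,
    }

    # ------------------------------------------------------------- tally/CI
    freqs = tally_frequencies(landscape)
    ci = binomial_ci(n_fusion_patients, len(landscape), config.ci_level)
    report["frequencies"] = freqs.to_dict(orient="records")
    report["fusion_ci"] = {
        "successes": ci.successes,
        "trials": ci.trials,
        "level": ci.level,
        "lower": ci.lower,
        "upper": ci.upper,
        "method": ci.method,
    }

    # ----------------------------------------------------------- exclusivity
    alt_cols = [c for c in EXCLUSIVITY_ALTERATIONS if c in landscape.columns]
    if len(alt_cols) == len(EXCLUSIVITY_ALTERATIONS):
        inp = exclusivity_from_landscape(landscape, alt_cols)
        test = bootstrap_exclusivity(
            inp, n_reps=config.n_reps, seed=seeds[3], scope=config.exclusivity_scope
        )
        report["exclusivity"] = {
            "alterations": alt_cols,
            "observed_coverage": test.observed_coverage,
            "n_reps": test.n_reps,
            "n_greater": test.n_greater,
            "p_value": test.p_value,
            "p_smoothed": test.p_smoothed,
            "p_tie_inclusive": test.p_tie_inclusive,
            "null_summary": test.null_coverage_summary,
            "seed": test.seed,
            "scope": test.scope,
        }
    else:
        report["exclusivity"] = None

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("pipeline complete; report at %s", outdir / "report.json")
    return report
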