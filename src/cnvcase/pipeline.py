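"""Config-driven end-to-end run: simulate/ingest -> burden -> CNVR -> rare
pipeline -> joint association -> assay calling, with a machine-readable run
manifest."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .association import (
    CopyNumberCall,
    fit_association,
    genotype_frequency_table,
    joint_genotypes_from_calls,
)
from .assays import call_ddpcr_wells, call_qpcr_plate, quant_frame
from .burden import (
    burden_frame,
    compare_burden,
    per_chromosome_tests,
    size_range_histogram,
    summarize_burden,
)
from .cnvr import annotate_cnvrs, build_cnvrs, cnvr_frame, test_cnvr
from .intervals import OverlapRule
from .io import (
    apply_probe_filter,
    read_gene_list,
    read_panel,
    read_sample_manifest,
    read_segments,
    write_panel,
    write_sample_manifest,
    write_segments,
)
from .rare import run_rare_pipeline
from .simulate import SimulationConfig, simulate_cohort, simulate_qpcr_plate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run: either a simulation config or ingest paths, never both."""

    out_dir: Path
    seed: int = 0
    simulation: Optional[SimulationConfig] = None
    segments_path: Optional[Path] = None
    segments2_path: Optional[Path] = None
    manifest_path: Optional[Path] = None
    freq_panel_path: Optional[Path] = None
    known_panel_path: Optional[Path] = None
    genes_path: Optional[Path] = None
    ancestry_component: str = "afr"
    overlap_rule: OverlapRule = field(default_factory=OverlapRule)
    min_probes_loss: int = 25
    min_probes_gain: int = 50

    def __post_init__(self) -> None:
        simulated = self.simulation is not None
        ingested = self.segments_path is not None
        if simulated == ingested:
            raise ValueError("exactly one of simulation config / input paths must be set")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("schema_version", 1) != 1:
            raise ValueError("unsupported config schema version")
        sim = raw.get("simulation")
        kwargs = dict(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            ancestry_component=raw.get("ancestry_component", "afr"),
        )
        if "overlap_rule" in raw:
            kwargs["overlap_rule"] = OverlapRule(**raw["overlap_rule"])
        for key in ("min_probes_loss", "min_probes_gain"):
            if key in raw:
                kwargs[key] = int(raw[key])
        if sim is not None:
            sim = dict(sim)
            sim.setdefault("seed", kwargs["seed"])
            kwargs["simulation"] = SimulationConfig(**sim)
        else:
            for key in (
                "segments_path",
                "segments2_path",
                "manifest_path",
                "freq_panel_path",
                "known_panel_path",
                "genes_path",
            ):
                if raw.get(key):
                    kwargs[key] = Path(raw[key])
        return cls(**kwargs)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "ancestry_component": config.ancestry_component,
        "overlap_rule": config.overlap_rule.describe(),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "seconds": round(time.time() - t0, 3),
                **(result or {}),
            }
            log.info("stage %s done in %.2fs", name, time.time() - t0)
            return result

        return deco

    state: dict = {}

    @stage("inputs")
    def _inputs():
        if config.simulation is not None:
            sim = config.simulation
            samples, segs1, segs2, panels, truth = simulate_cohort(sim)
            write_sample_manifest(samples, out / "manifest.tsv")
            write_segments(segs1, out / "segments_caller1.tsv")
            write_segments(segs2, out / "segments_caller2.tsv")
            write_panel(panels["frequency"], out / "panel_frequency.tsv")
            write_panel(panels["known"], out / "panel_known.tsv")
            truth.genotypes.to_csv(out / "ground_truth_genotypes.tsv", sep="\t", index=False)
            truth.segment_labels.to_csv(
                out / "ground_truth_segments.tsv", sep="\t", index=False
            )
            state.update(
                samples=samples, segs1=segs1, segs2=segs2, panels=panels,
                truth=truth, genes=None,
            )
        else:
            state["samples"] = read_sample_manifest(config.manifest_path)
            state["segs1"] = read_segments(config.segments_path)
            state["segs2"] = (
                read_segments(config.segments2_path) if config.segments2_path else []
            )
            state["panels"] = {
                "frequency": read_panel(config.freq_panel_path, "frequency")
                if config.freq_panel_path
                else None,
                "known": read_panel(config.known_panel_path, "known")
                if config.known_panel_path
                else None,
            }
            state["genes"] = read_gene_list(config.genes_path) if config.genes_path else None
            state["truth"] = None
        state["segs1"] = apply_probe_filter(
            state["segs1"], config.min_probes_loss, config.min_probes_gain
        )
        return {
            "n_samples": len(state["samples"]),
            "n_segments_caller1": len(state["segs1"]),
            "n_segments_caller2": len(state["segs2"]),
        }

    @stage("burden")
    def _burden():
        burdens = summarize_burden(state["segs1"], state["samples"])
        burden_frame(burdens).to_csv(out / "burden_per_sample.tsv", sep="\t", index=False)
        tests = []
        for measure in ("n_total", "n_del", "n_dup", "size_del", "size_dup"):
            r = compare_burden(burdens, state["samples"], measure, config.ancestry_component)
            tests.append(
                {
                    "measure": r.measure,
                    "odds_ratio": r.odds_ratio,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_value": r.p_value,
                    "method": r.method,
                }
            )
        pd.DataFrame(tests).to_csv(out / "burden_tests.tsv", sep="\t", index=False)
        per_chromosome_tests(burdens, state["samples"]).to_csv(
            out / "per_chromosome.tsv", sep="\t", index=False
        )
        size_range_histogram(state["segs1"]).to_csv(
            out / "size_histogram.tsv", sep="\t", index=False
        )
        return {"n_burden_rows": len(burdens)}

    @stage("cnvr")
    def _cnvr():
        regions = build_cnvrs(state["segs1"], state["samples"])
        tests = [
            test_cnvr(r, state["samples"], config.ancestry_component)
            for r in regions
            if r.n_carriers >= 2
        ]
        ann = annotate_cnvrs(regions, state["genes"]) if state["genes"] else None
        cnvr_frame(regions, tests, ann).to_csv(out / "cnvr.tsv", sep="\t", index=False)
        state["regions"] = regions
        return {"n_cnvrs": len(regions)}

    @stage("rare")
    def _rare():
        panels = state["panels"]
        if panels["frequency"] is None or panels["known"] is None:
            log.info("no reference panels supplied; rare stage skipped")
            return {"skipped": True}
        case_ids = {s.sample_id for s in state["samples"] if s.is_case}
        report = run_rare_pipeline(
            [s for s in state["segs1"] if s.sample_id in case_ids],
            [s for s in state["segs1"] if s.sample_id not in case_ids],
            panels,
            state["segs2"],
            config.overlap_rule,
        )
        report.steps_frame().to_csv(out / "rare_steps.tsv", sep="\t", index=False)
        report.table_frame(state["genes"]).to_csv(
            out / "rare_table.tsv", sep="\t", index=False
        )
        state["rare_report"] = report
        return {"cascade": report.counts}

    @stage("association")
    def _assoc():
        truth = state["truth"]
        if truth is None or truth.genotypes.empty:
            log.info("no risk-locus genotypes available; association stage skipped")
            return {"skipped": True}
        loci = sorted(truth.genotypes["locus_id"].unique())
        if len(loci) < 2:
            log.info("fewer than two risk loci; association stage skipped")
            return {"skipped": True}
        geno_to_cn = {"del": 1, "diploid": 2, "dup": 3}
        calls = [
            CopyNumberCall(r.sample_id, r.locus_id, geno_to_cn[r.genotype])
            for r in truth.genotypes.itertuples(index=False)
        ]
        genotype_frequency_table(calls, state["samples"]).to_csv(
            out / "genotype_freq.tsv", sep="\t", index=False
        )
        genos = joint_genotypes_from_calls(calls, loci[0], loci[1])
        table = fit_association(genos, state["samples"], config.ancestry_component)
        table.to_frame().to_csv(out / "association.tsv", sep="\t", index=False)
        return {"loci": loci[:2], "fit_method": table.method}

    @stage("assays")
    def _assays():
        truth = state["truth"]
        if truth is None or truth.genotypes.empty:
            return {"skipped": True}
        locus = sorted(truth.genotypes["locus_id"].unique())[0]
        geno_to_cn = {"del": 1, "diploid": 2, "dup": 3}
        true_cn = {
            r.sample_id: geno_to_cn[r.genotype]
            for r in truth.genotypes.itertuples(index=False)
            if r.locus_id == locus
        }
        plate = simulate_qpcr_plate(true_cn, seed=config.seed + 1)
        plate.to_csv(out / "qpcr_plate.tsv", sep="\t", index=False)
        results = call_qpcr_plate(plate, locus_id=locus)
        quant_frame(results).to_csv(out / "qpcr_calls.tsv", sep="\t", index=False)
        made = [r for r in results if r.cn_integer is not None]
        correct = sum(1 for r in made if r.cn_integer == true_cn[r.sample_id])
        return {
            "locus": locus,
            "n_called": len(made),
            "qpcr_accuracy": round(correct / len(made), 4) if made else None,
        }

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
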