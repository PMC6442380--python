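"""End-to-end orchestration: simulate -> enrich -> call regions ->
occupancy -> meta-profiles -> classify -> compare, from one config.

Every stage writes its outputs under the run directory and the run ends
with a manifest recording the config snapshot, per-stage output paths
with checksums, and timestamps.  Runs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .classify import classify_high_sa, extragenic_enhancers, replication_scores
from .compare_stats import compare_all_classes
from .enrichment import EnrichmentParams, log2_enrichment
from .metaprofile import meta_profile, peak_offset
from .occupancy import OccupancyTable, feature_occupancy, occupancy_summary
from .region_caller import call_enriched_regions, write_regions_bed
from .synthetic import (DepletionSpec, SimulationConfig, default_factors,
                        generate_layout, mock_condition,
                        sa_depletion_condition, simulate_early_replication,
                        simulate_factor_tracks, truth_occupancy, write_layout)
from .track_io import concat_feature_sets, write_bedgraph

log = logging.getLogger("cohesin_occupancy")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    run_dir: str
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    factors: Optional[List[str]] = None        # None = all default factors
    percentile: float = 95.0
    min_length: int = 300
    window: int = 500
    flank: int = 2000
    profile_bin: int = 10
    origin_flank: int = 25_000
    origin_profile_bin: int = 1_000
    pseudocount: float = 1.0
    normalization: str = "none"   # simulated pairs are depth-matched
    lambda_rep: float = 15_000.0
    compare_depletion: bool = True
    write_tracks: bool = False    # bedGraphs are bulky; opt in

    def __post_init__(self) -> None:
        if self.min_length < self.simulation.bin_width:
            raise StageError("region_caller",
                             f"min_length {self.min_length} < bin_width "
                             f"{self.simulation.bin_width}")
        if not (0 < self.percentile < 100):
            raise StageError("region_caller", "percentile must be in (0,100)")
        if self.window < self.simulation.bin_width:
            raise StageError("occupancy", "window must be >= bin_width")

    @staticmethod
    def from_file(path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimulationConfig.from_dict(raw.pop("simulation", {}))
        cfg = PipelineConfig(simulation=sim, **raw)
        return cfg


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    outputs: Dict[str, dict] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def add(self, key: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[key] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the synthetic-mode pipeline end to end."""
    run_dir = Path(config.run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__,
                           seed=config.seed, started=time.time())
    manifest.config["simulation"] = dataclasses.asdict(sim)
    eparams = EnrichmentParams(config.pseudocount, config.normalization)
    factors = default_factors()
    if config.factors is not None:
        factors = {k: factors[k] for k in config.factors}

    stage = "synthetic_data"
    try:
        log.info("simulating layout (seed %d)", config.seed)
        layout, truth = generate_layout(sim)
        conditions = [mock_condition()]
        if config.compare_depletion:
            conditions.append(sa_depletion_condition())
        truth_full = truth_occupancy(truth, factors, conditions, sim)
        paths = write_layout(run_dir, layout, truth_full, sim)
        for k, p in paths.items():
            manifest.add(k, Path(p))

        stage = "enrichment"
        enr = {}
        for cond in conditions:
            for name, params in factors.items():
                ip, inp = simulate_factor_tracks(layout, params, cond, sim,
                                                 truth=truth)
                enr[(name, cond.condition)] = log2_enrichment(ip, inp, eparams)
        edu_ip, edu_in = simulate_early_replication(layout, config.lambda_rep,
                                                    sim)
        edu = log2_enrichment(edu_ip, edu_in, eparams)
        if config.write_tracks:
            for (name, cond_label), track in enr.items():
                p = run_dir / f"enr_{name}_{cond_label}.bedgraph"
                write_bedgraph(track, p, suppress_zeros=True)
                manifest.add(f"track:{name}:{cond_label}", p)

        stage = "region_caller"
        sa_track = enr[("SA", "mock")] if ("SA", "mock") in enr \
            else next(iter(enr.values()))
        regions = call_enriched_regions(sa_track, config.percentile,
                                        config.min_length)
        log.info("called %d SA regions (threshold %.3f)", len(regions),
                 regions.threshold)
        rpath = run_dir / "sa_regions.bed"
        write_regions_bed(regions, rpath)
        manifest.add("regions", rpath)

        stage = "occupancy"
        occ_by_cond: Dict[str, OccupancyTable] = {}
        for cond in conditions:
            tables = [
                feature_occupancy(enr[(name, cond.condition)], layout,
                                  config.window, factor=name,
                                  condition=cond.condition)
                for name in factors]
            occ_by_cond[cond.condition] = OccupancyTable.concat(tables)
            p = run_dir / f"occ_{cond.condition}.tsv"
            occ_by_cond[cond.condition].to_tsv(p)
            manifest.add(f"occupancy:{cond.condition}", p)
        summaries = []
        for cls in ("promoter", "enhancer", "PRE", "origin", "random"):
            summaries.append(occupancy_summary(occ_by_cond["mock"], cls))
        spath = run_dir / "occupancy_summary.tsv"
        pd.concat(summaries, ignore_index=True).to_csv(spath, sep="\t",
                                                       index=False)
        manifest.add("occupancy_summary", spath)

        stage = "metaprofile"
        promoters = layout.by_class("promoter")
        origins = layout.by_class("origin")
        profiles = {}
        for name in factors:
            prof = meta_profile(enr[(name, "mock")], promoters,
                                config.flank, config.profile_bin)
            profiles[f"promoter:{name}"] = prof
            p = run_dir / f"profile_promoter_{name}.tsv"
            prof.to_tsv(p)
            manifest.add(f"profile:promoter:{name}", p)
        if len(origins):
            for name in factors:
                prof = meta_profile(enr[(name, "mock")], origins,
                                    config.origin_flank,
                                    config.origin_profile_bin)
                p = run_dir / f"profile_origin_{name}.tsv"
                prof.to_tsv(p)
                manifest.add(f"profile:origin:{name}", p)
        peaks = {k: peak_offset(v) for k, v in profiles.items()}

        stage = "classify"
        classification = classify_high_sa(promoters, regions, config.window)
        high_sa = classification.high_sa_subset(promoters)
        enhancers = layout.by_class("enhancer")
        transcripts = layout.by_class("transcript")
        extragenic = extragenic_enhancers(enhancers, transcripts,
                                          window=config.window)
        rep_scores = replication_scores(
            concat_feature_sets([promoters, enhancers, origins,
                                 layout.by_class("PRE"),
                                 layout.by_class("random")]), edu,
            config.window)
        rpath2 = run_dir / "replication_scores.tsv"
        rep_scores.to_tsv(rpath2)
        manifest.add("replication_scores", rpath2)
        cpath = run_dir / "class.json"
        cpath.write_text(json.dumps({
            "n_high": classification.n_high,
            "n_total": classification.n_total,
            "percent": classification.percentage,
            "n_extragenic_enhancers": len(extragenic),
            "n_enhancers": len(enhancers),
            "n_high_sa_used": len(high_sa),
            "peak_offsets": peaks,
        }, indent=2) + "\n")
        manifest.add("classification", cpath)

        stage = "compare_stats"
        if config.compare_depletion:
            depl_label = conditions[1].condition
            comparisons = []
            for name in factors:
                comparisons += [c.to_dict() for c in compare_all_classes(
                    occ_by_cond["mock"], occ_by_cond[depl_label], name,
                    ["promoter", "enhancer", "PRE", "origin"])]
            cmp_path = run_dir / "cmp.json"
            cmp_path.write_text(json.dumps(comparisons, indent=2) + "\n")
            manifest.add("comparisons", cmp_path)
    except (ValueError, KeyError) as exc:
        raise StageError(stage, str(exc)) from exc

    manifest.finished = time.time()
    mpath = run_dir / "manifest.json"
    manifest.write(mpath)
    log.info("pipeline complete: %s", mpath)
    return manifest
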