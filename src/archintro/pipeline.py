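"""End-to-end synthetic orchestration: simulate → filter → block → ILS →
affinity/tree → Tajima scan → machine-readable report.

The report JSON is deterministic for a fixed config (artifact file names
are relative, no timestamps are embedded), so identical config + seeds
yield byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from archintro import archaic_affinity as aff
from archintro import core_io, ld_blocks, selection, synthetic_data
from archintro.core_io import ARCHAIC, MODERN_CARRIER, MODERN_NONCARRIER
from archintro.ils import DEFAULT_BRANCH_ARCHAIC, DEFAULT_BRANCH_HUMAN, ils_probability

log = logging.getLogger("archintro")

SKIP_NO_BLOCK = "no divergent block found"


@dataclass
class RunConfig:
    simulation: synthetic_data.SimulationConfig = field(
        default_factory=synthetic_data.SimulationConfig
    )
    r2_threshold: float = 0.8
    max_window_bp: int = 1_000_000
    branch_human_gens: float = DEFAULT_BRANCH_HUMAN
    branch_archaic_gens: float = DEFAULT_BRANCH_ARCHAIC
    tajima_window: int = 10_000
    tajima_step: int = 100
    n_bootstrap: int = 100
    n_tree_noncarriers: int = 12
    tree_seed: int = 0
    outdir: str | Path = "archintro_run"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # annotate with the stage name
                raise StageError(name, exc) from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic analysis; returns the report dict and writes
    all artifacts (VCF, map, mask, truth, block/ILS summaries, Newick tree,
    sharing track, Tajima track, report.json) under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seeds": {
            "simulation": config.simulation.seed,
            "tree_bootstrap": config.tree_seed,
        },
        "config": {
            "r2_threshold": config.r2_threshold,
            "max_window_bp": config.max_window_bp,
            "branch_human_gens": config.branch_human_gens,
            "branch_archaic_gens": config.branch_archaic_gens,
            "tajima_window": config.tajima_window,
            "tajima_step": config.tajima_step,
            "n_bootstrap": config.n_bootstrap,
        },
        "artifacts": {},
        "stages": {},
    }

    sim = _simulate(config, outdir, report)
    panel = _filter(sim, report)
    block = _block_and_ils(config, sim, panel, report)
    _affinity(config, sim, panel, outdir, report)
    _tajima(config, sim, panel, outdir, report)
    _ = block

    report["artifacts"]["report"] = "report.json"
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


@_stage("simulate")
def _simulate(config: RunConfig, outdir: Path, report: dict):
    sim = synthetic_data.simulate_panel(config.simulation)
    labelled = sim.panel.with_groups(
        {h: MODERN_CARRIER for h in sim.truth.carrier_haplotypes}
    )
    sim = sim._replace(panel=labelled)
    core_io.write_vcf(sim.panel, outdir / "panel.vcf")
    core_io.write_genetic_map(sim.genetic_map, outdir / "map.tsv")
    core_io.write_mask(sim.mask, outdir / "mask.bed")
    synthetic_data.write_truth(sim.truth, outdir / "truth.tsv")
    report["artifacts"].update(
        {"vcf": "panel.vcf", "map": "map.tsv", "mask": "mask.bed", "truth": "truth.tsv"}
    )
    report["stages"]["simulate"] = {
        "n_haplotypes": sim.panel.n_haplotypes,
        "n_sites": sim.panel.n_sites,
        "n_carriers": len(sim.truth.carrier_haplotypes),
    }
    return sim


@_stage("filter")
def _filter(sim, report: dict):
    panel = core_io.filter_sites(sim.panel, sim.mask, drop_archaic_hets=True)
    report["stages"]["filter"] = {"n_sites_retained": panel.n_sites}
    return panel


def select_focal_site(panel) -> int | None:
    """Pick a focal variant: the site nearest the panel midpoint at which all
    modern carriers are derived and all modern noncarriers are ancestral.
    Returns its position, or None when no such site exists."""
    car = panel.indices_for(MODERN_CARRIER)
    non = panel.indices_for(MODERN_NONCARRIER)
    if car.size == 0 or non.size == 0 or panel.n_sites == 0:
        return None
    A = panel.alleles
    diagnostic = np.all(A[car, :] == 1, axis=0) & np.all(A[non, :] == 0, axis=0)
    idx = np.flatnonzero(diagnostic)
    if idx.size == 0:
        return None
    pos = panel.positions
    mid = (pos.min() + pos.max()) / 2
    best = idx[np.argmin(np.abs(pos[idx] - mid))]
    return int(pos[best])


@_stage("block_ils")
def _block_and_ils(config: RunConfig, sim, panel, report: dict):
    focal_pos = select_focal_site(panel)
    if focal_pos is None:
        report["stages"]["block"] = {"skipped": SKIP_NO_BLOCK}
        report["stages"]["ils"] = {"skipped": SKIP_NO_BLOCK}
        return None
    block = ld_blocks.call_block(
        panel, focal_pos, threshold=config.r2_threshold, max_window_bp=config.max_window_bp
    )
    length_cM = ld_blocks.block_genetic_length(block, sim.genetic_map)
    report["stages"]["block"] = block.to_dict()
    ils = ils_probability(
        length_cM,
        branch_human_gens=config.branch_human_gens,
        branch_archaic_gens=config.branch_archaic_gens,
    )
    report["stages"]["ils"] = ils.to_dict()
    return block


@_stage("affinity")
def _affinity(config: RunConfig, sim, panel, outdir: Path, report: dict):
    carriers = [
        h for h, g in zip(panel.haplotype_ids, panel.group_labels) if g == MODERN_CARRIER
    ]
    noncarriers = [
        h for h, g in zip(panel.haplotype_ids, panel.group_labels) if g == MODERN_NONCARRIER
    ]
    archaics = [h for h, g in zip(panel.haplotype_ids, panel.group_labels) if g == ARCHAIC]

    dm_all = aff.panel_distance_matrix(panel)
    dm_all.to_frame().to_csv(outdir / "distances.tsv", sep="\t")
    report["artifacts"]["distances"] = "distances.tsv"

    affinity: dict = {}
    if carriers:
        arch_rows = {h: panel.alleles[panel.haplotype_ids.index(h)] for h in archaics}
        nearest = {}
        for h in carriers:
            res = aff.nearest_archaic(panel.alleles[panel.haplotype_ids.index(h)], arch_rows)
            nearest[h] = {"labels": list(res.labels), "count": res.count}
        affinity["nearest_archaic"] = nearest

        track = aff.allele_sharing_track(panel, carriers, noncarriers, archaics[0])
        track.to_csv(outdir / "sharing.tsv", sep="\t", index=False)
        report["artifacts"]["sharing"] = "sharing.tsv"

    # tree on a reduced taxon set: deduped carriers, a capped number of
    # noncarriers, all archaics, rooted on the inferred ancestral sequence
    subset_ids = carriers + noncarriers[: 2 * config.n_tree_noncarriers] + archaics
    sub = panel.subset_haplotypes(subset_ids)
    sub = aff.panel_with_ancestral(sub)
    unique, multiplicity = aff.dedup_haplotypes(sub)
    if unique.n_haplotypes >= 3 and unique.n_sites > 0:
        dm = aff.panel_distance_matrix(unique).per_site(unique.n_sites)
        tree = aff.nj_tree(
            dm,
            outgroup_label="ancestral",
            bootstrap=config.n_bootstrap,
            seed=config.tree_seed,
            alleles=unique.alleles,
        )
        (outdir / "tree.nwk").write_text(tree.newick + "\n")
        report["artifacts"]["tree"] = "tree.nwk"
        affinity["tree"] = {
            "n_taxa": unique.n_haplotypes,
            "n_bootstrap": config.n_bootstrap,
            "multiplicity": {k: v for k, v in sorted(multiplicity.items())},
        }
        if carriers:
            kept_carriers = {
                h for h in unique.haplotype_ids if h in set(carriers)
            }
            clade = kept_carriers | {
                h for h in unique.haplotype_ids if h in set(archaics)
            }
            support = tree.clade_support(clade)
            affinity["tree"]["carrier_archaic_clade_support"] = support
    report["stages"]["affinity"] = affinity


@_stage("tajima")
def _tajima(config: RunConfig, sim, panel, outdir: Path, report: dict):
    moderns = panel.subset_haplotypes(
        [h for h, g in zip(panel.haplotype_ids, panel.group_labels)
         if g in (MODERN_CARRIER, MODERN_NONCARRIER)]
    )
    start = config.simulation.region_start
    end = start + config.simulation.region_length - 1
    track = selection.sliding_tajima(
        moderns, region=(start, end), window=config.tajima_window, step=config.tajima_step
    )
    track.to_frame().to_csv(outdir / "tajima.tsv", sep="\t", index=False)
    report["artifacts"]["tajima"] = "tajima.tsv"
    vals = track.values[~np.isnan(track.values)]
    report["stages"]["tajima"] = {
        "n_positions": int(track.positions.size),
        "mean_D": float(vals.mean()) if vals.size else None,
        "min_D": float(vals.min()) if vals.size else None,
    }
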