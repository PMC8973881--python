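"""Orchestration of the full study-shaped workflow.

Stages run in dependency order: simulate (or load) paired native/WGA data,
aggregate per-site kinetics, profile and compare motifs, detect extreme
loci, test feature enrichment, and compute concordance tables.  A run is
driven by a single JSON configuration (versioned schema) and is
deterministic under its seeds: re-running an identical configuration
reproduces byte-identical outputs.

Focal positions are 1-based in configuration files and on the command line,
matching the "2nd nucleotide of GATC" phrasing used in the field; they are
converted to 0-based offsets internally.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import concord, enrich, extremes, io, kinsim, motifkin, siteagg
from .util import spawn_seed

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_THRESHOLDS = {
    "min_valid": 25,
    "pct": 1.0,
    "flank": 10,
    "window": 41,
    "min_mapq": 127.0,
    "alpha": 1e-3,
    "fold_threshold": 2.0,
    "n_tests": None,
    "coverage_grid": [25, 30, 35],
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def load_config(path) -> dict:
    with open(path) as fh:
        config = json.load(fh)
    return validate_config(config)


def validate_config(config: dict) -> dict:
    if config.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported config schema_version {config.get('schema_version')!r}")
    cfg = dict(config)
    thresholds = dict(DEFAULT_THRESHOLDS)
    thresholds.update(cfg.get("thresholds", {}))
    if not 0 < thresholds["pct"] < 50:
        raise ValueError("pct must be in (0, 50)")
    if thresholds["min_valid"] < 1:
        raise ValueError("min_valid must be >= 1")
    if thresholds["window"] % 2 == 0:
        raise ValueError("window must be odd")
    cfg["thresholds"] = thresholds
    cfg.setdefault("motifs", [])
    cfg.setdefault("annotations", None)
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' or 'inputs' section")
    return cfg


def _plant_specs(sim_cfg: dict) -> list[kinsim.PlantSpec]:
    specs = []
    for p in sim_cfg.get("plants", []):
        specs.append(kinsim.PlantSpec(
            motif=p["motif"],
            focal_offset=int(p["focal"]) - 1,
            count=int(p["count"]),
            modification_multiplier=float(p.get("modification_multiplier", 1.0)),
            context_multipliers={int(k): float(v) for k, v in
                                 p.get("context_multipliers", {}).items()},
            strand=p.get("strand", "+")))
    return specs


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the workflow described by *config*; returns the summary dict.

    Outputs land in *outdir* with deterministic names; the summary is also
    written there as ``summary.json``.  A stage failure raises
    :class:`StageError` naming the stage; outputs of completed stages are
    retained alongside a ``FAILED`` marker file.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    th = config["thresholds"]
    base_seed = int(config.get("seed", 0) if seed is None else seed)
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": base_seed,
                     "stages": {}}
    stage = "setup"
    try:
        # --- simulate or load -------------------------------------------
        stage = "simulate"
        genome, planted, native_sites, wga_sites = _stage_data(
            config, outdir, base_seed, th, summary)

        # --- motifs ------------------------------------------------------
        stage = "motifs"
        motif_rows = []
        profiles = {}
        for entry in config["motifs"]:
            iupac = entry["iupac"].upper()
            focal = int(entry["focal"]) - 1
            occ = motifkin.scan_motif(genome, iupac)
            profile = motifkin.motif_profile(wga_sites, occ, iupac,
                                             flank=th["flank"])
            profiles[iupac] = profile
            roi = motifkin.ratio_of_increase(profile, wga_sites, focal)[0]
            call = motifkin.call_modification(
                native_sites, wga_sites, genome, iupac, focal,
                fold_threshold=th["fold_threshold"], alpha=th["alpha"])
            profile.table.to_csv(outdir / f"profile_{iupac}.tsv", sep="\t",
                                 index=False, float_format="%.6g")
            motif_rows.append({
                "motif": iupac, "focal": focal + 1,
                "n_occurrences": int(profile.n_occurrences),
                "mean_motif": roi.mean_ipd_motif,
                "mean_genome": roi.mean_ipd_genome,
                "ratio_of_increase": roi.ratio_of_increase,
                "ranksum_p": roi.ranksum_p,
                "native_wga_fold": call.stat.native_wga_fold,
                "native_wga_p": call.stat.native_wga_p,
                "modified": bool(call.modified),
            })
        if motif_rows:
            pd.DataFrame(motif_rows).to_csv(
                outdir / "motif_comparison.tsv", sep="\t", index=False,
                float_format="%.6g")
        summary["stages"]["motifs"] = {
            "n_motifs": len(motif_rows),
            "calls": {r["motif"]: {"fold": _round(r["native_wga_fold"]),
                                   "p": _format_p(r["native_wga_p"]),
                                   "modified": r["modified"]}
                      for r in motif_rows},
        }

        # --- extremes ----------------------------------------------------
        stage = "extremes"
        loci = extremes.detect_extreme_loci(wga_sites, pct=th["pct"])
        io.write_bed(extremes.loci_bed_frame(loci), outdir / "extreme_loci.bed")
        records = extremes.export_windows(loci, genome, width=th["window"])
        from Bio import SeqIO
        SeqIO.write(records, str(outdir / "extreme_windows.fa"), "fasta")
        extremeness = {}
        if profiles:
            n_tests = th["n_tests"] or extremes.bonferroni_family_size(
                [len(m) for m in profiles], flank=th["flank"])
            for iupac, profile in profiles.items():
                res = extremes.test_motif_extremeness(
                    profile, wga_sites, n_tests=n_tests, alpha=0.05)
                res.to_csv(outdir / f"extremeness_{iupac}.tsv", sep="\t",
                           index=False, float_format="%.6g")
                extremeness[iupac] = int(res["significant"].sum())
        summary["stages"]["extremes"] = {
            "n_high": int(len(loci.high)), "n_low": int(len(loci.low)),
            "hi_threshold": _round(loci.hi_threshold),
            "lo_threshold": _round(loci.lo_threshold),
            "significant_positions": extremeness,
        }

        # --- enrichment (optional) --------------------------------------
        stage = "enrich"
        if config["annotations"]:
            ann_path = Path(config["annotations"])
            if ann_path.suffix in {".gff", ".gff3"}:
                table = io.read_gff3(ann_path)
                regions = enrich.regions_from_table(table, "type")
            else:
                table = io.read_bed(ann_path)
                regions = enrich.regions_from_table(table, "name")
            result = enrich.region_enrichment(loci, regions, wga_sites)
            result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.6g")
            summary["stages"]["enrich"] = {
                "n_labels": int(result["label"].nunique()),
                "n_significant_q01": int((result["q"] < 0.001).sum()),
            }

        # --- concordance -------------------------------------------------
        stage = "concord"
        ratio_table = concord.replicate_ratio_by_coverage(
            native_sites, wga_sites, th["coverage_grid"])
        ratio_table.to_csv(outdir / "replicate_ratio.tsv", sep="\t",
                           index=False, float_format="%.6g")
        summary["stages"]["concord"] = {
            "coverage_grid": [int(c) for c in th["coverage_grid"]],
            "log2_ratio_sd": [_round(v) for v in ratio_table["sd"]],
        }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _stage_data(config, outdir, base_seed, th, summary):
    if "simulate" in config:
        sim = config["simulate"]
        model = kinsim.KineticsModelConfig(
            log_sigma=float(sim.get("log_sigma", 0.5)),
            coverage_per_strand=float(sim.get("coverage_per_strand", 30.0)),
            outlier_prob=float(sim.get("outlier_prob", 0.001)),
            outlier_scale=float(sim.get("outlier_scale", 50.0)),
            neighbor_mismatch_prob=float(
                sim.get("neighbor_mismatch_prob", 0.01)),
            seed=base_seed)
        genome, planted = kinsim.generate_genome(
            length=int(sim["length"]),
            gc_fraction=float(sim.get("gc_fraction", 0.36)),
            plant_specs=_plant_specs(sim),
            seed=spawn_seed(base_seed, 1))
        # enzyme-style plants modify every occurrence of their motif
        # (planting above only guarantees the occurrences exist)
        for p in sim.get("plants", []):
            if not p.get("modify_all_occurrences", False):
                continue
            iupac = p["motif"].upper()
            planted = [s for s in planted if s.motif_id != iupac]
            occ = motifkin.scan_motif(genome, iupac)
            planted.extend(kinsim.modification_sites_from_occurrences(
                occ, iupac, int(p["focal"]) - 1,
                float(p.get("modification_multiplier", 1.0)),
                {int(k): float(v) for k, v in
                 p.get("context_multipliers", {}).items()}))
        genome.to_fasta(outdir / "genome.fa")
        if planted:
            io.write_bed(kinsim.truth_bed_frame(planted),
                         outdir / "planted_truth.bed")
        native_obs = kinsim.simulate_reads(genome, planted, model,
                                           mode="native",
                                           seed=spawn_seed(base_seed, 2))
        wga_obs = kinsim.simulate_reads(genome, planted, model, mode="wga",
                                        seed=spawn_seed(base_seed, 3))
        if sim.get("write_reads", False):
            io.write_reads_tsv(native_obs, outdir / "native_reads.tsv")
            io.write_reads_tsv(wga_obs, outdir / "wga_reads.tsv")
        native_sites = siteagg.aggregate_sites(native_obs,
                                               min_valid=th["min_valid"])
        wga_sites = siteagg.aggregate_sites(wga_obs,
                                            min_valid=th["min_valid"])
        summary["stages"]["simulate"] = {
            "genome_length": len(genome), "n_planted": len(planted),
            "n_native_observations": int(len(native_obs)),
            "n_wga_observations": int(len(wga_obs)),
        }
    else:
        inputs = config["inputs"]
        genome = kinsim.ReferenceGenome.from_fasta(inputs["genome"])
        planted = []
        native_sites = io.read_sites_csv(inputs["native_sites"])
        wga_sites = io.read_sites_csv(inputs["wga_sites"])
    io.write_sites_csv(native_sites, outdir / "native_sites.csv")
    io.write_sites_csv(wga_sites, outdir / "wga_sites.csv")
    summary["stages"]["aggregate"] = {
        "n_native_sites": int(len(native_sites)),
        "n_wga_sites": int(len(wga_sites)),
    }
    return genome, planted, native_sites, wga_sites


def _round(v, digits: int = 6):
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return None
    return round(float(v), digits)


def _format_p(p):
    if p is None or not np.isfinite(p):
        return None
    return float(f"{p:.3e}")
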