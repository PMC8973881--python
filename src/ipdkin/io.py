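"""Readers and writers for the on-disk formats the package exchanges.

Conventions: in memory every coordinate is 0-based and strands are '+'/'-'.
Each format states its own convention below:

* per-read IPD TSV — ``read_id, contig, pos, strand, ref_base, ipd,
  neighbors_match``; ``pos`` 1-based; ``neighbors_match`` 0/1; tab-separated.
* per-site kinetics CSV (kineticsTools-style) — ``refName, tpl, strand, base,
  tMean, tErr, coverage[, modelPrediction, ipdRatio]``; ``tpl`` 1-based;
  strand 0=forward, 1=reverse; ``refName`` quoted.
* BED — 0-based half-open.
* GFF3 — 1-based closed, converted on read.
"""

from __future__ import annotations

import csv
import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

READS_TSV_COLUMNS = ["read_id", "contig", "pos", "strand", "ref_base", "ipd",
                     "neighbors_match"]

SITES_CSV_COLUMNS = ["refName", "tpl", "strand", "base", "tMean", "tErr",
                     "coverage"]


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(contigs: Mapping[str, str], path: str | os.PathLike) -> None:
    """Write contigs to FASTA with 60-column line wrapping."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Per-read IPD observations

def write_reads_tsv(observations: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write read-level IPD observations (pos 1-based, neighbors_match 0/1)."""
    out = observations.loc[:, READS_TSV_COLUMNS].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    out["neighbors_match"] = out["neighbors_match"].astype(np.int8)
    out.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-read IPD TSV back into 0-based in-memory form."""
    obs = pd.read_csv(
        path, sep="\t",
        dtype={"read_id": str, "contig": str, "strand": str, "ref_base": str},
    )
    missing = set(READS_TSV_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    obs["pos"] = obs["pos"].astype(np.int64) - 1
    obs["neighbors_match"] = obs["neighbors_match"].astype(bool)
    return obs[READS_TSV_COLUMNS]


# ---------------------------------------------------------------------------
# Per-site kinetics CSV (kineticsTools-style dialect)

def write_sites_csv(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write per-site kinetics in the kineticsTools-style CSV dialect.

    Expects in-memory columns contig, pos, strand, ref_base, mean_ipd,
    ipd_err, valid_count and optionally model_prediction / ipd_ratio.
    """
    out = pd.DataFrame({
        "refName": sites["contig"].astype(str),
        "tpl": sites["pos"].astype(np.int64) + 1,
        "strand": (sites["strand"] == "-").astype(np.int8),
        "base": sites["ref_base"].astype(str),
        "tMean": sites["mean_ipd"].astype(float),
        "tErr": sites.get("ipd_err", pd.Series(0.0, index=sites.index)).astype(float),
        "coverage": sites["valid_count"].astype(np.int64),
    })
    if "model_prediction" in sites.columns:
        out["modelPrediction"] = sites["model_prediction"].astype(float)
        out["ipdRatio"] = out["tMean"] / out["modelPrediction"]
    out.to_csv(path, index=False, quoting=csv.QUOTE_NONNUMERIC,
               quotechar='"', columns=out.columns)


def read_sites_csv(path: str | os.PathLike) -> pd.DataFrame:
    """Read the per-site kinetics CSV into in-memory column names."""
    raw = pd.read_csv(path)
    missing = set(SITES_CSV_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    sites = pd.DataFrame({
        "contig": raw["refName"].astype(str),
        "pos": raw["tpl"].astype(np.int64) - 1,
        "strand": np.where(raw["strand"].astype(int) == 1, "-", "+"),
        "ref_base": raw["base"].astype(str),
        "mean_ipd": raw["tMean"].astype(float),
        "ipd_err": raw["tErr"].astype(float),
        "valid_count": raw["coverage"].astype(np.int64),
    })
    if "modelPrediction" in raw.columns:
        sites["model_prediction"] = raw["modelPrediction"].astype(float)
    return sites


# ---------------------------------------------------------------------------
# BED / GFF3

def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a BED6 table; expects contig, start, end, name, score, strand."""
    intervals.to_csv(path, sep="\t", header=False, index=False,
                     columns=["contig", "start", "end", "name", "score", "strand"])


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED (3+ columns) into contig/start/end[/name/score/strand]."""
    names = ["contig", "start", "end", "name", "score", "strand"]
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      dtype={0: str})
    bed.columns = names[:bed.shape[1]] + list(bed.columns[len(names):])
    bed["start"] = bed["start"].astype(np.int64)
    bed["end"] = bed["end"].astype(np.int64)
    return bed


GFF3_COLUMNS = ["contig", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes"]


def read_gff3(path: str | os.PathLike,
              feature_types: Iterable[str] | None = None) -> pd.DataFrame:
    """Read GFF3 features, converting 1-based closed to 0-based half-open.

    Returns contig/type/start/end/strand; ``type`` is the feature label
    unless a subset is requested via *feature_types*.
    """
    gff = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=GFF3_COLUMNS, dtype={"contig": str})
    if feature_types is not None:
        gff = gff[gff["type"].isin(set(feature_types))]
    out = gff[["contig", "type", "start", "end", "strand"]].copy()
    out["start"] = out["start"].astype(np.int64) - 1
    out["end"] = out["end"].astype(np.int64)
    return out.reset_index(drop=True)


def read_motif_list(path: str | os.PathLike) -> list[tuple[str, int | None]]:
    """Parse a motif-list text file: one IUPAC string plus optional 0-based
    focal offset per line; '#' starts a comment."""
    motifs: list[tuple[str, int | None]] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            focal = int(fields[1]) if len(fields) > 1 else None
            motifs.append((fields[0].upper(), focal))
    return motifs
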