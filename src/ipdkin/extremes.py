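"""Extreme-IPD loci: top/bottom percentile detection, window export for
external motif discovery, and Bonferroni-corrected motif extremeness tests.

Thresholds use the nearest-rank order statistic with strict exceedance, so
on tie-free data exactly floor(pct% * N) sites are flagged on each side and
ties are never flagged.  Thresholds are computed over the pooled
distribution of all bases and strands by default; per-base thresholding is
available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinsim import ReferenceGenome
from .motifkin import MotifProfile, wilcoxon_ranksum
from .util import revcomp


@dataclass
class ExtremeLociSet:
    """Sites in the top/bottom *pct* percent of the site-mean distribution.

    ``loci`` has columns contig, pos, strand, class ('high'/'low') and
    mean_ipd.  With per-base thresholds, ``hi_threshold``/``lo_threshold``
    hold the pooled values for reference only.
    """

    pct: float
    hi_threshold: float
    lo_threshold: float
    loci: pd.DataFrame

    @property
    def high(self) -> pd.DataFrame:
        return self.loci[self.loci["class"] == "high"]

    @property
    def low(self) -> pd.DataFrame:
        return self.loci[self.loci["class"] == "low"]


def _thresholds(values: np.ndarray, pct: float) -> tuple[float, float]:
    n = values.size
    k = math.ceil((1.0 - pct / 100.0) * n)
    srt = np.sort(values)
    return float(srt[k - 1]), float(srt[n - k])


def detect_extreme_loci(
    sites: pd.DataFrame,
    pct: float = 1.0,
    per_base: bool = False,
) -> ExtremeLociSet:
    """Flag sites whose mean IPD is above the top-*pct* or below the
    bottom-*pct* threshold of the site-mean distribution.

    The high threshold is the k-th smallest site mean with
    k = ceil((1 - pct/100) * N); high loci lie strictly above it, and the
    low side is symmetric.  Under ties the rule is deterministic and tied
    values are never flagged.
    """
    if not 0.0 < pct < 50.0:
        raise ValueError("pct must be in (0, 50)")
    if not len(sites):
        raise ValueError("no sites to threshold")
    vals = sites["mean_ipd"].to_numpy()
    hi_all, lo_all = _thresholds(vals, pct)
    keep_cols = ["contig", "pos", "strand", "ref_base", "mean_ipd"]
    parts: list[pd.DataFrame] = []
    if per_base:
        for _, grp in sites.groupby("ref_base"):
            hi, lo = _thresholds(grp["mean_ipd"].to_numpy(), pct)
            parts.append(_classify(grp[keep_cols], hi, lo))
    else:
        parts.append(_classify(sites[keep_cols], hi_all, lo_all))
    loci = (pd.concat(parts, ignore_index=True)
            .sort_values(["contig", "pos", "strand"]).reset_index(drop=True))
    return ExtremeLociSet(pct=pct, hi_threshold=hi_all, lo_threshold=lo_all,
                          loci=loci)


def _classify(sites: pd.DataFrame, hi: float, lo: float) -> pd.DataFrame:
    vals = sites["mean_ipd"].to_numpy()
    out = sites.copy()
    out["class"] = np.where(vals > hi, "high",
                            np.where(vals < lo, "low", ""))
    return out[out["class"] != ""]


def export_windows(
    loci: ExtremeLociSet | pd.DataFrame,
    genome: ReferenceGenome,
    width: int = 41,
) -> list[SeqRecord]:
    """Extract sequence windows of *width* bases centred on each locus.

    Record ids encode ``contig:pos:strand:class`` (pos 0-based).  Windows
    clipped at a contig end carry ``clipped`` in the description.
    Minus-strand loci yield the reverse complement of the window.
    """
    if width % 2 == 0:
        raise ValueError("width must be odd so the centre base is defined")
    table = loci.loci if isinstance(loci, ExtremeLociSet) else loci
    if "class" in table.columns:
        table = table.rename(columns={"class": "cls"})
    elif "cls" not in table.columns:
        table = table.assign(cls="")
    half = width // 2
    records: list[SeqRecord] = []
    for row in table.itertuples(index=False):
        seq = genome.contigs[row.contig]
        lo = max(0, row.pos - half)
        hi = min(len(seq), row.pos + half + 1)
        window = seq[lo:hi]
        if row.strand == "-":
            window = revcomp(window)
        clipped = len(window) < width
        records.append(SeqRecord(
            Seq(window),
            id=f"{row.contig}:{row.pos}:{row.strand}:{row.cls}",
            description="clipped" if clipped else ""))
    return records


def loci_bed_frame(loci: ExtremeLociSet) -> pd.DataFrame:
    """BED6 rows for extreme loci; score = round(1000 * log2 mean IPD)."""
    t = loci.loci
    return pd.DataFrame({
        "contig": t["contig"],
        "start": t["pos"].astype(np.int64),
        "end": t["pos"].astype(np.int64) + 1,
        "name": t["class"],
        "score": np.round(1000.0 * np.log2(t["mean_ipd"])).astype(np.int64),
        "strand": t["strand"],
    })


def bonferroni_family_size(motif_lengths, flank: int = 10) -> int:
    """Default Bonferroni family: sum over motifs of (length + 2 * flank)."""
    return int(sum(m + 2 * flank for m in motif_lengths))


def test_motif_extremeness(
    profile: MotifProfile,
    sites: pd.DataFrame,
    n_tests: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bonferroni-adjusted rank-sum test of each motif position against the
    genome-wide same-base IPD distribution.

    Per relative position, site means are compared with all genome sites of
    the same base (mixed-base flank positions use the smallest per-base p).
    Raw p-values are multiplied by *n_tests* and capped at 1.  Positions
    with no usable sites report missing p.
    """
    n_positions = len(profile.table)
    if n_tests < n_positions:
        raise ValueError(
            f"n_tests ({n_tests}) smaller than positions tested ({n_positions})")
    rows = []
    for rel in profile.table["rel_pos"]:
        vals = profile.values_at(int(rel))
        if not len(vals):
            rows.append((int(rel), 0, np.nan, np.nan, False))
            continue
        p_min = np.inf
        for base, grp in vals.groupby("ref_base"):
            genome_vals = sites.loc[sites["ref_base"] == base,
                                    "mean_ipd"].to_numpy()
            if genome_vals.size == 0:
                continue
            _, p = wilcoxon_ranksum(grp["mean_ipd"].to_numpy(), genome_vals)
            p_min = min(p_min, p)
        if not np.isfinite(p_min):
            rows.append((int(rel), len(vals), np.nan, np.nan, False))
            continue
        adj = min(1.0, p_min * n_tests)
        rows.append((int(rel), len(vals), p_min, adj, adj < alpha))
    return pd.DataFrame(rows, columns=["rel_pos", "n", "raw_p", "adj_p",
                                       "significant"])
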