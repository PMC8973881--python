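"""Motif kinetics: IUPAC scanning, per-position IPD profiles with flanks,
the ratio-of-increase statistic, rank-sum testing and the native-vs-WGA
modification caller.

The central contrast is between two baselines for a motif's focal base:

* ratio of increase — mean IPD of the focal base over motif occurrences
  divided by the genome-wide mean IPD of that same base.  Sequence context
  alone moves this ratio, in native and WGA material alike.
* native/WGA fold — mean native IPD over a locus set divided by the mean
  WGA IPD at the same loci.  Only a covalent modification moves this fold,
  because amplification erases modifications while leaving sequence context
  intact.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinsim import ReferenceGenome
from .siteagg import SITE_KEY
from .util import iupac_regex, revcomp, validate_iupac

logger = logging.getLogger(__name__)

#: Largest smaller-sample size for which the rank-sum p-value is computed by
#: exact enumeration (tie-free samples only).
EXACT_RANKSUM_MAX_N = 8


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC motif with one or more 0-based focal offsets."""

    iupac: str
    focal_offsets: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        validate_iupac(self.iupac)
        if any(not 0 <= f < len(self.iupac) for f in self.focal_offsets):
            raise ValueError("focal offset outside motif")

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass
class MotifProfile:
    """Per-position IPD summary over motif occurrences.

    ``table`` has one row per relative position in [-flank, len+flank) with
    mean_ipd, se (standard error), and n_sites.  ``site_values`` keeps the
    underlying per-site means (rel_pos, ref_base, mean_ipd) for downstream
    rank-sum tests.  Relative positions read 5'->3' along the motif strand.
    """

    motif: str
    flank: int
    n_occurrences: int
    table: pd.DataFrame
    site_values: pd.DataFrame = field(repr=False)

    def values_at(self, rel_pos: int) -> pd.DataFrame:
        return self.site_values[self.site_values["rel_pos"] == rel_pos]


@dataclass(frozen=True)
class ComparisonStat:
    """Focal-base statistics for a motif or locus-set comparison."""

    focal_base: str
    mean_ipd_motif: float
    mean_ipd_genome: float
    ratio_of_increase: float
    ranksum_p: float
    n_motif: int
    n_genome: int
    native_wga_fold: float | None = None
    native_wga_p: float | None = None


def scan_motif(genome: ReferenceGenome, motif: MotifSpec | str) -> pd.DataFrame:
    """Find all occurrences of a degenerate motif on both strands.

    Overlapping matches are all reported.  A window matching on the plus
    strand is reported with strand '+'; a window whose reverse complement
    matches the motif is reported with strand '-' (its ``start`` stays in
    plus-strand coordinates).  Palindromic motifs therefore yield both.
    """
    iupac = motif.iupac if isinstance(motif, MotifSpec) else motif
    fwd = re.compile(f"(?=({iupac_regex(iupac)}))")
    rev = re.compile(f"(?=({iupac_regex(revcomp(iupac))}))")
    rows: list[tuple[str, int, str]] = []
    for contig, seq in genome.contigs.items():
        rows.extend((contig, m.start(), "+") for m in fwd.finditer(seq))
        rows.extend((contig, m.start(), "-") for m in rev.finditer(seq))
    occ = pd.DataFrame(rows, columns=["contig", "start", "strand"])
    return occ.sort_values(["contig", "start", "strand"]).reset_index(drop=True)


def motif_profile(
    sites: pd.DataFrame,
    occurrences: pd.DataFrame,
    motif: MotifSpec | str,
    flank: int = 10,
) -> MotifProfile:
    """Aggregate site kinetics into a per-position profile around a motif.

    For each occurrence, relative positions are read 5'->3' along the motif
    strand and the site value used is the one on that same strand; sites
    removed by the coverage filter are skipped.  Occurrences whose flanks
    run off a contig simply contribute nothing at those positions.
    """
    iupac = motif.iupac if isinstance(motif, MotifSpec) else motif
    m = len(iupac)
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if not len(occurrences):
        raise ValueError(f"no occurrences of motif {iupac!r}")
    rels = np.arange(-flank, m + flank, dtype=np.int64)
    start = np.repeat(occurrences["start"].to_numpy(np.int64), rels.size)
    strand = np.repeat(occurrences["strand"].to_numpy(), rels.size)
    contig = np.repeat(occurrences["contig"].to_numpy(), rels.size)
    rel = np.tile(rels, len(occurrences))
    pos = np.where(strand == "+", start + rel, start + (m - 1) - rel)
    long = pd.DataFrame({"contig": contig, "pos": pos, "strand": strand,
                         "rel_pos": rel})
    merged = long.merge(
        sites[SITE_KEY + ["ref_base", "mean_ipd"]], on=SITE_KEY, how="inner")
    if not len(merged):
        raise ValueError(
            f"no site kinetics available at any position of motif {iupac!r}")
    grp = (merged.groupby("rel_pos", as_index=False)["mean_ipd"]
           .agg(mean_ipd="mean", sd="std", n_sites="size"))
    grp["se"] = np.where(grp["n_sites"] > 1,
                         grp["sd"] / np.sqrt(grp["n_sites"]), 0.0)
    table = (grp[["rel_pos", "mean_ipd", "se", "n_sites"]]
             .set_index("rel_pos").reindex(rels).reset_index())
    table["n_sites"] = table["n_sites"].fillna(0).astype(np.int64)
    return MotifProfile(
        motif=iupac, flank=flank, n_occurrences=len(occurrences),
        table=table,
        site_values=merged[["rel_pos", "ref_base", "mean_ipd"]])


def wilcoxon_ranksum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sample rank-sum test with midranks for ties.

    Returns (W, p) where W is the rank sum of *x* in the pooled sample.
    With ``method="auto"`` the two-sided p-value is exact (full enumeration
    of rank assignments) when the smaller sample has at most
    ``EXACT_RANKSUM_MAX_N`` values and there are no ties; otherwise a normal
    approximation with tie-corrected variance and continuity correction is
    used.  ``method`` may force ``"exact"`` (tie-free input required) or
    ``"normal"``.
    """
    if method not in {"auto", "exact", "normal"}:
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:x.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (method == "exact"
                 or (method == "auto"
                     and min(x.size, y.size) <= EXACT_RANKSUM_MAX_N
                     and not has_ties))
    if use_exact:
        if has_ties:
            raise ValueError("exact enumeration requires tie-free samples")
        p = float(stats.mannwhitneyu(x, y, method="exact",
                                     alternative="two-sided").pvalue)
        return w, p
    n1, n2 = x.size, y.size
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    mu = n1 * (n + 1) / 2.0
    d = w - mu
    if d == 0:
        return w, 1.0
    z = (abs(d) - 0.5) / np.sqrt(var)  # continuity correction
    sf = float(stats.norm.sf(z))
    if not has_ties:
        # Edgeworth kurtosis term; the exact fourth cumulant of the
        # tie-free rank sum is -n1*n2*(n+1)*(n1^2+n2^2+n1*n2+n)/120
        kappa4 = -n1 * n2 * (n + 1) * (n1 * n1 + n2 * n2 + n1 * n2 + n) / 120.0
        gamma2 = kappa4 / (var * var)
        sf += gamma2 / 24.0 * (z ** 3 - 3.0 * z) * float(stats.norm.pdf(z))
    p = min(1.0, max(0.0, 2.0 * sf))
    return w, p


def ratio_of_increase(
    profile: MotifProfile,
    sites: pd.DataFrame,
    focal_offset: int,
) -> list[ComparisonStat]:
    """Ratio of the mean focal IPD over occurrences to the genome-wide mean
    IPD of the same base, with a rank-sum p against all same-base sites.

    A degenerate focal position yields one entry per resolved base plus a
    pooled entry (focal_base 'N'); a concrete focal position yields one.
    """
    focal = profile.values_at(focal_offset)
    if not len(focal):
        raise ValueError(f"no site kinetics at focal offset {focal_offset}")
    out: list[ComparisonStat] = []
    bases = sorted(focal["ref_base"].unique())
    groups = [(b, focal.loc[focal["ref_base"] == b, "mean_ipd"].to_numpy())
              for b in bases]
    if len(bases) > 1:
        groups.append(("N", focal["mean_ipd"].to_numpy()))
    for base, vals in groups:
        if base == "N":
            genome_vals = sites.loc[sites["ref_base"].isin(bases),
                                    "mean_ipd"].to_numpy()
        else:
            genome_vals = sites.loc[sites["ref_base"] == base,
                                    "mean_ipd"].to_numpy()
        if genome_vals.size == 0:
            raise ValueError(f"no genome-wide sites with base {base!r}")
        mean_motif = float(vals.mean())
        mean_genome = float(genome_vals.mean())
        _, p = wilcoxon_ranksum(vals, genome_vals)
        out.append(ComparisonStat(
            focal_base=base, mean_ipd_motif=mean_motif,
            mean_ipd_genome=mean_genome,
            ratio_of_increase=mean_motif / mean_genome,
            ranksum_p=p, n_motif=int(vals.size), n_genome=int(genome_vals.size)))
    return out


def compare_native_wga(
    native_sites: pd.DataFrame,
    wga_sites: pd.DataFrame,
    loci: pd.DataFrame,
) -> ComparisonStat:
    """Mean-IPD fold and rank-sum p between native and WGA samples at loci.

    *loci* is a DataFrame with contig, pos, strand — either focal positions
    from :func:`scan_motif` or an explicit list (e.g. previously called
    modification sites).  Loci missing from either table are skipped and
    counted in the log.
    """
    loci = loci[SITE_KEY].drop_duplicates()
    nat = loci.merge(native_sites[SITE_KEY + ["ref_base", "mean_ipd"]],
                     on=SITE_KEY)
    both = nat.merge(wga_sites[SITE_KEY + ["mean_ipd"]], on=SITE_KEY,
                     suffixes=("_native", "_wga"))
    skipped = len(loci) - len(both)
    if not len(both):
        raise ValueError("no loci shared between the native and WGA tables")
    if skipped:
        logger.info("compare_native_wga: %d/%d loci missing from one table",
                    skipped, len(loci))
    nat_vals = both["mean_ipd_native"].to_numpy()
    wga_vals = both["mean_ipd_wga"].to_numpy()
    fold = float(nat_vals.mean() / wga_vals.mean())
    _, p = wilcoxon_ranksum(nat_vals, wga_vals)
    base = both["ref_base"].mode().iat[0]
    return ComparisonStat(
        focal_base=str(base), mean_ipd_motif=float(nat_vals.mean()),
        mean_ipd_genome=float(wga_vals.mean()), ratio_of_increase=fold,
        ranksum_p=p, n_motif=len(both), n_genome=len(both),
        native_wga_fold=fold, native_wga_p=p)


def kmer_focal_table(
    sites: pd.DataFrame,
    genome: ReferenceGenome,
    k: int,
    focal_index: int,
    focal_base: str,
) -> pd.DataFrame:
    """Mean focal IPD for every k-mer carrying *focal_base* at *focal_index*.

    Both strands contribute: a minus-strand site's context is the reverse
    complement of the plus-strand window around it.  All 4**(k-1) k-mers
    with the required focal base are enumerated; absent ones get n = 0.
    """
    if not 0 <= focal_index < k:
        raise ValueError("focal_index must satisfy 0 <= focal_index < k")
    if focal_base not in "ACGT":
        raise ValueError(f"focal_base must be concrete, got {focal_base!r}")
    sel = sites[sites["ref_base"] == focal_base]
    kmers: list[str] = []
    vals: list[float] = []
    for contig, grp in sel.groupby("contig", sort=False):
        seq = genome.contigs[contig]
        L = len(seq)
        for pos, strand, mean_ipd in zip(grp["pos"].to_numpy(),
                                         grp["strand"].to_numpy(),
                                         grp["mean_ipd"].to_numpy()):
            if strand == "+":
                s = pos - focal_index
                if s < 0 or s + k > L:
                    continue
                kmer = seq[s:s + k]
            else:
                s = pos - (k - 1 - focal_index)
                if s < 0 or s + k > L:
                    continue
                kmer = revcomp(seq[s:s + k])
            if "N" in kmer:
                continue
            kmers.append(kmer)
            vals.append(mean_ipd)
    observed = pd.DataFrame({"kmer": kmers, "mean_ipd": vals})
    agg = observed.groupby("kmer")["mean_ipd"].agg(["mean", "size"])
    universe = ["".join(p) for p in itertools.product(
        *("ACGT" if i != focal_index else focal_base for i in range(k)))]
    table = agg.reindex(universe)
    table.columns = ["mean_focal_ipd", "n"]
    table["n"] = table["n"].fillna(0).astype(np.int64)
    table.index.name = "kmer"
    return table.reset_index()


@dataclass(frozen=True)
class ModificationCall:
    """Outcome of the native-vs-WGA test for one motif's focal position."""

    motif: str
    focal_offset: int
    stat: ComparisonStat
    modified: bool


def call_modification(
    native_sites: pd.DataFrame,
    wga_sites: pd.DataFrame,
    genome: ReferenceGenome,
    motif: MotifSpec | str,
    focal_offset: int,
    fold_threshold: float = 2.0,
    alpha: float = 1e-3,
) -> ModificationCall:
    """Call a motif focal position modified when the native/WGA fold exceeds
    *fold_threshold* with rank-sum p below *alpha*."""
    iupac = motif.iupac if isinstance(motif, MotifSpec) else motif
    occ = scan_motif(genome, iupac)
    if not len(occ):
        raise ValueError(f"motif {iupac!r} not found in the genome")
    m = len(iupac)
    pos = np.where(occ["strand"] == "+",
                   occ["start"] + focal_offset,
                   occ["start"] + (m - 1) - focal_offset)
    loci = pd.DataFrame({"contig": occ["contig"], "pos": pos,
                         "strand": occ["strand"]})
    stat = compare_native_wga(native_sites, wga_sites, loci)
    modified = (stat.native_wga_fold is not None
                and stat.native_wga_fold >= fold_threshold
                and stat.native_wga_p < alpha)
    return ModificationCall(iupac, focal_offset, stat, modified)
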