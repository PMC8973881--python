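"""Synthetic SMRT-kinetics generator with known ground truth.

Emulates the ingredients of single-molecule real-time sequencing kinetics
that the analysis modules consume: per-pulse interpulse durations (IPDs) that
are log-normal around base-specific arithmetic means, sequence-context
multipliers around planted motifs, modification multipliers that act only in
native (unamplified) material, Poisson per-strand coverage, rare large
outlier pulses, and a neighbour-mismatch validity flag.

The generative law for one observation at a site is

    IPD = mu_base * c_ctx * f_mod * exp(sigma * Z - sigma**2 / 2)

with Z standard normal, so the arithmetic mean of the emitted IPDs equals
``mu_base * c_ctx * f_mod`` exactly; multipliers therefore compose
multiplicatively on mean IPDs, which is the scale on which mean-IPD ratios
(native/WGA fold, ratio of increase) are defined downstream.  ``f_mod``
applies only when simulating native material — whole-genome-amplified (WGA)
material is modification-free and serves as the negative control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io
from .util import BASES, IUPAC_CODES, revcomp, validate_iupac

#: Default per-base arithmetic mean IPDs (dimensionless): A, C, G, T.
DEFAULT_BASE_MEANS = {"A": 1.38, "C": 0.95, "G": 1.00, "T": 0.65}

_COMPLEMENT_CODE = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_CODE[_a] = _b


@dataclass(frozen=True)
class ReferenceGenome:
    """Ordered contig collection; sequences uppercase over {A,C,G,T,N}."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome has no contigs")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if not set(seq) <= set("ACGTN"):
                raise ValueError(f"contig {name!r} has characters outside ACGTN")

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        return cls(io.read_fasta(path))

    def to_fasta(self, path) -> None:
        io.write_fasta(self.contigs, path)


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant ``count`` copies of an IUPAC motif.

    ``context_multipliers`` maps relative position (0 = first motif base,
    negative = upstream on the motif strand) to a multiplicative effect on
    the mean IPD of that position; it may extend beyond the motif to model
    upstream kinetic anomalies.  ``modification_multiplier`` additionally
    scales the focal position, but only in native mode.
    """

    motif: str
    focal_offset: int
    count: int
    modification_multiplier: float = 1.0
    context_multipliers: dict[int, float] = field(default_factory=dict)
    strand: str = "+"

    def __post_init__(self) -> None:
        validate_iupac(self.motif)
        if not 0 <= self.focal_offset < len(self.motif):
            raise ValueError("focal offset outside motif")
        if self.modification_multiplier <= 0:
            raise ValueError("modification multiplier must be positive")
        if any(c <= 0 for c in self.context_multipliers.values()):
            raise ValueError("context multipliers must be positive")
        if self.strand not in {"+", "-", "random"}:
            raise ValueError("strand must be '+', '-' or 'random'")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted motif occurrence.

    ``start`` is the 0-based plus-strand coordinate of the leftmost genomic
    base of the occurrence; for minus-strand sites the reverse complement of
    the resolved motif was inserted at that window.
    """

    contig: str
    start: int
    strand: str
    motif_id: str
    motif_length: int
    focal_offset: int
    modification_multiplier: float
    context_multipliers: dict[int, float]

    @property
    def focal_position(self) -> int:
        """Plus-strand genomic coordinate of the focal base."""
        if self.strand == "+":
            return self.start + self.focal_offset
        return self.start + self.motif_length - 1 - self.focal_offset

    def genomic_position(self, rel: int) -> int:
        """Plus-strand coordinate of motif-strand relative position *rel*."""
        if self.strand == "+":
            return self.start + rel
        return self.start + self.motif_length - 1 - rel


@dataclass(frozen=True)
class KineticsModelConfig:
    """Generative parameters of the synthetic kinetics model.

    ``base_mean_ipd`` are arithmetic means (dimensionless IPD units);
    ``log_sigma`` is the standard deviation of the natural-log IPD;
    ``coverage_per_strand`` the Poisson mean observation count per site and
    strand; ``outlier_prob``/``outlier_scale`` model rare very long pauses;
    ``neighbor_mismatch_prob`` the chance a read disagrees with the
    reference next to the site, which invalidates the observation downstream.
    """

    base_mean_ipd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_MEANS))
    log_sigma: float = 0.5
    coverage_per_strand: float = 30.0
    outlier_prob: float = 0.001
    outlier_scale: float = 50.0
    neighbor_mismatch_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.base_mean_ipd) != set(BASES):
            raise ValueError("base_mean_ipd must define A, C, G and T")
        if any(m <= 0 for m in self.base_mean_ipd.values()):
            raise ValueError("base mean IPDs must be positive")
        if self.log_sigma < 0:
            raise ValueError("log_sigma must be non-negative")
        if self.coverage_per_strand <= 0:
            raise ValueError("coverage_per_strand must be positive")
        if not 0 <= self.outlier_prob < 1:
            raise ValueError("outlier_prob must be in [0, 1)")
        if self.outlier_prob > 0 and self.outlier_scale <= 1:
            raise ValueError("outlier_scale must exceed 1")
        if not 0 <= self.neighbor_mismatch_prob < 1:
            raise ValueError("neighbor_mismatch_prob must be in [0, 1)")


def _resolve_iupac(motif: str, rng: np.random.Generator) -> str:
    """Resolve degenerate positions uniformly among their allowed bases."""
    return "".join(
        ch if len(IUPAC_CODES[ch]) == 1
        else IUPAC_CODES[ch][rng.integers(len(IUPAC_CODES[ch]))]
        for ch in motif)


def generate_genome(
    length: int,
    gc_fraction: float = 0.36,
    plant_specs: tuple[PlantSpec, ...] | list[PlantSpec] = (),
    seed: int = 0,
    contig_name: str = "chr1",
) -> tuple[ReferenceGenome, list[PlantedSite]]:
    """Draw an i.i.d. background genome and plant motif occurrences.

    Background bases are independent with P(G)=P(C)=gc_fraction/2.  Planted
    occurrences are non-overlapping; degenerate IUPAC positions are resolved
    uniformly per occurrence; minus-strand plants insert the reverse
    complement into the plus-strand sequence.  Returns the genome and the
    ground-truth planted sites.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    footprint = sum(len(s.motif) * s.count for s in plant_specs)
    if footprint >= length:
        motifs = ", ".join(sorted({s.motif for s in plant_specs}))
        raise ValueError(
            f"total planted footprint ({footprint}) exceeds genome length "
            f"({length}) for motifs {motifs}")

    rng = np.random.default_rng(seed)
    gc, at = gc_fraction / 2.0, (1.0 - gc_fraction) / 2.0
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8),
                     size=length, p=[at, gc, gc, at])

    occupied = np.zeros(length, dtype=bool)
    planted: list[PlantedSite] = []
    for spec in plant_specs:
        m = len(spec.motif)
        max_tries = 1000 * spec.count + 1000
        tries = 0
        placed = 0
        while placed < spec.count:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not place {spec.count} non-overlapping copies of "
                    f"motif {spec.motif!r}; planting density infeasible")
            start = int(rng.integers(0, length - m + 1))
            if occupied[start:start + m].any():
                continue
            strand = spec.strand
            if strand == "random":
                strand = "+" if rng.integers(2) == 0 else "-"
            resolved = _resolve_iupac(spec.motif, rng)
            inserted = resolved if strand == "+" else revcomp(resolved)
            seq[start:start + m] = np.frombuffer(
                inserted.encode(), dtype=np.uint8)
            occupied[start:start + m] = True
            planted.append(PlantedSite(
                contig=contig_name, start=start, strand=strand,
                motif_id=spec.motif, motif_length=m,
                focal_offset=spec.focal_offset,
                modification_multiplier=spec.modification_multiplier,
                context_multipliers=dict(spec.context_multipliers)))
            placed += 1

    genome = ReferenceGenome({contig_name: seq.tobytes().decode()})
    return genome, planted


def simulate_reads(
    genome: ReferenceGenome,
    planted: list[PlantedSite] | tuple[PlantedSite, ...],
    config: KineticsModelConfig,
    mode: str = "native",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate read-level IPD observations for every site and strand.

    Observation counts per (site, strand) are Poisson(coverage_per_strand).
    Modification multipliers at planted focal positions apply only when
    ``mode == "native"``; WGA material is simulated modification-free.
    Returns a DataFrame with columns read_id, contig, pos (0-based), strand,
    ref_base, ipd, neighbors_match.
    """
    if mode not in {"native", "wga"}:
        raise ValueError("mode must be 'native' or 'wga'")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    mean_lookup = np.ones(256)
    for b, m in config.base_mean_ipd.items():
        mean_lookup[ord(b)] = m

    frames: list[pd.DataFrame] = []
    read_counter = 0
    for contig, seqstr in genome.contigs.items():
        plus = np.frombuffer(seqstr.encode(), dtype=np.uint8)
        minus = _COMPLEMENT_CODE[plus]
        L = len(plus)
        valid = np.stack([plus != ord("N"), minus != ord("N")])

        site_mean = np.stack([mean_lookup[plus], mean_lookup[minus]])
        for site in planted:
            if site.contig != contig:
                continue
            si = 0 if site.strand == "+" else 1
            for rel, c in site.context_multipliers.items():
                g = site.genomic_position(rel)
                if 0 <= g < L:
                    site_mean[si, g] *= c
            if mode == "native":
                site_mean[si, site.focal_position] *= site.modification_multiplier

        counts = rng.poisson(config.coverage_per_strand, size=(2, L))
        counts[~valid] = 0
        n_total = int(counts.sum())
        pos = np.tile(np.arange(L, dtype=np.int64), 2)
        strand_idx = np.repeat(np.array([0, 1], dtype=np.int8), L)
        reps = counts.reshape(-1)
        pos = np.repeat(pos, reps)
        strand_idx = np.repeat(strand_idx, reps)
        mu = np.repeat(site_mean.reshape(-1), reps)

        sigma = config.log_sigma
        if sigma > 0:
            noise = np.exp(sigma * rng.standard_normal(n_total)
                           - 0.5 * sigma * sigma)
        else:
            noise = np.ones(n_total)
        ipd = mu * noise
        if config.outlier_prob > 0:
            ipd = np.where(rng.random(n_total) < config.outlier_prob,
                           ipd * config.outlier_scale, ipd)
        neighbors = rng.random(n_total) >= config.neighbor_mismatch_prob

        base_codes = np.where(strand_idx == 0, plus[pos], minus[pos])
        frames.append(pd.DataFrame({
            "read_id": _read_ids(read_counter, n_total),
            "contig": contig,
            "pos": pos,
            "strand": np.where(strand_idx == 0, "+", "-"),
            "ref_base": base_codes.view("S1").astype("U1"),
            "ipd": ipd,
            "neighbors_match": neighbors,
        }))
        read_counter += n_total

    if not frames:
        return pd.DataFrame(columns=io.READS_TSV_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _read_ids(start: int, n: int) -> np.ndarray:
    return np.char.add("r", np.arange(start, start + n).astype(str))


def modification_sites_from_occurrences(
    occurrences: pd.DataFrame,
    motif: str,
    focal_offset: int,
    modification_multiplier: float,
    context_multipliers: dict[int, float] | None = None,
) -> list[PlantedSite]:
    """Mark every motif occurrence as a modified site (enzyme-style action).

    Methyltransferases act on every copy of their recognition sequence, so a
    positive-control simulation should modify all occurrences — including
    both strands of a palindrome — not only deliberately planted copies.
    *occurrences* is a scan result (contig, start, strand).  Occurrences
    sharing a focal position and strand are deduplicated.
    """
    m = len(motif)
    seen: set[tuple[str, int, str]] = set()
    out: list[PlantedSite] = []
    for row in occurrences.itertuples(index=False):
        site = PlantedSite(
            contig=row.contig, start=int(row.start), strand=row.strand,
            motif_id=motif, motif_length=m, focal_offset=focal_offset,
            modification_multiplier=modification_multiplier,
            context_multipliers=dict(context_multipliers or {}))
        key = (site.contig, site.focal_position, site.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(site)
    return out


def focal_loci(planted: list[PlantedSite] | tuple[PlantedSite, ...]) -> pd.DataFrame:
    """Ground-truth focal loci of planted sites as (contig, pos, strand)."""
    return pd.DataFrame({
        "contig": [s.contig for s in planted],
        "pos": [s.focal_position for s in planted],
        "strand": [s.strand for s in planted],
    })


def truth_bed_frame(planted: list[PlantedSite] | tuple[PlantedSite, ...]) -> pd.DataFrame:
    """BED6 rows (0-based half-open) marking each planted focal base."""
    return pd.DataFrame({
        "contig": [s.contig for s in planted],
        "start": [s.focal_position for s in planted],
        "end": [s.focal_position + 1 for s in planted],
        "name": [f"{s.motif_id}:{s.focal_offset}" for s in planted],
        "score": [round(100 * s.modification_multiplier) for s in planted],
        "strand": [s.strand for s in planted],
    })


def write_dataset(
    observations: pd.DataFrame,
    path: str,
    planted: list[PlantedSite] | tuple[PlantedSite, ...] = (),
    truth_path: str | None = None,
) -> None:
    """Write the per-read TSV and, when planted sites are given, a
    ground-truth BED of their focal positions."""
    io.write_reads_tsv(observations, path)
    if planted:
        if truth_path is None:
            truth_path = str(path) + ".truth.bed"
        io.write_bed(truth_bed_frame(planted), truth_path)

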