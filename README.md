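# ipdkin

Separating DNA-modification signals from context-dependent DNA-polymerase
kinetics in single-molecule (SMRT) sequencing data.

## The problem

SMRT sequencing reports, for every incorporated base, the interpulse
duration (IPD) — the time between the fluorescence pulses of consecutive
nucleotide incorporations. Covalent base modifications such as
N6-methyladenine (6mA) slow the polymerase and raise the IPD at and near
the modified base, which is the basis of kinetic modification calling. But
sequence context alone (G-quadruplex-prone runs, quasi-palindromes, and
other non-B DNA motifs) also shifts IPDs, in some contexts by as much as a
true modification would. A locus with a high IPD is therefore ambiguous
until the kinetic effect of the naked sequence is measured.

The decisive control is whole-genome-amplified (WGA) material: amplification
with unmodified nucleotides erases covalent marks while leaving the sequence
intact. A *modification* raises the native IPD but not the WGA IPD; a
*context effect* raises both. `ipdkin` implements this comparison end to
end, together with the surrounding kinetic analyses, and ships a synthetic
kinetics generator with known ground truth so every stage can be exercised
and validated without sequencing data.

## The statistics at the core

For a site *s* on one strand, the site IPD is the trimmed mean of the valid
per-read IPDs at *s* (valid = neighbouring read bases match the reference
and the IPD is not an outlier of its locus; sites require ≥ 25 valid IPDs
per strand). On top of these site values:

- **Ratio of increase** of a motif's focal base
  `R = mean IPD over motif occurrences / genome-wide mean IPD of that base`,
  with a Wilcoxon rank-sum test against all same-base sites. This measures
  the *sequence-context* effect and is present in native and WGA samples
  alike.
- **Native/WGA fold** over a locus set
  `F = mean native IPD / mean WGA IPD` with a rank-sum p-value. Only a
  covalent modification moves `F` away from 1.
- **Extreme-IPD loci**: sites above the top-1% (or below the bottom-1%)
  order statistic of the pooled site-mean distribution; 41-bp windows
  around them are exported for motif discovery, and motif positions are
  tested for extremeness with Bonferroni correction.
- **Feature enrichment**: for a genomic region class,
  `fold = (k/n)/p0` where *n* is the number of eligible bases in the
  region, *k* the extreme loci among them and *p0* the genome-wide locus
  fraction; significance by a two-sided binomial test with
  Benjamini–Hochberg q-values across classes.
- **Concordance**: Pearson *r*, R² and RMSE between paired log2 IPDs
  (replicate profiles, or observed vs. model-predicted site IPDs), and the
  spread of per-site log2 ratios between replicates as a function of the
  minimum read coverage.

The synthetic generator draws per-read IPDs as
`IPD = mu_base * c_ctx * f_mod * exp(sigma*Z - sigma^2/2)` with Poisson
per-strand coverage, so configured multipliers compose exactly on
arithmetic means; `f_mod` applies only in native mode. Default base means
are A 1.38, C 0.95, G 1.00, T 0.65 (dimensionless).

## Worked example

```python
from ipdkin import (KineticsModelConfig, PlantSpec, aggregate_sites,
                    compare_native_wga, generate_genome, genome_base_means,
                    simulate_reads)
from ipdkin.kinsim import focal_loci

spec = PlantSpec("GATC", focal_offset=1, count=100,
                 modification_multiplier=8.57)
genome, planted = generate_genome(30_000, gc_fraction=0.36,
                                  plant_specs=[spec], seed=1)
config = KineticsModelConfig()          # A=1.38, C=0.95, G=1.00, T=0.65
native = aggregate_sites(simulate_reads(genome, planted, config,
                                        mode="native", seed=2))
wga = aggregate_sites(simulate_reads(genome, planted, config,
                                     mode="wga", seed=3))
stat = compare_native_wga(native, wga, focal_loci(planted))
print(f"native/WGA fold at GATC adenines: {stat.native_wga_fold:.2f} "
      f"(p = {stat.native_wga_p:.3g}, {stat.n_motif} loci)")
print(genome_base_means(wga).round(3))
```

prints

```
native/WGA fold at GATC adenines: 8.64 (p = 0, 67 loci)
      mean_ipd  n_sites
base
A        1.366    15299
C        0.938     8757
G        0.989     8602
T        0.642    15311
```

The planted 8.57-fold adenine modification is recovered from the
native/WGA contrast (67 of the 100 planted loci pass the ≥ 25-coverage
filter in both samples; the rank-sum p underflows to 0), and the
modification-free WGA table reproduces the configured per-base mean IPDs
to about 1%.

The same workflow is available from the shell:

```
ipdkin simulate --length 30000 --plant GATC:2:8.57:100 --mode native \
    --seed 2 --out sim/
ipdkin aggregate --reads sim/native_reads.tsv --out native_sites.csv
ipdkin run --config demo.json --out run/     # full pipeline from JSON
```

(`GATC:2` means the 2nd nucleotide of GATC; command-line focal positions
are 1-based.)

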