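# Methods

## Kinetic model of the synthetic generator

`kinsim` emulates the per-site structure of SMRT polymerase kinetics. Each
observation of a site (one read crossing one position on one strand) draws

    IPD = mu_base * c_ctx(site) * f_mod(site, mode) * exp(sigma * Z - sigma^2 / 2)

with `Z ~ N(0, 1)`. Because `E[exp(sigma*Z - sigma^2/2)] = 1`, the
arithmetic mean of the emitted IPDs equals the product of the configured
multipliers exactly. This mean-preserving log-normal parameterisation was
chosen deliberately: all downstream statistics (native/WGA fold, ratio of
increase) are ratios of arithmetic mean IPDs, so multipliers planted in the
generator are the quantities the analysis should recover, without
log-normal mean/median bookkeeping.

Parameters, units and defaults (IPDs are dimensionless throughout; no
measurement scale is assumed):

- `base_mean_ipd` — arithmetic mean IPD per template base; defaults
  A 1.38, C 0.95, G 1.00, T 0.65. These reproduce the large between-base
  differences seen in real kinetics (adenine slowest, thymine fastest).
- `log_sigma` — standard deviation of the natural-log IPD; default 0.5.
  Chosen to give a realistically broad log2 site-IPD distribution while
  keeping the bias of the Tukey-trimmed site mean (trimming a symmetric
  band on the log scale removes more of the heavy right tail on the linear
  scale, deflating the mean by ~1%) inside the generator's ±2% mean
  calibration contract at coverage 30.
- `coverage_per_strand` — Poisson mean of the per-site, per-strand
  observation count; default 30, a typical per-strand depth for kinetic
  calling.
- `outlier_prob` / `outlier_scale` — with probability 0.001 an IPD is
  multiplied by 50, emulating rare long pauses; these are exactly the
  events per-locus outlier trimming must absorb.
- `neighbor_mismatch_prob` — probability 0.01 that a read mismatches the
  reference next to the site, which invalidates the observation.

Context multipliers are attached to planted motif occurrences per relative
position (and may extend upstream/downstream of the motif, emulating
kinetic anomalies a few bases outside a motif); the modification
multiplier applies to the focal position only and **only in native mode**
— simulated WGA material is modification-free by construction, which is
the whole point of the control. Minus-strand plants insert the reverse
complement into the plus-strand sequence; relative positions always read
5'→3' along the motif strand. An enzyme-style helper can mark *every*
occurrence of a motif as modified (both strands of a palindrome), matching
how a methyltransferase such as Dam acts on its recognition site; the demo
pipeline uses it for its positive control.

What the generator does *not* model: read-length structure and error
profiles, pausing autocorrelation along a molecule, or circular-consensus
effects. Observations are independent per site. Passing tests therefore
validate the statistical machinery and its calibration, not robustness to
alignment artefacts or within-read dependence in real data.

## Site aggregation

Observations are grouped per (contig, position, strand); strands are never
pooled before the per-base genome means. An observation is valid if its
neighbour flag is set and it survives outlier trimming at its locus;
sites keep only `valid_count >= 25` (configurable; the inclusive reading of
the per-strand threshold was adopted). Reference-N sites are dropped.

Outlier trimming is two-sided Tukey fencing with k = 1.5 on log2 IPDs,
quartiles by linear interpolation. The upstream kinetics tooling this
mirrors does not publish its trimming rule, so a deterministic, documented,
robust rule was chosen and made pluggable (`trim=` accepts a callable or
`"none"`). Degenerate spreads behave sensibly: a constant site trims
nothing; a single huge outlier among constants is always removed.

Genome per-base means are unweighted averages of per-site means (weighting
by coverage is deliberately not done; with Poisson coverage the weights
would be nearly constant and the unweighted mean matches the per-site
definition of all other statistics).

## Rank-sum testing

`wilcoxon_ranksum` uses midranks for ties. With a smaller sample of at
most 8 and tie-free data the two-sided p is exact (full enumeration of the
rank-sum distribution). Otherwise a normal approximation is used with
tie-corrected variance, continuity correction, and — for tie-free data —
an Edgeworth kurtosis term using the exact fourth cumulant of the rank sum,

    kappa4 = -n1*n2*(N+1) * (n1^2 + n2^2 + n1*n2 + N) / 120,  N = n1 + n2.

The plain normal approximation errs by up to ~0.04 against exact
enumeration at the smallest sizes; with the Edgeworth term the worst error
over all tie-free grids with 3 ≤ min(n) ≤ 8 is below 0.02. At min(n) = 2
the exact distribution is too discrete for any continuous approximation
(attainable p-values at 2 vs 2 are 1/3, 2/3, 1); the exact path always
covers those sizes. Identical samples and zero-variance tie patterns
return p = 1.

## Motif statistics

IUPAC motifs are scanned on both strands (a window whose reverse complement
matches is reported on '-' with plus-strand start coordinates); overlapping
occurrences all count. Profiles average site means per relative position in
[-flank, len+flank), flank default 10, using the site on the occurrence
strand; error bars are standard errors (spread measure configurable in
principle — SE was adopted). The ratio of increase compares the focal base
against the genome-wide mean of the *same* base; degenerate focal positions
report one entry per resolved base plus a pooled entry. The rank-sum
baseline is all same-base sites (not a matched subsample). The native/WGA
caller flags a motif as modified when the fold exceeds a threshold
(default 2.0) with rank-sum p below alpha (default 1e-3); the fold
threshold sits far above context-only effects (~1.03 for GATC) and far
below genuine modification folds (several-fold).

## Extreme loci and enrichment

Extreme thresholds are nearest-rank order statistics with strict
exceedance over the pooled (all bases, both strands) site-mean
distribution — on tie-free data exactly floor(pct% · N) sites are flagged
per side, and ties are never flagged; per-base thresholding is available
as an option. Exported windows are 41 bp, centred, clipped (and marked) at
contig ends, reverse-complemented for minus loci. Motif-position
extremeness uses the rank-sum test per position with Bonferroni
multiplication; the default family size is sum over tested motifs of
(motif length + 2·flank).

Enrichment treats region "size" as the number of *eligible* bases
(coverage-filtered sites) in the region, not raw length (raw-length mode
available), so the binomial trials match the population the loci are drawn
from. The two-sided binomial p is the minimum-likelihood sum of point
masses ≤ pmf(k). q-values are Benjamini–Hochberg across region labels,
computed separately for high and low loci; overlapping annotation classes
are counted independently in each class.

## Concordance

All concordance metrics operate on log2 IPDs by default (kinetic effects
are multiplicative; a linear-scale option exists). R² is the coefficient
of determination of the identity-line prediction, `1 - SS_res/SS_tot`
with the predicted values taken as the predictor — not the square of r —
so a biased predictor is penalised. Profile correlation uses the motif
positions plus 10 upstream positions (upstream = 5' on the motif strand),
where context anomalies concentrate. The replicate table restricts to
sites with valid coverage ≥ c in both datasets for each grid value c; its
log2-ratio spread shrinking in c is the expected averaging behaviour and
is asserted in tests on independent replicate simulations.

## Pipeline and determinism

The pipeline is configured by one versioned JSON document (focal positions
1-based there, matching field phrasing; 0-based internally). All
randomness flows from a single seed through independent child seeds per
stage; rerunning an identical configuration reproduces byte-identical
outputs, which the test suite asserts. Stage failures abort with the stage
name, retain completed outputs and leave a `FAILED` marker.

## Problem sizes used in validation

The validation suites simulate 100-kb genomes at coverage 30 for
modification recovery (350 planted GATC sites so that ≥ 200 survive the
joint native/WGA coverage filter), 30-kb genomes at coverage 12 for
replicate-stabilisation checks, 100,000-point site tables for percentile
and enrichment checks, and a 25-kb demo pipeline. These sizes give the
recovery statistics comfortable margins (sampling CV of the fold well
under 2%) while keeping full runs to a couple of minutes.

## Known limitations

- The generator's independence assumptions (per-site, per-read) make
  variance estimates optimistic relative to real molecules with shared
  polymerase state.
- The Tukey-trimmed site mean is ~1% below the configured arithmetic mean
  under the default dispersion; fold-type statistics cancel this bias,
  absolute mean recovery carries it.
- Exact rank-sum enumeration is only engaged for min(n) ≤ 8; the
  Edgeworth-corrected approximation is validated to 0.02 absolute accuracy
  on small grids but remains an approximation in the far tails.
- BED/GFF3 readers cover the plain tabular subset of those formats
  (no fasta-embedded GFF, no bigBed).
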