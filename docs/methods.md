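# Methods

## Target-region fractions from size traces

A library's electropherogram is modelled as a piecewise-linear mass density
over fragment length (bp).  The target-region fraction is the trapezoidal
integral of the density over the size-selection window divided by the
integral over the full trace, with linearly interpolated points inserted at
the window edges.  This matches how instrument software reports "region
percent" values, is exact for piecewise-linear densities, and is stable
under grid refinement (tested to < 1e-6 under 2× upsampling).  Window
bounds are treated as inclusive; with continuous integration the choice is
immaterial.  Marker/primer peaks are not detected automatically — traces
may be cropped below a configurable size (`--trace-min-bp`, default
100 bp), since marker-peak conventions differ between instruments.
Fractions are reported as whole percents with half-up rounding for display
while full precision is kept internally.

## Pooling arithmetic

TRC = concentration × target fraction; masses are allocated strictly
proportional to expected-yield weights under one of two reference policies
(`per_max_weight_sample`: the largest-weight library receives the reference
mass, the worksheet idiom "20.0 ng each" under equal weights; `total_pool`:
masses sum to the reference).  Volumes are mass/TRC **at full precision**:
the bundled 14-library worksheet only reproduces exactly when the TRC is
not rounded before dividing (e.g. 20/(24.80 × 0.13) = 6.203 → 6.20 µL,
whereas the displayed TRC 3.22 would give 6.21).  Display rounding is
half-up (decimal, not banker's) because that is what bench worksheets use.
Yield is modelled as proportional to pooled target-region **mass** rather
than molarity: within a narrow window (420–520 bp) mass and molar fractions
are nearly proportional, and pooling is done by mass.  Plans scale
proportionately (`PoolPlan.scaled`), which preserves yield shares.

## Yield evenness statistics

CV uses the sample (n−1) standard deviation, which reproduces the reported
group CVs from their mean ± SD summaries.  Expected per-sample yields are
derived from **realized** lane totals divided by group size (or split by
weight), not from nominal lane capacity.  RE classification uses strict
inequalities ("less than 10%", "more than 25%"); boundary cases fall in the
middle band.  The AD threshold is simply RE level × equal-share
expectation, reported in Gb.

Pairwise ratio tests convert two yields to pseudo-counts at a configurable
unit (default 0.01 Gb per count), split the observed total by the expected
ratio, and compute a df = 1 chi-square statistic.  The statistic scales
with 1/unit and the p-value is monotone decreasing in it, so the unit is an
explicit parameter recorded in every result rather than a hidden
convention; p-values on continuous Gb quantities are unit-dependent and we
prefer transparency over false precision.

Coverage histograms count bases at each integer depth (percent of genome)
with a Poisson(λ = mean depth) reference — the no-bias expectation.
GC-binned coverage cuts the genome into 10-kb bins (a final partial bin is
kept if ≥ half-size, else merged into the previous bin), computes GC over
unambiguous A/C/G/T only, and flags bins with no unambiguous base.

## Pool simulator

The simulator emulates the workflow end to end: true concentrations are
lognormal (meanlog ln 23, sdlog 0.1, resembling the worksheet's
19.6–26.2 ng/µL range); fragment lengths are lognormal with mode ≈ 470 bp
and log-sd 0.6, which places ≈ 10–13% of mass in the 420–520 bp window as
observed; QC measurement noise is multiplicative lognormal on concentration
(CV 5%, a plausible fluorometer repeatability) and Gaussian on the **logit**
of the trace fraction (sd 0.05, keeping fractions inside (0, 1)); pipetting
noise is lognormal (CV 2%); and the lane is a fixed-capacity resource:
realized yield shares are Dirichlet-distributed around the true pooled
target-mass fractions with concentration 2000, so capacity is conserved
exactly and yields compete.  The published experiments report equal-weight
group CVs of ~5–11% without decomposing the sources; these defaults land
simulated CVs in that range but the simulator is a calibration instrument,
not a fitted model — all parameters are YAML-overridable.

Two structural properties are tested rather than assumed: (i) with all
noise off the yields are exactly proportional to the design weights; and
(ii) libraries with widely different true concentrations and size profiles
still split the lane exactly by weight when QC is exact — the TRC
mechanism's self-consistency.  Noise in the QC *measurement* necessarily
propagates into yields (the plan divides by the measured TRC while the tube
receives mass at the true TRC); the simulator models this faithfully.

## SNP filtering

Parental markers: biallelic sites where both parents are homozygous for
different alleles, each with depth ≥ 4, MQ ≥ 60 and QUAL ≥ 60 (inclusive
thresholds, per the ≥ wording of the protocol), outside the
transposable-element mask.  Multi-allelic records are skipped entirely —
the criteria presume a biallelic parental polymorphism.  BED intervals are
0-based half-open and VCF positions 1-based; the conversion happens once at
the mask boundary and is covered by boundary tests.  Progeny calls keep
only homozygous genotypes matching a parental allele at passing sites;
heterozygous calls are dropped rather than coded HET because at ≤ 1×
coverage a single read cannot distinguish heterozygosity — the sliding
window infers HET from mixed call runs downstream.  Rejections are tallied
per criterion (first failing criterion counts) for auditability.

## Breakpoint detection and bin construction

A window of 15 consecutive informative calls slides one SNP at a time; the
fraction f of P2 calls scores it P1 (f ≤ 0.3), P2 (f ≥ 0.7) or HET.
Window size and band edges follow the established sliding-window lineage
for low-coverage RIL genotyping and are config options; none of the
package's checks depend on the defaults.  Each SNP takes the call of the
window centred on it, runs become blocks, and block boundaries sit at the
midpoint between flanking discordant SNPs — so boundary placement error is
of the order of the inter-marker spacing, and detection resolution is
roughly the window span (15 / marker density).  Chromosomes with fewer
calls than the window collapse to a majority-vote block flagged
low-confidence.

Smoothing reassigns a sub-0.5-Mb HET block flanked by homozygous blocks of
one genotype (or a sub-0.5-Mb homozygous block flanked by HET) to the
surrounding genotype, iterated to fixpoint; blocks at chromosome ends are
never touched ("middle of" semantics), and a 0.5-Mb block is *not* short
(strict <).  When several blocks are eligible the **shortest is corrected
first**: random hom-leaning call runs inside long heterozygous tracts
(probability ≈ 6% per window at the default band) otherwise let the
HET-absorption rule bridge across them and drag true boundaries by up to
the 0.5-Mb rule distance.  Smallest-first removes the least-supported
feature before it can bridge, and makes the fixpoint insensitive to scan
order.  Smoothing runs before sample exclusion and before binning.

Samples with strictly more than 300 breakpoints are excluded.  Bin
construction cuts each chromosome into 100-kb intervals; each
(line, interval) takes the genotype covering the majority of the interval
(ties resolve to the preceding interval's genotype, avoiding spurious
bins); adjacent intervals with identical genotype columns across the whole
population merge into one bin marker.  Outputs use 1-based inclusive bp
spans.  Collinearity is the Pearson correlation between genetic (cM) and
physical (Mb) positions; map ordering itself (cM estimation, QTL scans) is
out of scope.

Breakpoint counts are reported on smoothed tracks (whether published totals
were counted before or after binning is not stated; smoothed-track counting
is the conservative choice since binning cannot create boundaries).

## Population generator

Lines descend from donor × recurrent → F1, backcross to the recurrent
parent, then single-seed-descent selfing to F₄ (three selfing meioses).
Every meiosis lays crossovers as a Poisson process per chromosome, no
interference (none is modelled in the protocol's lineage).  Expected
residual heterozygosity is ½·(½)³ ≈ 6.25% of the genome, verified by a
pedigree test.  Observation model for ≤ 1× coverage: heterozygous sites
report P1 or P2 with equal probability (a single sampled read), homozygous
sites flip with the call-error rate (default 1%), and every call is
independently missing (default 83%, reproducing ≈ 190 observed SNPs/Mb
from ≈ 1100 parental SNPs/Mb at ~0.74× coverage).  Defaults use a
scaled-down maize-like karyotype (5 × 30 Mb) so that population-scale runs
stay cheap; tests and the acceptance pipeline state their own problem sizes
explicitly (typically 50 lines × 2 × 40 Mb).

## Validation against truth

End-to-end crossover recovery is scored against the truth track passed
through the **same** < 0.5 Mb smoothing rule: sub-0.5-Mb true features are
removed by the pipeline's own published correction step, so their
boundaries are unrecoverable by design and form no part of the target set.
Recovery against raw truth is also reported (it differs by the frequency of
sub-0.5-Mb true blocks, ~3–7% under the tested conditions).  On 50 synthetic
lines with 1% call error and ≥ 1 informative marker per 50 kb, ≥ 95% of
recoverable crossovers are detected within 200 kb.  Detected breakpoint
counts exceed truth at direct homozygous–homozygous transitions, where the
window necessarily passes through the HET band and leaves a window-span
HET sliver (two boundaries for one crossover); counts therefore stay within
2× of truth, and the sliver width shrinks with marker density.

## What the synthetic data does and does not show

The generators emulate the *structure* of the real experiments — lane
competition, QC/pipetting noise, mosaic genomes, sparse noisy low-coverage
calls — with independent, stationary noise.  They do not emulate index
hopping, GC- or length-dependent amplification bias, segregation
distortion, structural variation, or non-uniform marker ascertainment.
Passing tests therefore demonstrate correctness of the algorithms and
robustness to the modelled noise, not performance guarantees on any
particular real dataset.

## Numerical and degenerate-input choices

Display rounding is half-up via `decimal`; internal values are never
rounded.  Zero-mass traces, empty weight lists, non-positive
concentrations, empty yield tables, length-mismatched depth vectors, zero
variance in collinearity inputs, and invalid simulator configs all raise
`ValueError` before any computation or sampling.  Both simulators are
bit-reproducible from a single integer seed; replicate sweeps derive
per-replicate seeds as seed + k.
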