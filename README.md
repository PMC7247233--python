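# aioseq

Computational toolkit for **all-in-one sequencing (AIO-seq)** library
pooling and for low-coverage genotype-to-bin-map construction in mapping
populations.

AIO-seq replaces per-sample ("one sample, one tube") size selection and
quantification of NGS libraries with a single pooled operation.  The pooling
currency is the **target region concentration (TRC)**: for library *i* with
whole-library concentration *c*ᵢ (ng/µL, fluorometric assay) and fraction
*fᵢ* of library mass inside the size-selection window (from the
electropherogram; 420–520 bp for paired-end 150 bp sequencing),

```
TRCᵢ = cᵢ · fᵢ              (ng/µL of sequencable target region)
mᵢ   ∝ wᵢ                   (target-region mass pooled ∝ expected yield share)
Vᵢ   = mᵢ / TRCᵢ            (volume pipetted into the pool, µL)
```

so every library contributes target-region mass in proportion to its
expected share *wᵢ* of the lane's output, whatever its concentration or
fragment-size profile.  The package implements that design calculation plus
everything needed to evaluate and stress-test it, and the downstream
analysis pipeline used for cheaply genotyped mapping populations:

- `aioseq.size_profile` — electropherogram trace parsing and target-window
  mass fractions (trapezoidal integration on the instrument grid);
- `aioseq.pooling` — TRC computation, mass allocation, pipetting volumes,
  expected yields, feasibility checks;
- `aioseq.yield_eval` — demultiplexed-yield evenness statistics (CV with the
  n−1 standard deviation, relative error, absolute-deviation thresholds),
  pairwise chi-square ratio tests, coverage histograms against the Poisson
  expectation, GC-binned coverage;
- `aioseq.pool_sim` — stochastic simulator of the whole pooling workflow
  (QC measurement noise, pipetting noise, Dirichlet lane competition);
- `aioseq.genotype_filter` — parental/progeny SNP filtering from VCF with a
  transposable-element BED mask (depth ≥ 4, MQ ≥ 60, QUAL ≥ 60, biallelic,
  fixed parental difference);
- `aioseq.binmap` — sliding-window recombination-breakpoint detection,
  sub-0.5-Mb block smoothing, >300-breakpoint sample exclusion, 100-kb
  interval bin-marker construction, genetic-vs-physical collinearity;
- `aioseq.popgen_sim` — ground-truthed BC₁F₄-style population generator.

## Worked example

Solve the pooling plan for seven rice whole-genome libraries with equal
expected yields and 20.0 ng of target region each (the bundled worksheet,
group A):

```python
from aioseq.datasets import rice_pool_worksheet
from aioseq.pooling import LibraryQC, design_pool

df = rice_pool_worksheet().query("group == 'A'")
qcs = [LibraryQC(f"A{r.sample}", r.conc, r.target_pct / 100, 1.0)
       for r in df.itertuples()]
plan = design_pool(qcs, reference_mass=20.0)
print(plan.display()[["library_id", "conc", "trc", "target_mass", "volume"]])
```

```
  library_id   conc   trc  target_mass  volume
0         A1  21.00  2.31         20.0    8.66
1         A2  25.60  3.33         20.0    6.01
2         A3  19.60  2.55         20.0    7.85
3         A4  20.40  2.45         20.0    8.17
4         A5  24.80  3.22         20.0    6.20
5         A6  22.20  2.66         20.0    7.51
6         A7  24.20  2.90         20.0    6.89
```

Library A1 has 11% of its mass in the 420–520 bp window, so its TRC is
21.00 × 0.11 = 2.31 ng/µL and 20.0/2.31 = 8.66 µL go into the pool.
Internally all arithmetic is at full precision (A5: 20/(24.80 × 0.13) =
6.203 µL, displayed 6.20); rounding is display-only, half-up at 2 decimals.
The same plan is available from the shell:

```sh
aioseq plan --qc qc.tsv --ref-mass 20 --out plan.tsv
```

Other subcommands: `aioseq trace` (target fractions from trace CSVs),
`aioseq eval` (yield reports and ratio tests), `aioseq simulate-pool`,
`aioseq simulate-pop`, `aioseq filter` (VCF → parental markers and progeny
calls) and `aioseq binmap` (calls → blocks → bin matrix).  Every run writes
a JSON manifest with config, input digests and seeds.

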