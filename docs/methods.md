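# Methods

This note documents the models and procedures implemented in `txport`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generators do and do not emulate.

## Spectral-count differential interactomics

### Model and procedure

Spectral counts are treated as a semi-quantitative proxy for protein
abundance in a purification. A recipe is an ordered pipeline over a
proteins × samples matrix with sample metadata (condition, replicate,
bait, no-tag flag):

1. **Flooring** (default 0.1): every count below the floor is set to the
   floor, so downstream log-ratios are finite for proteins absent from a
   sample. Idempotent by construction.
2. **Bait normalization.** `per_sample_bait` rescales each tagged sample
   so its bait count equals the cross-sample mean bait count, correcting
   sample-level recovery; `cross_condition_bait_ratio` rescales one
   condition by the ratio of condition-mean bait counts so the
   between-condition bait ratio is exactly 1 (assertable to machine
   precision). No-tag controls are never rescaled.
3. **Filters.** No-tag filter: remove proteins with mean no-tag count
   strictly above 10. Low-abundance filter: remove proteins with mean
   below 5 in *every* tested condition. Enrichment gates: fold over the
   no-tag mean (floored at 0.1 to avoid division by zero) and a tagged
   mean threshold, combined with `fail_either` (must pass both to stay,
   the default) or `fail_both`. Strictness conventions: "above 10" is
   > 10; "less than five/eight" is < 5 / < 8; "at least twofold" is
   |log2 ratio| ≥ 1 inclusive.
4. **Duplicate collapse.** Rows mapping to one canonical ID (explicit
   map, or the default rule of stripping a `__dup<k>` suffix) keep the
   row with the highest total count; ties go to the lexicographically
   smallest ID.
5. **Statistics.** log2(mean_B/mean_A) on the floored, normalized counts;
   average intensity over all tagged samples; a two-sided two-sample
   t-test on per-replicate normalized counts.
6. **Calls.** `up`/`down` at |log2 ratio| ≥ log2(fold threshold),
   additionally requiring p below the recipe's p threshold where one is
   set. The bait is reported but never called (its ratio is pinned by
   normalization). No multiple-testing correction is applied by default,
   matching the raw p < 0.1 convention of this assay class;
   Benjamini–Hochberg can be applied downstream on the p column.

Filters run in the order the preset narrates; because every filter is
row-wise, the provenance (marginal removals per step) is reproducible by
applying each filter in isolation on the staged matrix and doing set
arithmetic — the test suite and the reproduction script both verify this
equivalence on fuzzed matrices.

### t-test flavor

The default is the pooled-variance (Student) test. With the equal group
sizes used here the pooled and Welch statistics are identical and only
the degrees of freedom differ; at n = 3 per group Welch's Satterthwaite
df (≤ 4) makes the test measurably conservative (null rejection at the
0.1 level near 0.078 in simulation), while the pooled df keeps it
calibrated (0.100). Welch remains available via `equal_var=False`. Groups
with exactly zero variance return p = 1 when their means are equal and
otherwise have variances floored at 1e−12 before testing.

## ChIP-qPCR percent of input

Enrichment is 100 · 2^(Ct_input − c − Ct_IP) with c = log2(1/f) for an
input aliquot fraction f; at the standard f = 0.01, c = log2 100
(≈ 6.644). The constant is computed exactly rather than from the rounded
decimal, so simulation round trips are exact. Processivity is the
3'-amplicon percent divided by the 5'-amplicon percent, with replicate
percents averaged per amplicon *before* the ratio (ratio of means, not
mean of ratios: the per-replicate percent values are the published
plotting unit and the bar is their mean).

## Tiling-array tracks

**Loess MA normalization.** M = log2(IP/input) is regressed on
A = ½·log2(IP·input) with a robust locally weighted regression
(statsmodels lowess; span 0.3 of the data per local fit, 2 robustifying
iterations) and the fit subtracted. This removes smooth
intensity-dependent dye bias, and — as in any MA normalization — also
centers the global M level: absolute enrichment values are therefore
relative to the array-wide average, which is why the expressed-gene
filter threshold (log2 ratio > 1) presumes enriched gene bodies are a
minority of probes. Replicates are combined as the unweighted per-probe
mean of normalized log2 ratios, using available values where a replicate
is missing a probe.

**Gaussian smoothing.** One pass of kernel smoothing onto a regular grid
(default step 10 bp): the value at grid point g is the kernel-weighted
mean of probe values within ±4 sd (default sd 100 bp), with weights
renormalized over the probes actually present so edges and gaps do not
shrink the signal. Grid points with no probe in support are missing, not
zero. Smoothing is linear and shift-equivariant, which the tests assert
directly.

**Metagene profiles.** Genes at least 1 kb long with mean enrichment
log2 ratio strictly above 1 are retained. Each gene is split in the
middle: the 5' half is binned by distance from the TSS, the 3' half by
(negative) offset from the polyA site, in 10-bp bins; minus-strand genes
are coordinate-flipped first. A grid value is treated as a 10-bp span
and distances are span starts, making binning exact under strand
mirroring. Within a gene, a bin's values are averaged first; across
genes, bins are averaged unweighted with the contributing-gene count
reported; bins below a minimum gene count are missing.

**Processivity.** Per gene, the log2 ratio of mean occupancy over the
last versus first 300 bp, windows measured strand-aware inward from the
TSS and polyA site. Occupancy is averaged on the linear scale (log2
values are exponentiated, averaged, and re-logged), matching the
occupancy semantics of the quantity; mean-of-log2 is available via
`log_average=True`. Genes shorter than two windows get no score rather
than a shrunken window, and windows without coverage are reported as
missing with a reason.

The score is computed on the normalized, replicate-combined
**probe-level** signal, not the smoothed grid. The 300-bp window mean
already averages several probes, and Gaussian pre-smoothing (sd 100 bp)
bleeds flanking baseline signal into the end windows: in simulations
with planted decays, scoring the smoothed track attenuates the
recovered-vs-planted regression slope to ≈ 0.86, while probe-level
scoring recovers slope ≈ 1.00 at zero and low noise. Smoothed tracks are
still accepted for grid-based workflows, and the metagene stage stays on
the smoothed grid where the bleed is part of the intended visualization.

## FISH retention

Retention per strain is 100 · n_retained / n_scored with a Wilson score
interval (default 95 %), chosen over Wald because the observed
proportions sit at or near 0 and 1 where Wald degenerates. Strains are
compared with a two-sided Fisher exact test on the 2×2 table. Per-cell
scoring is an input: cells are tallied by eye in the source assay, and
automated image scoring is out of scope.

## Synthetic data

All randomness flows from one explicit seed through independently
spawned streams; identical seed and parameters give byte-identical
outputs.

**AP-MS counts.** Negative binomial (variance = mean + α·mean²) with
prey dispersion α = 0.2 by default — replicate-to-replicate variance of
spectral counts is not published for this assay class, so the dispersion
is a free, configurable choice at a level typical for count data. Prey
means are baseline (default 20) × per-sample bait efficiency ×
2^(planted log2 fold change, applied in non-reference conditions), plus
a background rate. No-tag controls draw from the background alone,
except a "sticky" fraction of preys (default 30 %) that appears there at
its full tagged mean — these represent resin binders and exercise the
no-tag and enrichment filters. The bait row uses a much tighter
dispersion (default 0.02): baits are recovered consistently by
construction of the purification, and realistic bait scatter would
otherwise inject a coherent log2 shift into every bait-normalized prey.
An optional duplicate injector emits `__dup<k>` rows to exercise
collapse logic.

**ChIP tracks.** A single synthetic contig (default 500 kb, so enriched
gene bodies remain a minority of probes, as on a whole-genome array)
with probes every 60 bp. Underlying log2 occupancy is baseline (0)
between genes and, within a gene, the gene enrichment level (default 2)
with a linear 5'→3' decline anchored so that the mean over the last
300 bp sits exactly the planted delta below the mean over the first
300 bp — the planted parameter is thus, by construction, the quantity
the processivity score estimates, rather than an endpoint drop that the
window means would attenuate by (L−300)/(L−1). Per probe, a random
average intensity A is drawn, a polynomial dye-bias curve evaluated at A
is added to M together with Gaussian log-scale noise, and (M, A) are
folded back into positive channel intensities.

**qPCR and FISH.** Ct pairs are the exact inverse of the percent-of-input
formula plus Gaussian cycle noise on the IP Ct; FISH tallies are
binomial draws per strain.

What the generators do **not** emulate: peptide-to-protein inference and
shared peptides, protein-load normalization artifacts, probe sequence
(Tm/GC) effects, spatial array artifacts, chromatin fragment-size
smearing of ChIP signal, replicate-correlated batch effects, or cell
segmentation/scoring ambiguity in FISH. Passing recovery tests therefore
demonstrates correctness of the implemented estimators under the stated
generative model, not robustness to every artifact of real data.

## Problem sizes and numerical choices

The validation suite and the reproduction script use desk-scale problem
sizes chosen to give tight Monte-Carlo error while staying quick: 200
null matrices of ~50 proteins (≈ 10,000 p-values, binomial SD 0.003 on
the rejection rate), 50 fuzzed matrices for provenance equivalence, 100
genes with decays uniform in [0, 2] at probe noise sd 0.05 for
processivity recovery, and 2,000 probes for loess bias removal.
Tolerances on exact identities are machine precision or the printed
precision of the constant involved; stochastic checks use 3-SD binomial
bands or frozen regression floors measured once from the generative
model. Degenerate inputs (zero-variance groups, empty windows, uncovered
genes, zero no-tag means) return defined values or flagged missing
results rather than NaNs propagating silently.

## Known limitations

- The enrichment-gate conjunction for the two-gate preset is
  grammatically ambiguous in its source; `fail_either` (pass both to
  stay) is the default and the choice is recorded in provenance.
- Published per-step removal counts for the two-condition TAP workflow
  (44, 495 of 706, leaving 170) imply overlapping removal sets;
  provenance here reports sequential marginal removals, which need not
  reproduce overlapping published counts without the deposited data.
- MA-loess normalization centers the genome-wide M level; absolute
  enrichment thresholds are only meaningful when enriched regions are a
  minority of probes.
- The replicate-combination rule for arrays (unweighted probe-wise mean)
  is a simple, symmetric default; the originally cited procedure is not
  described in enough detail to reproduce exactly.
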