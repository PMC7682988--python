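# txport

Quantitative analyses for studies of transcription-coupled mRNA export in
budding yeast: differential interactomics of affinity purifications scored
by MS spectral counts, ChIP-based RNA polymerase II (RNAPII) processivity
from qPCR and tiling arrays, and quantification of nuclear polyA-RNA
retention from FISH cell tallies. Every input kind has a synthetic-data
generator with known planted truth, so each stage can be validated by
parameter recovery.

Intended users are groups doing AP-MS interactome screens against no-tag
controls, RNAPII elongation/processivity ChIP experiments, or oligo-dT
FISH export assays who want the published filtering and quantification
rules as reusable, tested code rather than spreadsheet steps.

## What it computes

**Differential interactomes from spectral counts.** A proteins × samples
count matrix with a sample sheet (bait, condition, replicate, no-tag
flag) is processed by a `PurificationRecipe`: counts floored to 0.1,
normalized to the bait level (per-sample, or pinning the between-condition
bait ratio to exactly 1), contaminants removed (mean no-tag count > 10),
low-abundance preys removed (mean < 5 in both conditions), enrichment
gates applied (≥ 5-fold over no-tag, tagged mean ≥ 8), duplicate IDs
collapsed, then per protein

&nbsp;&nbsp;&nbsp;&nbsp;log2 ratio = log2( mean_B / mean_A ),&nbsp;&nbsp;
p from a two-sided two-sample t-test on replicate counts,

with `up`/`down` calls at |log2 ratio| ≥ 1 (and p < 0.1 where the recipe
uses a p gate). Three presets — `rpb1_fcp1`, `ubp15_tap`, `mex67_ubp15` —
encode the published workflows; every threshold is a parameter.

**ChIP-qPCR percent of input.** For an amplicon with cycle thresholds
Ct_input (measured on an input aliquot, fraction *f* of the IP material)
and Ct_IP:

&nbsp;&nbsp;&nbsp;&nbsp;% input = 100 · 2^(Ct_input − c − Ct_IP), c = log2(1/f)

(c = log2 100 ≈ 6.644 at the standard 1 % input). RNAPII processivity over
a long gene is the ratio of percent input at a 3' amplicon to a 5'
amplicon, with replicate percents averaged before the ratio.

**ChIP-chip tracks.** Two-channel probe intensities are loess-normalized
in MA space (M = log2 IP/input against A = mean log2 intensity),
replicates combined probe-wise, and the track smoothed once with a
Gaussian kernel (sd 100 bp) onto a 10-bp grid. Genes ≥ 1 kb with mean
enrichment log2 ratio > 1 are split in the middle and their halves
aligned on the TSS and polyA site to build a 10-bp-binned metagene
profile. Per-gene processivity is the log2 ratio of occupancy over the
last versus first 300 bp, scored on the normalized probe-level signal.

**polyA FISH retention.** Per-strain tallies (cells scored, cells with
nuclear polyA signal) become retention percentages with Wilson score
intervals and pairwise two-sided Fisher exact tests.

## Worked example

FISH tallies from four strains (`tallies.tsv` holds strain, n_scored,
n_retained — here the published counts 0/200, 0/200, 172/222, 11/227):

```sh
txport fish --tallies tallies.tsv --out-prefix fish
cat fish.retention.tsv
```

```text
strain	n_scored	n_retained	percent	ci_low	ci_high
WT	200	0	0	0	1.885
ubp15D	200	0	0	0	1.885
rsp5-1	222	172	77.48	71.54	82.48
ubp15D_rsp5-1	227	11	4.846	2.727	8.467
```

The rsp5-1 mutant retains polyA RNA in the nucleus in 77.5 % of cells
(95 % CI 71.5–82.5); deleting *UBP15* on top of it drops retention below
5 %. The pairwise table (`fish.pairwise.tsv`) puts the rsp5-1 vs double
mutant difference at p ≈ 1.4e−62.

Simulated AP-MS screen end to end:

```sh
txport simulate-apms --seed 7 --n-proteins 120 --out-prefix sim
txport interactome --counts sim.counts.tsv --samples sim.samples.tsv \
    --recipe mex67_ubp15 --conditions WT,mutant --out-prefix res
```

```text
INFO txport: retained 84 of 120 proteins
```

`res.result.tsv` lists every input protein with its log2 ratio, average
intensity, p-value, call, and (for removed proteins) the filter that
removed it; `res.provenance.tsv` records removals per step. With seed 7
the recipe makes 8 differential calls, e.g.

```text
protein  log2_ratio  p_value  call
P0003        -1.461    0.021  down
P0004        -2.020    0.080  down
P0069         1.078    0.038  up
```

recovering planted fold-changed interactors while the sticky-contaminant
layer is removed by the enrichment gate (`sim.truth.tsv` records the
planted values for comparison).

The ChIP side runs the same way: `simulate-chip` → `chip-normalize` →
`chip-smooth` → `chip-metagene` / `chip-processivity`, and `simulate-qpcr`
→ `chip-qpcr`. Every command writes a JSON manifest tying its output to
input digests, parameters, and the seed.

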