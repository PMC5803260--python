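# Methods

## The experimental design being modeled

The package targets site-anchored damage experiments in which a
restriction enzyme with ~1200 annotated genomic recognition sites is
activated in cells and cleaves a reproducible subset of them ("cut"
sites, ~80 at full scale), identified independently by a per-site
cleavage-efficiency score.  Coverage tracks (ChIP-seq of an RNA:DNA
helicase such as senataxin, of RNA polymerase II, and DRIP-seq of
RNA:DNA hybrids) are compared between an undamaged and a damaged
condition.  All downstream quantities are functions of windowed coverage
around the annotated sites, of gene annotations with expression levels,
and of qPCR cycle thresholds.

## Synthetic-data generative model

The simulator produces every input with known ground truth.

**Genome.**  `n_chromosomes` chromosomes of `chrom_length` bp carry
`n_genes` non-overlapping genes with uniform lengths in
`gene_length_range` and random strands, placed with random gaps inside an
`edge_margin` (default 20 kb) that keeps all analysis windows on-chromosome.
Expression is log-normal (`expression_log_mean` = 1, `expression_log_sd`
= 1, in arbitrary coverage units) with a `silent_gene_fraction` (default
0.3) set to zero, giving the long-tailed activity distribution that makes
four-way stratification meaningful.  Of `n_sites` annotated break sites,
`n_cut` carry the cut flag; a `cut_in_active_fraction` (default 0.8) of
cut sites is placed inside expressed genes and the rest in silent or
intergenic territory, reflecting that cleaved recognition sites occur in
both.  Cut sites draw a cleavage efficiency uniform in
`cleavage_efficiency_range` (default 0.4–1.0); uncut sites have
efficiency 0.  `min_site_spacing` (default 0) optionally enforces a
minimum distance between sites; the calibration preset uses it to make
quantification windows disjoint (below).

**Scale.**  The default configuration — one 2 Mb chromosome, 60 genes,
120 sites, 20 cut — preserves the full-scale geometry (site density,
cut fraction, window sizes) at a size where every stage runs in seconds;
`full_scale_config()` provides the full ~1200-site / 80-cut system on
4 × 3 Mb.  The annotation counts of the full-scale system are internally
inconsistent in the literature (1211 annotated sites vs 80 cut + 1139
uncut = 1219); both totals are exposed as presets and neither is
privileged.

**ChIP tracks.**  Expected coverage is a uniform background
(`background_rate` = 0.5 per bp) plus, for the helicase in the damaged
condition, one peak per cut site of half-width `enrichment_halfwidth`
(1 kb — the 1–2 kb accumulation window) and amplitude
`chip_enrichment × cleavage_efficiency × expression` of the containing
gene.  Silent and intergenic cut sites therefore get no helicase peak,
which is what couples recruitment to transcription.  PolII tracks carry
gene-body signal `polII_amp × expression`, condition-independent.  The
`generic` assay is background-only in both conditions and serves as the
exact null for calibration.  Peaks are boxcars by default (closed-form
window integrals make the generator testable against hand computation);
a Gaussian shape (σ = half-width/2) is available.

**DRIP tracks.**  Baseline (both conditions): background, gene-body
hybrids (`drip_body_amp × expression`) and TSS/TTS peaks
(`drip_tss_amp × expression`, half-width 750 bp) on expressed genes.  The
damaged condition multiplies, per cut site in an expressed gene, a
`drip_gain`-fold gain (default 2) over ±`dsb_gain_halfwidth` (5 kb), a
central depletion factor `1 − senataxin_activity × depletion_depth`
(defaults 1.0 × 0.8) over ±`depletion_halfwidth` (1 kb), and a
`body_loss` factor (0.5) on the damaged gene body *outside* the gain
window — break-proximal accumulation dominates locally while hybrids
decline across the rest of the damaged gene.  Setting
`senataxin_activity = 0` emulates helicase knockdown: the central
depletion disappears while the flanking gain remains.  A
`silent_gain_fraction` (0.1) of silent cut sites receives a reduced gain
(`silent_gain_scale` = 0.3), modeling the minority of seemingly
untranscribed loci that still gain hybrids.

**Noise.**  Per-base Poisson counts around the expected coverage by
default (integer counts, variance = mean, as for deduplicated
single-end read starts); a Gaussian alternative with standard deviation
`noise_scale × √mean` (clipped at zero) trades realism for speed;
`noise_model="none"` disables noise for closed-form tests.  The library
size of a simulated track is its total signal.

**qPCR.**  Ct = reference_ct − log_E(quantity) + N(0, noise_sd), with
efficiency E ∈ (1, 2] and E = 2 (perfect doubling) the default for all
assays — real efficiencies are assay-specific and unreported in the
motivating work, and E is configurable where it matters.  The resection
simulator inverts the ssDNA% formula analytically
(ΔCt = 1 + log₂(1/f − 0.5) for true single-stranded fraction f), so the
zero-noise round trip through the assay is exact to floating-point
precision.

**Determinism.**  Every stage draws from
`default_rng([seed, crc32(stage), …])` — one stream per (seed, stage
name), platform-independent; adding a stage never perturbs another
stage's draws, and identical configurations give bit-identical tracks,
tables and pipeline TSVs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mappability and GC biases, fragment-size
effects, copy-number and replication structure, chromatin-state
covariates of cleavage, spatial correlation of background noise,
inter-replicate biological variability of sequencing tracks, and qPCR
efficiency drift.  Tests demonstrate that the quantification is exact and
the statistics calibrated *given* the stated sampling model, not that the
model captures every property of sequencing data.

## Quantification conventions

* Coordinates are 0-based half-open everywhere in memory; conversion (if
  any) happens only at format boundaries.  Chromosome names match
  exactly; a mismatch is an error, never a silent drop.
* A site's anchor is the midpoint of its recognition interval, rounded
  down.  A window of half-width h covers [c − h, c + h), truncated at
  chromosome ends; mean statistics use the truncated width, and averaged
  profiles track per-offset denominators so truncation does not bias
  them.  Sites are never dropped for truncation.
* Windowed "counts" are sums of per-million-normalized per-base
  coverage (the sum-of-read-starts alternative is a matter of the track
  supplied, not of the window code).
* Heatmap bins report the **mean** signal per bin, so for fully covered
  windows bin-mean × bin-width sums exactly to the window sum
  (a conservation law the tests enforce).  Rows order by decreasing
  cleavage efficiency (or a supplied score), ties broken by site id.
* Metagene body bin b of a gene of length L covers bases
  [⌊(b−1)L/100⌋, ⌊bL/100⌋); minus-strand genes are reversed so bin 1 is
  always 5′.  Genes shorter than the body-bin count are excluded and
  counted.  Aggregation across genes is unweighted by default
  (length-weighting available), since per-gene profiles are already
  length-normalized.
* Quartiles use linear interpolation between order statistics (the
  default of mainstream statistics stacks); Tukey fences at
  q1 − 1.5 IQR and q3 + 1.5 IQR; whiskers are the extreme data values
  inside the fences; outliers lie strictly outside.
* "Genes near a DSB" means: a cut site inside the gene, or a cut site
  whose distance to the nearest gene base is strictly less than 1 kb.
  Uncut annotated sites never select a gene.

## Statistical choices

* Cut vs uncut compares **different** site sets, so the unpaired
  two-sided Mann–Whitney U test is used; "paired Mann–Whitney" is a
  contradiction this package resolves by also providing the Wilcoxon
  signed-rank test for before/after comparisons at the same sites.
* The U test uses exact enumeration when both groups have ≤ 8
  observations and the pooled values are tie-free, and the tie-corrected
  normal approximation with continuity correction otherwise (scipy's
  implementations of both).
* Calibration is verified by simulation: under the null generator
  (background-only track) the test rejects at the nominal 5% rate
  (500 replicates, within ±0.02), and at the default enrichment effect
  power exceeds 0.9.  The calibration design
  (`simulate.calibration_config`) spaces sites ≥ 2.5 kb apart and
  quantifies ±1 kb windows so that per-site signals are independent —
  overlapping windows share noise, violate exchangeability and inflate
  the type-I error, which is a property of the design, not of the test.
* No multiple-testing correction is applied: each track yields one
  planned comparison, and the pipeline report states this.

## qPCR assay interpretations

* The repair-kinetics readout ("percent of sites that remain broken") has
  no published closed form; this package uses the input-normalized
  two-power ratio s(t) = 2^(Ct_input − Ct_pulldown),
  100·s(t)/s(reference), normalizing to input at **every** time point.
  It is 100 at the reference by construction; values above 100 are
  reported as-is and flagged downstream.
* The ΔΔCt translocation frequency combines its two control amplicons by
  the arithmetic mean of their Cts (the geometric mean of their
  quantities), standard multi-reference practice.
* DRIP-qPCR defaults to percent-input; enrichment over a negative control
  region is provided as `qpcr.drip_enrichment` for users who prefer it.
* ssDNA% is clamped to [0, 100] for reporting (the raw formula ranges up
  to 200 as ΔCt → −∞); the raw value is available via `clamp=False`.
* Replicate aggregation (mean, s.e.m. with n−1 denominator) always
  happens after per-replicate assay computation, never on pooled Cts.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
and the acceptance script in under one minute on a single CPU: the
default simulated genome is 2 Mb / 120 sites / 20 cut; the full-scale
preset (4 × 3 Mb, 1211 sites, 80 cut) is used where the class-of-20
geometry itself is the claim; calibration uses 500 null and 100 powered
replicates on a 400 kb genome with 40 widely-spaced sites.  All of these
are configuration values, not limits of the implementation.

## Known limitations

The simulator's effects are piecewise-constant (boxcar) by default, so
averaged profiles have sharp shoulders rather than the smooth shapes of
real data.  Genome simulation places genes independently of each other
and sites independently of chromatin context.  The pipeline's DRIP
profile summaries average over cut sites in expressed genes only.
bigwig input is not implemented; bedGraph (with a chrom.sizes file) is
the canonical interchange, and any bigwig can be converted externally.
The Mann–Whitney exact path applies only to tie-free samples; heavily
tied small samples fall back to the approximation.
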