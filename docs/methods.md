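# Methods

## Scope and model

The package implements a population-level adaptive-introgression scan for an
admixed recipient population with three donor populations. Its inputs are
(a) per-SNP donor-copying proportions for the recipient (the output format of
chromosome-painting tools, reduced to `chrom pos p_MS p_BMX p_EUW`),
(b) phased biallelic genotypes for all populations (VCF 4.2),
(c) a QTL table, and (d) a chromosome-length table. Upstream steps — read
mapping, variant calling, phasing/imputation, and the painting EM itself —
are outside the package; the synthetic generator stands in for their output.

Coordinates are 0-based half-open in memory. On disk, SNP and QTL tables are
1-based inclusive and BED outputs 0-based half-open; every file header states
its convention and every writer round-trips through its reader.

## Windowed ancestry

Windows are non-overlapping 50-kb intervals per chromosome, with the terminal
window truncated at the chromosome end (total count Σ ceil(L/50 kb)); short
terminal windows are kept, not merged. Window donor means are unweighted
means over the SNPs in the window. Windows without SNPs carry undefined
means and are excluded from candidate calling and from all empirical
quantiles — they have no observable value under a SNP-averaged definition.

The genome-wide summary reports, per donor, the mean and standard error
across SNPs (SE = sample SD / √n) as the primary figure, with the mean
across SNP-bearing windows alongside. Across-SNPs is the primary definition
because the per-SNP track is the estimator's native resolution; whether a
published SE of this kind is taken across SNPs or windows is generally
ambiguous, so both are exposed.

## Hudson FST

Per biallelic site, with sample frequencies p₁, p₂ and allele-call counts
n₁, n₂ (missing genotypes reduce n at that site):

numerator (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1);
denominator p₁(1−p₂) + p₂(1−p₁). Sites with n < 2 in either population or
zero denominator (shared monomorphism) are undefined. This is the canonical
two-population estimator with the unbiased within-population correction; it
is symmetric in the populations and invariant to which allele is labelled
reference.

Site values may be negative; clamping to 0 happens only at the window level,
after averaging, so window values lie in [0, 1] while site-level noise
cancels correctly within a window. The recipient–Chinese composite track is
the per-window mean of the recipient–MS and recipient–BMX tracks, undefined
when either is.

Quantile thresholds use linear interpolation between order statistics
(numpy's default), a stated reproducible convention. "Extreme" means
strictly above the threshold.

## Candidate and top regions

Candidate windows require Chinese ancestry strictly greater than 0.5 and
MS–BMX FST not strictly above the 95% empirical quantile; both readings are
literal and each is a config switch. Windows with undefined FST cannot be
candidates. Adjacent survivors are also reported merged into runs.

Top-donor regions: seeds are taken in descending donor ancestry among
SNP-bearing, non-extreme-FST windows; a seed extends in both directions
while the neighbouring window is on the same chromosome, has donor ancestry
≥ 0.5, is not extreme-FST, is SNP-bearing, and is not already assigned to a
region. The stop rule uses ≥ 0.5 for continuation (stopping at "< 50%")
while candidate calling demands > 0.5 — the deliberate asymmetry follows
the two different phrasings of the respective rules and is configurable.
Regions rank by seed-window ancestry (not length), ties broken by earlier
genomic coordinate; the top five regions with at least two windows are
returned, with a `short` flag when fewer qualify.

## QTL filtering and enrichment

Filtering is two-stage with audited counts: linkage-mapped records drop
first (uncertain genomic locations), then records on non-autosomes (unknown
chromosome names count as non-autosomal, audited rather than fatal) or
spanning more than 1 Mb. Records with identical (trait group, chromosome,
start, end) collapse to one; identical intervals in *different* groups count
separately — the group-inclusive key is the primary tally and the
group-agnostic tally is reported in the audit for comparison. The peak is
the interval midpoint.

The permutation null concatenates the autosomal windows, in layout order,
into a circle and rotates the entire candidate-window set by a uniform
offset of 1..W−1 whole windows; peaks stay fixed, and membership is
window-level (a peak is inside a rotated region iff its home window index
is in the rotated set). Choices that matter:

- **Whole-window rotation.** Keeps rotated regions unions of grid windows
  and avoids base-pair edge effects at the circle seam; inter-region
  spacing is preserved exactly.
- **Identity offset excluded.** Offset 0 reproduces the observation, so
  including it would make the null tautologically contain the observed
  count; it is excluded from the draws (and from the exact-enumeration
  reference used in tests).
- **p = r/n.** The empirical p-value is the fraction of rotations whose
  count reaches the observed count; the (r+1)/(n+1) variant is available
  in principle but r/n is the default because it reproduces p-values that
  are exact multiples of 1/n_perm.
- **Shared offsets across scopes.** One offset stream serves the all-traits
  and the five per-group tests, so the six results are comparable under
  identical nulls; the seed is recorded in each result.

With 10,000 rotations the Monte-Carlo SE of a p near 0.05 is about 0.002.
The test is slightly conservative under the null because the count
distribution is discrete; calibration at nominal 5% is verified by
simulation in the test suite.

## Haplotype strips

For a region, phased biallelic SNPs are extracted (monomorphic-in-selection
columns dropped; missing or unphased genotypes are rejected — inputs are
assumed imputed and phased upstream). Each haplotype's distance to the
reference population is the Hamming distance to the reference majority
consensus (per-site ties → allele 0); a per-haplotype minimum-distance
alternative is available behind a flag. Rows are clustered by average
linkage on pairwise Hamming distances and cut at a configurable height
(default 0, i.e. blocks are groups of identical haplotypes — any positive
default would be arbitrary). Blocks are ordered by increasing mean distance
to the reference (ties by first input index); within a block rows sort by
(distance, allele string, input index). The allele-string term keeps
identical haplotypes adjacent in every case, which pure input-order
tie-breaking cannot guarantee once a cut height groups non-identical rows.
The tested artifact is the ordered structure; image rendering is a thin
optional layer.

## Synthetic data generator

The generator emulates the study conditions, not coalescent realism:

- **Donor frequencies** follow Balding–Nichols draws on a two-level tree:
  an Asian branch (drift F = 0.10) shared by MS and BMX diverges from the
  ancestral frequency (uniform on 0.05–0.95), then MS and BMX drift from
  the Asian node (F = 0.05 each) and EUW from the root (F = 0.20). The
  levels are chosen so MS–BMX differentiation sits clearly below either
  donor's differentiation from EUW, matching the qualitative relation in
  the real populations; no published simulator exists for this design.
- **Recipient ancestry** is a Markov tract process per haplotype and
  chromosome: exponential tract lengths (default mean 100 kb,
  switch rate 1e-5/bp), donors drawn from the stationary proportions
  (0.12, 0.13, 0.75). Inside planted sweep regions the draw is overridden
  by the boosted probability (default 0.95 for the boosted donor, the
  remainder split proportionally), and tracts truncate at sweep boundaries
  so the boost applies exactly inside the region. Each tract copies alleles
  from one randomly chosen donor haplotype, re-chosen at every switch —
  including same-donor switches, so tracts are the Markov segments and
  their mean length is 1/switch-rate. This preserves within-tract haplotype
  structure for the clustering module.
- **The ancestry track** delivered to the pipeline is the truth: the
  across-haplotype donor fraction at each SNP. Optional symmetric Dirichlet
  blur (concentration configurable, default off) mimics painting
  uncertainty, letting tests separate pipeline error from inference error.
- **The QTL table** mirrors the database composition: 35% linkage-mapped,
  five trait groups at the observed proportions
  (0.483/0.060/0.053/0.301/0.103), log-normal lengths (log-mean 9.0,
  log-SD 1.5, floor 40 bp, cap 1 Mb), a 2% non-autosomal decoy fraction to
  exercise the location filter, and a configurable fraction
  `enrichment_rho` of association-record midpoints planted uniformly inside
  sweep regions.
- **Scale.** The default genome is 18 autosomes × 5 Mb with SNP density
  2e-4/bp (~18,000 SNPs, ~10 per window), 40 donor haplotypes per panel and
  60 recipient haplotypes — a deliberately scaled-down genome that keeps
  every window/region/permutation mechanism identical to full scale while
  a complete study simulates in under a second.

All randomness flows from one seed through named generator streams
(`panels`, `admixed`, `qtl`); identical configs are bit-identical.

What the generator does **not** emulate: recombination maps or hotspots,
mutation, LD decay within donor panels (donor haplotypes are independent
Bernoulli draws per site), painting error beyond the optional Dirichlet
blur, tract-length calibration to a specific admixture age (the switch rate
is a free knob), and sex chromosomes beyond the QTL decoy label. Passing
tests therefore demonstrate the correctness and calibration of the
*pipeline* — aggregation, estimators, region logic, permutation inference —
on data with known truth, not the accuracy of chromosome painting on real
genomes.

## Numerical and degenerate-input conventions

- Proportions must sum to 1 within 1e-6 per SNP (readers reject offending
  lines by number); truth tracks satisfy 1e-9.
- Empty candidate sets make the permutation p undefined (with a reason
  code) rather than failing the run; zero peaks give p = 1 under the ≥
  comparison.
- Windows with no defined FST sites stay undefined and are excluded from
  means and quantiles; they terminate region extension.
- The pipeline manifest records config, seed, version and per-stage audit
  counts; timings go to the log so outputs stay byte-reproducible.

## Known limitations

- FST windows with very few SNPs are noisy; the top-5% exclusion therefore
  removes ~5% of genuinely introgressed windows at random, which bounds
  sweep-window recovery near 95% by construction.
- The ancestry/composite-FST correlation on synthetic data is reliably
  negative but weak, because the recipient copies donor haplotypes without
  recipient-specific drift; its magnitude on real data is not reproduced.
- The circular rotation preserves the candidate set's internal spacing but
  assumes exchangeability of window positions around the circle; strong
  large-scale heterogeneity in QTL density (e.g. assembly artifacts) would
  violate it on real data.
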