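# Methods

This note documents the models implemented in smmipkit, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the design choices made where the design was genuinely open.

## Assay model

A single-molecule molecular inversion probe (smMIP) is an oligonucleotide
with two targeting arms joined by a common backbone. The arms hybridize to
the flanks of a genomic target; gap-fill and ligation circularize the probe
around the captured sequence. The backbone carries a random tag (unique
molecular barcode, UMB) so that each captured molecule — not each PCR
copy — can be counted. With a 5-base tag the tag space is 4⁵ = 1024
molecules per probe; deduplicated coverage per probe is bounded by
min(raw reads, 1024).

The panel geometry is fixed: every probe captures `capture_length` bp
(default 110), and adjacent probes on the same tile must overlap by
`min_overlap`–`max_overlap` bp (default 20–40) so no targeted base falls in
a seam. Gaps between tiles (e.g. between exons) are expected and reported
as informational, not as violations. Coordinates are 0-based half-open
throughout; 1-based inclusive panel files are converted at the reader
boundary (`one_based=True`), which confines off-by-one risk to one line of
code.

## Read structure and assignment

Real smMIP libraries differ in where the arms and tag appear on each mate.
The package's declared structure — R1 = extension arm + insert, R2 = UMB +
ligation arm + reverse-complemented insert — is self-consistent with the
simulator and configurable at the assignment boundary. Arms are matched by
exact-position Hamming comparison with at most `max_arm_mismatch`
mismatches per arm (default 1, no indels): arms are primer-grade sequences,
so positional Hamming matching is fast and adequate at desk scale. Reads
shorter than arm + tag are unassigned; conservation (assigned + unassigned
= total) holds by construction. A post-alignment SAM/BAM intake that
recovers the tag from a `name#UMB` read-name suffix is provided for
pipelines that align first; alignment itself is external.

## Deduplication

Reads sharing (probe, UMB) are collapsed to a single representative chosen
uniformly at random under a caller-supplied seed (discard-at-random;
consensus collapse is a documented extension point). Tags containing N
cannot define a molecule and are excluded, counted separately. Groups are
processed in sorted order so identical inputs and seed give byte-identical
coverage reports. At depth m molecules per probe the expected number of
distinct tags is 4⁵(1 − (1 − 4⁻⁵)^m); the shortfall from m is tag-collision
loss, ≈ m²/2·4⁻⁵ for m ≪ 1024. Tests use this closed form as the oracle.

## Pool rebalancing

Under equimolar pooling each of n probes should draw 1/n of the run's
deduplicated reads. A probe is *under-performing* when its proportion
falls below `low_cut` **or** its deduplicated count is under `min_reads`
(default 30); the two signals are combined with OR because either alone
indicates the probe cannot support variant calling, and boosting an
already-adequate probe is cheap. Defaults `low_cut = 1e-4` and `high_cut =
1e-2` bracket the 1/n ≈ 0.001 expectation of a ~1000-probe pool by a
factor of ten either way; for panels of very different size the same
structure applies as 0.1/n and 10/n, and the cutoffs are parameters.
Proportions are computed on deduplicated reads (configurable): duplicates
measure amplification, not capture. The plan boosts under-performers
10-fold in the phosphorylated pool and adds an equimolar unphosphorylated
competitor for over-performers; competitor chemistry is not modelled beyond
a single named parameter (`competitor_effect`, default 0.5× effective
capture) that lives in the simulator.

## CNV calling

The caller re-implements the ExomeDepth family of read-depth methods used
by exon CNV tools on targeted panels:

1. **Aggregation.** Each probe maps to exactly one exon by maximal target
   overlap; per-sample deduplicated counts are summed per exon. Exons with
   zero counts in more than half the batch are masked. Batches need
   ≥ 17 samples by default (`enforce_min_batch=False` for toy tests): the
   expected fractions are estimated from the batch itself, and small
   batches make them unstable.
2. **Reference selection.** Candidates are ranked by Pearson correlation
   of count profiles with the test sample. The reference is the longest
   correlation-ranked prefix whose aggregated profile keeps the estimated
   test-vs-reference overdispersion within 15% of its minimum over all
   prefixes — accumulation effectively continues while the dispersion does
   not increase, and a poorly matched sample ranked last is left out.
   The dispersion statistic is the mean of squared standardized residuals
   (x − np)²/(np(1−p)), whose expectation is 1 + (n−1)ρ under a
   beta-binomial with overdispersion ρ. Exons where the test deviates
   grossly from the robust (median) batch profile — its own candidate
   CNVs — are flagged once (z² > χ²₁(0.995)) and held out of this
   comparison, so a real CNV cannot mask a bad reference choice, and ρ for
   the emission model is estimated on the same held-in exons
   (method of moments, clipped to [1e-6, 0.2]).
3. **Emission model.** For exon j with reference expected fraction p_j and
   test total N, the observed count is beta-binomial(N, p′_j, ρ) where the
   state with copy fraction m ∈ {0.5, 1, 1.5} scales the fraction on the
   odds scale: p′ = m·p/(m·p + 1 − p). For the small per-exon fractions
   involved this equals m·p to first order while remaining a probability.
4. **Decoding.** A three-state HMM (deletion / diploid / duplication) along
   each gene's exon order, transition probability into a CNV state 1e-4,
   CNV-state self-transition 0.9 (all surfaced in `CnvParams`), decoded by
   Viterbi. Non-diploid segments become calls with the summed per-exon
   log-likelihood ratio versus diploid as score and the mean
   observed/expected ratio; copy estimate 0 / 1 / 3+ from the ratio bands
   < 0.25 / < 0.75 / > 1.25. On ≤ 6 exons the Viterbi path is verified
   against exhaustive enumeration of all 3⁶ state paths.

Exon-level (rather than probe-level) windows are used because call
boundaries are reported in exons and a single exon typically carries 2–4
probes, which stabilizes counts. When sex metadata is provided, X-linked
exons are compared only against same-sex reference samples; otherwise a
warning is issued. Whole-sample normalization slightly shrinks the
apparent ratio of large duplications (a duplicated region inflates the
test total); deletions are unaffected in the limit and boundaries of
homozygous events are exact because deleted exons produce no molecules.

## qPCR relative quantification

The comparative-Ct method with a two-copy calibrator: RQ =
efficiency^(−ΔΔCt), efficiency 2.0 by default (perfect doubling; exposed
as a parameter since real assays run at 1.9–2.0). Copy bands are half-open
nearest-band intervals: [0.25, 0.75) → 1 copy, [0.75, 1.25) → 2,
[1.25, 1.75) → 3, anything outside → unclassified. RQ is strictly
decreasing in ΔΔCt and exactly 1 at ΔΔCt = 0.

## Diagnostic status, yield and concordance

Only P/LP variants are diagnostic; classification is input metadata
(ACMG-style assertion logic is out of scope). Autosomal-recessive genes
require a homozygous P/LP variant, ≥ 2 heterozygous P/LP variants
(compound hets are assumed in trans when unphased, which overcalls if both
hits are cis — flagged as an assumption), a homozygous CNV, or a
heterozygous SNV plus overlapping heterozygous CNV; X-linked genes accept
hemizygous (or homozygous) variants. Exactly one AR heterozygous P/LP hit
is *partial*. Stratum yields carry exact Clopper–Pearson 95% intervals
computed from beta quantiles. Concordance is case-level: a case is
concordant when every truth variant is recovered by id; extra findings do
not break concordance. A missed variant whose coordinates fall outside the
panel footprint is annotated `uncovered_target`, separating design gaps
from caller misses.

## Synthetic-data generator

The generator emulates: per-probe capture-efficiency variation (log-normal
with sd `capture_sigma`, default 0.5, plus a configured fraction of "poor"
probes scaled by `poor_factor` — reproducing the long lower tail of
per-probe coverage that motivates rebalancing), Poisson molecule sampling
at mean depth × efficiency × copy-state × pool weight, uniform 5-base
tags, geometric PCR duplicate counts (mean `pcr_dup_mean`, default 1.6,
giving a duplicate fraction near 38%), independent per-base substitution
errors (default 1e-3, ~Q30), heterozygous/homozygous SNVs drawn per
molecule, and exon-range CNVs as copy scalings {0, 0.5, 1, 1.5}. Default
cohort conditions are 17 samples at ~200 molecules per probe.

It does **not** emulate: real genomic sequence content or pseudogene
homology, GC or fragment-length bias, quality-score error profiles,
indels or structural rearrangements, capture chemistry kinetics, or
index hopping. Passing tests therefore demonstrate the correctness of the
molecule-accounting, rebalancing and copy-state inference logic under the
declared generative model — not performance on real libraries, where
alignment artifacts and homology (the classic failure mode for
pseudogene-shadowed genes) dominate.

A fast count-level path (`simulate_coverage_counts`) draws the same
molecules and tags without emitting reads; batch-level tests use it so the
default suite runs in seconds. Read-level problem sizes in tests are a few
thousand pairs per sample; batch-level CNV evaluations use 20 batches of
17 samples over two 14-exon genes (≈ 68 probes). All randomness flows
from `numpy.random.default_rng(seed)`; identical configs and seeds give
byte-identical FASTQs and manifests.

## Known limitations

- The pileup SNV caller is deliberately minimal (no indels, no base
  qualities, fixed genotype bands at 0.2/0.8); it exists so the
  simulate → process → call loop closes at desk scale.
- The reference-selection dispersion guard assumes most of the batch is
  well-behaved; a batch where half the samples share a systematic artifact
  would be absorbed into the reference.
- Duplications spanning a large share of a small panel shrink their own
  observed/expected ratio through the sample total (see above); on
  many-gene panels the effect is negligible.
- Multi-round rebalancing schedules and oligo synthesis/phosphorylation
  chemistry are out of scope.
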