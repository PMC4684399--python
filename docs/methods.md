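# Methods

This note documents the models and procedures `capmut` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Somatic classification

Calls are read from VCF 4.x with per-sample GT and AD fields;
multi-allelic records are decomposed into one paired call per ALT allele.
The classification is a pure function of one call:

* **Somatic rule.**  Somatic iff the tumor genotype contains the
  alternate allele and the normal genotype is homozygous reference.
  Genotypes are unordered and unphased; "contains" means at least one
  allele equals the ALT.
* **Hard filters.**  Substitutions (SNVs and MNVs, which are judged by
  the substitution rule set): quality < 40, QD < 5.0, HRun > 5,
  FS > 200.0.  Indels: quality < 40, QD < 2.0, ReadPosRankSum < −20.0,
  FS > 200.0.  Calls below the emit quality of 10 fail with their own
  reason.  All comparisons are strict, and an absent annotation passes
  its filter — "value < threshold" is false when there is no value, which
  mirrors how variant callers emit these annotations only when computable.
* **Confidence tiers.**  High confidence requires passing filters, an
  informative normal depth (sum of the allele-depth fields; a DP-based
  reading is possible but AD-sum is the reproducible default) of ≥ 10
  with ≤ 1 alternate read, and ≥ 3 alternate reads in the tumor.  Every
  somatic call is exactly one of high or low confidence.

## Effect annotation

Variants are annotated against transcript models (exon structure + CDS
bounds).  CDS substitutions are decided by translating the affected
codon(s) on the coding strand before and after the change; CDS indels by
whether the length change is a multiple of three.  Variants within
`splice_window` (default 2 bp, the canonical donor/acceptor dinucleotide)
*inside* an intron of a coding transcript are splicing.  Exonic non-CDS
positions are UTR5/UTR3 by their side of the CDS; positions within
1000 bp 5' of the transcription start are upstream; the remainder of the
transcript span is intronic; hits on non-coding transcripts are ncRNA;
everything else is intergenic.

When a variant hits several transcripts the most severe category wins.
The severity order is biological impact: frameshift > stopgain >
stoploss > splicing > non-frameshift indel > nonsynonymous > synonymous >
UTR5 > UTR3 > upstream > intronic > ncRNA > intergenic > unknown.

## Catalogue matching

All comparisons use a canonical variant spelling: common suffix then
prefix trimmed (alleles may become empty, as in unanchored `CT>-`
notation) and pure indels left-aligned against the reference.  Exact
matching is equality of canonical spellings, so representation-equivalent
indels (anchored vs unanchored, or shifted within a repeat) match
exactly.  Loose matching additionally accepts:

* **Shifted** — same alleles within a strict < 5 bp window.  For indels
  the shift is checked for repeat support (the set of
  representation-equivalent positions is enumerated by sliding through
  the homopolymer/tandem context); shifts without repeat support are
  still reported but flagged positional-only.
* **Split MNV** — a catalogue multi-nucleotide substitution is matched
  when the call set contains SNVs jointly reconstructing all its changed
  bases (callers often emit an MNV as separate adjacent SNV records).

Novel = matched by neither route.  The bookkeeping identity
known_exact + known_loose_only + novel = total holds on any input.

## Spectrum and enrichment

Substitutions are collapsed to the six pyrimidine-centered classes and
trinucleotide contexts to the 32 pyrimidine-centered X[Y]Z forms
(purine-centered windows are reverse-complemented); contexts whose flank
is off-contig or contains N are excluded and counted.

Strata: *coding* = CDS bases after class-precedence resolution
(CDS > UTR5 > UTR3 > upstream > intronic_flank > other); *non-coding* =
all other targeted bases, by default including the 30 bp intronic
analysis flanks (configurable, since it is a design choice whether flank
bases belong in the non-coding denominator).

Eligible denominators count each base once, independent of coverage:
G/C (or A/T) base counts for a class, per-context window counts (windows
centered in the stratum; flanks may extend outside it) for a context.
The per-class/context 2×2 table (mutated vs eligible−mutated, coding vs
non-coding, pooled across samples) yields OR = (a/b)/(c/d), the Woolf
log-OR normal-approximation 95 % CI, and a Wald p — algebraically the
stratum coefficient of a saturated binomial logistic model on the
aggregated counts, which is how the tests cross-check it against a GLM
fit.  Bonferroni multiplies by the family size: 6 for classes, 32 for
contexts (configurable; the family is the set of simultaneously reported
comparisons).  Any zero cell flags the result undefined rather than
raising.  A per-sample heterogeneity diagnostic fits binomial logistic
models with and without a stratum×sample interaction and reports the
likelihood-ratio χ² p-value; the pooled OR remains the headline number,
one per class, with per-sample tables available.

The Wald p and Fisher's exact p agree closely only in the asymptotic
regime (all cells well-populated, moderate effects); in deep tails the
normal approximation and the discrete exact test deviate by
construction.  The test suite checks 10 % agreement in the regime where
the equivalence holds.

Only filter-passing variants enter spectra; the somatic analyses restrict
to high-confidence somatic SNVs.  Ti/Tv is transitions (A↔G, C↔T) over
transversions, undefined (not an error) when there are no transversions.
Mutation rate is count/(stratum bases/10⁶).

## Copy number

Window log2 ratios: log2((t/s + ε)/(n + ε)) with ε = 0.5 and s the
total-depth library ratio; optional GC correction subtracts the median
log-ratio per GC decile.  Windows with normal coverage < 20 are removed.
Segmentation is a deliberately plain greedy merge (adjacent windows join
while |log2 − running mean| ≤ 0.4; the segment value is the mean of its
member windows) — a documented stand-in for a full segmentation
algorithm, and pre-segmented external tracks are accepted verbatim as
first-class input.

Gene calls use summed exon length (genes ≤ 400 bp not evaluable; the
alternative transcript-span reading is noted but not used), the
overlap-length-weighted mean log2 over exon-covering segments, and strict
thresholds > +2 / < −2.  Amplification requires every exon's mean to pass
— stable to single-window noise.  Homozygous deletion requires a
below-threshold *region* of ≥ 400 bp overlapping exonic sequence, where a
region is a maximal run of consecutive below-threshold segments: at
log2 ≈ −3 the residual tumor depth is a handful of reads, so window noise
(≈ 0.4 in log2 at 127×) fragments the greedy segmentation, while the
deletion in the genome is one region.  Concordance between tracks pairs
each segment midpoint of one track with the covering segment of the
other; Pearson r is undefined below 3 pairs or at zero variance.

## Synthetic data: what it emulates

The generator reproduces the study conditions as defaults:

| parameter | default | basis |
|---|---|---|
| samples | 6 tumor/normal pairs | study design |
| gene structure | 300 bp upstream, full 5'UTR, coding exons, first 1200 bp of 3'UTR | capture design |
| analysis flank | 30 bp into introns | analysis pipeline |
| GC | 51.1 % coding / 47.0 % non-coding | reported composition |
| somatic rates | 20.6 / 8.7 high-confidence mutations per Mbp (coding / non-coding) | reported rates |
| class shares | C/G→T/A most common (34.9 % coding, 35.1 % non-coding), C/G→G/C second in coding, A/T→G/C second in non-coding | reported spectra |
| germline SNP rate | 10⁻³ per targeted base, Ti/Tv 2.66 | reported known-SNP Ti/Tv, typical panel SNP density |
| depths | 127× tumor / 98× normal, Poisson (negative binomial when a dispersion is set) | reported coverage |
| homozygous fraction | 168/658 | reported zygosity split |

Values the source did not state were chosen once as field-typical and are
not revisited: 5'UTR 150 bp, introns 300 bp, intergenic spacers 400 bp,
CDS exons 120–480 bp (codon multiples, 2–5 exons/gene), low-confidence
fraction 0.15, hard-filter-failing fraction 0.05, somatic indel fraction
0.05 of somatic events, catalogue fraction 0.5 with 5 % of entries stored
position-shifted.  Split-MNV catalogue decoys default to 0 because each
planted pair adds coding SNVs beyond the configured rates; tests of the
loose matcher enable them explicitly.

The configured somatic rates are interpreted as the *high-confidence*
rates a screen reports; planting is inflated by
1/(1 − low_fraction − fail_fraction) and the substitution budget is
scaled by (1 − indel_fraction), so the classifier-recovered
high-confidence rate matches the configured value in expectation.
Evidence fields are drawn to land on the intended side of every
classifier threshold (high; low via one violated support rule; or a
failing QD), which is what makes tier-recovery exactly testable.

Sequence composition is sampled with an exact per-block GC quota;
overwriting start/stop codons costs ≈ 0.2 GC percentage points in coding
sequence, within the ± 1 point verification band.  One seeded generator
drives panel, cohort, then coverage in documented order, so all outputs
are byte-reproducible.

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level artifacts (mapping error, strand bias
actually correlated with sequence, OxoG-type damage), real trinucleotide
hotspot structure (placement is uniform over eligible bases unless
weighted), linkage between nearby variants, subclonal allele fractions,
GC-dependent coverage bias (coverage depths are independent of GC unless
a dispersion/correction is exercised), and real catalogue ascertainment
bias.

## Pipeline

`run_pipeline` stages classify → annotate → match → spectra/enrichment →
CNV → report, from either an `inputs` block (VCF/BED/FASTA/TSV paths) or
a `simulate` block.  It writes into a staging directory renamed into
place on success, so failures leave no partial output, and emits a
manifest (package version, seed, all thresholds, SHA-256 digests of
inputs) that is identical across reruns with identical inputs.  The
`capmut` CLI is a thin wrapper; the stage subcommands share the run-all
implementation because every stage is cheap relative to IO and reruns
are idempotent.

## Problem sizes

The shipped test suite and the acceptance script run at desk scale,
chosen as the package's own trade-off between statistical resolution and
turnaround: property suites use panels of 5–20 genes (25–80 kb);
CI-coverage of planted odds ratios uses 200 replicates per effect size
at ≈ 500 mutations per cohort; copy-number recovery uses 20 replicates
at study depths; the acceptance script simulates a 1,200-gene (~5 Mb)
panel — the scale of the real capture design — so the pooled rate
estimates carry ≈ 10 % sampling error, and its copy-number burden
includes moderate events alongside the high-level ones so the
truth-concordance correlation is computed on a genome with structure,
as in genomically unstable cell lines.

## Known limitations

* The effect annotator handles substitutions exactly but classifies CDS
  indels by length arithmetic only (no HGVS for indels, no
  re-translation across exon junctions for MNVs spanning them).
* The greedy segmenter is a stand-in: it conserves window means and
  recovers high-level events, but it is not a changepoint method and
  fragments low-depth regions (mitigated by region-level deletion
  calling).
* The Wald test is anti-conservative for sparse 2×2 tables; results with
  any cell below ~5 should be read via the flagged CI, or the table
  handed to an exact test.
* Catalogue loose matching assumes a diploid single-sample call set; it
  does not chain shifts with splits (a shifted constituent of a split
  MNV is not matched).
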