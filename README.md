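# capmut

Tumor/normal targeted-capture mutation screening, as a tested, reusable
pipeline.  `capmut` re-implements the bespoke analysis of a cancer
cell-line panel screen — paired tumor/normal variant calls over a custom
capture design (all coding exons plus UTRs and upstream regions of ~1,200
cancer genes) — for anyone who needs to reproduce or extend that style of
analysis: somatic variant classification, effect annotation, catalogue
matching, mutation-spectrum enrichment, and gene-level copy-number calls,
all exercised on synthetic cohorts with known ground truth.

## What it computes

**Somatic classification.** A call is *somatic* when the tumor genotype
includes the alternate allele and the matched normal is homozygous
reference.  GATK-style hard filters are applied per variant kind
(substitutions: qual < 40 ∨ QD < 5.0 ∨ HRun > 5 ∨ FS > 200; indels:
qual < 40 ∨ QD < 2.0 ∨ ReadPosRankSum < −20 ∨ FS > 200; emit threshold
qual ≥ 10).  A somatic call is *high confidence* when the filters pass,
the normal has informative depth ≥ 10 with ≤ 1 alternate-supporting read,
and the tumor has ≥ 3 alternate reads; otherwise *low confidence*.

**Effect annotation.**  Each variant receives one category from the
standard vocabulary (nonsynonymous/synonymous/stopgain/stoploss SNV,
frameshift/non-frameshift indel, splicing, UTR5/UTR3, upstream, intronic,
intergenic, ncRNA) by codon translation on the coding strand; *non-silent*
= exonic indels, nonsynonymous, stopgain, stoploss, or splicing.

**Catalogue matching.**  Calls are matched against a COSMIC-style
catalogue exactly (after left-alignment and allele trimming) and loosely
(positional shifts < 5 bp, representation-equivalent within repeats, and
multi-nucleotide substitutions reconstructed from adjacent SNV calls);
unmatched somatic variants are flagged novel.

**Spectrum enrichment.**  Substitutions are strand-collapsed onto the six
pyrimidine-centered classes and 32 trinucleotide contexts X[Y]Z.  For each
class or context the coding vs non-coding comparison is a 2×2 table of
mutated versus eligible source bases (G/C or A/T counts for classes,
per-context occurrence counts for contexts):

    OR = (a/b) / (c/d),   CI₉₅ = exp(ln OR ± 1.96·SE),
    SE = √(1/a + 1/b + 1/c + 1/d)

with a Wald p-value and Bonferroni adjustment over the family of reported
tests; a stratum×sample interaction check (binomial logistic LRT) is
reported as a heterogeneity diagnostic.  Ti/Tv ratios and mutations/Mbp
per stratum round out the summary.

**Copy number.**  Paired coverage windows (≤ 150 bp, target-derived) get
log2 tumor/normal ratios after library-size scaling, low-coverage windows
(normal < 20×) are removed, a simple greedy merge segments the ratios, and
genes are called: *amplification* when every exon mean exceeds +2,
*homozygous deletion* when a below −2 region of ≥ 400 bp overlaps exonic
sequence (genes ≤ 400 bp of exon are not evaluable).  Segmented tracks are
compared by Pearson correlation of midpoint-matched log2 values.

**Synthetic cohorts.**  `capmut.simulate` generates panels (300 bp
upstream, full 5'UTR, coding exons, first 1200 bp of 3'UTR per gene; GC
51.1 % coding / 47.0 % non-coding), six tumor/normal pairs with planted
germline and somatic variants whose read evidence lands on the intended
side of every classifier threshold, and coverage tracks with planted
amplifications and deletions — all bit-reproducible under a seed.

## Worked example

Pooling the published per-sample counts of the six-cell-line screen
(shipped as worked-example inputs in `capmut.studydata`):

```python
from capmut import studydata
from capmut.somatic import summarize_counts
from capmut.report import sanger_concordance

table = summarize_counts(studydata.table1_variant_records())
for row in ("total_somatic_high", "non_silent"):
    print(row, int(table.loc[row, ("total", "all")]),
          int(table.loc[row, ("total", "novel")]))

rates = sanger_concordance(
    studydata.sanger_validation_rows("high", studydata.SANGER_HIGH_CONFIDENCE)
    + studydata.sanger_validation_rows("low", studydata.SANGER_LOW_CONFIDENCE))
print(rates[rates["group"] == "pooled"].to_string(index=False))
```

prints

```
total_somatic_high 658 315
non_silent 378 63
tier  group  validated  analyzed  rate_percent
high pooled        111       118          94.1
 low pooled         14        54          25.9
```

i.e. 658 high-confidence somatic variants across the six lines of which
315 are novel; 378 non-silent (63 per line on average); 94.1 % of novel
high-confidence candidates and 25.9 % of low-confidence ones validate by
Sanger sequencing.  A single enrichment test:

```python
from capmut.spectrum import enrichment_test
r = enrichment_test("C>T", mutated_coding=10, eligible_coding=1000,
                    mutated_noncoding=5, eligible_noncoding=2000, m_tests=6)
print(f"OR={r.odds_ratio:.3f}  95% CI {r.ci_low:.3f}-{r.ci_high:.3f} "
      f"p_raw={r.p_raw:.4f}  p_adj={r.p_adjusted:.4f}")
```

```
OR=4.030  95% CI 1.374-11.823 p_raw=0.0111  p_adj=0.0668
```

— C>T substitutions hit 10 of 1,000 eligible coding bases versus 5 of
2,000 non-coding ones, a four-fold enrichment that survives neither the
family of six tests at α = 0.05 nor, notably, anyone ignoring the CI width
at these counts.

An end-to-end run on simulated inputs:

```sh
capmut run-all --config examples/simulated.yaml --out out/
```

writes the classified variant table, the summary-table counts, spectrum
and enrichment tables, segmented copy-number and gene calls, recurrence
matrices, and a reproducible run manifest.

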