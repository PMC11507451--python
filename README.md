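# eisa — exon–intron split analysis of bulk RNA-seq

Messenger RNA levels are set jointly by transcription and by
post-transcriptional fate (processing, export, decay).  Standard RNA-seq
differential expression, which counts only exon-mapped reads, cannot tell the
two apart.  Total-RNA libraries, however, also contain intron-mapped reads
from unspliced pre-mRNA, and these track transcription: a gene whose intron
signal rises while its exon signal stays flat is being transcriptionally
induced but post-transcriptionally suppressed — the signature, for example,
of a nonsense-mediated-decay (NMD) target held in check by mRNA surveillance.

`eisa` implements this split analysis for two-condition designs
(e.g. chow vs high-fat-diet mouse liver, n = 3 vs 3):

1. **Constitutive regions** — from a GTF, each gene's *constitutive exons*
   (bases exonic in every isoform, i.e. the intersection of per-isoform exon
   unions) and *constitutive introns* (bases within the gene span exonic in
   no isoform), so that a read's exon/intron status never depends on which
   isoform produced it.  Only transcripts with source `ensembl` /
   `ensembl_havana` are used.
2. **Counting** — uniquely mapped reads (SAM/BAM or a plain-text placement
   table) assigned per region class; multi-gene overlaps are discarded as
   ambiguous.
3. **Differential expression** at each level with a transparent
   negative-binomial pipeline: median-of-ratios size factors *ŝ*, moderated
   method-of-moments dispersions *α̂*, and a delta-method Wald test on
   log₂FC, with Benjamini–Hochberg FDR.  A gene is a DEG when
   FDR ≤ 0.05 and |log₂FC| ≥ 0.58.
4. **Split analysis** — per-gene pairs (Δintron, Δexon) of the two log₂ fold
   changes over the union of level DEGs; OLS of Δexon on Δintron and its R²
   summarise how faithfully transcription propagates to mature mRNA, and a
   decision table classifies each gene (post-transcriptionally
   suppressed/enhanced, concordant, exon-only).
5. **Feature statistics** — 3′/5′ UTR-length (and intron-length)
   distributions of each DEG subset against the top-10,000-by-baseMean
   background, compared with the two-tailed two-sample Kolmogorov–Smirnov
   test; long 3′ UTRs mark candidate NMD targets.
6. **Enrichment** — one-sided hypergeometric over-representation of DEG sets
   in GMT gene-set collections (adjusted p ≤ 0.01).

A fully seeded synthetic-data generator (`eisa.simulate`) emulates the target
study design — NB counts whose pre-mRNA effect Δt and post-transcriptional
effect Δp move independently (expected Δintron = Δt, Δexon = Δt + Δp), with a
planted decay-target subset carrying 3× 3′ UTRs — so every stage is testable
without external data.

## Worked example

```python
from eisa import SimConfig, NegativeBinomialDE, ExonIntronSplit
from eisa.simulate import simulate_truth, simulate_counts

config = SimConfig(n_genes=2000, seed=1)          # 5% decay targets planted
truth = simulate_truth(config, 1)
exon_counts, intron_counts, _ = simulate_counts(truth, 1)

exon_res = NegativeBinomialDE.from_count_matrix(exon_counts).fit()
print(exon_res.summary())

split = ExonIntronSplit(exon_res,
                        NegativeBinomialDE.from_count_matrix(intron_counts).fit()).fit()
print(split.summary())
```

```
Negative-binomial DE results (exon level)
================================================
genes tested        2000
DEGs (FDR<=0.05, |log2FC|>=0.58)  396  (199 up / 197 down)
size factors        ctrl_1=0.908  ctrl_2=1.086  ctrl_3=1.196  hfd_1=0.900  hfd_2=1.055  hfd_3=0.910
median dispersion   0.02866

Exon-intron split analysis
================================================
gene set            union of level DEGs (n=518)
R^2 (dExon~dIntron) 0.717
slope / intercept   0.745 / -0.184
categories:
  post_tx_suppressed  107
  post_tx_enhanced    15
  concordant_up       191
  concordant_down     184
  exon_only_up        8
  exon_only_down      13
  none                0
```

The 100 planted decay targets dominate the 107 `post_tx_suppressed` calls
(transcription up ~2.8-fold, mature mRNA flat), and their presence pulls the
Δexon~Δintron R² down from ≳0.92 (no post-transcriptional effects) to 0.72 —
the split analysis reading off exactly the regulation that was simulated.

A shell pipeline over files works the same way:

```bash
eisa simulate --seed 7 --n-genes 500 --outdir sim --reads
eisa run-all --config run.yaml        # annotation -> counts -> DE -> split -> UTR -> ORA
```

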