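# Methods

## The split-analysis model

For a two-condition bulk RNA-seq design the package estimates, per gene, two
log₂ fold changes: Δintron from reads in constitutive introns (a pre-mRNA and
hence transcription proxy) and Δexon from reads in constitutive exons (mature
mRNA).  Under the interpretive model

    Δintron ≈ Δt                 (transcriptional effect)
    Δexon   ≈ Δt + Δp            (transcription + post-transcriptional effect)

a gene with Δintron significantly non-zero but Δexon flat is
post-transcriptionally regulated (Δp ≈ −Δt), and the genome-wide R² of the
OLS of Δexon on Δintron measures how much of the mature-mRNA variation is
transcriptionally driven.  The model ignores alternative splicing by
construction: a read is only informative if its exon/intron status is the
same in every annotated isoform, which is exactly what the constitutive
region sets guarantee.

### Constitutive regions

* constitutive exons = base-wise intersection over isoforms of each
  isoform's exon union, merged into maximal intervals (bookended blocks are
  merged);
* constitutive introns = gaps of the all-isoform exon union, clipped to the
  gene span — bases exonic in no isoform.  Transcripts that do not span a
  gap still count it as constitutive; gene-span (not per-transcript)
  semantics were chosen because the "intron shared by all isoforms" reading
  is the one that makes the two region classes complementary within the
  span.  The two sets are disjoint by construction, and both are validated
  against a per-base boolean oracle in the tests.

Genes whose transcripts lie on multiple chromosomes or strands are rejected
rather than guessed at.  Internally all coordinates are 0-based half-open;
GTF and SAF files are read/written 1-based inclusive.

### Counting

Exon and intron counting are two independent passes with separate region
files, mirroring a two-annotation featureCounts run; a junction-spanning
read may therefore legitimately count at both levels.  Within a level a read
needs ≥1 aligned base of overlap (featureCounts' default), reads touching
regions of more than one gene are discarded as ambiguous, and only uniquely
mapped reads count (NH == 1 when the tag is present, else MAPQ ≥ a
configurable threshold, default 255).  Counting is unstranded and single-end
in semantics; mates are independent reads.  Per sample,
assigned + ambiguous + unassigned always equals the input read count.

### Differential expression

The DE step is a deliberately transparent NB pipeline rather than a wrapper
around an existing tool:

* **Pre-filter**: genes with two or fewer samples with raw count > 1 are
  removed.
* **Size factors**: median-of-ratios over genes positive in all samples.
* **Dispersion**: per-gene method of moments on normalised counts
  (condition means removed, residual df = n − 2), solved from
  Var = μ + αμ².  Raw estimates at n = 3 vs 3 carry ~4 df and are far too
  noisy for a plug-in Wald test (empirically ~2× type-I inflation), so each
  gene's estimate is shrunk toward the across-gene mean of the clipped
  estimates with prior weight `prior_df = 20` (estimate weight = residual
  df).  This is the package's own small-sample moderation, in the spirit of
  the empirical-Bayes shrinkage used by DESeq2/edgeR/limma; with hundreds of
  samples the prior weight is negligible and the raw per-gene estimator is
  recovered.  `alpha_min = 1e-8` floors the estimate; zero-mean genes are
  excluded.
* **Wald test**: log₂FC = log₂((q̄_t + c)/(q̄_c + c)) with pseudocount
  c = 0.5 (zero handling; configurable); the group-mean variance
  Var(q̄) = (q Σ 1/s + n α q²)/n² follows the NB model and is propagated
  through the log (delta method); p-values are two-sided normal tails.
  Not reproduced on purpose: LFC shrinkage, Cook's outlier handling,
  independent filtering.
* **BH adjustment** via statsmodels; DEG ⟺ FDR ≤ 0.05 ∧ |log₂FC| ≥ 0.58,
  both boundaries inclusive (0.58 is kept as the exact decimal, not
  log₂ 1.5).

Calibration: on all-null NB simulations (α = 0.05, n = 3 vs 3, 2000 genes)
the realised P(p < 0.05) sits at ~0.05–0.06 and BH calls essentially no
DEGs; with the true dispersion plugged in it is 0.047, so the residual
inflation is the price of estimating α from 6 samples.

### Split analysis, features, enrichment

Delta pairs are built for genes tested at both levels; the default gene set
for the correlation is the **union** of exon- and intron-level DEGs
(configurable: intersection / all).  R² is the squared Pearson correlation
of the OLS of Δexon on Δintron; intron is the predictor because it
represents the upstream (transcriptional) signal, though R² itself is
direction-free.  The category decision table is total and disjoint:
intron-only DEGs are post-transcriptionally suppressed (Δintron > 0) or
enhanced (< 0); double DEGs with matching signs are concordant; exon-only
DEGs lack transcriptional support; discordant double calls and non-DEGs fall
to `none`.

UTR lengths come from each gene's canonical transcript (external TSV map,
with a longest-CDS, then lexicographic, fallback): 5′/3′ UTR = exonic bases
before/after the CDS in transcript orientation, summed across exons;
non-coding transcripts are excluded from UTR comparisons.  Each DEG subset
(level × direction) is KS-compared (two-tailed, asymptotic p; exact behind a
flag) against the top-10,000-by-baseMean background of its own level; DEGs
remain inside the background (superset comparison).  Total
constitutive-intron length is carried alongside the UTR columns so the same
machinery covers intron-length comparisons.

Enrichment is one-sided hypergeometric over-representation of a DEG set in
GMT collections, members intersected with the universe (the same top-k
background), sets below 5 in-universe members skipped, BH-adjusted,
significant at adjusted p ≤ 0.01.

## The synthetic-data generator

`SimConfig` defaults encode the emulated study: two conditions × 3
replicates, NB counts with Var = μ + αμ², per-sample library factors
log-normal (σ = 0.08), and per-gene means

    μ_intron = s · L_intron · ρ · B · 2^(Δt·treated)
    μ_exon   = s · L_exon · B · 2^((Δt+Δp)·treated)

with B a log-normal per-bp concentration (median 0.5 reads/bp, σ = 1 —
deep total-RNA libraries) and ρ = 0.2 the pre-mRNA read density relative to
mRNA.  Gene structures: 3–8 exons (log-normal lengths, median 180 bp),
introns median 800 bp, 1–3 isoforms sharing a constitutive core (extra
isoforms skip one internal exon).  Effects: 10% of genes transcriptionally
up and 10% down with |Δt| ~ U(0.75, 1.7) (≈1.7–3.2-fold — typical DEG
magnitudes, and consistent with DEG counts being a few hundred per level out
of a few thousand testable genes); 5% are decay targets with Δt = +1.5,
Δp = −1.5 exactly.  Decay targets carry 3′ UTR = 3 × the background base
length (400 bp; others log-normal around it) and a doubled 5′ UTR; the decay
targets also form the planted gene set written to the GMT next to random
sets.  Default dispersion is α = 0.03, a representative genewise value for
inbred-mouse liver bulk RNA-seq; experiments that probe calibration and
sensitivity use α = 0.05 explicitly as a harder condition.

Reads, when requested, are placed uniformly within one interval of the
gene's region set at the NB count drawn for that gene/level/sample, so the
count matrices are the exact bookkeeping truth for the placements and
counting can be validated bit-for-bit.  All randomness flows through
`numpy.random.default_rng(seed)` (annotation, counts and reads use fixed
offsets of the base seed), making every artifact byte-reproducible.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real data: overlapping genes (no ambiguous assignments
arise by construction), unannotated splicing and intron retention,
3′-end/UTR annotation error, GC/length biases, batch effects, and the
correlation structure of real gene networks.  The generator validates the
pipeline's statistics under its own model, not the biology of any particular
dataset; on real accession data the headline quantities (R², DEG counts)
will differ.

## Validation experiments and problem sizes

`eisa.experiments` (driven by `scripts/acceptance.py` and
`tests/test_acceptance.py`) uses: 500 random genes for the interval-algebra
oracle; ~200 genes / ~80k placed reads for counting truth; 2000 genes for
the null, recovery, R²-separation and enrichment scenarios; 100 seeded
replicates of 2000 genes for the UTR/KS replication rate; and a 60-gene
read-level bundle run twice through the full pipeline for the determinism
check.  These sizes give stable Monte-Carlo estimates while keeping the full
battery at a few minutes on one CPU.

## Known limitations

* The Wald test is asymptotic; with 3 + 3 replicates its calibration relies
  on the dispersion moderation described above and is slightly liberal
  (~0.05–0.06 realised at nominal 0.05).
* Median-of-ratios normalisation assumes most genes unchanged; strongly
  asymmetric regulation (many more up- than down-regulated genes) biases
  fold changes slightly toward the minority direction, which is visible at
  the intron level when decay targets are abundant.
* No paired-end fragment model, no strand-aware counting, no multi-factor
  designs.
* UTR statistics require CDS annotation; non-coding genes are dropped from
  feature comparisons (counted and logged).
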