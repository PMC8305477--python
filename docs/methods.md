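# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `editscan`.

## Differential expression

Counts for TAR *g* in sample *j* are modelled as negative binomial with
mean μ_g·s_j (·2^LFC in the treated group) and dispersion α, i.e.
Var = μ + αμ². Size factors s_j are DESeq-style median-of-ratios: the
pseudo-reference is the per-TAR geometric mean over samples, restricted
to TARs with all-positive counts, and s_j is the median of the sample's
count-to-reference ratios (the median is taken on the ratio scale, not
in log space). The dispersion is a per-TAR method-of-moments estimate
max(0, (s² − m̄)/m̄²) computed within each group on normalized counts
and pooled with (n_g − 1) weights. With three replicates per group this
estimator is noisy; no shrinkage is applied (deliberately out of scope),
which is why the consensus rule below carries the specificity burden.

*Method A (Wald).* log2FC = log2((m̄_B + 0.5)/(m̄_A + 0.5)); the 0.5
pseudocount keeps all-zero TARs defined (they report log2FC 0, p 1).
The standard error propagates Var(m̄_g) = (m̄_g + α m̄_g²)/n_g through
the log via the delta method; the z statistic is referred to the
standard normal, two-sided.

*Method B (exact conditional).* Counts are divided by the size factor
and rounded, giving a common effective library size. Group totals Y_A,
Y_B are sums of iid NB variables (dispersion α/n per total), and the
test conditions on S = Y_A + Y_B: p is the sum of conditional
probabilities of all splits no more likely than the observed one
(weights within a factor 1 + 1e-12 count as ties, so exactly symmetric
configurations give p = 1 rather than slightly above). At α = 0 the
conditional law is Binomial(S, n_A/(n_A + n_B)) and the test coincides
with the exact binomial test, which is used as its oracle.

*Consensus.* A TAR is DE iff both methods give BH-adjusted p < 0.05
(strict) and |log2FC| > 1 (strict) and the two estimates agree in sign.
A sign conflict vetoes the call: a "DE-TAR" whose two fold-change
estimates point in opposite directions is uninterpretable. Direction
comes from the shared sign.

*Sample size.* n = ⌈2(z₁₋α/₂ + z_power)²(1/d + v²)/ln²Δ⌉ per group,
floored at one; d is mean per-gene coverage, v the biological
coefficient of variation, Δ the fold change. Defaults α = 0.05,
power = 0.8 — conventional values, chosen here because a design
calculation needs them and no better-motivated pair exists for this
setting.

## lncRNA classification

The classifier requires length > 200 nt (strict), ≥ 2 exons, and
unanimous *noncoding* votes from three predictors; a transcript already
annotated with the lncRNA biotype is accepted outright. Unanimity means
any single coding vote is enough to reject — the conservative direction
for calling something "non-coding".

* **ORF**: longest ATG..stop reading frame over the three sense-strand
  frames. Length in codons counts the start and excludes the stop;
  coverage is the ORF footprint including the stop divided by transcript
  length; an ORF running off the 3' end counts to the last complete
  codon. Vote *coding* iff length ≥ 100 codons or coverage ≥ 0.5
  (conventional cutoffs).
* **Fickett TESTCODE**: position-bias (max/min+1 of per-frame base
  counts) and composition parameters for the four bases, mapped through
  the published probability/weight lookup tables; vote *coding* at
  score ≥ 0.95, the classical TESTCODE threshold. Requires ≥ 200 nt;
  shorter sequences — which the length filter rejects anyway — are
  scored NaN with a coding vote so they can never pass via this route.
* **Hexamer LLR**: in-frame (step 3, frame 0) hexamer frequencies with
  add-one smoothing over the 4096-mer alphabet, trained on annotated
  coding CDS vs annotated lncRNA spliced sequences; score is the mean
  log(f_coding/f_noncoding) over the query's hexamers, vote *coding*
  when positive. By the Gibbs inequality the expected score is positive
  under the coding distribution and negative under the non-coding one,
  so the zero cutoff is the natural decision boundary.

Trans-acting links are all (lncRNA, mRNA) pairs with |r| ≥ threshold
(default 0.9) on log2(count+1) profiles over the same samples (≥ 3).
The log transform stabilises count variance; the source protocols are
split between 0.7 and 0.9 for this threshold, so it is exposed as a
config knob with 0.9 (the stricter reading) as default. Zero-variance
profiles are skipped with a warning since r is undefined for them.

## Editing-site discovery

Stages run in a fixed order, each recorded in an audit trail whose
counts chain (n_out of stage k = n_in of stage k+1):

1. **Hard filters** — remove a site when mean per-sample DP < 10,
   MQ < 40, QD < 2, MQRankSum < −12.5 or ReadPosRankSum < −8. All
   inequalities are strict, exactly as the thresholds are written, so
   boundary values pass. "Depth" is the mean per-sample DP by default
   (`dp_rule="min"` switches to the per-sample minimum). Missing
   annotations (e.g. rank sums absent without heterozygous evidence)
   pass the corresponding criterion — the GATK convention.
2. **Context** — remove sites within ±`splice_window` nt of any
   annotated exon/intron boundary (default 4 nt, common RNA-editing
   practice; the boundary position counts as distance 0 on the intron
   side), or inside the ssr/paralog/bidirectional masks. Pseudogene-like
   regions are handled through the paralog/custom mask channel; no
   de-novo detection.
3. **Prevalence** — keep sites with alt depth > 0 in at least
   ⌈fraction·n⌉ samples (default half, so 3 of 6; ceiling for odd n).
4. **SNP / hypervariable** — drop rs-annotated sites and sites where
   any sample's AAF exceeds 0.7 (strict; AAF = alt/(alt+ref), undefined
   at zero depth). "Any sample" means any of the six, configurable.
5. **Differential test** — per site, pool alt/ref depths per group into
   a 2×2 table and compute the df=1 chi-square without continuity
   correction (algebraically n(ad−bc)²/(row·column products) — the
   goodness-of-fit of the observed split against equal proportions).
   ΔAAF is the difference of *per-sample-mean* AAFs (robust to depth
   imbalance across samples), while the chi-square uses pooled depths;
   both are reported per site. BH FDR runs across all tested sites.
   Significance requires FDR < 0.001 and |ΔAAF| > 0.1, both strict; the
   ΔAAF rule is two-sided. A site with zero pooled depth in a group is
   flagged degenerate and reported with p = 1.
6. **Canonical restriction** — classify the substitution on the host
   gene's strand (intergenic sites default to '+'): A>G on sense =
   A-to-I, C>T on sense = C-to-U, all else noncanonical and removed.
7. **Consequence** — one call per site by severity: missense >
   synonymous > 5'UTR > 3'UTR > noncoding-exonic > intron > upstream >
   downstream > intergenic. CDS edits are translated with the standard
   genetic code on the coding strand. Upstream/downstream use a 5 kb
   window (the usual VEP default). `noncoding_exonic` covers exons of
   transcripts without a CDS, which the remaining categories cannot
   describe.

Running the significance test before the canonical split (with FDR over
all tested sites) mirrors the reported bookkeeping of the study design
this follows: a significant set first, canonical candidates second.

## Synthetic data

The generator emulates the study conditions: 2 groups × 3 replicates;
NB counts (dispersion 0.01, baseline means log-uniform 200–2000) with a
`de_fraction` (default 0.1) of TARs carrying |log2FC| = 2 with random
sign; per-sample size factors log-uniform on [0.7, 1.4], giving a
library-size CV near 0.1; 50 editing sites with per-group editing rates
(0.4, 0.05); 200 rs-annotated SNPs with AAF near 0, 0.5 or 1; 500 noise
sites with alt rate 0.01. Site depths are Poisson(50); alt depths are
Binomial(DP, rate) — the model under which the pooled chi-square is
exact — with a beta-binomial overdispersion knob
(`depth_overdispersion`) to stress that assumption.

Sequence construction: coding CDSs are ATG + codons from a
position-biased codon distribution + stop, spliced over 3–5 exons with
UTRs, so they carry real period-3 and hexamer structure; lncRNAs are
2–4-exon transcripts of 300–800 nt with a stop-in-all-three-frames
12-mer stitched in every 60 nt, capping any ORF far below the 100-codon
cutoff by construction. Half the lncRNAs are emitted with the annotated
biotype (training material and the annotated-biotype path), half as
`novel` (the discovery path). Bidirectional pairs are head-to-head genes
with TSS gap < 1 kb; (AC)₂₀ runs back the ssr mask. Editing sites sit
mid-exon (≥ 6 nt from boundaries) in unmasked coding genes, on sense-A
(A-to-I, 80%) or sense-C (C-to-U, 20%) positions; a configurable
fraction (default 0.1) of *noise* sites is drawn to fail one hard filter
each, while planted editing and SNP sites are always quality-clean so
that the statistical stages, not the quality stages, are what their
recovery measures.

What the generator does *not* emulate: alignment artefacts (soft-clip
pileups, multimapping), strand-bias structure in the rank-sum
annotations, correlated dispersion across genes, hyper-edited read
clusters, and allele-specific expression. Passing recovery benchmarks
therefore demonstrates the statistics and bookkeeping are correct under
the stated model, not that real-data artefact rates are matched.

Determinism: one `numpy` Generator seeded from `SimulationConfig.seed`
(default 22) drives genome/annotation construction; counts and variants
derive child seeds (+1, +2). Identical seeds give byte-identical output
files. Replicated benchmarks average over 20 seeds derived from a base
seed by a fixed stride.

## Numerical choices and edge cases

* BH adjustment enforces step-up monotonicity via a reverse cumulative
  minimum and preserves input order; empty input returns empty.
* Chi-square degenerates (a zero row or column margin) return (0, 1).
* The exact test's tie tolerance is multiplicative (1 + 1e-12) so that
  floating-point noise cannot split exact ties.
* `read_vcf` splits multi-allelic rows into biallelic SNVs, discarding
  AD entries of unchosen alternates, and skips (with a logged count)
  non-SNV alleles. INFO floats are rounded to 3 decimals on ingest to
  absorb float32 storage noise.
* Internal coordinates are 0-based half-open everywhere; GFF3 and VCF
  positions convert at the I/O boundary only.
* Benchmark problem sizes (20 seeds, 500 TARs, 750 sites per study)
  keep every suite comfortably fast while leaving binomial counting
  error on the measured rates well below the acceptance margins.

## Known limitations

* No dispersion shrinkage or GLM designs beyond two groups; no TMM.
* The chi-square on pooled depths ignores within-group sample
  heterogeneity; the beta-binomial simulation knob exists to probe
  this, and replicate-aware tests are a natural extension.
* The three coding-potential predictors are self-contained
  re-implementations of the corresponding feature families (ORF
  metrics, TESTCODE, hexamer usage), not reproductions of any published
  tool's trained weights; the hexamer model is corpus-dependent and
  should be retrained per annotation.
* Consequence annotation reports one most-severe call per site rather
  than all transcript-level effects.
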