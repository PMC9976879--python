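# Methods

## Overview

`regdriver` detects candidate non-coding *cis*-regulatory cancer driver
genes: genes whose tissue-matched regulatory regions are recurrently hit by
high-pathogenicity somatic SNVs *and* whose expression differs between
mutated and wild-type tumours. The unit of testing is the gene, via its
**regulatory space** — the union of all enhancers predicted to regulate it
in the tissue's enhancer–gene (Activity-by-Contact-style) map, each padded
by 250 bp, with every annotated coding interval (of any gene) removed and
the remainder merged into disjoint segments. Coordinates are 0-based
half-open internally; 1-based formats (MAF/VCF/CADD) are converted at the
reader boundary.

## Mutation evidence (p_M)

Only single-nucleotide variants with CADD-PHRED pathogenicity >= 10
("high-CADD" SNVs; the cutoff is configurable and swept in the robustness
analysis) are candidate driver mutations. Because some regions can generate
high-CADD alleles more easily than others, opportunity is counted in
**theoretical high-CADD mutations**: the (position, alternative-allele)
pairs inside the space whose score reaches the cutoff, up to 3 per base,
giving the per-gene count `s`.

The response of the background model is the high-CADD mutation frequency

```
y_g = n_g / (s_g * k)
```

where `n_g` is the number of cohort samples with >= 1 high-CADD SNV in the
space (at most one mutation per sample counts, damping kataegis-style local
hypermutation) and `k` the cohort size after QC. Samples with > 20%
exposure to POLE-deficiency (SBS10a/b, DBS3) or mismatch-repair-deficiency
(SBS6/14/15/20/21/44, DBS7/10, ID7) signatures are excluded beforehand.

A log-link Poisson-family GLM is fitted per tissue, one data point per
expressed gene ("expressed" = median expression > 0 across the tissue's
RNA samples; configurable). The response is a non-integer rate, so the fit
is quasi-likelihood: coefficients solve the Poisson score equations and a
Pearson chi-square/df dispersion scales all standard errors; coefficient
P-values use the t distribution on residual df. Candidate covariates:

| covariate | meaning | units/default |
| --- | --- | --- |
| 32 trinucleotide frequencies | pyrimidine-centred context composition of the space | fractions, sum 1 |
| `n_positions` | space length | bp |
| `gc_content` | G+C fraction of the space | [0, 1] |
| `repl_timing` | length-weighted mean replication-timing track value | track units |
| `base_activity` | enhancer-length-weighted mean enhancer activity | map units |
| `local_mut_freq` | all-CADD SNVs per bp per sample in the +/-50 kb non-coding non-enhancer flanks | /bp/sample |

Covariates are z-scored on the training genes; only covariates with
univariable P < 0.001 (same family/link) enter the multivariable model,
guarding against overfitting with ~300–20 000 genes per tissue. An
alternative "offset" mode (counts `n` with offset `ln(s k)`, the orthodox
rate formulation) is available behind a config switch; results metadata
records the mode.

The fitted model predicts `f = exp(x' beta)`, the expected frequency per
theoretical mutation per sample, clamped to [1e-12, 1-1e-12] (clamps are
logged; a clamp indicates a degenerate fit). The probability that one
sample carries >= 1 high-CADD mutation in the space is

```
p = 1 - (1 - f)^s
```

and the recurrence P-value is the right-sided binomial tail
`p_M = P(X >= n)`, `X ~ Binomial(k, p)`, computed with scipy's regularised
incomplete beta. `score_M = -log10(p_M)`.

## Expression evidence (p_E)

For each gene, over the tissue's RNA-bearing, QC-passing samples:

```
FPKM-UQ ~ 1 + MUT + CNV
```

again a log-link Poisson-family GLM with estimated dispersion; `MUT` is 1
when the sample carries a high-CADD SNV in the space, `CNV` the gene-level
copy number (untransformed numeric covariate; samples missing CNV are
dropped, a missing CNV table omits the term). `p_E` is the two-sided
t-statistic P-value of the `MUT` coefficient and the coefficient itself is
the signed **size effect** (positive = upregulated in mutated samples, on
the log scale). Genes with fewer than 2 high-CADD SNV *records* in the
space among RNA samples receive a missing `p_E` so a single mutation can
never drive a call.

## Combination and calling

`X = -2(ln p_M + ln p_E)` is referred to a scaled chi-square (Brown's
method). The scale `c = Var/2E` and df `2E^2/Var` use `E = 4` and
`Var = 8 + 2*cov`, with `cov` the empirical covariance of the two
`-2 ln p` vectors across the tissue's genes with both P-values (clipped to
[-4, 4], the attainable range for chi-square(2) margins). Independent
P-values recover Fisher's chi-square(4); perfectly dependent ones recover a
uniform null. With < 10 complete genes the covariance is not estimable and
Fisher's method is used with a warning. Benjamini–Hochberg runs per tissue
over genes with a defined combined P (missing p_E genes are excluded from
`m`; recorded in metadata). A gene is a **candidate regulatory driver**
iff `p_M < 0.05`, `p_E < 0.05` and `q < 0.15` (all strict); direction
follows the sign of the size effect. Pan-cancer candidates are the union
of per-tissue candidates with provenance retained.

## Post-hoc confidence filters

Candidates are annotated (never removed) by three screens:
`neighbor_underestimate` (median observed/expected mutated-sample ratio of
analysed genes with TSS within 100 kb exceeds 2 — the background model may
locally under-predict; neighbour ratios use high-CADD counts, consistent
with the main model), `shared_region_secondary` (the candidate shares a
*mutated* regulatory segment with another candidate and does not have the
top score_E; ties break by larger |size effect| then lexicographic gene
id), and `low_size_effect` (|size effect| < 0.4326, a calibration constant
taken as a config default because its definition rests on literature
curation outside this package's scope). The filters commute and only add
flags.

## Context analyses

* **Gene-set enrichment** — `log2(O/E)` with `E = R*D/G` over the analysis
  universe (expressed genes with enhancers in the tissue), P from a
  two-tailed Fisher's exact test; separate oncogene-in-upregulated and
  TSG-in-downregulated tables against non-candidate genes and non-driver
  genes.
* **Mutational profiles** — 96-channel pyrimidine-collapsed substitution
  counts, divided channel-wise by the trinucleotide frequency of the
  analysed regions (pooled per tissue) and renormalised, compared to
  signature catalogs by cosine similarity.
* **TFBS events** — enrichment of motif-break/gain annotations (consumed
  as precomputed input, e.g. a FunSeq2-style intersect) among candidate
  driver mutations vs control SNVs; all-CADD mutations by default, with a
  high-CADD-only mode.
* **Distances** — per mutation–target pair: |pos − TSS|, promoter-range
  (<= 250 bp) and distal (> 20 kb) fractions, and whether the target is
  the closest (protein-coding) gene, ties counting as closest.
* **Essentiality** — knockout-screen dependency scores gated on cell-line
  expression > 1 (TPM-like); mean dependency and % dependent lines
  (score > 0.5) vs control genes (two-tailed rank-sum), plus the fraction
  of genes with >= 1 dependent tissue-matched line against 10 000 draws of
  equally many unmatched lines, `p = 2 * min(one-tailed proportions)`
  floored at 1/iterations.
* **Recurrent top hits** (B-cell lymphoma analysis) — after removing
  mutations within 10 kb of an immunoglobulin gene body (direct AID/somatic
  hypermutation targets), positions qualify when they break a
  negative-regulator TFBS or create a positive-regulator TFBS
  ("both"-annotated TFs satisfy either arm), are high-CADD, recur (>= 2
  patients for gains, >= 3 for breaks) and shift target expression >=
  3-fold vs the wild-type median; alternative alleles at one position are
  pooled.

## Model evaluation

Chromosome-fold cross-validation: genomes with human-style chromosome
names use the fixed autosome grouping {1–2, 3–5, 6–8, 9–11, 12–16, 17–22}
(folds without members on small toy genomes report NaN); other genomes use
one fold per chromosome. Per fold the larger chromosome set trains and the
smaller is evaluated; explained variance is the squared Pearson
correlation of predicted (`k * p`) vs observed mutated-sample counts, after
excluding sex chromosomes and the top 1% most mutated elements (threshold
computed on the pooled counts per run).

## Synthetic cohorts

The generator draws everything from one seeded `numpy` generator
(byte-identical bundles per seed) and writes the exact dialects the readers
consume. Defaults (the study conditions of all shipped tests): 6
chromosomes x 2 Mb of uniform random sequence, 300 genes with two 150-bp
coding exons, 1–3 enhancers per gene (300–1500 bp, up to 200 kb from the
TSS, 10% shared with a neighbour), a 50-kb-binned Gaussian
replication-timing track, CADD-like scores with 10% of (position, alt)
pairs high-CADD, k = 200 samples (60% with RNA), 4 hypermutator samples
(flagged by POLE signature exposure and mutating 5x faster — removed by
QC). Each theoretical high-CADD pair mutates per sample with probability
`f = exp(-11.6 + 0.35*timing + 0.30*(activity-1))`; low-CADD pairs and the
non-enhancer genome mutate at the matching background rate (1.2e-6
/bp/sample genome-wide), so the local-rate covariate carries real signal.
Ten spiked driver genes (restricted to spaces with >= 300 theoretical
high-CADD sites) get a 10x rate and an expression effect of |beta| = 1
(80% up) applied multiplicatively to their mutated samples; expression is
lognormal around a baseline of ~500 with copy-number-linked scaling
(CNV ~ 2 * lognormal) and residual sd 0.5. The baseline rate was chosen so
a null gene expects ~1 mutated sample and a spiked gene ~10 — the
sparse-recurrence regime the method targets in whole-genome cohorts of a
few hundred tumours.

What the generator does *not* emulate: realistic sequence composition and
signature spectra, indels and structural variants, correlated enhancer
activity across genes, expression count noise (values are continuous
lognormal, matching the quasi-likelihood treatment rather than true
RNA-seq counts), and subclonal structure. Passing tests therefore
demonstrate internal statistical correctness and calibration of the
machinery, not performance on real tumour genomes.

## Numerical choices and degenerate inputs

Quasi-Poisson fits run IRLS at unit scale and apply the Pearson
chi-square/df dispersion to standard errors afterwards (refitting at a
near-zero fixed scale destabilises the convergence check; a perfect fit
keeps unit scale). `p_sample` uses `expm1/log1p` for tiny `f`. Genes with
`s = 0` are excluded from modelling and signalled, never silently zeroed.
Empty flanks impute the tissue-median local rate and flag the gene.
Resampling P-values are floored at 1/iterations. Tie-breaks (shared-region
winner) are deterministic and permutation-invariant. Fisher tables with an
empty margin report p = 1 with a warning.

## Problem sizes in shipped checks

The test-suite and the acceptance script run the full pipeline at the
default 300-gene / 200-sample scale (10 spiked seeds and 20 null seeds in
the test suite; 5 + 5 in the script, plus one cross-validation run, 2 000
genes for the combination-limit checks and 20 replicates for expression
effect recovery). These sizes give stable medians while keeping a complete
run in minutes on one core.
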