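# Methods

This note documents the statistical models behind `methlink`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing its
output.

## Setting

The package implements a gene-level integration of three modalities
measured on cord-blood CD34+ HSPCs from two groups (CTRL and LGA): bulk
per-CpG methylation fractions with per-sample clinical covariates,
single-cell chromatin accessibility (binary cell × peak), and single-cell
expression counts. The central object is the *gene-methylation score*, a
per-gene summary of differential methylation that weights each CpG by the
confidence of its assignment to the gene and by the regulatory potential of
its genomic context; everything downstream (GSEA, network annotation) ranks
or flags genes with it.

## Differential methylation

Each CpG's methylation percentage is regressed by OLS on group plus
maternal age, sex, ethnicity, batch and library complexity (categoricals
dummy-coded, first level dropped). Because the design matrix is shared by
all CpGs the fit is one matrix factorisation; the group coefficient is
tested with a two-sided t-test on n − p residual degrees of freedom.
Conventions:

* `meth_change` is the **unadjusted** difference of group means (LGA% −
  CTRL%, percentage points) while the p-value comes from the adjusted
  model. The effect size the score uses is therefore the raw group
  difference; the asymmetry is deliberate and kept throughout.
* DMC calling uses the nominal p (not BH q) with strict inequalities:
  p < 0.001 and |meth_change| > 25 pp. BH-adjusted q-values are still
  reported for every CpG.
* Constant CpGs get p = 1 and change = 0. A rank-deficient design fails
  fast naming the offending covariate.
* An optional limma-style empirical-Bayes variance moderation
  (moment-matched scaled-inverse-chi-square prior on residual variances) is
  available behind `moderate=True` but **off** by default: plain OLS keeps
  the per-CpG test exactly reproducible by any standard tool.

## CpG–gene linking and weights

Links come from two sources: distance (|CpG − TSS| ≤ window, default 50 kb,
a conventional cis window) and eQTL regions (which deliberately bypass the
window — that is what makes eQTL support informative). Duplicate pairs
merge to `source="both"`. Distances are signed and strand-aware (upstream
negative).

The weight functions are explicit, configurable defaults, since only their
qualitative behaviour is constrained (promoter/enhancer context and
proximity should raise the score):

| weight | form | default |
|---|---|---|
| LinkWeight, distance link | max(floor, exp(−ln2·\|d\|/h)) | half-life h = 10 kb, floor 0.1 |
| LinkWeight, eQTL link | constant | 1.0 |
| LinkWeight, both | max of the two | — |
| RegWeight | class lookup at the CpG position | promoter 1.0, enhancer 0.75, other 0.25 |

Class lookup consults the cell-type-specific intervals first; positions
classified "other" can fall back to a second, Ensembl-regulatory-style
interval table when one is supplied. Overlaps resolve promoter > enhancer.

## Gene-methylation score

Per link, `CpGScore = (−log10 p · meth_change) · LinkWeight · RegWeight`
(p = 0 clamped to the smallest positive double). Per gene, scores aggregate
separately over the promoter compartment (CpG inside *that gene's*
promoter interval — a per-gene notion, not the global regulatory class) and
the distal compartment:

    W_c   = 1 / ( Σ_i 1/|CpGScore_i| + k ),   k = 13.8
    score = W_prom · Σ(CpGScore)_prom + W_other · Σ(CpGScore)_other

Numerical conventions, all tested:

* the harmonic term uses |CpGScore| — signed reciprocals would make the
  weight undefined or negative for mixed-sign genes;
* exact zeros are skipped (a non-informative link must not annihilate the
  weight); an empty compartment contributes 0; a gene with no links scores 0;
* the printed weight expression is read as 1/(Σ 1/s + 13.8), i.e. a pure
  dampening weight: a single strong link is damped by ≈ 1/k, additional
  links increase the score sublinearly, and large CpG counts cannot inflate
  it;
* the form is **discontinuous at zero evidence**: a link with a tiny but
  nonzero |CpGScore| contributes a huge reciprocal and pulls the whole
  compartment toward 0. That is a property of the published form, not a
  bug; it means genes supported only by weak evidence are aggressively
  shrunk. The tests pin this behaviour down explicitly.

Validation (`validate_score`) reports rank correlations of the score with
per-gene DMC count, distance, and promoter context, plus Mann–Whitney
statistics separating DEGs from non-DEGs under the score versus
single-metric rankings (best −log10 p alone, largest |meth change| alone).
On synthetic data the score separates planted target genes with AUROC
≈ 0.99 and beats the |meth change|-only ranking in every tested seed.

## Enrichment machinery

`gsea_preranked` implements the weighted-KS enrichment statistic (weight
exponent 1 by default; exponent 0 is the classic rank-only KS and is
invariant to monotone transformations of the ranking). The null is a
gene-label permutation: random same-size sets from the ranked universe,
shared across sets of the same size. When C(N, size) ≤ n_perm the null is
enumerated exhaustively, making the p-value exact — this is what the
small-universe oracle tests exercise. NES = ES / mean(|null ES| of the same
sign); p = (1 + #{same-sign nulls with |ES| ≥ |obs|}) / (1 + #same-sign),
so p ≥ 1/(n_perm+1). Magnitude ties between the positive and negative
extreme deviation resolve to the positive side.

`regulon_gsea` runs the statistic twice per regulon — once on the
gene-methylation score (positive = hypermethylated) and once on expression
log2FC (negative = downregulated) — and flags `hyper_down` regulons passing
|NES| > 1.6 and q < 0.01 on both sides with those signs. **It defaults to
weight exponent 0**: the gene-methylation score is strongly heavy-tailed
(a handful of genes carry almost all the mass), and with exponent 1 the
permutation null saturates — any random set's weight concentrates in its
single highest-scoring member, so null |ES| ≈ 0.8 regardless of universe
size and no NES can clear a meaningful threshold. The rank-only statistic
keeps the null well-behaved on such rankings; exponent 1 remains available
as a parameter.

Over-representation and pathway-overlap tests are upper-tail
hypergeometrics (BH across sets); the overlap test's universe is the
collection of sets tested in both input tables.

## Chromatin

* Containment uses 0-based half-open intervals everywhere (a CpG at a
  peak's `end` coordinate is outside).
* DMC-in-open-chromatin enrichment: population = queried CpGs, successes =
  queried CpGs in peaks, draws = DMCs, observed = DMCs in peaks; upper-tail
  hypergeometric. Lineage-specific enrichment restricts the universe to
  CpG-containing peaks and BH-corrects across lineages.
* Differential accessibility: per peak, binary accessibility ~ group +
  log(total fragments) by logistic regression (own Newton solver), LRT
  against the depth-only model, χ²(1) p-values, BH. Separation or
  non-convergence triggers a ridge-penalised refit of **both** models
  (λ = 1e-3) so the deviance difference stays comparable; the fallback is
  logged. Effect size is log2 of the detection-fraction ratio with
  pseudocount 1e-3; calls at q < 0.001 and |log2FC| > 0.25. The solver is
  cross-checked against an independent maximum-likelihood fit and against
  the closed-form 2×2 G-statistic in the tests.
* Motif scanning: log-odds (log2, PWM floored at 1e-4) over both strands;
  a region is a hit when its best window reaches the motif's threshold.
  DMC windows are symmetric ±20 bp, i.e. [pos−20, pos+21), 41 bp.
  Background for motif enrichment is size-matched windows around randomly
  sampled queried CpGs (seeded) — a reproducible stand-in for GC-matched
  backgrounds.

## Regulon activity and network

AUCell-style activity: per cell, genes rank by expression with a seeded
random tie-break; activity is the area under the recovery curve of regulon
members within the top 5% of the ranking, normalised by the maximal area,
hence in [0, 1]. The closed-form uniform-placement expectation
(`expected_uniform_activity`) serves as the null reference in tests.
Differential activity is a rank-sum test with fold change defined as
mean(LGA)/mean(CTRL) − 1 (a relative change; flagged at q < 0.001 and
|fc| > 10%).

The network stage treats regulons as inputs. An edge TF→target survives
only if ≥ 1 peak associated with the target (promoter overlap or within
50 kb of the TSS) contains the TF's motif; per-TF concordance is the
fraction of targets so supported. Nodes carry the gene-methylation score
and DEG status; edges carry DMC containment and differential-accessibility
status of their supporting peaks. A `min_degree` view filter (single pass
on unfiltered degrees) mirrors the usual "two or more interactions"
presentation and is off by default.

## Synthetic-data generator

One linear chromosome (genes every ~30 kb, promoters −1500/+500 around the
TSS respecting strand, distal enhancers for 70% of genes, eQTL regions
tiling ≈ 34% of the chromosome with a fraction pointing at distant genes).
Methylation is simulated on the logit scale — per-CpG baseline + additive
covariate effects + group shift + N(0, 0.3) noise, squashed through the
logistic — so the linear-model stage is approximately well-specified while
fractions stay in [0, 1]. Planted effects:

* 5% of CpGs carry a +30 pp shift, 85% of them placed inside
  promoters/enhancers of 3% of genes (the "target genes");
* every CpG additionally receives a weak global hypermethylation bias,
  Exponential with mean 0.07·δ (≈ 2 pp at the default δ = 30), scaled by δ
  so that δ = 0 is an exact null — this reproduces the global
  hypermethylation shift of the study design and gives non-target genes a
  continuous score spectrum;
* 10% of peaks drop from open probability 0.40 to 0.15 in LGA cells, with
  per-cell lognormal depth entering through the same logistic link the DA
  model assumes;
* target genes are downregulated at log2FC −1 in negative-binomial counts;
  the first two regulons target exactly those genes, and each TF's
  consensus (12-mer, PWM 0.85/0.05, threshold 0.85·max score) is written
  into one associated peak per target;
* library complexity is drawn correlated with batch to exercise confounder
  adjustment.

Default sizes are desk-scale study stand-ins: 5000 CpGs, 600 genes, 16
samples per group, 300 cells per group, 400 peaks, 8 regulons. These sizes
keep a full pipeline run under ~10 s while leaving every recovery test
well-powered; the acceptance script uses them as-is, plus 25 repeated
1-seed simulations for the score-comparison experiment and a reduced
configuration (1000 CpGs/100 genes) for the double-run determinism check.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: read-level noise and coverage-dependent
measurement error in methylation fractions; spatial correlation between
neighbouring CpGs; doublets, ambient contamination and batch structure in
the single-cell modalities; overlapping/nested gene models and multiple
chromosomes; realistic motif redundancy between TF families; and effect
sizes, which are planted sharply (real contrasts are weaker and broader).
Calibration results (type-I error, sensitivity) are statements about the
generator's conditions, not about any particular cohort.

## Determinism

All randomness flows through `numpy.random.Generator` streams derived from
one seed per run (`SeedSequence([seed, stage])` inside the generator;
stage-offset seeds in the pipeline). The run manifest records seeds,
thresholds, per-stage row counts and sha256 checksums of every output;
rerunning a fixed config reproduces all checksums exactly.

## Known limitations

* The dampening constant k = 13.8 is taken as given; the package exposes it
  (`k_damp`) but offers no procedure to re-derive it.
* The score's zero-evidence discontinuity (above) means near-zero links are
  effectively vetoes; filtering non-informative CpGs before scoring is the
  practical remedy.
* The DA fallback's penalised LRT is approximate under complete separation;
  such peaks are rare and logged.
* GSEA NES values on small universes (hundreds of genes) are coarser than
  on genome-scale rankings; the exact-enumeration mode mitigates the
  p-values but not the NES granularity.
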