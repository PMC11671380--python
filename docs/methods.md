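# Methods

## The signature model

The package operationalizes a construction that is usually done by hand
across three browser tools: given an anchor gene whose protein marks a
specific anatomical compartment of a glioma, its *spatial inflammation
signature* is the set of genes that simultaneously (i) co-express with the
anchor across a tumor cohort, (ii) carry an inflammation annotation, and
(iii) are upregulated in the compartment of interest in region-dissected
expression data. Each criterion is a gene set; the signature is their
intersection, and every choice that the hand-workflow leaves implicit is
made explicit and configurable here.

**Co-expression cluster.** All genes are ranked by Spearman correlation with
the anchor across samples (mid-ranks for ties; zero-variance genes skipped;
the anchor excluded — its self-correlation is uninformative). The cluster
keeps the top *k* genes, default k = 500, with every gene tied at the
rank-k boundary included, so the cluster has *at least* k members. No
correlation floor is applied on top of the rank cut; the ranking direction
defaults to positive co-expression, with negative/absolute offered for
reuse as an enrichment ranking metric.

**Region-upregulated genes.** Samples carry one label from the five-region
vocabulary LE / IT / CT / MVP / PAN (leading edge, infiltrating tumor,
cellular tumor, microvascular proliferation, pseudopalisading cells around
necrosis — the compartment structure of region-dissected glioblastoma
RNA-seq). "Upregulated in the target regions" is defined as: Mann-Whitney U
of target-region samples vs all others, Benjamini-Hochberg correction
across genes, pass iff q < α (default 0.05) and log2 fold change (target
mean − rest mean) ≥ 1. The two-group rank test matches the package's
two-group testing elsewhere; BH is used because a per-gene scan needs an
FDR, and both thresholds are configuration, not constants. The hypoxic
workflow targets {PAN}, the perivascular workflow {MVP}.

**Inflammation annotation.** A local GMT file (e.g. an export of
inflammatory-response GO descendants). Membership is taken as given;
annotation services are deliberately out of scope so runs are offline and
reproducible. Gene symbols match exactly and case-sensitively throughout —
no alias resolution, by design: silent symbol mapping is a reproducibility
hazard and the right fix is upstream harmonization of the inputs.

**Scoring and stratification.** A sample's signature score is the mean of
the signature genes' z-scores (per-gene standardization across samples,
ddof = 1; zero-variance genes dropped with a warning; missing signature
genes dropped, not imputed). Mean-z is the simplest single-sample scheme
consistent with reading a score off a z-scored heat map; a rank-based
(ssGSEA-style) alternative was considered and rejected as the default
because it adds a tuning parameter without changing any downstream
decision in this design. Scores are split high/low at the median (or a
configurable quantile); ties at the cutpoint go to "low", deterministically.

## Evaluation

*Diagnostic*: ROC/AUC of the score against case/control labels. AUC is
computed from mid-ranks via the Mann-Whitney U relation — identical to the
trapezoidal area under the empirical curve and well-defined under score
ties; curve points come from the standard threshold sweep. *Prognostic*:
Kaplan-Meier product-limit curves per score group and the two-sided
Mantel-Cox log-rank test, computed from explicit risk tables (observed,
hypergeometric-expected and variance per event time) so the per-group O/E
decomposition is reported, with p from χ²₁. *Therapeutic*: per subject,
control and treated profiles are reduced to signature-gene log2 fold
changes (for qPCR input via ΔΔCt: replicates averaged, ΔCt against the
reference gene — GAPDH/Gapdh by default — per condition, fold = 2^(−ΔΔCt));
a subject is a responder iff a one-sided Wilcoxon signed-rank (alternative:
decrease) on those fold changes gives p < 0.05. The exact null is used up
to 15 nonzero, magnitude-untied genes, the normal approximation otherwise;
an all-zero fold-change vector is reported as a flagged non-responder with
p = 1 rather than an error. A per-subject gene-wise test is the only
responder rule computable from a paired single-measurement-per-gene design;
the threshold is configurable.

*Enrichment*: preranked GSEA with the weighted Kolmogorov-Smirnov running
sum — hit steps |score|^p normalized over set members (p defaults to 1),
miss steps 1/(N − n_set), ES the signed maximum deviation. Significance
uses a gene-permutation null (random same-size sets), the only null
available to a preranked list; p = (1 + #{same-sign |ES_null| ≥ |ES|}) /
(1 + #same-sign), NES = ES / mean |same-sign null ES|, and BH across sets
stands in for the desktop tool's native FDR. The p-value floor is therefore
1/(1 + #same-sign nulls), bounded below by 1/(n_perm + 1).

## The synthetic generator

The generator emits cohorts with exactly the structure the pipeline
assumes, plus ground truth, so every stage can be tested for *recovery*
rather than plausibility.

* **Co-expression** comes from a single shared latent factor F ~ N(0,1) per
  sample: the anchor is baseline + F, each block member is
  baseline + c·F + σ·ε. Since (anchor, member) is bivariate normal with
  Pearson correlation λ = c/√(c²+σ²), setting λ = 2·sin(π·ρ_s/6) yields the
  requested Spearman ρ_s (default 0.8) exactly in population.
* **Regional effect**: a fixed +2 log2FC added to region-up genes in
  target-region samples (region labels uniform over the five-region
  vocabulary). The shift is independent of F, so block∩region genes have a
  somewhat lower anchor correlation than pure block genes — a realistic
  nuisance that the recovery tests absorb.
* **Set layout**: the planted signature is, by construction, exactly
  block ∩ inflammation ∩ region-up. Overlaps are specified as explicit
  counts (triple 60; block∩inflammation +60, block∩region +40,
  inflammation∩region +20 beyond the triple) over 300/400/250-gene sets in
  a 2000-gene universe — counts rather than fractions keep the invariants
  (non-negative remainders, fits in the universe) checkable at
  construction. The 20 inflammation∩region genes outside the block are the
  designed confounders: they pass two of three criteria and enter the
  derived signature only when they crack the top-k by chance (~2–3 genes
  per cohort, the dominant term keeping recovery Jaccard ≈ 0.95 rather
  than 1).
* **Survival**: exponential event times with hazard h₀·exp(β·F) (defaults
  h₀ = 0.05/month, β = 1 per factor SD — a median of roughly 14 months at
  the baseline, in the range expected for aggressive glioma), censored by
  an independent exponential calibrated to a 30% censoring fraction at
  β = 0.
* **Diagnostics**: 50 control samples of pure background noise; cases
  additionally carry +2 log2 on the signature genes. With the shift at 0
  the case/control AUC is 0.5 by construction.
* **Paired treatment arm**: 16 subjects, one control and one treated
  profile each (measurement noise SD 0.3); in a planted 50% of subjects the
  treated profile's signature genes drop by 1 log2 unit. A 60-gene
  signature at that effect size gives per-subject power ≈ 1, so recovered
  responder counts concentrate at 8/16 plus a small false-positive excess
  (≈ 5% of non-responders).
* **qPCR plate**: per-gene baseline Ct ~ U(18, 30), treated mean Ct lower
  by log2(fold), replicate noise Gaussian (default 3 replicates, SD 0.1).

All randomness flows from one seed through one `numpy` Generator; the same
seed reproduces every output bit for bit, and the generator version is
stamped into the truth object.

What the generator does **not** emulate: negative-binomial count noise,
batch and platform effects, correlated gene-gene structure outside the
planted block, informative censoring, within-tumor region mixtures, or
scRNA-seq. Passing recovery tests therefore demonstrate that the pipeline's
inference is correct *under its own assumptions* — not that the derived
signatures would replicate on real cohorts.

## Numerical choices and degenerate inputs

Mann-Whitney uses enumeration-exact p when the pooled sample is ≤ 12 and
tie-free, otherwise the normal approximation with tie and continuity
corrections; a U exactly at its null mean (e.g. identical group multisets)
reports p = 1, and an all-constant gene reports (U = n₁n₂/2, p = 1) instead
of NaN. BH q-values come from the standard step-up with monotonicity
enforcement. Stratification refuses an all-identical score vector.
Correlations refuse zero-variance input. Empty derived signatures are a
warning, not an error: the pipeline writes the provenance and skips scoring
and evaluation. Percentages in cohort summary tables are rounded half-up to
two decimals in decimal arithmetic, matching clinical-table conventions.
Ranking ties anywhere (co-expression order, ranked lists) break by gene
name so outputs are order-independent and deterministic.

## Problem sizes in the shipped checks

The test suite exercises recovery on 20 default-sized cohorts (2000 × 250),
null calibration on 100 compact effect-free cohorts (120 genes, 260
samples) and 100 signal-free rankings (400 genes, 199 permutations), and
responder recovery on 50 paired 16-subject arms; the acceptance script uses
10/20/20-seed versions of the same computations. These sizes make the full
default run complete in minutes on one core while leaving every Monte-Carlo
margin comfortably wide of its threshold.

## Known limitations

The signature construction is set-based; it does not weight genes by
correlation strength or effect size. The log-rank test is the two-group
form (no stratification, no trend). ROC analysis assumes the labels are
given; it does not define what the case population should be. ΔΔCt assumes
perfect doubling per cycle (no amplification-efficiency correction).
Gene-permutation GSEA p-values are anti-conservative relative to
phenotype permutation when genes are co-expressed — acceptable here because
the package only consumes preranked lists.
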