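# gliosig

Anchor-gene **spatial inflammation signatures** for glioma transcriptomics.

High-grade gliomas organize inflammation spatially: damage-associated S100A
proteins mark distinct anatomical compartments of the tumor — S100A9 the
hypoxic/necrotic pseudopalisades (PAN), S100A11 the perivascular niche (MVP).
`gliosig` turns that observation into a reproducible pipeline. Starting from
an anchor gene *a*, a bulk expression matrix `X` (genes × samples,
log2 scale), a region-labelled cohort, and an inflammation annotation, it
derives a signature as the three-way intersection

```
S(a) = TopK_Spearman(a; X)  ∩  Inflammation  ∩  Up(target regions)
```

where `TopK_Spearman` is the cluster of (at least) *k* = 500 genes with the
highest Spearman correlation ρ with the anchor, and `Up` collects genes with
Mann-Whitney BH-adjusted q < 0.05 and log2 fold change ≥ 1 in the target
regions (LE / IT / CT / MVP / PAN vocabulary) versus the rest of the tumor.

Each sample is then scored with the mean per-gene z-score of the signature,
and the score is evaluated three ways:

* **diagnostic** — ROC/AUC against case/control labels, with
  AUC = U⁺/(n₊·n₋) via the rank–Mann-Whitney relation;
* **prognostic** — median-split Kaplan–Meier curves compared by the
  two-sided Mantel–Cox log-rank test, χ² = (ΣO−ΣE)²/ΣV;
* **therapeutic** — per-subject paired control-vs-drug profiles (tumor
  fragments or qPCR ΔΔCt fold changes, fold = 2^(−ΔΔCt)), with responders
  called by a one-sided Wilcoxon signed-rank on the signature genes'
  log2 fold changes.

A preranked gene-set enrichment module (weighted Kolmogorov–Smirnov running
sum, gene-permutation null) and a seeded synthetic-cohort generator with
full ground truth complete the toolkit. Intended users: computational
biologists evaluating compartment-specific expression signatures on bulk
RNA-seq cohorts.

## Worked example

Generate a synthetic cohort (2000 genes, 200 region-labelled tumor samples +
50 controls, a 300-gene co-expression block at Spearman 0.8 around S100A9, a
planted 60-gene signature) and run the full discovery chain:

```bash
gliosig simulate --seed 5 --out-dir sim
cat > pipe.yaml <<EOF
expression_path: sim/expression.tsv
metadata_path: sim/metadata.tsv
inflammation_gmt_path: sim/planted_sets.gmt
out_dir: run
anchor: S100A9
target_regions: [PAN]
seed: 5
EOF
gliosig run-all --config pipe.yaml
```

which prints

```
{
  "auc": 0.9078,
  "logrank_p": 6.7507519498510126e-12,
  "n_genes_used": 63,
  "signature_size": 63,
  ...
}
```

The derived signature holds 63 genes — the 60 planted ones plus 3
bystanders that entered the 500-gene co-expression cluster by chance
(Jaccard 0.95 against truth). Its score separates cases from controls with
AUC 0.91 and splits tumor survival decisively (log-rank p ≈ 7·10⁻¹²),
because the generator couples the hazard to the same latent factor that
drives the co-expression block. Artifacts (ranking TSV, regional results,
signature GMT, scores, KM curves, ROC points, provenance JSON) land in
`run/`; rerunning with the same config and seed reproduces them byte for
byte.

The same steps are available as library calls (`rank_coexpressed`,
`region_upregulated_genes`, `derive_signature`, `score_samples`,
`km_estimate`, `logrank_test`, `roc_auc`, `delta_delta_ct`,
`signature_response`, …); the CLI is a thin wrapper.

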