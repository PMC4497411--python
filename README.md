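# mirlineage

Integrative analysis of miRNA expression signatures in mammary epithelial
cell subsets: from raw TaqMan low-density-array Ct values through
differential expression, directional rotation gene-set tests against target
mRNAs, tumor miRNA-seq signature scoring, and histone-mark (ChIP-seq)
linkage.

## Pipeline stages

| Stage | Module | What it does |
|---|---|---|
| simulate | `mirlineage.synthetic_data` | Generate every input format with planted ground truth |
| preprocess | `mirlineage.ct_preprocess` | Ct export → log2 (`E = 40.5 − Ct`) → housekeeping-weighted cyclic loess (span 0.7, 5 iterations, weight 100) → expressed-probe filter (≥2 in ≥3 samples) |
| de | `mirlineage.linear_de` | Probe-wise linear models, empirical-Bayes moderated t/F, BH FDR; subset signature / ANOVA / basal-vs-luminal / stroma-vs-epithelium / cross-species contrasts; MDS and clustering summaries |
| targets | `mirlineage.target_rotation` | Directional rotation gene-set tests of each DE miRNA's predicted targets (inverse-correlation screen), barcode-plot data, hypergeometric GO enrichment |
| score | `mirlineage.tumor_signature` | Collapse technical replicates/isoforms, CPM filter, TMM, log2-CPM (prior 0.25), signature scores `sum(logFC·logCPM)/sum(|logFC|)`, subtype comparison |
| epilink | `mirlineage.epigenome_link` | Count ChIP reads over miRNA loci ±3 kb, NB fold changes at fixed dispersion 0.05 (prior count 1), regression through the origin against expression fold changes |

## CLI

Each stage is a subcommand; `run` chains all of them on a synthetic dataset
and writes a manifest with parameter values, per-stage seeds and output
hashes:

```sh
mirlineage simulate --outdir out/ --seed 1
mirlineage preprocess --ct out/ct_plates.csv --species mouse --out out/expr.tsv
mirlineage de --matrix out/expr.tsv --contrast basal-vs-luminal --out out/de.tsv
mirlineage targets --de out/de.tsv --mrna out/mrna_matrix.tsv \
    --map out/target_map.tsv --rotations 9999 --seed 1 --out out/screen.tsv
mirlineage score --counts out/tumor_counts.tsv --annot out/tumor_samples.tsv \
    --signature out/signature.tsv --out out/scores.tsv
mirlineage epilink --loci out/mirna_loci.bed \
    --reads MaSC/basal H3K4me3 out/reads_MaSC-basal_H3K4me3.bed ... \
    --de out/chip_de.tsv --out out/epilink.tsv

# or everything at once
printf 'outdir: out\nseed: 1\n' > config.yaml
mirlineage run --config config.yaml
```

All file formats are plain text: Ct plates as CSV (sample, probe,
probe_class, ct), matrices as TSV, loci and reads as BED6, target maps and
annotations as two-column TSV.

## Notes on the statistics

* Normalization is the classical all-pairs cyclic loess: per iteration and
  sample pair, a weighted degree-1 local regression of M on A (tricube
  kernel, housekeeping fit weights × 100) is subtracted/added with weight
  1/(2·(n−1)); adjustments accumulate within an iteration, so the result
  does not depend on sample order.
* Empirical-Bayes moderation estimates the prior (d0, s0²) by matching the
  first two moments of log s² to a scaled-F log distribution
  (digamma/trigamma inversion), with a d0 = ∞ branch when the observed
  variances are under-dispersed.
* The rotation test reduces each gene to the (residual df + 1)-dimensional
  subspace spanned by the tested contrast and the residuals, replaces the
  contrast direction with uniformly random unit vectors, and reports
  p = (exceedances + 1)/(B + 1) for the set mean of moderated t values.
* NB fold changes solve the fixed-dispersion score equation per group by
  Newton iteration after adding a library-size-scaled prior count.
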