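# aesig

Autoencoder decomposition of bulk tumor gene expression into
**tumor-extrinsic (TE)** and **tumor-intrinsic (TI)** prognostic signatures.

Given a gene×sample expression matrix and per-sample lymphocyte
infiltration scores, the pipeline:

1. log2-transforms and z-scores expression per gene (`preprocess`);
2. screens the top-k genes most positively (GH′) and most negatively (GL′)
   correlated with lymphocyte infiltration;
3. trains one symmetric autoencoder per panel (default 1000 → 400 → 100 →
   20 → … mirrored, ReLU hidden layers, linear reconstruction, regularized
   square loss, minibatch SGD with momentum — implemented in numpy with
   analytic gradients) (`autoencoder`);
4. selects each compartment's most prognostic bottleneck node by
   median-dichotomized univariate Cox screening, orients it (TE: higher =
   lower hazard; TI: higher = higher hazard), and attributes the node back
   to genes via the sum over encoder weight paths — a column of the product
   of the encoder weight matrices (`signature`);
5. scores external cohorts with the frozen models (per-cohort z-scoring,
   panel alignment with zero-fill for missing genes, no re-training)
   (`workflow`);
6. evaluates scores with KM/log-rank, uni/multivariate Cox, four-group
   TE×TI stratification, C-index model comparison, and responder
   rank-sum/ROC statistics (`survival`), plus tumor-genomic covariates
   (TMB, CNV burden, CYT index) (`genomic`) and pre-ranked permutation
   GSEA of the attribution weights (`enrichment`);
7. generates fully synthetic cohorts with planted immune/intrinsic latent
   factors, survival, mutation, CNV and response structure so the whole
   pipeline is testable offline (`synthetic`).

## CLI

```bash
# emit a synthetic cohort in pipeline-readable TSV/GMT formats
aesig simulate --seed 1 --out-dir cohort/

# train TE/TI signatures and save the model bundle (HDF5 weights + JSON meta)
aesig decompose --expr cohort/expression.tsv \
    --lymph-scores cohort/lymphocyte.tsv --clinical cohort/clinical.tsv \
    --k 250 --epochs 100 --hidden 128,64,20 --seed 1 --out-dir run/

# score any cohort with the saved bundle
aesig score --model run/model --expr cohort/expression.tsv --out scores.tsv

# survival evaluation: KM plots, log-rank, Cox, C-index, four-group medians
aesig survival --scores scores.tsv --clinical cohort/clinical.tsv \
    --covariates age,stage --out-dir surv/

# pre-ranked GSEA of the attribution weights
aesig gsea --weights run/te_gene_weights.tsv --gmt cohort/gene_sets.gmt \
    --nperm 1000 --seed 7 --out gsea.tsv
```

## Notes

- Matrices are oriented genes×rows, samples×columns everywhere; model
  bundles store gene panels inseparably from weights and are checksummed.
- Node indices are 0-based and re-derived per training run; they are data,
  not constants.
- Training is fully reproducible from the seed (initialization, shuffling
  and loss history included).
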