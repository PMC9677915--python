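# matreotype

Matrisome profiling of squamous cell lung carcinoma (SqCC) from bulk
RNA-seq: a tested, reusable implementation of an ECM-focused prognostic
analysis pipeline, together with a synthetic-cohort generator so every stage
can be exercised and validated without access to controlled patient data.

## Who this is for

Computational biologists analyzing bulk expression cohorts (tumor vs
adjacent non-tumor tissue, with survival follow-up) who want to:

- derive a **matrix risk signature** — a sparse set of extracellular-matrix
  (ECM) genes separating tumor from non-tumor tissue — and score samples
  with it;
- discover **matreotypes** — ECM-expression tumor subtypes (ECM-High /
  ECM-Low / Non-Tumor-like) — and test their association with survival and
  with canonical molecular subtypes;
- quantify matrix-driven **ligand–receptor interactions** and a
  **fibrosis score** per sample.

## The model in brief

**Matrix risk score.** For a sample with z-scaled expression `z_i` of the
`n` signature genes,

    score = Σ_{i=1..n} z_i · β_i ,

where `β_i = log(odds ratio)` of gene *i* from a Firth-penalized logistic
regression of tumor vs non-tumor class. Genes enter the signature by
elastic-net penalized logistic regression (α = 0.5) on differentially
expressed core-matrisome genes, with the penalty chosen by the
cross-validated one-standard-error rule on an 80/20 train/test partition.
Firth's correction (Jeffreys-prior penalization of the likelihood) keeps
the weights finite even under complete separation.

**Matreotypes.** Samples are clustered on z-scaled differentially expressed
core-matrisome genes by Monte-Carlo consensus clustering: subsampled
K-means consensus matrices summarized by the PAC score (proportion of
ambiguous clustering), compared against multivariate-normal reference
datasets that preserve the gene covariance eigenstructure. The cluster
number maximizes the relative cluster stability index (RCSI) among K with
Monte-Carlo p < 0.05. New samples are assigned by minimum Euclidean
distance to the cluster centroids; canonical SqCC subtypes (primitive /
classical / secretory / basal) are assigned by highest Pearson correlation
with published centroids.

**Interaction and fibrosis scores.** For a (ligand, receptor) pair the
per-sample interaction score is the product of the two z-scaled expression
values, `R_i · L_i`, aggregated to receptor classes or hallmark pathways by
the maximum over member pairs. The fibrosis score is `Σ w_i z_i` over a
±1-weighted idiopathic-pulmonary-fibrosis gene signature.

Outcome statistics (Kaplan–Meier, log-rank, Cox proportional hazards with
Efron ties, Fisher exact enrichment, Mann-Whitney with Benjamini-Hochberg
correction) connect all of the above to survival and clinical annotation.

## Worked example

Simulate a cohort, derive a risk signature, and check held-out performance:

```python
from matreotype import (SyntheticConfig, generate_bulk_cohort,
                        tmm_normalize_log2, differential_expression,
                        partition_cohort, zscale_genes, elastic_net_select,
                        firth_log_odds, matrix_risk_score, roc_auc)

cohort = generate_bulk_cohort(SyntheticConfig(seed=1, ecm_program_shift=0.0))
log2 = tmm_normalize_log2(cohort["expression"])       # filter + TMM + log2 CPM
meta = cohort["metadata"]

de = differential_expression(log2, meta["tissue_class"])
matrisome = set(cohort["truth_genes"].query("is_matrisome").index)
candidates = [g for g in de.table.index[de.table.significant] if g in matrisome]

train, test = partition_cohort(meta, 0.8, seed=1)
z_train = zscale_genes(log2.subset_genes(candidates).subset_samples(train))
sel = elastic_net_select(z_train, meta["tissue_class"], seed=1)
signature = firth_log_odds(z_train.subset_genes(sorted(sel["selected_genes"])),
                           meta["tissue_class"])

z_test = zscale_genes(log2.subset_genes(candidates).subset_samples(test),
                      reference=z_train)
scores = matrix_risk_score(z_test, signature)
print(len(signature.genes), "signature genes;",
      f"held-out AUC = {roc_auc(scores, meta['tissue_class']).auc:.3f}")
```

Output:

```
19 signature genes; held-out AUC = 0.997
```

19 of the cohort's 20 planted signature genes survive differential
expression and elastic-net selection with no false selections, and the
resulting risk score separates held-out tumor from non-tumor samples
almost perfectly — the behavior expected when the planted effect is one
latent SD per gene.

The same steps are available from the shell via the `matreotype` CLI
(`simulate`, `preprocess`, `de`, `risk-train`, `risk-score`, `cluster`,
`assign`, `survival`, `lri`, `score-sets`).

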