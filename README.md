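# morphoctx

Cellular morphometric subtyping of tumors from H&E histology.

Pathologists stratify tumors by eye; molecular subtyping needs assays that
many settings lack. `morphoctx` implements an image-only alternative: it
quantifies every cell nucleus in a slide, learns a dictionary of *cellular
morphometric biomarkers* (CMB) from those measurements, summarizes each
sample as the peak abundance of each biomarker among its cells, clusters
samples into *cellular morphometric subtypes* (CMS), transfers the subtype
model to new cohorts, and evaluates the clinical impact of biomarkers and
subtypes on survival and metastasis. It is aimed at computational
pathology and mouse-model researchers who want a tested, reproducible
reference implementation of this pipeline, exercised end to end on fully
synthetic cohorts (no external data needed).

## Model

- **Morphometry.** Each segmented nucleus is a vector of 15 properties
  (size, shape, boundary texture, intensity), z-scored with stored
  statistics x ↦ (x − μ)/σ.
- **Sparse coding.** A dictionary D ∈ ℝ^{256×15} of unit-norm atoms is
  learned from cells sampled at 1,000 per slide. Each cell x gets a
  nonnegative code α solving approximately
  min‖x − Dᵀα‖² s.t. α ≥ 0, ‖α‖₀ ≤ 30,
  by greedy pursuit with NNLS refitting (atoms enter by maximal positive
  residual correlation). α_j reads as the abundance of biomarker j in the
  cell.
- **Context representation.** A sample's context vector is the elementwise
  maximum of its cells' codes (max-pooling): c_j = max over cells of α_j.
- **Subtyping.** Consensus clustering of contexts (k-means, Euclidean, 500
  bootstrap subsamples at 80%); k chosen by minimal PAC with a log-rank
  tie-break; final labels from an average-linkage cut of 1 − consensus.
  Subtype 2 is anchored to the worse outcome. Transfer to a new cohort is
  nearest centroid: label = argmin_g ‖c − c̄_g‖₂.
- **Clinical evaluation.** Cox proportional hazards (Efron ties) with BH
  FDR for per-biomarker screens; maximally selected log-rank cutpoints for
  high/low splits; backward-AIC multivariable models; bootstrapped 60/40
  logistic classification (AUC, sensitivity, specificity); horizon-specific
  cumulative/dynamic survival AUC comparison of nested models with a paired
  bootstrap p.

A synthetic-cohort generator plants all of this structure (subtype-specific
nuclear geometry, a configured subtype hazard ratio, logistic metastasis
odds on chosen biomarkers) so every stage is testable; see
`docs/methods.md` for assumptions and limitations.

## Worked example

```python
import morphoctx as m

cohort = m.generate_cohort(m.trp53_preset(seed=0, cells_per_slide=100))
dictionary = m.learn_from_tables(cohort.features, rate=100, n_atoms=64,
                                 sparsity=8, n_iter=5, seed=0)
contexts = m.encode_cohort(cohort.features, dictionary)
model, results, trace = m.subtype_cohort(contexts, survival=cohort.clinical,
                                         k_range=range(2, 5), n_boot=100, seed=0)
print(trace.to_string(index=False))
curves, stat, p = m.km_logrank(model.assignments, cohort.clinical)
print(f"log-rank chi2 = {stat:.2f}, p = {p:.2e}")
```

prints

```
 k      pac  logrank_p  chosen
 2 0.000000   0.000937    True
 3 0.120703   0.002408   False
 4 0.124947   0.000839   False
log-rank chi2 = 10.95, p = 9.37e-04
```

k = 2 wins with PAC 0 (perfectly stable co-clustering — the cohort plants
two subtypes), and the recovered subtypes separate survival at p ≈ 1e-3:
the planted subtype hazard ratio of 1.893 is rediscovered from images of
cells alone. The scripts in `examples/` walk through each capability
(simulation, dictionary learning, subtyping, transfer + metastasis) and
print one-line interpretations; a thin CLI (`morphoctx simulate|segment|
features|learn|pool|subtype|transfer|survival`) wraps the same functions
for shell use.

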