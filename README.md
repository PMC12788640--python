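# histoimmune

Weakly supervised prediction of tumor immune-microenvironment levels from
histology tile bags, with single-cell-informed deconvolution pseudo-labels
and survival stratification.

## The problem

Bulk cohorts with whole-slide images (WSIs) — hepatocellular carcinoma being
the motivating case — usually lack direct measurements of immune cell
composition, yet immune infiltration (B cells, NK cells, monocytes, …) is
prognostic. `histoimmune` implements a three-stage workaround:

1. **Deconvolution.** Train an ensemble of neural regressors on *pseudo-bulk*
   mixtures — single-cell profiles aggregated at known Dirichlet-drawn
   proportions — so the model learns to map a bulk expression vector **x** to
   cell-type fractions **f** on the simplex. Applied to real bulk profiles,
   this yields per-patient immune fraction estimates.
2. **Weak supervision of imaging.** Median-split the estimated fraction of a
   target cell type into high/low pseudo-labels, and train multiple-instance
   learning (MIL) classifiers on each patient's bag of slide tiles
   {h₁,…,h_N}. Aggregators: mean pooling (CNN baseline), gated attention

   aₖ = softmaxₖ( wᵀ(tanh(V hₖ) ⊙ σ(U hₖ)) ),  z = Σₖ aₖ hₖ,

   and a transformer-encoder variant that models inter-tile dependencies
   before the same attention pooling. Ordinal labels use a cumulative
   multi-hot encoding (class c ↦ c+1 leading ones) trained with element-wise
   binary cross-entropy on logits.
3. **Survival stratification.** Kaplan–Meier curves and the two-group
   log-rank test on the predicted high/low groups, with quadratic-weighted
   Cohen's kappa and t-distribution confidence intervals for classification
   quality.

Everything runs on synthetic cohorts with planted ground truth (marker-gene
signatures, QC violations, signal tiles, hazard ratios), generated by the
`synthetic_data` module — no external dataset is required, and every
benchmark is seeded and reproducible. Single-cell QC (detected genes in
[250, 2500], mitochondrial fraction ≤ 5%), global-scaling log normalization,
upper-quartile bulk normalization, and adjusted-Rand-index evaluation of
clustering-vs-batch structure are included as first-class, tested stages.

The models are scikit-learn-style estimators — `DeconvolutionEnsemble` and
`MILClassifier` expose `fit` / `predict` / `get_params` — built on a compact
numpy autodiff engine (`histoimmune.nn`) whose gradients are verified against
finite differences in the test suite.

## Worked example

The whole chain from one config (library call shown; `histoimmune run
--config pipeline.yaml --out out/` is equivalent):

```python
from histoimmune.pipeline import run_pipeline
metrics = run_pipeline({"seed": 1}, "out/")
```

takes ~15 s on one CPU and prints/writes `out/metrics.json`:

```json
{
  "qc":       {"n_before": 1250, "n_after": 1058, "retained_fraction": 0.8464},
  "deconv":   {"median_per_sample_pcc": 0.986932, "mean_per_type_pcc": 0.979849},
  "labeling": {"threshold": 0.399272, "n_high": 100, "n_low": 100,
               "agreement_with_truth": 0.85},
  "mil":      {"mode": "att", "val_accuracy_vs_pseudo": 0.85,
               "val_qwk_vs_pseudo": 0.699332, "accuracy_vs_truth": 0.985},
  "survival": {"wsi_stratification":  {"chi2": 21.826046, "p": 2.99e-06},
               "ccd_stratification":  {"chi2": 6.622877,  "p": 0.01006771},
               "true_group_stratification": {"chi2": 21.274644, "p": 3.98e-06}}
}
```

Reading it: QC kept 85% of cells (the rest were planted low-quality); the
deconvolution ensemble recovers validation mixture fractions at median
per-sample Pearson r ≈ 0.99; the median split of the estimated target-type
fraction agrees with the planted truth for 85% of the 200 patients; the
gated-attention MIL model, trained only on those imperfect pseudo-labels,
recovers the *true* immune group of 98.5% of patients from their tiles; and
the MIL-predicted high/low groups separate survival (planted hazard ratio 2)
at log-rank p ≈ 3×10⁻⁶ — essentially as well as the true groups, and better
than the noisier expression-based split.

Individual stages are available as library functions and CLI subcommands
(`histoimmune synth sc|slides|survival`, `qc`, `normalize`, `ari`,
`deconv simulate|train|predict|eval`, `mil train|predict|eval`, `survive`).

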