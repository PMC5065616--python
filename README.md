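# nephroscreen

Imaging-based prediction of proximal-tubular-cell (PTC) toxicity from
high-content screens of cultured human kidney cells.

Most nephrotoxic xenobiotics damage the renal proximal tubule, but no
regulatory-approved in vitro test predicts that damage. This package
implements a phenotypic-profiling pipeline for that problem: cells treated
across a dose range are imaged in four fluorescence channels (DNA, RelA or
γH2AX, actin, whole-cell stain), 129 quantitative per-cell features are
extracted (Haralick texture, intensity, intensity ratios, marker
correlations, morphology, cell count), each feature's dose response is
condensed into a single maximal log₂ response, and a random-forest
classifier predicts the binary PTC-toxicity class with rigorously
leakage-free performance estimation.

The core quantities:

* **GLCM texture.** `GLCM(i,j)` counts co-occurrences of gray levels *i, j*
  at offset (Δx, Δy); 13 Haralick statistics (f_ASM = ΣΣ p², entropy
  f_E = −ΣΣ p log p, sum entropy, correlation, IMC2, …) of the normalized
  matrix are averaged over the 0°/45°/90°/135° offsets.
* **Δmax.** Δ = log₂(treated/vehicle) per feature and dose; the 4-parameter
  log-logistic fit Δ(x) = c + (d−c)/(1+exp(b(log x − log e))) is evaluated
  at a fixed 5 mM reference concentration, and the median over three
  biological replicates fills the 129 × 44 features × compounds matrix.
* **Classification.** Features normalized to [−1, 1] on training data only;
  random forests tuned over N_tree ∈ {10…500}, N_trial ∈ {1…5}; balanced
  accuracy = (sensitivity + specificity)/2 estimated by a four-set nested
  stratified 10-fold cross-validation over compounds, repeated 10 times.
* **Feature selection.** Recursive feature elimination ranked by
  out-of-bag permutation importance; the retained-subset accuracies are
  clustered by a 1-D Gaussian mixture (BIC = −2L_m + N_d log N_s picks the
  component count) and the smallest subset in the best cluster is selected.

A synthetic-data generator mirrors the study design (24 toxic / 20
non-toxic compounds, 7 doses 1.6–1000 μg/mL, 3 replicates) with planted
log-logistic effects whose 5 mM response is analytically known, so every
stage is testable without the original images. See `docs/methods.md` for
the full model description and assumptions.

## Worked example

Generate a small screen, build the Δmax matrix, and classify:

```python
import nephroscreen as ns

spec = ns.SyntheticPanelSpec(n_toxic=6, n_nontoxic=6, n_features=20,
                             n_informative=4, effect_size=3.0,
                             replicate_noise_sd=0.2, seed=42)
panel, compounds = ns.generate_dose_panel(spec)
matrix, provenance = ns.compute_dmax_matrix(panel, compounds)

report = ns.nested_cv(matrix, compounds["label"], n_folds=4, n_trials=2,
                      seed=0, config=ns.RFConfig((150,), (3,)))
enrichment = ns.cluster_and_test(matrix, compounds["label"])
```

Output (about a minute, dominated by the 720 curve fits):

```
matrix shape: (20, 12)   unconverged fits: 190/720
Dmax[dna_glcm_asm_mean, TOX01] = 3.46
Dmax[dna_glcm_asm_mean, NTX01] = 0.19
balanced accuracy: 96.9 +/- 3.1 %
cluster enrichment min P: 0.00108
```

The first planted feature shows a ~3.5 log₂-unit maximal response under a
toxic compound versus ~0 under a non-toxic one; the classifier separates
the classes almost perfectly, and hierarchical clustering of the compounds
is significantly enriched for the toxic class (hypergeometric P ≈ 1e-3).
Unconverged fits are flat noise-only dose series; they take the documented
fallback (observed Δ at the top dose) and are flagged in `provenance`.

A thin CLI wraps the two main workflows:

```sh
nephroscreen classify        --matrix dmax.csv --labels labels.csv --report out/
nephroscreen select-features --matrix dmax.csv --labels labels.csv --selector gmm
```

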