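# eegcomplex

Complexity and functional-connectivity analysis of resting-state EEG for
two-group (younger vs older) aging studies, with a synthetic cohort
generator so the entire pipeline is testable without access to clinical
recordings.

## The problem

Healthy aging changes both the *temporal complexity* of cortical activity
and the *coordination* between regions. Three families of EEG markers
capture this:

- **Wavelet-leader multifractal analysis.** From discrete wavelet
  coefficients `d_X(j,k)`, the leaders `L_X(j,k) = sup |d_X|` over the
  3-neighbourhood dyadic tree give structure functions
  `S_L(q,j) = (1/n_j) Σ_k L_X(j,k)^q ~ 2^{j ζ(q)}` and the singularity
  spectrum `D(h) = inf_{q≠0} (1 + qh − ζ(q))`. The log-cumulants of
  `ζ(q) = c1 q + c2 q²/2 + …` summarise it: `c1` is the overall smoothness
  (location of the peak of `D(h)`), `|c2|` the multifractality /
  intermittency (its width).
- **Multiscale sample entropy (MSE).** Sample entropy
  `h(r,m) = −ln C_{m+1}(r)/C_m(r)` (m = 2, r = 0.2, Chebyshev distance,
  self-matches excluded) computed on coarse-grained series
  `x_j = (1/τ) Σ y_i` for scales τ = 1…30; at 200 Hz, scale 30 is a
  0.15 s window. The scale 1–5 mean is the "fast-scale" feature.
- **Phase-lag index (PLI).** For each canonical band (delta 2–4, theta
  4–8, alpha 8–13, beta 13–30, gamma 30–60 Hz),
  `PLI_ab = |⟨sign sin(φ_a − φ_b)⟩|` from Hilbert phases, averaged over ten
  5 s epochs. It is blind to zero-lag (volume-conducted) coupling. Node
  strength `NS_a = (1/(K−1)) Σ_b PLI_ab` summarises each electrode.

The per-channel features feed mixed-design repeated-measures ANOVA
(Greenhouse–Geisser corrected, partial η² effect sizes), BH-FDR-controlled
post-hoc Welch t maps, Spearman NS–complexity correlations, and a
classifier: logistic regression on the first three principal components,
with the PCA fitted *inside* each fold of 20 × stratified 5-fold
cross-validation, scored by ROC AUC.

## Worked example

```python
from eegcomplex.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    output_dir="example_run",
    synth={"n_young": 8, "n_old": 8},   # reduced cohort for speed
    mse={"max_scale": 5},
    repeats=10,
    seed=1,
    feature_sets=[["c1", ["c1"]], ["ns_alpha", ["ns_alpha"]],
                  ["c1+ns_alpha", ["c1", "ns_alpha"]]],
)
run_pipeline(cfg)
```

The run directory then contains `features.csv`, the ANOVA/ANCOVA tables,
post-hoc maps, and `roc.csv`:

```
feature_set  auc_mean   auc_sd  repeats  folds
         c1  1.000000 0.000000       10      5
   ns_alpha  0.770312 0.092012       10      5
c1+ns_alpha  1.000000 0.000000       10      5
```

The synthetic older group is built with a lower Hurst exponent, weaker
intermittency and stronger fast (gamma-band-like) noise, so the pipeline
recovers the expected directions — here the younger/older medians were
0.287/0.268 for `c1`, 0.039/0.030 for `|c2|` and 1.286/1.369 for the
fast-scale entropy — and `anova.csv` reports the corresponding group
effects (`c1`: F = 109.2, p = 5.4e-08, partial η² = 0.886 on this toy
cohort). With this strong a contrast, `c1` alone already saturates the
AUC; alpha node strength alone (driven by the built-in C3–C4 alpha
coupling edge) is weaker, and combining blocks never hurts.

The same pipeline runs from the shell:

```bash
eegcomplex synth --out cohort --seed 1          # write a cohort as CSV
eegcomplex all --config config.yaml             # features + stats + ROC
```

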