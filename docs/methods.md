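# Methods notes

This note records the models implemented, the numerical conventions chosen
where the underlying methods admit variants, and what the synthetic cohort
does and does not emulate.

## Signal conditioning

All stages share one deterministic preprocessing path: a 4th-order
Butterworth bandpass (2–60 Hz) applied forward–backward (`sosfiltfilt`), so
filtering is zero-phase and Hilbert phase relations are preserved; the
first 60 s of a recording is the analysis epoch; 5 s (1,000 samples at
200 Hz) are trimmed from each end to discard the filter transient, leaving
the 10,000-sample complexity epoch; connectivity uses its ten contiguous
1,000-sample segments. Indexing is 0-based with half-open intervals.
Relative band power uses Welch's method (2 s Hann windows, 50 % overlap)
with trapezoid integration; the five band definitions (delta 2–4 … gamma
30–60 Hz) are fixed constants.

## Wavelet-leader multifractal analysis

- **Wavelet**: Daubechies-3 (three vanishing moments), configurable. At
  least two vanishing moments are required so polynomial trends do not
  masquerade as singularities.
- **Transform**: a pyramid filter bank with strict `valid` convolution —
  every retained coefficient is an inner product with true samples, no
  padding. Coefficients carry L¹ normalisation (`2^{-j/2}` on top of the
  orthonormal filters) so that fBm(H) yields ζ(q) = qH.
- **Leaders**: computed bottom-up over the dyadic tree
  (`s(j,k) = max(|d(j,k)|, s(j−1,2k), s(j−1,2k+1))`, leader =
  max over the 3-neighbourhood). Positions lacking a complete
  neighbourhood or complete descendants are dropped rather than padded;
  per-scale counts `n_j` shrink accordingly. A brute-force sup over all
  contained intervals verifies the recursion in the tests.
- **Fit range**: scales j = 3 … ⌊log₂N⌋ − 3 by default, requiring at least
  8 leaders per scale and 3 usable scales.
- **Fits are unweighted across scales.** Weighting scales by their leader
  count was tried and rejected: the fine scales, which dominate such
  weights, carry a known downward bias of leader statistics for rough
  signals, and with count weights the c1 of fBm(0.3) came back 0.06 too
  low. With equal scale weights the estimator recovers c1 within ±0.05
  for H ∈ {0.3, 0.5, 0.7, 0.8} and c2 within ±0.005 of −λ² for
  λ² ∈ {0.02, 0.05, 0.1} (n = 2¹⁵, 50 replicates).
- **Cumulants**: c_p = log₂(e) × slope of the p-th sample cumulant of
  ln L(j,·) against j — the standard low-variance estimator — rather than
  differentiating ζ(q). The q-grid for ζ and the Legendre transform is
  ±5 in steps of 0.25, q = 0 excluded; D(h) is the exact minimum over that
  grid, so it only represents spectrum slopes |D′| ≤ 5.
- The multifractal input is the broadband, z-scored 10,000-sample epoch.

## Multiscale entropy

m = 2, r = 0.2 in units of the scale-1 SD, held fixed across scales (the
series is z-scored once, then coarse-grained). Distance is Chebyshev;
matching is strictly `d < r`; self-matches are excluded; both match counts
use the N − m templates that admit an (m+1)-extension. Counting sorts
templates by their first coordinate and scans the `|Δ| < r` window — this
is *exactly* the naive O(N²) count (verified pairwise against a literal
double loop), just near-linear in practice. Undefined entropies (zero
matches) are NaN, never ±∞, and propagate through the scale 1–5 mean so a
silent average over missing values cannot occur.

## Phase-lag index

Eq.-level reading: taking "Δφ mod 2π" literally would make every phase
difference non-negative and the PLI trivially 1; the implemented
definition wraps into (−π, π], i.e. `sign(sin Δφ)`, the standard
formulation, under which a zero-lag common source and the antiphase
(dipole-opposite) projection both give PLI = 0 exactly. `sign(0) = 0`,
with |sin Δφ| < 1e−9 treated as zero so the floating-point value of
sin(π) also contributes nothing. The first and last 5 % of each epoch are
excluded from the average (analytic-signal edge transient). Per-epoch PLI
matrices are averaged across the ten epochs (not pooled sample-wise).

A finite-epoch floor: two *independent* band-limited signals have
autocorrelated phases (decorrelation time ≈ 1/bandwidth), so their
per-epoch |mean sign| does not vanish; at T = 1,000 samples this floor is
≈ 0.16 in the alpha band and larger for delta. Uncoupled-pair PLI values
should therefore be read against that floor, not against 0.

## Statistics

The mixed (split-plot) ANOVA is computed from orthonormal within-subject
contrasts: the between-subjects stratum tests the group effect on subject
means; each within stratum tests a group × within interaction on contrast
scores, with Greenhouse–Geisser ε = (tr S)²/(q tr S²) from the pooled
within-group contrast covariance, applied to both degrees of freedom.
This formulation reproduces pingouin's two-way mixed ANOVA F statistics
exactly and extends to the three-way group × electrode × scale layout
(Kronecker products of the contrast bases). Partial η² is
SS_effect/(SS_effect + SS_error). The ANCOVA enters the subject-level
covariate as a regressor in every stratum (one error df each), so the
group terms are assessed after the covariate.

Post-hoc tests are Welch (unequal variances — the two groups differ in
size); BH-FDR is applied to the p-values over the full published family
sizes (16, 480, 600, 80), with the t map reported alongside. The BH mask
is verified against a literal step-up implementation and against
statsmodels.

## Classification

PCA (first 3 components) and logistic regression are fitted on training
folds only; held-out probabilities of the 5 folds of a repeat pool into
one ROC, one AUC per repeat, 20 repeats; fold shuffling is seeded from
(seed, repeat) so different feature sets evaluated with one seed share
fold assignments and their per-repeat AUCs are pairable (paired t-test
across repeats). The logistic model carries a small ridge penalty
(λ ≈ 1/n) purely for stability at n ≈ 50. Under permuted labels the
pooled-ROC AUC is slightly pessimistic (≈ 0.47–0.49 rather than 0.50 at
n = 50) — the familiar anti-learning bias of cross-validation on null
data — which is within the tolerance used for the chance-level check.
Decision regions scan a PC plane at P(older) > 0.9 with all other
components at their grand mean; a single-class training set yields an
empty (or full) region by definition rather than an error.

## Synthetic cohort

Each channel is: z-scored MRW backbone + group-scaled fast noise + alpha
oscillation, mixed with a zero-lag broadband common source
(`(1−g)(backbone + noise) + g·common + oscillations`).

- **fBm/fGn** by exact circulant embedding (Davies–Harte), so increment
  covariances are exact and recovery tests are meaningful. **MRW**: fGn
  increments modulated by `exp(ω)` with
  cov(ω_i, ω_j) = λ² ln⁺(L/(|i−j|+1)), integral scale L = series length,
  mean −λ² ln L; theoretical c2 = −λ² (and c1 = H + λ²/2, within the
  recovery tolerance of H for the λ² used here). λ² = 0 reduces exactly
  to fBm.
- **Group defaults** (the study conditions): young H = 0.80, λ² = 0.08,
  fast-noise gain 0.30; old H = 0.70, λ² = 0.03, gain 0.45 (1.5×). These
  reproduce the *direction* of the aging contrasts (older: lower c1,
  lower |c2|, higher scale 1–5 entropy); no published effect magnitudes
  exist to target.
- **Fast noise is high-passed above 35 Hz** rather than white: the aging
  story it emulates is increased gamma-band activity, and band-limiting
  it lets it drive fast-scale entropy without swamping the mid-frequency
  wavelet scales that the fractal estimators read. (With white noise of
  comparable power the c1/|c2| group contrasts are erased — worth knowing
  when interpreting what the tests show about real data.)
- **Oscillations are band-filtered Gaussian noise** (unit SD, passband
  the band interior), not fixed-frequency sinusoids: a sinusoid per
  channel phase-locks spuriously with any channel whose frequency lands
  nearby, whereas filtered noise decorrelates at the band's time scale.
  Coupling edges mix linearly: `(1−s)·private + s·shared`, the shared
  component phase-shifted by rotating its analytic signal, so the lag is
  constant across time and frequency.
- **Not emulated**: head geometry and electrode forward models, artifacts
  (blinks, EMG), non-stationary state changes, realistic 1/f spectra
  beyond the MRW backbone. Passing tests demonstrate that the estimators
  recover known ground truth and directions under this model, not that
  the pipeline's effect sizes transfer to clinical EEG.

## Problem sizes used in the test suite

Recovery properties use 50 replicates of length 2¹⁵; the directional
cohort check uses the full 50-subject default cohort; the feature-fusion
property uses 50 independent cohort draws with the complexity (c1) and
alpha node-strength features (the fast-entropy block is omitted there to
keep the draw loop lean; the single-cohort check covers it). The worked
example in the README uses a reduced 8 + 8 cohort.
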