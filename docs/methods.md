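# Methods

This note documents the statistical model behind `chemotrace`, the
defaults and why they were chosen, what the synthetic data generator does
and does not emulate, and the numerical conventions that a user comparing
against other chemometrics software should know about.

## Preprocessing: Savitzky–Golay first derivative

TXRF spectra of digested tissue carry two nuisance effects that are
unrelated to elemental composition: a smooth scatter background and a
sample-to-sample multiplicative gain (matrix effects on beam scattering).
The pipeline's normalisation is a Savitzky–Golay filter with window 3,
polynomial order 1 and first derivative, applied per channel index (unit
spacing). For this parameter set the convolution weights are the central
difference (−1/2, 0, +1/2); constants vanish exactly and a linear baseline
contributes only its constant slope. "First-order smoothing with first
derivative" is interpreted as polynomial order 1 *and* derivative order 1
— for a 3-point window this is the only order that admits a first
derivative with smoothing.

Conventions that had to be fixed (other software differs):

- **Edge policy.** The filter is evaluated only where the full window
  fits; the first and last (window−1)/2 channels replicate the nearest
  interior value, preserving the channel count (3025 in, 3025 out). The
  alternative (`edge="drop"`) removes edge channels. Replication avoids
  fabricating curvature at the boundary; with a 3-point window it affects
  2 of 3025 channels.
- **Derivative scale.** Per channel index, not per keV. PLS-DA is
  invariant to a common scale factor after centring, so only consistency
  matters.
- The filter is strictly per-sample, so it is applied once, before
  cross-validation; no information leaks across CV folds. Centring (and
  optional scaling), which pool across samples, are refit inside every
  fold.

## PLS-DA

Class membership is dummy-coded: Y[i, c] = 1 iff sample i belongs to
class c, with classes ordered lexicographically. X is column-centred; Y is
column-centred. Unit-variance scaling of X (`autoscale`) is available but
off by default: derivative spectra already share a common intensity scale,
and autoscaling would inflate noise-only channels. The flag is recorded in
every report.

Components are extracted by NIPALS PLS2 with deflation of both X and Y
(the classical algorithm): u initialised to the Y column of maximal
variance; w ∝ Xᵀu (unit norm); t = Xw; c = Yᵀt/tᵀt; u ← Yc/cᵀc, iterated
to a relative score change below 1e-10 (max 500 iterations; two-class
problems converge in one step analytically). After convergence
p_a = Xᵀt/tᵀt, X ← X − tp_aᵀ, Y ← Y − tc_aᵀ. Regression coefficients are
assembled as B = W(PᵀW)⁻¹Cᵀ so that Ŷ = X_c B + ȳ. If X or Y deflates to
numerical zero the extraction stops early with a recorded warning rather
than an error.

The default component count is A = k − 1 for k classes — the dimension of
the class-mean subspace, and the point where Q² typically peaks (the
component-scan operation reports the empirical Q² optimum alongside for
comparison). Class assignment is argmax of the predicted dummy response;
exact ties resolve to the lexicographically smallest label. Alternatives
(score-space centroid distance, probabilistic posteriors) are out of
scope.

## Validation

- **LOO-CV.** For each of the n samples the model is refit on the other
  n − 1 and applied to the held-out sample. The procedure is deterministic
  and invariant to sample order. A fold that loses an entire class (only
  possible when a class has a single sample) is evaluated with a recorded
  warning: the dummy coding keeps the full label space, the missing class
  simply contributes a zero column in that fold.
- **R² / Q².** R² = 1 − ‖Y − Ŷ_train‖²_F / ‖Y − Ȳ‖²_F on the dummy
  response (non-decreasing in A); Q² = 1 − PRESS/TSS with PRESS summed
  over held-out predictions. Q² is defined on the dummy response
  (chemometrics convention), not on classification accuracy, which is
  reported separately.
- **ROC-AUC.** One-vs-rest per class, using the held-out predicted dummy
  score of the target class. The curve sweeps all distinct thresholds;
  trapezoidal AUC equals U/(n₊n₋) with ties counted 1/2, and the code
  asserts that identity at run time. AUC significance is the two-sided
  Mann–Whitney (Wilcoxon rank-sum) test with normal approximation, tie
  and continuity correction (scipy implementation); when all scores are
  identical the p-value is defined as 1.
- **Metric arithmetic.** Per class c: TP = counts[c,c], FN/FP are the
  off-diagonal row/column sums, TN the remainder; precision TP/(TP+FP),
  sensitivity TP/(TP+FN), specificity TN/(TN+FP); overall accuracy
  trace/total. Ratios of the form 0/0 (e.g. precision of a never-assigned
  class) are reported as NaN with an explicit flag, never silently 0;
  macro averages skip undefined entries.

## VIP

VIP_j = √(p Σ_a SS_a w²_ja / Σ_a SS_a), SS_a = (cᵀ_a c_a)(tᵀ_a t_a). With
unit-norm weight columns, mean(VIP²) = 1 exactly — enforced as an
invariant. Several multi-response VIP generalisations exist; this
(explained-Y-variance weighted) form is the most widely used and the only
variant choice is logged in the result object. Selection uses strict
inequality VIP > 1. Cross-dataset intersection is exact set algebra over
selected channel indices, reporting the full Venn decomposition and each
count as a fraction of p. Channel indices are 0-based internally, 1-based
(with energies in keV) in exported tables. VIP is post-hoc interpretation
only; the pipeline does not refit on selected channels.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not TXRF physics. Sample i of class c is

    gain_i · [ baseline(E) + Σ_e conc_{i,e} Σ_l r_l G(E; E_l, σ(E_l)) ] + noise

- **Channel axis**: 3025 channels, uniform over 0–17.5 keV, covering the
  K lines of Na…Sr and the Pb L lines under Mo-anode excitation. (Real
  instrument ranges vary; only the channel count is matched to the
  motivating study design.)
- **Element lines**: tabulated Kα/Kβ (L for Pb) energies with fixed
  branching ratios; Gaussian profiles of width σ(E) = √(a + bE) with
  (a, b) = (0.0012, 0.0005) keV², ≈ 150 eV FWHM at 6 keV — a typical
  silicon-drift-detector resolution. A gallium internal-standard line is
  present at fixed concentration (as in real TXRF practice) but carries
  no class signal.
- **Concentrations**: class means are per-element fold changes of
  tissue-typical baseline counts (phase-shifted cosine pattern, strength
  0.5 by default so classes differ by up to ±50%); sample-to-sample
  variation is log-normal with CV 0.2 — concentrations are positive and
  right-skewed in tissue.
- **Gain**: per-sample log-normal, mean 1, CV 0.15 — the multiplicative
  scatter/matrix nuisance that makes the derivative step consequential.
- **Noise**: Poisson counting noise by default (counts are hundreds to
  thousands at peak maxima); Gaussian and noise-free options exist.
- **Baseline**: positive linear trend plus a broad Gaussian scatter hump
  near 16 keV, ≈ 10–50% of major peak heights.
- **Study layout**: the default study is five datasets ("species") with
  k ∈ {4, 5, 4, 4, 5} origin classes × 30 replicates, one class reduced
  to 19 replicates, totalling 649 samples — mirroring a realistic
  multi-species sampling campaign where one stratum is under-sampled.
- **Ground truth**: an element is discriminative when the relative range
  (max−min)/mean of its class-mean concentrations exceeds `min_effect`
  (default 0.05); the ground-truth channel set is every channel within
  ±3σ of any line of a discriminative element. This is the oracle against
  which VIP selection is scored.

The `recovery_design` used in the end-to-end recovery test is the same
model in a deliberately high-SNR regime (fold changes ±70%, concentration
CV 0.08, gain and noise at defaults): it defines what "strong
class-specific signal" means for the parameter-recovery claim (LOO
accuracy ≥ 95%, top VIP channels inside the ground-truth set).

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: absorption edges, detector escape/sum peaks
and Compton structure; correlated element concentrations (real provenance
signatures co-vary geochemically); non-multiplicative matrix effects;
instrument drift between acquisition batches; label noise in the sampling
metadata. Results on synthetic data demonstrate correctness of the
algorithms and calibration of the statistics, not field performance.

## Null calibration and test-scale choices

Three statistical facts surfaced while validating the pipeline and are
worth knowing:

- Under permuted labels, LOO accuracy is slightly *pessimistically*
  biased below 1/k (removing a sample shifts the training class balance
  against its own class); the bias shrinks roughly like 1/n. The
  null-calibration test therefore runs at the study scale (n = 120),
  where the mean over 50 permutation replicates lies within three
  standard errors of 1/k, and additionally asserts the one-sided
  property that matters — no spurious learning above chance.
- Permuting labels does not null the *feature variance*: channels of
  class-varying elements retain the between-class mixture variance. The
  VIP no-enrichment check therefore generates data with no class signal
  at all and uses a design of six exchangeable single-line elements with
  equal baselines, so that under the null every element is equally likely
  to be selected and the binomial reference proportion is exact (within
  the peak-channel universe).
- Q² under a pure-noise response is negative in expectation; the rank-2
  construction (class means spanning exactly two directions) shows the
  expected Q² peak at A = 2 with degradation beyond, while R² keeps
  rising — the behaviour that motivates the k − 1 component rule.

Problem sizes in the test suite and acceptance script were chosen as the
smallest that exercise the claims at study-like shape: the recovery and
null-calibration runs use the full 3025-channel / 120-sample layout or a
200-channel reduction of it; the five-species acceptance study runs at
full scale (649 × 3025).

## Known limitations

- NIPALS convergence is power-iteration-like; for nearly degenerate
  leading eigenvalues many iterations may be needed (capped at 500 with a
  recorded warning). Cross-checks against another PLS2 implementation
  require both solvers to be converged well beyond their defaults.
- Only LOO cross-validation is provided (adequate for the ~30-replicate
  class sizes the pipeline targets); k-fold/Monte-Carlo CV, permutation
  tests of overall model significance, and multi-class AUC
  generalisations are not implemented.
- The TSV dialect (tab-separated, header row of energies) is a package
  convention; vendor binary formats are out of scope.
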