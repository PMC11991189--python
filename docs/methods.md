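# Methods

## Pipeline

The package implements a three-stage decoding pipeline for two-class
motor imagery (left vs right hand):

1. **Preprocessing** — zero-phase band-pass 8–30 Hz, cue-locked window
   extraction (6.8 s windows starting 1.9 s before the cue), optional
   channel selection.
2. **Channel reconstruction** — per-channel elastic-net regression of
   all montage channels on the time-delay embedding of the 8 recorded
   central channels.
3. **Feature extraction and classification** — CSP log-variance
   features and a linear maximum-margin classifier, with a full metric
   battery (confusion matrix, accuracy, Cohen's κ, per-class
   precision/recall/F1/support).

Model fitting (regression coefficients, CSP filters, SVM weights) uses
the training split only; held-out trials pass exclusively through stored
transforms.

## Channel reconstruction model

Each trial contributes columns `[x_t ; x_{t+τ}]` (the 8 channels at time
`t` stacked over the same channels at `t+τ`) to a 16 × n(m−τ) regressor
matrix; targets are the 22 channel values at time `t`.  No column mixes
samples from two trials.  The delay τ defaults to 1 sample (4 ms at
250 Hz): one lag adds temporal context without desynchronizing the
regressors from the targets; τ is validated as a positive integer and
exposed in the configuration.

Coefficients minimize

    (1/2N)·RSS + α·ρ·‖β‖₁ + (α(1−ρ)/2)·‖β‖₂²

with defaults α = 1, ρ = 0.5, `max_iter` = 1000 sweeps, `tol` = 1e-8 on
the maximum per-sweep coefficient change.  Predictors and response are
centered before fitting and the intercept restored at prediction time,
so predictions come back in microvolts.  Predictors are deliberately
*not* rescaled to unit variance by default: the default penalty values
are meaningful relative to microvolt-scale EEG, and rescaling would
silently multiply the effective penalty by the data's standard
deviation.  Unit-variance scaling is available (`scale=True`) for
standardized-design use.

The solver is cyclic coordinate descent with soft-thresholding over the
fixed row order of the design, operating on precomputed Gram quantities
(`G = XXᵀ` is shared by all 22 per-channel fits, making the 22 fits
essentially free after one pass over the data).  Each fit is
warm-started at the closed-form minimizer of the smooth (ridge) part of
its objective; coordinate descent is monotone from any start, so this
changes only the convergence speed — important because the lag-0 and
lag-τ copies of a band-limited channel are nearly collinear and a
cold-started sweep sequence converges very slowly along the associated
flat directions.  Zero-variance regressor rows are left centered at zero
and receive coefficient 0.

The ridge estimator (`fit_ridge`) uses the unnormalized
residual-sum-of-squares convention `(XXᵀ + λ₂I)⁻¹Xy`; the elastic net
with ρ = 0 corresponds to `λ₂ = N·α`.  A singular system at λ₂ = 0
falls back to the pseudoinverse with a warning.

Reconstruction quality is reported as per-channel r² pooled over all
test trials and samples, both per channel (with the mean over channels)
and pooled over everything; the two summaries answer slightly different
questions (typical channel vs total variance captured) and both are
computed.  Channels with zero variance have undefined r² and are
reported as missing.

By default the classification stage consumes the *full reconstructed*
montage, i.e. even the 8 recorded channels are replaced by their
(near-identity) reconstructions; `keep_recorded_inputs` splices the
recorded central channels back in instead.  Replacing everything keeps
the test-time channel covariance structure homogeneous — all channels
are the same linear function class of the inputs.

## CSP

Class covariances average per-trial channel covariances, each
trace-normalized first (robustness to trial-to-trial amplitude
differences).  The generalized eigenproblem `Σ₁w = λ(Σ₁+Σ₂)w` is solved
by whitening the composite covariance and eigendecomposing the whitened
`Σ₁` — numerically stabler than a direct generalized solve and
guaranteeing `W(Σ₁+Σ₂)Wᵀ = I` with eigenvalues in [0, 1].  Filters are
sorted by eigenvalue descending and signs fixed so each filter's
largest-magnitude entry is positive (ties: lowest channel index),
making `W` fully deterministic.

**Rank-deficient data.** Reconstructed montages have rank at most 16
(the delay-embedded input dimension) in 22 channels, so the composite
covariance is singular.  Eigendirections with relative eigenvalue below
1e-10 are *dropped* and the problem is solved in the remaining signal
subspace (`W` becomes rank × N; patterns are the pseudoinverse
columns).  Shrinkage regularization was considered and rejected: it
resurrects null-space directions whose near-zero eigenvalues sort to the
bottom of the spectrum, so the low-variance extreme of the filter bank —
exactly the filters that should capture the second class — lands in the
null space and carries no class information.  If the retained rank
cannot supply `2·m_pairs` filters, fitting raises.

The binary pipeline keeps `m_pairs = 3` filter pairs (6 components).
Features are `f_q = log(var(s_q) / mean_i var(s_i))` over the selected
components; the ratio normalization makes features invariant to global
amplitude scaling and gives the exact identity `Σ_q exp(f_q) = 2m`,
asserted in tests.  Zero-variance projections are floored at the
smallest positive float with a warning.

A one-versus-rest extension (`fit_csp_ovr`) fits one model per class
against the pooled rest and keeps the top `m_top = 2` filters per class
(8 features for 4 classes); it is provided for multi-class feature
extraction, while the classifier itself is binary by design.

## Classifier

Linear soft-margin SVM trained in the dual by SMO-style pairwise
coordinate ascent: at each step the maximally-KKT-violating pair (ties
broken by lowest index) receives the analytic two-variable update,
until the violation falls below 1e-8.  The box constant C defaults to
1.0 — CSP features of noisy EEG are not guaranteed separable, and the
hard-margin formulation is recovered as C → ∞.  Dual feasibility
(Σaᵢyᵢ = 0, 0 ≤ aᵢ ≤ C, w = Σaᵢyᵢxᵢ) is exact by construction and
asserted in tests after every fit.  The bias is the mean of
`yᵢ − w·xᵢ` over free support vectors (midpoint of the KKT bounds if
none are free).  A decision value of exactly zero is assigned to the
positive class.  Class ids are encoded internally as
`sorted(ids)[0] → −1`, `sorted(ids)[1] → +1`.

Cohen's κ is computed from the confusion matrix as
`(p_o − p_e)/(1 − p_e)` with expected agreement from the row/column
marginals; degenerate marginals (`p_e = 1`) yield a missing κ rather
than a division by zero.  Per-class metrics go through scikit-learn's
implementations.

## Window extraction conventions

Windows are 0-based half-open sample ranges
`[cue + round(start_offset·fs), + round(duration·fs))`.  The duration
(6.8 s) and start offset (−1.9 s) fully determine the range; the end
offset (2 s) and nominal imagery duration (3 s) are carried as paradigm
metadata only, since duration + start offset + end offset
over-determine a single window.  Cues whose window exceeds the
recording bounds are dropped with a logged count.  Windows do not
overlap (overlap fraction 0).

When data arrive already epoched, band-pass filtering is applied per
epoch; the zero-phase filter's edge transients (a few tens of samples
at 250 Hz) are accepted and fall outside the imagery interval.

## Synthetic benchmark

The generator emulates exactly the structure the reconstruction method
assumes: band-limited sources, linear instantaneous mixing, lateralized
class-dependent ERD.

* 8 Gaussian sources band-passed to 8–30 Hz, std 10 µV, co-located with
  the 8 input electrodes; placing the sources at the recorded
  electrodes makes the reduced montage sufficient for reconstruction by
  construction, so the method's premise is literally true in the null
  model and failures are attributable to the implementation.
* Mixing by a Gaussian distance kernel (width 0.3 head-radius units) on
  the schematic 10-20 montage geometry; full column rank.
* Trials of 6.8 s at 250 Hz; imagery occupies the 3 s after the cue,
  i.e. samples [1.9 s, 4.9 s) of the window, matching the cue-locked
  window geometry above.
* ERD: class 1 (left hand) multiplies left-hemisphere sources by
  (1 − erd_depth) during imagery; class 2 the right-hemisphere ones.
  Default depth 0.5 (a strong but physiological modulation); midline
  sources are unmodulated.
* White Gaussian sensor noise at 10 dB per-channel SNR by default.
  `deterministic_map=True` requires `snr_db=None` and makes every
  channel an exact linear function of the 8 input channels, with the
  map `A·A_in⁻¹` available in closed form for recovery checks.
* Labels alternate deterministically; everything is reproducible from
  one integer seed.

Benchmark sizes were chosen to exercise the full pipeline in seconds:
100 trials/class for the noisy benchmark (study-scale trial counts),
10–20 trials/class for auxiliary checks.

**What the generator does not emulate** — and therefore what passing
tests do *not* establish about real EEG: 1/f background spectra, ocular
and muscular artifacts, inter-subject and inter-session variability,
volume-conduction nonstationarity, and sources away from the recorded
electrodes.  On real recordings the central subset is only
approximately sufficient, so reconstruction r² and classification
accuracy are substantially lower than the synthetic figures; the
synthetic benchmark validates the machinery, not the field performance.

## Numerical choices

* Butterworth order 4, applied forward–backward (effective order 8,
  zero phase); phase fidelity matters because CSP consumes covariances
  of the filtered signals.
* Coordinate-descent convergence: max per-sweep coefficient change
  < 1e-8 (default); hitting `max_iter` warns and returns the current
  iterate.
* CSP rank threshold: relative eigenvalue 1e-10 on the composite
  covariance.
* SMO stopping tolerance 1e-8 on the KKT violation; quadratic terms
  floored at 1e-12 for degenerate (duplicate-point) pairs.
* Container values are written with 17 significant digits and parsed
  with round-trip float precision, so write→read is bit-exact.
* Stratified 70/30 splits are delegated to scikit-learn's stratified
  splitter with a fixed seed, then index-sorted so downstream fits are
  order-stable.

## Known limitations

* The classifier is strictly binary; 4-class OVR feature extraction
  exists but no multi-class decision rule is built on it.
* No artifact rejection, re-referencing, or notch filtering; inputs are
  assumed cleaned.
* A GDF/EDF reader is out of scope; the adapter surface is a function
  returning a `Recording`.
* The single 8–30 Hz band is fixed per run; no filter-bank variant.
* Hyperparameter search is not automated: α, ρ, τ, m_pairs and C are
  configuration values with the defaults above.
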