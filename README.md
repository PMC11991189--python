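# eegrecon

Reduced-electrode motor-imagery brain–computer interfacing: reconstruct a
full 22-channel EEG montage from 8 central electrodes, then classify
left- vs right-hand motor imagery from the reconstruction.

## The problem

Motor-imagery (MI) BCIs decode imagined hand movements from the
event-related desynchronization (ERD) of sensorimotor mu/beta rhythms
(8–30 Hz).  Dense montages (22+ electrodes) classify well but are slow to
set up, costly, and fragile; sparse montages are practical but discard
spatial information that spatial-pattern feature extraction needs.
`eegrecon` implements a middle path: record only 8 central electrodes
(C3, C1, Cz, C2, C4, CP1, CPz, CP2) over sensorimotor cortex and
*predict* the remaining montage channels with a regression model, so the
downstream spatial-filtering pipeline still sees a full montage.

## The method

**Channel reconstruction.** Each montage channel `y` is regressed on the
time-delay embedding of the 8 recorded channels: with `n` trials of `m`
samples and delay τ (default 1 sample), the regressors are the 2u = 16
rows `[x_t ; x_{t+τ}]` concatenated over trials (a 2u × n(m−τ) matrix).
Coefficients minimize the elastic-net objective

    (1/2N) Σ (y_i − x_i β)²  +  α ρ ‖β‖₁  +  (α(1−ρ)/2) ‖β‖₂² ,

with α = 1, ρ = 0.5 by default, solved by cyclic coordinate descent with
soft-thresholding (warm-started at the ridge closed form).  The ℓ2 term
stabilizes the heavily correlated EEG regressors; the ℓ1 term prunes
uninformative delayed copies.  Reconstruction quality is scored per
channel as r² = 1 − SSE/SST.

**Features and classification.** Signals are band-passed 8–30 Hz
(zero-phase 4th-order Butterworth), and Common Spatial Patterns are fit
on the training split: generalized eigenvectors of
`Σ₁ w = λ (Σ₁ + Σ₂) w`, with the 3 top and 3 bottom filters retained
(6 components).  Per trial, features are normalized log-variances
`f_q = log( var(s_q) / mean_i var(s_i) )` of the projected components.
A linear soft-margin SVM (deterministic SMO on the dual, box constant
C = 1) separates the two classes.  Reports include the confusion matrix,
accuracy, Cohen's κ, and per-class precision/recall/F1/support.

**Synthetic benchmark.** Because the pipeline's behaviour depends on
lateralized band-limited structure, the package ships a generator of
MI-like EEG: 8 mu/beta-band sources co-located with the input
electrodes, mixed into 22 channels by a distance-based leadfield, with
class-dependent lateralized ERD and configurable sensor SNR.  Ground
truth (the exact input→montage linear map in the noise-free case) is
known, so reconstruction and classification are testable end to end.

## Worked example

```python
from eegrecon import RunConfig, SynthConfig, compare_modes, generate

epochs = generate(SynthConfig(seed=42))        # 200 trials, 22 ch, 250 Hz
results, table = compare_modes(RunConfig(seed=42), epochs=epochs)
print(table)
print("mean reconstruction r2:",
      round(results["predicted_channel"].r2.mean, 4))
```

prints

```
                mode  Accuracy %  Kappa
0       full_channel       100.0    1.0
1  predicted_channel       100.0    1.0
2        few_channel       100.0    1.0
mean reconstruction r2: 0.9708
```

All three modes share the same 70/30 stratified split.  `full_channel`
is the dense-montage baseline, `few_channel` uses only the 8 recorded
electrodes, and `predicted_channel` replaces the montage with its
elastic-net reconstruction.  At the default benchmark (10 dB SNR, ERD
depth 0.5) reconstruction recovers ~97 % of held-out channel variance
and the reconstructed montage classifies as well as the recorded one —
the mechanism the method relies on, demonstrated at synthetic scale.

The same pipeline is scriptable from the shell:

```sh
eegrecon simulate --out sim.txt --seed 42
eegrecon compare --input sim.txt --seed 42 --out outdir
```

Real recordings can be supplied in the package's plain-text epoch
container (see `eegrecon.containers`); an adapter from GDF/EDF need only
produce a `Recording` (channels × samples plus cue events) and feed
`extract_windows`.

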