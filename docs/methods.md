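# Methods

`fallseg` implements a pre-impact fall-detection analysis for slipping-like
perturbations delivered during steady walking. The pipeline takes per-trial
whole-body segment kinematics, ranks body segments by how much of the signal's
independent structure they carry, classifies every time sample as walking or
perturbation with a small neural network under a nested leave-one-out
cross-validation, and scores detection latency and reliability per segment
combination. This note documents the model, the defaults, and the design
choices that were genuinely open.

## Data model

A *trial* is a 6-s window around a labelled perturbation onset, sampled at
100 Hz: 500 samples of walking phase (WP) followed by 100 samples of
perturbation phase (PP), 600 in all. The signal is the 3-D linear
acceleration of the centres of mass (CoM) of 15 body segments — head/neck,
chest, pelvis, and bilateral upper arms, forearms, hands, thighs, shanks,
feet — resolved in the global frame: 45 channels. A subject contributes 20
trials (2 sessions × 10 perturbation types). The ten types combine five belt
directions (N, N-diagonal, pure transversal, S-diagonal, S) with the
perturbed foot (left/right); paired codes such as NL/NR share a direction.

When only marker endpoints are available, segment CoM positions are located
along the proximal→distal axis at de Leva's adjusted anthropometric fractions
(overridable table) and accelerations are obtained by the three-point central
second difference, `a[t] = (p[t+1] − 2p[t] + p[t−1])·fs²`. The two boundary
samples replicate their nearest interior value so the 600-sample label
alignment is preserved; the alternative (dropping endpoints) would desynchronise
windows and labels. No smoothing is applied before differentiation by
default; a Butterworth pre-filter can be added by the caller but is not part
of the pipeline.

## Synthetic subjects

No motion-capture recordings ship with the package; the generator in
`fallseg.synth` produces trial sets with the statistical structure the
analysis assumes:

* **Walking**: each channel is a sum of two harmonics at the step cadence
  (default 1.8 Hz) and its double, with per-subject random phases and
  segment-specific amplitudes, larger distally (feet 2.5 m/s² base amplitude
  down to 0.5 m/s² for the head). Walking speed follows from a Froude number
  of 0.15 (`v = √(0.15·g·L)`, ≈1.10 m/s at leg length 0.822 m), the speed
  normalisation used for treadmill perturbation studies.
* **Perturbation response**: an exponentially damped oscillation (peak
  8 m/s² × per-segment gain, τ = 0.25 s, 6 Hz) starting at the onset plus a
  per-segment mechanical-chain lag — feet 0 ms, shanks/thighs 30 ms,
  pelvis/trunk/head 60 ms, arms/forearms/hands 80 ms. Default gains are
  largest in the distal extremities (feet 1.6, hands 1.3, trunk ≈0.4). The
  longitudinal/transversal components carry the belt-direction sign pattern;
  the vertical component carries the perturbed-side sign and is non-zero at
  the onset for every direction. The response is linear in the gain, so
  effect sizes are controlled exactly.
* **Noise**: i.i.d. Gaussian per channel, default SD 0.3 m/s².

All randomness flows from a subject master seed (per-trial noise seeds are
master ⊕ trial index), so trial sets are bit-reproducible. No published
quantitative description of per-segment perturbation amplitudes exists to
calibrate against; the gains above are free parameters chosen once as
physiologically plausible. What the generator deliberately omits: ground
contact events, inter-channel correlation structure of real gait,
non-stationarity, habituation across trials, and marker/soft-tissue artefact.
Tests passing on this surrogate therefore demonstrate that the *pipeline*
behaves as specified (separability → detection, information concentrated in
a segment → high rank), not that real falls are detected at any particular
rate.

## Segment ranking (ICA1)

The 20 trials concatenate into the dataset `M` (45 × 12000). The retained
component count `N` is the smallest PCA dimensionality explaining ≥95 % of
the variance of mean-centred `M` (threshold configurable; capped at the
numerical rank). Unmixing is FastICA with the log-cosh contrast and
deflation, run from 5 seeded restarts; the converged restart with the highest
log-cosh negentropy proxy is kept, making the fit deterministic given a seed.

The **Total Segment Weight** (TSW) of segment *s* is the cumulative absolute
loading of its three channels on the retained components, with each
component's mixing column first scaled to unit norm so no component dominates
by scale, normalised to percentages:

    TSW_s = 100 · Σ_i Σ_{c∈s} |Ã_{c,i}| / Σ_i Σ_c |Ã_{c,i}|,   Ã_{·,i} = A_{·,i}/‖A_{·,i}‖.

TSW is exactly invariant to component permutation and sign (the ICA
indeterminacies). The uniform (unweighted-by-component) cumulative rule is a
declared choice; weighting components by variance or negentropy would be an
alternative. The mixing matrix, not the unmixing matrix, is used because its
columns express how strongly each component appears *in* each channel. Ties
in the ranking break by canonical anatomical order. Subset selection is
bilateral: a lateral segment pulls in its contralateral partner (sensor
placement cannot anticipate the perturbed side); midline segments stand
alone.

## Classification (ICA2 + network)

For each outer fold, a fresh ICA (same algorithm) is fitted on the 19
training trials only and its time-invariant unmixing projects both training
and test trials into component space. The full-body combination uses the `N`
from the ranking stage; reduced subsets keep all 3 × (number of segments)
dimensions, since information reduction already happened by dropping
segments.

The classifier is a feed-forward network: `N` inputs → 80 tanh hidden units
(default) → 2 tanh outputs, one per class with one-hot ±1 targets
(W = (+1, −1), P = (−1, +1)). Training minimises full-batch MSE with
resilient backpropagation using the canonical constants η⁺ = 1.2, η⁻ = 0.5,
Δ₀ = 0.07, Δmax = 50, Δmin = 10⁻⁶. The implemented variant is iRprop⁻: on a
gradient-sign flip the step size shrinks and the gradient memory is zeroed,
so that coordinate skips one update (no weight backtracking). Weights
initialise uniform(−0.5, 0.5)/√fan-in from a derived seed. Early stopping is
best-validation-epoch checkpointing: validation MSE on the held-out inner
trial is evaluated every epoch and the weights of the minimising epoch are
returned; training stops after 25 epochs without improvement or at the epoch
cap (500 by default). Because gradients are full-batch, results are invariant
to sample order and bit-reproducible given the seed. The output encoding,
loss, cap and initialisation are declared choices — they are standard
companions of Rprop with tanh layers and make the 0.5 decoding threshold
natural.

## Detection and scoring

Each test-trial sample decodes to W, P or NA: the arg-max output unit's class
if its activity reaches 0.5, NA otherwise or on an exact tie. A perturbation
is detected when 5 consecutive samples are P (NA breaks a run); each maximal
run of ≥5 P samples registers one detection at its 5th sample. A run
straddling the onset is attributed to the phase containing that 5th sample —
either attribution would be defensible for this edge case, so one convention
is fixed, documented, and held constant across all comparisons. Per classified trial, the walking phase scores
FP/TN and the perturbation phase TP/FN; for a TP, the detection time is
measured from the onset to the end of the registering sample,
`DT = (index − onset + 1)/fs`, using the first post-onset detection only.

Aggregation over the 20 × 19 = 380 fold instances of a subject gives
Sensitivity = TP/(TP+FN), Specificity = TN/(TN+FP), and Accuracy as balanced
accuracy, (Sensitivity+Specificity)/2, the natural summary when the two
phases are scored separately. MDT is the mean ± sample SD (ddof = 1) of the TP
detection times. Zero-denominator metrics are reported as undefined (`None`),
never silently 0.

## Cross-validation structure

Outer loop: each of the 20 trials is held out once as the test set; ICA2 and
all training happen on the remaining 19. Inner loop: each of those 19 is held
out once for early stopping while the other 18 train the network. The test
trial therefore never influences ICA2 or training — asserted structurally in
the tests by zeroing the test trial and checking bit-identical trained
weights. The ranking stage is deliberately fit on all 20 trials: it models a
sensor-placement decision taken before the classifier is evaluated, not part
of the classifier itself. Per-fold seeds derive from the master seed and the
fold indices, so outer folds are independent and a serial rerun is
bit-identical.

## Statistics

Detection times per subject × perturbation type feed two analyses: a paired
t-test of each reduced combination against the full-body baseline (pairing by
subject × type; an all-zero difference vector is reported as t = 0, p = 1
rather than NaN), and per combination a two-way fixed-effects ANOVA of MDT on
direction (5 levels) and side (2 levels), main effects only (no
interaction), the usual model when each subject × type cell holds a single
averaged detection time. Missing cells (a type with no true
positives) raise an error naming them. Significance is flagged at p < 0.05.

## Problem sizes in the shipped checks

The default test suite and the acceptance script exercise the pipeline at
reduced size — one synthetic subject, 20 hidden units, a 100-epoch cap —
which the early-stopping rule usually undercuts by half. These sizes were
chosen as the smallest at which the end-to-end behaviour (detection within a
few samples of the transient onset, monotone MDT in the transient latency,
sensitivity/specificity above 0.9 at high SNR) is stable across seeds. The
synthetic MDT is a few tens of milliseconds: an idealised transient with
zero-lag foot response is detectable at the rule's floor (5 samples), unlike
a human recovery response, so synthetic MDT values are not comparable to
experimental ones — only their ordering and the classification rates are
meaningful.

## Known limitations

* The synthetic generator is a phenomenological surrogate, not a
  biomechanical simulation; absolute performance numbers on it do not
  transfer to real data.
* The ICA restart objective uses a one-point negentropy approximation;
  genuinely sub-Gaussian sources would need a different contrast.
* The pipeline is offline by design: ICA projection and classification are
  applied to complete recorded windows, not streamed.
* Local segment frames and angular kinematics are out of scope; only global
  linear CoM acceleration is modelled.
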