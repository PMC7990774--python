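# Methods

## The recombination model

A motor-imagery trial is a matrix `x ∈ R^{C×T}` of C channels by T samples
with a class label (which hand was imagined).  The working assumption is
that if `x_i` and `x_j` are trials of the same class, the composite trial
taking its right-hemisphere channel rows from `x_i` and its left-hemisphere
rows from `x_j` is again a draw from that class's distribution.  This holds
exactly when the two hemisphere channel blocks are conditionally independent
given the class, and approximately when inter-hemispheric coupling is weak
relative to within-hemisphere signal.  Real EEG violates it to some degree
(volume conduction, midline sources, bilateral networks); the synthetic
generator below satisfies it by construction, which is precisely why it can
serve as a positive control.

Per class with `n` trials the full recombination product has `n²` elements,
of which `n` are identity pairs `(i, i)` that reproduce the originals
bit-exactly.  We keep identity pairs in the output (the product read
literally), so "augmented set" already contains the originals and no
separate concatenation is needed; a subsampling cap (`max_pairs_per_class`)
always retains all identity pairs and draws the remainder uniformly without
replacement, seeded.  Generated trials are ordered by (class, right index,
left index) for determinism, and every trial carries a provenance record
`(method, right (subject, trial), left (subject, trial), label,
is_original)`.

The cross-subject variant pools the halves of all subjects except the
target `s` and takes the per-class product over the pooled halves — the
union over ordered source pairs `(i, j)`, `i ≠ s`, `j ≠ s`, with `i = j`
allowed (a flag restricts to `i ≠ j`).  By construction no hemisphere block
of any output trial originates from the target, making the result a valid
pre-training set for subject-adaptive training.

## Hemisphere assignment

10-20 labels encode laterality in the terminal character: odd digit left,
even digit right, `z` midline.  Midline electrodes are assigned alternately
— in montage order, the 1st, 3rd, 5th… midline channel goes left and the
2nd, 4th… right — which splits `m` midline channels `⌈m/2⌉ / ⌊m/2⌋`.  An
override table (label → side) replaces the automatic rule when a specific
published assignment must be reproduced.  Recombined trials are returned in
the original montage channel order (rows scattered back to their indices),
not as a stacked [R; L] block, so spatially structured classifiers see a
consistent layout.  Extended 10-5 names with `h` suffixes are out of scope;
labels with no terminal digit or `z` raise an error rather than guessing.

## Comparison augmenters

**Time flipping** appends the time-reversal of every trial: exact doubling,
label-preserving, and spectrum-magnitude-preserving (reversal conjugates
the DFT).  **Noise addition** appends copies with white Gaussian noise
rescaled per trial so that `var(trial)/var(noise)` equals the configured
SNR *exactly* (default 5, interpreted as a linear power ratio; a dB mode is
available).  Per-trial enforcement makes the SNR a testable post-condition
rather than an expectation.  Version 1 adds one copy per original (ratio 2,
matching flipping); version 2 draws source trials uniformly with
replacement until a caller-set target size — conventionally the matching
recombination output size — is reached.

## CSP baseline

Common spatial patterns maximize the variance ratio
`J(w) = w'C₁w / w'C₂w` of the two class covariances.  Since `J` is
invariant to rescaling of `w`, the constraint `w'C₂w = 1` pins the
maximizer, and the stationary points solve `C₁w = λC₂w`.  We solve the
symmetric-definite generalized eigenproblem directly
(`scipy.linalg.eigh`), take the eigenvectors of the k = 3 largest
eigenvalues as class-1 filters, and solve the swapped problem `(C₂, C₁)`
for the class-2 filters (equivalent to the smallest eigenvalues of the
original problem, but normalized `w'C₁w = 1` in their own denominator
metric).  The largest-magnitude entry of each filter is made positive to
fix the sign indeterminacy.

Class covariances default to the per-trial trace-normalized average
(`mean(XX'/tr(XX'))`), robust to inter-trial amplitude drift; the pooled
form (`ΣXX'`) is retained as an option for literal fidelity to the
textbook derivation.  A ridge `reg·(tr(C)/C)·I` with `reg = 1e-6` is added
to the denominator matrix before inversion to guard rank deficiency at
small trial counts.  Features are `log(var(w_f'x) / Σ_g var(w_g'x))` — log
normalized variance, the field-standard choice (the feature map is not
dictated by the CSP derivation itself); they are invariant to global
amplitude scaling.  The reference classifier is an RBF-SVM with unit cost
on the 2k features; all baseline claims are expressed as properties
(separability, chance level under permutation, recovery on synthetic data)
rather than dataset-specific accuracies.

Correctness of the eigen route is checked against an independent
cross-entropy Monte-Carlo maximizer of the Rayleigh quotient (10⁵ sampled
directions with elite-reweighted Gaussian proposals, no eigendecomposition
anywhere): on random SPD pairs at C = 6 the two agree in `J(w)` to well
below 10⁻³.

## Evaluation schemas

**IS (intra-subject):** per (subject, training-set size, repeat), a
class-balanced subset is drawn without replacement from the subject's
training pool with a generator spawned from the master seed and the cell's
coordinates (`SeedSequence(seed, spawn_key=(subject, size, repeat))`), the
configured augmenter is applied to the subset only, a fresh classifier is
fitted, and accuracy is measured on the subject's untouched test set.
Augmentation is re-applied per repeat (fresh subset ⇒ fresh product).

**AS (adaptive-subject):** stage 1 trains from scratch on the cross-subject
augmented set built from equal-size subsets of every other subject
(recombination uses the multi-subject variant; flipping and noise operate
on the mixed source pool, noise v2 resampling with replacement up to the
matching recombination size); stage 2 continues training — warm start — on
the target's own augmented subset; scoring is on the target's held-out
set.  A classifier that cannot warm-start is rejected with an error naming
the contract gap.  For the closed-form CSP baseline, warm start is defined
as pooling the stage-1 class covariances with the stage-2 estimates
weighted by trial counts before re-solving, and refitting the SVM on the
fine-tuning features; this carries spatial information across stages while
keeping the estimator deterministic.  A skip-pretrain flag makes an AS run
reduce exactly to the IS run with the same seeds.

Every run returns tidy records `(subject, schema, augmenter, size, repeat,
accuracy)` — one per cell, so `|records| = subjects × sizes × repeats` —
plus an audit trail of the (subject, trial) ids that fed augmentation and
the test ids of each cell; `assert_no_leakage()` verifies the intersection
is empty.  The per-subject summary accuracy is the grand mean over all
sizes and repeats.  Significance between two augmenters is assessed with a
classical paired t-test on per-subject means (n−1 degrees of freedom);
zero-variance differences raise an error instead of returning a silent
p-value.  Defaults are sizes 10–100 in steps of 10 with 10 repeats.  The
pluggable deep-classifier contract carries the conventional training
configuration (60 epochs, batch 16, Adam with lr 0.001, β₁ 0.9, β₂ 0.999,
no validation split) for user-supplied network backends; the shipped
baseline is the CSP-SVM.

## Preprocessing

Band-pass filtering uses a Butterworth design (bilinear transform with
prewarping, so the −3 dB points sit exactly at the cut-offs; default
[8, 30] Hz, order 5, realized in second-order sections for stability) and
is applied causally in a single pass by default — the effective order is
the design order — with a zero-phase forward-backward option behind a
flag.  Filtering continuous data then epoching is the default order; the
reverse is supported and differs only through edge transients.  Epoching
converts marker times by `sample = round(seconds × fs)` and cuts half-open
windows `[round(start·fs), round(end·fs))`, so a (0, 2.5) s window at
100 Hz is exactly 250 samples regardless of marker position.

## Synthetic generator

Each trial is `A (g_L τ_L s_L(t) + g_R τ_R s_R(t) + ε(t))` where `s_L, s_R`
are independent unit-variance band-limited Gaussian noises (default
8–12 Hz — stochastic phase and waveform, per-trial variance fixed at one),
`τ` are fixed topographies over each hemisphere's lateral channels peaking
at C3/C4 (weight 1.0 at the central electrodes, 0.7 at FC/CP sites, 0.25
elsewhere, zero on midline and the opposite hemisphere), `ε` is white
channel noise (sd 0.5 by default), and `A` is a per-subject mixing matrix
`I + N(0, 0.05)` *block-diagonal within each hemisphere* (midline rows
identity).  Class 0 ("left hand") multiplies the right-hemisphere source
amplitude by `1 − erd_depth` (default 0.6), class 1 the left — contralateral
ERD.  Defaults: 14 channels (12 lateral + Fz, Pz), 100 Hz, 2.5 s, 100
trials per class, balanced labels in seeded random order.

Because the sources and the background noise are hemisphere-separable and
the mixing never couples hemispheres, the left and right channel blocks are
exactly conditionally independent given the class — recombined trials are
true draws from the class-conditional distribution.  This is the point of
the generator and also its deliberate unrealism: real EEG has
inter-hemispheric coupling, 1/f spectra, artifacts, and nonstationarity,
none of which are modelled.  Passing tests on this generator therefore
validate the machinery and the method's internal logic (cardinalities,
fidelity, leakage, recovery of planted structure), not the augmenter's
benefit on real recordings.  Cohorts share topographies; subjects differ in
their mixing matrix and noise, with per-subject seeds spawned
deterministically from the master seed.

## Numerical and design choices

* Seeds: every stochastic step takes an explicit seed or derives one via
  `numpy.random.SeedSequence` spawning; identical seeds give bit-identical
  outputs (asserted in tests).
* Container payloads are float32 on disk (EEG dynamic range); round trips
  are bit-exact at that precision.  Writes are atomic (temp file + rename),
  so failed commands leave no partial outputs.
* Degenerate inputs fail loudly: empty montages or classes, zero-variance
  trials (covariance and SNR are undefined), windows outside the recording
  (the offending marker is named), k > C/2, non-PSD covariance inputs,
  single-class training sets, zero-variance paired differences.
* Tie-breaks: eigenvalue sorting is stable; midline alternation starts
  LEFT; recombination output order is (class, right, left).
* Problem sizes in the test-suite and the reproduction script (trial
  counts, sweep sizes, Monte-Carlo budgets) are chosen to exercise every
  code path at desk scale; the schemas' defaults (sizes 10–100, 10
  repeats) remain available for larger studies.

## Known limitations

* Two-class only (one-vs-rest CSP, filter-bank CSP and Riemannian variants
  are out of scope).
* The hemispheric split is binary; no 3-D electrode geometry, interpolation
  or re-referencing.
* The deep-classifier plug-in is a contract, not a shipped network; the
  reference decoder is the CSP-SVM.
* The generator's hemisphere independence makes it a best case for
  recombination; benefits measured on it do not transfer quantitatively to
  real EEG.
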