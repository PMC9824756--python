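# Methods

## Signal model and scope

The pipeline assumes emotion-related information in EEG is carried by
band-power structure that is stable enough within a trial to show up as
texture in a time–frequency image.  Each channel is treated independently
up to the final encoding stage; spatial structure across the scalp enters
only through the bag-of-words histogram that aggregates the per-channel
feature vectors of a trial.  Trials must be at least 2 s long (the data
model enforces this) so a spectrogram has more than one usable frame at the
default 1 s window.

## Preprocessing

* **Filter.**  Order-4 Butterworth band-pass, 4–45 Hz, applied
  forward–backward with reflect padding.  Zero-phase application squares
  the magnitude response — the analytic contract is ≥ 40 dB attenuation at
  1 Hz and ≤ 1 dB deviation at 25 Hz for `f_s = 200` Hz — and introduces no
  group delay, which keeps spectrogram timing aligned with the raw signal.
  The order and phase handling are package choices; only the 4–45 Hz band
  is fixed by the method.  Artifact removal beyond the band-pass (ICA,
  regression) is out of scope.
* **Channel selection** is configuration: an explicit channel-name list per
  dataset preset, applied by label so stored channel order is irrelevant.
  A variance-ranking helper exists for exploration but is not a canonical
  selection rule (no principled criterion for "which 32 of 64 electrodes"
  exists in this method family; presets mirror dataset-native layouts).

## Spectrogram

Frames of `L` samples (default `round(f_s)`, i.e. 1 s) with hop `L/2`;
frame `m` starts at `m·hop`; the frame count is `floor((n − L)/hop) + 1`.
The full-`L` DFT of the windowed frame gives `S(m,k)`; the amplitude
`A = |S|²/L` makes the per-frame Parseval identity `Σ_k A(m,k) = Σ_i
E_w(i)²` hold to rounding (relative error < 1e−9, asserted for Hann,
Hamming, Gaussian and rectangular windows).  Window shape defaults to
Hamming; all framing parameters are configurable.

Rendering: optional dB compression `10·log10(A + 1e−12)`, per-image
min–max normalisation (a constant matrix renders as uniform mid-gray, by
definition), frequency increasing upward, bilinear resize with half-pixel-
center coordinate mapping to 224×224.  Only passband rows (4–45 Hz) are
rendered by default: after filtering, out-of-band rows are numerical noise
floor and would consume most of the image's dynamic range under min–max
normalisation.  Both the crop and the log compression can be switched off.
The grayscale plane in [0, 1] is the texture-descriptor input, with no
8-bit requantisation; the deep backend receives the grayscale replicated
to three channels (or a matplotlib colormap if configured).

## OMTLBP_SMC texture descriptor

Sampling geometry (P = 8, radii {1, 2, 3}): angles are measured
counter-clockwise from the +column axis; sub-pixel positions are bilinearly
interpolated.  Orientation fans at radius 2 (5 sub-samples, 22.5° apart)
and radius 3 (7 sub-samples, 15° apart) start one octant before the fan's
nominal 45°·k direction, so adjacent fans share sub-samples — the
"overlapped multi-oriented fusion".  Radius 1 samples the exact unit circle
(diagonals interpolated at radius 1.0); a `grid` mode snaps diagonals to
the integer 8-neighborhood for users who prefer the classic LBP lattice.

Scale fusion produces three structures: `U1 = P¹` (unfused — the only
well-defined reading for the innermost scale), `U2 = (P¹+P²)/2`,
`U3 = (P²+P³)/2`.  Per structure and pixel, the LDSMT decomposes
`Q = U − C` into signs (zero counts as positive) and magnitudes; the riu2
encoder maps each 8-bit pattern to its set-bit count when it has at most
two circular 0↔1 transitions, else to the catch-all code 9.  The magnitude
threshold `ρ_m` is the structure's mean magnitude over the whole image
(image-level rather than per-patch, following the established
sign/magnitude/center LBP convention, so codes are comparable across
pixels); the center bit thresholds at the global image mean `ρ_I`.

Histogram layout: per structure a 10×10×2 joint histogram flattened with
the sign code slowest, then magnitude, then center; structures concatenate
in order 1, 2, 3 → 600 values.  Every interior pixel (stride 1, 3-pixel
border) contributes once per structure, so the unnormalised mass is
3 × interior-pixel count; the descriptor is L1-normalised by default.

Numerical choice: all values entering a threshold comparison are quantised
at 1e−12 before comparing.  Interpolation weights do not sum to exactly 1
in floating point, so without this a constant image would produce
arbitrary sign patterns from ~1e−16 residues; with it, numerically
constant neighbourhoods encode as exact equality (code triple (8, 8, 1)).
The vectorised implementation is asserted bit-for-bit identical to an
independent pixel-by-pixel reference on random images.

## Deep backend

The backend contract is: 3-channel image in, fixed-length vector out,
deterministic, inference-only.  The canonical backend is an
ImageNet-pretrained GoogLeNet's final 1000-way fully-connected layer,
pre-softmax by default (richer dynamic range; softmax available as an
option), with the weights' published mean/std preprocessing.  It is an
optional install; without torch it raises an explicit error naming the
alternative.

The `mock` backend is a deterministic seeded Gaussian random projection
used for all tests and the synthetic study.  It average-pools each channel
to 28×28 before projecting: pooling keeps the matrix at 2352×1000 (a
full-resolution projection would be ~1.2 GB) while preserving sensitivity
to single-pixel changes, and a linear map of the spectrogram image retains
exactly the band-layout information the synthetic classes differ in.  It
is a stand-in for a trained network's features, not an emulation of them:
passing tests show the pipeline machinery is sound, not that mock features
match CNN features on real EEG.

## Vocabulary and encoding

Raw 1600-vectors are z-scored per dimension from training data only
(constant dimensions get unit scale); without this the deep and texture
halves, whose scales differ by orders of magnitude, would make Euclidean
distances meaningless.  K-means runs independently within each class
(k = 8 words per class by default, the value at which this method family
peaks; a global-clustering mode exists for comparison).  The in-package
Lloyd implementation uses greedy farthest-point seeding from a seeded RNG,
relative centroid-movement threshold 1e−6, cap 300 iterations, and records
the per-iteration objective so its monotone non-increase is testable;
scikit-learn's KMeans serves as an independent cross-check in the tests,
never as the implementation.

Encoding assigns each standardized channel vector to its nearest word
(lowest index on ties) and accumulates counts over the trial's channels;
counts are L1-normalised by default (both modes exposed).  Classifiers:
inverse-distance-weighted KNN (10 neighbours, Euclidean) by default, RBF
and cubic-polynomial SVMs as alternatives; KNN vote ties resolve to the
lowest class index.

## Evaluation protocol

Canonical: stratified 5-fold cross-validation in which the scaler,
vocabulary and classifier are re-fitted inside every fold from that fold's
training trials only — a fold-audit test asserts the vocabulary never sees
test trials.  A stratified 70/30 holdout is provided as a secondary mode
(the two protocols are reported explicitly and never mixed).  Reports
carry per-fold accuracies, their mean, the summed confusion matrix and the
full configuration.

## Synthetic study conditions

The generator emulates class-conditional band power: per class one or more
oscillation bands, realised per channel as a sinusoid with random in-band
frequency, random phase, and a 0.1–0.5 Hz raised-cosine burst envelope,
over a 1/f^α Gaussian noise floor (α = 1, frequency-domain shaping) —
amplitude-modulated sinusoids rather than filtered noise because their
band power has a closed-form oracle.  Band "relative power" is the
un-modulated oscillation power over the total noise power (default 6).
Optional 50 Hz line noise and 0.3 Hz drift exercise the filter.  Defaults:
3 classes (alpha 8–13 Hz, beta 18–25 Hz, low-gamma 32–42 Hz), 8 channels,
200 Hz, 10 s, 30 trials per class — small enough for fast full-pipeline
runs while exercising multi-channel encoding; a DEAP-like preset
(32 channels, 128 Hz, 63 s, 2 classes) mirrors the benchmark geometry.
Everything derives from a single `SeedSequence`, so datasets are pure
functions of (spec, trials_per_class).

What passing means: with well-separated bands the classes are nearly
noiseless in feature space, so perfect cross-validated accuracy verifies
the chain end to end (parameter recovery), while the label-permutation
control pins the null at chance.  Real EEG has overlapping spectra,
non-stationarity, inter-subject variability and correlated channels; the
synthetic study makes no claim about accuracy under those conditions.

## Known limitations

* No physiological realism in the generator (no volume conduction, no real
  artifact morphology) and no event/stimulus handling.
* The DEAP/SEED `.mat` adapters follow the published layouts but are
  untested against the gated downloads; rating-to-class binning must be
  made explicit in configuration.
* Only P = 8 and radii {1, 2, 3} are implemented for the texture operator.
* The texture descriptor's cost is linear in image pixels (~0.3 s per
  224×224 image single-threaded), dominating extraction time.
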