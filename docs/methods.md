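# Methods

## Problem and model

Road hypnosis is a trance-like driving state in which the driver keeps an
apparently normal posture and trajectory while perception and reaction are
degraded.  The package treats its identification as latent-state decoding:
an unobserved two-state first-order Markov chain S_t ∈ {normal, hypnosis}
evolves at the fused observation rate (1 Hz by default) and emits a
multimodal feature vector o_t assembled from EEG band power, smoothed
eye-tracking channels, and vehicle kinematics.

Classical HMMs specify a generative emission density b_j(o_t) per state.
Here the emissions are *discriminative*: for each state j a gradient-boosted
tree ensemble is trained one-vs-rest to regress the 0/1 indicator of state j
under squared error (plus the trees' L2 leaf penalty), its raw score is
mapped to a probability by Platt scaling, the calibrated per-state scores
are renormalised into posteriors p(S_j | o_t), and decoding uses the scaled
likelihood

    b̂_j(o_t) = p(S_j | o_t) / p(S_j),

the standard bridge from a classifier to the forward/Viterbi recursions:
dividing by the training prior makes the quantity proportional to the true
likelihood p(o_t | S_j), and per-step proportionality constants change
neither the filtered posteriors nor the Viterbi argmax (the total
log-likelihood shifts by a data-independent constant; the suite asserts this
invariance).  Transitions and the initial distribution are estimated
supervised from labelled sequences with additive smoothing κ (default 1),
which keeps minority-state rows away from zero.

The "actual observed probability" that the boosted regressors target is not
an observable quantity; the 0/1 state indicator is the only consistent
regression target for a per-state scorer that is subsequently calibrated,
and that is what is implemented.  Platt sigmoids are fitted on *out-of-fold*
raw scores (internal stratified 3-fold) with Platt's smoothed targets, so
the calibrator never sees the over-confident in-sample scores of a boosted
ensemble.

A separate linear readout maps a standardized feature row to a continuous
hypnosis degree: fourteen coefficient slots, of which ten carry the named
features (speed; the five EEG bands; gaze velocity; both pupil diameters;
inter-pupillary distance) and four are reserved padding with coefficient 0.
The shipped default weights are the published regression coefficients
(intercept 0.471); a refit mode re-estimates them by least squares on the
training rows.  Which of the two a deployment should prefer is genuinely
open; the printed weights are the default because they are reproducible
without data.

## Feature extraction

**EEG** (default 500 Hz, 4 channels — the rates of the non-eye streams are
configuration, since only the eye tracker's 100 Hz is fixed by the hardware
table): drop configured channels → common-average reference → ideal
band-pass via an FFT brick-wall mask on [0.5, 40] Hz (applied symmetrically
to ± frequencies; idempotent by construction) → sliding-window Welch PSD
(0.5 s windows; segment length defaults to the whole window; Hann taper;
non-overlapping segments) → band power as the Riemann sum of the PSD over
bins whose centre lies in [f1, f2), for δ 0.5–4, θ 4–8, α 8–12, β 12–30,
γ 30–40 Hz → mean across retained channels (per-channel output available).
PSD scaling is the density convention P = |X|²·2/(fs·Σw²), the only scaling
under which band powers integrate to signal variance (the suite checks
Parseval on a unit tone and exact equality with the raw periodogram for one
rectangular segment).  A one-sample window step is supported; the pipeline
default is 0.1 s, which is indistinguishable after 1 Hz alignment and an
order of magnitude cheaper.

**Eye tracking** (100 Hz): invalid/outlier repair (validity flag,
physiological pupil range 1.5–9 mm, 5× scaled-MAD rule; interior runs
linearly interpolated, edge runs held) → windowed-sinc FIR low-pass
(fc 8 Hz, M = 101) → FIR high-pass by spectral inversion (fc 0.1 Hz,
M = 201) → 20-sample trailing moving average.  Filters are Hamming-tapered,
odd-order, hence exactly linear-phase; the (M−1)/2 group delay is
compensated and edges are reflection-padded.  The ideal low-pass impulse
response is the standard windowed sinc, sin(2π(fc/fs)(k−M/2))/(π(k−M/2))
with centre tap 2fc/fs.  The drift high-pass is applied to all eye channels.
The outlier rule and pupil range are implementation choices; no published
values exist for them.

**LLE.**  A locally-linear-embedding of the joint smoothed eye state is
available (off by default; the named channels are the default fusion set):
K-nearest neighbours (K = 12), constrained least-squares reconstruction
weights with trace-scaled Tikhonov regularization 1e−3, embedding from the
bottom eigenvectors of (I−W)ᵀ(I−W).  Standard LLE weights are asymmetric; a
symmetrized variant (W+Wᵀ)/2 is available behind a flag but conflicts with
the row-sum constraint and is not the default.  Two numerical points:
(i) the trivial constant mode is removed by shifting it above the spectrum
with a rank-one update rather than by discarding the first eigenvector,
because on degenerate inputs the dense eigensolver returns an arbitrary
basis of the near-null space that mixes the constant into every vector;
(ii) exactly collinear, *irregularly spaced* points are an ill-conditioned
input — the non-trivial eigenvalues collapse toward zero and ordering
recovery fails for any standard LLE implementation (scikit-learn's included,
verified in the cross-check test); evenly spaced degenerate inputs are
recovered exactly.

**Vehicle** (10 Hz): sliding means of speed and acceleration (window 5 s,
step 1 s — chosen to resolve state dynamics at the 1 Hz fusion grid),
population-variance speed std, and point-by-point jerk (forward
difference).  Speed may be ingested in km/h with conversion at read time.

**Fusion.**  Each feature stream is averaged onto a uniform 1 Hz grid over
a 1 s half-open window [t, t+T); rows with any empty window are dropped and
counted.  Columns are z-scored with *population* moments estimated on the
training rows only and serialized with the model.  Rows are labelled from
the annotated intervals (half-open; unlabelled time is normal driving), and
class counts are logged — the hypnosis class is expected to be the minority
and is never rebalanced; imbalance is handled by the model itself.

## Synthetic data

The generator emulates the statistical structure the decoder assumes, not
the biophysics of any sensor.  Defaults (the package's study conditions):
26 sessions of 300 s — a deliberately scaled-down stand-in for
commute-length sessions that keeps every stage exercisable — latent chain at
1 Hz with A = [[0.95, 0.05], [0.10, 0.90]] (hypnosis occupancy 1/3,
minority), sessions starting in normal driving.  Per state: EEG is a sum of
five band-limited unit-variance Gaussian components amplitude-modulated per
1 s step by state-dependent standard deviations (hypnosis: δ, θ ×1.5,
β ×0.6 — the β-band effect is the designed dominant feature); pupil
diameters are state-level means with AR(1) fluctuations (φ = 0.95, damped
in hypnosis); gaze velocity is a rectified Gaussian with a lower hypnotic
mean; IPD is near-constant; speed is AR(1) around a state mean with damped
hypnotic variability, and acceleration is its exact finite difference.
Band components are filtered over the whole record and then modulated —
equivalent band structure to per-block filtering, without boundary
artifacts.  Dropouts are injected into the eye stream at rate 0.01 to
exercise cleaning.  Effect directions are drowsiness-plausible configuration
values, not claims about real data; tests reference the generator's
config, never real-data feature rankings.

What passing tests therefore show: the pipeline recovers the latent
structure *it assumes* — Markov switching, variance-coded EEG states,
damped-fluctuation eye states.  What they cannot show: robustness to
artifacts (ocular/EMG contamination, sensor drift beyond AR(1)), to
non-Markov state dynamics, to label noise from manual annotation, or
real-world effect directions and sizes.

## Evaluation and interpretation

Six regression metrics (MSE, RMSE, MAE, maximum error, R², explained
variance; population variances; R²/EV flagged undefined when Var(y) = 0)
score the continuous readout; classification accuracy is the fraction of
grid rows whose Viterbi state equals the label, with a segment-level
variant (majority vote per maximal constant-label segment) reported
alongside, since either level can be the quantity of interest.
Cross-validation folds are whole recordings (sessions), shuffled once by
seed and split into K near-equal groups — row-level shuffling would leak
temporally adjacent rows of one session across the train/validation
boundary of a sequence model.  The headline number is the *mean* of the
per-fold accuracies.

Interpretation delegates to the boosted trees themselves: total gain /
total cover / split frequency aggregated over all trees of both per-state
scorers; exact tree-path Shapley attributions via the ensemble's native
`pred_contribs` (additivity base + Σ contributions = raw output is asserted
to 1e−6); a hand-rolled local surrogate (Gaussian perturbations, distance-
kernel weights, weighted least squares) whose recovery of a genuinely
linear model is the contract; L1-penalized selection via coordinate-descent
lasso paths with CV; and recursive feature elimination dropping the
lowest-importance feature per round.

## Numerical choices

- Decoding in scaled/log space; emission floor 1e−12; Viterbi ties break to
  the lower state index; log-likelihood = Σ log c_t.
- Boosted-tree defaults: 200 trees, depth 4, learning rate 0.1, L2 weight
  1.0, single-threaded, fixed seed (no published hyperparameters exist;
  these are conventional mid-size settings).
- Transition smoothing κ = 1; population moments everywhere (matching the
  windowed-std convention); half-open intervals and 0-based sample
  indexing throughout; synchronization is crop-to-overlap only, so raw
  samples stay bit-faithful.
- The band-pass low edge defaults to 0.5 Hz (the δ-band floor); the
  documented alternative 0.2 Hz is a parameter.

## Known limitations

Supervised training only (no Baum–Welch); two states by default though N is
configurable; the degree readout's provenance (HMM fit vs. separate
regression) is ambiguous in the source, so both modes exist; synthetic
validation cannot certify real-data performance (see above); LLE is
ill-conditioned on exactly degenerate irregular inputs; EDF ingest requires
the optional `mne` dependency.
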