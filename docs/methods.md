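# Methods

## The measurement problem

Whether acute stress leaves a readable trace in everyday computer-mouse
kinematics is an open question in behavioral psychophysiology.  The
canonical study design compares a high-stress and a low-stress group of
participants who each perform the same set of goal-directed mouse tasks
twice — a baseline (practice) run and an application run after the
stress manipulation — so that every kinematic outcome can be analysed as
a condition × stage interaction on top of strong practice and
individual-difference effects.  This package implements that analysis
chain end to end: event-based pointer-log ingestion, preprocessing,
seventeen kinematic features, trajectory imaging, the frequentist stage
(2×2 mixed ANOVAs with partial η²), and the machine-learning stage
(five-fold cross-validated classifiers/regressors with label-permutation
significance tests).  Because raw cohorts of this kind are rarely
published, a synthetic cohort generator with the same statistical
structure drives all tests and examples.

## Data model and preprocessing

Pointer logs are event-based: a record is created whenever the browser
reports a positional change or a button press, so sampling is
client-dependent (20–200 Hz, median near 60 Hz).  Events carry integer
millisecond timestamps and integer pixel coordinates (origin top-left).

Preprocessing follows three steps:

1. **Artifact removal.**  Among consecutive move events, the later
   member of any pair sharing a timestamp or sharing both coordinates is
   dropped, applied left-to-right so a run collapses to its first
   element.  Click events are exempt.  The operation is idempotent.
2. **Duration-outlier exclusion.**  Within each stage of a task, the
   median task duration is computed once; participants strictly above
   three times that median are removed from the task (both stages, to
   keep difference-score designs balanced).  Automated session
   validation (timestamp order, screen bounds, trial counts) replaces
   manual visual inspection for reproducibility.
3. **Uniform resampling.**  The surviving move stream is linearly
   interpolated onto a 15 ms grid from the first to the last move
   timestamp; a trailing partial interval is dropped rather than
   extrapolated.  Stationary periods are smeared linearly, by design —
   no idle-time reconstruction is attempted.

## Kinematic features

Seventeen features in three blocks; 16 apply to the point-and-click and
drag-and-drop tasks, 13 to the slider, 14 to the pursuit task.
Inapplicable features are absent from a session's vector, never
zero-filled.

* **Temporal:** task time; working time (from the work-start marker —
  the first click for the click tasks, the first sample inside the
  pursuit circle otherwise); mean and SD of sample-to-sample speed
  (px/s); mean and SD of positive and of negative speed change (px/s²),
  an empty sign class scoring 0 to keep the table rectangular.
* **Spatial:** total path length; mean and SD of the absolute turning
  angle between consecutive movement vectors (arccos of the normalized
  dot product, degrees in [0, 180], zero-length segments skipped);
  directional changes per axis (sign changes of the nonzero coordinate
  deltas).
* **Task-specific:** total/mean/SD of the perpendicular distance of
  every trial sample to the infinite line through the trial's start and
  end positions, pooled across trials (point-and-click trials span
  click *k* → click *k*+1, the first trial starting at the first move
  event; drag trials span a press to the release of a successful drop);
  and the pursuit in-circle ratio, time inside the moving circle over
  time outside it, the denominator floored at one sample interval so
  perfect pursuit stays finite.

All SDs are population (n) SDs, chosen for internal consistency and so
the brute-force test oracle is unambiguous.  Signed-angle and
per-trial-averaged variants were deliberately not used.

## Trajectory images

For the image-based analysis route, raw (non-interpolated) events are
rendered as a scatter on a white 224×224 canvas whose axes map the
participant's screen.  Move events take colors from the perceptually
ordered purple→yellow viridis gradient at relative sequence position
i/(n−1) — the first event is always RGB (68, 1, 84) and the last always
(253, 231, 37) — and click events are black, drawn on top.  Baseline
inclusion is realised by stacking the application image above the
baseline image.  Canvas size, dot radius (2 px) and the colormap are
configuration-pinned conventions.  The imaging module guarantees
deterministic, byte-identical PNGs; any downstream convolutional
classifier is out of scope.

## Frequentist stage

Each feature (and each self-report measure, as the manipulation check)
is analysed with a 2×2 mixed ANOVA: condition (between) × stage
(within).  With two within-levels the design reduces exactly to
difference scores d = application − baseline and participant means m:

* interaction — two-sample test on d (its F is exactly the squared
  pooled t, an identity that holds for unbalanced groups and is asserted
  to 1e−10 in the tests);
* stage — test of the overall mean of d;
* condition — two-sample test on m.

Partial η² is SS_effect/(SS_effect + SS_error) with the error stratum of
the effect.  The closed form agrees with pingouin's general
implementation to ~1e−13, which the test suite uses as an independent
oracle.  Per-task Bonferroni thresholds follow the feature counts:
.0031, .0031, .0038, .0036 (reported rounded to 4 decimals).  Post-hoc
comparisons are unadjusted two-sided pooled-variance t-tests with
Hedges' g (J = 1 − 3/(4·df − 1)).  Power uses the fixed-effects
noncentral-F formulation, λ = N·η²/(1−η²); at N = 994, η² = .015 it
gives .82 at α = .0031 and .97 at α = .05.  No sphericity correction is
needed for a two-level within factor.

## Machine-learning stage

Six specifications per task and target: {L2 logistic regression
(liblinear, C = 1.0) | RBF-SVM (C = 1.0, γ = 1/(n_features × variance of
the flattened feature matrix)) | random forest (50 trees, no depth
limit)} × {application-only features | application − baseline difference
scores}; the regression targets swap in OLS, the SVR and the forest
regressor.  No hyperparameter tuning, by design.  Features are
median/IQR-scaled (linear-interpolation quantiles; zero-IQR columns
centered only); by default the scaler is fit within each training fold —
the leakage-free reading — with whole-matrix scaling available behind a
flag for replication of pipelines that scaled up front.

Scores are mean five-fold (stratified, seeded-shuffle) CV accuracy or
R².  Significance comes from 500 refits on permuted labels with
re-partitioned folds per permutation; the true model must strictly beat
the permuted score (ties count against it) at least 475/500 times for
p < .05 and 496/500 for the six-model Bonferroni level .0083
(thresholds are ceil((1−α)·n_perm) for other permutation counts).
Regression models whose CV R² does not exceed the mean-predictor null
(R² = 0 on its own training data) skip the permutation test.

## Synthetic cohort generator

The generator emulates the study conditions rather than any particular
recorded cohort.

* **Movements** are minimum-jerk submovements with Fitts'-law durations
  MT = a + b·log₂(D/W + 1) (defaults a = 0.15 s, b = 0.15 s/bit, typical
  of mouse pointing), sampled at the participant's client rate with ±20%
  inter-sample jitter, plus signal-dependent lateral noise — Gaussian
  with SD = γ·(instantaneous speed), γ = 0.008 px per px/s — the
  standard neuromotor-noise baseline.  Terminal speed is zero, so the
  noiseless path ends exactly on target.  With probability 0.3 the
  movement lands slightly off target (offset scale tied to γ) and one
  corrective submovement finishes the trial.
* **Tasks** reproduce the four geometries: 17 click circles, 12
  center→corner drags with press/release events and a 5% reset-on-miss,
  12 horizontal slider trials, and one 25 s circular pursuit (path
  radius 150 px, circle radius 30 px, one revolution).  Pursuit tracking
  error is a smooth AR(1) process (φ = 0.95, stationary SD 14 px) plus a
  80–150 ms per-participant lag.  One fixed trial layout per task is
  shared by all participants, stages and conditions, mirroring the study
  design's identical-task constraint.
* **Sampling rates** mix a 0.4 point mass at 60 Hz (display-refresh
  clustering) with a log-uniform draw over [20, 200]; the empirical
  median over large cohorts sits in [50, 70] Hz.
* **Effects** are multiplicative on movement tempo: a practice gain of
  1.05 at the application stage; optional condition×stage gains on speed
  and noise for high-stress application sessions.  Both stress gains
  default to 1.0 — the null configuration — because the frequentist and
  ML stages are meant to be exercised under realistic no-effect
  conditions; nonzero values are opt-in exercise parameters.
* **Self-reports** (per-task SAM valence/arousal, twelve mood items,
  stress and nostalgia items, all 0–4) are participant intercept + stage
  shift + condition×stage shift + Gaussian noise (SD 0.8), clipped to
  the scale.  The interaction shift is calibrated in closed form from
  the balanced difference-score design, δ = 2√2·σ·√(η²/(1−η²)), with
  η² = .015 by default; the calibration is exact at the design point and
  recovery is verified at ±.005 over repeated cohorts.  The nostalgia
  item receives no condition effect (specificity control).

What the generator does **not** model: the stressor task itself,
fatigue or drift within a session, left-handed asymmetries, pixel
quantization beyond integer rounding, hardware-specific acceleration
curves, or pauses from off-task behavior.  Passing tests therefore
demonstrate that the pipeline recovers structure it is supposed to
recover and stays calibrated under a realistic null — not that any
particular real cohort would show (or hide) a stress effect.

## Numerical conventions and test sizes

Timestamps are integer milliseconds; grid interpolation uses float
positions.  Quantiles use linear interpolation.  Angle computations
clip cosines to [−1, 1]; degenerate (zero-length) vectors are skipped,
and a trajectory with no valid angle raises.  Random streams derive
from a single master seed via spawned seed sequences, making cohorts
byte-identical across reruns.

The statistical property checks run at deliberately modest problem
sizes chosen once: permutation calibration pools 160 null tests (20
cohorts × 8 label redraws, 200 permutations each); injected-effect
recovery uses 20 cohorts of 400 participants on the point-and-click
task; the separability probe uses 100 participants.  The permutation
calibration band [.03, .07] is evaluated against a Monte-Carlo estimate
whose own standard error is ≈.015, so the check is informative but
coarse; the tie-against-the-model convention makes the test slightly
conservative by construction.

## Known limitations

* The mixed ANOVA is specialised to the 2×2 design; more levels would
  need the general decomposition (pingouin covers that case).
* The in-circle ratio is unbounded under perfect pursuit (denominator
  floor); robust scaling absorbs this downstream, but the feature is
  heavy-tailed by construction.
* Difference-score designs silently drop participants missing a
  baseline (with a logged warning), which can unbalance conditions in
  extreme cases.
* The image route guarantees only the encoder; no claim is made about
  any particular downstream classifier's accuracy.
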