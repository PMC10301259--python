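# Methods

## Scope and data model

`tripgait` models trip-outcome risk (no fall / L-fall / E-fall) from
regular-gait kinematics. Two input levels are supported: marker-level
records (frames × markers × 3D positions at 120 Hz; x anterior, y
vertical, z mediolateral, metres) and feature-level tables (n rows × 40
named gait features plus an `outcome` label). The original cohort data
are not available, so both levels are backed by synthetic generators
whose parameters are the study conditions themselves (cohort size 298
split 192/84/22; demographics age 69.6 ± 6.33 y, weight 75.2 ± 17.2 kg,
height 1.67 ± 0.10 m, 128 M / 170 F).

## The 40-feature canon

The published protocol counts 40 features but does not itemise them; its
enumeration (speeds, COM state, durations, step length, toe clearance,
trunk/hip/knee/foot angles at gait events, swing-phase extrema) pins down
about 30. We fix a canonical, symmetric set of exactly 40:

* 5 speeds (average and maximum COM speed over the cycle; instantaneous
  anteroposterior COM velocity at pre-TD, LO, post-TD);
* COM position relative to the posterior BOS and MOS at each of the
  three events (6);
* swing time, step time, step length, toe clearance, gait cycle time (5);
* trunk angle at LO and post-TD and maximum trunk flexion over the
  cycle (3);
* hip, knee and foot angles for both limbs at each of the three events
  (18);
* perturbed-limb swing extrema of hip flexion, knee flexion and foot
  angle (3).

This is a superset of every named quantity in the protocol and of all 20
features with published class summaries. Angle conventions: horizontal
reference via atan2 in the sagittal plane; a vertical trunk is 90°, a
fully extended knee 180°, a flat foot 0°. "Maximum trunk flexion" and
"maximum knee flexion" are the *minima* of the respective angle signals
(flexing lowers both on this convention), reported as the angle attained
at peak flexion — this matches the published scales (≈86° trunk, ≈119°
knee). Toe clearance is the swing-phase maximum of the perturbed toe
height above its own stance-level baseline, which makes it invariant to
where the lab origin sits.

Two points the protocol leaves open are resolved as follows and exposed
nowhere else: "maximum gait speed" uses the anteroposterior COM velocity
component (not the 3D magnitude), and the trunk segment runs from the
bilateral shoulder midpoint to the bilateral hip midpoint.

## Margin of stability

The printed MOS formula divides the COM velocity by g/l, which has units
of 1/s² · m⁻¹ — dimensionally inconsistent with a length. We implement
the extrapolated-COM form the protocol cites (Hof): the velocity is
divided by the inverted-pendulum eigenfrequency √(g/l), giving a margin
in metres. BOS_min is the rear heel marker's x coordinate at the
evaluated instant. Leg length defaults to the mean hip-midpoint height
above the lowest heel sample and can be overridden on the `BodyModel`.

## Body model

COM kinematics use a 13-segment rigid-body model with de Leva-style,
sex-dependent mass and COM-location fractions (head, torso, pelvis and
bilateral upper arm, forearm+hand, thigh, shank, foot). The required
marker set carries no head or arm markers, so those segments are
anchored to the shoulder–hip line; during level walking the arms hang
near the trunk, so the approximation mainly smooths the COM trajectory
and leaves cycle-average speed untouched (every marker advances exactly
one stride per cycle). Velocity is by central differences at the
sampling rate.

## Gait events

The protocol's events came from force plates, which are out of scope; we
detect them from kinematics. Each signal's "grounded band" is the lowest
`clearance_fraction` (default 10%) of its vertical range; touchdowns are
the starts of sufficiently long grounded runs of the heel, liftoffs the
ends of grounded runs of the toe, both refined to the frame nearest the
linearly interpolated band crossing (this keeps time-based features
stable under resampling to within <1%). Runs shorter than
`min_contact_s` (default 0.1 s) are rejected as jitter. A record in
which either limb yields no usable cycle raises an error naming the
limb. Frames are 0-based and event intervals are closed at both ends.

## Synthetic cohort generator

Feature tables are drawn from class-conditional Gaussians. Only marginal
means ± SDs are published for the 20 top-ranked features, so the default
correlation is identity per class, with an optional user-supplied
per-class correlation matrix (symmetric PSD enforced; sampling uses a
Cholesky factor with an eigenvalue-clipped fallback for singular PSD
inputs). Class counts are exact (192/84/22), not multinomially sampled.
Gaussian marginals are an assumption: the published summaries say
nothing about skew, and the smallest class (n = 22) makes its SDs noisy
estimates — distributional-recovery tests should be read accordingly.

The other 20 canonical features carry no published class summaries; they
are given realistic class-independent marginals (documented in
`synthetic.py`), which makes them uninformative by construction — a
deliberate mirror of the fact that they were not among the top-ranked
half. Demographics are likewise sampled independently of outcome,
mirroring the finding that no demographic survived feature selection.

Because the published marginals overlap heavily between classes, a
pipeline trained on the default cohort cannot — and should not — reach
the real-data accuracies; marginal-only sampling discards whatever
between-feature covariance drove the original separability. The
`separation_boost` parameter scales between-class mean differences about
the count-weighted grand mean; boost 3 creates a separable regime used
by the recovery tests (macro AUC > 0.95 for the 20-feature model,
chance-level AUC after label permutation). Passing those tests shows the
pipeline recovers signal it is given, not that real gait data are this
separable.

## Synthetic gait trials

The marker-level generator builds a planar (sagittal-dominant) periodic
walker: a pelvis advancing at constant speed with a sinusoidal vertical
bob (minima at touchdowns) and small mediolateral sway; feet that roll
through a heel rocker (landing dorsiflexed +15°, pitching flat about the
planted heel), a flat phase, a push-off (plantarflexing to −25° about
the planted toe) and a swing whose toe advances on a raised-cosine
profile and rises as sin(πτ); knees placed by two-link inverse
kinematics between hip and ankle (anterior solution, reach clamped). The
swing phase occupies a fixed 38% of the gait cycle. Ground truth is
exact by construction: average gait speed (periodicity makes the COM
advance exactly one stride per cycle), step time and cadence, step
length (heels land on the footfall grid), maximum toe clearance (the
sine apex equals the configured value), and trunk angle (constant
90° − lean). Step length must satisfy step_length = gait_speed·60/cadence;
an inconsistent triple is rejected rather than silently reconciled.
Marker noise is isotropic Gaussian jitter added after construction.

What the generator does *not* emulate: trip perturbations and recovery
responses, arm swing, soft-tissue artefact, marker dropout, asymmetric
or pathological gait, and realistic joint-angle waveforms beyond the
event-level scale (e.g. mid-stance knee flexion is exaggerated relative
to real gait because the pelvis height profile is a single sinusoid).
Round-trip tests therefore validate the *extraction pipeline's*
correctness, not the realism of any biomechanical simulation.

## ReliefF

Multiclass ReliefF with k = 10 neighbours by default (configurable), all
instances used, Manhattan distance on range-normalised features,
prior-weighted misses per contrasting class. When a class has ≤ k
members the neighbour count truncates to what exists (with a warning)
and the update divides by the actual count. Constant features contribute
zero. Final ordering breaks weight ties by input column order, so
rankings are reproducible. The implementation is checked exactly against
a brute-force enumerating oracle on small tables. The neighbour count,
metric and no-subsampling choices are not pinned down by the protocol;
they follow the algorithm's standard formulation and are exposed as
parameters. Top-50% selection rounds half up (40 → 20, 3 → 2).

## Ensemble and elimination

The classifier is a bagged ensemble of Gini decision trees: each of
`n_learning_cycles` trees grows on a bootstrap resample (n draws with
replacement) with all features available at every split, constrained by
`max_num_splits` (a tree with s splits has s + 1 leaves) and
`min_leaf_size` = 5. Posteriors are across-tree means of leaf class
frequencies. scikit-learn's `RandomForestClassifier` with
`max_features=None` provides exactly this. Class imbalance is left as-is
— no resampling or class weights; the optimal-cutoff analysis is the
imbalance mitigation.

Hyperparameters (`n_learning_cycles` ∈ [10, 500], `max_num_splits` ∈
[1, n−1], both log-uniform) are tuned by seeded random search, budget 30
draws by default, scored by inner 3-fold stratified log-loss. Random
search replaces Bayesian optimisation deliberately: identical search
space, reproducible under a single seed, and at 30 draws the difference
on a 298-row problem is within fold noise.

Backward elimination starts from the 20 selected features: train, score
impurity importance, drop the lowest (ties drop the feature ranked lower
in the ReliefF order), repeat to a single feature — 20 nested models.
During elimination the hyperparameter search runs once, on the full
starting subset, and is reused: elimination consumes only the importance
*ranking*, which is insensitive to the exact tree count, and re-searching
at every size would multiply cost for no change in the dropped-feature
sequence in practice. A `per_subset` mode re-searches at every size.

## Evaluation protocol

Five-fold stratified cross-validation repeated 10 times gives 50
train/test splits (fold class proportions within one row of the global
proportions). Per split and subset: fit on the training fold, score the
test fold, compute one-vs-rest ROC per class (trapezoidal AUC) and
record the macro AUC over classes present in that fold. The model series
is evaluated at problem size 298 × ≤20 features with, by default, one
budget-30 hyperparameter search on the largest subset shared across the
series (`tune_mode="once"`); `per_subset` and fully honest `per_fold`
re-tuning are available where the extra cost is justified.

The printed optimal-cutoff criterion ("maximum of TPR + FNR") is
degenerate because TPR + FNR ≡ 1; we implement the standard reading,
Youden's J = TPR − FPR (= TPR + TNR − 1), with ties resolved toward the
lower threshold (higher sensitivity). Cutoffs are estimated per class on
the *training* split and applied to the test split by default — the
honest protocol; `cutoff_mode="test"` pools the test scores instead, for
comparison with descriptions that do not separate the two.

Assigning a class from per-class scalar cutoffs needs a rule the
protocol does not state: a row goes to the class whose posterior clears
its cutoff; with several (or no) claimants the largest margin
(posterior − cutoff) wins, exact ties going to the earlier class in the
class order. At cutoffs of 0.5 this reduces to argmax whenever any
posterior exceeds 0.5.

Per-class accuracy is the true-positive rate; overall accuracy is
computed per fold and averaged across the 50 splits (prevalence-weighted
recombination of per-class rates is provided separately as
`overall_accuracy` and agrees with per-fold averaging up to rounding —
on published accuracy rows the two differ by ≤0.1 percentage points).
One-way ANOVA compares the 20 AUC distributions (explicit
sum-of-squares decomposition; degenerate inputs defined: zero
between-group variance → F = 0, zero within-group variance → F = ∞);
post-hoc paired t-tests compare model pairs on per-split AUC differences,
uncorrected by default with a Bonferroni option. Best model: maximum
mean AUC (ties → fewer features); optimal model: fewest features with
mean AUC > 0.95 × maximum.

## Feature selection placement

Ranking, selection and elimination run once on the full table, *outside*
the CV loop, as the protocol's description orders the steps. This leaks
selection information into the test folds and will flatter absolute
AUCs; it is retained as the default because the nested series and its
reporting tables require a single global feature order. Readers
comparing against fully nested protocols should re-run with selection
inside the loop (the building blocks — `relieff_rank`,
`build_nested_models`, `evaluate_subset` — compose per fold) and expect
lower AUCs.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through
`numpy.random.SeedSequence` spawns (generator, fold shuffling, search
draws, tree seeds), so a rerun with the same config is bit-identical;
every output artefact embeds the seed and a config hash. Ties anywhere
(ranking weights, importances, cutoffs, class assignment) break
deterministically by prior ordering. Default problem sizes — 298 rows,
40-feature pool, 20 nested models, 50 splits, budget-30 search — run in
a few minutes on one CPU; the recovery tests use the same sizes.

## Known limitations

* Marginal-only cohort sampling cannot reproduce real between-feature
  covariance; absolute accuracies on unboosted synthetic data are not
  comparable to real-data results.
* The gait generator is a kinematic caricature: correct at the contract
  quantities, stylised elsewhere.
* Event detection assumes reasonably clean vertical heel/toe signals;
  heavy occlusion or non-periodic gait defeats it.
* E-fall (n = 22) statistics are fragile at study scale: per-fold TPRs
  for a class with 4–5 test members are coarse by necessity.
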