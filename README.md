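# tripgait

Trip-related falls are a leading cause of injury in older adults, and the
way someone walks *before* a trip carries information about whether they
would fall if tripped. `tripgait` is a reusable, tested implementation of
a fall-risk modelling pipeline for gait-lab researchers and biomechanists:
it turns regular-walking motion-capture kinematics into 40 spatiotemporal
and angular gait features, ranks them, trains classifier families over
nested feature subsets, and evaluates how well they separate three trip
outcomes — **no fall**, **fall with lowering strategy (L-fall)** and
**fall with elevating strategy (E-fall)**.

## What it computes

For one gait cycle bounded by two touchdowns of the unperturbed (right)
foot, enclosing the perturbed (left) foot's liftoff (LO) and touchdown
(post-TD), the package extracts:

* **Gait speeds** from the whole-body centre of mass (COM), computed with
  a 13-segment, sex-dependent anthropometric model: average and maximum
  over the cycle plus instantaneous anteroposterior COM velocity at the
  three events.
* **COM state**: COM position relative to the posterior base of support
  (rear heel) and the margin of stability in Hof's extrapolated-COM form

  MOS = (COM − BOS_min) + v_COM / √(g / l)

  with g gravity and l leg length, at each event.
* **Spatiotemporal measures**: swing time, step time, gait cycle time,
  step length, toe clearance.
* **Sagittal segment angles** against the horizontal, Θ = atan2(Δy, Δx):
  trunk (shoulder–hip), hip (hip–knee), foot (toe–heel) and the composed
  knee angle Θknee = atan2(knee_y − ankle_y, knee_x − ankle_x) + (180 − Θhip),
  evaluated at the three events for both limbs, plus swing-phase extrema
  for the perturbed limb and the cycle's peak trunk flexion.

Modelling follows a fixed protocol: multiclass **ReliefF** ranks the
feature pool and the top 50% are selected; a **bagged decision-tree
ensemble** (Gini trees, minimum leaf size 5, tuned tree count and split
cap) is trained and its impurity-based predictor importance drives
backward elimination, one feature at a time, producing 20 nested models;
each model is assessed over **5-fold stratified cross-validation repeated
10 times** (50 test sets) with one-vs-rest ROC curves, macro AUC, and
per-class accuracy at the default 0.5 cutoff and at the **Youden-optimal
cutoff** (maximising TPR − FPR). A one-way ANOVA and post-hoc paired
t-tests compare the models' AUC distributions; the *best* model maximises
mean AUC and the *optimal* model is the smallest one whose mean AUC
exceeds 95% of that maximum.

Because the original motion-capture cohort is not public, the package
ships a synthetic-data module that (a) draws labelled feature tables from
the published class-conditional means ± SDs (192 / 84 / 22 subjects by
class) and (b) synthesises planar marker-level walking trials with known
ground truth, so every stage is testable end to end.

## Worked example

```bash
tripgait simulate-gait --gait-speed 1.2 --cadence 120 --seed 2 --out trial.csv
tripgait extract --markers trial.csv --out features.csv
```

`features.csv` holds one row with the 40 named features; for this trial
the extractor reports (abridged):

```
Gait speed in gait cycle   1.200000   # m/s, equals the configured speed
Step time                  0.500000   # s, cadence 120 steps/min
Toe clearance              0.159985   # m, max perturbed-toe rise in swing
Trunk angle at LO         87.000000   # deg, 90 - 3 deg forward lean
MOS at LO                  0.805921   # m, extrapolated-COM margin
```

A full modelling run on a simulated cohort:

```bash
tripgait run-all --seed 1 --out-dir run1
```

prints

```json
{
  "best_model_features": 7,
  "optimal_model_features": 4,
  "n_models": 20,
  "n_auc_samples_per_model": 50,
  "config_hash": "..."
}
```

meaning twenty nested models were each evaluated on 50 cross-validation
test sets; the 7-feature model had the highest mean AUC (0.863) and the
4-feature model was the smallest within 95% of it. `run1/` contains the
per-cutoff accuracy tables, the AUC long table, the ReliefF ranking, the
elimination record and a manifest with the seed, config hash and library
versions. On the default (unboosted) synthetic cohort the class marginals
overlap heavily, so absolute AUCs are modest by construction — see
`docs/methods.md` for what the generator does and does not emulate.

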