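# Methods

This note records the models, conventions and design choices behind
`pmifusion`, in the order the pipeline runs them.

## Synthetic cohorts

The generator emulates a rat degradation study: four organs (lung, liver,
kidney, skeletal muscle) sampled at 14 fixed post-mortem days
(0, 1, 2, 3, 5, 7, 9, 12, 15, 18, 21, 24, 27, 30), six rats per day in
the training study (84 rats, 336 organ samples) and an external
validation cohort of two rats per day (28 rats). Each organ sample yields
a peak table as instrument software would export it: migration time (s),
molecular mass (kDa), peak height (fluorescence units), one row per
detected fragment.

**Signal model.** Ground truth is the packaged 45-fragment reference
catalog (mass, migration time, organ membership per fragment). Each
(fragment, organ) pair gets a rise-then-decay height trajectory

    h(t) = A · exp(rise · (t − t_peak))    t < t_peak
    h(t) = A · exp(−decay · (t − t_peak))  t ≥ t_peak

with `A` log-uniform in [100, 800] fluorescence units, `t_peak` uniform
in [0, 30] days, and rates uniform in [0.08, 0.35] /day, drawn from a
dedicated `trajectory_seed` (default 1234) so the training and external
cohorts share the same biology while their measurement noise streams are
independent. Any smooth family whose class-conditional heights differ
across days would serve; rise-then-decay reflects degradation products
that accumulate and then decompose, and it naturally produces peaks that
appear or vanish over post-mortem time once the detection threshold is
applied.

**Noise model.**

| parameter | default | units | rationale |
|---|---|---|---|
| `noise_sigma` | 0.45 | lognormal σ | calibrated (3-seed grid over 0.45/0.55/0.65) so single-organ random-forest external accuracies land at the study's operating point: lung 0.607, liver 0.524, kidney 0.762, muscle 0.667 on the calibration seeds |
| `organ_noise_multipliers` | lung 1.25, liver 1.6, kidney 0.8, muscle 1.0 | × | makes the kidney the most and the liver the least informative organ, matching the reported organ ordering (deep organs are less protease-rich than the liver) |
| `jitter_sigma` | 0.004 | relative | keeps within-fragment migration deviations well below the 2% identity tolerance; a value ≥ 0.01 triggers a warning |
| `mass_jitter_sigma` | 0.02 | relative | of the order of the catalog's reported mass SDs |
| `detection_threshold` | 20 | fluorescence | peaks below it are dropped, creating the late/early dropout structure |

Heights are multiplied by `exp(σ · m_organ · N(0,1))` — multiplicative
lognormal noise because intensities are positive. Replicate draws are
consumed before the threshold test, so raising the threshold can only
remove peaks (monotone dropout), and σ → 0 drives within-time-point
coefficient of variation to 0.

**What the generator does not emulate**: raw fluorescence traces, ladder
peaks, calibration drift, temperature/humidity covariates, rat-level
random effects (noise is independent per peak), and any real biochemical
identity of the fragments. Green tests on synthetic cohorts therefore
demonstrate that the *pipeline machinery* behaves as specified under a
plausible signal structure — not that the biological effect sizes are
real.

**Split.** The training study is divided by *rat* (all four organ samples
of a rat stay together) into 70% train / 30% internal validation,
stratified by PMI day, with `ceil(0.3 · 84) = 26` internal-test rats.
Splitting by sample instead would leak a rat's other organs into
training and invalidate the multi-organ fusion comparison.

## Fragment confirmation

Peaks from different samples are the same fragment when their migration
times deviate by less than 2% (relative). The matcher processes peaks in
ascending migration time; a peak joins the cluster with the nearest
running-mean migration (deviation < tolerance), otherwise seeds a new
cluster. Two refinements are load-bearing:

* **Same-sample exclusion.** The instrument has already resolved two
  peaks of one electropherogram as distinct molecules, so peaks sharing a
  `sample_id` never merge. Without this rule, real catalogs are
  unrecoverable: the reference catalog itself contains same-organ
  fragment pairs only 0.6–2% apart in migration time (e.g. 28.80 vs
  28.99 s in lung), inside any useful tolerance.
* **Cross-organ mass agreement.** Matching runs per organ; per-organ
  fragments are then linked into one study-wide numbered catalog
  (ascending migration time) by union-find over candidate links, applied
  smallest migration deviation first, refusing links that would put two
  clusters of one organ into one fragment. A link additionally requires
  cluster mean masses within 1% (`mass_tolerance`): migration time alone
  cannot separate cross-organ coincidences such as 29.88 s (kidney) vs
  29.90 s (lung/muscle), which differ by 0.07% in migration but 1.6% in
  mass.

A post-hoc soundness pass unassigns any peak whose deviation from its
fragment's final mean reaches the tolerance, so the catalog invariant
holds unconditionally. On a zero-jitter, zero-dropout cohort this
procedure recovers the 45 reference fragments and their organ sets
exactly; at the default jitter it yields ≈ 50–55 fragments because
closely spaced fragments split or merge — deliberate realism, since real
peak tables carry the same ambiguity.

A fragment is retained for an organ only if at least one time point shows
it in ≥ 5 of the 6 biological replicates. The rule is "at ≥ 1 time
point", not "at every time point": fragments that appear only late
post-mortem are genuine indicators. External-cohort peaks are assigned to
the *training* catalog (nearest fragment of the sample's organ within
tolerance, never reusing a fragment within one sample); no new fragments
are created at predict time and unmatched peaks are dropped with a log
message. Undetected fragments enter the feature matrix as height 0 (true
absence of signal), duplicate assignments keep the taller peak, and
columns are z-scored with mean/SD estimated on training rows only
(constant columns pass through centered).

## Model search and rank-sum selection

Per organ, four selectors × five classifiers = 20 pipelines. Selector
tuning uses stratified 5-fold cross-validated accuracy on training data
only (folds shrink automatically when a class has fewer members than
folds, with a plain K-fold fallback below two):

* **LASSO** — features with any nonzero coefficient in an L1 multinomial
  logistic model, penalty from 10 log-spaced values in [1e-2, 1e2]; if
  the winner zeroes everything, fall back to all features with a warning.
* **RFE** — recursive elimination (step 1) driven by random-forest
  importances, subset size by cross-validated accuracy (`RFECV`).
* **SFS / SBS** — hand-written greedy forward/backward search scored by
  cross-validated accuracy of a logistic model, stopping when no single
  step strictly improves the score (scikit-learn's sequential selector
  cannot express this stopping rule). Backward search keeps ≥ 1 feature.

Classifier settings (deliberately plain, all seeded, recorded in
`ExperimentConfig`): LR — multinomial, L2, C = 1; SVM — RBF kernel with
probability calibration (soft voting needs probabilities); RF — 100
trees; GBDT — 100 stages, depth 3; MLPC — one hidden layer of 100 units
with early stopping (disabled below 20 training samples, where the
validation split would be degenerate).

Metrics per cohort: accuracy; macro-averaged precision and recall
(classes with no predicted positives contribute 0); macro one-vs-rest
AUC over the classes present in the evaluated cohort. Macro averaging is
the natural convention for this class-balanced design.

**Rank-sum selection.** Within each of the 8 columns (4 metrics ×
internal/external) the best of M models scores M, the worst 1, ties share
the average of their positions — the only simple scheme that produces
half-integer totals. Column scores always sum to M(M+1)/2. The model
with the highest total wins; ties break by external accuracy, then model
name. A single failing pipeline is recorded as failed and excluded from
ranking rather than aborting the grid.

## Ensembles and fusion

All combiners operate on member class-probability matrices over the
ordered day set; argmax ties (within 1e-9, which absorbs float noise in
weighted averages) resolve toward the *earlier* day — deterministic and
conservative.

* **Soft voting** — unweighted mean of member probabilities.
* **Soft-weighted voting** — weights proportional to each member's
  internal-validation accuracy (the common convention when weights are
  otherwise unspecified; equal performers reduce it to soft voting).
* **Stacking** — meta-features are each member's out-of-fold class
  probabilities on training data (members refit per stratified fold);
  the meta-learner is a multinomial logistic model; members are refit on
  the full training data afterwards. A class with fewer than two
  training samples is a stratification error.

Single-organ ensembles combine the five classifiers trained on one
organ's features under each selector (4 selectors × 3 combiners = 12
candidates per organ, ranked by the same rank-sum rule). Multi-organ
fusion runs each organ's best pipeline on that organ's features and
fuses the four probability vectors per rat; rows align by `rat_id` and a
rat missing an organ sample is an error, never imputed.

**Pruning.** Greedy backward elimination: evaluate removal of every
active member, apply the removal with the largest *strictly* positive
improvement in internal-validation accuracy, repeat until none improves.
Ties on improvement remove the member with the lowest individual
internal accuracy. External data never enters the objective.

**Pruning stability.** On a 26-rat internal set, accuracy moves in steps
of 1/26, so greedy selection is noisy in a well-understood way: removing
a genuinely informative but weak member strictly improves the small
validation score in a third to a half of simulated replicates, and an
exhaustive all-subsets oracle *agrees* with the greedy choice in those
cases — this is the classic overfitting of ensemble selection to small
validation sets, not an algorithmic defect. Alternatives were examined
and rejected: a log-likelihood objective collapses soft voting to the
single sharpest member (linear opinion pooling does not reward diversity
in log space), and enlarging the evaluation set with out-of-fold
training predictions leaves the effect in place. Consequences: with all
four organs as members the designed-weak liver is often (correctly)
pruned, and in the adversarial-member study the planted adversary is
reliably discarded but a weak informative member sometimes follows it.
The 20-seed replication in `scripts/acceptance.py` reports the measured
rates; expect the fused-beats-best-single property in roughly 14–17 of
20 replicates and exact adversary isolation in roughly 10–14 of 20 under
the default conditions.

## Problem sizes and determinism

The test suite and the acceptance script run the full study design (84 +
28 rats) for the catalog, matching and fusion studies; the matcher
oracle uses 200 random instances of ≤ 30 peaks; ranking conservation
uses 500 random metric tables (enumeration oracle for M ≤ 4); the
end-to-end experiment is exercised on a miniature configuration (3 time
points × 2 rats, support rule scaled to 2-of-2) chosen so a full run
completes in well under a minute. The 20-seed fusion study takes a few
minutes on one CPU.

Every stochastic component draws from a seed derived from one global
seed via `numpy.random.SeedSequence`, per pipeline stage, so stages can
be rerun in isolation and two runs of the same configuration produce
byte-identical artifacts (verified by checksum in the suite).

## Known limitations

* The degradation kinetics are stand-ins: the synthetic trajectories are
  statistically plausible but make no claim of biological realism, and
  no real dataset ships with the package.
* Fragment matching at realistic jitter is ambiguous for fragments
  closer than the tolerance; the pipeline tolerates (and logs) the
  resulting catalog distortion rather than pretending it away.
* Hyperparameters are fixed at plain defaults; the search tunes only
  selector penalty/size. No class-imbalance handling, no probability
  calibration analysis, no continuous-PMI regression (PMI is treated as
  14 ordered classes, and only the tie-break exploits the order).
* Multi-class AUC is computed over classes present in the evaluated
  cohort; on very small cohorts this can differ from the full-class
  definition.
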