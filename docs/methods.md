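# Methods

This note documents the models, statistical procedures, parameter
defaults and design choices behind `isoensemble`, and what the synthetic
generators do and do not emulate.

## Dominance ranking

Percent wins for a mouse is 100 × (trials won) / (trials participated
in), pooled over all tournament days (default 3). Ranks within a cage are
assigned in descending percent wins; ties break first by head-to-head
wins between the tied pair, then by lexicographic mouse id. Both
tie-breaks are deterministic so a tournament record maps to exactly one
rank table. Ranks are integers 1…N with 1 = dominant; downstream
correlations use the integer rank as regressor by default (configurable
to percent wins).

## Lick-bout segmentation

Consecutive licks belong to one bout while their inter-lick interval is
≤ `ili_threshold_s` (default 1.0 s); runs with fewer than `min_licks`
licks (default 3) are discarded but their licks are counted, so
Σ bout licks + discarded licks = total licks always holds. The 1 s / 3
licks criterion is conventional in rodent licking work; the field has no
single standard, so both are parameters and analyses report them.
Summaries are total licks, bout count and mean licks per bout (missing
when there are no bouts).

Condition contrasts fit a two-way ANOVA with Type III sums of squares and
sum-coded factors (robust to mildly unbalanced cells), post-hoc
per-rank condition contrasts with Holm correction, and a Pearson
rank-vs-metric correlation per condition. When only one rank level is
present the contrast collapses to a paired t-test (by mouse) or Welch
t-test when pairing is impossible.

## Social-contact rule

Per frame, distance = ‖intruder body − resident head‖ and the approach
angle is the unsigned angle between the heading vector (body → head) and
the head → intruder vector, in [0°, 180°]. A frame is interaction iff
distance ≤ 60 px **and** angle ≤ 135°, both inclusive for deterministic
boundary behavior. The 135° bound is read as an upper bound on the
approach cone (interaction unless the resident faces away); the
alternative reading (facing-away criterion) would invert the comparison
and is not supported by the geometry of approach. Frames with tracking
dropouts or a degenerate heading are never interaction. Runs are merged
across gaps < `merge_gap_s` (default 0.2 s) and kept when ≥ `min_dur_s`
(default 0.5 s); merging precedes the duration filter so brief tracking
flickers do not split an otherwise long bout. Interval endpoints are
frame edges: a run of frames i…j spans [i/fps, (j+1)/fps).

## Peri-event tensors and normalization

Events are aligned with a baseline window of −5…0 s and a response
window of 0…5 s in 0.25 s bins (all configurable); raw samples are
averaged within bins, and trials whose window is not fully covered by the
recording are dropped with a count. Z units come from the pooled
baseline across trials per neuron (sample SD, ddof = 1); pooling is used
because per-trial SDs over ~20 baseline bins are unstable. Neurons with
baseline SD < 1e-6 are excluded as degenerate. Z-scoring is invariant to
per-neuron affine transforms of the raw trace with positive gain;
negative gain flips excited and inhibited, as it should.

## Responsive-neuron classification

Per neuron, the per-trial difference d_t = (mean response) − (mean
baseline) is tested with a Wilcoxon signed-rank test, and the magnitude
criterion uses the **standardized mean response**

  z = mean(d_t) / (SD(d_t) / √n_trials),

which is ~N(0, 1) for an unmodulated neuron. A neuron is excited when
p ≤ α (= 0.05) and z ≥ +1.98, inhibited when p ≤ α and z ≤ −1.98, else
unclassified. 1.98 is the two-sided 95% critical value of a standard
normal / large-df t; applying it to the raw pooled-sample mean Z instead
would give the rule essentially zero power *and* zero false-positive rate
(the mean of n_trials × n_bins unit-variance samples has SD ≪ 1), which
would contradict both the intended ~5% null flag rate and the recovery of
moderate planted responses, so the standardized reading is used for all
event classes. Measured on 1000 simulated null neurons (20 trials) the
flag rate is ~4.6%, within two binomial SEs of α.

Fewer than `min_trials` (default 5) trials yields "none" with a recorded
reason rather than an unstable label.

## Functional clustering and enrichment

Trial-averaged time courses are standardized per neuron (zero mean, unit
SD) and clustered with Ward linkage; on standardized rows squared
Euclidean distance is a monotone transform of correlation distance, so
this realizes correlation-based clustering within Ward's variance
framework. The cut is at k = 9 clusters by default (k is configurable
and should be audited, e.g. with silhouette scores). Cluster ids are
relabeled by descending peak of the cluster-mean time course, making the
labeling deterministic and order-invariant. Enrichment of a neuron group
g in cluster c is reported as (n_cg/N_g) / Σ_g′ (n_cg′/N_g′) — the
group-size-normalized share, 1/#groups under no enrichment — with a
chi-square contingency test (no continuity correction) across
cluster × group.

## Pseudo-simultaneous decoding

Features are per-trial mean Z in a feature window (default the response
window). Per resample, each neuron contributes `n_trials_per_class`
(default 20) pseudo-trials per class, and a linear SVM (C = 1) in a
pipeline with fold-internal standardization is scored by 5-fold
cross-validation; defaults are 100 resamples.

Fold handling is the load-bearing choice: each neuron's real trials are
partitioned into the 5 folds first, and fold f's pseudo-trials are drawn
(with replacement) only from that neuron's fold-f real trials. Naive
resampling across all trials lets the same real trial feed training and
held-out pseudo-trials; finite-sample class-mean differences then become
learnable and class-independent data decode at ~0.6. With fold-aware
construction the null is unbiased — though conditional on one finite
trial set the expected accuracy still fluctuates around 0.5 (SD ~0.1 at
15 trials/class, 10 neurons), so chance-level audits should average over
independent datasets, as the test suite does. Pseudo-trials destroy
cross-animal noise correlations by construction, which typically inflates
decodable information relative to truly simultaneous recordings; decoding
accuracies are comparable between conditions analyzed the same way, not
absolute information estimates. Group comparisons use Kruskal–Wallis
with pairwise Mann–Whitney post hocs (Holm correction); the two-group
case is the plain rank-sum test.

## Ensemble overlap

The co-registration rate is (global ids present in every listed session)
/ (mean per-session neuron count). Ensemble overlap between two
sessions counts neurons responsive in a given direction in both, out of
the neurons co-registered across those two sessions (not all sessions —
this maximizes usable cells and is recorded in the output). Excited and
inhibited ensembles are analyzed separately. The overlap chi-square
compares two condition pairs as a 2×2 table of (overlapping,
non-overlapping) counts out of each pair's reference ensemble, without
Yates correction by default (flag available).

## Synthetic generators

All generators draw from one seeded `numpy.random.Generator` per call;
identical configuration and seed give bit-identical output, which the
pipeline test pins down to byte-identical files (HDF5 is written without
modification timestamps).

* **Tournaments** draw winners from a logistic win probability on latent
  skill differences; the default ladder spacing (3.0) makes planted ranks
  recoverable while leaving occasional upsets. Zero spread gives fair
  coins; infinite spread, deterministic wins.
* **Lick streams** draw a Poisson bout count (rate default 0.35/min over
  a 1 h session), licks per bout as min + Poisson, within-bout intervals
  of 0.15 s with 20% multiplicative jitter, and between-bout gaps ≥ 2 s —
  twice the default segmentation threshold — so the planted bout
  decomposition is the unique segmentation answer. The session-total
  SD has the compound-Poisson closed form λ·Var(l) + λ·E[l]², exposed as
  `CohortConfig.licks_sd` so planted effects can be stated in SD units.
* **Cohorts** plant alcohol-lick means of
  base + a·(rank−1) + b·SI + c·(rank−1)·SI with defaults a = 50, b = 100,
  c = 50 licks (positive a: subordinates drink more, matching the
  observed direction under integer rank coding); water licks carry no
  rank effect. Subordinate ranks realize isolation escalation through
  licks per bout at fixed bout count; dominant ranks through bout number
  — the qualitative microstructure dissociation reported for real
  cohorts. Published reports of such cohorts give no lick-rate
  distributions, so the base rates are realistic placeholders, exposed in
  the config. At this noise level an interaction of 1.0 SD/rank-step is
  detected in only ~60% of 16-mouse cohorts; the acceptance property uses
  a 1.5 SD/step effect, the scale of the very large reported
  isolation × rank interactions (detected ~90%).
* **Pose sessions** script contact episodes with geometric margins
  (distance 20–45 px, cone ≤ 80°) wide enough that truncated ±3 px
  keypoint jitter cannot cross the 60 px / 135° rule, and keep the
  intruder ≥ 74 px away outside episodes. Generated tracks emulate
  keypoint geometry only — no identity swaps, occlusions or
  pose-estimation confidence structure.
* **Calcium traces** are white Gaussian noise plus event-locked
  single-exponential transients (τ default 1 s) scaled in noise-SD
  units; per-class responsive ensembles are disjoint by default. Real
  calcium data have autocorrelated noise, bleaching and crosstalk that
  the generator does not emulate, so green tests establish correctness
  of the analysis logic, not robustness to those artifacts.
* **Identity maps** make each of the per-session quota of cells fully
  tracked with the stated probability (Binomial count), and fill the
  remainder with cells appearing in strict session subsets.

## Known limitations

The ANOVA treats mice as independent observations per condition
(between-subjects); a mixed model with per-mouse intercepts would gain
power on real repeated-measures data but is indistinguishable here
because the generator has no mouse-level random effect. The bout
criterion, peri-event windows, Z basis, cluster count and decoder
hyperparameters are field conventions rather than values fixed by any
single reference; all are exposed as parameters. Printed statistics from
real cohorts (specific r², F, χ² values) depend on unreleased data and
are not reproduction targets of this package.
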