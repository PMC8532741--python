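# Methods

## Problem and scope

Canine ADHD-like behavior (hyperkinesis / hypersensitivity–hyperactivity)
is typically assessed through owner questionnaires, which are subjective.
An alternative is to track the dog on overhead video during a normal
veterinary consultation and quantify *how* it moves: treated hyperactive
dogs move fast and erratically around the room, healthy controls explore
calmly. This package implements that assessment chain on top of tracker
output (per-frame detections), not on raw video: ingestion and quality
filtering, movement-feature extraction, classifier selection and
evaluation, the per-dog H-score, and the group-level clinical statistics.
Object detection itself (the neural-network tracker) is out of scope;
detections are an input format.

## Ingestion and quality control (`trajectory_io`)

Detections arrive as one CSV row per (frame, object) with an image-plane
point, an optional bounding box and a confidence in [0, 1]. The position
of a detection is the bounding-box centroid when a box is present,
otherwise the given point, converted to room centimetres with separate
x/y scales (room and image aspect ratios differ). The trial span is the
full frame range of the file; frames without a detection are missing
slots. Slot times come from the frame grid (`frame / fps`); the file's
time column is validated for monotonicity but not trusted per row.

Two clean-up operations mirror standard tracker post-processing:

* **Gap filling** — interior missing runs of at most `max_gap_frames`
  (default 15 ≈ 0.5 s at 30 fps) are linearly interpolated; longer runs
  and leading/trailing gaps stay missing. Extrapolation beyond the first
  or last detection is deliberately not performed: it fabricates data.
* **Smoothing** — centred moving average (default window 5 frames) over
  the sequence of detected samples; endpoints use shrunken windows.

The inclusion rule for a recording is: fraction of frames with the
animal detected ≥ 0.70 **and** mean detection confidence ≥ 0.70, both
inclusive and configurable; for dog–robot trials it applies to both
objects. Both quantities are computed on the *raw* detections and are
preserved by gap filling, so interpolation can never promote a rejected
recording. Every violated criterion is reported as a reason.

## Movement features (`features`)

A cleaned trajectory is reduced to a gap-free polyline (missing slots
dropped) and summarised by:

* **Expert-style locomotion features** — total distance (cm), average
  speed (cm/s), fraction of time moving (speed > 2 cm/s), mean and SD of
  the absolute turning angle, number of direction reversals
  (|turn| > π/2), room coverage on a 20 cm grid, and the 90th percentile
  of speed.
* **Five tortuosity indices** from the movement-ecology literature:
  * *Straightness* = net displacement / path length ∈ [0, 1].
  * *MSD*: mean squared displacement over lags {1, 2, 5, 10, 30} s
    averaged over start times, summarised by the mean over admissible
    lags. Lags are converted to whole sample counts via the median
    sampling interval (sampling is near-uniform after gap filling).
  * *Intensity of use* = path length / √(convex-hull area) (hulls via
    shapely). Degenerate (collinear) hulls yield an undefined marker.
  * *Sinuosity* S = 2·[p·((1+c)/(1−c) + b²)]^(−1/2), with p the mean
    step, c the mean turning-angle cosine and b the step-length CV,
    measured on a constant-chord rediscretized path (default chord
    q = 5 cm). After rediscretization b = 0 by construction; c → 1
    (straight path) returns 0 by the limit convention; c = −1 with
    b = 0 is undefined.
  * *Fractal D*: divider method. For 10 log-spaced divider sizes ε in
    [2, 50] cm the walked length L(ε) = n·ε + remainder is regressed as
    log L on log ε, D = 1 − slope, clipped to [1, 2] with a warning.
    A straight line has constant L(ε), hence D = 1 exactly.
* **Dog–robot interaction features** (DR trials) — mean and minimum
  distance to the robot, fraction of time within 50 cm, number of
  approach events (crossings below the radius, re-armed only after
  retreating beyond 1.2×, i.e. 20% hysteresis), and latency to first
  entry (trial duration if never). A moving robot is interpolated onto
  the dog's time base.

Rediscretization finds, from each anchor, the *first* point along the
polyline at chord distance exactly q (outward root of the per-segment
quadratic); the same walk underlies the fractal divider counts. All
defaults (q, divider range, move threshold, grid cell, proximity radius,
MSD lags) are configuration, chosen as sensible magnitudes for a few-
metre consultation room; no canonical values exist for this setting.

Undefined features (too-short path, degenerate hull) are NaN with a
recorded reason and are imputed downstream by training-fold medians,
never at extraction time.

## Classification and the H-score (`selection_model`)

One row per dog (first visits only; follow-ups are scored, never trained
on), label H (treated for excessive ADHD-like behavior) or C (healthy
control). Four selection methods each propose a subset of k = 5
features: univariate ANOVA F, chi-squared on min-max-scaled features
(the test needs non-negative input; movement features are signed),
impurity importance of a 500-tree random forest, and RFE around the same
forest eliminating one feature per step. Selection runs once on the full
first-visit cohort and the fixed subsets are then compared — mirroring a
two-stage protocol where subsets are chosen before model comparison.
The out-of-fold metrics therefore evaluate classifiers *given* the
subsets, not the selection step itself; with n = 38 this is a known,
accepted source of optimism.

Nine classifier families (SGD with logistic loss, random forest, k-NN,
Gaussian process, four naive-Bayes variants, SVM with probability
output) run at library defaults with a fixed seed, each inside an
impute-median → min-max-scale pipeline fit per training fold. k-NN's
k = 5 is capped at the training-fold size so tiny cohorts stay well
defined. Every (classifier, subset) pair is evaluated by leave-one-out
cross-validation; the predicted label is the 0.5-thresholded out-of-fold
probability, so the pooled confusion counts are always recomputable from
the stored probabilities. Precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), each defined as 0 with a warning when its denominator
vanishes; ROC AUC is computed from the pooled out-of-fold probabilities.
Ranking is by F1, then AUC, then ids (deterministic tie-break).

The **H-score** of a trial is the model's predicted probability of the H
class. Dogs in the training cohort are scored out-of-fold — the only
leakage-free choice; follow-up visits are scored by the full model fit
on all first visits. The shipped default model uses exploration-trial
features only; dog–robot features are selected and modelled separately
when DR trials are present.

## Group statistics (`group_stats`)

The package ships the published per-dog H-scores as fixtures (19 + 19
first visits, 11 follow-ups). Three statistics are computed on them:

* **Mann–Whitney U**, two-tailed, reported as min(U₁, U₂) with midrank
  (½-credit) tie handling — the orientation under which the fixture data
  give U = 49.5. The p-value is exact (enumeration) for tie-free samples
  with n₁·n₂ ≤ 400, otherwise the tie-corrected normal approximation
  with continuity correction (scipy). On the fixtures, which contain
  ties, the asymptotic two-tailed p ≈ 1.4 × 10⁻⁴.
* **Group medians** of first-visit scores (0.96 H, 0.26 C on fixtures).
* **Paired reduction**: among H-group dogs with both visits, those whose
  follow-up score is *strictly* lower (ties are not reductions): 8 of 11
  on the fixtures.

## Synthetic cohort (`synthetic`)

Dog locomotion is emulated by a correlated random walk: per frame the
heading gains a wrapped-Cauchy turning angle with concentration κ
(mapped to the Cauchy parameter ρ = κ/(1+κ)), the step is
speed · dt with log-normal multiplicative noise (CV 0.3), walls reflect
specularly (speed-preserving), and a two-state renewal process inserts
pauses (entry rate per second, exponential-mean durations). An optional
fixed robot exerts a configurable heading drift. Tracker noise is
emulated on top: per-frame Bernoulli dropout (default 0.05), Gaussian
confidence draws (0.9 ± 0.05, clipped to [0, 1]) and 1 cm position
jitter.

Regime defaults encode the qualitative clinical contrast: calm = 8 cm/s,
κ = 8, pause rate 0.1/s; hyperactive = 30 cm/s, κ = 1, pause rate
0.01/s; room 340 × 220 cm (alternative 260 × 160 cm), 30 fps, 180 s
trials, 19 dogs per group. These are synthetic stand-ins chosen to
realize the described behavioral contrast, not estimates from clinical
data — no distributional parameters of real dog movement are published,
so passing the synthetic end-to-end checks demonstrates that the
*pipeline* is correct and sensitive, not that real cohorts are this
separable. In particular the synthetic regimes are far cleaner than
clinic reality: no owner/vet interaction, no scent-driven loitering, no
out-of-frame privacy cropping, and jitter/dropout that are i.i.d. rather
than pose-dependent. Observed features also carry a jitter-induced
upward bias in apparent speed (a real tracker artifact as well); the
parameter-recovery harness therefore checks *monotone* recovery
(Spearman), not unbiasedness.

Seeding: every cohort/ladder derives per-trial seeds from one base seed
via `numpy.random.SeedSequence`; identical configs and seeds reproduce
byte-identical detection files and reports.

## Problem sizes used by tests and the acceptance script

The shipped checks run the default 19 + 19 cohort at 180 s / 30 fps for
the classifier harness, 4-level ladders × 10 dogs × 60 s for parameter
recovery, 50 seeded 60-point random paths for the tortuosity oracle
suite, and 100 random small-sample pairs for the rank-statistic oracle —
sizes chosen to exercise the full pipeline at the study's own scale
while keeping a complete run in the order of a minute.

## Known limitations

* The published clinic-cohort classifier metrics (≈ 81% F1) cannot be
  re-derived here: they require the original consultation videos, which
  are not deposited. The synthetic cohort substitutes a correctness and
  sensitivity check, not a replication.
* Grid-based room coverage is not invariant under rotation of the path
  (no grid statistic is); all other features are rigid-motion invariant
  to 1e-9 and tested as such.
* Median imputation and once-per-cohort feature selection are simple,
  deliberate choices; with 38 rows anything richer overfits.
* The p-value convention for the published U statistic is not stated in
  the source tables; we report the tie-corrected asymptotic value and
  treat only U, the medians and the reduction count as exactly
  reproducible.
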