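# Methods

## Problem and model

Ambulatory two-lead ECG carries, per beat, morphological information (the
P-QRS-T waveform) and rhythm information (the RR-interval sequence). Beats
of supraventricular origin (SVB: N and S classes of the AAMI EC57
grouping) conduct through the normal pathway and resemble the patient's
dominant morphology; ventricular beats (VB: V and F) are wide, differently
shaped, usually lack a P wave, and arrive early. The classifier exploits
exactly this structure in two stages: a cheap morphological gate that
clears the overwhelming SVB majority, and a trainable classifier for the
residue, where the class balance is far more even and a richer feature
description pays off.

### Preprocessing

All records are brought to 250 Hz by piecewise-linear interpolation
(annotation fiducials rescaled and rounded half-away-from-zero), then
band-limited to 0.05–75 Hz. The filter is a 2nd-order Butterworth
high-pass at 0.05 Hz cascaded with a 4th-order Butterworth low-pass at
75 Hz, applied forward–backward for zero phase; only the band itself is
prescribed, the realization is a package choice. Note the 0.05 Hz corner
implies a ~20 s settling time: short test signals must be long enough for
the zero-phase transient to die out. Two composite leads are derived:
magnitude `mag[i] = √(lead1²+lead2²)` and velocity
`vel[i] = √(Δlead1²+Δlead2²)` with `vel[0] = 0` (the first difference is
undefined at the record start).

### Stage 1: template bank and adaptive threshold

* **Learning period (first 10 s).** Beats are greedily grouped: a beat
  joins the first subgroup whose running-average velocity window it
  correlates with at or above the learning segment's OCT, else founds a
  new one. Subgroups score `0.7·(members/max_members) +
  0.3·(1 − qrs_dur/max_qrs_dur)`: the predominant rhythm must dominate,
  QRS shortness only breaks near-ties (the 0.7/0.3 weights are a package
  choice, configurable through the constants in `stage1`). The winner's
  average becomes the reference template; ACT is initialized to the
  learning OCT (default 90 when fewer than two beats exist).
* **Matching.** Correlation is the normalized inner product of two 180 ms
  (45-sample) velocity windows anchored at QRS onset; for nonnegative
  windows it lies in [0, 100] %. A reference match (corr ≥ ACT) decides
  SVB immediately and updates the reference by exponential running
  average with new-beat weight 1/8 — standard ECG averaging practice
  giving an effective memory of ~8 beats. Non-reference templates are
  tried in insertion order; a fully unmatched beat founds a new template
  while the bank holds < 8 (no replacement policy — deliberately, since
  replacement strategies are unvalidated for this design).
* **Threshold adaptation.** Per closed 10 s segment the OCT is the
  highest value in {98, 97.5, …, 80} at which ≥ 75 % of the segment's
  beats correlate at/above it with ≥ 25 % of the other beats (per-beat
  counting); ACT then relaxes toward it,
  `ACT ← 0.75·ACT + 0.25·OCT`, clipped to [80, 98]. The geometric memory
  means a constant OCT c is approached as `0.75^i`.

### QRS delineation and P-wave detection

The architecture assumes QRS boundaries and a P-wave flag exist; both
detectors here are deliberately simple, pluggable plumbing:

* **Boundaries.** QRS onset is the last sample before the fiducial where
  the 5-sample-smoothed velocity stays below a threshold for ≥ 20 ms
  (searched ≤ 150 ms back); offset is the symmetric forward search
  (≤ 300 ms). The threshold is 10 % of the beat's peak velocity, floored
  at 1.4× the local median velocity: on noisy band-passed signal the
  smoothed noise floor approaches 10 % of peak and the pure rule fails
  intermittently, misaligning template windows. When no quiet run exists
  the boundary falls back to the quietest sample in the search range; a
  flat beat degenerates to fiducial ± 1 sample.
* **P wave.** A beat has a P wave iff a *true interior local maximum* of
  the magnitude lead in [onset − 200 ms, onset − 40 ms] exceeds both 5 %
  of the beat's peak magnitude and 2× the window median. Requiring an
  interior maximum matters: a premature beat's window often contains the
  monotone tail of the preceding T wave, which must not count. With
  < 200 ms of pre-window the learning-period default (present) applies.

### Features F1–F20 and the 210-element expansion

Match codes are coded reference = 0 / other = 1 / none = −1. Correlations
F6–F8 are always measured against the reference template in its state at
the beat's arrival (not the later-updated state). QRS activity is
`100·mean(mag)/max(mag)` and mobility `100·Σvel/Σmag` over the 180 ms
window; both are scale-free area descriptors (activity grows, mobility
shrinks for wide ventricular complexes). `curRR`/`nextRR` normalize to
the mean of the last up-to-four intervals; `relRRv` is the mean absolute
successive RR difference over the trailing 10 s divided by its mean
interval (the "reference RR variability" is not otherwise pinned down;
this choice is documented and configurable). While no reference template
exists, reference-side defaults apply: P present, corr 80 %, QRSdur
100 ms, QRSact 100 %, QRSmob 100 %; missing neighbours at record edges
take the same defaults. The expansion appends the 190 products Fi·Fj
(i<j, lexicographic, no squares): 20 + 190 = 210 columns with a frozen
index map (`expanded_feature_names`), e.g. column 116 is F6·F18.

Decisions for non-fast-tracked beats are *delayed* one beat: beat k's
F3/F8 need beat k+1's Stage-1 outcome; at the record end defaults
substitute.

### Stage-2 classifiers

Class convention throughout: class 1 = SVB (negative), class 2 = VB
(positive). All label ties resolve to VB, favouring ventricular
sensitivity; LDA's boundary equality goes to class 2 for the same reason.

* **k-means + nearest centroid.** Lloyd iterations from k random distinct
  rows, ≤ 100 iterations, empty clusters re-seeded to the farthest row;
  10 replicates, keeping the one with the best training
  (Mean(Se,PPV), Se). Clusters are labeled by majority class; prediction
  is the nearest centroid's label (Euclidean, lowest index on ties).
* **Fuzzy percentile.** Per feature and class the empirical CDF F_c
  (midpoint convention at ties) gives confidence `1 − |2F_c(x) − 1|`:
  1 at the class median, 0 outside the class range. The class with the
  larger mean confidence over the selected features wins. The mapping
  from percentile rank to confidence is a committed interpretation — the
  tent function is the simplest map that is maximal at the median and
  vanishes outside the observed range.
* **LDA.** Pooled covariance `Σ̂ = [(n₁−1)Σ̂₁+(n₂−1)Σ̂₂]/(n₁+n₂−2)`,
  coefficients `â = Σ̂⁻¹(μ̂₁−μ̂₂)`, decision `λ(y) > ln(π₂/π₁)` for
  class 1. A reciprocal condition estimate of Σ̂ below 1e−12 raises a
  conditioning error, which the stepwise trainer uses to exclude the
  offending (collinear) feature permanently. Standardized coefficients
  (â scaled by the pooled standard deviations) and the apparent error
  rate APER = (N−n₁₁−n₂₂)/N are recorded.
* **Classification tree.** Exhaustive univariate splits at midpoints
  between adjacent distinct values; deviance `i_D = 2n·(−Σp_j ln p_j)`
  (natural log; equal to 2n× entropy), Gini `1 − Σp_j²` (for two classes
  `2p₁(1−p₁)`), or the twoing rule
  `i_T = (p_L p_R/4)(Σ|p_jL − p_jR|)²`. Class proportions are
  prior-reweighted at every node (`p_jm ∝ π_j·n_jm/n_j(root)`) during
  *growth only*; a consequence worth noting is that the root's
  reweighted proportions equal the priors exactly, so a fully pruned
  stump under equal priors is a tie and predicts VB. A node is terminal
  when pure, smaller than `min_impure = 10` rows, or unsplittable; split
  ties break to the lowest feature index, then lowest threshold.
  Pruning iteratively collapses the internal node whose removal least
  increases the resubstitution misclassification count (unweighted —
  priors do not enter the pruning cost), recording the full sequence;
  "decision nodes" counts internal split nodes here, and a collapse of a
  deep subtree may skip intermediate counts.

### Stepwise training and sweeps

Forward selection refits the classifier once per candidate feature per
step and keeps the candidate maximizing training Mean(Se,PPV) (ties:
higher Se, then lower index), stopping when no candidate raises either
the criterion or Se; `max_steps` defaults to 150. Training metrics are
resubstitution metrics — validation happens once, on held-out data. The
cluster sweep covers k = 2…10 (rule of thumb `√(210/2) ≈ 10`). The prior
sweep returns the first grid pair with Se > PPV whose criterion is within
0.5 percentage points of the grid maximum ("not deteriorated"),
falling back to the criterion maximizer. The tree bypasses stepwise
selection entirely — it self-selects features — and uses the prior sweep
and the pruning scan instead.

### Evaluation accounting

Stage-1 accounting: TN/FP split SVB beats by reference match, TP/FN split
VB beats the same way; beats matched to a *secondary* template count as
non-matched (they proceed to Stage 2). Combined accounting uses the final
decision from either stage; a VB beat fast-tracked by Stage 1 is an
unrecoverable false negative, which is the architecture's known
sensitivity ceiling. V-only figures restrict the positive class to
V-annotated beats (F beats dropped from positive counts), matching common
reporting practice. Q-annotated beats flow through both stages but are
excluded from every count; undefined metrics (zero denominators) are
reported as undefined, never 0 or 100.

## Synthetic data

`gen_ecg_stream` emulates: two-lead PQRST morphology as Gaussian bumps
(narrow ~90 ms QRS with P wave for normal beats; wide ~160 ms bifid
complexes without P, discordant T, opposite lead-2 polarity for PVCs),
prematurity (PVC at 0.7 of the base RR) with compensatory pause, and
additive white noise (default 0.02 mV RMS). It does **not** emulate
baseline wander, respiration, electrode motion artefacts, atrial
arrhythmias, conduction blocks, or fusion morphologies — so a passing
pipeline test shows the mechanics are correct under controlled morphology
separation, not database-level performance on real pathology.

`gen_feature_table` draws the 20 basic features directly from the
class-conditional distributions observed on large ambulatory training
data (frequencies for the discrete F1–F5, Gaussian mean±std for the
continuous F6–F20, correlation features clipped to [0, 100]), features
independent per class apart from an optional F6–F18 correlation knob
(no covariances are available to emulate; F6·F18 is the single most
informative product, so its joint structure is the one worth
controlling). Because real feature correlations are absent, classifier
scores on these tables characterize the training machinery, not expected
clinical accuracy.

## Problem sizes and numerical choices

The acceptance script and the performance tests train on 5000 beats per
class and validate on an independent 5000-per-class table (generator seed
offset by one); stepwise selection is capped at 3 steps for LDA/fuzzy and
2 for k-means, and the cluster model uses a fixed k = 4 — the criterion
is already comfortably above 90 % there, and the full k-sweep / deeper
traces are exercised on small fixtures instead. The synthetic evaluation
record is 300 s at 75 bpm with 10 % PVCs. Other numerics: natural
logarithms throughout entropy/deviance; `0·ln 0 = 0`; QRS activity is
clamped at 100 % against float round-off at mean = max; k-means and all
sweeps are seeded and bit-reproducible; all models serialize to versioned
JSON and reload bit-identically.

## Known limitations

* The QRS delineator and P-wave detector are intentionally minimal; on
  real records a validated delineator should be plugged in (the beat
  context construction accepts any boundary source).
* Secondary-template dynamics (bank order, no replacement) are simple
  first-hit policies; long recordings with evolving morphologies would
  need replacement strategies.
* The fuzzy confidence map and the subgroup score weights are committed
  interpretations where the design was genuinely open; both are isolated
  behind single functions/constants.
* Stepwise selection is greedy and O(steps × features × fit); it is the
  intended training protocol, not an efficient feature selector.
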