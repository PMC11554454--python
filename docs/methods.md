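# Methods

## Microstate model and estimation pipeline

The package treats resting EEG as a sequence of quasi-stable scalp
topographies. Estimation follows the classical topographic-analysis
recipe:

**Global field power.** GFP(t) = √(Σᵢ uᵢ(t)² / n) over the
average-referenced potentials uᵢ — the per-sample spatial RMS, equal to
the population standard deviation across electrodes. (The common
printed form of this formula sometimes drops the radical; the RMS
convention is used here, consistent with GFP's meaning as field
strength in µV.)

**Peak selection.** Topographies are sampled at local GFP maxima, the
moments of highest signal-to-noise. A peak must strictly exceed its
left neighbour and at least match its right neighbour (the leftmost
sample represents a plateau); peaks are then retained greedily in
descending GFP order under a 10 ms minimum spacing, and 1,000 retained
peaks per subject are sampled uniformly without replacement for
clustering.

**AAHC with polarity ignored.** Every peak map starts as a singleton
cluster. A cluster's GEV contribution is Σ members (GFP·|corr to
centroid|)² normalized by the total Σ GFP²; with raw (unnormalized)
average-referenced maps this equals the top eigenvalue of the cluster's
outer-product scatter matrix, and the polarity-invariant centroid is
the corresponding eigenvector — the sign-blind analogue of the mean,
which a plain average cannot provide. The algorithm repeatedly
*atomizes* the cluster with the smallest contribution and reassigns
each freed map, one at a time, to the surviving cluster with the
highest absolute spatial correlation, updating the receiving centroid
incrementally; it stops at k = 4 clusters. On small structured map sets
(≤ 8 maps drawn from two orthogonal families with random polarity and
mild noise) the greedy result coincides with the exhaustive best
2-partition to 1e-9; on unstructured pure-noise sets it can land in a
local optimum, one instance of which is pinned in the test suite as
documentation.

**Two-level clustering.** Clustering runs per subject first; each
subject's k unit-norm templates are pooled with unit weight and
clustered again for group templates. Pooled maps are sorted
deterministically before the group pass and per-subject sampling seeds
derive from the subject id, so results are independent of subject
order. Group templates are matched to canonical A–D reference maps
(A/B: diagonal gradients, C: posterior–anterior gradient, D:
fronto-central maximum) by maximizing total |spatial correlation| over
all 24 permutations.

**Backfitting and temporal parameters.** Every sample is labeled with
the template of highest |spatial correlation| (ties to the lowest class
index; zero-variance samples inherit the preceding label). Duration is
the mean run length per class in ms (edge runs included), occurrence
the number of runs per second, contribution the fraction of samples,
and transition probabilities are segment-wise and row-normalized with a
structurally zero diagonal — so occurrence × duration = contribution
up to rounding, and observed rows sum to one. An optional sliding
majority vote over a configurable window (default **off** at the
function level; the pipeline configuration uses 40 ms) suppresses
single-sample label flickers at low-field moments; see "Known
limitations" for why this matters at 1 kHz.

## Statistics and prediction

Group comparisons use Student's pooled-variance two-sample t
(identical whether computed from raw vectors or mean ± sd summaries —
which is how the published demographic tables are reproduced at the
desk), Pearson chi-square without continuity correction for 2×2 sex
tables, Pearson correlation with two-sided p from the t distribution,
and Benjamini–Hochberg FDR across the 24 features (a per-family variant
is available). The pooled form rather than Welch is used because it is
what the published summary statistics reproduce; Welch is exposed for
sensitivity analysis.

Response prediction is XGBoost (learning rate 0.01, max depth 6, min
child weight 2, reg_lambda 1) under stratified 5-fold cross-validation:
each fold serves once as the 20 % test set; early stopping (patience
50, cap 500 rounds — a slow learning rate needs many rounds) monitors
an inner stratified 20 % split of the training fold so the test fold
never informs model selection. Metrics are computed per fold and pooled
over out-of-fold scores; AUC is the midrank Mann–Whitney statistic.
Feature importance is total split gain averaged over the five fold
models. Remission follows the strict rule: reduction rate > 0.30 *or*
post-treatment HAMD-24 < 7.

## The synthetic cohort generator

Real patient recordings are not publicly deposited, so validation runs
on cohorts with known ground truth. The generator emulates eyes-open
resting EEG at the study scale — a 60-channel 10-10 montage at 1 kHz,
5-minute recordings — as:

* a **semi-Markov label path**: run lengths geometric per sample with
  per-class mean dwell; the successor class drawn from the entry rates
  restricted to the other classes (consecutive runs always differ);
* **rendering**: sample = activation × class template + spatially
  correlated Gaussian noise, then average-referenced. The activation is
  |g(t)|·σ_env with g a unit-variance Gaussian process band-limited to
  15 Hz: marginally a |Gaussian| of sd `gfp_envelope_sd`, nonnegative
  (polarity flips are *not* simulated; polarity invariance is exercised
  by explicit sign-flip tests), and temporally smooth like real
  oscillatory EEG — a temporally white activation would put ~94 % of
  its power outside the 1–30 Hz analysis band and make the recording
  physically implausible. Noise is white in time, mixed across channels
  by a Gaussian distance kernel (smoothness 0 = white in space).

Defaults (one choice, stated here): mean dwells (60, 75, 90, 110) ms —
distinct per class, inside the 60–120 ms range reported for resting
microstates, so that rank-based validation is informative; equal entry
rates 0.25; activation sd 50 µV (typical GFP a few µV); noise sd 4 µV
with smoothness 0.15, giving a mean per-sample |correlation| of ≈ 0.70
between each sample and its generating template — a deliberately
moderate SNR; per-subject lognormal parameter variability with CV 0.1;
HAMD-24 scores normal per group, truncated to the 0–76 scale, with
group means taken from the published clinical summaries; depressed
cohorts carry a 30 % microstate-D dwell deficit and a 20 % class-C
entry-rate reduction. Canonical template geometry (diagonal tilt 0.5,
bump width 0.35) keeps the six pairwise map |correlations| balanced at
≈ 0.15–0.55, so no class is disproportionately easy or hard to confuse.
Seeding is hierarchical (cohort seed + subject index via NumPy seed
sequences); identical specs reproduce byte-identical cohorts.

### What the validation shows — and does not

The validation battery (`eegstates.validation`, reproduced by
`scripts/acceptance.py`) establishes, at the study conditions above:
group templates recover the generating maps with |corr| > 0.95 (measured
≈ 0.998) on 20-subject cohorts; group-template GEV ≈ 0.74; noise-free
recordings are segmented exactly (GEV = 1) and are invariant to
arbitrary polarity flips; the overall mean duration at an 80 ms uniform
dwell condition is recovered within 5 % from the full backfit of
rendered 5-minute recordings; a planted 30 % duration-D deficit
(n = 40 vs 70) is detected after FDR in ≥ 90 % of replicates (50
replicates used) while shuffled labels give ≈ 5 % per-feature type-I
error (500 permutations); and prediction reaches AUC > 0.95 on a
strongly separable responder cohort, collapses to ≈ 0.5 under label
permutation, and ranks a single planted informative feature first by
total gain.

None of this certifies performance on real EEG: the generator has no
artifacts (ocular/cardiac removal is a no-op hook), no volume-conduction
forward model, discrete topography switches rather than oscillatory
field reversals, and geometric dwell distributions. Passing tests show
the *estimators* are correct and well calibrated, not that real PSD
patients have these effect sizes.

## Numerical and design choices

* **Filter**: 4th-order Butterworth per pass, applied forward-backward
  (zero phase). Filtering and average-referencing commute (both
  linear); the pipeline filters first.
* **Interpolation**: inverse-distance weighting (power 2) over montage
  coordinates rather than spherical splines — sufficient for the
  synthetic data this package ships with, and the interface leaves room
  for a spline backend for real high-density recordings.
* **Tie-breaks**: lowest class index everywhere; all stochastic steps
  are generator-seeded.
* **Group templates are computed per group** (a shared-template flag is
  available), and backfitting labels *all* samples, not only GFP peaks.
* **Recovery analyses backfit the rendered recordings directly** rather
  than band-passing them first: the synthetic signal is already
  in-band, and a 1 Hz high-pass would subtract the nonzero time-mean
  map that the nonnegative-activation design produces — a generator
  artifact with no analogue in real, polarity-oscillating EEG. The
  filter itself is verified separately on sinusoids.
* **FDR family**: all 24 features at once by default; per-type families
  (durations / occurrences / contributions / transitions) by flag.
* **Early stopping** uses an inner training split, never the test fold;
  without this the permutation-null AUC is visibly optimistic.

## Known limitations

* With the 40 ms label-smoothing window off, the |Gaussian| activation's
  zero crossings fragment backfit runs at 1 kHz and mean durations
  collapse to a few ms; the window is therefore part of the pipeline
  configuration. Window widths beyond ~40 ms over-merge and inflate all
  durations.
* The backfit duration estimator carries a small class-conditional bias
  at moderate SNR (the most distinctive map, D, is over-estimated by
  ~10 %; mutually confusable gradients by −3 %). Consequently,
  per-subject rank-order recovery of duration/contribution is evaluated
  on cohorts without per-subject parameter variability, where the
  target ordering is well defined (measured 100 % of subjects); with CV
  0.1 variability, ~15–20 % of subjects draw near-tied or swapped true
  parameters for adjacent classes, and no estimator could recover a
  rank for them (measured ≈ 75–80 %, reported as a diagnostic).
* The exhaustive-partition oracle for AAHC is limited to ≤ 12 maps and
  k = 2 by combinatorics.
* EDF support is plain 16-bit single-rate EDF: reading via MNE with a
  header check that rejects mixed-rate files, writing via a minimal
  built-in writer (metadata fields are not preserved beyond labels,
  rate and physical ranges).
* Problem sizes in the shipped studies (20-subject recovery cohorts, 50
  power replicates, 500 permutations, 5 permutation seeds for the
  prediction null) are the package's chosen trade-off between
  statistical resolution and a few minutes of single-CPU runtime;
  every study function takes size parameters for larger runs.
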