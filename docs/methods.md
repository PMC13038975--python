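# Methods

## The model

EEG microstate analysis summarizes the multichannel scalp potential at each
moment by the best-matching member of a small set of template topographies.
Classically the match ignores the sign of the map — a topography and its
negation count as the same state. This package implements the
*polarity-considered* variant: every base template map `T` is paired with its
negation `-T`, and the winner-take-all assignment runs over the signed set.
For five base maps (named A–E by convention) this yields ten signed states
(A+…E+, A−…E−) and a label alphabet of integers 0–9, where 0–4 index the
"+" maps in template-file order and 5–9 their "−" partners.

The labeling pipeline for one epoch is:

1. slide a window grid over the epoch (half-open windows `[s, s+length)`;
   a window fits when `s + length ≤ t_end`);
2. average each window over time, channel-wise, to one topography;
3. average-reference the topography and compute its Pearson correlation
   across channels with every template (templates are stored zero-mean and
   unit-norm, so the correlation reduces to a dot product);
4. assign the argmax of the *signed* correlation over the 2k signed
   templates (polarity considered), or of the *absolute* correlation over
   the k base maps (polarity ignored).

Because `corr(u, -T) = -corr(u, T)`, the polarity-considered winner is
always the polarity-ignored winner's base map, with the sign of the
correlation selecting the + or − partner. This identity is asserted by a
property test.

The resulting integer sequences are the classification features (ordinal
coding, one integer per window). A one-hot representation exists behind a
flag in the analysis utilities but the classifiers consume the raw integer
sequence, which is the representation the labeling stage naturally emits.

## Windows and time conventions

Time is in seconds internally; the sample index of time `t` is
`round((t - tmin) * sfreq)`. Two canonical grids are used: 100 ms windows at
25 ms steps (75% overlap) for occurrence-frequency maps and the temporal
generalization matrix, and 10 ms windows at 1 ms steps (90% overlap; 391
windows on 0–400 ms) for classification features. Both are plain
`WindowSpec` values and fully configurable.

Degenerate windows (zero-variance topography, correlation undefined)
receive the sentinel label −1 and are forward-filled from the previous
window by default; a leading sentinel survives and is excluded from
frequency counts, while classifiers impute it with the per-window modal
label of the training fold (fit inside each fold, so no leakage).
Exact correlation ties break to the lowest template index — deterministic,
and in practice a measure-zero event.

## Template derivation

Templates can be read from TSV or derived from data: the global field power
(GFP — the spatial standard deviation of the average-referenced map) is
computed per sample, maps are extracted at strict GFP local maxima at least
10 ms apart (at most 2,500 per recording, uniformly subsampled with a
seed), and clustered with a polarity-invariant modified K-means:

- assignment by maximal *squared* spatial correlation (so `u` and `-u`
  always co-cluster);
- centroid update by the dominant eigenvector of the members' scatter
  matrix;
- explained variance = mean squared correlation of each map with its
  assigned centroid; iteration stops when it improves by less than `tol`
  (default 1e-6) or after 500 sweeps; best of 20 seeded restarts kept;
- empty clusters reseeded with the currently worst-explained map;
- returned maps sign-fixed so the channel with the largest absolute loading
  is positive (polarity semantics enter only via explicit expansion).

Initialization draws k maps without replacement. These numerical choices
(restarts, tol, max_iter, init, empty-cluster rule, sign convention) are
the package's own defaults; they are recorded here because the algorithm's
definition does not pin them down.

`average_centroids` builds the 7-template "artificial" variant by appending
re-normalized means of base-map pairs (e.g. A/B and D/E).

## The synthetic oddball generator

The recordings the method was designed for are not redistributable, so the
package ships a generator that emulates their statistical structure with
known ground truth:

- 32 channels (10-10 names), epochs −200 to 1000 ms at 1000 Hz, 320
  standard and 80 target trials by default;
- per trial, a piecewise-constant sequence of signed microstate segments;
  segment durations are geometric at sample resolution (memoryless, mean
  80 ms by default — the middle of the 60–120 ms range typical of
  microstate literature);
- each segment's signed label is drawn from a class-conditional,
  piecewise time-varying categorical prior. The default standard-class
  prior is uniform over the ten signed labels; the target-class prior
  boosts C+/E+ to 0.25 each in 0–200 ms, C−/D−/E− to 0.20 each in
  200–400 ms, and C+/E+ again after 500 ms — the oddball occupancy pattern
  the labeling stage is meant to resolve;
- EEG = amplitude (5 µV) × envelope × signed template map + spatially
  correlated Gaussian noise (2 µV per channel by default), then
  average-referenced. The envelope is a rectified 10 Hz sinusoid: GFP waxes
  and wanes within a segment without flipping the topography, because
  polarity is a property of the map, not the envelope;
- noise is i.i.d. Gaussian per channel mixed by a symmetric Toeplitz
  matrix with unit-norm rows (`smoothness**|i−j|` decay), giving
  controllable spatial correlation at constant per-channel SD;
- base template maps are smooth random maps, pairwise orthogonalized.
  Canonical A–E values are not public, so these are synthetic stand-ins —
  orthogonality makes planted-label recovery exact in the noiseless limit.

Because segment labels are drawn at segment *onset*, segments started
before a prior change persist across it with the memoryless mean duration
τ: a window-averaged occupancy effect over a span T is attenuated by
`1 − (τ/T)(1 − exp(−T/τ))` relative to the asymptotic prior difference.
Tests account for this carryover explicitly.

What the generator does not emulate: volume conduction from dipolar
sources (no lead field), ocular/muscle artifacts, inter-participant
topography variability, or 1/f spectral structure. Passing tests therefore
demonstrate correctness of the *pipeline mechanics* — labeling, counting,
cross-validation, statistics — not field-ready decoding performance on
real EEG.

Two derived configurations support calibration experiments:
`null_oddball_config` gives both classes the same uniform prior (no class
effect — downstream AUC must sit at chance), and
`polarity_contrast_config` makes the classes differ *only* by sign
(standard trials draw from the "+" block, target trials from the "−"
block), so polarity-ignored labeling is blind to the effect by
construction while polarity-considered labeling separates the classes.

## Classification

Six model families: SVM, Random Forest, Logistic Regression, XGBoost and
LightGBM gradient boosting, and an unsupervised 2-means baseline (clusters
mapped to their majority training class, prediction by nearest centroid,
score = signed centroid-distance difference). Evaluation is nested
five-fold cross-validation at the trial level: stratified outer folds score
held-out trials (20% each; every trial predicted exactly once out-of-fold),
and an inner five-fold grid search maximizing F1 selects hyperparameters
per outer fold before refitting on the full outer-training set.

F1 uses "target" as the positive class: `F1 = 2TP / (2TP + FP + FN)`,
defined as 0 (with a warning) when the denominator vanishes. AUC is pooled
over the out-of-fold scores (per-fold AUCs are also reported) in the
Mann–Whitney form with ties counted 0.5.

The SVM grid is C ∈ {0.01, 0.1, 1, 10, 100}, kernel ∈ {linear, rbf,
sigmoid}, gamma ∈ {scale, auto, 1}. Grids for the other families are
modest package defaults (trees ∈ {100, 300}, depth ∈ {3, 6, unlimited};
L2 strength ∈ {0.01…10}; boosting learning rate ∈ {0.05, 0.1}, depth
∈ {3, 6}) and fully user-overridable. LightGBM runs with
`min_child_samples=5` because trial-level EEG folds often hold only a few
dozen trials per class, where the library default of 20 forbids any split.

The temporal generalization matrix trains at each interior window on the
three-window feature (t−1, t, t+1) and tests at every interior position;
boundary windows are excluded rather than padded, so the matrix is
(n_windows − 2)². The inner hyperparameter search runs per training window
by default (`search=False` fixes the first grid value instead).

## Statistics

Occurrence frequency of label l in window w is the fraction of trials
labeled l there, per class; sentinel windows are excluded from the counts
(columns then sum to < 1, which is reported rather than renormalized away
in the frequency maps). Per-participant trial-averaged one-hot time courses
equal this quantity and feed the group statistics.

Class differences are tested per label with pointwise one-sample
t-statistics across participants, thresholded two-sided at p < 0.05
(t distribution, df = n − 1). Maximal supra-threshold runs form temporal
clusters scored by summed |t|; the null distribution is the maximum cluster
mass over 1,000 permutations. The default permutation scheme flips the sign
of whole participant difference time-series, which preserves temporal
autocorrelation; a circular-shift-in-time scheme is available as an
alternative reading of "shuffling restricted to the temporal dimension".
P-values use the (1 + exceedances)/(1 + n_perm) correction. Note that a
draw flipping *every* participant reproduces |t| exactly, so the smallest
attainable p exceeds 1/(1 + n_perm) by the count of sign-symmetric draws —
a property the tests pin down. Windows with zero variance across
participants (t undefined) are excluded and reported.

Participant rows are canonically sorted before the null is drawn; the
one-sample t is permutation-invariant in participants, so this changes no
observed statistic but makes cluster p-values independent of participant
ordering.

Benjamini–Hochberg FDR runs over the cluster p-values pooled across all
labels (per-label pooling behind a flag); correction is applied at the
cluster level, not pointwise. `split_by_prediction` partitions trials by
out-of-fold correctness so the same analysis can be repeated on correctly
and incorrectly classified trials.

## Reconstruction and DISS

The trial-averaged one-hot label distribution at each window weights the
(unit-norm) template maps; their sum is the reconstructed topography.
Fidelity against the grand-averaged EEG window map is measured by global
dissimilarity, `DISS(u, v) = ||u/||u|| − v/||v|||| = sqrt(2 − 2r)` with r
the spatial cosine: 0 for identical configurations, 2 for polarity-inverted
ones. Both maps are channel-mean-subtracted before normalization, making
the measure well-defined for raw (non-average-referenced) imports; this
convention is deliberate and documented because the bare formula does not
subtract means. Windows whose grand average cancels to a zero map (e.g.
trials split evenly between a template and its negation) are flagged and
excluded from the mean with the count reported, since DISS is undefined
there.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the pipeline at desk scale:
null-calibration at 100+100 trials × 10 seeds, planted-template recovery at
1,500 maps, type-I calibration at 200 replicates × 500 permutations, and
polarity-advantage runs at 40+40 trials × 5 seeds with reduced
hyperparameter grids. These sizes were chosen so each property is resolved
well beyond its tolerance by a single CPU; the underlying defaults
(320/80 trials, full grids, 1,000 permutations) remain the package
defaults for analysis use.

## Known limitations

- The generator's channel "geometry" is the channel ordering; spatial
  noise correlation and map smoothness are along that ordering, not true
  scalp distance.
- The K-means baseline's cluster-to-class mapping (majority vote) is one
  defensible choice among several; its chance-level behavior is the only
  property relied upon.
- Balanced classes are assumed downstream of `balance_trials`; unbalanced
  input triggers a warning, not reweighting.
- No temporal smoothing / minimum-duration relabeling of label sequences,
  and no threshold-free cluster enhancement; clusters are temporal only.
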