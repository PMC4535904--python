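# Methods

## Input model

The unit of observation is one running cycle of one body side, represented
by nine sagittal-plane angle waveforms (foot, ankle, knee, hip, pelvis,
spine, thorax, neck, head; degrees). Marker processing, smoothing and
event detection are assumed done upstream; the pipeline starts from
per-cycle angle series. Each waveform is resampled to `n_time`
equidistant points spanning 0–100% of the cycle inclusive (default 201),
using a natural cubic spline (linear for series shorter than four
samples); upstream kinematics are already spline-smoothed, so a cubic
interpolant neither adds nor removes structure at this density.

## Standardization

The assembled matrix has one row per trial-side and 9 × `n_time` columns
(1809 by default). Per-column means over all rows are subtracted. For the
scale there are two defensible readings: unit SD per *column*, or one
pooled SD per *variable set* (one angle's whole 201-point block). The
default is block pooling — the block is divided by
`sqrt(mean(centered_block²))`, computed over all rows and the block's
columns — because per-column scaling would flatten the time-dependent
variance structure of the cycle, which is exactly the information the
variability-weighted analyses rely on. Per-column scaling remains
available as `standardize(..., mode="column")`. Both directions of the
mapping are exposed (`standardize_row`, `inverse_standardize`), and the
inverse is exact to machine precision; all back-projected angle profiles
go through it.

A zero-variance block (constant angle over all trials) has no defined
scale and raises a degenerate-data error rather than silently dividing by
an epsilon.

## Clustering

K-means with the squared-Euclidean objective, greedy spread-out (k-means++)
seeding, and best-of-`restarts` selection by inertia (defaults: 25
restarts, fixed seed, so the chosen model is reproducible). The number of
clusters is the candidate with the highest mean silhouette (Euclidean);
ties break toward the smaller K. The default scan range 2–40 keeps any
plausible optimum for a 20-subject cohort interior to the range. Mean
silhouettes at or below 0.5 trigger a "weak structure" warning, following
the usual silhouette interpretation bands. A clustering in which every
cluster is a singleton has silhouette 0 by convention.

The merge tree uses Ward linkage by default — its variance objective is
the agglomerative counterpart of K-means — and exports as a scipy linkage
matrix, nested lists, or Newick text. Loading-rate tables are plain
contingency tables normalized per group; the per-group figure reported in
summaries is the maximum rate over clusters, so "fully combined in one
cluster" reads as rate 1.

## Classification

Each two-group comparison trains a linear-kernel SVM (regularization
C = 1.0, exposed in the config; at these n/p ratios — tens to hundreds of
rows against 1809 columns — groups are typically separable and the
solution is insensitive to C, but fixing it keeps runs reproducible) and
evaluates it by leave-one-out at the single-row level: one trial-side per
fold, both sides of a subject participate. Internally the linear Gram
matrix is computed once per comparison and each fold solves the same
maximal-margin problem on the cached kernel, which changes nothing about
the solution and avoids re-computing 1809-dimensional dot products per
fold. Zero decision values resolve to the first group, for determinism.

Significance: the smallest c with `P(X ≥ c) ≤ α` for X ~ Binomial(n, 0.5),
α = 0.05, computed from exact tail sums per comparison's actual n — so
comparisons with unequal trial counts get their own critical counts. For
n ≤ 4 no attainable count is significant and the comparison is reported as
non-significant with `critical_count = None`.

Discriminant profiles are the unit-normalized SVM weight vectors; the
selected variables are exactly `{i : |wᵢ| > 2·SD(w)}` (for roughly normal
weight vectors this keeps ≈ 4.6% of columns). Group means are
back-projected to degrees; the weight vector itself is reported per angle
block in standardized units, since its angle-space magnitude has no single
natural unit.

## Symmetry index

Per subject × condition: with at least two trials per side, the left mean
waveform is subtracted from the right, each point is divided by the pooled
SD `sqrt((var_L + var_R)/2)` (equal-weight pooling of the two sides'
sample variances, ddof 1), the signed quotients are summed over the full
concatenated waveform, and the absolute value is taken. Summing *signed*
differences before the absolute value allows opposite-signed asymmetries
to cancel across the cycle; that is the stated definition of the index and
is kept as the default (an angle-subset switch is available, e.g. a
lower-limb-only index). Points with pooled SD below 1e-9° are excluded
with a warning to avoid division blow-ups on degenerate synthetic inputs.
The index is invariant to swapping sides, zero for identical sides, and
its magnitude grows with the number of summed points — absolute values are
therefore comparable only within a fixed layout.

## Statistical battery

* Kruskal-Wallis (tie-corrected H, chi-square p) across the four
  conditions; identical data short-circuit to H = 0, p = 1.
* Friedman chi-square within complete subject blocks (incomplete blocks
  dropped with a warning); the two-condition case falls back to the direct
  rank formula since the scipy routine requires three groups.
* Wilcoxon-Mann-Whitney with a hand-computed tie-corrected normal Z (no
  continuity correction), because the effect size of interest is
  Rosenthal's r = |Z|/√N with the 0.1/0.3/0.5 low/medium/large bands; U is
  cross-checked against scipy in the tests.
* Holm step-down (statsmodels) for the post-hoc families: pairwise
  condition comparisons after Kruskal-Wallis, and paired t-tests after the
  running-speed repeated-measures ANOVA. Speed enters as subject ×
  condition means; all-identical speeds short-circuit to F = 0, p = 1.
* The sex-subgroup analysis (Friedman per sex, Mann-Whitney between sexes
  per condition) is run un-corrected, as a secondary analysis.

## Synthetic cohorts

Each angle waveform is a sum of: a fixed smooth population template
(two-harmonic Fourier shapes with per-angle offsets and amplitudes roughly
tracking sagittal range of motion during running; no physiological-fidelity
claim); a per-subject offset waveform (scale `sigma_subject`); a
per-subject × condition perturbation for each non-reference condition
(scale `delta_cond`), constant across that subject's trials; a per-subject
asymmetry waveform added to the right side only, scaled `alpha_neutral` in
the reference condition and `alpha_splint` otherwise; and per-trial smooth
noise (scale `sigma_trial`). All random components are Fourier series with
harmonics 0..`n_harmonics` (default 4) and i.i.d. normal coefficients
scaled so the pointwise variance equals the requested scale squared —
smooth and exactly cyclic, as time-normalized kinematics are; white noise
would be unrealistically rough. Which side carries the asymmetry is
irrelevant to a side-difference index, so it is fixed to the right.

Defaults, chosen once as a plausible recreational-runner regime: 20
subjects (25% female), 4 conditions, 5 trials per condition and side,
`sigma_subject` = 4.0°, `delta_cond` = 1.5°, `alpha_neutral` = 1.5°,
`alpha_splint` = 0.5°, `sigma_trial` = 0.75°. The subject-to-trial
variance ratio (5.3) puts the cohort in the regime where subjects are
recoverable by clustering; the condition effect is double the trial noise,
so within-subject condition classification is strong; asymmetry is three
times larger without a splint than with one. Per-trial running speeds are
drawn around 3.4 m/s with no condition effect, matching the design where
speed is a controlled covariate. `drop_trials` thins a cohort to emulate
excluded trials (e.g. 800 → 682 rows) while guaranteeing at least one
trial per subject × condition × side cell.

What the generator does **not** emulate: inter-angle correlation beyond
the shared template, speed-kinematics coupling, non-stationary fatigue
effects, or realistic missingness patterns. Green tests on synthetic data
therefore validate the *computational chain* (recovery of injected
structure, calibration under the null), not biomechanical claims about
real cohorts.

Two emergent properties of this regime are worth noting when comparing
with real cohorts. First, because each subject's condition perturbation is
consistent across trials, the pooled across-subject condition comparison
can sit well above 0.5 even though there is no shared condition direction:
under leave-one-out, the held-out trial's subject × condition cluster-mates
remain in the training set and a high-capacity linear separator can use
them. In real cohorts with weaker effect-to-noise ratios this rate drops
to chance; with `delta_cond = 0` the pipeline's rates are calibrated at
0.5, which is the property the null test checks. Second, the symmetry
index sums ~1800 normalized points, so its absolute scale (hundreds under
the defaults) is much larger than for indices computed on data whose
side-differences cancel more strongly; only ordering and ratios across
conditions are meaningful comparisons.

## Problem sizes used in the shipped checks

The test suite and acceptance script pick cohort sizes as the package's
own trade-off between statistical resolution and desk-scale runtimes: the
subject-recovery and headline acceptance runs use the full 20 × 4 × 5 × 2
design (682 rows after thinning); the condition-effect monotonicity grid
uses 4 subjects × 5 trials at 101 time points over `delta_cond` ∈
{0.25, 0.5, 1, 2} with 10 seeds; the asymmetry grid uses 6 subjects over
`alpha` ∈ {0, 0.5, 1, 2} with 10 seeds; the null calibration uses 8
subjects × 4 trials with `delta_cond = 0` over 10 seeds. Oracle checks
(exhaustive K-means partitioning, direct silhouette and rank-test
formulas, enumeration-based Mann-Whitney, exact binomial tails) run at
n ≤ 10.

## Known limitations

* The silhouette scan is a heuristic; on data without block structure it
  still returns an argmax (with a weak-structure warning) rather than
  declining to choose.
* Friedman is not tie-corrected in the denominator (scipy's convention);
  with heavily tied symmetry values its p is conservative.
* `read_matlab_database` is a best-effort adapter: it needs the variable
  names of the deposited matrix and labels supplied by the caller and does
  not handle split archives itself.
* The Mann-Whitney p uses the normal approximation even at small n, where
  exact enumeration would differ; the effect size, not the p, is the
  primary output of the subgroup analysis.
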