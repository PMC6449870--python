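# Methods

This note documents the statistical models, the synthetic-data generators,
and the numerical choices behind `reprophen`. The package analyses
high-content RNAi screens of early reprogramming: per-well colony feature
tables, a transcriptome time course with knockdown samples, and
single/double-knockdown colony counts.

## Screen normalization and feature selection

Each physical plate is a batch: every feature is Z-scored within its plate,
`z = (x − mean)/SD`, using the sample SD (ddof 1) over **all** wells of the
plate, controls included — plate statistics are a sample, and the
normalization is applied "per plate" with no stated exclusions, so none are
made. A feature that is constant on a plate carries no within-plate signal;
it is set to zero with a warning rather than propagating a division by
zero. Replicate wells are averaged per knockdown arithmetically; missing
wells are skipped (never imputed) and the replicate count is recorded.

Redundant features are eliminated greedily: features are scanned in
descending-variance order (ties broken by name, so the scan is
deterministic) and a feature is retained only if its absolute Pearson
correlation with every already-retained feature is ≤ 0.8. Variance ordering
keeps the most informative member of each redundant group; the retained set
provably satisfies the pairwise constraint, every dropped feature conflicts
with a retained one, and re-applying the filter is a no-op. These three
properties are verified against an independently coded oracle on all small
inputs in the test suite.

## Phenotype clustering and hit ranking

Knockdown profiles are partitioned by K-means (k-means++ initialization,
10 restarts, fixed seed; default k = 5, exposed as a parameter since the
choice of k is an empirical observation, not a derived quantity). Features
are ordered for display by Euclidean average-linkage hierarchical
clustering; the linkage choice only affects display. The cluster report
counts nt and positive controls per cluster and flags the cluster with the
most nt controls as the reference phenotype.

Two rankings are combined. (1) Each knockdown's profile is
Pearson-correlated with each positive-control profile; the per-control
correlations are combined by their arithmetic mean — a symmetric,
scale-free choice (a `max` combination is available). (2) An ensemble of
two deliberately different classifier families — a regularized logistic
model and a random forest — is trained on known facilitators versus all
remaining knockdowns (no positive-unlabelled correction: the unlabelled
set is treated as negative, which biases scores conservatively), and the
two predicted probabilities are averaged. Performance is reported as the
AUC of cross-validated ensemble probabilities (stratified 5-fold); the
chance baseline is estimated by label permutation with lighter model
settings (fewer trees, 3 folds), which does not move the chance level.
Hits are the union of the top-N combined-correlation scores, the
knockdowns above an ML-score quantile, and an explicit user inclusion list
for low-scoring "roadblock" candidates.

## Transcriptome correlations

Counts are normalized to counts-per-million and transformed as
log2(CPM + 1). "Most variable" genes are ranked by the variance of the
log-normalized values — the log scale prevents high-abundance transcripts
from dominating the ranking — with a deterministic tie-break by gene id.
Replicates are averaged per condition before correlating; correlation
matrices are symmetrized and given an exact unit diagonal. The cross-modal
table lists, per knockdown pair, the expression correlation, the
high-content feature correlation, their product (a both-axes concordance
score), and a flag for pairs exceeding user thresholds (default 0.7) on
both axes.

## Pseudotime projection

The progression model embeds all samples (time course and knockdowns
together) by PCA on the centered log-normalized top-variable genes, swaps
the axes so x = PC2 — the component that tracks time in this design — and
rotates all coordinates rigidly by 15° (counter-clockwise positive; the
sign is exposed). PCA leaves two sign ambiguities, and both are fixed
deterministically: x is oriented so time-course day increases with x, and
y so the time-course arc opens downward (correlation of y with the squared
centered day ≤ 0). Without the second convention the unsigned rotation
would be applied to an arbitrarily reflected embedding.

A second-order polynomial `y = c₀ + c₁x + c₂x²` is fitted by OLS to the
per-day means of the rotated time-course samples within the fit range
(default days 2–7). Degree 2 is fixed: the trajectory is a single smooth
arc and higher degrees invite extrapolation artifacts.

Every sample is then projected onto the curve by minimizing the squared
distance `D(x) = (x − p_x)² + (f(x) − p_y)²` — a quartic — exactly: the
cubic `D'(x) = 0` is solved (numpy companion-matrix roots), real roots are
clamped to the fit domain, the endpoints are added, and the global minimum
is taken. Beyond-domain projections clamp to the endpoints because
extrapolating a quadratic is unreliable. Equidistant candidates resolve
toward smaller x (earlier pseudotime), which is conservative for "delayed"
calls. The projected x is the pseudotime proxy; `√D` is the off-trajectory
residual. Day estimates interpolate a calibration table built from each
time-course day's own projection (made monotone by a running maximum,
clamped at the ends), which makes statements like "comparable with day 3–4"
well defined even where x compresses nonlinearly in day. A knockdown is
flagged delayed when its day estimate trails the nt control's by more than
a threshold (default 1 day).

## Epistasis test

Colony ratios divide each condition's replicate counts by the mean of the
control replicates (the control mean is the sole denominator; replicates
are not paired). Under independent knockdown effects the expected double-
knockdown ratio is the product of the two single-knockdown mean ratios;
the interaction test asks whether the observed double-knockdown ratios
deviate from that product (two-tailed; a positive deviation — more
colonies than expected — is an alleviating interaction).

The expected product is *estimated* from two single-knockdown means and
the shared control mean, and carries roughly three times the sampling
variance of the observed mean it is compared against (four lognormal
means contribute; the shared control partially cancels). Treating it as a
known constant therefore inflates the type-I error several-fold — at
cv = 0.1 with 6 replicates the nominal 5% test rejects ~25% of true nulls.
The default test instead propagates this uncertainty by the delta method
over all four sample means (the control's gradient term captures its
appearance in both the observed ratio and the expected product), with
Welch–Satterthwaite degrees of freedom. Monte-Carlo calibration over
10,000 simulated null pairs puts the empirical rejection rate at ~0.045
for α = 0.05, and power ≈ 1 at γ = 2. The fixed-expected one-sample
variant remains available (`propagate=False`) and its anti-conservatism is
itself asserted by a test. With zero variance everywhere the test
degenerates to an exact comparison, flagged as such. Every statistic is
invariant to rescaling all counts by a common factor.

The Monte-Carlo calibration utility is vectorized across pairs for speed;
a unit test pins its statistic to the per-pair analysis path on identical
data, so the calibration exercises exactly the formula applied to user
data.

## Synthetic-data generators

All generators are deterministic given their config (including the seed)
and return the planted truth alongside the data.

**Screen.** Six 96-well plates, 300 library targets split across plates,
seven nt controls and three positive controls (Trp53, Myc, Oct4) on every
plate, four replicate transfections. Each of five phenotype classes has a
fixed Gaussian archetype scaled by `class_effect_size` (default 3
feature-SD units); each plate×replicate adds a batch offset
(`plate_effect_sd`, default 1) that per-plate Z-scoring removes; wells add
i.i.d. Gaussian noise (`noise_sd`, default 1). Additive Gaussian noise is
the simplest model matching Z-scored feature data. Class proportions
default to (0.10, 0.35, 0.25, 0.22, 0.08); class 1 is the facilitator-like
archetype, the last class the blocker archetype shared with the Myc/Oct4
controls (severe-impairment phenotype), nt controls carry the class-2
("normal") archetype and Trp53 a normal-like one — mirroring where those
controls fall in the real screen. Roles follow classes (class 1 →
facilitator, last class → blocker, otherwise neutral), so blocker recall
and facilitator AUC are well-defined recovery targets. The effect/noise
defaults are not calibrated to the real screen (the paper's per-feature
noise magnitudes are unpublished); they define a regime in which the
pipeline should succeed, so passing tests demonstrate correct machinery,
not real-data performance.

**Time course.** Expression follows a one-dimensional trajectory in a 2-D
latent space: a linear "time" axis (1 latent unit/day) and a quadratic
"arc" axis (amplitude 0.95), centered over days 0–7. The arc axis carries
more variance than the time axis so that PC2 — not PC1 — tracks time, as
in the real data. The trajectory's linear tilt is calibrated per design so
that the principal frame of the full sample cloud sits exactly 15° from
the trajectory's symmetry frame: the standard analysis (swap, rotate 15°,
quadratic fit) is then exactly the right model for the planted data, and
planted quantities are recoverable without structural misfit. The
calibration search stays on the branch contiguous with the untilted
design; a second root exists at large positive tilt but leaves PC2 with so
little variance that the embedding drowns in measurement noise. Knockdowns
sit at planted progression points (default: nt at day 5.7, the rest evenly
spaced over days 2.5–6.8, inside the fitted range) and are displaced along
the local outward normal — away from the arc's concave side, where the
foot point of the orthogonal projection is unique — by offsets following a
fixed interleave spanning 0–5 latent units. The interleave is deliberately
not seed-dependent: the planted design is a constant study layout, and
only measurement noise varies across seeds (seed-random offset assignments
perturb the principal frame and occasionally fold the embedding,
confounding recovery tests with design variation). Latent positions map to
per-gene log-rates through a Gaussian loading matrix balanced against
baseline abundance, so trajectory movement preserves total expression to
first order — otherwise the per-sample CPM normalizer varies nonlinearly
along the trajectory and bends the geometry the projection is meant to
recover. Counts are negative-binomial (dispersion 0.1, a typical bulk
replicate-to-replicate value) scaled to an expected 500,000 counts per
sample, with 2,000 genes and three replicates per condition. The generator
emulates smooth trajectories and orthogonal perturbations only — not
batch effects, discrete cell-state switches, or mapping artifacts — so
recovery results bound what the method can do on clean data, not on
arbitrary real data.

**Colony counts.** Expected counts follow the multiplicative model exactly
(`E[AB] = control_mean · e_A · e_B · γ`), with mean-preserving lognormal
noise at a stated coefficient of variation — the natural noise model for
positive count ratios — and 6 replicates, matching the confirmatory
design. Defaults plant alleviating interactions (γ = 2.0, 1.8, 1.4) on the
Brca1–Bard1, Wdr5–Brca1 and Wdr5–Bard1 pairs over single-knockdown effects
of 0.35, 0.40 and 0.30.

## Problem sizes and determinism

The demo and the acceptance script use the default study conditions
throughout: the 6×96-well screen in quadruplicate, 2,000-gene time courses
with 30 knockdowns, ten simulation seeds for recovery statistics, 1,000
random instances for the projection-optimality check, and 10,000 simulated
pairs for the epistasis null. These sizes make every run complete in about
a minute on a single CPU while keeping Monte-Carlo error small. All
randomness flows from explicit seeds; outputs carry the config hash and
seed, and reruns are bit-identical.

## Known limitations

* The greedy feature filter is order-dependent by design; a different
  retention rule (e.g. keep-last or clustering-based) would retain a
  different, equally valid non-redundant set.
* The facilitator ensemble treats unlabelled knockdowns as negatives;
  true-but-unknown facilitators in the library depress its scores.
* The pseudotime model assumes a single smooth arc; trajectories that
  branch or self-intersect violate the quadratic model and the projection
  becomes ill-posed where the curve folds.
* Day estimates outside the fitted day range clamp to its ends; "earlier
  than day 2" and "later than day 7" are not distinguished further.
* The epistasis module tests one pair at a time (a confirmatory design);
  it applies no multiple-testing correction across many pairs.
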