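# Methods

`dynconn` implements a resting-state functional-connectivity analysis chain —
motion quality control, group spatial ICA, static FC, sliding-window dynamic
FC with deep clustering, and case-control statistics — together with a
synthetic-cohort generator that provides ground truth for every stage. This
note records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Synthetic cohorts

Each subject carries `n_sources` (default 10) spatially independent sources:
disjoint half-cosine blobs over `n_voxels` (default 500) voxels plus faint
background, which makes the spatial maps sparse and therefore super-Gaussian —
the regime in which infomax ICA separates well. Source dynamics follow a
first-order Markov chain over `n_states` (default 4) covariance states with
stay probability 0.95 per TR, giving geometric dwell times with mean
1/(1−0.95) = 20 TR ≈ 18 s. At each timepoint the source vector is drawn from
a zero-mean Gaussian with the active state's covariance; voxel data are the
spatial mixing of the sources plus i.i.d. Gaussian noise (`noise_sd`, default
0.2 against unit-variance sources). Defaults mirror the target acquisition:
295 volumes at TR = 0.906 s, two groups of 10.

State covariances are built once per cohort from random rank-3 Gaussian
factors plus identity loading, rescaled to unit diagonal: this guarantees
symmetric positive definiteness, gives each state a distinct correlation
pattern (off-diagonals commonly |r| = 0.3–0.7, between-state pattern
correlations near zero), and differs between states in pattern rather than
power. A non-zero `group_effect` shifts all off-diagonal entries of the case
group's state covariances, with an eigenvalue floor restoring definiteness;
at 0 (the default) the two groups share one generative model, which is what
the null-calibration tests rely on.

Motion traces are a smooth random walk (translation steps σ = 0.05 mm,
rotation steps σ = 0.001 rad per frame) with occasional single-frame
translation spikes (rate `motion_spike_rate`, amplitude 0.5–2.5 mm). The
walk scales were chosen so mean framewise displacement sits near 0.3 mm,
typical of a school-age cohort that passes QC. Real head motion has richer
spectral structure (respiratory and slow drifts); the synthetic traces only
exercise the QC arithmetic and thresholds, so passing QC tests says nothing
about classifier-grade motion realism.

What the generator does **not** model: haemodynamic response convolution,
physiological noise, scanner drift, or spatial autocorrelation of the noise.
Recovery results on these cohorts therefore demonstrate correctness of the
pipeline's algorithms, not expected performance on scanner data.

## Quality control

Framewise displacement follows the Power formulation:
FD_t = Σ|Δd_i| + r·Σ|Δθ_j| with head radius r = 50 mm converting radians to
millimetres of arc. Maximum absolute displacement is the Euclidean distance
of the translation vector from the reference volume (the middle volume, the
usual motion-correction reference; configurable). Exclusion uses strict
inequalities: mean FD > 0.5 mm or maximum displacement > 4 mm. The motion
file dialect is six whitespace-delimited columns, rotations (radians) first —
the common realignment-output convention — with a switch to flip the order.
FD depends only on frame-to-frame differences, so it is invariant to constant
offsets, and scales linearly with the assumed head radius for pure rotations;
both properties are tested.

## Group spatial ICA

Timepoints are channels and voxels are samples. Per subject, temporal PCA
(SVD of the voxel-demeaned T×V matrix) keeps `n_subject_pcs` directions;
subjects are concatenated across time and reduced to `n_group_pcs` channels
by an EM principal-subspace iteration (Roweis' algorithm; cap 500 iterations,
tolerance 1e−6 on the largest principal angle between successive subspaces),
rotated to principal axes afterwards. An exact SVD route exists and serves as
the oracle in tests (principal angles < 1e−3 required).

Infomax ICA is written here in its natural-gradient form with the logistic
nonlinearity, ΔW ∝ (I + (1 − 2y)uᵀ)W, on internally whitened data, in
shuffled mini-blocks, with learning-rate annealing (×0.9 whenever the
Frobenius weight change grows) and convergence at weight change < 1e−6.
scikit-learn provides only FastICA, which is deliberately left out of the
implementation path so it could serve as an independent check if wanted.
Component sign is fixed by positive skewness of each map — the paperless but
necessary convention that makes runs comparable.

ICASSO: ICA is repeated `n_ica_runs` times from random initial weights,
the pooled components are clustered by average linkage on 1 − |correlation|
cut at the component count, and each cluster's stability index I_q is its
mean intra-cluster similarity minus its mean similarity to everything
outside. Aggregate maps are cluster centrotypes. Components with I_q ≤ 0.8
are flagged for exclusion. Back-reconstruction composes the subject PCA
basis, the subject's block of the group PCA basis, and the ICA mixing matrix
into subject time courses (T×C), with subject maps obtained by least-squares
regression of the subject data on those time courses — the GICA
back-reconstruction that is analogous to dual regression.

Desk-scale defaults (subject PCA 30, group PCA 12, 10 components, 10 runs)
keep identical algorithmics at tractable cost; full-scale settings
(120/100/100/20) are plain configuration.

Spectral screening of component time courses uses a Welch spectrum (Hann
window, segment length 64, 50% overlap — the estimator's settings are the
package's declared defaults, not inherited from elsewhere): the power ratio
integrates P(f) below 0.10 Hz against the 0.15–0.25 Hz band (floored at
1e−12 of total power so it stays finite), and the dynamic range is
max(P) − min(P). The grey-matter/artefact overlap criterion used in visual
component review cannot be automated faithfully; an optional mask-overlap
fraction plus a manual include/exclude list stands in for it.

## Time-course post-processing

Fixed order, asserted by the pipeline: polynomial detrend (order 3: linear,
quadratic, cubic, constant absorbed), despike, Butterworth low-pass.

Despiking flags points whose deviation from a leave-one-out running median
(window 7, the centre sample excluded; mirrored boundaries) exceeds 3 robust
standard deviations (1.4826 × MAD of the residual series). Excluding the
centre matters: a median that contains its own centre reproduces it on
locally monotone stretches, deflating the MAD while spike tails keep full
scale, which over-flags marginal points and can cascade. The scale is floored
at 10% of the series SD — on (near-)noiseless smooth data the residual MAD
shrinks to curvature level, and deviations below a tenth of the signal's own
scale are not spikes worth replacing. Flagged points are replaced by a cubic
spline through the nearest 4 clean points per side (boundary spikes
extrapolate). Detection and replacement iterate to a fixpoint, because a
large spike can mask a neighbour within one pass; the fixpoint construction
makes the operation idempotent (verified exactly in tests). More than 50% of
points flagged is treated as unusable data. On Gaussian white noise the flag
rate is ~0.3% (tested < 2%).

The low-pass filter is a fifth-order Butterworth at 0.15 Hz applied
forward–backward (zero phase, DC gain exactly 1, magnitude squared per
pass). Note on verification: the analog-prototype magnitude
1/(1+(f/fc)^10) predicts a two-pass gain of ≈ 0.053 at 0.20 Hz, but at this
sampling rate (1/0.906 Hz) bilinear warping puts the digital filter's true
two-pass gain at ≈ 0.033; tests therefore check the measured attenuation
against the designed filter's transfer function, not the analog formula.

## Static FC

Pairwise Pearson correlation between component time courses, Fisher
z-transformed, with correlations clipped to ±(1 − 1e−12) before atanh so
degenerate pairs produce large finite values rather than infinities; the
diagonal is undefined and stored as NaN. A constant time course is an error
naming the component.

## Sliding-window dynamic FC

The taper convolves a length-50 rectangle with a unit-area Gaussian
(σ = 6 TR, support ±4σ), truncates to the window length, renormalizes to
sum 1 (keeping the weighted covariance on one scale for any σ), and
symmetrizes against floating-point convolution asymmetry. Windows slide in
steps of 1 TR: 246 windows for 295 timepoints.

Per window, the taper-weighted covariance goes through the graphical lasso
(L1 penalty λ on the precision matrix), back to correlation, then Fisher z,
yielding one E = n(n−1)/2 edge vector per window. λ = 0 is the exact
empirical path (an ill-conditioned covariance then raises an error advising
λ > 0). Per-window fits run the coordinate-descent solver at tolerance 1e−3
with 50 iterations: across heavily overlapping windows this matches fully
converged fits to ~4e−3 in z at roughly half the cost.

λ is chosen per subject by 5-fold cross-validation over contiguous window
blocks on a 10-point log grid in [0.01, 1]: training windows' covariances
are pooled, the penalized precision is fitted, and the held-out pooled
covariance is scored by Gaussian log-likelihood; ties go to the smaller λ.
Pooling makes the score cheap and stable; it treats windows as exchangeable
within a fold, which is adequate for selecting a single per-subject penalty.
Whether the taper should enter the likelihood itself is unsettled; weighted
covariance followed by a standard graphical lasso is used.

## Deep clustering and state metrics

Edge features are z-scored per edge across all pooled windows (so the MSE
objective weighs edges comparably), then encoded by a fully connected
autoencoder: encoder 512-256-32, mirrored decoder, ReLU on hidden layers,
linear bottleneck and output, Adam (learning rate 0.001), MSE loss, 200
epochs with batch size 50. The network is implemented directly on numpy
(float32 parameters, fused in-place Adam updates via a numba kernel when
available) so training is exactly reproducible from its seed.

Exemplar windows are selected per subject at strict local maxima of the
per-window variance across edge features; a monotone or constant variance
series falls back to evenly spaced exemplars (logged). Clustering is
two-stage: 128 k-means++ repetitions (max 1000 iterations) on the encoded
exemplars keep the lowest-SSE centroid set, which then initializes a single
k-means run (max 10 000 iterations) over all encoded windows.

The number of states uses the within/between ratio
r(k) = mean point-to-own-centroid distance / mean pairwise centroid
distance. The elbow is formalized as the candidate k lying furthest below
the chord joining the curve's endpoints (the kneedle construction), with two
refinements: if r rises immediately after the smallest candidate (splitting
a true cluster pushes centroids together), that smallest k is the elbow; and
the selection is flagged low-confidence when the maximal bow depth is less
than a third of the curve's range, the signature of a featureless smoothly
decaying curve. A maximum-second-difference rule was tried first and
rejected: with 50-TR windows over ~20-TR dwells the ratio curve is smooth
and convex, and discrete curvature then always peaks at the first interior
candidate regardless of where the true bend is, while the chord rule locates
the planted state count on the same curves.

Per subject and state: fractional occupancy is the fraction of windows
assigned to the state (summing to 1 exactly); mean dwell time is the mean
contiguous run length of the state's window labels times the step duration,
reported in seconds. States a subject never visits have occupancy 0 and
*undefined* dwell time — NaN, never imputed zero — and are dropped from
group tests with a log entry. Subject state-FC matrices are element-wise
medians of the subject's windows in the state. Cluster labels are matched
across runs or against ground truth by Hungarian assignment on centroid
correlations.

### Temporal resolution limit

A 50-TR (45.3 s) window cannot resolve geometric dwells of mean 20 TR: most
windows straddle two or three dwell segments. An oracle assignment (each
window labelled with its majority ground-truth state — the best any
window-level method can do) still shows a mean absolute occupancy error of
≈ 0.07 and a dwell-time rank correlation of only ≈ 0.5 against the planted
per-subject run lengths, while occupancy *correlation* stays high (≈ 0.91).
The pipeline's measured recovery sits at this oracle ceiling, and its state
*patterns* are recovered essentially exactly (Hungarian-matched correlations
≈ 0.95); the residual temporal error is a property of sliding-window
measurement under fast switching, not of the estimator. Interpreting dwell
times from windowed dFC on fast-switching data should bear this in mind.

## Group statistics

Edge-wise case-control tests regress each edge on [1, age, sex] in a single
pooled regression (pooling avoids group-specific centering artifacts), then
apply a two-tailed equal-variance two-sample t-test to the residuals
(df = n₁ + n₂ − 2 = 40 at 22 + 20 subjects, where |t| = 2.02 ↔ p ≈ 0.05 —
used as a degrees-of-freedom checkpoint in tests). Benjamini–Hochberg FDR at
0.05 is applied separately to the static-FC edge family and to each state's
edge family; significance is judged on q only. Dwell time and occupancy use
ordinary-least-squares ANCOVA (metric ~ group + age + sex, group coded
case = 1); no robust variant is fitted. Sex is coded 0/1, age in years.

## Pipeline and reproducibility

`run_pipeline` executes simulate → QC → group ICA (optional) →
post-processing → static FC → dynamic FC → statistics from one `RunConfig`,
writing TSV outputs and a JSON manifest (stage seeds, per-subject λ,
selected k, exclusions, final autoencoder MSE). One master seed expands into
per-stage seeds through `numpy.random.SeedSequence.spawn` in a fixed stage
order (simulate, ICASSO, autoencoder, k-means), so stochastic stages can be
re-run in isolation; identical config and seed reproduce all outputs
byte-identically.

Problem sizes in the shipped tests and the acceptance script are the
generator defaults above (20 subjects × 295 timepoints × 10 sources; 246
windows per subject; candidate k in 2..8; 10 cohort seeds per recovery
check), with the desk-scale ICA settings for the ICA stages. The recovery
runs likewise proportion the encoder widths to their 45 edge features
(128-64-32, bottleneck kept at 32): the default 512-256-32 widths are sized
for a full 465-edge analysis, and on the small feature space the narrower
encoder recovers states equally well. A still smaller encoder with a 16-d
bottleneck degrades state-count selection and is not used.

## Known limitations

- No haemodynamic convolution or physiological noise in the generator; no
  scrubbing of individual frames (whole-subject exclusion only).
- Dwell-time and occupancy estimates inherit the sliding-window smearing
  quantified above whenever true dwells are shorter than the window.
- Expert visual review of component spatial maps is replaced by spectral
  criteria plus an optional mask overlap; atlas-based network naming and
  voxelwise permutation inference on spatial maps are out of scope.
- The EM group PCA and hand-written infomax target correctness and
  reproducibility, not large-cohort throughput.
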