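# Methods

This note documents the models, estimators, numerical choices and
limitations behind `mipflasso`.

## Preprocessing

Epochs are cropped to a half-open window [t_start, t_end) (0-based
sample indexing; the default analysis window is 2.5–6 s, spanning the
imagery period of a standard cue-paced trial). Six candidate windows
T1–T6 (2.5–4.5, 4–6, 2.5–6, 2.5–3.5, 3–4, 4–5 s) are provided; only
T3 is used by default. Multi-window stacking for data augmentation is
possible by running the pipeline per window and concatenating trials,
but is not part of the default path.

The filter bank tiles 4–40 Hz with five band widths (2, 4, 8, 16,
32 Hz): for each width w the range is covered by contiguous tiles
[f_lo + kw, f_lo + (k+1)w] truncated at f_hi, keeping a truncated
final tile iff its width is ≥ w/2. This yields 35 bands
(18 + 9 + 5 + 2 + 1). The tiling rule itself (contiguity, the
half-width cutoff) is this package's convention; alternative tilings
can be supplied by constructing `FilterBankSpec` with different
widths/range. Filters are second-order Butterworth band-passes
applied forward–backward (zero phase, effective magnitude order 4)
with reflective padding, so in-band transients keep their latency —
important when covariance is computed on short epochs. Examples and
tests mostly use a reduced two-band bank over 8–30 Hz (the mu/beta
range); this keeps the feature dimension p = n_bands·C(C+1)/2 small
without changing any code path.

## Riemannian features

Per (trial, band) spatial covariances use Ledoit–Wolf shrinkage by
default: the analytic convex combination with a scaled identity
guarantees positive definiteness for short or rank-deficient epochs.
A fixed-ridge fallback (1e−6·trace/C on the diagonal) and the plain
estimator are available.

The Fréchet mean is computed by the standard fixed-point iteration
M ← M^{1/2} exp(mean_i log(M^{−1/2} C_i M^{−1/2})) M^{1/2},
initialised at the arithmetic mean, tolerance 1e−8 on the Frobenius
norm of the tangent update, at most 50 iterations (non-convergence
raises, carrying the last residual). The tangent reference is fitted
per band on pooled training trials (both classes); class-wise
references would also be defensible but the pooled mean is the
conservative choice and keeps the feature map label-free.
Vectorisation takes the upper triangle with off-diagonals scaled by
√2, so the Euclidean norm of a tangent vector equals the
affine-invariant geodesic distance to the reference exactly — this
identity, the exp/log round trip, and congruence invariance of the
metric are all asserted to 1e−8–1e−10 in the tests. Geodesic
distances to class means are not appended as extra features.

## Mutual information and adaptive weights

Entropies are computed in nats (natural log; a `base` argument
converts). Continuous tangent features are discretised into
equal-frequency bins (default 8; 4 for small-n regression benches),
ties broken by stable rank so bins stay balanced even for discrete
features. MI is the plug-in estimate of the binned feature against
the label; no bias correction is subtracted (the plug-in bias
(K−1)(L−1)/2n is small at the sample sizes used and a shuffle floor
can be computed by the caller). The adaptive weight is
α_j = e^{−r I_j}, r = 5 by default, floored at 1e−8 so the
back-transformation β̂_j = β*_j/α_j cannot overflow. Weights are
computed on training folds only; computing them on the full set would
leak label information into the penalty.

## The MIPF-LASSO solver

Columns are standardized to zero mean and unit Euclidean norm, so
ρ_ij = x_iᵀx_j is the exact sample correlation; the response is
centered (binary labels are coded ±1 first). Correlations are clipped
to |ρ| ≤ 0.999 before forming W — duplicated tangent features do
occur, and the 1/(1−ρ²) denominators must stay finite.

W is defined with the factor 2 (W_ii = Σ_{j≠i} 2/(1−ρ_ij²),
W_ij = −2ρ_ij/(1−ρ_ij²)) so that βᵀWβ equals the pairwise fusion sum
*exactly*; a half-scaled convention would merely rescale λ₂. The
square-root factor uses Cholesky when W is numerically positive
definite and the symmetric eigen square root with negative eigenvalues
clipped at zero otherwise. The λ₁ = 0 ridge-fusion closed form
(XᵀX + λ₂W)⁻¹Xᵀy is solved by Cholesky with a 1e−10 jitter retry for
numerically semidefinite systems.

The loss is the plain residual sum of squares (no 1/2n factor), so
the coordinate-descent update is β*_j ← S(x_jᵀr_{(−j)}, λ₁/2)/‖x_j‖²
and the null threshold is λ₁ ≥ 2 max_j |x_jᵀŷ|. Sweeps are cyclic in
fixed order, convergence is max |Δβ*| < 1e−6 (default), capped at
10⁴ sweeps; hitting the cap flags `converged=False` rather than
raising. Warm starts are used along λ₁ paths. When λ₂ = 0 the
augmentation rows are identically zero and are skipped; the solution
is unchanged. Ablation variants reduce the model exactly:
`adaptive_lasso` (λ₂ = 0), `lasso` (λ₂ = 0, α = 1), `none` (least
squares, all features kept). Multi-class labels are handled
one-vs-rest for selection (union of supports) with a natively
multi-class SVM and macro-averaged F1/G-mean.

Scale note: W's entries grow like p (each diagonal sums p−1 terms),
so useful λ₂ values are roughly 1/p-scale; the tuning grids used in
the benches are chosen accordingly.

## Tuning

The (λ₁, λ₂) search is k-fold cross-validation over user grids
(λ₁ naturally expressed as fractions of λ₁_max). Scores are
"downstream": classification uses stratified folds and the accuracy
of an RBF-SVM trained on the selected features; regression uses the
mean-squared error of an ordinary least-squares refit on the selected
support (relaxed-LASSO style — refitting removes the L1 shrinkage
bias, so the score ranks supports rather than shrunken predictors).
The winner is chosen by a one-standard-error rule: among grid points
within one SE of the best mean score, the sparsest model (fewest
selected features, then larger λ₁, then larger λ₂) is returned. The
sparsity-first tie-break is deliberate: with the fusion penalty a
larger λ₂ can *grow* the support via the grouping effect, so "larger
λ is sparser" does not hold and sparsity must be read off the fits
themselves. The whole procedure is deterministic given the seed.

## Synthetic data

`gen_two_class_trials` emulates the band-limited covariance contrast
(ERD/ERS-like) between motor-imagery classes: white Gaussian noise is
band-pass filtered (same filter implementation as the preprocessing
stage) and spatially mixed by the square root of a class-specific
target covariance — a random SPD base matrix for class 0, the same
matrix with the upper half of its eigenvalues inflated by
(1 + class_sep) for class 1 — plus white sensor noise of standard
deviation `noise_sd`. Defaults (8 channels, 40 trials/class, 3.5 s at
250 Hz, class_sep 1, noise 0.5, 8–30 Hz band) correspond to a small
but realistic single-subject session. class_sep = 0 makes the classes
identically distributed; class_sep = 3 (eigenvalue ratio 4 on half
the channels) is the "strong separation" condition used in the
end-to-end checks. Not modelled: eye blinks, line noise, channel
drift, nonstationarity across trials — so passing tests demonstrate
that the geometry and selection machinery work, not robustness to
real-EEG artifacts.

`gen_sparse_regression` draws block-equicorrelated Gaussian columns
(x = √ρ z_block + √(1−ρ) ε, blocks of 5 by default, standardized
after generation) with exactly k nonzero coefficients of magnitude
`beta_scale` and alternating sign, one per block. The
support-recovery study condition is n = 100, p = 50, k = 5,
ρ = 0.5, beta_scale = 1, noise 0.25 (a high-SNR regime where support
recovery is information-theoretically comfortable), 5-fold CV over
λ₁/λ₁_max ∈ {0.5, 0.3, 0.2, 0.1, 0.05, 0.02} and
λ₂ ∈ {0, 0.01, 0.04}, with MI weights computed against the response
discretised into 4 equal-frequency classes.

## Problem sizes and determinism

Tests and the acceptance script run the pipeline at desk scale —
8 channels, 2 bands, 50 trials, 10 generator seeds; solver oracles at
n ≤ 60, p ≤ 15 against a FISTA minimiser of the untransformed
objective — sizes chosen so the full suite completes in well under a
minute while still exercising every code path, including p > n
(p = 3n). All randomness flows through `numpy.random.default_rng`
seeds carried in the generator specs and configs; identical inputs
give identical reports.

## Known limitations

- The fusion matrix W is dense p × p; at the full 35-band, 22-channel
  feature dimension (p = 8855) forming W takes ~600 MB. For such
  sizes run per-band selection or reduce the bank; a sparse/implicit
  W is future work.
- The plug-in MI estimator is biased upward at small n; weights are
  therefore slightly compressed toward each other, which only dampens
  (never flips) the informativeness ordering.
- The coordinate-descent reduction relies on the augmented design
  being exact; correlation clipping perturbs J(β) for |ρ| > 0.999 by
  design.
- Multi-class selection is one-vs-rest; no dedicated multinomial
  objective.
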