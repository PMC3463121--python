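# Methods

## Model

Given R input omics blocks X_1..X_R (samples × variables; e.g. copy-number
variation, DNA methylation, microRNA expression) and a response block Y
(samples × genes), all centered and measured on the same K samples, one
component of multi-block partial least squares (MBPLS) seeks unit-norm
loading vectors w_i and q and unit-norm block weights b maximizing the
covariance between the super score

    t = T b,   T = [X_1 w_1, ..., X_R w_R],

and the response score u = Y q.  The block weights b report how much each
omics layer contributes to the shared covariance structure.  The classic
solver is the block-scores iterative cycle: regress u on each block to get
w_i, form the block scores t_i = X_i w_i, combine them into the super block
T, and run one PLS step between T and Y (b, t, q, u), repeating until t
stabilizes.  We initialize u deterministically at the response column of
maximal variance, so runs are exactly reproducible.

The sparse variant (sMBPLS) adds lasso penalties on every loading vector
and, optionally, on the latent variables themselves.  Each regression step
is followed by soft thresholding, `sign(x) · max(|x| − λ, 0)`, the proximal
operator of the ℓ1 penalty.  Rather than tuning continuous penalty weights,
sparsity is parameterized by integer *degrees of sparsity* — the number of
nonzero entries a vector may keep.  Requesting d survivors is equivalent to
thresholding at the (d+1)-th largest absolute value of the pre-threshold
vector, and this order-statistic λ is recomputed at every iteration so the
degrees, not the λ's, are the fixed tuning parameters.  Exact ties at the
threshold are resolved deterministically by keeping the tied entries with
the smallest indices.

Thresholding the block scores t_i and the response score u (the "sample
degree") selects samples as well as variables.  The nonzero supports of the
converged vectors delineate a multi-dimensional regulatory module (MDRM):
a set of samples, a set of variables in each input block, and a set of
response genes with a coherent cross-block covariance pattern.  A module's
sample set is the joint nonzero support of t and u, since a module's input
and response profiles must coincide on the same samples.

Sign indeterminacy (flipping all of w_i, t_i, t, q, u leaves b and the
covariance unchanged) is removed by forcing the largest-magnitude entry of
q positive.

## Sequential extraction

After a component converges, its signal is removed from every block by
super-score projection deflation,

    X_i ← X_i − t (X_iᵀ t)ᵀ / (tᵀ t),   Y ← Y − t (Yᵀ t)ᵀ / (tᵀ t),

followed by re-centering; deflated blocks are exactly orthogonal to t when
sample selection is off.  Extraction repeats until (i) a module cap is
reached (default 100), (ii) the component objective falls below a floor
fraction (default 0.05) of the first module's objective, or (iii) a fit
degenerates (e.g. the data are exhausted); the stop reason is recorded.
The floor is a declared surrogate for "no further significant gain" and is
exposed as a parameter.

## Preprocessing

Variables with little variation are dropped by a coefficient-of-variation
filter σ/|μ| < threshold (default 0.1, configurable; population σ).
Variables whose mean is numerically zero (|μ| < 1e-12) bypass the unstable
ratio and are kept unless σ is also proportionally zero — centered data
routinely has tiny means.  Surviving columns are mean-centered and, by
default, scaled to unit variance so blocks with different units contribute
comparably; scaling is switchable and every step is logged in the dataset's
preprocessing record.  Preprocessing is idempotent.

## Degree tuning by cross-validation

Degrees are selected by L-fold cross-validation (default L = 5): samples
are randomly partitioned into folds of near-equal size; for each candidate
degree combination a single sparse component is fitted on each training
split (held-out rows are centered with training means only) and scored on
the held-out rows.  The default fold score is the held-out squared error of
the rank-1 response prediction

    score_l = (1/K_l) · ‖Y^(l) − d · T̂^(l) b qᵀ‖²_F,

where T̂^(l) collects the held-out block scores under the training loadings
and d = (uᵀt)/(tᵀt) is the training inner-relation coefficient of the PLS
model u ≈ d·t.  At R = 1 this is the standard sparse-PLS held-out MSEP.
We considered the simpler gap ‖û − d·T̂b‖² between the held-out response
score and its super-score prediction (shipped as
`score_discrepancy_score`): it is cheaper but cannot penalize response-side
undershoot — any support that captures the latent scores reproduces û — and
without the inner-relation coefficient its systematic amplitude mismatch
between û and T̂b grows with the signal, so it ranks degree combinations
essentially at random in our experiments.  The total score sums over folds;
the smallest score wins, with exact ties broken toward the sparser
configuration (smaller total degree, then lexicographic).  A training fold
that empties a support disqualifies the candidate with +∞.  Because the
full cartesian degree grid is infeasible, `ladder_grid` builds the
practical subset: geometric ladders applied jointly across blocks and
crossed with a response ladder.

Two caveats, measured on synthetic data: prediction-error CV of shrinkage
estimators is biased toward configurations mildly denser than the truth
(smaller λ means less shrinkage bias), so candidate grids should be spaced
by rough orders of magnitude rather than fine steps; and degree selection
is only meaningful where the planted signal is strong enough for the data
to identify it — the CV recovery experiment in the acceptance suite
therefore uses a clear-signal scenario (latent scale 2.0, noise 0.5).

## Evaluation statistics

Module–module and module–truth agreement is scored per dimension (each
input block, the response genes, and the samples whenever both modules
select proper sample subsets) with the hypergeometric upper-tail
probability of the observed intersection, Bonferroni-corrected across the
compared dimensions (the family size is overridable for genome-scale
pair screens).  Truth recovery requires significance in every compared
dimension; module–module robustness screens conventionally require three.
`dimensions_missing` counts input omics layers from which a module selected
nothing — the characteristic failure of single-merged-block sparse PLS.
Per-block relevance is assessed by the Pearson correlation between the
block latent t_i and the response latent u over the module's samples, with
the two-sided p-value from the exact Student-t transform
r·sqrt((K−2)/(1−r²)) on K−2 degrees of freedom; blocks with empty loading
support are reported as excluded.

## Synthetic data

The simulator follows the generative model Y = XB + E.  Background: every
cell carries Gaussian noise of scale `noise_sd`; input rows can instead be
drawn from a multivariate normal with AR(1) covariance ρ^|j−k| (times
noise_sd²) to inject multicollinearity among input variables.  Each planted
module adds a shared rank-1 signal: a latent sample-score vector τ
(standard normal on the module's samples, centered across them, scaled by
`latent_scale`) times signed loadings with magnitudes drawn uniformly from
`signal_range` (signs ± with equal probability, so anti-correlated layers —
as with methylation — occur).  The latent is centered within the module so
planted columns have exactly zero mean: without this, global centering
smears the module over off-module cells and exact noiseless support
recovery becomes ill-posed.  Because all blocks and the response share τ,
the response's planted part is structurally a noisy linear image of the
inputs.  All randomness flows from a single integer seed and datasets are
bit-reproducible.

The `benchmark` scenario: K = 100 samples, three input blocks of 200
variables, 200 response genes, one planted module of 20 samples × 30
variables per block × 30 genes, signal magnitudes in [0.5, 1], noise_sd 1,
AR(1) ρ = 0.3, latent scale 0.5, seeds 1..50 for the replicate experiments.
The latent scale is the one constant the scenario had to fix by design: it
places the planted signal where it shapes the local covariance of its
submatrix but is swamped in the global covariance that the non-sparse
baseline maximizes.  Measured consequences at these desk-scale shapes
(50 replicates): the two-step classic baseline fails the truth-overlap
test on 48/50 replicates, while a single sparse fit initialized at the
classic solution fully recovers the module on only 7/50 — at K = 100 with
200-variable blocks, global dilution and reliable sparse recovery cannot
hold simultaneously; scanning the latent scale moves the trade-off but
never removes it (at scale ≥ 0.8 both methods recover the module; at
≤ 0.5 even a fit seeded at the true latent can drift off it).  Larger
problems (more variables per block, more samples) separate the two
regimes; the packaged scenario keeps runs in seconds.

What the simulator does not emulate: realistic copy-number segmentation,
methylation beta distributions, block-specific variance scales, overlapping
or hierarchically nested modules, and non-Gaussian noise.  In particular,
because the three input blocks are symmetric and share one latent, the
merged single-block sparse PLS baseline almost never drops two whole input
dimensions here (it either locks onto the shared latent, taking variables
from all blocks, or onto noise, which spreads across blocks); real
multi-omics data with unbalanced covariance scales across layers is where
that failure mode dominates.  Passing tests on these simulations therefore
demonstrate correctness of the machinery and the sparse-vs-dense
separation, not performance on real tumor profiles.

## Numerical choices

- Convergence: relative change of t below `tol` (default 1e-6), `max_iter`
  500; non-convergence returns the fit flagged `converged = False` with a
  warning rather than an error.
- The sparse fit is initialized at the converged classic-MBPLS response
  score of the same (possibly deflated) data.
- The covariance objective t·u/(K−1) is recorded per iteration.  With soft
  thresholding and the order-statistic λ recomputed each iteration, this
  sequence is *not* guaranteed monotone (the normalized soft-thresholded
  update maximizes the penalized form, not the raw covariance); measured
  on 100 seeded instances, most show transient decreases of up to ~0.15
  before settling.  Hard top-d selection would ascend the raw covariance
  exactly, but soft thresholding is the method's defining operator and is
  retained.  In the noiseless case λ = 0 on the planted support and the
  ascent is exact.
- Degenerate inputs raise typed errors: all-zero blocks, zero latent
  variables in deflation, constant vectors in correlation tests,
  over-filtered blocks (naming the block), degrees out of range.
- Sample degrees larger than a CV training fold are clamped to the fold
  size (selecting every training sample), the faithful restriction of
  "no sample selection at that size".

## Known limitations

- Single-component machinery only: multi-component regression prediction
  (orthogonalized coefficients, multi-component transforms) is out of
  scope; `transform` projects new samples onto one component.
- The alternating solver is a local method; with a single deterministic
  start it inherits the classic solution's basin.  Modules weaker than the
  global noise floor may be missed even when locally identifiable.
- Missing values are not imputed; inputs must be finite.
- The overlap test treats dimensions independently; correlated selections
  across dimensions make the Bonferroni correction conservative.
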