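# Methods

## Model and estimation

The package treats a calcium recording as N non-negative ΔF/F traces
sampled at δt = 0.1 s. The generative picture is a linearized Hopfield
network: recorded neurons couple through hidden units via a synaptic
matrix ξ (N × N_hidden); integrating out fast hidden dynamics yields the
effective coupling T = ξξᵀ, symmetric and of rank ≤ N_hidden. Discretized
at the frame interval, the dynamics are V(t+δt) = T·V(t) + V_ext + ε(t).

Estimation inverts this map: each neuron's next-frame value is regressed
on the whole population's current values (OLS with intercept), filling
row i of T̂ and the external drive V̂_ext,i. No symmetry or rank
constraint is imposed on T̂ — the regression is the estimator, and the
fitted matrix is generally asymmetric. The contiguous first 75% of lagged
rows train the model; the remainder reports an out-of-sample grand-mean
squared error (per-neuron errors are also exposed). Minimization is
per-neuron OLS, which for a summed squared loss is exactly equivalent to
the joint problem. Plain OLS is the default; a ridge option exists for
ill-conditioned real recordings but is off everywhere in the validation
suite.

### Identifiability and the minimum-data bound

`min_data_requirement` counts n(n+1)/2 unique symmetric couplings plus n
drives (1,325 for n = 50) and converts to a duration at one frame per
unknown (132.5 s ≈ 2.2 min at 10 Hz). This is the conventional
counting bound; it is *necessary*, not sufficient. In particular, a
stable autonomous linear system observed without noise relaxes to its
fixed point, so a single noise-free trajectory excites only the Krylov
subspace of the initial deviation and the design matrix becomes
ill-conditioned or rank-deficient no matter how long the recording. The
package therefore lets `fit_connectivity` stack several recording
sessions (restarts), which provide the persistent excitation required for
exact identification; with process noise, a single long session
identifies T consistently because the noise itself excites all
directions.

## Synthetic data generator

The generator is the study's stand-in for the miniscope recordings:
~20–50 neurons, 10 Hz, thousands of frames per condition.

- **ξ draw and sign ratio.** ξ entries are Gaussian with a common
  positive shift tuned by bisection so the off-diagonal positive fraction
  of T matches a 2:1 excitatory:inhibitory target, the ratio typical of
  cortical functional couplings. Only the observed ratio is targeted; no
  claim is made about the biological generative process.
- **Stability rescaling.** T (and ξ with it, preserving T = ξξᵀ) is
  rescaled so that both the full matrix and its off-diagonal-zeroed
  version have spectral radius ≤ 0.9. Scaling only the off-diagonal part
  would be enough for the forecasting stage (which drops the diagonal),
  but the ξξᵀ diagonal is large and positive and the *simulation* uses
  the full matrix; bounding both radii guarantees decaying free dynamics
  in every stage.
- **External drive.** V_ext = (I − T)·b with baselines b drawn uniformly
  (default 0.5–1.5 in units of ΔF/F; the analysis scripts use 8–14 so a
  mid-level threshold binarizes meaningfully). This makes the noise-free
  fixed point exactly b, strictly positive, so noiseless trajectories
  started near it stay positive and clipping never engages.
- **Noise model.** Additive iid Gaussian on the update, then clipping at
  zero, the simplest model producing a non-negative signal with a noise
  floor. No calcium-kernel biophysics (GCaMP kinetics, spike
  deconvolution) is modeled: passing tests show the *estimators* are
  correct under the stated dynamics, not that real indicators obey them.
- **RC cycle.** The single-neuron circuit analogy charges as
  V_b(1 − e^{−t/τ}) and discharges from the reached level as a continuous
  offset exponential. A literal piecewise form with discharge branch
  V_b e^{−t/τ} would jump discontinuously at the switch time; the
  continuous variant is implemented.
- **Landscape sampler.** Draws the scaled variable from
  p(m′) ∝ exp(−Σ c_j m′ʲ) truncated to [−2.7, 2.7] by inverse CDF on a
  10⁵-point grid (refining the grid further changes sampled values by
  less than the Monte-Carlo error at the n used here).

## Preprocessing

Values strictly below the threshold are zeroed; equality survives (and
binarizes to 1). The threshold is selected by a sensitivity sweep over a
grid (integers 0–20 by default): per threshold, the lagged regression is
refitted on a random 70% of time points and consecutive fits are compared
by the relative Frobenius change of the stacked (coefficients,
intercepts), with ε = 1e−12 guarding the denominator. The subset is drawn
once per sweep, not per threshold, so comparisons are paired and
thresholds that do not alter the data score exactly zero. The chosen
threshold is the smallest one from which every subsequent score stays
below the tolerance (default 0.05, one repeat; both exposed as config —
there is no canonical value for either).

## Graph metrics

Off-diagonal positive entries form the functional-excitatory digraph,
negatives (absolute value) the functional-inhibitory one; edge j→i
carries |T_ij|. Weights act directly as additive shortest-path lengths —
the stated convention of the underlying graph library — even though this
makes strong couplings "far"; absolute values are used for inhibitory
lengths because negative lengths break shortest-path algorithms. The
diameter is the maximum weighted eccentricity within the largest
(strongly) connected component, reported with the fraction of nodes that
component covers; betweenness uses the standard (N−1)(N−2) directed
normalization with endpoints excluded; communities come from seeded
Louvain modularity maximization on the undirected weighted projection
(reciprocal weights summed). Graphs are directed by default (T̂ is
asymmetric); an undirected mode and an edge-weight floor exist as config
toggles for comparability with analyses that used them.

## Stimulation forecasts

Forecasts unroll V ← T₀V + V_ext(t) stepwise with T₀ the fitted matrix
with zeroed diagonal (the self-term is excluded at forecast time only;
the regression itself leaves the diagonal unconstrained). The stepwise
recursion is algebraically identical to the explicit matrix-power
summation, which is kept as an independent oracle in the tests rather
than as the implementation. Post-cutoff decay rates are per-neuron
log-linear slopes; neurons whose trajectory touches zero or goes negative
are flagged undefined. Shipped protocols (ramp-then-cutoff, rectangular
pulse) are parametric, not reconstructions of any particular published
stimulus whose amplitudes are unknown.

## Energy landscape

m(t) is the fraction of binarized-active neurons per frame. The series is
standardized with the population (1/n) standard deviation (fixed for
determinism; immaterial at n ≈ 18,000 frames). The density of m′ is
estimated by a Gaussian KDE with Scott's-rule bandwidth, evaluated on a
regular grid of 10⁶ bins spanning [−2.7, 2.7] via linear histogramming
plus FFT convolution with the kernel (truncated at 6 bandwidths), making
the dense grid cheap; the density is floored at 1e−300 before taking
−log. A quartic Σ c_j m′ʲ is then fitted to −log p̂ by weighted least
squares with weights ∝ p̂. The weighting is the single most consequential
free choice in this stage: unweighted regression over the full grid is
dominated by the enormous −log values where the density underflows, i.e.
by exactly the region containing no data. The unweighted mode remains
available as config. Coefficients are mapped to unscaled m-space by
polynomial composition with the affine back-transform (exact binomial
expansion).

Stability: the state is *stable* iff E′ has a root with E″ > 0 strictly
inside the assessment domain; otherwise *unstable*, with the downhill
direction given by the lower-energy domain edge. Verdicts can flip with
the domain, so it is an explicit argument; the pipeline assesses over the
observed range of m′ (clipped to the grid support), the region where the
KDE is informed by data. The verdict is invariant under the
scaled/unscaled reparameterization when the domain is transformed
accordingly (property-tested). The binarization reference voltage is
taken as 1 (binary units), and the effective temperature is fixed at
k_BT_eff = 1; neither is estimated.

## Problem sizes and numerical choices

The validation battery uses 20-neuron networks with 4,000-frame sessions
(80 × 50-frame restarts for the noise-free identification check), 50,000
samples for landscape recovery, and 100 random ≤ 8-node digraphs against
exhaustive oracles — sizes at which every oracle is exact and the whole
suite runs in seconds. Unit tests evaluate the KDE on a 10⁵-bin grid
after verifying that coefficients move by < 1e−3 between 10⁵ and the
default 10⁶ bins; the acceptance script and the analysis pipeline use the
full 10⁶-bin grid. Rank-deficient lagged designs (e.g. all-zero traces)
fall back to the minimum-norm pseudo-inverse with a logged warning rather
than failing.

## Known limitations

- The linear lag-1 model has no thresholding, saturation, or plasticity;
  inferred couplings are statistical, not anatomical.
- The generator's clipping makes heavily noise-driven simulations mildly
  nonlinear near zero; parameter-recovery claims hold in the regime where
  clipping is rare (positive fixed points, moderate noise).
- The quartic landscape is a local expansion: multi-well structure beyond
  degree 4, time-resolved landscapes, and temperature estimation are out
  of scope.
- Threshold selection assumes a noise floor separable from signal
  transients; on data without that separation the sweep legitimately
  selects the smallest threshold or reports that none qualifies.
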