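# Methods

This note documents the models implemented in `popcircuit`, the numerical
choices behind them, what the synthetic data do and do not emulate, and the
known limitations. It is the package's own account of its science; every
number quoted here is computed by the test suite or `scripts/acceptance.py`.

## 1. The L2/3 circuit model

Four populations of leaky integrate-and-fire neurons (1700 excitatory,
70 PV, 115 5HT₃ₐR, 45 SOM) are driven by 1500 L4 excitatory spike sources.
Voltage obeys

    dV/dt = ( g_e (E_e − V) + g_i (E_i − V) − (V − V_rest) ) / τ_m

with conductances stored in units of the target's leak conductance
(1/R_in), which makes the equation dimensionless in conductance and avoids
unit bookkeeping. Conductances decay exponentially (τ_syn,e = 2 ms;
τ_syn,i = 40 ms for E/5HT₃ₐR/SOM targets, 16 ms for PV) and are
incremented instantaneously when a presynaptic spike passes a Bernoulli
release test (p_rel = 0.25 everywhere). All intrinsic, synaptic and
connectivity values ship in `popcircuit/data/circuit_defaults.yaml`.

**Conductance calibration.** Experimental synaptic strengths are PSP
amplitudes, so each per-synapse peak conductance ḡ is set analytically so
that the linearized single-synapse response — driving force frozen at the
holding potential (V_rest for EPSPs, −55 mV for IPSPs) — peaks at the
drawn amplitude. The bi-exponential peak has the closed form

    v(t) = ḡ D τ_s/(τ_m − τ_s) (e^(−t/τ_m) − e^(−t/τ_s)),
    t* = τ_m τ_s ln(τ_m/τ_s)/(τ_m − τ_s),

collapsing to the α-function peak ḡD/e when τ_s = τ_m. The acceptance
suite verifies the calibration against direct ODE integration to 1%.

**Synaptic amplitudes.** Per-synapse amplitudes are log-normal with
ln-location ln(median) and ln-variance 2·ln(mean/median) — the unique
log-normal matching a reported mean/median pair — truncated at 8 mV.
Inhibitory amplitudes are treated as magnitudes throughout (hyperpolarizing
PSPs appear with mixed sign conventions in tabulated data).

**Stimulation protocol.** A trial is 50 ms of forward Euler at
dt = 0.01 ms. Each active L4 cell fires once at a time drawn from
N(25 ms, 2 ms), clipped into the window (the 2 ms jitter is part of the
modeled volley; the mid-window center is the package's choice). After a
spike, V resets to V_rest (the conventional choice of reset potential)
and is clamped for the
refractory period. A neuron scores 1 if it crosses threshold at least
once; extra spikes are disregarded. ON probability q(f) is the fraction of
10 ON-subset permutations × 10 release repeats = 100 trials with a spike.
Spike-time jitter is drawn once per permutation; release noise is fresh
per repeat.

**L4 fraction grid.** The default stimulation grid is 13 evenly spaced
fractions spanning [0, 1]. With the shipped parameters the expected direct
L4 depolarization of an E cell is ≈ 45·f mV against a 30 mV
rest-to-threshold gap, so the q(f) transition sits at intermediate-to-high
fractions; a grid confined to small f would miss it entirely, so the
full-range grid is the package default.

**Reduced-scale runs.** `scale < 1` shrinks every population
proportionally. Because each neuron's expected synaptic input scales with
presynaptic count, the package compensates by scaling per-synapse PSP
amplitudes by 1/scale (standard mean-field downscaling; the 8 mV cap still
applies). This preserves the mean drive while increasing input
fluctuations — response curves are noisier and shallower than at full
scale, but perturbation directions are preserved, which is what the
reduced-scale checks assert. `scale_compensate=False` disables the
compensation; the uncompensated quarter-scale circuit is essentially
silent over the whole f range.

**Perturbation sweep.** 76 parameters are perturbed by ±20%: counts,
probabilities, time constants, resistances and amplitudes move
multiplicatively (mean/median amplitude pairs in tandem); V_rest moves by
0.2·(V_th − V_rest) toward threshold, V_th by the same amount away from
rest, E_e scales its distance from V_rest (of the excitatory population,
as E_e is shared), and each E_i its distance from that cell type's V_th.
Refractory periods (irrelevant when almost no neuron spikes twice) and the
six structurally absent connections are excluded. Shifts are measured as
the change in the excitatory-population mean of per-neuron logistic
(slope, threshold) fits versus the default network, using identical
build/stimulus seeds for variance reduction — the null perturbation
therefore reproduces the default bit for bit and shifts exactly zero.

A note on the circuit's cell-type wiring: the shipped parameter set gives
SOM cells direct L4 input (pcon = 0.15), while 5HT₃ₐR cells receive
none. The purely disynaptic
activation pathway is exercised through the 5HT₃ₐR population, which
responds at strong drive only via L2/3 excitatory relays.

## 2. The logistic response model

Each neuron's spike probability is logistic in a scalar drive f. On the
standard-normal drive, the model maps (slope β, threshold θ) to activity
statistics:

* mean rate μ(β, θ) = ∫ q(f) φ(f) df,
* homogeneous/heterogeneous pair correlation
  ρ = (E[q_a q_b] − μ_a μ_b)/√(μ_a(1−μ_a) μ_b(1−μ_b)), the correlation of
  the conditionally independent Bernoulli spike trains.

The threshold is the input where q = q_t = 0.01:
f_thresh = f₁ᐟ₂ + ln(q_t/(1−q_t))/β ≈ f₁ᐟ₂ − 4.5951/β.

**Quadrature.** Default scalar evaluations use adaptive quadrature split
at the curve midpoint (absolute accuracy ≲ 1e−10 even for β = 10⁴); a
fixed 201-node Gauss–Hermite rule (`method="gauss"`) is available for
speed inside loops and agrees to ~1e−5 for β ≤ 5, degrading to ~1e−3 by
β ≈ 20. Contour root-finding (threshold at fixed μ) uses Brent's method
with an expanding bracket; correlation is monotone along fixed-rate
contours, which the suite checks and the contour-span scan exploits.

**Degenerate slopes.** At β = 0 the scalar functions treat the curve as
flat at its midpoint value (q ≡ 1/2, μ = 1/2, ρ = 0). In the
threshold-parameterized population model the continuous β → 0 limit is
instead q → q_t (the threshold pins the curve at q_t); sampling and
population integration use that continuous form, and Gaussian slope mass
below zero is truncated to β = 0. The two conventions meet only in how an
exactly-zero slope is labelled; no fitted or sampled configuration
occupies that point with positive probability.

**Fitting.** Per-neuron q(f) data are fit by binomial maximum likelihood
with a logit link (statsmodels GLM). All-silent, all-saturated or
non-monotone-degenerate responses are returned flagged rather than
raising; perfectly separated (step) data get β capped at 10⁴ with the
midpoint at the step and a `separated` flag. Sweep summaries exclude
flagged fits and report the count retained.

**Sensitivities.** ∂(μ, ρ)/∂(β, θ) use central differences with relative
step h·max(|param|, 1), h = 1e−3 by default; a slope step that would cross
β ≤ 0 falls back to a flagged one-sided difference. Central differencing
is second-order, which the suite verifies against the analytic integrand
∂μ/∂θ = −β E[q(1−q)].

## 3. The population logistic model

Cell-to-cell heterogeneity is a 2D Gaussian over (threshold, slope) with
five parameters (two means, two s.d.s, one correlation). Forward
prediction integrates over the parameter distribution with a
tensor-product Gauss–Hermite rule (13 nodes/dimension) through the
covariance Cholesky factor, and over the shared drive with 61 nodes;
truncated-slope nodes are clamped at zero. The expected pairwise
correlation couples every pair of parameter nodes through the drive, i.e.
an O(K²) node-pair sum over E_f[q_a q_b]. Degenerate covariances
(sd = 0 or |ρ| = 1) reduce to 1D/point rules. Quadrature orders are fixed,
so predictions are deterministic; 13/61 nodes agree with 61/301 nodes to
~1e−7 on physiological-range parameters.

**Fit.** The accept/reject stochastic descent perturbs all five
parameters with zero-mean Gaussian noise and accepts only error
reductions, where the error is the raw summed squared difference of the
three predicted vs target statistics. Defaults: step s.d. 2% of each
parameter's scale, tolerance 1e−6, iteration cap 2×10⁵, 5 seeded restarts.
A fixed step cannot land inside an ever-shrinking error ball (the
acceptance probability of a 5D Gaussian step into a radius-r target decays
like r⁵), so the step s.d. is halved after 300 consecutive rejections;
`step_decay=1.0` restores the fixed-step variant. The accepted-error
trajectory is non-increasing by construction and asserted. With three
constraints and five parameters the problem is under-determined: fits
reproduce the target statistics to tolerance, but distinct parameter
vectors can do so equally well — `validate_fit` (sample from the fitted
Gaussian, recompute statistics, compare with Monte-Carlo error bars) is
the convergence check, and recovered parameters are interpreted only up to
this identifiability.

## 4. Calcium binarization

ΔF/F → rate: second-order Butterworth low-pass at normalized cutoff 0.16,
applied forward–backward for zero phase (the cutoff coefficient is part of
the preprocessing convention; the order and zero-phase application are the
package's choices); exact inversion of the discrete 2 s
exponential kernel (y[n] − a·y[n−1], a = exp(−1/(τ f_s))); zeroing of all
points below twice the s.d. of the deconvolved trace's negative values
(a trace with no negative points gets floor 0, logged); scaling by
78.4 spikes/s per unit deconvolved ΔF/F. Rates are averaged within 1-s
bins and converted to ON probabilities by the Poisson zero-count
complement p_on = 1 − exp(−λ) — the derivation fixes the minus sign.
Summary statistics: mean and s.d. across neurons of time-averaged p_on,
and the mean Pearson correlation of p_on time series over all pairs
(constant series are skipped and counted; an all-constant raster yields a
flagged undefined correlation).

## 5. Population tracking entropy

The model stores the synchrony distribution p(K) (additive pseudocount 1
per count bin) and the conditional ON probabilities P(i ON | K)
(Jeffreys-style 0.5 pseudocount), with each conditional column
renormalized by scale-and-clip iteration so its sum equals K.
Probabilistic rasters are first expanded into 20 seeded Bernoulli draws
per bin; an exact Poisson-binomial route for p(K) exists for validation.

A pattern x with count K has probability p(K)·w(x|K)/Z_K with Bernoulli
weight w and normalizer Z_K over count-K patterns. Z_K, the conditional
marginals, and sequential conditional sampling all use the
elementary-symmetric-polynomial dynamic program (prefix/suffix tables),
which is exact, O(N·K) per count class, and numerically stable to a few
hundred neurons — no sampled approximation of the normalizer is needed at
the population sizes used here. Entropy is estimated as the seeded sample
mean of −log₂P over model draws (exact enumeration for N ≤ 15), with an
exact DP decomposition H = H(K) + Σ p(K) H(x|K) as a cross-check; both
routes agree to the Monte-Carlo error in the suite. Binary neurons bound
entropy/neuron by 1 bit, and the synthetic sweep (rates 0.01–0.5,
correlations 0–0.5, N ≤ 100) respects the bound.

The entropy-vs-N sweep draws 20 random subsets per size (10 to 100 in
steps of 10, truncated to the raster), averages entropy/neuron, and fits
H/N = A·e^(−bN) + C·e^(−dN) + e by multistart nonlinear least squares with
b, d, e ≥ 0, evaluating the fit at N = 100 as the standardized estimate.
If no start converges, the largest-size empirical value is returned
flagged. Noiseless double-exponential inputs are recovered to ~1e−6 in
h100.

## 6. Bootstrap statistics

Group-mean differences use the pooled-null bootstrap: pool both groups,
redraw groups of the original sizes with replacement, and take the
two-sided tail mass of the null difference at the observed one, with an
add-one correction p = (1 + #{|Δ_null| ≥ |Δ_obs|})/(n_boot + 1) so p is
never exactly zero (the tail-mass integral this implements is a density
idealization; finite resampling needs the correction). Default n_boot = 10⁵ in tests; 10⁷ is available. Type-I
error at α = 0.05 calibrates to ≈5% over 1000 replicate experiments.

Confidence ellipses bootstrap the (difference of) group means, take the
2×2 covariance of the bootstrap means, and draw the level-α boundary with
semi-axes √(χ²₀.₉₅,₂ · eigenvalues). Two-group ellipses resample each
group independently. The χ² construction assumes the covariance known, so
finite cohorts undercover mildly (measured ≈0.91 at n = 25, ≈0.94 at
n = 100, approaching 0.95 asymptotically); the calibration test runs at a
size where the plug-in bias is negligible. A Hotelling-type correction
would fix small-n coverage but would change the construction, so it is
deliberately not applied.

## 7. Synthetic data: scope and limits

The generator draws each neuron's (threshold, slope) once from the
population Gaussian (identity fixed across time), a shared standard-normal
drive per 1-s bin (i.i.d. — the analytic model has no temporal
correlation), and conditionally independent Bernoulli spikes. The
fluorescence forward model places each spike uniformly within its bin on
the 3.9 Hz frame grid (bin edges shared with the rate aggregation),
convolves with a 2 s exponential kernel of configurable per-spike
amplitude (default 0.10 ΔF/F — the indicator's per-spike amplitude is a
knob, not a claim), and adds i.i.d. Gaussian noise (default s.d. 0.02).

Passing tests on these data show that the analysis chain inverts its own
generative assumptions; they do not validate the assumptions against real
recordings. Not emulated: indicator nonlinearity and saturation,
photobleaching, neuropil contamination, motion artifacts, temporal
correlation in the drive, refractoriness, or slow drift in firing rates.

## 8. Problem sizes and defaults

Unit tests run the circuit at 1/10 scale (structure, dynamics) and probe
full scale only where an effect requires it (disynaptic 5HT₃ₐR
activation). The perturbation-direction checks use quarter scale with
3 seed pairs and the 13-level [0, 1] grid. The entropy sweep uses 2000
bins and 4000 entropy samples per raster; the recovery grid fits 27
targets with default fit settings. These sizes are the package's chosen
desk-scale study conditions; all are parameters, not constants.

## 9. Known limitations

* The circuit model makes deliberate simplifications: homogeneous
  5HT₃ₐR population, no layer 2/3 split, random connectivity, no
  short-term plasticity, no spontaneous background drive.
* The population fit's recovered parameters are identifiable only up to
  the three-statistic constraint surface.
* The population tracking model is implemented from its two-component
  definition with the package's own smoothing choices; other estimators
  of the same family may regularize differently.
* Entropy estimates inherit smoothing bias at small bin counts (the
  pseudocount on p(K) adds mass to unseen synchrony levels).
* The compensated reduced-scale circuit preserves mean drive but not
  fluctuation statistics; quantitative slope/threshold values at reduced
  scale are not comparable to full scale, only their perturbation
  directions.
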