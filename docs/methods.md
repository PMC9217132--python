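# Methods

This document describes the model, the estimators, the synthetic-data
generator and the numerical choices implemented in `eispec`, together with
their assumptions and known limitations.

## 1. Forward model

### 1.1 Dynamics

Each region is modelled as a linearized two-population neural mass: an
excitatory population with mean membrane deflection `x_e(t)` and an
inhibitory population with `x_i(t)`. Synaptic input is filtered by a
unit-area gamma kernel

```
f_tau(t) = (t / tau^2) exp(-t / tau),      F_tau(omega) = 1 / (1 + j omega tau)^2
```

with separate excitatory and inhibitory time constants `tau_e`, `tau_i`.
In the frequency domain the coupled equations are

```
x_e = F_e(omega) [ g_ee x_e - g_ei x_i + p ]
x_i = F_i(omega) [ g_ei x_e - g_ii x_i + p ]
```

where `g_ee`, `g_ii` are recurrent gains, `g_ei` the cross-coupling (fixed
to 1 during fitting), and `p(t)` a white-noise drive with spectral density
`noise_sd^2`. Solving the 2x2 linear system per frequency (Cramer's rule;
`forward.local_transfer`) gives the transfer functions `H_e(omega)`,
`H_i(omega)` from drive to each population.

### 1.2 Spectrum

The regional signal is `x_e + x_i`. With a drive common to both populations
(default) the closed-form one-sided power spectral density is

```
S(f) = noise_sd^2 | H_e + H_i |^2
```

and with independent drives `noise_sd^2 (|H_e|^2 + |H_i|^2)`. All spectra
are handled in decibels, `psd_db = 10 log10 S`, on a fixed analysis grid of
1-35 Hz in 0.5 Hz steps (69 bins).

The 2x2 determinant cannot vanish for admissible parameters: over the full
fitting bounds box its smallest relative magnitude is ~0.16 (a complex
quantity cannot be driven to zero by the single real degree of freedom
`omega`), so the closed form is well-defined everywhere the optimizer can
go. A degeneracy guard still raises `NumericalDegeneracyError` defensively.

### 1.3 Time-domain simulation

For validation the same system is integrated as a 10-dimensional linear
stochastic state-space model (each gamma kernel contributes a 2-state
critically damped chain). Discretization uses the exact Van Loan method:
the matrix exponential of the augmented block matrix yields both the state
transition matrix and the exact discrete-time noise covariance, so the
simulation has no time-step bias (an Euler option exists for comparison).
Integration is rejected with `InstabilityError` if the state diverges;
stability can be checked up front with `forward.is_stable`.

Note that the optimizer's traditional starting point
(`tau = 17 ms, g = 0.5`) is itself a linearly *unstable* parameter set: the
closed-form spectrum is still a well-defined function of frequency there,
but no stationary process exists, so simulations must use damped parameter
sets. Validation code draws parameters by rejection sampling with an
eigenvalue margin.

### 1.4 Welch expectation

The Welch estimator is unbiased for the true PSD *convolved with the
window's power response*, not for the PSD itself; near weakly damped
resonances the difference (spectral leakage) reaches several dB.
`spectral.welch_expectation_db` computes `E[P_welch]` by convolving the
closed-form two-sided linear PSD with the squared Hann window transform.
This is the correct closed-form reference when validating simulations, and
it is what the forward-oracle acceptance test compares against.

## 2. Spectral estimation

`spectral.compute_psd_db` wraps `scipy.signal.welch` with Hann windows of
2 s and 50% overlap, restricted to the 1-35 Hz analysis band. Canonical
bands are delta-theta (2-7 Hz), alpha (8-12 Hz), beta (13-35 Hz) and
broadband (1-35 Hz); band power is the mean dB value over the band's bins.

For a 600 s recording this gives K ~ 599 overlapping segments. Accounting
for Hann-window correlation between 50%-overlapped segments
(K_eff ~ K/1.06), the per-bin standard deviation of the dB spectrum is

```
sigma_dB = (10 / ln 10) / sqrt(K_eff)  ~  0.18 dB
```

This first-principles noise floor motivates the generator default below.

## 3. Parameter inference

### 3.1 Cost

The fit minimizes the negative Pearson correlation between empirical and
model dB spectra (`fitting.pearson_db_cost`). Correlation is invariant to
additive dB offsets, i.e. to overall amplitude scaling of the signal, which
is deliberately not modelled; the residual mean offset is reported
separately as `scaling_offset_db`.

### 3.2 Optimizer protocol

Basin-hopping over `x = (tau_e, tau_i, g_ee, g_ii)` with bounds
tau in [5, 30] ms and gains in [0.1, 10], starting from (17, 17, 0.5, 0.5),
temperature 0.1, step size 4, and L-BFGS-B local minimization. If the
optimum lands on a parameter bound, the whole search is retried with step
size 6 and the better result kept. The default `n_iterations` is 2000;
cohort-scale runs use substantially fewer (see Section 6).

Two numerical choices matter:

- **Box normalization.** The optimizer works in units of the bounds box
  (`u = (x - lo)/(hi - lo)`, all coordinates in [0, 1]), which equalizes
  curvature across parameters and roughly halves the L-BFGS-B iterations
  needed per hop. Hops remain uniform steps of the protocol's step size in
  natural units. The local iteration cap (60) must not be reduced much
  below ~40: starving the local minimizer breaks convergence badly.
- **Mirror polish.** The spectrum is nearly invariant under exchanging the
  excitatory and inhibitory channels, `(tau_e, g_ee) <-> (tau_i, g_ii)`;
  the sole asymmetry enters through a term proportional to
  `(1/tau_e - 1/tau_i)`. The cost surface therefore has a mirrored local
  optimum whose noiseless correlation reaches r ~ 0.999, and random hopping
  sometimes settles there. After hopping, both the incumbent and its
  channel-swapped reflection are polished to full local convergence and the
  lower-cost point kept. This is purely cost-driven: the true mode has
  strictly lower cost on noiseless spectra and in ~90% of 1 dB-noise cases.

The per-row cost kernel is numba-compiled; it matches the reference numpy
implementation to 1e-16.

### 3.3 Identifiability

With per-bin spectral noise at 1 dB, `tau_i` is close to the
identifiability limit when the inhibitory channel is strongly overdamped
(large `g_ii`): its resonance is too shallow to pin down. Estimates remain
essentially unbiased (the acceptance tests require mean time-constant bias
below 1 ms at 1 dB noise), but single-region variance is large. At the
0.18-0.2 dB noise level of a 600 s Welch spectrum both time constants are
well identified.

## 4. Synthetic cohort generator

`cohort.generate_cohort` draws a controls/patients cohort on a region list
(default: the 68 Desikan-Killiany cortical parcels):

- **Parameters.** Per subject, a random effect per parameter (SD 1.0 for
  time constants in ms, 0.25 for gains) shifts a group mean; per ROI an
  independent effect of the same SD is added. Patient group means are
  shifted by (+4, +1, +0.3, -0.4) for (tau_e, tau_i, g_ee, g_ii): slower
  excitatory and inhibitory kinetics, higher excitatory and lower
  inhibitory gain. Values are clipped to the fitting bounds.
- **Spectra.** The exact closed-form dB spectrum of each subject x ROI
  parameter set plus i.i.d. Gaussian dB noise, default 0.2 dB per bin -
  the realistic Welch estimator floor for a 600 s recording derived in
  Section 2 (an earlier 1 dB placeholder put `tau_i` below its
  identifiability limit and was corrected from first principles).
- **Molecular maps.** Tau-PET SUVR couples to the *true* regional tau_e
  z-score (slope 0.10) and amyloid-beta SUVR to the true tau_i z-score
  (slope 0.10), around bases 1.64 and 1.99, with measurement noise SD 0.15.
  Cross-couplings are zero by default, so dissociation observed downstream
  is genuinely generated, not assumed.

Realism caveats: noise is independent across bins (Welch bins are slightly
correlated in reality), there is no spatial correlation between neighbour
ROIs beyond the subject effect, and SUVR couplings are linear.

## 5. Statistics

- **Z-scoring** (`stats.zscore_vs_controls`): per ROI, against the control
  mean and SD of that ROI. Controls self-standardize exactly (mean 0, SD 1
  to machine precision) by construction.
- **Associations** (`stats.association_model`): on patients only,
  `measure_z ~ 1 + tau_suvr + ab_suvr` with a subject random intercept
  (statsmodels MixedLM, REML). `variance="per_roi"` rescales rows by
  first-pass ROI residual SDs, turning the heteroscedastic model into a
  homoscedastic one. p-values use a between-within degrees-of-freedom
  approximation (rows minus subjects minus predictors) by default. If the
  default gradient-based optimizer hits a singular profiled information
  matrix, the fit falls back to derivative-free Powell.
- **Regional group maps** (`stats.regional_group_map`): per-ROI Welch
  t-tests, Benjamini-Hochberg corrected at q = 0.10 (statsmodels
  `multipletests`, verified against the literal step-up definition).
- **Mediation** (`mediation.mediate`): product-of-coefficients with OLS
  (default) or mixed-model path regressions; indirect = a*b, direct from
  the outcome model, and total = direct + indirect *exactly* under OLS.
  Sobel (delta-method) or bootstrap (resampling subjects) confidence
  intervals. Five canonical decompositions are run by `run_hypotheses`:
  amyloid-beta acting on band powers through tau_i_z, and tau acting
  through tau_e_z, each controlling for the other tracer.

## 6. Problem sizes

The sizes used in tests and examples are this package's own choices, set to
keep a full simulate-fit-analyze round tractable on one CPU:

- End-to-end checks use 8 controls + 8 patients x 16 ROIs with 30
  basin-hopping iterations per fit (~0.1 s per regional fit, ~30 s per
  cohort round); 20 seeds complete in ~10 minutes.
- Recovery checks use 200 basin-hopping iterations; production analyses
  can afford the protocol's full 2000.
- Forward-oracle checks use 600 s simulations at 200 Hz with a 60 s
  burn-in discarded.

## 7. Limitations

- The model is linear; real spectra contain 1/f aperiodic components,
  alpha peaks of non-E/I origin and measurement noise not captured here.
- Amplitude information is discarded by the correlation cost; only
  spectral *shape* constrains the parameters.
- The mirror near-degeneracy means individual noisy fits can still swap
  channels; group-level statistics tolerate the resulting (rare, unbiased)
  outliers, but single-subject interpretation of `tau_e` vs `tau_i` at
  high noise should be cautious.
- Mediation on cross-sectional synthetic data estimates associations
  consistent with a causal path, not causality itself.
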