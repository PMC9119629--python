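# Methods

This note records the model, its numerical treatment, the choices made
where the design was genuinely open, and what the synthetic data used in
the tests does and does not establish. Internal units are milliseconds
and micromolar throughout; published per-molar per-second rate constants
are converted once at load time.

## Sensor chains and the conditional release rate

Each release mechanism is a continuous-time birth-death chain over the
number of calcium ions bound (0…N, with N = 5 for the fast synchronous
sensor and N = 2 for the slow asynchronous one). The generator `T` at
calcium concentration `c` has binding rates `(N−n)·k₊·c`, unbinding
rates `n·bⁿ⁻¹·k₋` (the cooperativity factor `b = 0.25 < 1` slows
unbinding as more ions are bound), and an extra `−γ` on the fully bound
diagonal: fusion removes the vesicle from the tracked state space
("killing"). The matrix convention is column = current state, row = next
state, so propagation is the left-multiplication `s(t+Δt) = (I+Δt·T)s(t)`;
this is documented to prevent transposition bugs.

Renormalizing `s` to unit sum after every step conditions the chain on
survival; `γ·s_N(t)` is then the instantaneous release rate given that no
release has yet occurred — the quantity a single-vesicle experiment with
replacement would measure. Without renormalization the state vector
decays as vesicles fuse and the readout conflates rate with depletion.

Numerics:

* Default step Δt = 0.005 ms. The linear (Euler) propagator shares its
  eigenvectors with the exact `exp(Δt·T)`, so both converge to the same
  quasi-stationary distribution; transients carry a first-order error in
  Δt (verified by a step-halving convergence test), and the propagator is
  validated against `scipy.linalg.expm` at 1e−6 per state from the
  quasi-stationary start.
* Step-size safety: if `Δt·max|T_nn| ≥ 1` at the requested step the
  quasi-stationary solver shrinks its internal step; the trace
  propagator instead raises an error naming the offending time, since
  silently changing the grid would desynchronize the output.
* Calcium traces sampled coarser than Δt (the synthetic generator's
  default grid is 0.1 ms) are linearly interpolated; linear was chosen
  for continuity, and nothing downstream depends on higher smoothness.
* The quasi-stationary rate is computed by renormalized power iteration
  in 1 ms blocks (the block matrix built once by repeated squaring),
  converged to relative change < 1e−10 per ms; a direct eigen-solve of
  the killed generator is kept as an independent cross-check, and the
  two agree to 1e−6 relative. An equilibrium-restricted flux-balance
  formula (`ν_{N−1}·λ_{N−1}·γ/(γ+μ_N)`) is a useful sanity check but is
  only accurate to a few per cent: it ignores how killing distorts the
  lower states.
* Detailed-balance equilibrium (no killing) is evaluated in log space so
  arbitrarily high concentrations cannot overflow.
* Trace-driven runs initialize from the quasi-stationary state at the
  trace's first value, so the conditional rate starts at its resting
  value rather than with an artificial transient.

At 100 nM resting calcium the computed quasi-stationary rates are
5.698e−9 ms⁻¹ (synchronous) and 1.834e−5 ms⁻¹ (asynchronous); at low
calcium they follow power laws with exponents equal to the site counts
(5 and 2), and at high calcium they saturate at the fusion rates γ from
below.

## Synthetic calcium traces

The generator emulates trial-averaged free-calcium measurements at a
release site: a 100 nM baseline plus, per spike, a multi-exponential
transient whose amplitude decays with sensor-to-cluster distance with
length constant 0.204 μm, shifted by a fixed onset delay that absorbs
the convention of timing spikes immediately before the action
potential's rising phase. The generator is strictly linear — transients
superpose and values never undershoot baseline. It does **not** model
buffer saturation near the channel cluster (which in reality adds a
fast decay component close in and changes the shape with distance), nor
stochastic per-trial fluctuations. The default transient decomposition
(2 μM/1.5 ms, 0.12 μM/20 ms, 0.015 μM/250 ms at the reference distance)
is an illustrative fixture with realistic magnitudes and time scales,
not a calibrated claim; consequently, tests driven by these traces
establish correctness of the machinery (propagation, superposition,
distance scaling), not quantitative fidelity to any particular synapse.
An impulse protocol (one elevated grid sample on a constant background)
is provided for impulse-response studies; on a zero background the
downstream hazard decays with a single exponential component, which the
suite checks via the instantaneous-time-constant estimator.

## Release profile and onset filter

The phenomenological profile is `r(t) = r₀ + Σ_c (P_c/τ_c)e^(−t/τ_c)u(t)`
with each component convolved by an ex-Gaussian onset-delay density
`a(t; k, μ, σ)` (exponential rate k ⊛ normal(μ, σ)). `P_c` is a mass
(expected releases), not a probability, and may exceed one; the filter
only re-times release, preserving each `P_c` exactly.

* The ex-Gaussian density and CDF are evaluated in log space via
  `scipy.special.log_ndtr`, stable for arbitrarily large `k·σ` (the
  naive closed form overflows at `k·σ` ≈ 38). `scipy.stats.exponnorm`
  serves as an independent oracle in the tests, never as the
  implementation.
* The exponential ⊛ ex-Gaussian convolution has the closed form
  `(k/(k−λ))·EMG(t;λ,μ,σ) − (λ/(k−λ))·EMG(t;k,μ,σ)` with `λ = 1/τ`;
  when `|k−λ| < 1e−9 ms⁻¹` this cancels catastrophically and the
  Erlang-Gaussian limit
  `λ[(t−μ−λσ²)·EMG(t;λ,μ,σ) + λσ²·φ_σ(t−μ)]` is used instead. A
  quadrature convolution oracle checks both branches at 1e−6 relative.
* Multi-spike combination: in expectation, each spike's component
  response is multiplied by `Π_{later j} (1 − D_c(t−t_sj))` using that
  component's own filter parameters; the spontaneous rate enters exactly
  once. A fixed-arrival mode applies hard Heaviside switching instead,
  processing arrivals in arrival-time order so the hand-off stays well
  defined even if a later spike's calcium overtakes an earlier one's.

## Facilitation

`P_c(n) = P_c0·F_c(n)` with `F_c = Π_i f_ci^ξ_ci`. Between spikes each
linear factor decays exponentially (τ_ci); at a spike it increments by
one minus a saturation correction `(d/N_ci)^N_ci`, so `f` can never
exceed `N_ci` and each factor contributes at most `L_ci = N_ci^ξ_ci`.
The pre-first-spike state is fully decayed (`f = 0`), so the first
spike's update yields `f = 1` and `F = 1`: a first spike behaves exactly
like a spike after an infinite rest, with no special-casing. Components
with `(N = 1, ξ = 0)` do not facilitate (the slowest, ~1 s components
are constrained this way by default). Facilitation applies only to the
masses `P_c`, never to the filter parameters. Negative ξ (release-
independent depression) is representable in the data model but ships in
no default table.

## Event sampler

The profile is read as the rate of an inhomogeneous Poisson process.
Per trial, per spike, per component: one ex-Gaussian arrival delay, a
Poisson(P_c(n)) count, exponential(τ_c) candidate times from the
arrival, truncation at the component's next arrival (in arrival-time
order). Spontaneous events form a homogeneous Poisson process at r₀.
The expected yield of a spike whose component arrival is followed Δ
later by the next one is `P·(1−e^(−Δ/τ))`, which the suite verifies by
Monte Carlo. A `single_vesicle` mode keeps only the first event (the
strict hazard reading) and can re-arm after an exponential refractory
delay with mean ε = 6.34 ms; the refractory default is off so ensemble
histograms can be validated against the analytic profile. Identical
seeds give identical event lists.

Validation compares 10⁵-trial histograms (0.5 ms bins over 0–100 ms)
against the bin-integrated analytic profile using exact two-sided
Poisson tail tests at the 3σ-equivalent level, allowing up to 1% of
bins outside — the chance-corrected reading of a per-bin 3-s.e. band
across 200 bins. Bin-integrated (not midpoint) expectations matter:
near onset the profile varies by two orders of magnitude within a bin.

## Fitting

Two stages, mirroring how the parameter tables were originally derived:
stage 1 fits per-case component masses to a rate trace with decay
constants and filter parameters frozen; stage 2 fits the facilitation
metaparameters to the pattern of final-spike masses across the stimulus
bank. The cost is `α·FVU(y,f) + β·FVU(log y, log f)` (α = β = 1 by
default): the linear term weights fast high-amplitude components, the
log term the slopes of slow ones. Optimization is Nelder-Mead over the
logarithms of the parameters (positivity by construction), with seeded
jittered restarts; ties go to the lowest cost, then the earliest
restart.

The stimulus bank crosses ramps of 1–5 spikes at ISIs {2, 5, 10, 20} ms
with probe spikes {2, 5, 10, 20, 50, 100, 200} ms after the ramp plus a
no-probe case: 160 raw cases, de-duplicated to 136 trains by collapsing
the one-spike ramps, which have no ISI. (A further 16 coincidences —
ramp n with probe equal to the ramp ISI versus ramp n+1 without probe —
are deliberately left uncollapsed to keep the conventional case count;
labels, not time sequences, are unique.)

Stage-2 identifiability deserves a caution: 5-spike ramps drive the
linear factors only to f ≈ 4.9, so for factors with large step counts N
the saturation term distinguishes candidate fits only at the ~1e−10
level and plain Nelder-Mead stalls on nearly flat shelves with N (hence
L) badly wrong while τ and ξ recover. The fitter therefore (i) polishes
by restarting the simplex at the incumbent, and (ii) for two-factor
components runs a deterministic scan over the split of the total
log-saturation between the factors, both orderings, with step counts
reset, keeping the best basin. On noiseless synthetic masses this
recovers all metaparameters of the shipped tables; on noisy data L for
weakly saturating factors should be treated as poorly constrained —
longer or faster stimulus ramps would be needed to pin it down. The
instantaneous time constant `τ(t) = −1/(d ln(r−r(0))/dt)` is estimated
with a 5-point Savitzky-Golay smoothed derivative; samples with
non-positive excess rate are NaN-flagged, never dropped silently.

## Known limitations

* The calcium generator is a stand-in for trial-averaged measurements:
  no spatial modelling, no buffer saturation, no noise.
* The well-mixed species hook (`generic_ctmc_step`) propagates any
  user-supplied generator but ships no channel/buffer/pump rate tables.
* Vesicle-pool dynamics (depletion, recycling, augmentation) are out of
  scope; single-vesicle mode plus refractory is the only pool-like
  behaviour.
* Steady-state facilitation under long trains is extrapolation: the
  stimulus bank probes at most 5-spike ramps, and the saturation limits
  of weakly saturating factors are not well constrained by it.
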