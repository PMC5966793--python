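# Methods

This note documents the model implemented in `driftmem`, its assumptions,
the numerical choices behind the implementation, what the synthetic-data
generator does and does not emulate, and known limitations.

## Model

### Encoding and decoding

A remembered angular location θ is represented by M neurons with von Mises
tuning, `r_i ∝ exp(κ cos(θ − φ_i))`, preferred values φ_i evenly tiling the
circle. Normalization is exact: rates are divided by their actual sum so
that the population encoding one of N items emits γ/N spikes·s⁻¹ to
machine precision (the Bessel-function form `M I₀(κ)` is only the large-M
limit of that sum). Spike counts are Poisson. Maximum-likelihood decoding
reduces, for this tuning profile, to the direction of the spike-weighted
resultant Σ nᵢ e^{iφ_i}; an antipodal pattern with zero resultant leaves
the likelihood flat and is resolved deterministically toward the smallest
wrapped preferred value among spiking neurons (a measure-zero event under
the model).

### Decoding-error distribution

For k decoded spikes the error density is

p(Δθ | k, κ) = (2π I₀(κ)^k)⁻¹ ∫₀^k ψ_k(r) e^{κ r cos Δθ} dr ,

which follows from the sufficiency of the resultant vector: under uniform
spike directions the resultant length r and direction are independent with
density ψ_k(r)/2π, and tilting by the von Mises weight e^{κ Σcos θ_i} =
e^{κ r cos Δθ} gives the joint law. k = 1 is treated analytically (a von
Mises density). ψ_k is estimated by Monte Carlo — 10⁶ uniform random walks,
histogrammed in 512 bins on [0, k] (96 bins in the sweep configuration) —
once per k, with a fixed internal seed; all walks for k ≤ k_max come from
a single cumulative pass. Each bin stores the mean and variance of r
within it, and the exponential integral uses the second-order cumulant
correction e^{c r̄ + c²σ²/2} per bin: the kernel varies by a factor e^{c h}
across one bin (c = κ cos Δθ, h the bin width), and a plain midpoint rule
at coarse binning leaves a systematic shape distortion that the delay
parameters would otherwise absorb. With the correction, 96-bin and
1024-bin densities agree to total variation ~10⁻⁵. The
simulate-and-decode oracle in the test suite is the binding definition of
correctness for this density (total variation < 0.02 at 10⁵ draws across
k ∈ {1, 2, 5, 10} × κ ∈ {5, 22, 50}).

The error grid is 720 equally spaced points on (−π, π]; on a uniform
periodic grid the trapezoid rule coincides with the rectangle rule, which
is what all circular quadratures use. Angles are radians internally and
degrees at every I/O boundary.

### Latency

Integration of population spikes to the threshold m at rate ρ = γ_eff/N
gives an Erlang(m, ρ) integration time; the observable latency adds an
independent shifted-exponential residual (rate ν, offset o). The latency
density is computed by FFT convolution of the two sampled factors on a
uniform grid ([0, 3] s at 1 ms by default). Each sampled factor is rescaled
to its exact in-window mass before convolving — the residual's jump
discontinuity at t = o otherwise inflates the rectangle-rule mass by
ν·dt/2 (≈ 0.5% at the default resolution). Density below the offset is set
to exactly zero (known support). The tabulated mean and variance agree
with the closed forms mN/γ + o + 1/ν and m(N/γ)² + 1/ν² to better than
0.5%.

### Spike survival

A spike emitted at time t survives to the end of the integration window
t_m with probability e^{−(t_m−t)/τ}. Averaging over the uniform emission
times of the first m − 1 spikes gives the survival probability
p_s(t_m) = (τ/t_m)(1 − e^{−t_m/τ}), continuous at t_m = 0 with limit 1.
The final spike always survives, so k − 1 ~ Binomial(m − 1, p_s(t_m)) and
k ≥ 1 always. The Erlang distribution of t_m is marginalized by trapezoid
quadrature on 2000 nodes covering [0, 20·m/ρ], quadratically clustered
near zero to control the short-time region; binomial terms are evaluated
in log space (xlogy) so p_s = 1 is exact. An event-level spike-process
simulation (integrate, decay, count) validates the distribution to
TV < 0.01.

### Delay mechanisms

* `linear_decay`: γ_eff = max(γ − ω·t_d, 0). The absolute slope form is
  the default because ω carries units s⁻² (a rate lost per second), which
  matches the canonical search range for this parameter, and because a
  slope of ≈ 0.16 s⁻² then corresponds to < 1% gain loss over a 4 s delay
  — the regime in which near-zero decay estimates are reported. The
  gain-normalized alternative γ·max(1 − ω·t_d, 0) is available via
  `relative_slope=True`.
* `exp_decay`: γ_eff = γ e^{−λ t_d}.
* `const_drift` / `setsize_drift`: the encoded value performs Brownian
  motion during the delay; the accumulated increment is von Mises with
  concentration χ = χ₀/t_d or χ₀/(N·t_d) (variance grows linearly in time,
  and in the set-size variant with the number of stored items). Gain — and
  therefore the latency distribution — is untouched, bit for bit.

Drift convolution is performed spectrally: the von Mises kernel's Fourier
coefficients are the Bessel ratios I_n(χ)/I₀(χ), so the circular
convolution multiplies the density's DFT by those ratios. This is exact
for grid-bandlimited densities and, unlike a tabulated kernel, does not
alias when χ is large enough that the kernel is narrower than the 0.5°
grid spacing (χ₀ ≈ 4600 at the shortest delay gives a kernel SD ≈ 0.6°).
At t_d = 0 the drift concentration is +∞ (identity kernel) by convention.

## Likelihood and fitting

The per-trial likelihood is the product of the marginal error density and
the marginal latency density for the trial's (N, t_d) cell; the coupling
of the two observables through the shared integration time is ignored,
consistent with marginalizing the spike count in the error factor. Both
densities are tabulated once per condition cell and evaluated by linear
interpolation on the density scale, floored at 10⁻¹² before the log so
quadrature zeros do not poison sums. A latency below the offset o is a
genuine support violation and contributes −∞ (flagged per trial; during
fitting the simplex responds by reducing o). Trials may be pooled across
experiments within a participant.

Drift and decay are only applied to the delay period, not to the brief
accumulation window itself.

Fitting is two-stage per participant:

1. **Grid search.** ν and o affect only the latency factor; κ, τ and the
   drift parameter only the error factor; γ and m both (for decay
   variants the mechanism parameter attenuates the gain and therefore
   enters both factors as a shared axis). The two factors are tabulated
   independently and combined by summation over the shared axes; the
   combined value at any grid point equals the direct dataset
   log-likelihood at that parameter vector (asserted to 10⁻⁹). Default
   ranges: γ ∈ (2³, 2⁹) in 25 log steps, m ∈ (2², 2⁷) in 11 log steps
   (rounded to integers), κ ∈ (2³, 2⁷) in 9, τ ∈ (2⁻⁶, 2) in 8,
   ν ∈ (1, 15) in 15 linear, o ∈ (0.1, 0.3) in 11 linear steps, plus the
   mechanism parameter with its discrete no-decay (ω = 0) and no-drift
   (χ₀ = ∞) sentinels. A log grid cannot include λ = 0, so the
   exponential-decay grid runs geometrically from ln(2)/2⁸ to ln(2); the
   no-decay limit is reachable by refinement.
2. **Nelder–Mead refinement** from multiple grid starts, on
   log-transformed positive parameters. Start selection is stratified:
   the best grid cell of each of the top distinct spike thresholds m,
   then of the top distinct tuning widths κ. The simplex sees m only
   through rounding, so it cannot leave the integer plateau it starts on
   — the grid must carry that dimension; and the error factor has a
   second basin in which a short survival time (k ≈ 1) with much sharper
   tuning mimics the true spike-count mixture, so κ strata let the
   simplex settle both basins and keep the better. Each refinement runs
   two stages: a profile stage with the mechanism parameter held at its
   start value (the likelihood is nearly flat along the mechanism ridge,
   where gain shifts partly compensate it, and a joint simplex tends to
   stall partway up that ridge), then a release stage over all seven
   parameters. After the multistart, one further refinement restarts from
   the winner with the mechanism at its no-effect stand-in; the fit with
   the highest attained likelihood is kept. The integer threshold is
   rounded at every evaluation; reported thresholds are integers. The
   mechanism parameter is clipped to [10⁻⁴, 10⁶] — finite stand-ins for
   the no-decay and no-drift sentinels; fits at the caps are flagged
   "virtually no drift/decay" rather than excluded. The refined
   log-likelihood never falls below the grid value (the start is kept if
   the simplex cannot improve it).

Variants are compared on raw summed log-likelihood (equal parameter
counts). γ and m trade off along a ridge — many (γ, m) pairs produce
nearly the same latency distribution — so individual estimates of these
two parameters are less stable than the latency predictions they imply;
recovery is therefore assessed on the predicted median latency as well as
on the parameters themselves.

## Trial classification

Exclusion filters (applied in order, first violation reported): response
saccade onset within [0.15, 2] s of the cue; amplitude within [50%, 150%]
of the array eccentricity; correction saccades deflecting the response by
at most 15°; no blink before fixation is re-established. The filter is
idempotent and order-independent across rows.

Retained trials are classified with a three-component mixture: von Mises
about the target, von Mises about each nontarget (shared concentration,
equal sub-weights — swap errors), and uniform guesses. The fit is by EM
with a method-of-moments concentration update (Best–Fisher inverse of
I₁/I₀); the log-likelihood is non-decreasing across iterations. Trials
with a target-component posterior strictly above 75% are labelled target
responses; a posterior exactly at the threshold is not a target. When the
fitted concentration collapses below 0.5 the von Mises components are
indistinguishable from the uniform component; the degeneracy is resolved
in favor of "uniform" and the concentration flagged unidentifiable.
Condition summaries report RMSD of wrapped signed deviations (degrees) and
median latency per (N, t_d) cell; circular SD and mean absolute error are
available alternatives; cells with fewer than 5 target trials are flagged,
not dropped.

## Synthetic data

The generator emulates the experimental design: set sizes {1, 2, 4} ×
delays {0.5, 1, 2, 4} s, balanced cells (~24 trials per cell per
participant), item locations uniform on the circle with ≥ 30° pairwise
separation. Trials are simulated at the event level from the same
mechanisms the likelihood tabulates: Erlang integration times, binomial
spike survival, vector-sum decoding of spike directions drawn from the von
Mises tuning profile (the dense-tiling limit that the analytic error
density describes; the finite-M population is exercised separately by the
decoding oracle, and the error density is insensitive to M once tuning
curves tile densely — M = 64 vs. 1024 differ by far less than the
Monte-Carlo tolerance), drift increments, and the shifted-exponential
residual. Default generating parameters sit near the regime the task
produces (γ = 95, m = 7, κ = 26, τ = 0.2 s, ν = 9.2 s⁻¹, o = 0.21 s,
χ₀ = 4600).

Lapses: with probability 2.2% the response is generated about a randomly
chosen nontarget (swap), with 0.4% uniformly. Swaps are undefined at set
size 1 and fold back into target responses there; mixture-recovery checks
therefore use set sizes {2, 4}. Lapse latencies are drawn from the same
latency model as target responses — a documented simplification, flagged
in the truth sidecar, since the model makes no claim about lapse
latencies. A configurable ~20% of trials (4% per filter type) violate the
exclusion rules to exercise the filters.

What the generator does **not** emulate: gaze trajectories and saccade
kinematics (records start at parsed trial level), the elevated latency at
the shortest delay seen in real data (attributed to preparedness, outside
the memory model), response biases, attraction/repulsion between items,
and sequential dependencies. Passing recovery tests therefore show that
the pipeline is self-consistent and identifiable in the modeled regime,
not that real data satisfy these idealizations.

## Simulation sizes and numerical defaults

Three tiers of numerical settings are provided. The default
(`ModelConfig()` with `ParameterGrid.table_default`) uses the canonical
search ranges and fine quadratures (1 ms latency grid on [0, 3] s, 512-bin
ψ tables, 2000 quadrature nodes). Simulation studies use
`ParameterGrid.sweep` (the same spans with ~4–9 steps per dimension and
the integer-m ladder {4, 7, 12}) with `ModelConfig.sweep()` (2 ms latency
grid on [0, 2.5] s, 96-bin moment-corrected ψ tables, 400 quadrature
nodes); `ParameterGrid.coarse` / `ModelConfig.fast()` sit between the two.
The simplex stage carries the precision; the grid only localizes the
starts.

Study sizes used by the simulation experiments: parameter recovery fits
20 replicate participants of 1200 trials (100 per condition cell) with
three stratified starts; model recovery fits all four variants to 10
drift-generated participants of 1440 trials each with two starts; the
decay-collapse check uses 9600-trial no-delay-effect datasets, a size at
which the sampling error of the fitted mechanism parameter lies below the
1% gain-loss threshold being tested (the fitted decay of a boundary-true
mechanism is half-normal, so at small samples its magnitude is dominated
by noise rather than by the mechanism). Forward consistency is checked
with 10⁵ simulated trials per variant and condition cell against the
default densities.

## Known limitations

* γ–m ridge: the latency factor constrains mainly m/ρ and the error factor
  mainly the surviving-spike count, so γ and m estimates trade off;
  compare variants and interpret latency predictions rather than these
  parameters individually at small n.
* The latency model cannot produce a higher median with equal variance
  across set sizes (an Erlang's mean and variance move together); real
  datasets showing that pattern will be fit imperfectly regardless of
  variant.
* Swap errors are injected phenomenologically; the population model here
  does not itself produce cue-binding errors (that requires conjunctive
  coding, out of scope).
* ψ_k tables are Monte Carlo estimates; their sampling noise (10⁶ walks)
  is far below the likelihood tolerances used here but is the ultimate
  precision floor of the analytic error densities.
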