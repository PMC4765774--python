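# Methods

## Model

Per-cell abundance of a degron-tagged protein in a growing bacterial
culture is modelled as

    dP/dt = α − μ·P − Vmax·P/(Km + P)

- **α** — synthesis rate, proteins·cell⁻¹·h⁻¹. Construct-specific
  (promoter, RBS, copy number), so it is never compared across constructs;
  it is eliminated by the control subtraction below.
- **μ·P** — dilution by growth; μ in h⁻¹ is measured per interval from
  log-OD slopes, never assumed.
- **Vmax·P/(Km+P)** — Michaelis–Menten proteolysis. Default working values
  for the ClpAP/N-degron system: Vmax = 15,000 proteins·cell⁻¹·h⁻¹,
  Km = 600 proteins·cell⁻¹ (≈1 μM in a 1 fL cell). At typical balanced-
  growth abundances (~10,000–40,000 proteins/cell) P ≫ Km, degradation is
  effectively zero order, and the model reduces to the linear balance
  `dP/dt + μP = α − β` with β ≈ Vmax, whose closed form
  `P(t) = (α−β)/μ + (P₀−(α−β)/μ)e^(−μt)` is used as the oracle for the
  numerical integrator.

Numerics: adaptive LSODA with rtol 1e-8, atol 1e-6 proteins/cell, dense
output for event location. `Km = 0` with `Vmax > 0` is treated as the
strict zero-order limit (degradation = Vmax while P > 0), not an error;
the resulting vector-field discontinuity at P = 0 is irrelevant in the
operating regime (P ≫ 0) where the limit is used. Abundances are clipped
at 0 on output (integrator noise only). The `mu = 0` closed form falls
back to the linear-in-time limit.

`steady_state` solves the nonnegative root of
`μP² + (μKm + Vmax − α)P − αKm = 0` in closed form; with μ = 0 an
equilibrium exists only when the protease can saturate above α, otherwise
an unbounded-growth error is raised.

## Rate estimation

Per replicate: P_j = activity_j/OD_j; dilution events (recorded as a
per-sample factor ≥ 1) rescale OD to cumulative biomass for μ computation
but leave P untouched. Per consecutive interval:
μ_i = Δln(OD_cum)/Δt, dP/dt_i = ΔP/Δt, P̄_i the endpoint mean, and
net rate (α−β)_i = dP/dt_i + μ_i·P̄_i. The replicate's net rate is the
mean over a window of at most 4 intervals (five time points), at least 3.
When more intervals exist than the cap, the earliest contiguous run whose
μ values agree within 15 % relative spread is chosen (balanced-growth
selection); failing that, the first intervals are used. A global
exponential μ fit is deliberately not the default — interval slopes track
drifts in growth that a global fit would average away.

β is the difference of group-mean net rates, control minus condition. The
two groups are unpaired, so the s.e.m. is propagated in quadrature
(condition-only s.e.m. available via `sem_mode`). Negative β estimates
are reported as-is so downstream tests remain unbiased. Significance
between groups uses Welch's unequal-variance two-sided t-test (robust to
the unequal replicate counts and variances typical of strain comparisons);
degenerate zero-variance groups return p = 1 (identical) or 0 (disjoint
constants) explicitly.

A zero-order validity flag is raised (never failed on) when min(P) <
10·Km in matching units: below that, the apparent β underestimates Vmax
by roughly the occupancy factor P/(Km+P);
`correct_first_order_bias` provides the corresponding rescaling.

## Synthetic data

The generator emulates shake-flask experiments: OD600 growing
exponentially from 0.05, dilution into fresh medium when OD exceeds 1
(factor recorded; per-cell P unaffected), sampling each hour over 4 h,
6 biological replicates per condition, and multiplicative lognormal noise
(mean exactly 1) applied independently to OD and activity readings with a
default CV of 5 % — a typical plate-reader noise scale chosen once as a
stand-in, since instrument noise is rarely characterised. All randomness
flows from one seeded `numpy` Generator; identical designs are
bit-identical.

Balanced-growth replicates start at the model steady state: stationary
per-cell abundance is the definition of balanced growth, and it makes the
finite-difference estimator exact at zero noise (the identity
`dP/dt + μP̄ = α − β` holds exactly for constant P, while on a transient
the endpoint-mean P̄ introduces an O((μΔt)²) discretization bias).

Induction experiments start from the pre-condition steady state, switch
at t_induction to leak_fraction·α synthesis, and ramp degradation in as
`Vmax·(1 − e^(−Δt/clpp_delay))` — a first-order activation emulating
protease accumulation; resuspension lag on OD is a separate knob. These
non-idealities are exactly the effects that make measured knockdowns lag
ideal predictions.

What the generator does **not** emulate: heteroscedastic or correlated
noise, sampling jitter, blank-subtraction error, plasmid-loss
subpopulations, growth-rate feedback from the knockdown target, and
stochastic (molecule-level) degradation. Passing recovery tests therefore
demonstrates estimator correctness under the model's own assumptions, not
robustness to every real-data pathology.

## Post-induction β

After synthesis repression, P decays — balanced growth does not hold. The
repression-only arm replaces the protease-deletion strain as the
no-degradation reference (same leak synthesis, no Vmax). Because the
arithmetic-mean slope rule is biased on transients, the default estimator
uses the interval identity exact for any zero-order trajectory,

    α − β = μ·(P₁ − P₀·e^(−μΔt)) / (1 − e^(−μΔt)),

which reduces to μ·P̄ for stationary data; the plain slope rule remains
available (`method="slopes"`, agreeing within a few percent at Δt = 0.5 h).
Arms must share their sampling grid — no implicit interpolation. The
zero-order validity flag is attached to the result, since post-induction
abundance typically falls toward Km and the reported β is then a lower
bound on Vmax.

## Knockdown analysis

`simulate_knockdown` integrates the full ODE from P₀ after setting
α → leak·α and Vmax per mode (repression only: 0; combined: Vmax), and
reads t50/t90 — time to 50 % / 10 % of the abundance at induction — from
integrator root events. With zero leak and no degradation,
t50 = ln 2/μ analytically, the test oracle. `growth_rate_sweep` tabulates
both modes across μ; the benefit ratio t50_repression/t50_combined is ≥ 1,
equals 1 iff Vmax = 0, and grows monotonically as μ falls — degradation
matters most exactly when dilution is weakest, e.g. when depleting an
essential protein slows growth.

## Units

Internally proteins·cell⁻¹ and hours. Measurement data arrive as
activity/OD; the calibration slope (default 10 proteins·cell⁻¹ per
RFU·OD600⁻¹) is linear and applies to rates unchanged. It derives from a
rough purified-protein correlation, so converted values carry a
coarse-calibration flag and should be read as order-of-magnitude.
Molarity uses a 1 fL cytoplasmic volume (configurable); residue flux
multiplies by the construct's residue count, obtainable from an
amino-acid FASTA.

## Problem sizes

Default verification sizes: 6 replicates × 5 time points per condition;
500 stochastic datasets for the bias/coverage study; knockdown sweeps
over 6 growth rates. These are the package's standard reference
configurations; all complete in seconds.

## Known limitations

- β is apparent and zero-order by construction; near Km it is biased low
  (flagged, optionally rescaled, never silently corrected).
- The control-subtraction assumes the control strain shares α with the
  test condition; perturbation plasmids or inducers that change synthesis
  shift β estimates (use matched controls).
- No nonlinear least-squares fit of the full ODE to time courses is
  provided: identifiability of (Vmax, Km) from activity/OD data in the
  saturated regime is poor, and the interval estimator uses the data
  where they are informative.
- Welch's test is a pragmatic default for small unpaired groups; exact
  permutation tests are out of scope.
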