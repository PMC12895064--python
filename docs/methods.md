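# Methods

## Model families

Every feature (molecule) is modelled as a deterministic waveform plus
i.i.d. Gaussian observation noise. Four families are considered, all
parameterised by an initial amplitude A ≥ 0 (signal units), an angular
frequency ω > 0 (rad/h, period T = 2π/ω), and an equilibrium value y:

- **harmonic** — `A·exp(γt/2)·cos(ωt+φ) + y`, the extended harmonic
  oscillator. The amplitude-change coefficient γ (per hour) makes the
  envelope grow (`forced`, γ > 0) or decay (`damped`, γ < 0).
- **square** — carrier sinusoid plus a third harmonic with fixed weight
  0.25: `A·exp(γt/2)·[sin(ωt+φ) + 0.25·sin(3ωt+3φ)] + y`. The envelope
  multiplies the whole two-component sum, so γ rescales the waveform
  uniformly rather than only its fundamental.
- **cycloid** — fundamental plus second harmonic,
  `A·exp(γt/2)·(−0.5)·[cos(2ωt+2φ) − 2·cos(ωt+φ)] + y`, an asymmetric
  shape produced by a circadian and an ultradian (T/2) component. The
  ultradian frequency is hard-locked at 2ω, never searched separately.
- **transient** — a periodic gated Gaussian impulse. With the cycle
  phase u = t mod T, the signal is `A·exp(−½((u−p_τ)/σ)²) + y` wherever
  u ≥ p_τ and the baseline y before the onset within each cycle. The
  onset p_τ ∈ [0, T) and width σ > 0 are in hours. This family carries
  no exponential envelope, so its regulation class is reported as
  `not_applicable`. The one-sided gate means the impulse rises
  instantaneously at u = p_τ and decays as a half-Gaussian; σ is bounded
  to [Δt/2, T/4] (Δt = sampling interval) to keep it identifiable —
  narrower than half a sampling step cannot be resolved, wider than a
  quarter period stops being an impulse.

The harmonic-multiple ratios (3ω, 2ω) and mixing constants (0.25, −0.5,
2) are fixed constants of the families. This is deliberate: a free
multi-harmonic regression fits more shapes but loses the one-to-one map
between parameters and regulatory interpretation.

The exponent is exp(+γt/2) so that the sign of γ reads directly as
forced/damped; |γ| is capped at 6/t_max (envelope change at most e^±3
over the observed span) to prevent unidentifiable exponential blow-up.

## Fitting

Each family is fitted to the replicate-resolved point cloud (replicates
are never averaged — that preserves the error degrees of freedom used by
the F-test) with bounded trust-region-reflective least squares and
analytic jacobians. Tolerances: 1e-8 on parameters and cost, at most
5000 function evaluations per start. Bounds: ω ∈ [2π/(T(1+ρ)),
2π/(T(1−ρ))] with expected period T (default 24 h) and period tolerance
ρ (default 0.25); A ≥ 0; y within the data range ± 2 spreads; A at most
4 data spreads.

Phase and impulse location make the objective multimodal, so fitting
multi-starts deterministically:

- oscillatory families: 8 equispaced initial phases in [0, 2π), with
  A₀ = (max−min)/2, y₀ = mean, γ₀ = 0, ω₀ = 2π/T;
- transient: the onset is *profiled out*. The gate makes the objective
  discontinuous in p_τ (a finite-difference jacobian explodes at the
  onset), so p_τ is frozen at each candidate — the observed timepoint of
  the per-cycle maximum, one candidate per cycle — while the smooth
  parameters (A, ω, σ, y) are solved with analytic jacobians; p_τ is
  then refined on a coarse-to-fine grid (steps Δt/4, then Δt/16) and the
  solution is polished by a final smooth five-parameter solve, which is
  valid because the objective is smooth between gate crossings.

The family with the lowest SSR is selected; exact ties break toward
fewer parameters, then toward the fixed order harmonic > square >
cycloid > transient (simplest interpretation first). Flat series
short-circuit to an exact A = 0 fit; series with fewer observations than
parameters + 1 are skipped with a warning, never aborting a batch. There
is no randomness anywhere in fitting: identical input gives identical
output, and features are independent work units (any execution order
yields the same results).

## Rhythmicity calling

The selected model is tested against its zero-amplitude reduction: with
A = 0 every family collapses to the constant y, so all q = p − 1 shape
parameters become inert and the lack-of-fit statistic is

    F = ((SSR₀ − SSR₁)/q) / (SSR₁/(n − p)) ~ F(q, n − p),

with SSR₀ the residual sum of squares about y and SSR₁ the model's.
SSR₀ < SSR₁ clamps to F = 0 (p = 1); an exact fit (SSR₁ = 0 with
non-trivial improvement) is flagged `perfect_fit` and reported with
p = 0 rather than dividing by zero.

Agreement between fitted and observed values is confirmed with Kendall's
τ (tau-b, tie-corrected; exact small-sample distribution where scipy
provides it, normal approximation under ties). Both p-value families are
Benjamini–Hochberg adjusted across all analysed features — one family
per statistic, not per model kind — and a feature is called rhythmic
only if **both** adjusted values fall below α (default 0.05). This
conjunction is deliberately conservative: after best-of-four selection
and nonlinear fitting, the raw F-test is anticonservative on pure noise
(its nominal null distribution does not account for selection or for the
effective flexibility of the fit — empirically ~30% of flat-noise
features reach raw p < 0.05), and it is the τ confirmation plus BH step
that restores control. On 1000 flat-noise features the end-to-end
rhythmic-call rate is ~0 at α = 0.05.

Regulation is classified from the fitted γ against a stability band of
±0.01/h (configurable): below −0.01 damped, above +0.01 forced,
otherwise stable. The default corresponds to at most ≈ ±27% envelope
change over 48 h — visually flat.

## Synthetic panels

The generator emulates a dense circadian design: period 24 h, span 48 h
(two cycles), sampling every 2 h, two replicates, i.i.d. Gaussian noise
per observation — matching the least-squares objective. Default
parameter ranges: A ∈ [1,3], γ ∈ {−0.05, 0, +0.05}, φ ∈ [0, 2π),
y ∈ [−1, 1], p_τ ∈ [0, 24), σ ∈ [1, 3] h. Panels mix all four families
plus flat nulls and are bit-for-bit reproducible from their seed.

What the generator does **not** emulate: count noise (negative binomial
overdispersion), batch effects, missing-at-random structure,
heteroscedasticity, autocorrelated noise, or period drift across days.
Passing tests therefore demonstrate correctness of the fitting and
calling machinery under the model's own assumptions, not robustness to
every artefact of real omics data; on real tables the z-score
normalisation (default on) removes scale differences but not
distributional ones.

## Numerical choices and edge cases

- Time is continuous hours with t = 0 at the first sample; no zeitgeber
  re-anchoring.
- During optimisation p_τ is bounded by [0, T(1+ρ)) because the period
  varies with ω; the fitted p_τ is wrapped modulo the fitted period so
  the reported value always satisfies 0 ≤ p_τ < T.
- Z-scoring uses the population standard deviation; zero-variance
  features are passed through unchanged and resolve to A = 0 downstream.
- Missing cells are dropped per feature, never imputed.
- Results are written at 6 significant digits; `period_hours` = 2π/ω is
  a derived convenience column. For transient fits the γ and φ columns
  are empty; for the other families p_τ and σ are empty.

## Known limitations

- **Transient amplitude is weakly identified at sparse sampling.** With
  2-h sampling, an impulse of width σ ∈ [1,3] h places only one or two
  samples on its flank per cycle, so height A and width σ trade off:
  the least-squares optimum frequently has a narrower, taller (or wider,
  shorter) impulse than the truth while fitting the data better than the
  true parameters do. Under the reference design with noise sd 0.1 and
  A = 2, the period is recovered within ±0.5 h in ≈ 90% of simulations
  but the amplitude lands within ±10% in only ≈ 50% — an identifiability
  limit of the design, not an optimiser failure (in every missed
  replicate the fitted SSR is below the SSR at the truth). Amplitude
  estimates for the oscillatory families do not suffer from this
  (> 95% within ±10% under the same conditions). Denser sampling or
  wider impulses restore amplitude identifiability.
- **Late-onset transients can be unobservable.** Because the gate is
  one-sided, an impulse with onset p_τ inside the last inter-sample gap
  of the cycle (p_τ > T − Δt at the final sampled phase) contributes
  nothing at any sampled time: the realized series is exactly constant
  and is — correctly — fitted as a zero-amplitude flat signal. Under the
  default generator (p_τ uniform over the cycle, 2-h sampling) roughly
  Δt/T ≈ 8% of transient draws are of this kind, which bounds attainable
  model-"recovery" on transient panels below 100% even without noise.
- The raw F-test p-value should not be interpreted marginally (see
  above); use the adjusted values and the composite rhythmic flag.
- One expected period per run; free-running period drift and
  differential rhythmicity between conditions are out of scope.
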