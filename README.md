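# rhythmfit

Detection and characterisation of rhythmic behaviour in temporal omics
data — bulk or single-cell transcriptomics, proteomics, metabolomics, or
any feature-by-time abundance table sampled over one or more cycles.

Many biological rhythms are not sinusoidal: square-like on/off
expression, asymmetric crest/trough profiles driven by a circadian plus
an ultradian component, and short periodic impulses from a stable
baseline are all common and are misclassified or missed by
single-sinusoid methods. `rhythmfit` fits four bounded waveform families
to every molecule and lets the data choose:

| family | model, x(t) | shape |
|---|---|---|
| harmonic | A·e^{γt/2}·cos(ωt+φ) + y | damped/forced sinusoid |
| square | A·e^{γt/2}·[sin(ωt+φ) + 0.25·sin(3ωt+3φ)] + y | flattened, square-like |
| cycloid | A·e^{γt/2}·(−0.5)·[cos(2ωt+2φ) − 2·cos(ωt+φ)] + y | asymmetric, 24 h + 12 h pair |
| transient | A·exp(−½((u−p_τ)/σ)²) + y for u = t mod 2π/ω, u ≥ p_τ; else y | periodic impulse |

Here A is the initial amplitude, γ the amplitude-change coefficient
(γ < 0 damped, γ > 0 forced, |γ| small stable), ω the angular frequency
(period 2π/ω hours), φ the phase, y the equilibrium value, and, for the
impulse family, p_τ the within-cycle onset and σ the impulse width. The
harmonic-multiple frequencies (3ω, 2ω) and the mixing coefficients are
fixed constants of the families, which keeps every fitted parameter
interpretable.

Per feature, all four families are fitted by bounded nonlinear least
squares and the lowest sum of squared residuals (SSR) wins. Rhythmicity
is then called by a lack-of-fit F-test of the chosen model against its
zero-amplitude reduction (a constant at y),

F = ((SSR₀ − SSR₁)/q) / (SSR₁/(n − p)),  q = p − 1,

confirmed by Kendall's τ between fitted and observed values; both
p-value families are Benjamini–Hochberg adjusted across the batch and a
molecule is rhythmic only if both adjusted values pass α (default 0.05).
The fitted γ classifies each rhythmic molecule as damped, forced, or
stable.

## Worked example

```python
import numpy as np
import rhythmfit as rf
from rhythmfit.models import ModelParameters, TWO_PI

truth = ModelParameters(A=2.0, gamma=-0.03, omega=TWO_PI / 24, phi=1.2, y=0.5)
times = np.repeat(np.arange(0.0, 48.0, 2.0), 2)          # 2 h grid, 2 replicates
rng = np.random.default_rng(7)
values = rf.evaluate_harmonic(truth, times) + rng.normal(0.0, 0.2, times.size)

fits = rf.fit_all_models(rf.TimeSeries("demo_gene", times, values))
best = rf.select_best(fits)
```

Running this (`python examples/fit_single_series.py`) prints:

```
 harmonic: SSR=   1.243  RMSE=0.161
   square: SSR=   3.468  RMSE=0.269
  cycloid: SSR=   8.178  RMSE=0.413
transient: SSR=  19.628  RMSE=0.639

best model: harmonic
  amplitude A      = 1.845   (truth 2.0)
  gamma (per hour) = -0.0245 (truth -0.03: damped)
  period (hours)   = 23.88  (truth 24)
```

The harmonic family has the lowest SSR, so it is selected; the fitted
amplitude, period, and damping coefficient recover the generating values
to within the noise, and γ ≈ −0.025/h falls below the −0.01/h stability
band, so the molecule is classified as actively damped.

For a whole table, use the batch entry point or the CLI:

```python
dataset = rf.read_table("expression.csv", layout="wide")   # columns ZT0_r1, ZT0_r2, ...
calls = rf.run_analysis(dataset, rf.RunConfig(expected_period=24, alpha=0.05))
rf.write_results(calls, "results.csv")
```

```
rhythmfit simulate --seed 3 --n-per-class 25 --out panel.csv --truth truth.csv
rhythmfit run --input panel.csv --layout wide --period 24 --alpha 0.05 --output results.csv
```

The results CSV carries one row per molecule: the selected family, all
fitted parameters (plus the derived period in hours), RMSE, the F and τ
statistics with raw and BH-adjusted p-values, the regulation class, and
the rhythmic flag. `examples/` holds short narrative scripts for
single-series fitting, batch analysis, and regulation classification.

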