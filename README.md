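# tfcdiff

Anomalous-diffusion modelling of binned clinical time series.

Long-term monitoring of a diagnosed parameter — here thoracic fluid
content (TFC, the inverse of chest electrical impedance, 1/Ohm, measured
by impedance cardiography in heart-failure care) — routinely shows
sudden large excursions that a Gaussian picture of symptom evolution
treats as near-impossible.  `tfcdiff` implements the alternative: the
parameter's probability density evolves under a fractional Fokker–Planck
equation (FFPE),

    ∂P/∂t = D_t^{1−α} K_α ∂²P/∂x²,   0 < α < 2,

whose solution spreads as ⟨(x−x₀)²⟩ = 2K_α t^α / Γ(1+α), i.e. with
Hurst exponent H = α/2.  For α < 1 the propagator is cusped and
fat-tailed, so large jumps of the monitored parameter are expected
events.  The package is aimed at researchers who want to fit this model
to binned longitudinal registrations, or to study when such a fit is
informative at realistic cohort sizes.

It provides:

* `tfcdiff.propagator` — the FFPE Green's function as a similarity
  series with a fixed-Talbot inverse-Laplace oracle, moments, and
  admissibility checks (density nonnegative, normalized, slot masses in
  [0, 1]);
* `tfcdiff.evolution` — evolution of a 15-slot binned distribution by
  convolution with the propagator, pooled stationary estimates,
  total-variation diagnostics;
* `tfcdiff.fitting` — (α, K_α) estimation by minimizing the RMSE between
  evolved and observed slot frequencies (grid search + Nelder–Mead),
  reporting H = α/2;
* `tfcdiff.synthetic_data` — a continuous-time random walk (CTRW)
  cohort generator emulating irregular clinical registration (605
  patients / ~2860 measurements by default, Pareto waits, Gaussian
  jumps, 31-day registration periods);
* `tfcdiff.io` / `tfcdiff.cli` — CSV/JSON formats and a `tfcdiff`
  command-line pipeline.

## Worked example

Simulate a cohort with subdiffusive latent dynamics (exponent 0.8),
bin it into 31-day periods, and fit the model:

```python
import numpy as np
from tfcdiff import (SimulationConfig, FitConfig, simulate_cohort,
                     bin_observations, fit_params)

cfg = SimulationConfig(n_patients=1058, ctrw_alpha=0.8, seed=3, n_periods=12)
table = simulate_cohort(cfg)                      # ~5000 visit records
obs = bin_observations(table, cfg.slot_edges, cfg.period_length_days, 12)
fit = fit_params(obs, FitConfig(target="all_periods", initial="first_period",
                                horizon_t=12.0, k_grid=np.logspace(-2, 2, 21)))
print(f"alpha = {fit.alpha:.3f}  K_alpha = {fit.k_alpha:.2f}  "
      f"H = {fit.hurst:.3f}  rmse = {fit.rmse:.4f}")
```

which prints

```
alpha = 0.770  K_alpha = 12.21  H = 0.385  rmse = 0.0136
```

The fitted exponent α ≈ 0.77 recovers the generating value 0.8 within
the single-cohort sampling scatter (σ(α̂) ≈ 0.14 at this sample size —
see `docs/methods.md`); H < 1/2 is the fat-tail signature, and the RMSE
is on the scale of the slot masses (each of the 15 slots holds a
probability, so 0.0136 means the model misses a typical slot frequency
by about one percentage point).

The same pipeline from the shell:

```sh
tfcdiff simulate --seed 3 --out obs.csv --binned-out binned.csv
tfcdiff fit --obs binned.csv --out fit.json
tfcdiff propagator --alpha 0.47 --k 1 --t 1 --x0 0 --grid -10:10:201 --out prop.csv
```

`prop.csv` tabulates the cusped subdiffusive density at the exponent the
model estimates for the clinical cohort (α = 0.47, H = 0.235).

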