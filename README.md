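# fibrenew

Renewal-process and M/M/∞ birth–death analysis of phase-singularity
(PS) and wavelet population dynamics in fibrillation.

## The problem

Atrial fibrillation continually creates and destroys short-lived
organizing features — phase singularities (the pivots of re-entrant
rotors and the free ends of wavefronts) and the propagating wavefronts
themselves. If their formation is a Poisson stream with rate constant
λf (per ms) and each entity is destroyed independently at rate λd
(per ms), the number of concurrently alive entities is an M/M/∞ queue
with closed-form steady state:

    N = λf / λd                       (mean count, the offered load ρ)
    P(N = n) = ρⁿ e^(−ρ) / n!         (Poisson count distribution)

The count trajectory also defines an empirical birth–death transition
matrix whose second largest eigenvalue modulus (SLEM) sets the spectral
gap 1 − SLEM — the *mixing rate* at which the population relaxes to its
quasi-stationary distribution. Because the continuous-time relaxation
modes are −k·λd, slowing both rate constants at fixed ρ leaves the mean
count unchanged but slows mixing, which is the proposed mechanism for
spontaneous termination of fibrillation.

`fibrenew` implements the whole chain for anyone studying these
dynamics in mapped fibrillation data or simulations: electrogram
preprocessing (QRS subtraction, zero-phase Butterworth filtering,
dominant frequency, sinusoidal recomposition, Hilbert phase), PS
detection by two topological-charge methods, zero-phase wavefront
extraction, bipartite tracking into an event look-up table, exponential
renewal-rate estimation with χ² goodness of fit and stationarity
diagnostics, the M/M/∞ predictions, and the birth–death spectral
analysis — plus a synthetic-data module that generates every input with
known ground truth.

## Worked example

Simulate a 10⁶ ms epoch at λf = 0.27/ms, λd = 0.05/ms, re-estimate the
rates from the event stream, and compare the M/M/∞ predictions with the
observed running count:

```python
from fibrenew import synthetic_data as sd, renewal_stats as rs, mminf_model as mm
from fibrenew.types import MMInfParams

params = MMInfParams(lambda_f=0.27, lambda_d=0.05, duration_ms=1_000_000, seed=1)
events = sd.simulate_mminf_events(params, kind="PS")

inter, lifetimes = rs.extract_intervals(events, kind="PS")
fit_f = rs.fit_exponential(inter)       # lambda_f from inter-formation times
fit_d = rs.fit_exponential(lifetimes)   # lambda_d from uncensored lifetimes

pred = mm.predict_pmf(fit_f.lambda_per_ms, fit_d.lambda_per_ms, n_max=20)
series = mm.population_series(events, dt_ms=1.0)
rep = mm.compare_to_observed(pred, series, stride=100)
spec = mm.estimate_bd_matrix(series)
```

This prints (via the fields of the returned objects):

```
lambda_f = 0.2700/ms  (95% CI 0.2690-0.2710, GOF p = 0.65)
lambda_d = 0.0500/ms  (95% CI 0.0499-0.0502, GOF p = 0.06)
predicted mean count = 5.40, observed = 5.41
count distribution vs Poisson: chi2 = 14.15, p = 0.44
SLEM = 0.9515, spectral gap = mixing rate = 0.0485
```

Both rate constants are recovered, the mean equation predicts the
observed average count (5.4 entities), the count histogram is
consistent with Poisson(ρ), and the one-ms-lag spectral gap sits at
λd·dt ≈ 0.05 — the slowest relaxation mode of the birth–death chain.

The same analysis runs from the shell on files:

```sh
fibrenew simulate --lambda-f 0.27 --lambda-d 0.05 --duration 1000000 --seed 1 --out events.csv
fibrenew epoch --input events.csv --input-kind events --epoch-ms 1000000 --out report.json
```

and on phase movies via `fibrenew detect` / `track` / `fit` /
`predict` / `spectral`, with `scale-study` and `contrast` for the
field-of-view and cohort analyses. See `docs/methods.md` for the model,
conventions and numerical choices.

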