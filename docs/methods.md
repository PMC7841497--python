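# Methods

## The model

Fibrillation sustains itself by continually regenerating short-lived
organizing features: phase singularities (PS — the pivots of re-entrant
rotors and the free ends of wavefronts) and the wavefronts themselves.
`fibrenew` treats the formation and destruction of these entities as
renewal processes: inter-formation times and lifetimes are i.i.d.
exponential with rate constants λf (formations per ms, population-level
Poisson arrivals) and λd (per entity per ms). Under those two
assumptions the concurrent entity count N(t) is an M/M/∞ queue, and its
stationary law is closed-form:

- mean count N = λf / λd (the offered load ρ),
- count distribution P(N = n) = ρⁿ e^(−ρ) / n! (Poisson).

Beyond the stationary predictions, the count trajectory defines an
empirical birth–death transition matrix at lag one frame. Its second
largest eigenvalue modulus (SLEM) gives the spectral gap 1 − SLEM,
identified here with the *mixing rate*: the speed at which the count
chain relaxes to its quasi-stationary distribution. The continuous-time
generator of the M/M/∞ chain has eigenvalues −k·λd (k = 0, 1, 2, …), so
scaling both rate constants down by a factor c at fixed ρ leaves the
mean count unchanged but slows mixing by exactly c. That is the
mechanism behind the sustained-versus-terminating contrast: episodes
with slower rate constants spend longer away from quasi-stationarity,
giving stochastic excursions toward extinction more room.

## Analysis chain and its parameters

1. **Preprocessing** (`signal_processing`). Electrograms: optional
   average-beat QRS subtraction (window 120 ms); zero-phase Butterworth
   band-pass (defaults 1–500 Hz human, 30–500 Hz sheep, order 4,
   forward–reverse); dominant frequency from the in-band periodogram
   peak (search band 3–15 Hz); sinusoidal recomposition using
   single-cycle cosine wavelets at the dominant period with amplitude
   equal to the clipped negative slope; Hilbert-transform phase.
   Voltage movies instead get a per-frame normalized Gaussian spatial
   filter (σ = 4 px) before per-pixel Hilbert phase.
2. **Detection** (`phase_mapping`). The kernel detector reports a PS
   wherever the wrapped-phase circulation around a 2×2 plaquette is
   ±2π (position at the plaquette center, chirality = sign). The
   double-ring detector requires the same ±1 winding on Chebyshev rings
   of radius 1 and 2 px and merges adjacent candidate pixels; it cannot
   report within 2 px of the boundary (incomplete outer ring) — a
   documented blind spot. Wavefronts are zero-phase isolines: marching
   squares on sin φ at level 0 keeping only the cos φ > 0 branch, with
   interior contour ends recorded as free ends.
3. **Tracking**. Frame-to-frame association is minimal-total-distance
   bipartite matching (Hungarian assignment; greedy nearest-neighbour
   available) within radius r, chirality-consistent for PS; wavefronts
   match by shared-pixel polyline overlap (threshold 1 px, vertices
   rasterized to their unit cell so sub-pixel drift still overlaps).
   Defaults follow clinical basket practice: r = 4 mm, minimum lifetime
   τ = 10 ms. Intervals are half-open [onset, offset): a single-frame
   entity has lifetime dt. Entities alive at the last frame are
   right-censored; entities present in frame 0 are left-censored.
4. **Rate estimation** (`renewal_stats`). λf is the exponential MLE of
   pooled inter-formation times, λd of uncensored lifetimes
   (right-censored lifetimes are excluded, not imputed; the exclusion
   bias is < 1% once λd·T ≳ 100, checked by simulation). When tracking
   imposed τ, lifetimes are fitted as τ plus an exponential excess.
   Confidence intervals use the exact gamma pivot for n ≤ 500 and the
   normal approximation beyond.
5. **Model comparison** (`mminf_model`). Observed mean and count
   histogram versus the Poisson prediction (χ², bins pooled from the
   tail to expected ≥ 5); predicted-versus-observed mean correlation
   across epochs (Pearson). The pipeline decorrelates the running count
   before the χ² by subsampling at ~3 destruction time constants,
   because consecutive frames of N(t) are strongly autocorrelated and
   would otherwise inflate the statistic; on short epochs the stride is
   capped so at least 100 snapshots remain.
6. **Spectral analysis**. The transition matrix is estimated on states
   0…max(count) ("maximum tracked states"); never-visited rows get an
   absorbing self-loop and are flagged and excluded from the quoted
   state count. SLEM is the second largest eigenvalue *modulus*
   (complex eigenvalues allowed — empirical matrices need not be
   reversible); mixing rate = spectral gap = 1 − SLEM at the series'
   native frame interval, which is recorded because the gap scales
   with it.

## Numerical choices

- **Phase conventions.** Phase lives in (−π, π]; wrapped differences in
  [−π, π). All phase interpolation (grid upsampling, decimation)
  operates on the unit phasor e^{iφ} and takes the angle of the
  interpolated phasor — linear interpolation of wrapped angles tears at
  the branch cut.
- **Frame-quantized intervals.** Intervals measured from a tracked
  movie are multiples of the frame interval. A ceiling-quantized
  exponential is geometric in the step count, so for such samples the
  rate MLE is λ = −ln(1 − 1/mean steps)/dt (the plain reciprocal mean
  is biased by ~dt/2) and the χ² GOF tests step counts against the
  fitted geometric law with lattice atoms pooled to expected ≥ 5.
  Continuous samples use equal-probability bins (K = min(n/5, 30),
  df = K − 2). Null rejection rates of both paths were verified at
  5–8% by simulation.
- **GOF degrees of freedom.** Interval GOF charges one parameter
  (df = K − 2). The count-histogram comparison uses df = K − 1: its
  Poisson mean comes from the rate fits, not from the histogram.
- **Generator discretization.** The one-frame chain of a generator Q is
  exp(Q·dt) (always stochastic). The Euler form I + Q·dt is provided
  but valid only while dt < 1/max|Qnn|; beyond that it has negative
  entries and a spurious eigenvalue modulus above 1.
- **Ties and determinism.** Assignment ties are broken by lowest entity
  id; every simulation takes one seeded `numpy` Generator per call and
  records the seed in metadata; repeated runs of the pipeline on the
  same input are byte-identical.
- **Stationarity diagnostics.** Autocorrelation of the inter-formation
  sequence with the ±1.96/√n white-noise band, plus λ estimates from 20
  random sub-windows (10% of the epoch each); the stream is flagged
  non-stationary when ≥ 2 windows sit more than 3 SE from the
  full-epoch rate (a single 3-SE excursion among 20 windows is expected
  under the null). A zero-variance interval sequence is flagged
  degenerate rather than tested.

## What the synthetic data emulates — and what it does not

`simulate_mminf_events` *is* the model: Poisson formations, independent
exponential lifetimes, right-censoring at the epoch boundary. Locations
are uniform and carry no spatial correlation. `script_from_events`
plants one static spiral defect per event (rejection-sampled to keep
concurrent defects ≥ 6 px apart) and renders the wrapped angle of
∏(z − zᵢ)^{qᵢ}·e^{−iωt}, so detector+tracker recovery can be scored
against exact truth; `make_pair_script` instead creates and destroys
defects as opposite-chirality pairs, conserving total topological
charge. The two-variable excitable medium (Aliev–Panfilov class, k = 8,
a = 0.1, ε₀ = 0.002, μ₁ = 0.2, μ₂ = 0.3, D = 1, explicit Euler at
dt = 0.04 on a 120×120 grid, 12.9 ms per time unit) produces planar
waves under S1 and a figure-of-eight spiral pair under an interior S2
patch delivered 45 time units after S1 — a timing tuned empirically to
the vulnerable window of this medium. Synthetic electrograms are
atrial sinusoids plus a derivative-of-Gaussian far-field template at
known R-times, with the clean component retained as ground truth.

Epoch cohorts for the termination contrast add between-epoch rate
heterogeneity: a lognormal tempo multiplier (CV 0.35) scales both rates
together and an independent lognormal load multiplier (CV 0.15)
perturbs ρ. These spreads were chosen to match the between-epoch
dispersion visible in clinical basket cohort summaries (rate CIs
implying a rate CV of roughly 0.4 and a mean-count CV of roughly 0.15);
without them every epoch of a cohort would estimate an almost identical
mean count and any rate difference would masquerade as a count
difference.

None of the generators reproduce ionic action-potential morphology,
atrial anatomy, fibrosis, meandering rotor trajectories, or
measurement noise in electrode contact. Passing tests therefore show
that the estimators and the spectral analysis are correct *given* the
renewal structure, and that the detection/tracking chain is exact on
ideal topological defects — not that clinical recordings satisfy the
renewal assumptions; that question is what the stationarity and GOF
diagnostics are for on real data.

## Problem sizes

Library defaults and test problem sizes were chosen at desk scale:
simulated epochs of 10⁵–10⁶ ms at the three observed rate regimes
(0.27/0.05, 0.035/0.013, 0.002/0.001 per ms), movies of 32×32–64×64
pixels and 1.5–3 k frames, cohorts of 24 epochs of 90 s. Cohort-level
clinical effect sizes (regression R² across dozens of patients,
absolute SLEM means of specific recordings) depend on unreleased
recordings and are covered instead by the property-level analogues in
the test suite.

## Known limitations

- PS detection cannot distinguish rotational activation from conduction
  block; no endo–epicardial pairing; 2-D grids only.
- The double-ring detector is blind within 2 px of the boundary and
  merges defects closer than ~3 px.
- The χ² count comparison assumes the decorrelation stride renders
  snapshots independent; for epochs much shorter than ~300 destruction
  time constants the test is anticonservative.
- Exponential is the only lifetime law fitted; alternative laws
  (Weibull, gamma) are out of scope beyond the GOF diagnostic.
- The empirical transition matrix uses unrestricted transition counting
  (multi-step jumps between frames allowed) at the native frame
  interval; the gap therefore scales with dt and comparisons across
  recordings must hold dt fixed.
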