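# Methods

## The measurement and the model

Raw bovine milk is ~87% water, and over the microwave band (0.5–40 GHz)
its complex permittivity ε*(ω) = ε′ − iε″ is dominated by the
orientational relaxation of bulk water, perturbed by everything dissolved
or emulsified in it.  The package models a measured spectrum as

    ε*(ω) = ε∞ + Δε / (1 + (iωτ)^α) + σ_dc / (iωε0) + A(iω)^(n−1)

with ω = 2πf in rad/s.  The Cole–Cole term carries the bulk-water
dispersion: Δε (dielectric strength) measures how much orientable bulk
water responds, τ (relaxation time, ps) how fast, and α ∈ (0, 1] the
symmetric broadening of the loss peak (α = 1 is the Debye limit; milk
sits near 0.98–0.99).  σ_dc (S/m) is the ionic dc conductivity, visible
as a 1/ω tail in ε″ at the low end of the band, and A(iω)^(n−1) is the
Jonscher tail of a slower, sub-band process.  ε0 is taken as
8.85 × 10⁻¹² F/m.  Fractional powers use the principal branch,
(iωτ)^α = (ωτ)^α e^{iαπ/2}, and the reported loss is ε″ = −Im ε*, so both
loss terms are positive.

The biological premise: milk-fat-globule surfaces bind hydration water.
More fat (or more globule surface) converts bulk water to bound water,
which cannot follow a GHz field, so Δε falls — a negative fat–Δε
coupling.  Reproductive state modulates fat globule size through
progesterone, which is why the fitted parameters carry a pregnancy
signal.

## Fitting

`fit_spectrum` minimises the stacked relative residual
[(ε′_m−ε′_o)/ε′_o ; (ε″_m−ε″_o)/max(ε″_o, 0.05)] with scipy's
trust-region-reflective least squares under physical box bounds
(ε∞ ∈ [1,10], Δε ≤ 120, τ ∈ [1,50] ps, α ∈ (0.5,1], σ_dc ∈ [0,3] S/m).
Relative weighting matches the instrument's relative accuracy class (~5%
on both parts); the 0.05 floor on the loss denominator keeps weights
finite where ε″ crosses zero.  The Jonscher term is frozen at A = 0 by
default — it is not resolvable inside the band for milk-like spectra —
and can be freed.

Initialisation is physics-based: τ from the loss-peak position restricted
to the upper half of the log band (below that, the conductivity tail can
masquerade as a peak); (ε∞, Δε) by solving the two-point Debye system at
the band endpoints given that τ (the band top at 40 GHz sits
mid-dispersion for water-like τ, so reading ε∞ directly off ε′(40 GHz)
overestimates it badly); σ_dc from ε″·ωε0 at the lowest frequency.  The
default is 5 starts (the guess plus four seeded ±30% perturbations,
tolerance 1e-10, ≤2000 evaluations each); for simulated cohorts the
single-start preset `COHORT_FIT_OPTIONS` is used, which was verified to
reach the same optimum as the multi-start default on this spectrum family
and keeps the tens of thousands of fits in a cohort study fast.

Parameter uncertainties per fit come from the Gauss–Newton covariance at
the optimum; replicate SDs (each sample is measured in triplicate in the
emulated workflow) use the n−1 denominator.

## The synthetic cohort generator

No real herd data ship with the package; the generator emulates the
study conditions so every downstream stage is testable.

* **Milk solids** are independent normals — fat 3.37 ± 0.54%, protein
  3.36 ± 0.09%, lactose 4.74 ± 0.11% — floored at 0.5%.
* **Latent dielectric parameters** per sample sit around a
  literature-informed milk baseline at 25 °C (ε∞ = 5.5, Δε = 68,
  τ = 9 ps, α = 0.985, σ_dc = 0.9 S/m — these are not study-reported
  values) with reproductive-stage-dependent dispersion, and for
  established pregnancy (day ≥ 16 after a successful AI) a small mean
  offset (≈2 plateau SDs: Δε −0.6, τ +1.2 ps, α +0.004, σ −0.02) that
  displaces the operating point.  The offsets are what make the pregnant
  state form a distinct, compact cluster in PCA score space, matching the
  qualitative biplot finding; without them a tightened cluster nested
  concentrically in the baseline cloud has *negative* silhouette.
* **Stage dispersions.**  The post-day-16 plateau SDs are the observed
  values (Δε 0.3, τ 0.6 ps, α 0.002, σ 0.01 S/m).  The pre-insemination
  and failed-AI dispersions are *calibration constants*: they were set by
  simulating the full simulate → 5%-noise → triplicate-fit → stage-SD
  pipeline and solving (two-point scans at 150 cohort seeds per point
  with common random numbers, verified on independent seeds; the
  per-cohort drop statistic has an SD of ~10–13 points, so low-powered
  scans mislead) so that the expected percent drop in fitted-Δε SD is
  44% for the pregnant design and 3.26% for the nonpregnant design.
  The two arms are calibrated independently — the displaced stage-3
  operating point changes the fit-noise level slightly — landing at
  0.695 (stage 1), 0.832 (before) and 0.789 (after a failed AI).
* **Fat–Δε coupling.**  Within each stage,
  Δε = base + r·S·z_fat + S·√(1−r²)·η, which realises an exact
  within-stage correlation r and total SD S simultaneously (a single
  fixed slope cannot satisfy both the −0.66 correlation and the 0.3
  stage-3 SD ceiling given fat SD 0.54).  The configured target
  (−0.66) is the correlation to be *measured* on fitted parameters;
  since fit noise (SD e ≈ 0.40 on a triplicate-mean Δε, a measured
  calibration constant) attenuates correlation by s/√(s²+e²) ≈ 0.90, the
  latent coupling is deepened to −0.73.  Infeasible configurations
  (|latent r| > 1) raise a calibration error.
* **Instrument noise** multiplies every ε′ and ε″ point by independent
  1 + N(0, 0.05) draws (the probe's relative accuracy class), flooring
  ε″ at 0.  Each sample gets three replicate noisy spectra.
* **Designs.**  Weekly (12 cows, 7-day interval, ~8 months), daily (10
  cows, 65 days) and a cross-sectional random survey (117 single
  samples, 50 pregnant).  Fixture designs reproduce the exact analysis
  point counts: pregnant 66/8/14 across stages over five cows,
  nonpregnant 70/69 before/after over seven cows.  SCC (log-normal) and
  days-in-milk (uniform 30–300) are nuisance columns; a weather column
  is not generated.

All randomness flows from one root seed through named
`numpy.random.SeedSequence` children, so identical seeds give identical
tables and spectra, and adding a pipeline stage never perturbs earlier
draws.

What the generator does **not** emulate: lactation-curve dynamics,
between-cow baseline differences (no cow random effect), solids
covariances, temperature drift, or probe-contact artefacts.  Passing
tests therefore show that the analysis machinery recovers what this
generative model puts in — not that the biological effect sizes hold on
real herds.

## Staged variability analysis

Records of cows with a successful AI are partitioned into stage 1
(pre-insemination, day-since-insemination ≤ 0), stage 2 (days 1–15) and
stage 3 (day ≥ 16); failed-AI cows split into before/after at the first
failed insemination, the AI day itself counting as "after".  Day
counting starts at 1 the day after insemination.  The headline statistic
is the percent drop 100·(SD_ref − SD_cmp)/SD_ref of the per-stage sample
SD of a fitted parameter, by default stage 1 vs stage 3 (pregnant,
pooled over cows) and before vs after (nonpregnant); the pairing is a
configuration option, and stages with fewer than two points report an
absent SD rather than zero.

## Correlations and PCA

Pearson correlations are pairwise-complete with two-sided p-values from
the t-transform on n−2 degrees of freedom, unadjusted for multiplicity.
Zero-variance columns flag their pairs as undefined instead of
propagating NaNs.  PCA standardises each of (Δε, τ, α, σ_dc) to zero
mean and unit variance first — the units differ by orders of magnitude,
so the correlation-matrix decomposition is the only sensible one — and
fixes loading signs by making the largest-magnitude entry of each
component positive.  Cluster separation between stage groups in score
space is summarised by the mean silhouette.

## The classifier

A self-normalizing network: four inputs (Δε, τ, α, σ_dc) → eight dense
layers of 50 units with SELU activation (λ = 1.0507009873554805,
α = 1.6732632423543772) and alpha dropout p = 0.01 after each → one
sigmoid output; 18 151 parameters.  Weights are LeCun-normal (zero mean,
variance 1/fan_in), which with SELU keeps activations near zero
mean/unit variance through depth — verified as a property test.  Alpha
dropout saturates dropped units to −λα and rescales so the
self-normalizing property survives; it is training-only.

Implementation is pure NumPy (forward, backprop, Adam), which keeps the
dependency footprint small and makes the whole training loop exactly
reproducible from one seed (initialisation, class down-sampling, the
15-per-class holdout, dropout masks, batch order).

Training: Adam with β1 = 0.9, β2 = 0.999, ε = 1e-5, learning rate 1e-3,
20 epochs, full batch by default (a few hundred points).  Loss is binary
cross-entropy; the held-out test set doubles as the validation series of
the learning curves.  The majority class is randomly down-sampled to the
minority size before splitting.

Feature scaling: the pregnancy signal lives in small excursions around a
common milk baseline, so features are centred at fixed reference values
(Δε 68, τ 9 ps, α 0.985, σ 0.9 S/m) and divided by typical day-to-day
deviation scales (0.5, 1, 0.003, 0.015).  Plain division by gross
reference magnitudes leaves the inputs as near-constant vectors, and the
network then cannot learn at all (training loss pinned at ln 2).  Both
centers and scales are configuration constants fixed before any split,
so no statistics leak between train and test.

On the default synthetic pool the classifier reaches holdout accuracies
around 0.7–0.8; the signal is partly the stage-3 mean offset and partly
the variance contrast between states.  The study's own herd-data
accuracy is not a reproducible quantity here, since that data is not
available.

## Problem sizes and numerical choices

The default frequency grid is 201 log-spaced points over 0.5–40 GHz.
The variability-drop quantities are averaged over 20 cohort seeds (the
per-seed drop has SD ≈ 12 points, dominated by the 14-point stage-3
sample); the full-path fat-coupling correlation is estimated on
200-sample cohorts, averaged over a few independent cohorts for a stable
estimate; solids means use n = 10 000.  Convergence tolerance for fits
is 1e-10 on the relative objective; ties and degenerate inputs
(flat spectra, single-point stages, constant PCA columns, empty classes)
raise typed errors or flagged-absent values as described above.

## Known limitations

* The generator's effect sizes are calibrated, not mechanistic: the 44%
  drop is built in by construction, so recovering it validates the
  statistics pipeline, not the biology.
* Replicate noise is independent per point; real VNA errors are
  correlated across frequency, which would make fitted-parameter noise
  larger than modelled here at equal point-wise accuracy.
* The classifier sees samples as exchangeable; it ignores cow identity
  and time ordering, as does the emulated protocol.
* Correlation p-values are always recomputed from r and n via the
  t-transform, never copied from external tables; a "density %"-style
  covariate without a defined measurement is not generated.
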