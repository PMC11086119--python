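# lactowave

Microwave dielectric spectroscopy (MDS) of raw bovine milk as a
non-invasive window on reproductive state.  The package implements the
full analysis chain for detecting pregnancy-associated change in milk
from 0.5–40 GHz complex permittivity spectra:

1. **Forward model & fitting** — the permittivity of milk is modelled as
   a Cole–Cole bulk-water dispersion plus ionic dc conductivity and a
   Jonscher low-frequency tail,

   ε\*(ω) = ε∞ + Δε / (1 + (iωτ)^α) + σ_dc/(iωε0) + A(iω)^(n−1),

   and fitted to measured spectra by bounded multi-start complex
   nonlinear least squares (`fit_spectrum`), giving per-sample
   (Δε, τ, α, σ_dc) with replicate SDs.
2. **Synthetic cohort generation** — seeded simulation of the study's
   three sampling protocols (weekly n=12, daily n=10 over 65 days, and a
   117-sample random survey with 50 pregnant cows), with milk solids,
   a negative fat–Δε coupling, pregnancy-stage-dependent parameter
   dispersion, and 5% relative instrument noise in triplicate.
3. **Staged variability analysis** — partition of longitudinal fits into
   pre-insemination / early-pregnancy (days 1–15) / established-pregnancy
   (day ≥ 16) stages, or before/after a failed insemination, and the
   percent drop in per-stage SD of each parameter.
4. **Multivariate statistics** — Pearson correlation matrices of the
   fitted parameters against milk solids, and standardised PCA with
   biplot exports and silhouette-based cluster separation.
5. **Pregnancy classifier** — a self-normalizing neural network (8 × 50
   SELU layers with alpha dropout, single sigmoid output, Adam, binary
   cross-entropy; pure NumPy) trained on class-balanced, reference-scaled
   (Δε, τ, α, σ_dc) features.

It is aimed at researchers in biosensing / dairy-science labs who want
to prototype or stress-test this kind of dielectric pregnancy-monitoring
pipeline without instrument access: everything runs on synthetic cohorts
whose generative truth is known, so recovery can be checked end to end.

See `docs/methods.md` for the model, calibration and design choices.

## Worked example

```python
import numpy as np
import lactowave as lw
from lactowave.pipeline import fit_cohort
from lactowave.variability import drop_report

# a five-cow pregnant cohort with the study's stage point counts 66/8/14
preg = fit_cohort(lw.simulate_cohort(lw.CohortDesign.pregnant_fixture(seed=3)))
print({k: round(v, 1) for k, v in drop_report(preg)["drops_pct"].items()})

# seven cows whose insemination failed (70/69 points before/after)
non = fit_cohort(lw.simulate_cohort(lw.CohortDesign.nonpregnant_fixture(seed=3)))
print({k: round(v, 1) for k, v in drop_report(non)["drops_pct"].items()})
print("r(delta_eps, fat) =",
      round(np.corrcoef(non['delta_eps'], non['fat_pct'])[0, 1], 2))
```

prints (seed 3):

```
{'delta_eps': 61.9, 'tau': 51.9, 'alpha': 53.5, 'sigma_dc': 32.7}
{'delta_eps': 5.7, 'tau': 20.0, 'alpha': 14.1, 'sigma_dc': 0.1}
r(delta_eps, fat) = -0.57
```

i.e. on this cohort draw the day-to-day SD of the dielectric strength Δε
collapses by ~62% once pregnancy is established (the expected drop over
many cohorts is 44%; a single 14-point stage-3 sample makes any one
cohort noisy), the other Cole–Cole parameters tighten similarly, while
the nonpregnant herd shows only small drops, and the fitted Δε carries
the built-in negative correlation with milk fat.

The same steps are exposed as a CLI:

```bash
lactowave simulate --design pregnant-fixture --seed 3 --out run/
lactowave fit run/spectra/P001_d002_r0.csv
lactowave pipeline --seed 7 --out runs/full    # simulate→fit→stats→classifier
```

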