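# herfret

Quantifying HER2–HER3 receptor dimerization in tissue by FLIM-FRET, and
asking what it predicts.

The HER2–HER3 heterodimer is the most potently mitogenic pair of the HER
(ErbB) receptor family and the target of dimerization-blocking therapeutics.
Its level in a tumour cannot be read off HER2 expression alone: in a network
where HER1–4 all compete for each other, the steady-state amount of
HER2–HER3 dimer can be almost uncorrelated with total HER2 or HER3.
Measuring the dimer itself requires a proximity assay; Förster resonance
energy transfer (FRET) read out by fluorescence lifetime imaging (FLIM) is
the most stringent, reporting donor–acceptor proximity below ~10 nm through
the shortening of the donor fluorophore's excited-state lifetime:

```
FRET efficiency  E = 1 − τ_DA / τ_D
```

with τ_D the donor (Alexa546-band) lifetime alone and τ_DA its lifetime in
the acceptor's presence, each taken as the region-of-interest average of
per-pixel fits to time-correlated single-photon-counting (TCSPC) decay
histograms.

This package implements that pipeline end to end as tested, reusable
components, driven by a synthetic-data generator in place of patient tissue:

- **`herfret.synthetic`** — forward models: TCSPC photon-count cubes
  (donor-only and donor+acceptor serial sections, Poisson noise, log-normal
  photon texture, spatially localized short-lifetime autofluorescence) and
  patient cohorts (receptor abundances → network equilibrium → FRET → 
  proportional-hazards survival outcomes, with clinico-pathological
  covariates drawn from published cohort marginals).
- **`herfret.flim`** — per-pixel Poisson maximum-likelihood decay fitting
  (mono- and bi-exponential), lifetime maps, lifetime-window filtering to
  suppress autofluorescence, ROI averaging, FRET efficiency.
- **`herfret.network`** — mass-action dimerization equilibria of the HER
  family (simple 3-receptor and detailed 4-receptor models), an independent
  kinetic (ODE) route to the same steady state, population simulations and
  the correlation regimes between [E23] and total HER2/HER3.
- **`herfret.cohort`** — ROC with the Youden-optimal cutpoint, Kaplan–Meier
  curves, univariate and full multivariate Cox proportional-hazards models
  at 5- and 10-year horizons, Fisher exact association tests.
- **`herfret.io` / `herfret.pipeline` / `herfret.cli`** — TIFF+JSON and CSV
  formats, the deterministic end-to-end pipeline, and the `herfret` command.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from herfret import (
    DecaySimConfig, FlimConfig, simulate_core_pair, core_fret,
    CohortSimConfig, simulate_cohort, run_cohort_analysis,
)

# one tissue core: 20% of the donor population dimerized, 30% of photons
# from short-lifetime autofluorescence
cfg = DecaySimConfig(image_shape=(64, 64), fret_fraction=0.2,
                     auto_fraction=0.3, photons_per_pixel=5000, seed=7)
donor, donor_acceptor = simulate_core_pair(cfg)
res = core_fret(donor, donor_acceptor, FlimConfig(filter_window=(1.2, 4.0)))
print(f"tau_D = {res.tau_d:.3f} ns, tau_DA = {res.tau_da:.3f} ns, "
      f"E = {100 * res.fret_efficiency:.2f}%")

# a synthetic cohort and its survival analysis
table = simulate_cohort(CohortSimConfig(n_patients=300, seed=1))
report = run_cohort_analysis(table)
hr = report["cox_multivariate"][10.0].summary.loc["fret_high"]
print(f"Youden threshold = {report['threshold']:.2f}%")
print(f"10-yr multivariate HR (FRET high vs low) = {hr['hr']:.2f} "
      f"({hr['ci_low']:.2f}-{hr['ci_high']:.2f}), p = {hr['p']:.2g}")
```

Output:

```
tau_D = 2.799 ns, tau_DA = 2.486 ns, E = 11.18%
Youden threshold = 9.72%
10-yr multivariate HR (FRET high vs low) = 4.75 (2.80-8.05), p = 7e-09
```

The core-level lifetimes recover the generative model (a 20% FRET fraction
at half the donor lifetime fits to E ≈ 11.2% once window truncation is
accounted for), and in the cohort the dichotomized FRET signal carries a
strong independent hazard for distant metastasis, because the generator
links the hazard to the latent HER2–HER3 dimer level.

The same stages are scriptable from the shell:

```sh
herfret simulate-flim --outdir core0 --seed 1 --fret-fraction 0.2
herfret fret --donor core0/donor.tif --da core0/donor_acceptor.tif
herfret simulate-cohort --n 300 --seed 1 --out cohort.csv
herfret cohort --table cohort.csv --threshold auto
herfret run-all --seed 1 --outdir run1
```

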