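# Methods

This note documents the models behind `herfret`, the defaults that matter,
the numerical choices, and what the synthetic data does and does not
emulate.

## TCSPC decay model and fitting

A TCSPC acquisition records, per pixel, a histogram of photon arrival times
over a repetition window `T` (default 12.5 ns, an 80 MHz repetition rate)
split into `n_bins` bins (default 256, matching 256×256-pixel, 256-bin
acquisitions). The emission of a fluorophore with lifetime τ, truncated to
the window and with a delta-function instrument response, puts a photon into
bin `k` (edges `t_k = k·T/n`) with probability

```
p_k(τ) = (e^(−t_k/τ) − e^(−t_{k+1}/τ)) / (1 − e^(−T/τ)).
```

Counts are Poisson, so fitting maximizes the Poisson likelihood rather than
least squares — at 256 bins most bins hold only a handful of photons and
Gaussian approximations bias the estimate.

**Mono-exponential MLE.** Substituting `r = e^(−T/(n·τ))` turns `p_k` into a
window-truncated geometric distribution in the bin index — a one-parameter
exponential family whose sufficient statistic is the mean bin index. The
MLE therefore solves the monotone scalar equation

```
E_model[k](r) = r/(1−r) − n·r^n/(1−r^n) = k̄_data,
```

found by bisection to machine precision. No initial guess, no optimizer
state: fits are exactly deterministic and cheap enough to fit every pixel
of a 256×256 cube in well under a second. Histograms whose mean bin index
falls outside the attainable range (e.g. all photons in the first bin) are
flagged non-converged. Fit quality is reported as a reduced Pearson
chi-square against the fitted model.

The dispersion of this estimator sits at the Cramér–Rao bound: at τ=2.5 ns
and 10⁴ photons the Monte-Carlo SD is within ~10% of the bound computed
from the numerically differentiated Fisher information (the acceptance
script recomputes both).

**Bi-exponential MLE.** Two lifetimes and a photon fraction, maximized with
L-BFGS-B over (log τ_short, log τ_long, logit f) from two fixed deterministic
starts seeded by the mono fit. One lifetime can be fixed or bounded (e.g. a
known autofluorescence band). Nested-model safeguards: a minor fraction
below 1% falls back to the mono fit; lifetimes within 5% of each other
collapse to mono with a degeneracy flag (the two-component model is
unidentifiable there).

**Lifetime maps and filtering.** Per-pixel mono fits (optionally after
summing histograms over b×b blocks; the map is then at the binned
resolution) with an intensity threshold of 100 photons/pixel (400 for
bi-exponential mode). Autofluorescence suppression is a two-stage
surrogate for the unpublished filtering algorithm used with real FFPE
material: (1) fit each pixel, (2) keep pixels whose fitted lifetime falls
inside an acceptance window bracketing the donor band (default 1.2–4.0 ns).
The filter is idempotent and never revalidates a pixel. An alternative
bi-exponential mode fits a bounded short-lifetime contaminant per pixel and
reports the long component.

**ROI averaging and FRET.** The region-of-interest lifetime is the
photon-weighted mean of valid-pixel lifetimes (uniform weighting is a
config option; the choice matters little for the homogeneous synthetic
cores but is surfaced because "average lifetime" is ambiguous).
FRET efficiency is `E = 1 − τ_DA/τ_D` from the filtered donor-only and
donor+acceptor ROI means. Negative E (τ_DA > τ_D, possible because the two
cubes come from serial sections) is reported with a flag, never clipped:
clipping would distort downstream ROC behaviour.

Note one systematic of the mono-fit-on-mixture readout: for a donor
population with FRET fraction `ff` at τ_fret = τ_donor/2, the fitted
mixture lifetime matches mean arrival times under window truncation, so the
recovered E is slightly above the naive `ff·(1 − τ_fret/τ_donor)` (11.2%
instead of 10% at ff = 0.2). The pipeline's inverse map accounts for this
when choosing a core's FRET fraction from a target efficiency.

## Synthetic cubes

Per pixel the expected histogram is
`photons · [w_auto·p(τ_auto) + (1−w_auto)·((1−ff)·p(τ_donor) + ff·p(τ_fret))]`,
with Poisson counts drawn from it. Defaults: τ_donor = 2.8 ns (Alexa546
band), τ_fret = 1.4 ns, τ_auto = 0.6 ns, 5000 photons/pixel expected.

- *Photon texture*: a unit-mean log-normal factor per pixel (σ = 0.3), so
  intensity thresholding is exercised.
- *Autofluorescence*: spatially localized blobs (a Gaussian-smoothed random
  field thresholded at the right coverage), with contaminant photon weight
  0.9 inside blobs and 0 outside; coverage is set so the photon-averaged
  contamination equals `auto_fraction`. Localization is deliberate: a
  spatially uniform contaminant would bias every pixel equally and no
  per-pixel filter could help; localized contamination is exactly what
  lifetime filtering exploits, and matches how autofluorescent structures
  (collagen, elastin, fixation artefacts) appear in FFPE tissue.
- *Serial sections*: the donor-only and donor+acceptor cubes are
  independent realizations sharing tissue-level parameters — no pixel
  registration, since the readout is ROI averages.
- An optional Gaussian IRF convolution is available in the forward model;
  the fitters assume a delta IRF (deconvolution is out of scope), so the
  default forward model keeps the IRF off and the fitting oracles stay
  closed-form.

What this does *not* emulate: optics and spectral bleed-through, detector
afterpulsing/dead-time, within-core biological heterogeneity of the FRET
fraction, registration artefacts. Passing tests therefore demonstrate the
correctness of the estimators under the stated noise model, not robustness
to every property of real tissue data.

## HER receptor network

Receptors E1..E4 form reversible dimers `E_i + E_j ⇌ E_ij` with
dissociation constants `Kd_ij`; at equilibrium `[E_ij]·Kd_ij = f_i·f_j`
for free monomer concentrations `f_i`, with the homodimer convention
`[E_ii] = f_i²/Kd_ii` and conservation counting `2·[E_ii]`. The system is
closed (no synthesis, degradation, trafficking or ligand binding): the
argument being modelled is purely a binding-equilibrium one.

Two solvers: (1) the algebraic route — a geometrically damped fixed-point
iteration on the free concentrations (globally stable and
positivity-preserving) polished by batched Newton steps, converged to
relative conservation residuals below 1e-12 and checked to 1e-8 on every
state an analysis produces; (2) the kinetic route — integration of
`d[E_ij]/dt = kon·f_i·f_j − koff·[E_ij]` (LSODA, rtol 1e-12) from the
all-monomer state until the largest relative derivative falls below 1e-10.
The two agree to better than 1e-6 on random instances of both models; the
kinetic route serves as the independent oracle in tests. The batch solver
vectorizes across patients, which is what makes the 500-replicate survival
studies cheap.

**Models.** The *simple* model has receptors HER1–3 and heterodimers only
(E12, E13, E23). The *detailed* model has HER1–4 and all ten pairs.
Defaults (normalized concentration units): heterodimer Kd = 1;
**homodimer Kd = 100**. The weak-homodimer default is both biological
(HER3 is kinase-impaired and homodimerizes poorly; heterodimerization with
HER2 is the dominant mode) and structural: with strong homodimerization
HER1 is sequestered as ~√(total₁), which damps the patient-to-patient
variation in free HER1 that drives the decorrelation between [E23] and the
totals; the detailed model then no longer reproduces the regime behaviour
the simple model shows.

**Population regimes.** Per patient, totals are drawn from
Normal(mean, cv·mean) truncated at zero by re-drawing (no point mass at
zero), default cv = 0.3, n = 400 patients. Named regimes (means for
HER1..HER4): `C` = (100, 1, 1, 1), `D` = (100, 0.1, 1, 1),
`her2_over` = (1, 100, 1, 1), `her3_over` = (1, 1, 100, 1). Pearson
correlation on raw concentrations is primary (matching scatter-plot
practice), Spearman is reported alongside. Observed behaviour, computed by
the acceptance script:

- Regimes C and D (HER1 dominant): |r(E23, total₂)| and |r(E23, total₃)|
  ≈ 0.1–0.2 — the dimer level forgets the totals, because free HER1 enters
  the denominator of both free HER2 and free HER3 and its spread dominates.
- HER2 over-expression: r(E23, total₃) ≈ 0.99 while r(E23, total₂) ≈ 0.1 —
  flooding by one partner makes the dimer track the *scarce* partner; HER3
  over-expression mirrors it.
- Isolated E23 binding (all other pairs off, comparable abundances):
  both correlations are strong, ≈ 0.69. This has a sharp ceiling: in the
  weak-binding limit E23 ∝ T2·T3 and corr(T2·T3, T2) = 1/√(2 + cv²), which
  is 0.692 at cv = 0.3 and at most 1/√2 ≈ 0.707 for any cv; saturation
  (min-like binding) only lowers it. "Strong correlation" in this baseline
  therefore means ≈ 0.7, not arbitrarily close to 1.

A caution on estimation: the sample Pearson coefficient in the
HER1-dominated regimes is heavy-tailed (one low-HER1 patient can produce
an extreme E23 and dominate the statistic), so single-draw correlations at
n = 400 scatter far beyond the usual (1−r²)/√n scale. Regime properties are
therefore always summarized as means over several fixed seeds, both in the
tests and the acceptance script.

## Synthetic cohorts

One row per patient, generated as: receptor abundances (regime C, detailed
model by default — a HER1-rich background where HER2 status and dimer level
decouple) → equilibrium [E23] → `z = standardize(log [E23])` → observed
FRET efficiency `7.7 + 4.0·z + N(0, 1.5)` percent → survival. The log
scale for z is deliberate: concentrations act multiplicatively and raw
[E23] is heavily right-skewed; a linear-in-raw-E23 hazard would be driven
by a few extreme patients and break the proportional-hazards design. The
FRET map centres the cohort at the observed-cohort mean (7.7%) with a
spread giving roughly the observed 0–22% range.

Event times follow `hazard = 0.025·exp(β·z)` per year with
β = log(3.91) by default (the published 10-year multivariate hazard ratio,
used as a design point), independent exponential censoring at 0.05/yr and
an administrative cap at 15 yr. These rates were calibrated once so the
median event-or-follow-up time is ≈ 7.6 yr with ≈ 29% events, matching the
cohort the generator stands in for. Covariates use the published marginal
frequencies (ER+ 84%, PR+ 59%, size>20 mm 60%, grade 3 50%, nodal groups
39/44/16%, HER3 localisation C/C+M/M±C 50/26/20%, with stated NA rates);
HER2 IHC is derived from total HER2 through increasing cutpoints (3+ ≈ top
17%, positive = 3+), and is the only covariate coupled to the network;
everything else is independent — enough joint structure to exercise the
multivariate Cox machinery without inventing unpublished correlations.
The table keeps `e23` and `z_dimer` as labelled generator-truth columns;
parameter-recovery studies fit `z_dimer` so the estimand equals the
generative β (fitting the noisy FRET surrogate would measure attenuation
bias instead, a property of the measurement, not of the Cox fitter).

## Survival analysis

- **ROC/Youden**: candidate cutpoints are midpoints between consecutive
  sorted unique scores; the returned threshold maximizes
  sensitivity + specificity − 1, ties broken toward the lower threshold;
  AUC is the Mann–Whitney statistic. Outcome labels for survival ROC:
  event within the horizon (10 yr default); patients censored earlier
  without an event are excluded from labelling only, never from the
  survival models.
- **Dichotomization** is strictly `fret_eff > threshold` (the boundary
  convention is documented because published usage is ambiguous).
- **Kaplan–Meier** and **Cox** (Efron ties, Wald 95% CIs) are delegated to
  lifelines; horizon analyses administratively censor at 5/10 yr first.
  The multivariate model uses complete cases only; univariate models use
  all rows available for their covariate. Convergence/collinearity
  warnings mark a result `unreliable` rather than silently passing. No
  multiple-testing correction is applied (none is applied in the practice
  being reproduced).
- **Fisher exact** (two-sided, hypergeometric summation) associates the
  FRET-high/low grouping with each covariate, multi-level covariates
  collapsed to their natural 2×2 contrast.
- Calibration note: re-optimizing the Youden threshold on each null
  dataset and then testing the resulting grouping is anti-conservative by
  construction. Type-I-error calibration therefore uses a fixed threshold
  (8.56%); the power analysis uses the per-replicate Youden threshold, as
  an analyst would.

## Determinism and pipeline

Every stochastic stage takes an explicit seed; the pipeline spawns
per-stage seeds from the master seed via `numpy.random.SeedSequence`
(fixed spawn keys, all below 2³¹). Cubes are written as multi-page TIFF
(uint16, one page per time bin, increasing time) with a JSON sidecar;
tables as CSV. The run manifest records per-artifact SHA-256 checksums;
re-running a config reproduces every byte, which the test-suite asserts.
The default demo (20 cores at 64×64 px, cohort n = 300) completes in a few
seconds on one CPU; replicate studies in the acceptance script (200
coverage + 200 power + 500 null cohorts at n = 500) run in about a minute
thanks to the vectorized equilibrium solver and the closed-form mono MLE.

## Known limitations

- The lifetime filter is a surrogate with stated parameters, not a
  reproduction of the unpublished algorithm used on the original tissue.
- The network model is a closed binding equilibrium; open-system fluxes,
  ligands and competing non-HER partners are excluded, so its regime
  magnitudes (correlations) depend on the chosen Kd/cv defaults and only
  the directions are robust claims.
- The cohort generator's covariates are marginally calibrated but mostly
  independent; it cannot be used to study confounding structure beyond the
  HER2-IHC/dimer link it encodes.
- Bi-exponential fits near the degeneracy boundary (lifetimes within ~5%)
  are intentionally collapsed to mono rather than reported with unstable
  uncertainties.
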