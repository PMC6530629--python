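# Methods

## Survival models

All survival computations are carried on the negative-log scale,
−ln S ("lethal lesions per nucleus"), and exponentiated only at the
user-facing boundary. This matters for the mixture: a strongly
radiosensitive bulk population can reach −ln S ≈ 90 at 10 Gy, which
underflows double precision in linear space; the mixture log-survival is
therefore accumulated with `logaddexp`,

    ln S_mix = logaddexp(ln(1−f) + ln S_PC, ln f + ln S_CSC) − logaddexp(ln(1−f), ln f),

where the second term (= ln 1 up to rounding, −1.3·10⁻¹⁸ in double
precision) is subtracted so that S(0) = 1 holds exactly rather than to
1 ulp. Weights of exactly 0 or 1 enter as −∞ and drop out of
`logaddexp` exactly, so the degenerate mixtures reduce bit-for-bit to
their single component.

### Microdosimetric conversion factor

The targeted-effect model augments the linear coefficient by
z·β₀ with z = y_D/(ρ π r²). The site size is stored as a *diameter* (the
conventional way microdosimetric sites are quoted) and the formula uses
the radius r = diameter/2: with y_D = 4.68 keV/μm, ρ = 1 g/cm³ and a
1 μm site this yields z = 0.9547 Gy, the canonical value for
kilovoltage X-rays, whereas using the diameter in πr² would give a
quarter of it. Unit constants (1 keV = 1.602176634·10⁻¹⁶ J exactly,
μm→m, g/cm³→kg/m³) are pinned in one place in `core.py`.

### Non-targeted term

The bystander lethality −ln S_NT = δ(1−e⁻ˣ)e⁻ˣ needs a conversion
factor γ inside X(D) = (α_b + γβ_b)D + β_bD². γ is exposed as an
explicit parameter of `NTEParameters`; the fitting estimator defaults it
to the site's specific-energy factor z, mirroring the (α₀ + zβ₀)
structure of the targeted term. The term is bounded by δ/4 (maximum of
δu(1−u) on u ∈ [0,1], attained where the activation survival e⁻ˣ = ½)
and vanishes at D = 0 and as D → ∞.

## Fitting

The objective is the sum of squared deviations of *natural-log* survival
(base only rescales the objective, not the argmin). The dose-0 point, if
present, is an ordinary observation; every model passes through it
exactly, so it anchors nothing.

The minimiser is a two-stage search, fully deterministic given the seed:

1. **Monte-Carlo stage.** `n_samples` (default 10⁵) parameter vectors
   are drawn uniformly within box bounds (defaults: α-type coefficients
   in [0, 10] Gy⁻¹, β-type in [0, 1] Gy⁻², fractions and δ in their
   natural ranges; all configurable). Draws violating the
   radioresistance constraint α₀CSC ≤ α₀PC, β₀CSC ≤ β₀PC are rejected.
   Draws are evaluated vectorised in blocks of 10⁴ with the running best
   logged; ties are broken by draw order (first found wins).
2. **Polish stage.** A bounded trust-region least-squares refinement
   (`scipy.optimize.least_squares`, TRF) is started from each of the
   `polish_starts` (default 100) best draws, and the best polished point
   is kept, never worse than the sampled best. For the mixture the
   polish runs in the reparameterised space (α₀PC, β₀PC, u_α, u_β,
   f) with α₀CSC = u_α·α₀PC, u ∈ [0,1]², which turns the ordering
   constraint into a box. A single local descent from the single best
   draw is not reliable here: the mixture objective has narrow,
   well-separated basins (a tiny resistant fraction trades off against
   the resistant coefficients), and in roughly one random stream in ten
   the best draw lies in a basin whose local optimum is far from the
   global one. One hundred TRF starts cost well under a second and made
   the global optimum reproducible across every random stream we
   exercised in the test suite.

Increasing `n_samples` with the same seed extends the same draw stream,
so the pre-polish best objective is monotone non-increasing in the
budget.

The fitted curve, not the parameter vector, is the well-identified
object: on noise-free data the refit reproduces the generating curve to
< 0.1% everywhere while f_CSC is only pinned to within an order of
magnitude. Tests and acceptance checks therefore assert on predictions
and bracketing, not parameter equality.

### Fit quality and uncertainty

χ² is computed on the linear survival scale, (1/N)Σ(S_exp −
S_model)²/σ², using the dataset's per-point standard deviations; points
without a positive σ are excluded with a warning, and the statistic is
reported as unavailable rather than guessed when no σ exists.

Standard errors come from a seeded nonparametric bootstrap: observations
are resampled with replacement (B = 200 by default) and each resample is
refitted with a fresh seed drawn from the bootstrap stream. Resampling
observations rather than residuals was chosen because the replicate
structure behind each summarised dose point is unknown. How the original
reference uncertainties were computed is not stated anywhere we could
reproduce; the bootstrap is this package's own documented choice.

## Synthetic data

`simulate_survival` emulates a colony-formation assay: for each dose in
a grid (default {0, 0.5, 1, 2, 4, 6, 8, 10} Gy, spanning the 0–10 Gy
range of kilovoltage X-ray experiments) it draws `n_replicates`
(default 3, a typical assay) survivals S_true·exp(ε),
ε ~ N(0, σ_log²), and summarises them into a mean and sample SD.
Multiplicative log-normal noise is used because clonogenic scatter
scales with the survival level and the fit operates on log survival.
Replicate values above 1 — possible near 0 Gy — are clamped to 1 and
counted with a warning.

What the generator does **not** emulate: Poisson colony-counting noise
and plating-efficiency normalisation, dose-delivery uncertainty,
inter-experiment (day) effects, or any dose correlation in the errors.
Passing recovery and calibration tests therefore demonstrates that the
estimator inverts its own generative model faithfully — not that real
assays satisfy that model.

## Numerical and design choices

- **Degenerate inputs.** Datasets with fewer points than the parameter
  count (3 for LQ, 6 for the five-parameter fits) or with all doses
  identical are rejected before any computation. Surviving fractions
  ≤ 0 are errors; values > 1 are clamped to 1 with a warning.
  (−ln S)/D at D = 0 raises rather than silently returning the limit.
- **Infinite α/β.** β = 0 gives a genuinely infinite ratio, represented
  as `math.inf` (BED then equals the physical dose nd), never as a large
  sentinel.
- **Zero-width bounds.** Setting an upper search bound equal to the
  lower one (e.g. `delta_max=0`) pins that parameter, which is how the
  targeted-effect-only restriction of the bystander model is obtained
  for nested-model comparisons.
- **Mixture α/β is never pooled**: the two-population survival law has
  no single LQ-equivalent ratio, so BED is reported per subpopulation.
- **Estimator shape.** The fitting machinery is packaged as
  scikit-learn-style estimators (`fit`/`predict`,
  `get_params`/`set_params`, trailing-underscore fitted attributes) so
  the models compose with sklearn pipelines and model selection; the
  `fitting` module provides thin dataset-level wrappers returning
  parameter dataclasses.

## Problem sizes

Default budgets were chosen so that a full mixture fit (10⁵ draws + 100
polish starts) runs in well under a second on one core. The calibration
study in the test suite uses 50 simulated assays at 10⁴ draws each; the
bootstrap calibration check uses 50 fresh datasets against B = 100
resamples of one dataset at reduced draw budgets, which is ample for the
factor-of-three agreement it asserts.

## Known limitations

- The IMK repair-kinetics machinery (dose-rate and cell-cycle effects)
  is outside scope; only the acute-irradiation targeted-effect form is
  implemented.
- The mixture weights subpopulations by number fraction only; any
  plating-efficiency difference between stem and bulk cells would fold
  into the apparent f_CSC.
- f_CSC and the CSC coefficients are weakly identifiable from survival
  curves alone (see above); treat fitted CSC parameters as
  curve-descriptors unless corroborated (e.g. by flow-cytometric marker
  fractions).
- The bootstrap SE reflects sampling of dose points, not replicate-level
  noise, and will be conservative or anticonservative depending on how
  the summarised points were produced.
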