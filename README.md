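# radiocsc

Radiobiological modelling of clonogenic survival for tumour cell
populations that contain a small radioresistant cancer-stem-cell (CSC)
subpopulation, with Monte-Carlo least-squares curve fitting, a
synthetic-data generator for validation, and biologically-effective-dose
(BED) calculus for fractionated radiotherapy.

## The problem

Clonogenic survival of irradiated cancer cell lines often departs from
the classical linear–quadratic (LQ) law at high dose (≳ 8 Gy): the
measured surviving fraction sits above the LQ extrapolation. One
mechanistic explanation is population heterogeneity — a small fraction
of radioresistant stem-like cells dominates survival once the bulk
("progeny") cells are gone. This package implements that two-population
model and everything needed to use it in practice: fitting it to
dose–survival data, comparing it against the LQ model, predicting how
the dose–response curve deforms as the CSC fraction grows, and
translating fitted parameters into BED for treatment-planning-style
comparisons.

## Models

All models are written on the natural-log survival scale.

**Linear–quadratic (LQ)**

    −ln S(D) = αD + βD²,    α [Gy⁻¹], β [Gy⁻²]

**Microdosimetric-kinetic targeted effect (IMK)** — the linear
coefficient is augmented by a specific-energy term derived from the
dose-mean lineal energy y_D [keV/μm] in a micrometre water site of
diameter d (radius r = d/2), density ρ:

    −ln S(D) = (α₀ + z·β₀)D + β₀D²,    z = y_D / (ρ π r²)  [Gy]

For 150 kVp X-rays (y_D = 4.68 keV/μm) in a 1 μm site, z = 0.954 Gy.

**Two-population mixture** — progeny cells (PC) and cancer stem cells
(CSC), each following the IMK form, mixed by number fraction f_CSC with
the radioresistance constraint α₀CSC ≤ α₀PC, β₀CSC ≤ β₀PC:

    S(D) = (1 − f_CSC)·S_PC(D) + f_CSC·S_CSC(D)

**Non-targeted (bystander) extension** — an additional lethality term
that vanishes at zero and very high dose,

    −ln S_NT = δ(1 − e⁻ˣ)e⁻ˣ,   X(D) = (α_b + γβ_b)D + β_bD²,

multiplied onto the targeted-effect survival (S = S_T·S_NT).

**BED** — for n fractions of d Gy, BED = nd(1 + d/(α/β)); for the IMK
model α/β = α₀/β₀ + z, reported separately per subpopulation.

Fitting minimises Σᵢ(ln S_obs,i − ln S_model,i)² by uniform Monte-Carlo
sampling of the parameter vector within box bounds (10⁵ draws by
default, constraint-violating draws rejected) followed by a bounded
trust-region least-squares polish from the best draws. Fits are
deterministic functions of (data, settings, seed). Fit quality is also
reported as χ² = (1/N)Σᵢ(S_exp,i − S_model,i)²/σᵢ² on the linear scale,
and parameter uncertainty via a seeded nonparametric bootstrap.

## Worked example

```python
from radiocsc import (
    FitConfig, FractionationRegimen, IMKParameters, MicrodosimetricSpec,
    MixtureModel, SimulationConfig, bed_report, fit_mixture,
    microdosimetric_factor, simulate_survival,
)

spec = MicrodosimetricSpec(y_d=4.68, rho=1.0, site_diameter_um=1.0)
print(round(microdosimetric_factor(spec), 4))          # 0.9547 Gy

# ground truth: a mixture with 0.183% stem cells
truth = MixtureModel(pc=IMKParameters(0.332, 0.055),
                     csc=IMKParameters(0.007, 0.002), f_csc=0.00183)

# synthetic clonogenic assay: 8 doses in 0-10 Gy, 6 replicates, 5% log noise
data = simulate_survival(SimulationConfig(truth=truth, spec=spec,
                                          n_replicates=6, sigma_log=0.05, seed=42))

result = fit_mixture(data, spec, FitConfig(n_samples=100_000, seed=0))
print(f"objective {result.objective:.4g}  chi2 {result.chi_square:.4g}")
# objective 0.001929  chi2 0.3237

t = result.theta
print(t.pc.alpha0, t.pc.beta0, t.f_csc)
# 0.314, 0.0593, 0.00536  (truth: 0.332, 0.055, 0.00183)

print(bed_report(truth, FractionationRegimen(37, 2.0), spec))
#   model population  alpha_beta_gy      bed_gy
#     IMK         PC           6.99       95.17
#     IMK        CSC           4.45      107.22
```

The fit recovers the bulk-population coefficients and the survival curve
closely; the stem-cell coefficients and f_CSC individually are only
weakly identified from noisy data (here f_CSC lands within a factor of
three of the truth) — the curve, not the individual CSC parameters, is
the well-determined object. The BED table shows the standard
2 Gy × 37 prostate regimen evaluated per subpopulation: 95.2 Gy for the
bulk cells and 107.2 Gy for the stem cells at these generating
parameters.

The same workflow is available from the shell:

```bash
radiocsc simulate --params params.json --sigma-log 0.05 --seed 42 --out data.csv
radiocsc fit --input data.csv --model imk_mixture --seed 0 --out-dir out/
radiocsc predict --params params.json --out curve.csv
radiocsc bed --params params.json --fractions 37 --dose-per-fraction 2.0
radiocsc sweep --params params.json --out sweep.csv
```

Parameter files are flat JSON
(`{"alpha0_pc": ..., "beta0_pc": ..., "alpha0_csc": ..., "beta0_csc": ...,
"f_csc": ..., "y_D": 4.68, "rho": 1.0, "site_diameter_um": 1.0}`);
survival CSVs carry the header
`cell_line,dose_gy,surviving_fraction,sd,n_replicates`.

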