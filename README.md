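# wheatpheno

Analysis pipeline for high-throughput wheat phenotyping under combined
heat and drought, for plant physiologists and breeders working with
automated greenhouse platforms (twice-daily multispectral + thermal
imaging and pot weighing).

The experimental design it targets: wheat genotypes grown in pots,
measured from 15 to 37 days after sowing (DAS); at DAS 30 the
temperature is raised to 38/31 °C and plants split into a well-watered
arm (WW38) and a water-deficit arm (WD38, sustained at ≥30% field
capacity), with soil-only pots tracking non-transpirational water loss.
Because such raw datasets are rarely deposited, the package includes a
*virtual greenhouse* generator that reproduces the statistical structure
of the design with full ground truth, so the entire pipeline is testable
end to end.

## What it computes

- **Trait QC** (`wheatpheno.qc`): iterative Grubbs outlier screening per
  replicate group, imputation, a replicate-reproducibility filter
  (median replicate-trajectory correlation > 0.7 and replicate pairs
  significantly above random pairs), and stepwise collinearity pruning
  until every trait's variance inflation factor (VIF) is below 5.
- **Variance partitioning** (`wheatpheno.variance`): per-trait, per-day
  two-way ANOVA splitting phenotypic variance into genotype (G),
  environment (E) and interaction (G×E) significance, corrected per
  (day, effect) family (Benjamini–Hochberg FDR by default) and expressed
  as LOD scores, LOD = −log₁₀(adjusted P); plus hierarchical clustering,
  Duncan's multiple range test with compact letter displays, and Welch
  t-tests between treatments.
- **Water use** (`wheatpheno.water`): evapotranspiration as pot water
  loss per hour between weighings, corrected by the treatment-matched
  soil-only rate, aggregated daily and normalized by harvest biomass.
- **Biomass prediction** (`wheatpheno.biomass`): regression of harvest
  fresh/dry weight on image geometry (projected area `area.low` and
  pyramidal volume `volumepyr = area·height/3`), with a stratified 70/30
  split, 10-fold CV for hyperparameters, and the acceptance rule
  R² > 0.7 ∧ MRSRE < 0.3 ∧ |μ| < 0.05 (squared Pearson correlation,
  root mean squared relative error, mean relative bias). The accepted
  model with least bias predicts the whole biomass trajectory.
- **Growth dynamics** (`wheatpheno.growth`): nonlinear fits of the
  trajectory with bell-shaped `a·exp(−(t−b)²/2c²)`, logistic, Gompertz
  and other forms on the 24–41 DAS window; Timemax and Biomass at
  Timemax from the fitted curve; growth rate
  GR = ln(B_Timemax − B_T1)/(Timemax − T1) and water-use efficiency
  WUE = ΔB / (Δwater supplied − soil-only loss); and the five
  stress-tolerance indices — mean productivity, biomass reduction
  (WD/WW), inflection-point stability (ΔTimemax), GR ratio and WUE
  ratio — rescaled to [0, 1] and clustered per genotype.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
from wheatpheno.design import ExperimentDesign
from wheatpheno.synthetic import make_profiles, simulate_experiment
from wheatpheno.pipeline import run_tolerance_analysis

design = ExperimentDesign(n_genotypes=4, n_replicates=5)
profiles = make_profiles(design, tolerant=(0,), sensitive=(3,))
ds = simulate_experiment(design, profiles, seed=1)
result = run_tolerance_analysis(ds, seed=1)

traj = result["trajectory"]; ev = traj.evaluation
print(f"biomass model: {traj.model_name}  R2={ev.r2:.3f}  "
      f"MRSRE={ev.mrsre:.3f}  mu={ev.mu:+.4f}")
fit = result["fits"][("G01", "WW38")]
print(f"G01/WW38 growth fit: {fit.model_name}  R2={fit.r_squared:.3f}  "
      f"Timemax={fit.timemax:.1f} DAS  Biomass={fit.biomass_at_timemax:.1f} g")
print(result["indices"].round(3).to_string())
print("clustered genotype order:", result["leaf_order"])
```

prints

```
biomass model: svm_linear  R2=0.986  MRSRE=0.027  mu=+0.0076
G01/WW38 growth fit: bell  R2=0.999  Timemax=35.1 DAS  Biomass=16.0 g
          mean_productivity  biomass_reduction  inflection_point_stability  gr_ratio  wue_ratio
genotype
G01                  15.977              1.003                      -0.129     0.991      3.317
G02                  16.361              0.755                       1.430     0.811      3.679
G03                  18.760              0.743                       1.391     0.893      2.095
G04                  18.656              0.507                       1.047     0.699      1.906
clustered genotype order: ['G03', 'G04', 'G01', 'G02']
```

The four genotypes were simulated with genotype 1 built *tolerant*
(same growth curve under deficit) and genotype 4 built *sensitive*
(half the biomass under deficit). The pipeline recovers exactly that:
G01's biomass reduction ratio is ~1 with a stable inflection point and
unchanged growth rate, G04 keeps only ~51% of its biomass with the
largest growth-rate drop, and the intermediate genotypes fall in
between. A linear support-vector regressor predicted biomass from image
geometry with 2.7% relative error and negligible bias, and the
bell-shaped growth model was selected for every genotype × treatment
(R² ≈ 0.99).

A CLI mirrors the library for shell use:
`wheatpheno simulate | qc | lod | evap | predict-biomass | fit-growth |
indices` (see `wheatpheno --help`).

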