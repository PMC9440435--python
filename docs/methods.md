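# Methods

`wheatpheno` re-implements, as a tested and reusable pipeline, the
computational analysis of a high-throughput wheat phenotyping experiment
under combined heat and drought: ten spring wheat genotypes grown in 1 L
pots, imaged (ten multispectral bands, thermography) and weighed twice a
day from 15 to 37 days after sowing (DAS); at DAS 30 the temperature is
raised to 38/31 °C and the plants split into a well-watered arm (WW38,
restored to ~95% field capacity at each weighing) and a water-deficit arm
(WD38, water withheld until the pot reaches 30% field capacity, then
sustained at that floor). Soil-only pots per treatment track
non-transpirational water loss. Because the raw experimental data are not
publicly deposited, the package ships a synthetic "virtual greenhouse"
generator with complete ground truth; every downstream module is
validated against it.

## Virtual greenhouse generator (`synthetic`)

**Growth.** Each genotype × treatment carries a bell-shaped fresh-weight
curve

    FW(t) = a · exp(−(t − b)² / (2 c²))

with amplitude `a` (g), peak day `b` (DAS) and width `c` (days). Default
profiles spread `a` linearly over 16–24 g across genotypes and peak days
over `b = 38 ± 2` DAS; under WD38 the amplitude is scaled by 0.75 and the
peak advanced by one day. "Tolerant" genotypes keep their amplitude under
deficit; "sensitive" ones lose half. Within the observed window the curve
is vegetative growth; the declining limb beyond the peak stands in for
the post-vegetative plateau/decline the bell family models.

**Traits.** Exposed projected area (`area_low`, mm²) and plant height
(mm) are allometric in FW (900 mm² g⁻¹; 60 mm + 14 mm g⁻¹). Band
intensities and leaf temperature are a baseline plus (i) a canopy
coupling term proportional to the genotype's normalized growth-curve
shape FW(t)/a (+10 trait-sd for bands, −8 sd for leaf temperature —
developing canopies change reflectance and run cooler), (ii) a constant
genotype offset, and (iii), after stress onset in the WD arm only, a
treatment offset plus a genotype × treatment interaction offset
(defaults: +4 sd treatment and ±2 sd interaction on NIR bands
700–970 nm; +6 sd/±2 sd on leaf temperature; zero on UV/visible bands).
The canopy coupling exists because the replicate-reproducibility
criterion (replicate trajectory correlations significantly above random
plant pairs) is unsatisfiable for any trait whose expected trajectory is
flat or common to all genotypes; genotype-specific temporal structure is
what that filter detects in real data. Measurement noise is additive
Gaussian per trait (bands 1.0, leaf temperature 0.4 °C, area 300 mm²,
height 3 mm).

**Gravimetrics.** Pot weight = 600 g tare + water. Plant-available water
capacity is 110 g; WW pots are restored to 95% of it at every weighing,
WD pots after onset are irrigated back to the 30% floor only once they
fall below it. Transpiration on each inter-weighing interval is
`coefficient × FW(t_start)` (defaults 100 mg h⁻¹ g⁻¹ FW under WW, ×0.75
under WD) and soil-only evaporation is constant per treatment
(250/80 mg h⁻¹ WW/WD; deficit soil surfaces crust and evaporate less).
The recorded weight is pre-irrigation and the irrigation amount attaches
to the same timestamp, so interval loss = `w_i + irrigation_i − w_{i+1}`
exactly, and the recorded per-interval truth integrates to the
plant-attributed loss to machine precision. These magnitudes were chosen
once for physical coherence with the treatment definition: the deficit
arm must actually reach its 30% floor mid-way through the stress week
(so that post-onset irrigation exists and the water-use-efficiency
denominator is positive), while no pot may ever go dry overnight. With a
much larger capacity the withholding phase never ends and WUE under
deficit is undefined.

**Artifacts.** Outliers are additive shifts of k measurement-sd (random
sign) on single cells; missingness is completely at random. Injected
positions are recorded in the ground truth. Note a statistical fact the
tests document: with 5 replicates the two-sided Grubbs critical value at
α = 0.05 (1.715) lies just below the attainable maximum
G = (n−1)/√n = 1.789, so even an 8-sd outlier is flagged only ~77% of
the time (detection depends on the realized spread of the clean
replicates); 20-sd outliers are flagged with certainty.

**What the generator does not emulate.** Band-specific spectral dynamics
(all bands share one canopy factor, so collinearity among bands is
stronger than in real data and VIF pruning is correspondingly more
aggressive), diurnal transpiration cycles, phenology beyond the
vegetative window, spatial greenhouse effects, and imaging segmentation
errors. Passing tests show the *analysis* is correct under the assumed
data-generating structure, not that real data meet that structure.

## Quality control (`qc`)

Replicate groups are (genotype, treatment, trait, timepoint). The Grubbs
screen iterates one-at-a-time on each group (repeat-until-clean, α
uncorrected across iterations, default 0.05), using the closed-form
two-sided critical value G = ((n−1)/√n)·√(t²/(n−2+t²)) with
t = t₁₋α/(2n), n−2. Flagged values are deleted and imputed, along with any
other missing cells, by the replicate-group mean — the pooled estimator
of the cell expectation, deterministic for any seed and exact on
noise-free data; an iterative model-based imputer would satisfy the same
contract but adds nothing for a cell-structured design. Traits are kept
when, in at least one treatment, the median over genotypes of the mean
pairwise Pearson correlation between replicate trajectories exceeds 0.7
and a one-sided Welch t-test finds replicate-pair correlations above
those of an equal number of seeded random cross-genotype pairs
(P < 0.05). Collinearity is then pruned by stepwise VIF: the trait with
the largest VIF (auxiliary OLS with intercept; infinite under exact
collinearity) is removed until all survive below 5, ties and infinities
broken by dropping the lexicographically last label.

## Variance partitioning (`variance`)

Twice-daily measurements are averaged per plant per day. Each (trait,
day) gets a two-way fixed-effects ANOVA with interaction
(`value ~ genotype * treatment`, type II sums of squares, statsmodels);
days before stress onset have one irrigation arm, so only the genotype
term is testable and E / G×E are not-applicable. If all observations are
identical every applicable P is 1 by convention. Raw P values are
corrected across traits within each (day, effect) family —
Benjamini–Hochberg by default, Bonferroni behind a flag, since both
appear in the source analysis — and expressed as LOD = −log₁₀(adjusted
P), with P floored at 10⁻¹⁶ (LOD cap 16). Heatmap ordering uses
agglomerative clustering (Euclidean distance, complete linkage) on
label-sorted rows, which makes the leaf order independent of input
order. Duncan's multiple range test uses studentized-range points at
protection level 1−(1−α)^(p−1) for a span of p ordered means, the
harmonic mean group size for unbalanced designs, the containment rule
(a range inside a non-significant range is non-significant), and a
compact letter display built from maximal mutually-non-significant runs.
Treatment contrasts within genotype are two-sided Welch t-tests.

## Water use (`water`)

Evapotranspiration is the water loss per hour between consecutive
weighings, `(w_i + irrigation_i − w_{i+1})/Δt`, in mg H₂O h⁻¹; negative
computed losses are flagged as anomalies, never silently clipped. The
treatment's mean soil-only rate on the matching interval is subtracted;
corrected rates are floored at zero with the flooring count reported.
Daily evapotranspiration is the summed corrected loss per calendar DAS
(an interval attributed to its starting day); normalized values divide
the final complete day's evapotranspiration by harvest aboveground or
root dry weight. Irrigation amounts come from the explicit irrigation
field; for data sources that only log weights, positive weight jumps can
be treated as irrigation behind `infer_irrigation=True`.

## Biomass prediction (`biomass`)

Pyramidal volume is `area × height / 3`; any other constant would be
absorbed by the regression coefficients. The model suite (OLS, ridge,
lasso, elastic net, linear SVR — the linear family that passes model
selection in this kind of data; further regressors can be supplied) is
evaluated on a 70/30 train/test split stratified by
genotype × treatment, with 10-fold cross-validation inside the training
split for hyperparameters. Acceptance requires R² > 0.7 (squared Pearson
correlation of predicted vs observed), MRSRE < 0.3 (root mean squared
relative error) and |μ| < 0.05 (mean relative bias; the absolute value is
used because bias can be negative). Among accepted models the smallest
|μ| wins (ties by MRSRE); the winner is refit on all harvest-day data
and applied to every timepoint's features to give the predicted biomass
trajectories FW_sv / DW_sv.

## Growth dynamics (`growth`, `pipeline`)

Growth-model forms: bell, logistic, Gompertz, exponential, linear,
quadratic, monomolecular. Nonlinear forms are fitted by
Levenberg–Marquardt least squares with documented initialization (bell:
a₀ = max y, b₀ = argmax day, c₀ = window span / 4; sigmoids:
1.05·max y, 0.5 d⁻¹, median day; polynomials at their closed-form
solution); non-convergence is recorded per model, not fatal. Fit quality
is R² = 1 − SSE/SST on the fitted window and an F-test against the
constant-mean model with (p−1, n−p) degrees of freedom; a fit passes
when R² > 0.7 and P < 0.05. The fitting window is 24–41 DAS
(observations end at 37; the curve is extrapolated to the 41-DAS
forecast bound). Timemax is the argmax of the fitted curve on the window
— closed form for the bell (peak day clamped into the window), a
0.01-day grid scan otherwise — and Biomass at Timemax the curve value
there.

The end-to-end pipeline fits all candidate forms to each
genotype × treatment mean trajectory of predicted biomass (floored at
zero, since linear regressors can extrapolate marginally below zero for
tiny plants) and then selects **one common model class**: the class
passing the quality criteria for every series with the highest mean R².
Comparing genotypes through a single curve family keeps Timemax and the
indices commensurable; on these trajectories bell and logistic are often
within ΔR² < 0.005 of each other when the observed arc is monotone, and
per-series selection would mix families arbitrarily.

Growth rate is computed literally as

    GR = ln(B_Timemax − B_T1) / (Timemax − T1),    T1 = 30 DAS,

the printed form of the source definition (the logarithm of the biomass
gain; dimensionally odd but kept as stated); the conventional relative
growth rate (ln B₂ − ln B₁)/Δt is available via `method="rgr"`. Water
use efficiency is

    WUE = (B_Timemax − B_T1) / ((H₂O_Timemax − H₂O_T1) − soil-only loss),

with cumulative irrigation per pot as the supplied water and the
treatment-matched mean soil-only loss over the same window as the
non-transpirational correction; a non-positive denominator yields an
explicit missing value. The five tolerance indices per genotype are
mean productivity (B̄ of the two arms), biomass reduction (WD/WW ratio),
inflection-point stability (Timemax_WW − Timemax_WD, days), GR ratio and
WUE ratio (both WD/WW). Indices are min-max rescaled to [0, 1] per
column (a constant column is set to 0.5 and flagged) and genotypes
clustered with the same deterministic linkage.

## Problem sizes used in tests and the acceptance script

Simulated experiments in the test-suite use 4 genotypes × 2 treatments ×
5 replicates (2 soil pots per treatment) over the full DAS 15–37 window;
the type-I-error study uses 4 genotypes × 3 replicates over DAS 28–33
(100–200 null datasets); the growth-recovery study uses 100 seeded bell
trajectories at 2% amplitude noise; the discrimination study 50 seeded
experiments with one built-tolerant and one built-sensitive genotype.
These sizes give stable statistics while keeping the whole suite quick
to run.

## Known limitations

- The generator's single canopy factor overstates between-band
  collinearity; VIF pruning on default synthetic data keeps fewer
  spectral traits than a real campaign would.
- Soil evaporation is constant per treatment; real bare-soil evaporation
  declines as the surface dries.
- The supplied-water WUE denominator depends on when the deficit arm's
  irrigation resumes; under prolonged withholding it is small, so WUE
  under deficit is systematically larger than under well-watered
  conditions in this design — a property of the definition, not a bug.
- Each day is analysed independently in the LOD scan; no repeated
  measures or mixed-effects structure is modelled, by design.
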