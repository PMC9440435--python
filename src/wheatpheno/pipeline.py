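"""End-to-end analysis: dataset -> biomass trajectories -> growth fits ->
water accounting -> stress-tolerance indices.

This is the orchestration layer over the individual modules; each step
can also be run on its own.  Growth models are fitted on genotype x
treatment mean trajectories of the predicted biomass; water supplied is
the cumulative irrigation of each pot, and the non-transpirational
correction is the mean soil-only water loss of the matching treatment
over the same window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomass import (
    FEATURE_COLUMNS,
    TrajectoryPrediction,
    evaluate_model_suite,
    harvest_feature_table,
    select_and_predict_trajectory,
)
from .design import PhenoDataset
from .growth import (
    GrowthFit,
    ToleranceIndexSet,
    fit_growth_models,
    growth_rate,
    index_table,
    rescale_and_cluster,
    select_growth_model,
    tolerance_indices,
    water_use_efficiency,
)
from .water import hourly_evapotranspiration


def predict_biomass_trajectories(
    ds: PhenoDataset,
    target: str = "aerial_fw_g",
    seed: int = 0,
    suite=None,
) -> TrajectoryPrediction:
    """Evaluate the regression suite on harvest-day features and predict
    the biomass trajectory of every plant over the full time course."""
    features = harvest_feature_table(ds.trait_table)
    final_das = features["das"].max()
    final_tod = features.loc[features["das"] == final_das, "time_of_day"].max()
    harvest_feats = features[
        (features["das"] == final_das) & (features["time_of_day"] == final_tod)
    ].merge(ds.harvest_table[["plant_id", target]], on="plant_id")
    strata = harvest_feats["genotype"] + "|" + harvest_feats["treatment"]
    evaluations = evaluate_model_suite(
        harvest_feats[FEATURE_COLUMNS],
        harvest_feats[target],
        suite=suite,
        seed=seed,
        strata=strata,
    )
    return select_and_predict_trajectory(
        evaluations,
        harvest_feats[FEATURE_COLUMNS],
        harvest_feats[target],
        features,
    )


def genotype_growth_fits(
    predictions: pd.DataFrame,
    models: Sequence[str] = ("bell", "logistic", "gompertz", "linear"),
    window: tuple[float, float] = (24.0, 41.0),
) -> dict[tuple[str, str], GrowthFit | None]:
    """Fit growth models per genotype x treatment mean trajectory and
    select one common model class for the whole experiment.

    Candidate classes are ranked by mean R^2 over all series among the
    classes whose fit passes the quality criteria (R^2 > 0.7, P < 0.05)
    for *every* genotype and treatment; comparing genotypes through a
    single curve family keeps Timemax and the tolerance indices
    commensurable.  If no class passes everywhere, each series falls
    back to its own best passing fit.
    """
    daily = (
        predictions.groupby(["genotype", "treatment", "das"])["predicted"]
        .mean()
        .rename("value")
        .reset_index()
    )
    # regression extrapolation can dip marginally below zero for tiny
    # plants; biomass is floored at zero before curve fitting
    daily["value"] = daily["value"].clip(lower=0.0)
    all_fits: dict[tuple[str, str], list[GrowthFit]] = {}
    for (geno, trt), sub in daily.groupby(["genotype", "treatment"], sort=True):
        all_fits[(geno, trt)] = fit_growth_models(sub, models=models, window=window)

    best_class, best_mean_r2 = None, -np.inf
    for name in models:
        per_series = [
            next(f for f in fits if f.model_name == name)
            for fits in all_fits.values()
        ]
        if all(f.passed for f in per_series):
            mean_r2 = float(np.mean([f.r_squared for f in per_series]))
            if mean_r2 > best_mean_r2:
                best_class, best_mean_r2 = name, mean_r2

    chosen: dict[tuple[str, str], GrowthFit | None] = {}
    for key, fits in all_fits.items():
        if best_class is not None:
            chosen[key] = next(f for f in fits if f.model_name == best_class)
        else:
            chosen[key] = select_growth_model(fits)
    return chosen


def cumulative_water_supplied(
    gravimetric: pd.DataFrame, t: float
) -> pd.Series:
    """Cumulative irrigation (g) per plant pot up to fractional DAS t."""
    plants = gravimetric[~gravimetric["is_soil_only"]]
    upto = plants[plants["time"] <= t]
    return upto.groupby("pot_id")["irrigation_g"].sum()


def soil_only_loss(
    gravimetric: pd.DataFrame, treatment: str, t_from: float, t_to: float
) -> float:
    """Mean water loss (g) of the treatment's soil-only pots on
    intervals starting within [t_from, t_to)."""
    soil = gravimetric[
        gravimetric["is_soil_only"] & (gravimetric["treatment"] == treatment)
    ]
    losses = []
    for _, pot in soil.groupby("pot_id"):
        iv = hourly_evapotranspiration(pot)
        sel = iv[(iv["t_start"] >= t_from) & (iv["t_start"] < t_to)]
        losses.append(sel["water_loss_mg"].sum() / 1000.0)
    if not losses:
        raise ValueError(f"no soil-only pots for treatment {treatment}")
    return float(np.mean(losses))


@dataclass
class GenotypeWaterUse:
    gr: dict[str, float] = field(default_factory=dict)
    wue: dict[str, float] = field(default_factory=dict)


def genotype_rates(
    ds: PhenoDataset,
    fits: Mapping[tuple[str, str], GrowthFit | None],
    t1: float,
    gr_method: str = "as_printed",
) -> dict[str, GenotypeWaterUse]:
    """GR and WUE per genotype and treatment from the selected fits and
    the gravimetric record.

    Biomass at T1 and at Timemax come from the fitted curve; water use
    is the mean cumulative irrigation of the genotype's pots between T1
    and Timemax minus the treatment's mean soil-only loss on the same
    window.
    """
    grav = ds.gravimetric_table
    pots = ds.harvest_table[["plant_id", "genotype", "treatment"]]
    out: dict[str, GenotypeWaterUse] = {}
    for (geno, trt), fit in fits.items():
        record = out.setdefault(geno, GenotypeWaterUse())
        if fit is None:
            record.gr[trt] = np.nan
            record.wue[trt] = np.nan
            continue
        b_t1 = float(fit.curve(t1))
        gain = fit.biomass_at_timemax - b_t1
        record.gr[trt] = growth_rate(
            fit.biomass_at_timemax, b_t1, fit.timemax, t1, method=gr_method
        )
        ids = pots[(pots["genotype"] == geno) & (pots["treatment"] == trt)][
            "plant_id"
        ]
        w_t1 = cumulative_water_supplied(grav, t1)
        w_tmax = cumulative_water_supplied(grav, fit.timemax)
        supplied = (
            w_tmax.reindex(ids).fillna(0.0) - w_t1.reindex(ids).fillna(0.0)
        ).mean()
        soil = soil_only_loss(grav, trt, t1, fit.timemax)
        record.wue[trt] = water_use_efficiency(gain, float(supplied), 0.0, soil)
    return out


def run_tolerance_analysis(
    ds: PhenoDataset,
    seed: int = 0,
    t1: float | None = None,
    models: Sequence[str] = ("bell", "logistic", "gompertz", "linear"),
    window: tuple[float, float] = (24.0, 41.0),
    target: str = "aerial_fw_g",
    suite=None,
) -> dict:
    """Full chain from a dataset to the rescaled, clustered index matrix.

    Returns a dict with the trajectory prediction, the selected fits,
    per-genotype GR/WUE, the raw and rescaled index tables and the
    genotype leaf order from hierarchical clustering.
    """
    design = ds.ground_truth.get("design")
    if t1 is None:
        if design is None:
            raise ValueError("t1 (stress onset DAS) must be given for real data")
        t1 = float(design.stress_onset_das)
    treatments = tuple(
        design.treatments if design is not None
        else sorted(ds.trait_table["treatment"].unique())
    )
    traj = predict_biomass_trajectories(ds, target=target, seed=seed, suite=suite)
    fits = genotype_growth_fits(traj.predictions, models=models, window=window)
    rates = genotype_rates(ds, fits, t1)
    sets: list[ToleranceIndexSet] = []
    for geno in sorted({g for g, _ in fits}):
        sets.append(
            tolerance_indices(
                geno,
                {trt: fits.get((geno, trt)) for trt in treatments},
                gr=rates[geno].gr,
                wue=rates[geno].wue,
                treatments=treatments,
            )
        )
    indices = index_table(sets)
    usable = indices.dropna(how="any")
    rescaled, order, constant = (
        rescale_and_cluster(usable) if len(usable) >= 2 else (usable, list(usable.index), [])
    )
    return {
        "trajectory": traj,
        "fits": fits,
        "rates": rates,
        "indices": indices,
        "rescaled": rescaled,
        "leaf_order": order,
        "constant_indices": constant,
    }
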