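"""Virtual greenhouse: simulated phenotyping experiments with known truth.

Generates the data structure a twice-daily wheat phenotyping run produces —
multispectral band intensities, leaf temperature, image-derived geometry,
pot gravimetrics with irrigation events, and harvest biomass — from
genotype profiles whose growth curves, transpiration coefficients and
trait effect sizes are known exactly.  Every dataset carries its ground
truth, so downstream modules (QC, LOD scoring, evapotranspiration,
biomass prediction, growth modelling) can be validated against it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import (
    MEASUREMENT_HOURS,
    TREATMENTS,
    WD,
    WW,
    ExperimentDesign,
    GenotypeProfile,
    PhenoDataset,
    TraitEffect,
)

#: the ten narrow-band LED wavelengths (nm) of the imaging setup
BAND_WAVELENGTHS = (365, 460, 525, 570, 645, 670, 700, 780, 890, 970)
#: wavelengths treated as near-infrared (respond to water status)
NIR_WAVELENGTHS = frozenset({700, 780, 890, 970})

BAND_TRAITS = tuple(f"band_{w}" for w in BAND_WAVELENGTHS)
GEOMETRY_TRAITS = ("area_low", "height")
DEFAULT_TRAITS = BAND_TRAITS + ("leaf_temp",) + GEOMETRY_TRAITS

# pot physics: 1 L pot, tare (pot + dry substrate) and water at field
# capacity; capacity is sized so that withholding water at stress onset
# draws a transpiring pot down to the 30 % deficit floor within the
# stress week, as the water-deficit regime requires
POT_TARE_G = 600.0
FIELD_CAPACITY_G = 110.0
WW_TARGET_FRACTION = 0.95   # well watered: restore to >90 % field capacity
WD_TARGET_FRACTION = 0.30   # water deficit: sustain a minimum of 30 % FC

DEFAULT_SOIL_EVAP = {WW: 250.0, WD: 80.0}  # mg h^-1

# ambient baselines: leaf temperature tracks the day regime (25 C -> 38 C
# after onset); band baselines are arbitrary reflectance-intensity units
LEAF_TEMP_BASE_PRE = 24.0
LEAF_TEMP_BASE_POST = 34.0
BAND_BASELINES = {
    f"band_{w}": 20.0 + 0.06 * (w - 365) for w in BAND_WAVELENGTHS
}

# canopy coupling: reflectance intensities and leaf temperature track
# canopy development (the genotype's normalized growth-curve shape), in
# units of the trait's measurement sd; transpiring canopies run cooler
BAND_CANOPY_COUPLING = 10.0
LEAF_TEMP_CANOPY_COUPLING = -8.0

DEFAULT_NOISE_SD = {
    **{t: 1.0 for t in BAND_TRAITS},
    "leaf_temp": 0.4,
    "area_low": 300.0,
    "height": 3.0,
}


class SimulationError(RuntimeError):
    """Raised when a simulation reaches a physically inconsistent state."""


# ---------------------------------------------------------------------------
# profiles


def make_profiles(
    design: ExperimentDesign,
    *,
    amplitude_range: tuple[float, float] = (16.0, 24.0),
    wd_amplitude_factor: float = 0.75,
    peak_das: float = 37.0,
    peak_spread_days: float = 1.5,
    width_days: float = 6.5,
    transp_ww: float = 100.0,
    transp_wd_factor: float = 0.75,
    gxe_sd_multiple: float = 2.0,
    tolerant: Sequence[int] = (),
    sensitive: Sequence[int] = (),
    noise_sd: Mapping[str, float] | None = None,
    null: bool = False,
) -> list[GenotypeProfile]:
    """Build one profile per genotype with evenly spread effect sizes.

    Genotype i gets a bell amplitude linearly spaced across
    ``amplitude_range`` under WW38; under WD38 the amplitude is scaled by
    ``wd_amplitude_factor`` and the peak advanced by one day, except for
    genotypes listed in ``tolerant`` (amplitude preserved) or
    ``sensitive`` (amplitude halved).  Peak days are spread over
    ``peak_das +- peak_spread_days`` so genotypes differ in growth
    timing, not just size.  On top of the canopy-coupled baseline, band
    and temperature traits carry genotype-specific constant offsets; NIR
    bands additionally respond to the water-deficit treatment, with a
    genotype-by-treatment interaction of ``gxe_sd_multiple`` measurement
    standard deviations.  ``null=True`` zeroes every genotype, treatment
    and interaction offset and gives all genotypes one common growth
    curve.
    """
    ww_label, wd_label = design.treatments
    n = design.n_genotypes
    noise = dict(DEFAULT_NOISE_SD if noise_sd is None else noise_sd)
    amplitudes = np.linspace(*amplitude_range, n)
    g_spread = np.linspace(-1.0, 1.0, n)
    profiles = []
    for i in range(n):
        name = f"G{i + 1:02d}"
        a_ww = float(np.mean(amplitude_range)) if null else float(amplitudes[i])
        if null:
            factor, peak_shift = 1.0, 0.0
        elif i in tolerant:
            factor, peak_shift = 1.0, 0.0
        elif i in sensitive:
            factor, peak_shift = 0.5, -1.0
        else:
            factor, peak_shift = wd_amplitude_factor, -1.0
        b_i = peak_das if null else peak_das + peak_spread_days * g_spread[i]
        growth = {
            ww_label: (a_ww, b_i, width_days),
            wd_label: (a_ww * factor, b_i + peak_shift, width_days),
        }
        # deficit pots transpire less in every scenario (stomatal closure
        # under drying soil); the null case only zeroes *trait* effects
        transp = {
            ww_label: transp_ww,
            wd_label: transp_ww * transp_wd_factor,
        }
        effects: dict[str, TraitEffect] = {}
        if not null:
            for trait in BAND_TRAITS:
                wavelength = int(trait.split("_")[1])
                sd = noise.get(trait, 1.0)
                is_nir = wavelength in NIR_WAVELENGTHS
                effects[trait] = TraitEffect(
                    genotype=3.0 * sd * g_spread[i],
                    treatment=4.0 * sd if is_nir else 0.0,
                    interaction=gxe_sd_multiple * sd * g_spread[i] if is_nir else 0.0,
                )
            sd_t = noise.get("leaf_temp", 0.4)
            effects["leaf_temp"] = TraitEffect(
                genotype=1.5 * sd_t * g_spread[i],
                treatment=6.0 * sd_t,
                interaction=gxe_sd_multiple * sd_t * g_spread[i],
            )
        profiles.append(
            GenotypeProfile(
                name=name,
                growth_params=growth,
                transpiration_coeff=transp,
                trait_effects=effects,
                noise_sd=noise,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# trait expectations


def _expected_trait_value(
    profile: GenotypeProfile,
    trait: str,
    times: np.ndarray,
    treatment: str,
    design: ExperimentDesign,
) -> np.ndarray:
    """Noise-free expected value of one trait over measurement times."""
    wd_label = design.treatments[1]
    onset = design.stress_onset_das
    post = times >= onset
    if trait == "area_low":
        return profile.area_per_fw * np.asarray(profile.biomass(times, treatment))
    if trait == "height":
        fw = np.asarray(profile.biomass(times, treatment))
        return profile.height_offset + profile.height_per_fw * fw
    eff = profile.trait_effects.get(trait, TraitEffect())
    a = profile.growth_params[treatment][0]
    shape = np.asarray(profile.biomass(times, treatment)) / a  # in (0, 1]
    sd = profile.noise_sd.get(trait, 1.0)
    if trait == "leaf_temp":
        base = np.where(post, LEAF_TEMP_BASE_POST, LEAF_TEMP_BASE_PRE).astype(float)
        base = base + LEAF_TEMP_CANOPY_COUPLING * sd * shape
    else:
        base = BAND_BASELINES.get(trait, 0.0) + BAND_CANOPY_COUPLING * sd * shape
    values = base + eff.genotype
    if treatment == wd_label:
        values = values + post * (eff.treatment + eff.interaction)
    return values


# ---------------------------------------------------------------------------
# gravimetrics


def simulate_gravimetrics(
    profile: GenotypeProfile | None,
    growth_curve: pd.Series | None,
    design: ExperimentDesign,
    soil_evap_rate: float,
    seed: int | np.random.Generator,
    *,
    treatment: str = WD,
    pot_id: str = "pot",
    weight_noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate twice-daily pot weighings with restore-to-target irrigation.

    ``growth_curve`` is the plant fresh-weight series indexed by fractional
    DAS at the measurement times; pass ``None`` (with ``profile=None``) for
    a soil-only pot.  Transpiration on each inter-measurement interval is
    held at ``transpiration_coeff * FW(t_start)`` so the recorded truth
    integrates exactly to the plant-attributed water loss.  The recorded
    weight is the pre-irrigation weight; ``irrigation_g`` is added
    immediately after the weighing, so the water lost on the interval
    [t_i, t_i+1] is ``weight_i + irrigation_i - weight_i+1``.

    Returns ``(records, truth)`` where truth holds the per-interval true
    transpiration and soil-evaporation rates in mg h^-1.
    """
    if soil_evap_rate < 0:
        raise ValueError("soil_evap_rate must be >= 0")
    rng = np.random.default_rng(seed)
    wd_label = design.treatments[1]
    times = design.measurement_times
    if growth_curve is not None:
        fw = np.asarray(growth_curve.reindex(times).to_numpy(), dtype=float)
        if np.isnan(fw).any():
            raise ValueError("growth_curve must cover every measurement time")
        coeff = profile.transpiration_coeff[treatment]
        transp_rates = coeff * fw  # mg h^-1, constant per interval from start
    else:
        transp_rates = np.zeros_like(times)

    target_ww = WW_TARGET_FRACTION * FIELD_CAPACITY_G
    target_wd = WD_TARGET_FRACTION * FIELD_CAPACITY_G
    water = target_ww
    rows = []
    truth_rows = []
    for i, t in enumerate(times):
        weight = POT_TARE_G + water
        if weight_noise_sd > 0:
            weight += rng.normal(0.0, weight_noise_sd)
        if water < 0:
            raise SimulationError(
                f"pot {pot_id}: negative water content at DAS {t:.2f}; "
                "irrigation policy cannot sustain the demand"
            )
        stressed = treatment == wd_label and t >= design.stress_onset_das
        if stressed:
            irrigation = max(0.0, target_wd - water) if water < target_wd else 0.0
        else:
            irrigation = max(0.0, target_ww - water)
        rows.append(
            {
                "pot_id": pot_id,
                "treatment": treatment,
                "is_soil_only": growth_curve is None,
                "time": t,
                "das": int(np.floor(t)),
                "weight_g": weight,
                "irrigation_g": irrigation,
            }
        )
        water += irrigation
        if i + 1 < len(times):
            dt_h = (times[i + 1] - t) * 24.0
            loss_mg = (transp_rates[i] + soil_evap_rate) * dt_h
            water -= loss_mg / 1000.0
            truth_rows.append(
                {
                    "pot_id": pot_id,
                    "t_start": t,
                    "t_end": times[i + 1],
                    "transpiration_mg_h": transp_rates[i],
                    "soil_evap_mg_h": soil_evap_rate,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# full experiment


def simulate_experiment(
    design: ExperimentDesign,
    profiles: Sequence[GenotypeProfile],
    seed: int,
    *,
    traits: Sequence[str] = DEFAULT_TRAITS,
    soil_evap_rate: Mapping[str, float] | None = None,
    harvest_noise_cv: float = 0.03,
) -> PhenoDataset:
    """Simulate a complete experiment: traits, gravimetrics and harvest.

    One profile per genotype is required.  The same integer seed always
    yields bit-identical tables.  Harvest fresh/dry weights are the true
    curve values at the final day perturbed by a ``harvest_noise_cv``
    coefficient of variation (zero noise_sd on every trait together with
    ``harvest_noise_cv=0`` gives an exactly noise-free dataset).
    """
    if len(profiles) != design.n_genotypes:
        raise ValueError(
            f"need one profile per genotype: got {len(profiles)} profiles "
            f"for {design.n_genotypes} genotypes"
        )
    soil_evap = dict(DEFAULT_SOIL_EVAP if soil_evap_rate is None else soil_evap_rate)
    rng = np.random.default_rng(seed)
    times = design.measurement_times
    hours = np.asarray(MEASUREMENT_HOURS[: design.measurements_per_day])

    trait_rows = []
    grav_frames = []
    transp_frames = []
    harvest_rows = []
    expected_rows = []
    fw_rows = []

    for profile in profiles:
        for treatment in design.treatments:
            fw_curve = pd.Series(
                np.asarray(profile.biomass(times, treatment)), index=times
            )
            fw_rows.append(
                pd.DataFrame(
                    {
                        "genotype": profile.name,
                        "treatment": treatment,
                        "time": times,
                        "fw_g": fw_curve.to_numpy(),
                    }
                )
            )
            expected = {
                trait: _expected_trait_value(profile, trait, times, treatment, design)
                for trait in traits
            }
            for trait in traits:
                expected_rows.append(
                    pd.DataFrame(
                        {
                            "genotype": profile.name,
                            "treatment": treatment,
                            "trait": trait,
                            "time": times,
                            "value": expected[trait],
                        }
                    )
                )
            for rep in range(1, design.n_replicates + 1):
                plant_id = f"{profile.name}_{treatment}_r{rep}"
                for trait in traits:
                    sd = profile.noise_sd.get(trait, 0.0)
                    values = expected[trait] + (
                        rng.normal(0.0, sd, size=len(times)) if sd > 0 else 0.0
                    )
                    trait_rows.append(
                        pd.DataFrame(
                            {
                                "plant_id": plant_id,
                                "genotype": profile.name,
                                "treatment": treatment,
                                "das": np.repeat(design.das_values, len(hours)),
                                "time_of_day": np.tile(hours, len(design.das_values)),
                                "trait": trait,
                                "value": values,
                            }
                        )
                    )
                grav, truth = simulate_gravimetrics(
                    profile,
                    fw_curve,
                    design,
                    soil_evap[treatment],
                    rng,
                    treatment=treatment,
                    pot_id=plant_id,
                )
                grav.insert(1, "genotype", profile.name)
                grav_frames.append(grav)
                transp_frames.append(truth)

                fw_final = float(fw_curve.iloc[-1])
                noise = (
                    rng.normal(0.0, harvest_noise_cv, size=3)
                    if harvest_noise_cv > 0
                    else np.zeros(3)
                )
                aerial_fw = fw_final * (1.0 + noise[0])
                aerial_dw = fw_final * profile.dw_fraction * (1.0 + noise[1])
                root_dw = aerial_dw * profile.root_fraction * (1.0 + noise[2])
                harvest_rows.append(
                    {
                        "plant_id": plant_id,
                        "genotype": profile.name,
                        "treatment": treatment,
                        "aerial_fw_g": aerial_fw,
                        "aerial_dw_g": aerial_dw,
                        "root_dw_g": root_dw,
                        "n_leaves": int(rng.integers(4, 9)),
                        "n_tillers": int(rng.integers(1, 5)),
                    }
                )

    # soil-only pots per treatment
    for treatment in design.treatments:
        for k in range(1, design.n_soil_pots + 1):
            pot_id = f"soil_{treatment}_s{k}"
            grav, truth = simulate_gravimetrics(
                None,
                None,
                design,
                soil_evap[treatment],
                rng,
                treatment=treatment,
                pot_id=pot_id,
            )
            grav.insert(1, "genotype", "")
            grav_frames.append(grav)
            transp_frames.append(truth)

    ground_truth = {
        "design": design,
        "profiles": {p.name: p for p in profiles},
        "soil_evap_rate": soil_evap,
        "fw_curves": pd.concat(fw_rows, ignore_index=True),
        "expected_traits": pd.concat(expected_rows, ignore_index=True),
        "transpiration": pd.concat(transp_frames, ignore_index=True),
        "effects": _effect_table(profiles),
        "outliers": [],
        "missing": [],
    }
    return PhenoDataset(
        trait_table=pd.concat(trait_rows, ignore_index=True),
        gravimetric_table=pd.concat(grav_frames, ignore_index=True),
        harvest_table=pd.DataFrame(harvest_rows),
        ground_truth=ground_truth,
    )


def _effect_table(profiles: Iterable[GenotypeProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for trait, eff in p.trait_effects.items():
            rows.append(
                {
                    "genotype": p.name,
                    "trait": trait,
                    "genotype_offset": eff.genotype,
                    "treatment_offset": eff.treatment,
                    "interaction_offset": eff.interaction,
                }
            )
    columns = [
        "genotype",
        "trait",
        "genotype_offset",
        "treatment_offset",
        "interaction_offset",
    ]
    return pd.DataFrame(rows, columns=columns)


def simulate_null_dataset(
    design: ExperimentDesign,
    seed: int,
    *,
    traits: Sequence[str] = BAND_TRAITS[:3] + ("leaf_temp",),
) -> PhenoDataset:
    """Dataset with no genotype, treatment or interaction signal.

    All plants share one growth curve and every trait is pure measurement
    noise around a common baseline — the null for LOD type-I-error checks.
    """
    profiles = make_profiles(design, null=True)
    return simulate_experiment(design, profiles, seed, traits=traits)


# ---------------------------------------------------------------------------
# artifacts


def inject_artifacts(
    ds: PhenoDataset,
    outlier_rate: float,
    outlier_magnitude: float,
    missing_rate: float,
    seed: int,
) -> PhenoDataset:
    """Corrupt a copy of the trait table with outliers and missing cells.

    Outliers are additive shifts of ``outlier_magnitude`` measurement
    standard deviations (random sign) on single cells; missingness is
    completely at random.  Positions are recorded in the returned
    dataset's ground truth; the input dataset is left untouched.
    """
    for name, rate in (("outlier_rate", outlier_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= rate <= 0.2:
            raise ValueError(f"{name} must be in [0, 0.2]")
    out = ds.copy()
    if outlier_rate == 0 and missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    table = out.trait_table
    n = len(table)

    noise_sd = {}
    for p in ds.ground_truth.get("profiles", {}).values():
        noise_sd.update(p.noise_sd)

    def _cell_sd(trait: str) -> float:
        if trait in noise_sd and noise_sd[trait] > 0:
            return noise_sd[trait]
        sd = float(table.loc[table["trait"] == trait, "value"].std())
        return sd if sd > 0 else 1.0

    n_outliers = int(round(outlier_rate * n))
    n_missing = int(round(missing_rate * n))
    chosen = rng.choice(n, size=n_outliers + n_missing, replace=False)
    outlier_idx, missing_idx = chosen[:n_outliers], chosen[n_outliers:]

    outlier_records = []
    for idx in outlier_idx:
        row = table.iloc[idx]
        shift = outlier_magnitude * _cell_sd(row["trait"]) * rng.choice([-1.0, 1.0])
        table.iat[idx, table.columns.get_loc("value")] = row["value"] + shift
        outlier_records.append(
            {
                "row": int(idx),
                "plant_id": row["plant_id"],
                "trait": row["trait"],
                "das": int(row["das"]),
                "time_of_day": float(row["time_of_day"]),
                "original": float(row["value"]),
                "shift": float(shift),
            }
        )
    missing_records = []
    for idx in missing_idx:
        row = table.iloc[idx]
        missing_records.append(
            {
                "row": int(idx),
                "plant_id": row["plant_id"],
                "trait": row["trait"],
                "das": int(row["das"]),
                "time_of_day": float(row["time_of_day"]),
                "original": float(row["value"]),
            }
        )
        table.iat[idx, table.columns.get_loc("value")] = np.nan

    out.ground_truth["outliers"] = outlier_records
    out.ground_truth["missing"] = missing_records
    return out


# ---------------------------------------------------------------------------
# I/O


def write_dataset(ds: PhenoDataset, outdir: str | Path) -> None:
    """Write trait_table.csv, gravimetric.csv, harvest.csv, ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.trait_table.to_csv(outdir / "trait_table.csv", index=False)
    ds.gravimetric_table.to_csv(outdir / "gravimetric.csv", index=False)
    ds.harvest_table.to_csv(outdir / "harvest.csv", index=False)
    gt = ds.ground_truth
    serializable = {
        "soil_evap_rate": gt.get("soil_evap_rate", {}),
        "outliers": gt.get("outliers", []),
        "missing": gt.get("missing", []),
        "effects": gt["effects"].to_dict(orient="records") if "effects" in gt else [],
        "fw_curves": gt["fw_curves"].to_dict(orient="records")
        if "fw_curves" in gt
        else [],
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1)
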