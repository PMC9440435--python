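"""Experiment design and genotype parameterization for the virtual greenhouse.

The study design emulated here: spring wheat genotypes grown in 1 L pots,
imaged and weighed twice a day from 15 to 37 days after sowing (DAS), with
half of the plants switched to a water-deficit regime (WD38, >=30% field
capacity) at DAS 30 while the other half stays well watered (WW38, >90%
field capacity); both treatments run at elevated temperature from DAS 30.
Soil-only pots per treatment track non-transpirational water loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

WW = "WW38"
WD = "WD38"
TREATMENTS = (WW, WD)

#: clock hours of the two daily weighing/imaging passes
MEASUREMENT_HOURS = (8.0, 16.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Dimensions and schedule of a (virtual) phenotyping experiment.

    Parameters
    ----------
    n_genotypes, n_replicates
        Genotypes and replicate plants per genotype x treatment.
    treatments
        Treatment labels; the second label is the water-deficit arm.
    das_start, das_end
        First and last measurement day (days after sowing).
    stress_onset_das
        Day the temperature is raised and the irrigation arms diverge.
    measurements_per_day
        Weighing/imaging passes per day.
    n_soil_pots
        Soil-only (plant-free) pots per treatment.
    forecast_das
        Upper bound of the growth-model extrapolation window.
    """

    n_genotypes: int = 10
    n_replicates: int = 5
    treatments: Sequence[str] = TREATMENTS
    das_start: int = 15
    das_end: int = 37
    stress_onset_das: int = 30
    measurements_per_day: int = 2
    n_soil_pots: int = 3
    forecast_das: int = 41

    def __post_init__(self) -> None:
        if not (self.das_start <= self.stress_onset_das <= self.das_end):
            raise ValueError("stress_onset_das must lie within the DAS range")
        if self.measurements_per_day < 1:
            raise ValueError("measurements_per_day must be >= 1")
        for name in ("n_genotypes", "n_replicates", "n_soil_pots"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.treatments) != 2:
            raise ValueError("exactly two treatments are supported")

    @property
    def das_values(self) -> np.ndarray:
        return np.arange(self.das_start, self.das_end + 1)

    @property
    def measurement_times(self) -> np.ndarray:
        """All measurement times as fractional DAS, twice daily by default."""
        hours = np.asarray(MEASUREMENT_HOURS[: self.measurements_per_day])
        return (self.das_values[:, None] + hours[None, :] / 24.0).ravel()

    @property
    def n_timepoints(self) -> int:
        return len(self.das_values) * self.measurements_per_day

    @property
    def n_plants(self) -> int:
        return self.n_genotypes * self.n_replicates * len(self.treatments)


@dataclass(frozen=True)
class TraitEffect:
    """Additive shifts of one trait: genotype main effect, treatment main
    effect applied after stress onset, and their interaction."""

    genotype: float = 0.0
    treatment: float = 0.0
    interaction: float = 0.0


@dataclass
class GenotypeProfile:
    """Ground-truth parameterization of a single genotype.

    growth_params maps treatment -> (a, b, c) of the bell-shaped biomass
    curve y(t) = a * exp(-(t - b)^2 / (2 c^2)) with a in g fresh weight,
    b in DAS and c in days.  transpiration_coeff is mg H2O per hour per g
    aboveground fresh weight, per treatment.  trait_effects hold additive
    offsets per trait name.  Allometry links fresh weight to exposed area
    (mm^2 per g) and plant height (mm per g); dry matter is a fixed
    fraction of fresh weight.
    """

    name: str
    growth_params: Mapping[str, tuple[float, float, float]]
    transpiration_coeff: Mapping[str, float]
    trait_effects: Mapping[str, TraitEffect] = field(default_factory=dict)
    area_per_fw: float = 900.0
    height_per_fw: float = 14.0
    height_offset: float = 60.0
    dw_fraction: float = 0.18
    root_fraction: float = 0.35
    noise_sd: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for trt, (a, b, c) in self.growth_params.items():
            if a <= 0 or c <= 0:
                raise ValueError(f"bell parameters a, c must be > 0 ({trt})")
        if self.area_per_fw <= 0 or self.height_per_fw <= 0:
            raise ValueError("allometry coefficients must be > 0")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")

    def biomass(self, t: np.ndarray | float, treatment: str) -> np.ndarray | float:
        a, b, c = self.growth_params[treatment]
        t = np.asarray(t, dtype=float)
        return a * np.exp(-((t - b) ** 2) / (2.0 * c**2))


@dataclass
class PhenoDataset:
    """Container for one simulated (or loaded) experiment.

    trait_table
        Long format: plant_id, genotype, treatment, das, time_of_day,
        trait, value.
    gravimetric_table
        pot_id, genotype (empty for soil-only), treatment, is_soil_only,
        time (fractional DAS), das, weight_g (pre-irrigation),
        irrigation_g (water added right after the weighing).
    harvest_table
        plant_id, genotype, treatment, aerial_fw_g, aerial_dw_g,
        root_dw_g, n_leaves, n_tillers.
    ground_truth
        True curves, transpiration series, effect sizes and injected
        artifact positions; empty for real data.
    """

    trait_table: pd.DataFrame
    gravimetric_table: pd.DataFrame
    harvest_table: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def copy(self) -> "PhenoDataset":
        import copy as _copy

        return PhenoDataset(
            trait_table=self.trait_table.copy(),
            gravimetric_table=self.gravimetric_table.copy(),
            harvest_table=self.harvest_table.copy(),
            ground_truth=_copy.deepcopy(self.ground_truth),
        )
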