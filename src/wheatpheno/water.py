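"""Gravimetric evapotranspiration and water-use analysis.

Pot water loss per hour between consecutive weighings is the raw
evapotranspiration signal.  Soil-only pots under the same irrigation
regime estimate the non-transpirational component; subtracting the
treatment's mean soil-only rate interval by interval leaves plant
transpiration.  Daily aggregates and biomass-normalized values feed the
trait-evapotranspiration correlation analysis.

Gravimetric records use the convention that the recorded weight is the
pre-irrigation weight and ``irrigation_g`` is added immediately after
the weighing, so the loss on an interval is
``weight_start + irrigation_start - weight_end``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_KEYS = ["t_start", "t_end"]


def hourly_evapotranspiration(
    records: pd.DataFrame, *, infer_irrigation: bool = False
) -> pd.DataFrame:
    """Per-interval water loss and hourly rate for one pot.

    ``records`` needs columns time, weight_g, irrigation_g (plus
    pot_id/treatment which are carried through); time is fractional DAS
    and must be strictly increasing.  With ``infer_irrigation=True`` the
    irrigation column is ignored and any positive weight jump between
    consecutive records is treated as irrigation (for data sources that
    do not log irrigation explicitly).  Negative computed losses are
    kept and flagged as anomalies, not clipped.
    """
    if len(records) < 2:
        raise ValueError("need at least two gravimetric records")
    rec = records.sort_values("time").reset_index(drop=True)
    t = rec["time"].to_numpy(dtype=float)
    if not (np.diff(t) > 0).all():
        raise ValueError("timestamps must be strictly increasing")
    w = rec["weight_g"].to_numpy(dtype=float)
    if infer_irrigation:
        irr = np.maximum(0.0, np.append(w[1:] - w[:-1], 0.0))
    else:
        irr = rec["irrigation_g"].to_numpy(dtype=float)
    hours = np.diff(t) * 24.0
    loss_g = w[:-1] + irr[:-1] - w[1:]
    out = pd.DataFrame(
        {
            "t_start": t[:-1],
            "t_end": t[1:],
            "hours": hours,
            "water_loss_mg": loss_g * 1000.0,
            "rate_mg_h": loss_g * 1000.0 / hours,
            "anomaly": loss_g < 0,
        }
    )
    for col in ("pot_id", "treatment"):
        if col in rec.columns:
            out.insert(0, col, rec[col].iloc[0])
    out["das"] = np.floor(out["t_start"]).astype(int)
    return out


def pot_water_balance(records: pd.DataFrame) -> float:
    """Conservation residual for one pot:
    sum of interval losses - (sum of irrigation - net weight change);
    exactly zero on noise-free data."""
    intervals = hourly_evapotranspiration(records)
    rec = records.sort_values("time")
    total_loss = float(intervals["water_loss_mg"].sum()) / 1000.0
    irrigation = float(rec["irrigation_g"].iloc[:-1].sum())
    net_change = float(rec["weight_g"].iloc[-1] - rec["weight_g"].iloc[0])
    return total_loss - (irrigation - net_change)


def soil_reference_rates(gravimetric: pd.DataFrame) -> pd.DataFrame:
    """Mean soil-only evaporation rate per treatment and interval."""
    soil = gravimetric[gravimetric["is_soil_only"]]
    if soil.empty:
        raise ValueError("no soil-only pots in the gravimetric table")
    frames = [
        hourly_evapotranspiration(g) for _, g in soil.groupby("pot_id", sort=True)
    ]
    rates = pd.concat(frames, ignore_index=True)
    return (
        rates.groupby(["treatment"] + INTERVAL_KEYS)["rate_mg_h"]
        .mean()
        .rename("soil_rate_mg_h")
        .reset_index()
    )


def correct_soil_evaporation(
    plant_rates: pd.DataFrame, soil_rates: pd.DataFrame
) -> pd.DataFrame:
    """Subtract the treatment-matched soil-only rate interval by interval.

    Corrected rates are floored at zero; the number of floored intervals
    is reported in the ``floored`` column (True where flooring applied).
    Missing soil coverage for any plant interval is an error.
    """
    merged = plant_rates.merge(
        soil_rates, on=["treatment"] + INTERVAL_KEYS, how="left", validate="m:1"
    )
    if merged["soil_rate_mg_h"].isna().any():
        missing = merged.loc[merged["soil_rate_mg_h"].isna(), "treatment"].unique()
        raise ValueError(
            f"no soil-only reference covering some intervals for treatment(s) "
            f"{list(missing)}"
        )
    raw_corrected = merged["rate_mg_h"] - merged["soil_rate_mg_h"]
    merged["corrected_rate_mg_h"] = raw_corrected.clip(lower=0.0)
    merged["floored"] = raw_corrected < 0
    return merged


def daily_evapotranspiration(corrected: pd.DataFrame) -> pd.DataFrame:
    """Total corrected water loss per pot per calendar DAS (g day^-1).

    An interval is attributed to the day it starts on (the overnight
    interval counts toward the evening measurement's day).
    """
    out = corrected.copy()
    out["corrected_loss_g"] = out["corrected_rate_mg_h"] * out["hours"] / 1000.0
    daily = (
        out.groupby(["pot_id", "das"])["corrected_loss_g"]
        .sum()
        .rename("evap_daily_g")
        .reset_index()
    )
    return daily


def normalized_evapotranspiration(
    daily: pd.DataFrame, harvest: pd.DataFrame
) -> pd.DataFrame:
    """Final-day evapotranspiration per g of harvested dry biomass.

    Returns one row per plant with evap_daily_g (final complete day),
    evap_per_aerial_dw and evap_per_root_dw; a zero biomass component
    leaves the corresponding ratio as NaN.
    """
    final_das = daily["das"].max()
    final = daily[daily["das"] == final_das].rename(columns={"pot_id": "plant_id"})
    merged = harvest.merge(final[["plant_id", "evap_daily_g"]], on="plant_id")
    with np.errstate(divide="ignore", invalid="ignore"):
        merged["evap_per_aerial_dw"] = np.where(
            merged["aerial_dw_g"] > 0,
            merged["evap_daily_g"] / merged["aerial_dw_g"],
            np.nan,
        )
        merged["evap_per_root_dw"] = np.where(
            merged["root_dw_g"] > 0,
            merged["evap_daily_g"] / merged["root_dw_g"],
            np.nan,
        )
    return merged


def analyze_water_use(
    gravimetric: pd.DataFrame, *, infer_irrigation: bool = False
) -> pd.DataFrame:
    """Full per-pot chain: interval rates for every plant pot, corrected
    by the treatment-matched soil-only reference."""
    plants = gravimetric[~gravimetric["is_soil_only"]]
    if plants.empty:
        raise ValueError("no plant pots in the gravimetric table")
    frames = [
        hourly_evapotranspiration(g, infer_irrigation=infer_irrigation)
        for _, g in plants.groupby("pot_id", sort=True)
    ]
    rates = pd.concat(frames, ignore_index=True)
    soil = soil_reference_rates(gravimetric)
    return correct_soil_evaporation(rates, soil)


def evap_trait_correlations(final_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-treatment Pearson correlations between evapotranspiration
    measures and biomass / architecture traits.

    ``final_table`` holds one row per plant with a ``treatment`` column,
    the evapotranspiration columns (evap_daily_g and normalized forms)
    and the harvest traits (aerial_dw_g, root_dw_g, shoot_root_ratio,
    n_leaves, ...).  Constant columns yield NaN correlations (undefined,
    left marked rather than dropped).
    """
    results = {}
    numeric = final_table.select_dtypes("number").columns
    for treatment, sub in final_table.groupby("treatment", sort=True):
        if len(sub) < 3:
            raise ValueError(
                f"need >= 3 plants per treatment, got {len(sub)} for {treatment}"
            )
        results[treatment] = sub[numeric].corr(method="pearson")
    return results
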