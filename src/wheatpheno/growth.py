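"""Mechanistic growth modelling and stress-tolerance indices.

Predicted biomass trajectories are fitted with a suite of growth-model
forms by nonlinear least squares; a fit is acceptable when R^2 > 0.7 and
the F-test against the constant-mean model gives P < 0.05, and among
acceptable fits the highest R^2 wins.  The fitted curve's maximum on the
modelling window defines Timemax (day of maximum biomass) and Biomass at
Timemax.  From the fitted curves, the per-pot water record and the two
treatment arms, each genotype receives:

    GR        = ln(B_Timemax - B_T1) / (Timemax - T1)    per treatment
    WUE       = (B_Timemax - B_T1) /
                ((water supplied at Timemax - at T1) - soil-only loss)
    MP        = (B_Timemax^WW + B_Timemax^WD) / 2        mean productivity
    BRR       = B_Timemax^WD / B_Timemax^WW              biomass reduction
    IPS       = Timemax^WW - Timemax^WD                  inflection stability
    GR ratio  = GR^WD / GR^WW
    WUE ratio = WUE^WD / WUE^WW

where T1 is the day of stress imposition.  The GR formula takes the
logarithm of the biomass *difference* as printed in its source
definition; the conventional relative growth rate
(ln B2 - ln B1) / dt is available behind ``method="rgr"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_WINDOW = (24.0, 41.0)
TIMEMAX_SCAN_STEP = 0.01  # days, for model forms without a closed-form argmax


# ---------------------------------------------------------------------------
# model forms


def bell(t, a, b, c):
    """Bell-shaped growth: y = a * exp(-(t-b)^2 / (2 c^2))."""
    return a * np.exp(-((t - b) ** 2) / (2.0 * c**2))


def logistic(t, a, k, t0):
    return a / (1.0 + np.exp(-k * (t - t0)))


def gompertz(t, a, k, t0):
    return a * np.exp(-np.exp(-k * (t - t0)))


def exponential(t, a, r):
    return a * np.exp(r * t)


def linear(t, m, q):
    return m * t + q


def quadratic(t, a2, a1, a0):
    return a2 * t**2 + a1 * t + a0


def monomolecular(t, a, k, t0):
    return a * (1.0 - np.exp(-k * (t - t0)))


def _init_bell(t, y):
    return [max(y.max(), 1e-6), t[int(np.argmax(y))], (t.max() - t.min()) / 4.0]


def _init_sigmoid(t, y):
    return [max(y.max(), 1e-6) * 1.05, 0.5, float(np.median(t))]


def _init_exponential(t, y):
    ylog = np.log(np.clip(y, 1e-9, None))
    r, loga = np.polyfit(t, ylog, 1)
    return [np.exp(loga), r]


def _init_monomolecular(t, y):
    return [max(y.max(), 1e-6) * 1.1, 0.1, float(t.min()) - 1.0]


def _init_linear(t, y):
    return list(np.polyfit(t, y, 1))


def _init_quadratic(t, y):
    return list(np.polyfit(t, y, 2))


MODEL_FORMS: dict[str, tuple[Callable, Callable, list[str]]] = {
    "bell": (bell, _init_bell, ["a", "b", "c"]),
    "logistic": (logistic, _init_sigmoid, ["a", "k", "t0"]),
    "gompertz": (gompertz, _init_sigmoid, ["a", "k", "t0"]),
    "exponential": (exponential, _init_exponential, ["a", "r"]),
    "linear": (linear, _init_linear, ["m", "q"]),
    "quadratic": (quadratic, _init_quadratic, ["a2", "a1", "a0"]),
    "monomolecular": (monomolecular, _init_monomolecular, ["a", "k", "t0"]),
}


@dataclass
class GrowthFit:
    """One fitted growth model plus quality metrics and curve summary."""

    model_name: str
    parameters: dict[str, float]
    r_squared: float
    fit_p_value: float
    timemax: float
    biomass_at_timemax: float
    window: tuple[float, float]
    converged: bool
    n_points: int = 0

    @property
    def passed(self) -> bool:
        return bool(
            self.converged and self.r_squared > 0.7 and self.fit_p_value < 0.05
        )

    def curve(self, t):
        func = MODEL_FORMS[self.model_name][0]
        return func(np.asarray(t, dtype=float), *self.parameters.values())


def _fit_quality(y: np.ndarray, resid: np.ndarray, n_params: int) -> tuple[float, float]:
    """R^2 and F-test P value against the constant-mean model."""
    n = len(y)
    sse = float((resid**2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return (1.0, 0.0) if sse == 0 else (0.0, 1.0)
    r2 = 1.0 - sse / sst
    df_num, df_den = n_params - 1, n - n_params
    if df_num <= 0 or df_den <= 0 or sse == 0:
        p = 0.0 if sse < sst else 1.0
        return r2, p
    f = ((sst - sse) / df_num) / (sse / df_den)
    return r2, float(stats.f.sf(f, df_num, df_den))


def fit_growth_models(
    series: pd.DataFrame,
    models: Sequence[str] = tuple(MODEL_FORMS),
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> list[GrowthFit]:
    """Fit each requested model form to a (das, value) biomass series.

    Observations inside ``[window[0], window[1]]`` are used (typically
    the data end before the window's forecast bound, so the curve is
    extrapolated up to it for the Timemax search).  Non-convergence of a
    form is recorded on its GrowthFit, not raised.  Initialization per
    form: bell starts at (max y, argmax day, window span / 4); sigmoids
    at (1.05 max y, 0.5 / day, median day); polynomial forms at their
    least-squares solution.
    """
    das = series["das"].to_numpy(dtype=float)
    y = series["value"].to_numpy(dtype=float)
    keep = (das >= window[0]) & (das <= window[1])
    t, y = das[keep], y[keep]
    if len(t) < 5:
        raise ValueError("need at least 5 timepoints inside the fitting window")
    if (y < 0).any():
        raise ValueError("biomass must be non-negative")
    fits = []
    for name in models:
        func, init, param_names = MODEL_FORMS[name]
        try:
            p0 = init(t, y)
            if name in ("linear", "quadratic"):
                params = np.asarray(p0, dtype=float)  # closed-form LSQ
            else:
                params, _ = optimize.curve_fit(func, t, y, p0=p0, maxfev=20_000)
            resid = y - func(t, *params)
            if not np.isfinite(resid).all():
                raise RuntimeError("non-finite residuals")
            r2, p = _fit_quality(y, resid, len(params))
            fit = GrowthFit(
                model_name=name,
                parameters=dict(zip(param_names, map(float, params))),
                r_squared=r2,
                fit_p_value=p,
                timemax=np.nan,
                biomass_at_timemax=np.nan,
                window=window,
                converged=True,
                n_points=len(t),
            )
            fit.timemax, fit.biomass_at_timemax = extract_timemax(fit, window)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            fit = GrowthFit(
                model_name=name,
                parameters={},
                r_squared=np.nan,
                fit_p_value=np.nan,
                timemax=np.nan,
                biomass_at_timemax=np.nan,
                window=window,
                converged=False,
                n_points=len(t),
            )
        fits.append(fit)
    return fits


def select_growth_model(fits: Sequence[GrowthFit]) -> GrowthFit | None:
    """The acceptable fit (R^2 > 0.7, P < 0.05) with the highest R^2;
    ties by fewer parameters, then by model name.  None if nothing
    passes."""
    if not fits:
        raise ValueError("no fits supplied")
    passing = [f for f in fits if f.passed]
    if not passing:
        return None
    return min(
        passing, key=lambda f: (-f.r_squared, len(f.parameters), f.model_name)
    )


def extract_timemax(
    fit: GrowthFit, window: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Day and value of the fitted curve's maximum on the window.

    The bell form has the closed-form argmax at its peak day b (clamped
    into the window); every other form is scanned on a 0.01-day grid.
    """
    if not fit.converged:
        raise ValueError("cannot extract Timemax from a non-converged fit")
    lo, hi = window if window is not None else fit.window
    if fit.model_name == "bell":
        tmax = float(np.clip(fit.parameters["b"], lo, hi))
    else:
        grid = np.arange(lo, hi + TIMEMAX_SCAN_STEP / 2, TIMEMAX_SCAN_STEP)
        tmax = float(grid[int(np.argmax(fit.curve(grid)))])
    return tmax, float(fit.curve(tmax))


# ---------------------------------------------------------------------------
# growth rate and water use efficiency


def growth_rate(
    biomass_at_timemax: float,
    biomass_at_t1: float,
    timemax: float,
    t1: float,
    method: str = "as_printed",
) -> float:
    """Growth-rate statistic over the stress window.

    ``as_printed`` computes ln(B_max - B_T1) / (Timemax - T1) — the
    logarithm of the biomass gain itself.  ``rgr`` computes the
    conventional relative growth rate (ln B_max - ln B_T1) / dt.
    Returns NaN when the gain or the interval is non-positive.
    """
    dt = timemax - t1
    gain = biomass_at_timemax - biomass_at_t1
    if dt <= 0 or gain <= 0:
        return np.nan
    if method == "as_printed":
        return float(np.log(gain) / dt)
    if method == "rgr":
        if biomass_at_t1 <= 0:
            return np.nan
        return float((np.log(biomass_at_timemax) - np.log(biomass_at_t1)) / dt)
    raise ValueError(f"unknown growth-rate method: {method!r}")


def water_use_efficiency(
    biomass_gain: float,
    water_at_timemax: float,
    water_at_t1: float,
    non_transpirational: float = 0.0,
) -> float:
    """Biomass produced per unit of transpired water (g g^-1):
    gain / ((water supplied at Timemax - at T1) - soil-only loss).
    NaN when the corrected water use is non-positive."""
    denom = (water_at_timemax - water_at_t1) - non_transpirational
    if denom <= 0:
        return np.nan
    return float(biomass_gain / denom)


# ---------------------------------------------------------------------------
# tolerance indices


@dataclass
class ToleranceIndexSet:
    """Five stress-tolerance indices of one genotype (WD38 vs WW38)."""

    genotype: str
    mean_productivity: float = np.nan
    biomass_reduction: float = np.nan
    inflection_point_stability: float = np.nan
    gr_ratio: float = np.nan
    wue_ratio: float = np.nan
    gr: dict[str, float] = field(default_factory=dict)
    wue: dict[str, float] = field(default_factory=dict)
    available: bool = True

    def as_row(self) -> dict[str, float]:
        return {
            "genotype": self.genotype,
            "mean_productivity": self.mean_productivity,
            "biomass_reduction": self.biomass_reduction,
            "inflection_point_stability": self.inflection_point_stability,
            "gr_ratio": self.gr_ratio,
            "wue_ratio": self.wue_ratio,
        }


def tolerance_indices(
    genotype: str,
    fits: Mapping[str, GrowthFit | None],
    gr: Mapping[str, float] | None = None,
    wue: Mapping[str, float] | None = None,
    treatments: tuple[str, str] = ("WW38", "WD38"),
) -> ToleranceIndexSet:
    """Compute the five indices from the two treatment arms' fits.

    ``fits`` maps treatment -> selected GrowthFit (None if no model
    passed); ``gr`` and ``wue`` map treatment -> value.  A missing or
    failed fit marks the whole index set unavailable (NaN throughout).
    """
    ww, wd = treatments
    fit_ww, fit_wd = fits.get(ww), fits.get(wd)
    if fit_ww is None or fit_wd is None:
        return ToleranceIndexSet(genotype=genotype, available=False)
    b_ww, b_wd = fit_ww.biomass_at_timemax, fit_wd.biomass_at_timemax
    out = ToleranceIndexSet(
        genotype=genotype,
        mean_productivity=(b_ww + b_wd) / 2.0,
        biomass_reduction=b_wd / b_ww if b_ww > 0 else np.nan,
        inflection_point_stability=fit_ww.timemax - fit_wd.timemax,
        gr=dict(gr or {}),
        wue=dict(wue or {}),
    )
    if gr and np.isfinite(gr.get(ww, np.nan)) and gr[ww] != 0:
        out.gr_ratio = gr[wd] / gr[ww]
    if wue and np.isfinite(wue.get(ww, np.nan)) and wue[ww] != 0:
        out.wue_ratio = wue[wd] / wue[ww]
    return out


def index_table(index_sets: Sequence[ToleranceIndexSet]) -> pd.DataFrame:
    """Genotype x index DataFrame from a collection of index sets."""
    rows = [s.as_row() for s in index_sets]
    return pd.DataFrame(rows).set_index("genotype")


def rescale_and_cluster(
    indices: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Min-max rescale each index column to [0, 1] and cluster genotypes.

    A constant column carries no contrast and is set to 0.5 throughout
    (reported in the returned flag list).  Returns (rescaled matrix,
    genotype labels in dendrogram leaf order, flagged constant columns).
    """
    from .variance import cluster_matrix

    if len(indices) < 2:
        raise ValueError("need at least two genotypes")
    if not np.isfinite(indices.to_numpy(dtype=float)).all():
        raise ValueError("indices must be finite for rescaling")
    rescaled = indices.copy().astype(float)
    constant = []
    for col in rescaled.columns:
        lo, hi = rescaled[col].min(), rescaled[col].max()
        if hi == lo:
            rescaled[col] = 0.5
            constant.append(col)
        else:
            rescaled[col] = (rescaled[col] - lo) / (hi - lo)
    order, _ = cluster_matrix(rescaled)
    return rescaled, order, constant
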