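"""Biomass prediction from image-derived geometry.

Aboveground fresh and dry weight at harvest are regressed on the exposed
projected area (area.low, mm^2) and the pyramidal plant volume
(volumepyr = area x height / 3, mm^3).  A suite of regression models is
evaluated with a stratified 70/30 train/test split and 10-fold
cross-validation inside the training split for hyperparameter choice;
a model is acceptable when, on the held-out split,

    R^2 > 0.7   and   MRSRE < 0.3   and   |mu| < 0.05

where R^2 is the squared Pearson correlation of predicted vs observed,
MRSRE the root mean squared relative error and mu the mean relative
bias.  The accepted model with the smallest |mu| (ties broken by MRSRE)
is refit on all harvest-day data and applied to the whole time course to
produce the predicted biomass trajectories (FW_sv / DW_sv).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

FEATURE_COLUMNS = ["area_low", "volumepyr"]


def pyramidal_volume(area: float | np.ndarray, height: float | np.ndarray):
    """Pyramidal plant volume V = area x height / 3 (mm^3)."""
    area = np.asarray(area, dtype=float)
    height = np.asarray(height, dtype=float)
    if (area < 0).any() or (height < 0).any():
        raise ValueError("area and height must be non-negative")
    volume = area * height / 3.0
    return float(volume) if volume.ndim == 0 else volume


def selection_metrics(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float, float]:
    """(R^2, PCC, MRSRE, mu) of predicted vs observed.

    PCC is the Pearson correlation, R^2 its square; MRSRE the root mean
    squared relative error and mu the mean relative bias, both on
    (pred - obs) / obs.  Observed values must be strictly positive.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must share a length >= 2")
    if (obs == 0).any():
        raise ValueError("observed values must be nonzero for relative errors")
    rel = (pred - obs) / obs
    mrsre = float(np.sqrt(np.mean(rel**2)))
    mu = float(np.mean(rel))
    if obs.std() == 0 or pred.std() == 0:
        pcc = np.nan
    else:
        pcc = float(np.corrcoef(obs, pred)[0, 1])
    r2 = pcc**2 if np.isfinite(pcc) else np.nan
    return r2, pcc, mrsre, mu


# ---------------------------------------------------------------------------
# model suite


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("model", estimator)])


def core_suite() -> dict[str, tuple[object, Mapping[str, list]]]:
    """The mandatory linear-family suite: estimator + CV parameter grid."""
    return {
        "ols": (LinearRegression(), {}),
        "ridge": (_scaled(Ridge()), {"model__alpha": [0.01, 0.1, 1.0, 10.0]}),
        "lasso": (_scaled(Lasso(max_iter=50_000)),
                  {"model__alpha": [0.001, 0.01, 0.1, 1.0]}),
        "elastic_net": (
            _scaled(ElasticNet(max_iter=50_000)),
            {"model__alpha": [0.001, 0.01, 0.1], "model__l1_ratio": [0.2, 0.5, 0.8]},
        ),
        "svm_linear": (
            _scaled(LinearSVR(max_iter=500_000, tol=1e-5)),
            {"model__C": [0.1, 1.0, 10.0, 100.0]},
        ),
    }


@dataclass
class ModelEvaluation:
    """Held-out performance and acceptance status of one regressor."""

    model_name: str
    r2: float
    pcc: float
    mrsre: float
    mu: float
    passed: bool
    best_params: dict = field(default_factory=dict)
    estimator: object | None = None

    @staticmethod
    def criteria(r2: float, mrsre: float, mu: float) -> bool:
        return bool(r2 > 0.7 and mrsre < 0.3 and abs(mu) < 0.05)


def evaluate_model_suite(
    features: pd.DataFrame,
    targets: pd.Series,
    suite: Mapping[str, tuple[object, Mapping]] | None = None,
    split_fraction: float = 0.7,
    folds: int = 10,
    seed: int = 0,
    strata: Sequence[str] | None = None,
) -> list[ModelEvaluation]:
    """Evaluate every model of the suite on a stratified 70/30 split.

    ``features`` holds the harvest-day predictors (one row per plant),
    ``targets`` the matching FW or DW values.  ``strata`` (e.g.
    genotype x treatment labels) stratifies the split when given.
    Hyperparameters are chosen by ``folds``-fold cross-validation inside
    the training split; the three acceptance criteria are judged on the
    held-out split.
    """
    if suite is None:
        suite = core_suite()
    if not suite:
        raise ValueError("model suite is empty")
    x = features.to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    n = len(y)
    if n < 20:
        raise ValueError(f"need >= 20 observations, got {n}")
    x_tr, x_te, y_tr, y_te = train_test_split(
        x,
        y,
        train_size=split_fraction,
        random_state=seed,
        stratify=list(strata) if strata is not None else None,
    )
    if len(x_tr) < folds:
        raise ValueError("fewer training observations than CV folds")
    evaluations = []
    for name, (estimator, grid) in suite.items():
        if grid:
            search = GridSearchCV(
                clone(estimator), dict(grid), cv=folds,
                scoring="neg_mean_squared_error",
            )
            search.fit(x_tr, y_tr)
            fitted = search.best_estimator_
            best_params = dict(search.best_params_)
        else:
            fitted = clone(estimator)
            fitted.fit(x_tr, y_tr)
            best_params = {}
        pred = fitted.predict(x_te)
        r2, pcc, mrsre, mu = selection_metrics(y_te, pred)
        evaluations.append(
            ModelEvaluation(
                model_name=name,
                r2=r2,
                pcc=pcc,
                mrsre=mrsre,
                mu=mu,
                passed=ModelEvaluation.criteria(r2, mrsre, mu),
                best_params=best_params,
                estimator=fitted,
            )
        )
    return evaluations


@dataclass
class TrajectoryPrediction:
    model_name: str
    evaluation: ModelEvaluation
    predictions: pd.DataFrame  # plant_id, das, time_of_day(optional), predicted


class NoAcceptableModelError(RuntimeError):
    """No model met the three acceptance criteria; metrics attached."""

    def __init__(self, evaluations: list[ModelEvaluation]):
        self.evaluations = evaluations
        lines = ", ".join(
            f"{e.model_name}: R2={e.r2:.3f} MRSRE={e.mrsre:.3f} mu={e.mu:.3f}"
            for e in evaluations
        )
        super().__init__(f"no model passed the acceptance criteria ({lines})")


def select_and_predict_trajectory(
    evaluations: list[ModelEvaluation],
    harvest_features: pd.DataFrame,
    harvest_targets: pd.Series,
    features_over_time: pd.DataFrame,
    feature_columns: Sequence[str] = tuple(FEATURE_COLUMNS),
) -> TrajectoryPrediction:
    """Pick the accepted model with the lowest predictive bias and
    predict the biomass trajectory at every timepoint.

    Selection among passing models: smallest |mu|, ties broken by
    smallest MRSRE.  The chosen model is refit on all harvest-day data
    before being applied to ``features_over_time`` (which needs the
    feature columns plus plant_id and a time axis).
    """
    passing = [e for e in evaluations if e.passed]
    if not passing:
        raise NoAcceptableModelError(evaluations)
    chosen = min(passing, key=lambda e: (abs(e.mu), e.mrsre))
    refit = clone(chosen.estimator)
    refit.fit(harvest_features.to_numpy(dtype=float),
              np.asarray(harvest_targets, dtype=float))
    predicted = refit.predict(
        features_over_time[list(feature_columns)].to_numpy(dtype=float)
    )
    out = features_over_time.drop(columns=list(feature_columns)).copy()
    out["predicted"] = predicted
    return TrajectoryPrediction(
        model_name=chosen.model_name, evaluation=chosen, predictions=out
    )


def harvest_feature_table(trait_table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-plant-and-timepoint feature table (area_low, height,
    volumepyr) from the long trait table."""
    geometry = trait_table[trait_table["trait"].isin(["area_low", "height"])]
    wide = geometry.pivot_table(
        index=["plant_id", "genotype", "treatment", "das", "time_of_day"],
        columns="trait",
        values="value",
    ).reset_index()
    wide["volumepyr"] = pyramidal_volume(
        wide["area_low"].clip(lower=0.0), wide["height"].clip(lower=0.0)
    )
    return wide
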