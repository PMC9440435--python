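"""Trait quality control: outliers, imputation, reproducibility, collinearity.

The cleaning chain applied before any variance partitioning:

1. Grubbs' test on each replicate group (same genotype, treatment, trait
   and timepoint) flags and removes outliers, iterating until the group
   is clean.
2. Missing cells (including removed outliers) are imputed from the
   observed members of the same replicate group.
3. Traits whose replicate trajectories do not agree (median replicate
   correlation over genotypes <= 0.7, or replicate correlations not
   significantly above random plant pairs) are dropped as irreproducible.
4. Stepwise variance-inflation-factor (VIF) selection removes the most
   collinear trait until every survivor has VIF < 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

REPLICATE_KEYS = ["genotype", "treatment", "trait", "das", "time_of_day"]


# ---------------------------------------------------------------------------
# Grubbs outlier screen


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t closed form."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


@dataclass
class GrubbsResult:
    """Outcome of an iterative Grubbs screen on one replicate vector."""

    flagged: list[int]
    statistics: list[tuple[int, float, float]]  # (index, G, critical)
    testable: bool


def grubbs_screen(values: Sequence[float], alpha: float = 0.05) -> GrubbsResult:
    """Iteratively flag the most extreme value while it exceeds the
    two-sided Grubbs critical bound at ``alpha``.

    Returned indices refer to positions in the input vector.  Vectors
    shorter than 3 cannot be tested and come back with
    ``testable=False``; a zero-spread vector has an undefined G and
    yields no outliers.
    """
    if not 0.0 < alpha <= 0.5:
        raise ValueError("alpha must be in (0, 0.5]")
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        return GrubbsResult(flagged=[], statistics=[], testable=False)
    active = list(range(len(x)))
    flagged: list[int] = []
    statistics: list[tuple[int, float, float]] = []
    while len(active) >= 3:
        sub = x[active]
        sd = sub.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        g = dev[k] / sd
        crit = grubbs_critical(len(sub), alpha)
        if g > crit:
            idx = active.pop(k)
            flagged.append(idx)
            statistics.append((idx, float(g), float(crit)))
        else:
            break
    return GrubbsResult(flagged=flagged, statistics=statistics, testable=True)


def screen_table(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[dict]]:
    """Run the Grubbs screen over every replicate group of a long trait
    table; flagged values are set to NaN (deleted) and reported."""
    out = table.copy()
    removed = []
    for key, group in out.groupby(REPLICATE_KEYS, sort=False):
        obs = group.dropna(subset=["value"])
        result = grubbs_screen(obs["value"].to_numpy(), alpha)
        for idx, g, crit in result.statistics:
            row = obs.iloc[idx]
            removed.append(
                {
                    **dict(zip(REPLICATE_KEYS, key)),
                    "plant_id": row["plant_id"],
                    "value": float(row["value"]),
                    "G": g,
                    "critical": crit,
                }
            )
            out.loc[obs.index[idx], "value"] = np.nan
    return out, removed


# ---------------------------------------------------------------------------
# imputation


def impute_missing(
    table: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, list[dict]]:
    """Fill missing trait values from their replicate group.

    Each NaN cell is replaced by the mean of the observed values in its
    (genotype, treatment, trait, timepoint) group — the pooled estimate
    of the group's expected value, deterministic for any seed.  A group
    with no observed member at all is unimputable and raises.
    """
    out = table.copy()
    missing_mask = out["value"].isna()
    if not missing_mask.any():
        return out, []
    group_means = out.groupby(REPLICATE_KEYS)["value"].transform("mean")
    still_missing = missing_mask & group_means.isna()
    if still_missing.any():
        key = out.loc[still_missing, REPLICATE_KEYS].iloc[0].tolist()
        raise ValueError(f"group with no observed values, cannot impute: {key}")
    imputed = []
    for idx in out.index[missing_mask]:
        row = out.loc[idx]
        imputed.append(
            {
                **{k: row[k] for k in REPLICATE_KEYS},
                "plant_id": row["plant_id"],
                "imputed_value": float(group_means.loc[idx]),
            }
        )
    out.loc[missing_mask, "value"] = group_means[missing_mask]
    return out, imputed


# ---------------------------------------------------------------------------
# replicate reproducibility


@dataclass
class TraitReproducibility:
    trait: str
    testable: bool = True
    per_treatment: dict = field(default_factory=dict)  # trt -> (median_r, p)
    kept: bool = False


def _trajectories(sub: pd.DataFrame) -> pd.DataFrame:
    """Wide matrix time x plant of one trait within one treatment."""
    sub = sub.assign(t=sub["das"] + sub["time_of_day"] / 24.0)
    return sub.pivot_table(index="t", columns="plant_id", values="value")


def _pair_corr(mat: pd.DataFrame, a: str, b: str) -> float:
    x, y = mat[a].to_numpy(), mat[b].to_numpy()
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def reproducibility_filter(
    table: pd.DataFrame,
    r_threshold: float = 0.7,
    alpha: float = 0.05,
    n_random_pairs: int | None = None,
    seed: int = 0,
) -> tuple[list[str], list[str], list[TraitReproducibility]]:
    """Keep traits whose replicate trajectories agree beyond chance.

    For each trait and treatment, the Pearson correlation between the
    time trajectories of every replicate pair within a genotype is
    computed; criterion (i) requires the median over genotypes of the
    genotype-mean replicate correlation to exceed ``r_threshold``, and
    criterion (ii) requires replicate-pair correlations to be
    significantly higher (one-sided Welch t-test at ``alpha``) than
    correlations of random cross-genotype plant pairs.  A trait is kept
    iff both hold in at least one treatment.

    Returns (kept, dropped, per-trait details).
    """
    rng = np.random.default_rng(seed)
    kept, dropped, details = [], [], []
    for trait, tsub in table.groupby("trait", sort=True):
        detail = TraitReproducibility(trait=trait)
        n_times = tsub.groupby("plant_id").size().max()
        if n_times is None or n_times < 3:
            detail.testable = False
            details.append(detail)
            dropped.append(trait)
            continue
        for treatment, sub in tsub.groupby("treatment", sort=True):
            mat = _trajectories(sub)
            plants = list(mat.columns)
            geno_of = sub.drop_duplicates("plant_id").set_index("plant_id")["genotype"]
            rep_corrs, geno_means = [], []
            for geno, members in geno_of.groupby(geno_of):
                ids = [p for p in members.index if p in mat.columns]
                pair_r = [
                    _pair_corr(mat, a, b) for a, b in combinations(sorted(ids), 2)
                ]
                pair_r = [r for r in pair_r if np.isfinite(r)]
                if pair_r:
                    rep_corrs.extend(pair_r)
                    geno_means.append(float(np.mean(pair_r)))
            if not geno_means:
                continue
            median_r = float(np.median(geno_means))
            n_rand = n_random_pairs if n_random_pairs is not None else len(rep_corrs)
            rand_corrs = []
            attempts = 0
            while len(rand_corrs) < n_rand and attempts < 20 * max(n_rand, 1):
                a, b = rng.choice(plants, size=2, replace=False)
                attempts += 1
                if geno_of.get(a) == geno_of.get(b):
                    continue
                r = _pair_corr(mat, a, b)
                if np.isfinite(r):
                    rand_corrs.append(r)
            if len(rand_corrs) >= 2 and len(rep_corrs) >= 2:
                t_res = stats.ttest_ind(
                    rep_corrs, rand_corrs, equal_var=False, alternative="greater"
                )
                p_value = float(t_res.pvalue)
            else:
                p_value = np.nan
            passed = median_r > r_threshold and np.isfinite(p_value) and p_value < alpha
            detail.per_treatment[treatment] = {
                "median_r": median_r,
                "p_value": p_value,
                "passed": bool(passed),
            }
        detail.kept = any(v["passed"] for v in detail.per_treatment.values())
        details.append(detail)
        (kept if detail.kept else dropped).append(trait)
    return kept, dropped, details


# ---------------------------------------------------------------------------
# VIF stepwise selection


def compute_vifs(matrix: pd.DataFrame) -> pd.Series:
    """VIF of each column: 1/(1-R^2) of regressing it on the others
    (with intercept); infinite under perfect collinearity."""
    cols = list(matrix.columns)
    x = matrix.to_numpy(dtype=float)
    vifs = {}
    for j, col in enumerate(cols):
        y = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(len(y)), others])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        sst = float(((y - y.mean()) ** 2).sum())
        if sst == 0:
            vifs[col] = 1.0
            continue
        r2 = 1.0 - float((resid**2).sum()) / sst
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def vif_select(
    matrix: pd.DataFrame, vif_threshold: float = 5.0
) -> tuple[list[str], list[dict]]:
    """Stepwise removal of the most collinear trait.

    While any VIF is at or above the threshold, the trait with the
    largest VIF is removed (ties — including several infinite VIFs —
    broken by dropping the lexicographically last label, so the outcome
    is deterministic).  Returns the surviving labels and the removal
    trace with the VIF each trait had when dropped.
    """
    if matrix.shape[1] < 2:
        return list(matrix.columns), []
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("need more observations than traits for VIF selection")
    current = matrix.copy()
    trace = []
    while current.shape[1] >= 2:
        vifs = compute_vifs(current)
        worst = vifs.max()
        if worst < vif_threshold:
            break
        candidates = sorted(vifs.index[vifs == worst])
        victim = candidates[-1]
        trace.append({"trait": victim, "vif_at_removal": float(worst)})
        current = current.drop(columns=[victim])
    return list(current.columns), trace


# ---------------------------------------------------------------------------
# full chain


@dataclass
class QCReport:
    outliers_removed: list[dict]
    imputed_cells: list[dict]
    traits_kept: list[str]
    traits_dropped_reproducibility: list[dict]
    traits_dropped_vif: list[dict]
    reproducibility: list[TraitReproducibility]

    def to_dict(self) -> dict:
        return {
            "outliers_removed": self.outliers_removed,
            "imputed_cells": self.imputed_cells,
            "traits_kept": self.traits_kept,
            "traits_dropped_reproducibility": self.traits_dropped_reproducibility,
            "traits_dropped_vif": self.traits_dropped_vif,
        }


def run_qc(
    table: pd.DataFrame,
    *,
    grubbs_alpha: float = 0.05,
    r_threshold: float = 0.7,
    repro_alpha: float = 0.05,
    vif_threshold: float = 5.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, QCReport]:
    """Outlier removal, imputation, reproducibility and VIF filtering in
    sequence; returns the cleaned long table (kept traits only) and a
    report of everything removed."""
    screened, removed = screen_table(table, grubbs_alpha)
    completed, imputed = impute_missing(screened, seed)
    kept_r, dropped_r, details = reproducibility_filter(
        completed, r_threshold, repro_alpha, seed=seed
    )
    dropped_repro = [
        {
            "trait": d.trait,
            "median_r": {t: v["median_r"] for t, v in d.per_treatment.items()},
        }
        for d in details
        if not d.kept
    ]
    reduced = completed[completed["trait"].isin(kept_r)]
    wide = reduced.assign(
        t=reduced["das"] + reduced["time_of_day"] / 24.0
    ).pivot_table(index=["plant_id", "t"], columns="trait", values="value")
    kept_v, vif_trace = vif_select(wide.dropna(), vif_threshold)
    cleaned = reduced[reduced["trait"].isin(kept_v)].reset_index(drop=True)
    report = QCReport(
        outliers_removed=removed,
        imputed_cells=imputed,
        traits_kept=sorted(kept_v),
        traits_dropped_reproducibility=dropped_repro,
        traits_dropped_vif=vif_trace,
        reproducibility=details,
    )
    return cleaned, report
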