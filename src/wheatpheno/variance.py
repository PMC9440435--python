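"""Per-day variance partitioning into G, E and GxE significance (LOD scores).

For every trait and measurement day a two-way fixed-effects ANOVA with
interaction (value ~ genotype * treatment) yields raw P values for the
genotype (G), environment (E) and interaction (GxE) terms.  Days before
stress onset have a single treatment arm, so only the genotype term is
testable there.  P values are corrected across traits within each
(day, effect) family — Benjamini-Hochberg by default, Bonferroni behind
a flag — and expressed as LOD scores, -log10 of the adjusted P.

The module also provides the group-comparison statistics used
downstream: hierarchical clustering of LOD / index matrices,
Duncan's multiple range test with a compact letter display, and the
two-treatment Welch t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

EFFECTS = ("G", "E", "GxE")

#: adjusted P values are floored here, capping the LOD at 16
P_FLOOR = 1e-16
LOD_CAP = -np.log10(P_FLOOR)


# ---------------------------------------------------------------------------
# per trait-day model


def fit_trait_day_model(
    values: Sequence[float],
    genotype: Sequence[str],
    treatment: Sequence[str],
) -> dict[str, float]:
    """Raw P values of the G, E and GxE terms for one trait on one day.

    With two treatment arms, a two-way ANOVA with interaction is fitted
    (type II sums of squares); with a single arm (pre-onset days) a
    one-way genotype ANOVA is used and E / GxE come back as NaN
    (not applicable).  A genotype x treatment cell with no observations
    is an error.  If every observation is identical there is no variance
    to partition and all applicable P values are 1 by convention.
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "genotype": list(genotype),
            "treatment": list(treatment),
        }
    )
    genotypes = sorted(df["genotype"].unique())
    treatments = sorted(df["treatment"].unique())
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    if df["value"].nunique() <= 1:
        p_g = 1.0
        p_e = p_gxe = 1.0 if len(treatments) > 1 else np.nan
        return {"G": p_g, "E": p_e, "GxE": p_gxe}
    if len(treatments) < 2:
        groups = [g["value"].to_numpy() for _, g in df.groupby("genotype")]
        f_res = stats.f_oneway(*groups)
        p = 1.0 if np.isnan(f_res.pvalue) else float(f_res.pvalue)
        return {"G": p, "E": np.nan, "GxE": np.nan}
    counts = df.groupby(["genotype", "treatment"]).size()
    for g in genotypes:
        for t in treatments:
            if (g, t) not in counts.index:
                raise ValueError(f"empty cell: genotype={g}, treatment={t}")
    model = ols("value ~ C(genotype) * C(treatment)", data=df).fit()
    table = anova_lm(model, typ=2)
    pvals = table["PR(>F)"]

    def _get(term: str) -> float:
        p = pvals.get(term, np.nan)
        return 1.0 if np.isnan(p) else float(p)

    return {
        "G": _get("C(genotype)"),
        "E": _get("C(treatment)"),
        "GxE": _get("C(genotype):C(treatment)"),
    }


def scan_trait_days(
    table: pd.DataFrame, stress_onset_das: int | None = None
) -> pd.DataFrame:
    """Fit the per-day model for every (trait, das) of a long trait table.

    Twice-daily measurements are averaged per plant per day before the
    fit.  If ``stress_onset_das`` is given, days before it are treated
    as single-arm regardless of labels (the arms are indistinguishable
    before the irrigation regimes diverge).
    """
    daily = (
        table.groupby(["plant_id", "genotype", "treatment", "das", "trait"])["value"]
        .mean()
        .reset_index()
    )
    rows = []
    for (trait, das), sub in daily.groupby(["trait", "das"], sort=True):
        trt = sub["treatment"]
        if stress_onset_das is not None and das < stress_onset_das:
            trt = pd.Series(["pre-onset"] * len(sub), index=sub.index)
        pvals = fit_trait_day_model(sub["value"], sub["genotype"], trt)
        for effect in EFFECTS:
            rows.append(
                {"trait": trait, "das": int(das), "effect": effect,
                 "raw_p": pvals[effect]}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# multiplicity adjustment and LOD


@dataclass
class LODMatrix:
    """Long table of raw/adjusted P and LOD per (trait, das, effect)."""

    table: pd.DataFrame  # trait, das, effect, raw_p, adjusted_p, lod
    method: str

    def pivot(self, effect: str) -> pd.DataFrame:
        sub = self.table[self.table["effect"] == effect]
        return sub.pivot_table(index="trait", columns="das", values="lod")


def adjust_and_score(raw: pd.DataFrame, method: str = "bh") -> LODMatrix:
    """Correct raw P values across traits within each (das, effect)
    family and convert to LOD = -log10(adjusted P), capped at 16.

    ``method`` is ``"bh"`` (Benjamini-Hochberg FDR, the default) or
    ``"bonferroni"``.  NaN raw P values (not-applicable terms) stay NaN.
    """
    mt_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if mt_method is None:
        raise ValueError(f"unknown correction method: {method!r}")
    if ((raw["raw_p"].dropna() < 0) | (raw["raw_p"].dropna() > 1)).any():
        raise ValueError("raw P values must lie in [0, 1]")
    out = raw.copy()
    out["adjusted_p"] = np.nan
    for _, idx in out.groupby(["das", "effect"], sort=False).groups.items():
        sub = out.loc[idx, "raw_p"]
        ok = sub.notna()
        if ok.sum() == 0:
            continue
        adj = multipletests(sub[ok].to_numpy(), method=mt_method)[1]
        out.loc[sub.index[ok], "adjusted_p"] = adj
    out["lod"] = -np.log10(np.clip(out["adjusted_p"], P_FLOOR, 1.0))
    return LODMatrix(table=out, method=method)


# ---------------------------------------------------------------------------
# clustering


def cluster_matrix(
    matrix: pd.DataFrame, axis: int = 0
) -> tuple[list, np.ndarray]:
    """Deterministic hierarchical clustering (Euclidean, complete
    linkage) of the rows (axis=0) or columns (axis=1) of a matrix.

    Rows are pre-sorted by label so the result does not depend on input
    order; returns the labels in dendrogram leaf order plus the linkage
    matrix.  A single row is returned unchanged.
    """
    data = matrix.T if axis == 1 else matrix
    if not np.isfinite(data.to_numpy(dtype=float)).all():
        raise ValueError("matrix must be finite for clustering")
    data = data.sort_index()
    labels = list(data.index)
    if len(labels) < 2:
        return labels, np.empty((0, 4))
    z = linkage(pdist(data.to_numpy(dtype=float)), method="complete")
    order = leaves_list(z)
    return [labels[i] for i in order], z


# ---------------------------------------------------------------------------
# Duncan's multiple range test


@dataclass
class LetterDisplay:
    """Compact letter display: groups sharing a letter do not differ."""

    letters: dict[str, str]  # group label -> letter string
    means: dict[str, float]
    significant_pairs: list[tuple[str, str]]


def duncan_letters(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> LetterDisplay:
    """Duncan's multiple range test with a compact letter display.

    Group means are ranked; a pair spanning ``p`` ordered means differs
    if its range exceeds ``q * sqrt(MSE / n_h)`` where ``q`` is the
    studentized-range point at Duncan's protection level
    ``1 - (1 - alpha)^(p-1)`` and ``n_h`` the harmonic mean group size
    (the classical extension for unbalanced designs).  A range contained
    in a non-significant range is itself declared non-significant.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": list(groups)})
    stats_per_group = df.groupby("group")["value"].agg(["mean", "count"])
    if (stats_per_group["count"] < 2).any() or len(stats_per_group) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    k = len(stats_per_group)
    n_total = len(df)
    sse = float(
        df.groupby("group")["value"].transform(lambda v: v - v.mean()).pow(2).sum()
    )
    df_err = n_total - k
    mse = sse / df_err
    n_h = k / float((1.0 / stats_per_group["count"]).sum())

    ordered = stats_per_group.sort_values("mean")
    names = list(ordered.index)
    means = ordered["mean"].to_numpy()

    if mse == 0:
        sig = {
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if means[j] - means[i] > 0
        }
    else:
        se = np.sqrt(mse / n_h)
        nonsig_windows: list[tuple[int, int]] = []
        sig = set()
        for span in range(k, 1, -1):
            q = stats.studentized_range.ppf((1.0 - alpha) ** (span - 1), span, df_err)
            critical = q * se
            for i in range(0, k - span + 1):
                j = i + span - 1
                contained = any(a <= i and j <= b for a, b in nonsig_windows)
                if contained:
                    continue
                if means[j] - means[i] > critical:
                    sig.add((i, j))
                else:
                    nonsig_windows.append((i, j))
        # a pair inside any non-significant window is non-significant
        sig = {
            (i, j)
            for (i, j) in sig
            if not any(a <= i and j <= b for a, b in nonsig_windows)
        }

    # compact letter display: maximal runs of mutually non-significant groups
    letters: dict[str, list[str]] = {name: [] for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_idx = 0
    covered_upto = -1
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            (a, b) in sig for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        if j <= covered_upto and i > 0:
            continue
        letter = alphabet[letter_idx % len(alphabet)]
        letter_idx += 1
        for m in range(i, j + 1):
            letters[names[m]].append(letter)
        covered_upto = j
    return LetterDisplay(
        letters={name: "".join(ls) for name, ls in letters.items()},
        means={name: float(ordered.loc[name, "mean"]) for name in names},
        significant_pairs=[(names[i], names[j]) for i, j in sorted(sig)],
    )


# ---------------------------------------------------------------------------
# two-treatment comparison


@dataclass
class TTestResult:
    p_value: float
    statistic: float
    significant: bool
    testable: bool = True


def treatment_ttest(
    values: Sequence[float],
    treatment: Sequence[str],
    alpha: float = 0.05,
) -> TTestResult:
    """Two-sided Welch t-test between the two treatment arms of one
    genotype and trait; untestable if either arm has < 2 observations."""
    df = pd.DataFrame({"value": np.asarray(values, float), "trt": list(treatment)})
    arms = [g["value"].to_numpy() for _, g in df.groupby("trt", sort=True)]
    if len(arms) != 2 or min(len(a) for a in arms) < 2:
        return TTestResult(np.nan, np.nan, False, testable=False)
    if np.array_equal(np.sort(arms[0]), np.sort(arms[1])) and arms[0].std() == 0:
        return TTestResult(1.0, 0.0, False)
    res = stats.ttest_ind(arms[0], arms[1], equal_var=False)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return TTestResult(p, float(res.statistic), bool(p < alpha))
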