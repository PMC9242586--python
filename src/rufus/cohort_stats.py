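"""Cohort-level statistics: regional summaries, group comparisons, PCA
correlation, and the body-mass ~ ancestry mixed-model analysis.

Regional summaries (mean, sample SD, min, max) are computed on per-sample
fields such as ancestry proportions, admixture timing in years, or mean
block lengths in Mb; the SD always uses the n-1 denominator. Group contrasts
use Welch's unequal-variance t test. Principal components of a genotype or
dosage matrix are correlated (Pearson) with per-sample ancestry to check
that the leading axis of genetic variation tracks red wolf ancestry; PC
signs are arbitrary, so |r| is reported alongside the signed value.

The morphology analysis regresses body weight (kg) on red wolf ancestry
with sex and age as candidate covariates and the trapping region as a
random intercept, over eight a priori candidate models compared by AIC
(maximum-likelihood fits, so AICs are comparable across fixed-effect
structures). Significance of a fixed effect is judged by its 95% confidence
interval excluding zero. Rounding to table precision happens only at the
reporting layer, never inside computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "summarize_by_group",
    "group_ratio",
    "welch_test",
    "pc_ancestry_correlation",
    "CANDIDATE_MODELS",
    "ModelFit",
    "fit_morphology_models",
    "published_cohort_summary",
]


def summarize_by_group(values, groups) -> pd.DataFrame:
    """n / mean / sample SD / min / max per group for one numeric field.

    ``values`` and ``groups`` are aligned sequences; NaN values are dropped
    (with their group labels). Singleton groups have NaN SD and
    ``sd_defined=False``. Raises when a group label carries no values.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no non-missing values to summarize")
    empty = df.groupby("group")["value"].count() == 0
    if empty.any():
        raise ValueError(f"empty group(s): {list(empty.index[empty])}")
    out = df.groupby("group")["value"].agg(
        n="count", mean="mean", sd=lambda v: v.std(ddof=1),
        min="min", max="max",
    ).reset_index()
    out["sd_defined"] = out["n"] > 1
    return out


def group_ratio(mean_a: float, mean_b: float) -> float:
    """Ratio of two group means (e.g. red wolf vs coyote mean block size)."""
    if mean_b == 0:
        raise ZeroDivisionError("denominator mean is zero")
    if mean_a <= 0 or mean_b < 0:
        raise ValueError("group means must be positive")
    return mean_a / mean_b


def welch_test(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sided t test: (t, df, p).

    Uses the Welch-Satterthwaite degrees of freedom. Each group needs at
    least two observations, and at least one group must have positive
    variance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both groups have zero variance and unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def pc_ancestry_correlation(matrix, ancestry, n_pcs: int = 2) -> pd.DataFrame:
    """Pearson correlation of each leading PC score with per-sample ancestry.

    ``matrix`` is samples x variables (a genotype or dosage ``.values`` array
    or an object exposing one); missing cells are mean-imputed per variable
    before the centered PCA. ``ancestry`` may be per-sample values or each
    sample's group-mean ancestry — both orientations of the published
    correlation are supported by passing the appropriate vector. Returns a
    frame with pc, r, abs_r, and explained variance ratio.
    """
    x = np.asarray(getattr(matrix, "values", matrix), float)
    y = np.asarray(ancestry, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    if len(y) != x.shape[0]:
        raise ValueError("ancestry vector length does not match sample count")
    col_mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_mean, x)
    x = x[:, x.std(axis=0) > 0]
    if np.std(y) == 0:
        raise ValueError("ancestry vector is constant")
    n_pcs = min(n_pcs, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(x - x.mean(axis=0))
    rows = []
    for k in range(n_pcs):
        s = scores[:, k]
        if np.std(s) == 0:
            raise ValueError(f"PC{k + 1} is constant")
        r = float(stats.pearsonr(s, y).statistic)
        rows.append({"pc": k + 1, "r": r, "abs_r": abs(r),
                     "explained_var": float(pca.explained_variance_ratio_[k])})
    return pd.DataFrame(rows)


# The eight a priori candidate fixed-effect structures (response: weight in
# kg; random intercept: trapping region in every model).
CANDIDATE_MODELS: dict[str, tuple[str, ...]] = {
    "intercept": (),
    "auto": ("z_auto",),
    "x": ("z_x",),
    "auto+x": ("z_auto", "z_x"),
    "auto+sex": ("z_auto", "sex"),
    "auto+age": ("z_auto", "age_class"),
    "auto+sex+age": ("z_auto", "sex", "age_class"),
    "x+sex": ("z_x", "sex"),
}

_TERM_TO_FORMULA = {"z_auto": "z_auto", "z_x": "z_x",
                    "sex": "C(sex)", "age_class": "C(age_class)"}


@dataclass
class ModelFit:
    """One candidate model's fit: AIC, fixed effects, and CI table."""

    name: str
    terms: tuple[str, ...]
    formula: str
    aic: float
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    mixed: bool  # False when the random-intercept fit was singular (OLS fallback)
    converged: bool
    group_var: float | None = None  # random-intercept variance (None for OLS)

    def covers(self, coefficient: str, truth: float) -> bool:
        lo, hi = self.conf_int.loc[coefficient]
        return bool(lo <= truth <= hi)


def _fit_one(name: str, terms: tuple[str, ...], data: pd.DataFrame) -> ModelFit:
    rhs = " + ".join(_TERM_TO_FORMULA[t] for t in terms) or "1"
    formula = f"weight_kg ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.mixedlm(formula, data, groups=data["region"]).fit(reml=False)
            # a zero-boundary random-effect variance degenerates the
            # likelihood (non-finite AIC): the model collapses to OLS
            singular = ((not res.converged) or np.isnan(res.bse_fe).any()
                        or not np.isfinite(res.aic))
        except (np.linalg.LinAlgError, ValueError):
            res, singular = None, True
    if not singular:
        fe = res.fe_params.index
        ci = res.conf_int().loc[fe]
        ci.columns = ["lo", "hi"]
        return ModelFit(name, terms, formula, float(res.aic),
                        res.fe_params, res.bse_fe, ci, True, bool(res.converged),
                        float(res.cov_re.iloc[0, 0]))
    ols = smf.ols(formula, data).fit()
    ci = ols.conf_int()
    ci.columns = ["lo", "hi"]
    return ModelFit(name, terms, formula, float(ols.aic),
                    ols.params, ols.bse, ci, False, True, None)


def fit_morphology_models(metadata: pd.DataFrame,
                          ancestry: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, ModelFit]]:
    """Fit the eight candidate weight ~ ancestry mixed models, ranked by AIC.

    ``metadata`` needs sample, region, sex, age_class, weight_kg; ``ancestry``
    needs sample, z_auto, z_x. Rows without weight are dropped; at least 10
    remaining individuals are required. Returns the AIC ranking table (best
    first, with delta-AIC) and the fit for every candidate model. Singular
    random-intercept fits fall back to a fixed-intercept OLS fit with
    ``mixed=False``.
    """
    data = metadata.merge(ancestry[["sample", "z_auto", "z_x"]], on="sample")
    data = data.dropna(subset=["weight_kg"]).reset_index(drop=True)
    if len(data) < 10:
        raise ValueError(f"only {len(data)} individuals with weight; need >= 10")
    fits = {name: _fit_one(name, terms, data)
            for name, terms in CANDIDATE_MODELS.items()}
    table = pd.DataFrame(
        [{"model": f.name, "aic": f.aic, "mixed": f.mixed, "converged": f.converged}
         for f in fits.values()]
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table, fits


# regions pooled as the "significantly lower ancestry" comparison group in
# the published cohort (everything outside Cameron except Calcasieu, whose
# single sample is in neither comparison group)
_NON_CAMERON = ("Jefferson Davis", "Iberville", "East Baton Rouge")


def published_cohort_summary() -> pd.DataFrame:
    """Recompute the headline regional numbers from the bundled cohort tables.

    Every row is one derived quantity: overall and regional ancestry means,
    the Cameron timing mean, northwestern-Cameron block statistics, the red
    wolf / coyote block-size ratios, and the Cameron vs. outer-parish Welch
    comparisons. ``value`` is unrounded; ``value_rounded`` applies the
    table precision (2 decimals for proportions, 1 for years/Mb/ratios).
    Only fixture data enters — no sequence-level inputs are required.
    """
    from .formats_io import load_cohort

    c = load_cohort()
    cameron = c[c["parish"] == "Cameron"]
    outer = c[c["parish"].isin(_NON_CAMERON)]
    nw = c[c["region"] == "Cameron-NW"]
    ne = c[c["region"] == "Cameron-NE"]
    jd = c[c["parish"] == "Jefferson Davis"]

    rows: list[tuple[str, float, int, int]] = []  # name, value, n, decimals

    def add(name, value, n, dec):
        rows.append((name, float(value), int(n), dec))

    add("autosomal_ancestry_mean", c["auto_ancestry"].mean(), len(c), 2)
    add("autosomal_ancestry_sd", c["auto_ancestry"].std(ddof=1), len(c), 1)
    add("x_ancestry_mean", c["x_ancestry"].mean(), len(c), 2)
    add("x_ancestry_sd", c["x_ancestry"].std(ddof=1), len(c), 1)
    add("outer_parish_autosomal_ancestry_mean", outer["auto_ancestry"].mean(), len(outer), 2)
    add("outer_parish_x_ancestry_mean", outer["x_ancestry"].mean(), len(outer), 2)
    add("cameron_autosomal_timing_years", cameron["auto_timing_years"].mean(), len(cameron), 1)
    add("nw_cameron_autosomal_ancestry_mean", nw["auto_ancestry"].mean(), len(nw), 2)
    add("nw_cameron_autosomal_timing_years", nw["auto_timing_years"].mean(), len(nw), 1)
    add("nw_cameron_redwolf_block_mean_mb", nw["redwolf_mb"].mean(), len(nw), 1)
    add("nw_cameron_redwolf_block_sd_mb", nw["redwolf_mb"].std(ddof=1), len(nw), 1)
    add("nw_cameron_block_ratio",
        group_ratio(nw["redwolf_mb"].mean(), nw["coyote_mb"].mean()), len(nw), 1)
    add("ne_cameron_block_ratio",
        group_ratio(ne["redwolf_mb"].mean(), ne["coyote_mb"].mean()), len(ne), 1)
    add("jefferson_davis_redwolf_block_mean_mb", jd["redwolf_mb"].mean(), len(jd), 1)

    _, _, p_auto = welch_test(cameron["auto_ancestry"], outer["auto_ancestry"])
    _, _, p_x = welch_test(cameron["x_ancestry"], outer["x_ancestry"])
    add("welch_p_autosomal_ancestry", p_auto, len(cameron) + len(outer), 8)
    add("welch_p_x_ancestry", p_x, len(cameron) + len(outer), 8)

    df = pd.DataFrame(rows, columns=["quantity", "value", "n", "decimals"])
    df["value_rounded"] = [round(v, d) for v, d in zip(df["value"], df["decimals"])]
    return df.drop(columns="decimals")
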