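"""Home-range-size inference: group comparisons, collinearity screening,
candidate mixed-model fits, and AICc model selection machinery.

Responses are log10 home-range areas. Candidate models are linear
mixed-effects models (identity link) with a per-animal random intercept,
fit by maximum likelihood so AICc is comparable across fixed-effect
structures. The parameter count k follows the convention of the published
candidate tables: intercept = 1, each named term +1 (reproductive status
counts as a single term despite entering as two dummies), a quadratic term
+1, and variance components uncounted; a standard count is available via
``k_convention="standard"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import variance_inflation_factor

log = logging.getLogger(__name__)

RS_LEVELS = ["solitary", "cub-of-year", "cub1plus"]  # solitary = reference


@dataclass
class ModelRecord:
    """One candidate model: terms, parameter count, fit and ranking."""

    terms: tuple
    k: int
    logl: float
    aicc: float
    daicc: float | None = None
    weight: float | None = None
    r2: float | None = None
    coef: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if not self.name:
            self.name = "+".join(self.terms) if self.terms else "null"


@dataclass
class ComparisonResult:
    records: list
    best: ModelRecord
    confidence_set: list
    importance: dict
    averaged_coef: dict
    sign_consistent: bool


def group_compare(
    areas: pd.DataFrame,
    status_col: str = "rs",
    area_col: str = "log10_area",
    age_col: str | None = "age_class",
):
    """Status comparison of log10 home-range areas.

    First a two-sample t-test of solitary subadults vs adults (pooled iff
    P > 0.05, reported either way); then a one-way ANOVA over the three
    reproductive statuses with Tukey HSD pairwise contrasts (Tukey-Kramer on
    unbalanced groups, statsmodels' default).
    """
    out = {}
    if age_col and age_col in areas.columns:
        sol = areas[areas[status_col] == "solitary"]
        sub = sol.loc[sol[age_col] == "subadult", area_col]
        adu = sol.loc[sol[age_col] == "adult", area_col]
        if len(sub) >= 2 and len(adu) >= 2:
            t, p = stats.ttest_ind(sub, adu)
            out["subadult_t"] = float(t)
            out["subadult_p"] = float(p)
            out["pooled"] = bool(p > 0.05)
        else:
            out["pooled"] = True

    groups = [
        areas.loc[areas[status_col] == lev, area_col].to_numpy()
        for lev in RS_LEVELS
        if (areas[status_col] == lev).sum() >= 2
    ]
    if len(groups) < 2:
        raise ValueError("need at least 2 status groups with >= 2 ranges each")
    f, p = stats.f_oneway(*groups)
    out["anova_f"] = float(f)
    out["anova_p"] = float(p)
    out["anova_df"] = (len(groups) - 1, sum(map(len, groups)) - len(groups))
    present = [lev for lev in RS_LEVELS if (areas[status_col] == lev).sum() >= 2]
    mask = areas[status_col].isin(present)
    tukey = pairwise_tukeyhsd(
        areas.loc[mask, area_col].to_numpy(), areas.loc[mask, status_col].to_numpy()
    )
    out["tukey"] = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return out


def collinearity_screen(
    covariates: pd.DataFrame,
    response: pd.Series,
    r_threshold: float = 0.6,
    vif_threshold: float = 10.0,
):
    """Pairwise-correlation screen plus a VIF gate for candidate models.

    Pairs with |Pearson r| >= 0.6 may not co-occur in one model; within a
    pair, the covariate with the stronger univariate association with the
    response (smaller OLS P) is preferred. Constant covariates are excluded
    with a warning. Returns (kept, excluded_pairs, vif_check) where
    ``vif_check(terms)`` tests a candidate's VIFs against the threshold.
    """
    cov = covariates.copy()
    constant = [c for c in cov.columns if cov[c].nunique() <= 1]
    for c in constant:
        log.warning("constant covariate %s excluded", c)
    cov = cov.drop(columns=constant)

    pvals = {}
    for c in cov.columns:
        X = sm.add_constant(cov[c].to_numpy())
        pvals[c] = float(sm.OLS(response.to_numpy(), X).fit().pvalues[1])

    corr = cov.corr()
    excluded_pairs, dropped = [], set()
    cols = list(cov.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if abs(corr.loc[a, b]) >= r_threshold:
                loser = a if pvals[a] > pvals[b] else b
                excluded_pairs.append((a, b, float(corr.loc[a, b]), loser))
                dropped.add(loser)
    kept = [c for c in cols if c not in dropped]

    def vif_check(terms):
        terms = [t for t in terms if t in cov.columns]
        if len(terms) < 2:
            return True, {}
        X = sm.add_constant(cov[terms].to_numpy())
        vifs = {
            t: float(variance_inflation_factor(X, j + 1))
            for j, t in enumerate(terms)
        }
        return all(v <= vif_threshold for v in vifs.values()), vifs

    return kept, excluded_pairs, vif_check


def _design(df: pd.DataFrame, terms: tuple) -> tuple[np.ndarray, list]:
    cols, names = [np.ones(len(df))], ["intercept"]
    for t in terms:
        if t == "rs":
            for lev in RS_LEVELS[1:]:
                cols.append((df["rs"] == lev).to_numpy(float))
                names.append(f"rs[{lev}]")
        elif t.endswith("^2"):
            base = t[:-2]
            cols.append(df[base].to_numpy(float) ** 2)
            names.append(t)
        else:
            cols.append(df[t].to_numpy(float))
            names.append(t)
    return np.column_stack(cols), names


def count_k(terms: tuple, convention: str = "published") -> int:
    """Parameter count: intercept=1, +1 per named term (status counts once)."""
    if convention == "published":
        return 1 + len(terms)
    k = 1 + sum(2 if t == "rs" else 1 for t in terms)
    return k + 1  # + residual variance (standard count)


def aicc(logl: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError("n - k - 1 <= 0; model rejected")
    return -2.0 * logl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def fit_one(
    df: pd.DataFrame,
    terms: tuple,
    response: str = "log10_area",
    group: str = "animal_id",
    k_convention: str = "published",
) -> ModelRecord:
    """ML fit of one candidate with a per-animal random intercept.

    When no animal contributes more than one range the random-intercept
    variance is unidentifiable (confounded with the residual), so the model
    collapses to its sigma_b = 0 boundary and is fit by OLS; the same
    fallback applies if the mixed optimizer fails numerically. R^2 is the
    squared correlation between fitted (fixed-effects) and observed
    responses, 0 by definition for the null model.
    """
    X, names = _design(df, terms)
    y = df[response].to_numpy(float)
    groups = df[group].to_numpy()
    singleton = pd.Series(groups).value_counts().max() <= 1
    fe_params = None
    if not singleton:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.MixedLM(y, X, groups=groups).fit(
                    reml=False, method="bfgs", maxiter=200
                )
                logl, fe_params = float(fit.llf), fit.fe_params
            except np.linalg.LinAlgError:
                log.warning(
                    "mixed fit failed for %s; OLS fallback", "+".join(terms) or "null"
                )
    if fe_params is None:
        ols = sm.OLS(y, X).fit()
        logl, fe_params = float(ols.llf), ols.params
    fitted = X @ fe_params
    if np.std(fitted) > 0 and len(terms) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    k = count_k(terms, k_convention)
    return ModelRecord(
        terms=tuple(terms),
        k=k,
        logl=logl,
        aicc=aicc(logl, k, len(y)),
        r2=r2,
        coef=dict(zip(names, map(float, fe_params))),
    )


def fit_candidates(
    df: pd.DataFrame,
    candidate_sets: list,
    response: str = "log10_area",
    group: str = "animal_id",
    k_convention: str = "published",
) -> list[ModelRecord]:
    """Fit every candidate term list and rank by AICc (delta and weights)."""
    records = []
    for terms in candidate_sets:
        try:
            records.append(
                fit_one(df, tuple(terms), response, group, k_convention)
            )
        except ValueError as err:
            log.warning("model %s rejected: %s", "+".join(terms) or "null", err)
    deltas, weights = akaike_weights([r.aicc for r in records])
    for r, d, w in zip(records, deltas, weights):
        r.daicc, r.weight = float(d), float(w)
    records.sort(key=lambda r: r.aicc)
    return records


def akaike_weights(aicc_values) -> tuple[np.ndarray, np.ndarray]:
    """Delta AICc and Akaike weights w_i = exp(-d_i/2) / sum exp(-d_j/2)."""
    a = np.asarray(aicc_values, float)
    if len(a) == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def confidence_set(records: list) -> list:
    """Models whose Akaike weight is within 10% of the best model's weight."""
    w_best = max(r.weight for r in records)
    return [r for r in records if r.weight >= 0.10 * w_best]


def importance_weights(conf_set: list, terms=None) -> dict:
    """Per-term importance: summed weights of set members containing the term."""
    if terms is None:
        terms = sorted({t for r in conf_set for t in r.terms})
    return {
        t: float(sum(r.weight for r in conf_set if t in r.terms)) for t in terms
    }


def plausibility_ratio(importance: dict, term_a: str, term_b: str) -> float:
    """importance(A) / importance(B): how much more plausible term A is."""
    if importance.get(term_b, 0.0) == 0.0:
        raise ZeroDivisionError(f"term {term_b} has zero importance")
    return importance[term_a] / importance[term_b]


def model_average(conf_set: list, best: ModelRecord | None = None) -> ComparisonResult:
    """Conditional model averaging over the confidence set.

    Each coefficient is averaged with weights renormalized over the set
    members containing it; the sign-consistency report compares the averaged
    coefficients to the best model's.
    """
    best = best or min(conf_set, key=lambda r: r.aicc)
    names = sorted({c for r in conf_set for c in r.coef})
    averaged = {}
    for c in names:
        members = [r for r in conf_set if c in r.coef]
        wsum = sum(r.weight for r in members)
        averaged[c] = sum(r.weight * r.coef[c] for r in members) / wsum
    sign_ok = all(
        np.sign(averaged[c]) == np.sign(best.coef[c])
        for c in best.coef
        if best.coef[c] != 0
    )
    return ComparisonResult(
        records=conf_set,
        best=best,
        confidence_set=conf_set,
        importance=importance_weights(conf_set),
        averaged_coef=averaged,
        sign_consistent=bool(sign_ok),
    )


def random_effect_check(
    df: pd.DataFrame,
    terms: tuple,
    response: str = "log10_area",
    group: str = "animal_id",
) -> dict:
    """Likelihood-ratio test of the random-intercept variance being zero.

    Uses the boundary-corrected 0.5*chi2_0 + 0.5*chi2_1 mixture reference.
    Skipped (with a note) when no animal contributes more than one range.
    """
    counts = df[group].value_counts()
    if (counts <= 1).all():
        return {"status": "skipped", "note": "no repeated animals"}
    X, _ = _design(df, terms)
    y = df[response].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = sm.MixedLM(y, X, groups=df[group].to_numpy()).fit(
            reml=False, method="bfgs", maxiter=200
        )
        ols = sm.OLS(y, X).fit()
    lrt = max(2.0 * (mixed.llf - ols.llf), 0.0)
    p = 0.5 * stats.chi2.sf(lrt, 1) + (0.5 if lrt == 0 else 0.0)
    var = float(np.asarray(mixed.cov_re)[0, 0])
    return {"status": "ok", "variance": var, "lrt": float(lrt), "p": float(p)}


def polynomial_check(
    df: pd.DataFrame,
    best: ModelRecord,
    lsi_terms=("s1lsi", "s2lsi", "s3lsi", "wlsi"),
    response: str = "log10_area",
    group: str = "animal_id",
    k_convention: str = "published",
) -> list:
    """Add the quadratic of each shape index in the best model and refit."""
    extra = []
    for t in best.terms:
        if t in lsi_terms:
            terms = tuple(best.terms) + (f"{t}^2",)
            extra.append(fit_one(df, terms, response, group, k_convention))
    return extra


def records_table(records: list) -> pd.DataFrame:
    """Candidate-model table mirroring the published layout."""
    return pd.DataFrame(
        [
            {
                "model": r.name, "k": r.k, "AICc": r.aicc,
                "dAICc": r.daicc, "w": r.weight, "R2": r.r2,
            }
            for r in records
        ]
    )
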