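"""Evaluation of linkage results: confusion counts, the four accuracy
indices, linkage-bias regression and distribution comparisons.

Sensitivity (the share of true matches the algorithm finds) and PPV (the
share of produced links that are true) are the primary indices; with a
candidate-pair universe the true-negative-based indices (specificity,
NPV) are computed too, though with millions of easy non-matches they are
close to 1 by construction and rarely informative.  Linkage bias is
assessed two ways: a multivariable logistic regression of match success
on background characteristics, and Pearson chi-squared comparisons of
the covariate distributions in the full gold-standard dataset versus the
linked subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from .records import GoldStandard

#: Reference category per covariate in the bias regression.
REFERENCE_CATEGORIES = {
    "sex": "F",
    "age_group": "18-34",
    "ethnicity": "Other",
    "residence": "Permanent",
    "education": "None",
    "employment": "Not working",
    "wealth_quintile": 1,
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def _extract_links(result) -> set:
    if hasattr(result, "links"):
        return set(result.links)
    return set(result)


def confusion(result, gold: GoldStandard,
              universe: Iterable[tuple]) -> ConfusionCounts:
    """Four-way classification of a pair universe.

    ``result`` may be a LinkageResult or a plain set of pairs.  Links
    outside the universe are flagged with a warning and counted as false
    positives.
    """
    links = _extract_links(result)
    universe = set(universe)
    gold_pairs = set(gold.pairs)
    if not gold_pairs <= universe:
        raise ValueError("gold-standard pairs must lie inside the universe")
    outside = links - universe
    if outside:
        warnings.warn(f"{len(outside)} link(s) outside the evaluation "
                      "universe; counted as false positives")
    tp = len(links & gold_pairs)
    fp = len(links - gold_pairs)
    fn = len(gold_pairs - links)
    tn = len(universe) - tp - (len(links & universe) - tp) - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, PPV, NPV; zero denominators give None."""
    def ratio(num, den):
        return None if den == 0 else num / den

    return Metrics(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        ppv=ratio(c.tp, c.tp + c.fp),
        npv=ratio(c.tn, c.tn + c.fn),
    )


def sensitivity_ppv(links: set, gold: GoldStandard) -> tuple[float, float]:
    """Sensitivity and PPV without a pair universe (the usual report)."""
    links = _extract_links(links)
    gold_pairs = set(gold.pairs)
    tp = len(links & gold_pairs)
    sens = tp / len(gold_pairs) if gold_pairs else float("nan")
    ppv = tp / len(links) if links else float("nan")
    return sens, ppv


# ---------------------------------------------------------------------------
# bias regression

def _design_matrix(table: pd.DataFrame,
                   covariates: Iterable[str]) -> tuple[pd.DataFrame, list]:
    cols = {}
    labels = []
    for cov in covariates:
        values = table[cov]
        uniq = list(pd.unique(values.dropna()))
        try:
            uniq = sorted(uniq)
        except TypeError:
            uniq = sorted(uniq, key=str)
        ref = REFERENCE_CATEGORIES.get(cov)
        if ref not in uniq:
            ref = uniq[0]
        levels = [lv for lv in uniq if lv != ref]
        for lv in levels:
            name = f"{cov}[{lv}]"
            cols[name] = (values == lv).astype(float)
            labels.append(name)
    X = pd.DataFrame(cols, index=table.index)
    return X, labels


def bias_regression(table: pd.DataFrame,
                    outcome: str = "matched_strict",
                    covariates: Optional[Iterable[str]] = None) -> dict:
    """Multivariable logistic regression of match success on covariates.

    Returns odds ratios with Wald 95% CIs per non-reference category,
    McFadden pseudo-R-squared, and an overall Wald chi-squared test that
    all slope coefficients are zero.  Covariates with a single observed
    level, or causing complete separation, are dropped with a warning.
    """
    if covariates is None:
        covariates = [c for c in REFERENCE_CATEGORIES if c in table.columns]
    covariates = list(covariates)
    y = table[outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; model is undefined")
    usable = []
    for cov in covariates:
        if table[cov].nunique() < 2:
            warnings.warn(f"covariate {cov!r} has fewer than 2 levels; dropped")
        else:
            usable.append(cov)

    while True:
        X, labels = _design_matrix(table, usable)
        X = sm.add_constant(X, has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not np.all(np.isfinite(fit.bse)):
                raise np.linalg.LinAlgError("non-finite standard errors")
            break
        except (np.linalg.LinAlgError, Exception) as exc:  # separation etc.
            if len(usable) <= 1:
                raise ValueError("logistic model could not be fit") from exc
            # drop the covariate whose categories most perfectly predict
            # the outcome, then retry
            worst, worst_sep = usable[0], -1.0
            for cov in usable:
                sep = (table.groupby(cov)[outcome].mean()
                       .sub(0.5).abs().max())
                if sep > worst_sep:
                    worst, worst_sep = cov, sep
            usable.remove(worst)
            warnings.warn(f"covariate {worst!r} dropped (separation)")

    params = fit.params.drop("const")
    se = fit.bse.drop("const")
    or_table = pd.DataFrame({
        "term": params.index,
        "odds_ratio": np.exp(params.values),
        "ci_low": np.exp(params.values - 1.959963984540054 * se.values),
        "ci_high": np.exp(params.values + 1.959963984540054 * se.values),
        "p_value": fit.pvalues.drop("const").values,
    }).reset_index(drop=True)

    pseudo_r2 = 1.0 - fit.llf / fit.llnull
    slope_idx = [i for i, name in enumerate(fit.params.index)
                 if name != "const"]
    b = fit.params.values[slope_idx]
    cov_bb = fit.cov_params().values[np.ix_(slope_idx, slope_idx)]
    wald_chi2 = float(b @ np.linalg.solve(cov_bb, b))
    from scipy.stats import chi2 as chi2_dist
    wald_p = float(chi2_dist.sf(wald_chi2, df=len(slope_idx)))

    return {
        "odds_ratios": or_table,
        "pseudo_r2": float(pseudo_r2),
        "wald_chi2": wald_chi2,
        "wald_df": len(slope_idx),
        "wald_p": wald_p,
        "n": int(len(table)),
        "covariates_used": usable,
        "model": fit,
    }


# ---------------------------------------------------------------------------
# distribution comparison

CountVector = Union[Mapping, pd.Series]


def chi_square_counts(gold_counts: CountVector,
                      matched_counts: CountVector) -> tuple[float, int, float]:
    """Pearson chi-squared on a k x 2 table of category counts.

    The two columns (full gold-standard dataset vs. linked subset) are
    treated as independent samples; no continuity correction.  Categories
    empty in both columns are dropped with a warning.
    """
    g = pd.Series(gold_counts, dtype=float)
    m = pd.Series(matched_counts, dtype=float)
    if set(g.index) != set(m.index):
        raise ValueError("category sets differ between the two columns")
    m = m.reindex(g.index)
    empty = (g == 0) & (m == 0)
    if empty.any():
        warnings.warn(f"dropping empty categories: {list(g.index[empty])}")
        g, m = g[~empty], m[~empty]
    if len(g) < 2:
        raise ValueError("need at least 2 non-empty categories")
    table = np.column_stack([g.values, m.values])
    chi2, p, df, _ = chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def compare_distributions(gold_counts: Mapping[str, CountVector],
                          matched_counts: Mapping[str, CountVector]
                          ) -> pd.DataFrame:
    """Per-variable chi-squared comparison of category-count vectors."""
    rows = []
    for var in gold_counts:
        chi2, df, p = chi_square_counts(gold_counts[var], matched_counts[var])
        rows.append({"variable": var, "chi2": chi2, "df": df, "p_value": p})
    return pd.DataFrame(rows, columns=["variable", "chi2", "df", "p_value"])


def covariate_count_tables(table: pd.DataFrame,
                           outcome: str = "matched_any"
                           ) -> tuple[dict, dict]:
    """Category counts for the full gold table and its matched subset."""
    gold_counts, matched_counts = {}, {}
    matched = table[table[outcome] == 1]
    for cov in REFERENCE_CATEGORIES:
        if cov not in table.columns:
            continue
        g = table[cov].value_counts()
        m = matched[cov].value_counts().reindex(g.index, fill_value=0)
        gold_counts[cov] = g
        matched_counts[cov] = m
    return gold_counts, matched_counts
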