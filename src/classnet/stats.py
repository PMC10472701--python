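"""Sex-stratified descriptives, OLS associations, effect sizes and screening.

The analysis stage mirrors a conventional observational workflow: descriptive
comparisons by sex (Student's t for continuous variables, Pearson chi-square
without continuity correction for categoricals), one simple ("bivariate")
linear regression of academic performance per predictor, Cohen's
f^2 = R^2/(1-R^2) as the effect size, purposeful predictor screening at
p < 0.25 (the Hosmer-Lemeshow criterion), and one multivariate OLS per sex
with the screened predictors entered jointly.

Listwise deletion is applied per model, so bivariate and multivariate sample
sizes may differ; every result reports ``n_used``. Standard errors ignore
classroom clustering by design; cluster-robust errors are available via
``cov_type="cluster"`` for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigError, DegenerateInputError

logger = logging.getLogger(__name__)

DEFAULT_REFERENCES = {"location": "rural", "family_structure": "other"}
F2_CAP = 1e6  # sentinel when R^2 == 1 (perfect fit)


@dataclass(frozen=True)
class RegressionResult:
    stratum: str
    predictor: str
    level: str | None
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    f2: float
    n_used: int
    model_tag: str

    def __post_init__(self):
        if not np.isnan(self.beta) and not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("confidence interval must bracket beta")


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum,
                "predictor": r.predictor,
                "level": r.level,
                "beta": r.beta,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "f2": r.f2,
                "n_used": r.n_used,
                "model_tag": r.model_tag,
            }
            for r in results
        ]
    )


def cohens_f2(r2_full: float, r2_reduced: float = 0.0) -> float:
    """Cohen's effect size f^2 = (R2_full - R2_reduced) / (1 - R2_full)."""
    if not 0.0 <= r2_reduced <= r2_full <= 1.0:
        raise ValueError("need 0 <= r2_reduced <= r2_full <= 1")
    if r2_full >= 1.0 - 1e-12:
        return F2_CAP
    return (r2_full - r2_reduced) / (1.0 - r2_full)


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def describe_by_sex(
    df: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-sex summaries with a t-test / chi-square comparison per variable.

    Returns a tidy frame with formatted ``girls`` / ``boys`` summaries
    ("mean (SD)" or "n (%)") and the numeric p-value of the sex comparison.
    """
    if "sex" not in df.columns:
        raise ConfigError("describe_by_sex: table lacks a 'sex' column")
    girls = df[df["sex"] == "girl"]
    boys = df[df["sex"] == "boy"]
    rows = []
    for var in continuous:
        g = girls[var].dropna()
        b = boys[var].dropna()
        if len(g) < 2 or len(b) < 2:
            logger.warning("describe_by_sex: stratum with n<2 for %s; p missing", var)
            p = np.nan
        else:
            p = float(sps.ttest_ind(g, b, equal_var=equal_var).pvalue)
        rows.append(
            {
                "variable": var,
                "level": None,
                "girls": f"{g.mean():.2f} ({g.std(ddof=1):.2f})" if len(g) else "",
                "boys": f"{b.mean():.2f} ({b.std(ddof=1):.2f})" if len(b) else "",
                "p_value": p,
                "test": "t",
            }
        )
    for var in categorical:
        table = pd.crosstab(df[var], df["sex"])
        for sex_level in ("girl", "boy"):
            if sex_level not in table.columns:
                table[sex_level] = 0
        table = table[["girl", "boy"]]
        if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
            p = np.nan
        else:
            chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
            p = float(p)
        totals = table.sum(axis=0)
        for level, row in table.iterrows():
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    "girls": f"{row['girl']} ({100 * row['girl'] / max(totals['girl'], 1):.1f})",
                    "boys": f"{row['boy']} ({100 * row['boy'] / max(totals['boy'], 1):.1f})",
                    "p_value": p,
                    "test": "chi-square",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Regression models
# ---------------------------------------------------------------------------

def _expand_predictor(
    df: pd.DataFrame, var: str, references: dict[str, str]
) -> pd.DataFrame:
    """Design columns for one predictor; categoricals become indicator contrasts."""
    col = df[var]
    is_categorical = var in references or col.dtype == object or str(col.dtype) == "category"
    if not is_categorical:
        return col.astype(float).to_frame(var)
    ref = references.get(var)
    levels = [lv for lv in pd.unique(col.dropna())]
    if ref is None or ref not in set(map(str, levels)):
        fallback = sorted(map(str, levels))[0]
        if ref is not None:
            logger.warning(
                "reference level %r absent from %r in this sample; using %r",
                ref, var, fallback,
            )
        ref = fallback
    out = {}
    for lv in sorted(map(str, levels)):
        if lv == ref:
            continue
        out[f"{var}[{lv}]"] = (col.astype(str) == lv).astype(float)
    design = pd.DataFrame(out, index=df.index)
    design[col.isna()] = np.nan
    return design


def _split_name(column: str) -> tuple[str, str | None]:
    if column.endswith("]") and "[" in column:
        var, level = column[:-1].split("[", 1)
        return var, level
    return column, None


def _fit_ols(y: pd.Series, design: pd.DataFrame, cov_type: str = "nonrobust", groups=None):
    X = sm.add_constant(design, has_constant="add")
    if cov_type == "cluster":
        model = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        model = sm.OLS(y, X).fit()
    return model


def bivariate_scan(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    stratum: str,
    references: dict[str, str] | None = None,
    cov_type: str = "nonrobust",
    cluster_col: str | None = None,
) -> list[RegressionResult]:
    """One simple OLS of ``outcome`` per predictor, with listwise deletion.

    Categorical predictors expand to indicator contrasts against their
    reference level and yield one result row per non-reference level, all
    sharing the simple model's f^2. Constant predictors are skipped with a
    warning.
    """
    references = DEFAULT_REFERENCES if references is None else references
    results: list[RegressionResult] = []
    for var in predictors:
        design = _expand_predictor(df, var, references)
        frame = pd.concat([df[outcome].astype(float), design], axis=1).dropna()
        if cluster_col is not None:
            frame = frame.join(df[cluster_col]).dropna()
        y = frame[outcome]
        X = frame[design.columns]
        if len(frame) < X.shape[1] + 2 or any(X[c].nunique() < 2 for c in X.columns):
            logger.warning("bivariate_scan: %s constant or too few cases; skipped", var)
            continue
        model = _fit_ols(
            y, X, cov_type=cov_type,
            groups=frame[cluster_col] if cluster_col else None,
        )
        r2 = model.rsquared
        f2 = cohens_f2(min(max(r2, 0.0), 1.0))
        if f2 == F2_CAP:
            logger.warning("bivariate_scan: %s gives a perfect fit; f2 capped at %g", var, F2_CAP)
        ci = model.conf_int(alpha=0.05)
        for colname in X.columns:
            name, level = _split_name(colname)
            results.append(
                RegressionResult(
                    stratum=stratum,
                    predictor=name,
                    level=level,
                    beta=float(model.params[colname]),
                    ci_low=float(ci.loc[colname, 0]),
                    ci_high=float(ci.loc[colname, 1]),
                    p_value=float(model.pvalues[colname]),
                    f2=f2,
                    n_used=int(model.nobs),
                    model_tag="bivariate",
                )
            )
    return results


def screen_predictors(
    results: list[RegressionResult], alpha: float = 0.25
) -> list[str]:
    """Predictors with any level's bivariate p strictly below ``alpha``.

    Multi-level categoricals enter or leave whole. Preserves first-seen
    order. Raises on an empty candidate list.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("screening alpha must be in (0, 1)")
    if not results:
        raise ConfigError("screen_predictors: empty bivariate results")
    order: list[str] = []
    keep: set[str] = set()
    for r in results:
        if r.predictor not in order:
            order.append(r.predictor)
        if not np.isnan(r.p_value) and r.p_value < alpha:
            keep.add(r.predictor)
    return [p for p in order if p in keep]


def multivariate_model(
    df: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    stratum: str,
    references: dict[str, str] | None = None,
    cov_type: str = "nonrobust",
    cluster_col: str | None = None,
) -> tuple[list[RegressionResult], float]:
    """Joint OLS with all screened predictors; returns rows plus model f^2.

    Every result row carries the model-level f^2 (one effect size per
    multivariate model). Raises if the design is rank-deficient, naming the
    collinear columns.
    """
    if not predictors:
        raise ConfigError("multivariate_model: empty predictor list")
    references = DEFAULT_REFERENCES if references is None else references
    designs = [_expand_predictor(df, var, references) for var in predictors]
    design = pd.concat(designs, axis=1)
    cols = [df[outcome].astype(float), design]
    if cluster_col is not None:
        cols.append(df[cluster_col])
    frame = pd.concat(cols, axis=1).dropna()
    if len(frame) <= design.shape[1] + 2:
        raise DegenerateInputError(
            f"multivariate_model: only {len(frame)} complete cases for "
            f"{design.shape[1]} predictors in stratum {stratum}"
        )
    y = frame[outcome]
    X = frame[design.columns]
    _check_rank(X)
    model = _fit_ols(
        y, X, cov_type=cov_type, groups=frame[cluster_col] if cluster_col else None
    )
    f2 = cohens_f2(min(max(model.rsquared, 0.0), 1.0))
    ci = model.conf_int(alpha=0.05)
    results = []
    for colname in X.columns:
        name, level = _split_name(colname)
        results.append(
            RegressionResult(
                stratum=stratum,
                predictor=name,
                level=level,
                beta=float(model.params[colname]),
                ci_low=float(ci.loc[colname, 0]),
                ci_high=float(ci.loc[colname, 1]),
                p_value=float(model.pvalues[colname]),
                f2=f2,
                n_used=int(model.nobs),
                model_tag="multivariate",
            )
        )
    return results, f2


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank >= arr.shape[1]:
        return
    # identify offending columns via the R diagonal of a QR factorization
    _, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    bad = [X.columns[i - 1] for i in range(1, arr.shape[1]) if diag[i] < tol]
    raise DegenerateInputError(f"rank-deficient design; collinear columns: {bad}")
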