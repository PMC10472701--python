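"""Two-step normalization of skewed variables and the KS normality check.

The two-step approach first replaces each value by its fractional rank
``r / (n + 1)`` (mean ranks for ties, n = non-missing count) and then maps
that rank through the inverse standard-normal CDF, rescaling the result to a
target mean and SD (by default the input's own moments). The output is a
monotone transform of the input: order is preserved exactly, ties map to
equal outputs, and a second application changes nothing beyond moment
matching because the ranks are unchanged.

Normality is assessed with the one-sample Kolmogorov-Smirnov statistic
against a normal with the sample's own mean and SD (Lilliefors plug-in, the
convention SPSS uses for its K-S test with estimated parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.diagnostic import lilliefors

from .errors import DegenerateInputError

MIN_KS_N = 8


@dataclass(frozen=True)
class TransformSpec:
    """Target moments for one variable; ``None`` preserves the input's."""

    variable: str
    target_mean: float | None = None
    target_sd: float | None = None

    def validate(self) -> None:
        if self.target_sd is not None and self.target_sd <= 0:
            raise ValueError("target_sd must be > 0")


def ks_normality(values) -> tuple[float, float]:
    """Lilliefors-style KS statistic and p-value; needs >= 8 non-missing values."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < MIN_KS_N:
        raise DegenerateInputError(
            f"ks_normality needs >= {MIN_KS_N} non-missing values, got {x.size}"
        )
    if np.ptp(x) == 0:
        raise DegenerateInputError("ks_normality: all values identical")
    stat, pvalue = lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(pvalue)


def two_step_transform(
    values, spec: TransformSpec | None = None
) -> np.ndarray:
    """Fractional rank -> inverse normal -> rescale to target moments.

    Missing values are excluded from ranking and reinserted as NaN. Requires
    at least two distinct non-missing values. The sample SD uses ddof=1.
    """
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    obs = x[mask]
    if np.unique(obs).size < 2:
        raise DegenerateInputError(
            "two_step_transform needs at least 2 distinct non-missing values"
        )
    if spec is not None:
        spec.validate()
    target_mean = spec.target_mean if spec and spec.target_mean is not None else obs.mean()
    target_sd = spec.target_sd if spec and spec.target_sd is not None else obs.std(ddof=1)

    ranks = rankdata(obs, method="average")
    z = norm.ppf(ranks / (obs.size + 1))
    z = (z - z.mean()) / z.std(ddof=1)
    out = np.full_like(x, np.nan)
    out[mask] = target_mean + target_sd * z
    return out


def transform_table(
    df: pd.DataFrame, variables: list[str], suffix: str = "_t"
) -> pd.DataFrame:
    """Add a two-step-transformed column ``<var><suffix>`` per variable.

    The transform is fit on the whole table (pooled across classrooms and
    sexes), mirroring a single pooled normalization step before any
    stratified modelling.
    """
    out = df.copy()
    for var in variables:
        if var not in df.columns:
            raise KeyError(f"variable {var!r} not in table")
        out[var + suffix] = two_step_transform(df[var].to_numpy())
    return out
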