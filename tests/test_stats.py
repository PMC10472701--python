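"""Tests for descriptives, OLS scans, effect sizes and predictor screening."""

import numpy as np
import pandas as pd
import pytest

from classnet.errors import ConfigError, DegenerateInputError
from classnet.stats import (
    F2_CAP,
    RegressionResult,
    bivariate_scan,
    cohens_f2,
    describe_by_sex,
    multivariate_model,
    screen_predictors,
)


def make_result(predictor, p, stratum="girls", **kw):
    defaults = dict(
        level=None, beta=0.1, ci_low=0.0, ci_high=0.2, p_value=p,
        f2=0.01, n_used=100, model_tag="bivariate",
    )
    defaults.update(kw)
    return RegressionResult(stratum=stratum, predictor=predictor, **defaults)


# ---------------------------------------------------------------- effect size

def test_cohens_f2_closed_form_grid():
    for r2 in np.linspace(0.0, 0.95, 40):
        assert cohens_f2(r2) == pytest.approx(r2 / (1 - r2), abs=1e-12)
    assert cohens_f2(0.0) == 0.0
    assert cohens_f2(0.5) == pytest.approx(1.0, abs=1e-12)
    assert cohens_f2(0.4 / 1.4) == pytest.approx(0.40, abs=1e-12)  # invert f2=R2/(1-R2)
    assert cohens_f2(0.6, r2_reduced=0.2) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        cohens_f2(0.2, r2_reduced=0.5)


# ---------------------------------------------------------------- descriptives

def test_identical_strata_give_p_one():
    values = list(range(10))
    df = pd.DataFrame(
        {"sex": ["girl"] * 10 + ["boy"] * 10, "score": values + values}
    )
    out = describe_by_sex(df, continuous=["score"], categorical=[])
    assert out.loc[0, "p_value"] == pytest.approx(1.0)
    assert out.loc[0, "test"] == "t"


def test_equal_proportions_chi_square_p_one():
    df = pd.DataFrame(
        {
            "sex": ["girl"] * 100 + ["boy"] * 100,
            "group": (["a"] * 30 + ["b"] * 70) * 2,
        }
    )
    out = describe_by_sex(df, continuous=[], categorical=["group"])
    assert np.allclose(out["p_value"], 1.0)
    assert set(out["test"]) == {"chi-square"}
    assert out.loc[0, "girls"] == "30 (30.0)"


def test_tiny_stratum_p_missing(caplog):
    df = pd.DataFrame({"sex": ["girl", "boy", "boy"], "score": [1.0, 2.0, 3.0]})
    out = describe_by_sex(df, continuous=["score"], categorical=[])
    assert np.isnan(out.loc[0, "p_value"])


def test_t_test_power_matches_noncentral_t():
    """Empirical rejection rate under a 0.2-SD shift tracks closed-form power."""
    from scipy.stats import nct, t as t_dist

    n = 400  # per stratum
    delta = 0.2
    ncp = delta / np.sqrt(1 / n + 1 / n)
    crit = t_dist.ppf(0.975, 2 * n - 2)
    power = 1 - nct.cdf(crit, 2 * n - 2, ncp) + nct.cdf(-crit, 2 * n - 2, ncp)
    rng = np.random.default_rng(21)
    reps, rej = 400, 0
    for _ in range(reps):
        df = pd.DataFrame(
            {
                "sex": ["girl"] * n + ["boy"] * n,
                "ap": np.concatenate([rng.normal(delta, 1, n), rng.normal(0, 1, n)]),
            }
        )
        out = describe_by_sex(df, continuous=["ap"], categorical=[])
        rej += out.loc[0, "p_value"] < 0.05
    se = np.sqrt(power * (1 - power) / reps)
    assert abs(rej / reps - power) < 4 * se


# ---------------------------------------------------------------- regressions

def test_ols_matches_normal_equations():
    df = pd.DataFrame(
        {"y": [1.0, 2.0, 2.5, 3.9, 5.1, 4.2], "x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]}
    )
    res = bivariate_scan(df, "y", ["x"], stratum="girls")[0]
    X = np.column_stack([np.ones(6), df["x"]])
    beta = np.linalg.solve(X.T @ X, X.T @ df["y"])
    assert res.beta == pytest.approx(beta[1], abs=1e-9)
    assert res.n_used == 6


def test_categorical_expansion_with_reference():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {
            "y": rng.normal(size=90),
            "family_structure": ["nuclear", "single_parent", "other"] * 30,
        }
    )
    res = bivariate_scan(df, "y", ["family_structure"], stratum="boys")
    levels = {r.level for r in res}
    assert levels == {"nuclear", "single_parent"}  # 'other' is the reference
    assert all(r.predictor == "family_structure" for r in res)
    assert len({r.f2 for r in res}) == 1  # one simple model, one f2


def test_perfect_fit_hits_sentinel():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0]})
    df["x"] = df["y"]
    res = bivariate_scan(df, "y", ["x"], stratum="girls")[0]
    assert res.beta == pytest.approx(1.0)
    assert res.f2 == F2_CAP


def test_constant_predictor_skipped(caplog):
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0], "x": [5.0] * 4})
    assert bivariate_scan(df, "y", ["x"], stratum="girls") == []


def test_ci_coverage_under_null():
    """95% CI for an unrelated predictor covers zero ~95% of the time."""
    rng = np.random.default_rng(17)
    n, reps, covered = 400, 500, 0
    for _ in range(reps):
        df = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        r = bivariate_scan(df, "y", ["x"], stratum="girls")[0]
        covered += r.ci_low <= 0.0 <= r.ci_high
    assert abs(covered / reps - 0.95) < 0.03


def test_orthogonal_predictors_bivariate_equals_multivariate():
    n = 64
    t = np.arange(n)
    x1 = np.cos(2 * np.pi * t / n)
    x2 = np.sin(2 * np.pi * t / n)  # exactly orthogonal to x1 and to the constant
    y = 1.0 + 2.0 * x1 - 3.0 * x2
    df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    bi = {r.predictor: r.beta for r in bivariate_scan(df, "y", ["x1", "x2"], "girls")}
    multi, _ = multivariate_model(df, "y", ["x1", "x2"], "girls")
    for r in multi:
        assert r.beta == pytest.approx(bi[r.predictor], abs=1e-9)


def test_duplicated_predictor_raises_named_rank_error():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"y": rng.normal(size=30), "x1": rng.normal(size=30)})
    df["x2"] = df["x1"]
    with pytest.raises(DegenerateInputError, match="x2"):
        multivariate_model(df, "y", ["x1", "x2"], "girls")


def test_multivariate_needs_enough_cases():
    df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [0.1, 0.4, 0.2]})
    with pytest.raises(DegenerateInputError):
        multivariate_model(df, "y", ["x"], "girls")


def test_f2_affine_invariance():
    rng = np.random.default_rng(9)
    df = pd.DataFrame({"y": rng.normal(size=200), "x": rng.normal(size=200)})
    df["y"] += 0.4 * df["x"]
    _, f2 = multivariate_model(df, "y", ["x"], "girls")
    scaled = pd.DataFrame({"y": 3.0 * df["y"] - 7.0, "x": -0.5 * df["x"] + 2.0})
    _, f2_scaled = multivariate_model(scaled, "y", ["x"], "girls")
    assert f2_scaled == pytest.approx(f2, abs=1e-9)


def test_listwise_deletion_counts():
    df = pd.DataFrame(
        {
            "y": [1.0, 2.0, 3.0, 4.0, np.nan, 6.0, 2.5, 3.5],
            "x": [0.1, np.nan, 0.3, 0.4, 0.5, 0.6, 0.2, 0.8],
        }
    )
    r = bivariate_scan(df, "y", ["x"], "girls")[0]
    assert r.n_used == 6  # two rows lost to missingness


# ---------------------------------------------------------------- screening

def test_screening_threshold_semantics():
    results = [make_result("a", 0.01), make_result("b", 0.24), make_result("c", 0.26)]
    assert screen_predictors(results) == ["a", "b"]
    assert screen_predictors([make_result(p, 0.5) for p in "abc"]) == []
    with pytest.raises(ConfigError):
        screen_predictors([])
    # boundary: strictly-less-than
    assert screen_predictors([make_result("edge", 0.25)]) == []


def test_multilevel_categorical_enters_whole():
    results = [
        make_result("family_structure", 0.6, level="nuclear"),
        make_result("family_structure", 0.1, level="single_parent"),
        make_result("age", 0.9),
    ]
    assert screen_predictors(results) == ["family_structure"]


def test_screening_retention_under_global_null():
    """Each null predictor should be retained with frequency ~ alpha."""
    rng = np.random.default_rng(30)
    n, reps = 300, 300
    retained = 0
    for _ in range(reps):
        df = pd.DataFrame({"y": rng.normal(size=n), "x": rng.normal(size=n)})
        res = bivariate_scan(df, "y", ["x"], "girls")
        retained += "x" in screen_predictors(res, alpha=0.25)
    assert abs(retained / reps - 0.25) < 0.075  # 3 binomial SEs
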