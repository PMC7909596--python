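"""Comparison statistics: frozen closed-form oracles, degenerate-input
conventions, invariances, and agreement with reference implementations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anthroscan.errors import RegressionError, SampleSizeError
from anthroscan.stats import (
    PairedSample,
    bland_altman,
    compare_methods,
    delta_means,
    paired_ttest,
    read_pairs_csv,
    regression_eval,
    rmsd,
    samples_from_frame,
    significance_stars,
)


# ---------------------------------------------------------------------------
# delta convention
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ca,da,expected", [
    (91.7, 91.1, -0.6),   # chest, single-camera scanner column
    (84.2, 78.5, -5.7),   # waist, same column
    (98.9, 96.0, -2.9),   # hip
    (91.7, 94.7, 3.0),    # chest, multi-camera scanner
    (50.0, 50.0, 0.0),
])
def test_delta_is_da_minus_ca(ca, da, expected):
    assert delta_means(ca, da) == pytest.approx(expected, abs=1e-9)


def test_delta_antisymmetry():
    assert delta_means(10.0, 12.5) == -delta_means(12.5, 10.0)


# ---------------------------------------------------------------------------
# paired t test
# ---------------------------------------------------------------------------

def test_ttest_frozen_example():
    t, df, p, mean_d, sd_d = paired_ttest(PairedSample([10, 12, 14],
                                                       [11, 11, 15]))
    assert t == pytest.approx(0.5, rel=1e-12)
    assert df == 2
    assert p == pytest.approx(2.0 / 3.0, rel=1e-9)


def test_ttest_df1_closed_form():
    # p = 2*(1 - Cauchy CDF at t=2): the t distribution with df=1
    t, df, p, *_ = paired_ttest(PairedSample([0, 0], [1, 3]))
    assert (t, df) == (2.0, 1)
    assert p == pytest.approx(2 * (0.5 - np.arctan(2.0) / np.pi), rel=1e-9)


def test_ttest_zero_difference_convention():
    ca = np.array([30.0, 40.0, 50.0])
    t, df, p, mean_d, sd_d = paired_ttest(PairedSample(ca, ca))
    assert (t, p) == (0.0, 1.0)


def test_ttest_constant_offset_is_degenerate_certainty():
    ca = np.array([30.0, 40.0, 50.0])
    t, df, p, mean_d, sd_d = paired_ttest(PairedSample(ca, ca + 2.0))
    assert np.isinf(t) and t > 0
    assert p == 0.0


def test_ttest_sample_size_error():
    with pytest.raises(SampleSizeError):
        paired_ttest(PairedSample([1.0], [2.0]))


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def test_regression_exact_fit():
    slope, intercept, r2, rmse = regression_eval(
        PairedSample([1, 2, 3], [2, 4, 6]))
    assert (slope, intercept) == (2.0, 0.0)
    assert r2 == 1.0
    assert rmse == 0.0


def test_regression_frozen_example():
    slope, intercept, r2, rmse = regression_eval(
        PairedSample([0, 1, 2], [0, 1, 2.2]))
    assert slope == pytest.approx(1.1, rel=1e-12)
    assert intercept == pytest.approx(-1.0 / 30.0, rel=1e-9)
    assert r2 == pytest.approx(1.0 - (1.0 / 150.0) / (182.0 / 75.0), rel=1e-9)


def test_regression_constant_predictor_errors():
    with pytest.raises(RegressionError):
        regression_eval(PairedSample([5, 5, 5], [1, 2, 3]))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_bland_altman_frozen_example():
    bias, loa, slope, r2 = bland_altman(PairedSample([10, 20, 30],
                                                     [11, 19, 33]))
    assert bias == pytest.approx(1.0)
    assert loa == (pytest.approx(1 - 1.96 * 2), pytest.approx(1 + 1.96 * 2))
    assert slope == pytest.approx(24.0 / 222.0, rel=1e-12)


def test_bland_altman_constant_offset():
    ca = np.array([10.0, 20.0, 30.0])
    bias, loa, slope, r2 = bland_altman(PairedSample(ca, ca + 2.0))
    assert bias == 2.0
    assert loa == (2.0, 2.0)
    assert slope == 0.0


def test_bland_altman_identity():
    ca = np.array([10.0, 20.0, 30.0])
    bias, loa, slope, r2 = bland_altman(PairedSample(ca, ca))
    assert bias == 0.0
    assert loa == (0.0, 0.0)


def test_loa_width_is_exactly_392_sd():
    rng = np.random.default_rng(5)
    ca = rng.uniform(50, 90, 40)
    da = ca + rng.normal(1, 2, 40)
    s = PairedSample(ca, da)
    bias, loa, *_ = bland_altman(s)
    sd = (da - ca).std(ddof=1)
    assert loa[1] - loa[0] == pytest.approx(2 * 1.96 * sd, rel=1e-12)


# ---------------------------------------------------------------------------
# invariances (property tests)
# ---------------------------------------------------------------------------

@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6))
def test_swap_antisymmetry(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 30))
    ca = rng.uniform(20, 120, n)
    da = ca + rng.normal(0, 2, n)
    if np.std(da - ca, ddof=1) == 0:
        return
    s, sw = PairedSample(ca, da), PairedSample(da, ca)
    assert paired_ttest(sw)[0] == pytest.approx(-paired_ttest(s)[0], rel=1e-9)
    assert bland_altman(sw)[0] == pytest.approx(-bland_altman(s)[0], rel=1e-9)
    assert delta_means(da.mean(), ca.mean()) == pytest.approx(
        -delta_means(ca.mean(), da.mean()), rel=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10 ** 6),
       st.floats(min_value=-50, max_value=50),
       st.floats(min_value=0.1, max_value=10))
def test_location_scale_behaviour(seed, c, s_factor):
    rng = np.random.default_rng(seed)
    ca = rng.uniform(20, 120, 12)
    da = ca + rng.normal(1, 2, 12)
    base_t = paired_ttest(PairedSample(ca, da))[0]
    base_r2 = regression_eval(PairedSample(ca, da))[2]
    shifted = PairedSample(ca + c, da + c)
    assert paired_ttest(shifted)[0] == pytest.approx(base_t, rel=1e-6)
    assert regression_eval(shifted)[2] == pytest.approx(base_r2, rel=1e-6)
    scaled = PairedSample(ca * s_factor, da * s_factor)
    assert paired_ttest(scaled)[0] == pytest.approx(base_t, rel=1e-6)
    assert regression_eval(scaled)[2] == pytest.approx(base_r2, rel=1e-6)
    assert bland_altman(scaled)[0] == pytest.approx(
        s_factor * bland_altman(PairedSample(ca, da))[0], rel=1e-6)


def test_reference_implementation_agreement():
    """t/p/OLS/Bland-Altman must match scipy & statsmodels to 1e-6 relative."""
    from scipy import stats as sps
    import statsmodels.api as sm

    rng = np.random.default_rng(42)
    for _ in range(25):
        n = int(rng.integers(5, 60))
        ca = rng.uniform(15, 130, n)
        da = ca * rng.uniform(0.9, 1.1) + rng.normal(1, 2, n)
        s = PairedSample(ca, da)
        t, df, p, *_ = paired_ttest(s)
        ref = sps.ttest_rel(da, ca)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        slope, intercept, r2, rmse = regression_eval(s)
        lr = sps.linregress(ca, da)
        assert slope == pytest.approx(lr.slope, rel=1e-9)
        assert r2 == pytest.approx(lr.rvalue ** 2, rel=1e-6)
        bias, loa, ba_slope, ba_r2 = bland_altman(s)
        d, m = da - ca, 0.5 * (da + ca)
        fit = sm.OLS(d, sm.add_constant(m)).fit()
        assert ba_slope == pytest.approx(fit.params[1], rel=1e-6)
        assert ba_r2 == pytest.approx(fit.rsquared, rel=1e-6, abs=1e-9)


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def test_compare_methods_synthetic_cohort():
    rng = np.random.default_rng(7)
    ca = rng.uniform(60, 110, 35)
    da = ca + rng.normal(2, 1, 35)
    report = compare_methods([PairedSample(ca, da, "waist", "sim")])
    row = report.iloc[0]
    assert 1.5 <= row.ba_bias <= 2.5
    assert row.r2 > 0.9
    assert row.delta_mean > 0
    assert row.p < 1e-4
    assert row.stars == "***"


def test_compare_methods_identity_cohort():
    rng = np.random.default_rng(8)
    samples = []
    for site in ("waist", "hip"):
        ca = rng.uniform(60, 110, 20)
        samples.append(PairedSample(ca, ca.copy(), site, "sim"))
    report = compare_methods(samples)
    assert (report.delta_mean == 0).all()
    assert (report.p == 1.0).all()
    assert (report.r2 == 1.0).all()


def test_delta_column_consistent_with_means():
    rng = np.random.default_rng(9)
    ca = rng.uniform(60, 110, 15)
    da = ca + rng.normal(0.5, 1, 15)
    report = compare_methods([PairedSample(ca, da, "chest", "sim")])
    row = report.iloc[0]
    assert row.delta_mean == pytest.approx(row.da_mean - row.ca_mean,
                                           abs=1e-12)


def test_rmsd_differs_from_regression_rmse():
    rng = np.random.default_rng(10)
    ca = rng.uniform(60, 110, 30)
    da = ca + rng.normal(2, 1, 30)
    s = PairedSample(ca, da)
    # constant-bias data: paired RMSD sees the bias, regression RMSE does not
    assert rmsd(s) > regression_eval(s)[3]


def test_significance_stars_tiers():
    assert significance_stars(5e-5) == "***"
    assert significance_stars(5e-3) == "**"
    assert significance_stars(3e-2) == "*"
    assert significance_stars(0.2) == ""


def test_read_pairs_csv_roundtrip(tmp_path):
    import pandas as pd

    df = pd.DataFrame({
        "scan-id": ["a", "b", "c", "a", "b", "c"],
        "device": ["s1"] * 6,
        "site": ["waist"] * 3 + ["hip"] * 3,
        "ca-cm": [80.0, 85.0, 90.0, 95.0, 100.0, 105.0],
        "da-cm": [81.0, 86.0, 91.0, 96.0, 99.0, 104.0],
    })
    path = tmp_path / "pairs.csv"
    df.to_csv(path, index=False)
    samples = read_pairs_csv(path)
    assert {s.site for s in samples} == {"waist", "hip"}
    assert all(s.n == 3 for s in samples)
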