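import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trabecula.allometry import (
    BUILTIN_METRICS,
    RegressionResult,
    classify_allometry,
    fit_loglog,
    isometric_slope,
    select_body_size_proxy,
    sma_common_slope_test,
    sma_slope,
    species_means,
)


def make_xy(seed=0, n=30, slope=0.7, noise=0.05):
    rng = np.random.default_rng(seed)
    lx = rng.uniform(0.5, 2.0, n)
    ly = 0.3 + slope * lx + rng.normal(0, noise, n)
    return 10.0**lx, 10.0**ly


# ---------------------------------------------------------------------------
# fit_loglog


def test_fit_matches_scipy_linregress():
    x, y = make_xy()
    r = fit_loglog(x, y)
    ref = stats.linregress(np.log10(x), np.log10(y))
    assert r.slope == pytest.approx(ref.slope)
    assert r.intercept == pytest.approx(ref.intercept)
    assert r.p_value == pytest.approx(ref.pvalue)
    assert r.r_squared == pytest.approx(ref.rvalue**2)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    assert r.ci_high - r.ci_low == pytest.approx(2 * tcrit * ref.stderr)


def test_fit_names_offending_rows():
    x = np.array([1.0, -2.0, 3.0, 4.0])
    y = np.array([1.0, 1.0, np.nan, 1.0])
    with pytest.raises(ValueError, match=r"rows \[1, 2\]"):
        fit_loglog(x, y)


def test_fit_requires_x_variance():
    with pytest.raises(ValueError, match="variance"):
        fit_loglog(np.ones(5), np.arange(1.0, 6.0))


@settings(max_examples=30, deadline=None)
@given(
    slope=st.floats(-2, 2),
    intercept=st.floats(-1, 1),
)
def test_fit_recovers_exact_line(slope, intercept):
    lx = np.linspace(0.2, 1.4, 12)
    x, y = 10.0**lx, 10.0 ** (intercept + slope * lx)
    r = fit_loglog(x, y)
    assert r.slope == pytest.approx(slope, abs=1e-8)
    assert r.ci_low - 1e-8 <= slope <= r.ci_high + 1e-8


# ---------------------------------------------------------------------------
# Allometry calls


def test_isometric_slope_table():
    assert isometric_slope("bv_tv") == 0
    assert isometric_slope("tb_n") == -1
    assert isometric_slope("csa") == 2
    assert isometric_slope("conn_d") == -3


def test_classify_trichotomy():
    assert classify_allometry((0.5, 0.4, 0.6), 0.55) == "0"
    assert classify_allometry((0.5, 0.4, 0.6), 0.3) == "+"
    assert classify_allometry((0.5, 0.4, 0.6), 0.7) == "-"


def test_classify_accepts_fitted_result():
    x, y = make_xy(slope=0.7)
    r = fit_loglog(x, y)
    assert classify_allometry(r, BUILTIN_METRICS["tb_th"]) == "-"


@settings(max_examples=50, deadline=None)
@given(
    lo=st.floats(-3, 3),
    width=st.floats(0.01, 2),
    frac=st.floats(0, 1),
    iso=st.floats(-3.5, 3.5),
)
def test_classify_always_returns_a_call(lo, width, frac, iso):
    hi = lo + width
    slope = lo + frac * width
    call = classify_allometry((slope, lo, hi), iso)
    assert call in {"+", "-", "0"}
    if lo <= iso <= hi:
        assert call == "0"


def test_regression_result_invariant():
    with pytest.raises(ValueError):
        RegressionResult(
            slope=1.0, intercept=0, ci_low=1.2, ci_high=1.4,
            p_value=0.5, r_squared=0.5, n=10,
        )


# ---------------------------------------------------------------------------
# Proxy selection and species means


def proxy_frame():
    rng = np.random.default_rng(4)
    n = 40
    mass = rng.uniform(100, 5000, n)
    good = mass ** (1 / 3) * np.exp(rng.normal(0, 0.02, n))
    bad = mass ** (1 / 3) * np.exp(rng.normal(0, 0.5, n))
    return pd.DataFrame(
        {
            "mass_g": mass,
            "izl": good,
            "width": bad,
            "position": np.tile(["ps1", "ps2"], n // 2),
        }
    )


def test_proxy_prefers_tighter_measurement():
    out = select_body_size_proxy(proxy_frame(), candidate_columns=["width", "izl"])
    assert out["measurement"] == "izl"
    assert out["position"] in {"ps1", "ps2"}


def test_proxy_drops_missing_mass_with_warning():
    df = proxy_frame()
    df.loc[0, "mass_g"] = np.nan
    with pytest.warns(UserWarning, match="missing mass"):
        out = select_body_size_proxy(df, candidate_columns=["width", "izl"])
    assert out["measurement"] == "izl"


def test_species_means_raw_and_log():
    df = pd.DataFrame(
        {
            "taxon": ["A", "A", "B", "B"],
            "position": ["ps1"] * 4,
            "clade": ["X", "X", "Y", "Y"],
            "v": [1.0, 100.0, 4.0, 4.0],
        }
    )
    raw = species_means(df, value_columns=["v"])
    assert raw.loc[raw["taxon"] == "A", "v"].item() == pytest.approx(50.5)
    log = species_means(df, value_columns=["v"], scale="log")
    assert log.loc[log["taxon"] == "A", "v"].item() == pytest.approx(10.0)
    assert (raw["clade"] == ["X", "Y"]).all()  # constant metadata carried


# ---------------------------------------------------------------------------
# SMA


def test_sma_slope_formula():
    # sma_slope logs internally: check against the textbook formula on logs
    x, y = make_xy(seed=2, slope=-1.5, noise=0.05)
    lx, ly = np.log10(x), np.log10(y)
    b = sma_slope(x, y)
    expected = np.sign(np.corrcoef(lx, ly)[0, 1]) * ly.std(ddof=1) / lx.std(ddof=1)
    assert b == pytest.approx(expected)
    assert b < 0


def test_common_slope_zero_on_identical_groups():
    x, y = make_xy()
    res = sma_common_slope_test({"g1": (x, y), "g2": (x, y)})
    assert res.lr_statistic == pytest.approx(0.0, abs=1e-6)
    assert res.p_value > 0.99
    assert res.verdict == "equal"


def test_common_slope_detects_different_slopes():
    x1, y1 = make_xy(seed=9, slope=2.0, noise=0.05, n=60)
    x2, y2 = make_xy(seed=10, slope=0.2, noise=0.05, n=60)
    res = sma_common_slope_test({"steep": (x1, y1), "flat": (x2, y2)})
    assert res.p_value < 1e-6
    assert res.verdict == "not equal"
    assert res.group_slopes["steep"] > res.group_slopes["flat"]
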