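import numpy as np
import pytest
from scipy import stats

from conftest import make_synthetic_result
from g2mcycle.scenarios import make_scenario
from g2mcycle.sensitivity import (average_concentration, averaged_quantities,
                                  average_log_sensitivity, fuzzy_analysis,
                                  log_sensitivity, log_sensitivity_report,
                                  partial_rank_correlation)


# ---------------------------------------------------------------- averaging

def test_average_of_constant_trajectory_is_the_constant():
    t = np.arange(0.0, 100.0, 0.1)
    res = make_synthetic_result(("Mdm2", np.full_like(t, 0.37)), t)
    assert average_concentration(res, "Mdm2") == pytest.approx(0.37)


def test_average_of_whole_periods_of_a_sinusoid_vanishes():
    t = np.arange(0.0, 100.0, 0.01)
    res = make_synthetic_result(("Mdm2", np.sin(2 * np.pi * t / 48.0)), t)
    # 96 hourly samples = two full periods
    assert average_concentration(res, "Mdm2") == pytest.approx(0.0, abs=1e-6)


def test_average_matches_direct_hourly_sum(wt_result):
    """The implementation must equal the plain discrete sum over the 96
    sample points (no trapezoid weighting)."""
    direct = np.mean([np.interp(j * 1.0, wt_result.times,
                                wt_result.species("MPF"))
                      for j in range(1, 97)])
    assert average_concentration(wt_result, "MPF") == pytest.approx(
        direct, abs=1e-10)


def test_span_too_short_raises():
    t = np.arange(0.0, 50.0, 0.1)
    res = make_synthetic_result(("Mdm2", np.zeros_like(t)), t)
    with pytest.raises(ValueError):
        average_concentration(res, "Mdm2")


def test_vectorised_averages_match_scalar_path(wt_result):
    allq = averaged_quantities(wt_result)
    for name, idx in [("MPF", 1), ("Mad2:Cdc20P", 33)]:
        assert allq[idx] == pytest.approx(
            average_concentration(wt_result, name), abs=1e-12)


# ------------------------------------------------- logarithmic sensitivity

def test_zero_valued_parameter_has_zero_sensitivity(params):
    scen = make_scenario(p53_null=True)
    assert log_sensitivity(params, "Mdm2", "k_s28", scenario=scen) == 0.0


def test_structurally_disconnected_parameter_has_negligible_sensitivity(params):
    """Securin sits downstream of the checkpoint: its synthesis rate
    cannot move the Wip1 average."""
    s = log_sensitivity(params, "Wip1", "k_s24")
    assert abs(s) < 1e-6


def test_report_matrix_matches_single_entry_path(params):
    report = log_sensitivity_report(params, quantities=["Mdm2", "Wip1"],
                                    parameters=["k_s31", "k_s32"])
    single = log_sensitivity(params, "Mdm2", "k_s31")
    i, j = report.quantities.index("Mdm2"), report.parameters.index("k_s31")
    assert report.matrix[i, j] == pytest.approx(single, rel=1e-9)


def test_average_log_sensitivity_is_a_row_mean():
    from g2mcycle.sensitivity import SensitivityReport

    rng = np.random.default_rng(5)
    matrix = rng.uniform(0, 2, size=(4, 9))
    report = SensitivityReport("synthetic", [f"q{i}" for i in range(4)],
                               [f"p{j}" for j in range(9)], matrix)
    assert np.allclose(average_log_sensitivity(report), matrix.mean(axis=1),
                       atol=1e-12)
    zero = SensitivityReport("z", ["q"], ["a", "b"], np.zeros((1, 2)))
    assert average_log_sensitivity(zero)[0] == 0.0


# ------------------------------------------------------------------- PRCC

def _brute_force_prcc(X, y, j):
    """Definitional oracle: rank everything, regress column j and y on the
    remaining columns, correlate the residuals."""
    Xr = np.apply_along_axis(stats.rankdata, 0, X)
    yr = stats.rankdata(y)
    others = np.column_stack([np.ones(len(y)), np.delete(Xr, j, axis=1)])
    rx = Xr[:, j] - others @ np.linalg.lstsq(others, Xr[:, j], rcond=None)[0]
    ry = yr - others @ np.linalg.lstsq(others, yr, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def test_prcc_matches_definitional_oracle():
    rng = np.random.default_rng(11)
    X = rng.uniform(0, 1, size=(200, 5))
    y = 3.0 * X[:, 1] + 0.1 * rng.normal(size=200)
    prcc, pvals = partial_rank_correlation(X, y)
    for j in range(5):
        assert prcc[j] == pytest.approx(_brute_force_prcc(X, y, j), abs=1e-10)
    assert prcc[1] > 0.95
    assert all(abs(prcc[j]) < 0.2 for j in range(5) if j != 1)
    assert np.all((prcc >= -1) & (prcc <= 1))
    assert np.all((pvals >= 0) & (pvals <= 1))


def test_prcc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(13)
    X = rng.uniform(0.1, 1, size=(150, 4))
    y = X[:, 0] - 2 * X[:, 2] + 0.05 * rng.normal(size=150)
    base, _ = partial_rank_correlation(X, y)
    Xt = X.copy()
    Xt[:, 0] = np.exp(5 * Xt[:, 0])     # strictly increasing
    Xt[:, 2] = Xt[:, 2] ** 3
    transformed, _ = partial_rank_correlation(Xt, y)
    assert np.allclose(base, transformed, atol=1e-12)


def test_prcc_zero_variance_output_flagged():
    X = np.random.default_rng(17).uniform(0, 1, (50, 3))
    y = np.full(50, 0.7)
    prcc, pvals = partial_rank_correlation(X, y)
    assert np.allclose(prcc, 0.0)


# ------------------------------------------------------------------ fuzzy

@pytest.fixture(scope="module")
def small_band(params):
    return fuzzy_analysis(params, ["k_s31", "k_s32"],
                          alpha_levels=(0.0, 0.5, 1.0),
                          quantities=["Mdm2", "Wip1", "p53_total"],
                          T=48.0)


def test_fuzzy_band_zero_at_alpha_one(small_band):
    assert np.allclose(small_band.bands[:, :, -1], 0.0)


def test_fuzzy_bands_nested_in_alpha(small_band):
    b = small_band.bands
    assert np.all(b[:, :, 1] <= b[:, :, 0] + 1e-15)
    assert np.all(b[:, :, 2] <= b[:, :, 1] + 1e-15)
    assert np.all(b >= 0)


def test_fuzzy_alpha_validation(params):
    with pytest.raises(ValueError):
        fuzzy_analysis(params, ["k_s31"], alpha_levels=(1.5,))
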