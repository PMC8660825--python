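import numpy as np
import pytest

from g2mcycle.parameters import SYNTHESIS_PARAMS, ParameterSet
from g2mcycle.registry import CONSERVATION_LAWS, INDEX, N_SPECIES, SPECIES
from g2mcycle.rhs import (derived_quantities, numerical_jacobian, rhs_core,
                          rhs_full, rhs_p53_module)


def random_state(seed):
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.0, 0.5, N_SPECIES)
    # keep the state on the CDK1-normalisation manifold
    for name in ("MPF", "preMPF", "p21:MPF"):
        y[INDEX[name]] = rng.uniform(0.0, 0.3)
    pool = y[[INDEX["MPF"], INDEX["preMPF"], INDEX["p21:MPF"]]].sum()
    y[INDEX["CDK1"]] = 1.0 - pool
    return y


def test_p53_plk1_complex_equation_balances_at_equilibrium(params):
    """When binding and release fluxes of the p53P:Plk1P complex are
    equal, its derivative vanishes."""
    y = random_state(0)
    kf, kr = params["k_f17"], params["k_r17"]
    y[INDEX["p53P"]] = 0.2
    y[INDEX["Plk1P"]] = 0.3
    y[INDEX["p53P:Plk1P"]] = kf * 0.2 * 0.3 / kr
    dy = rhs_full(0.0, y, params)
    assert dy[INDEX["p53P:Plk1P"]] == pytest.approx(0.0, abs=1e-12)


def test_origin_is_fixed_point_without_synthesis(params):
    no_syn = params.with_edits({k: 0.0 for k in list(SYNTHESIS_PARAMS)
                                + ["k_s31.1", "k_s32.1"]})
    dy = rhs_full(0.0, np.zeros(N_SPECIES), no_syn)
    assert np.allclose(dy, 0.0, atol=1e-14)


@pytest.mark.parametrize("seed", range(20))
def test_jacobian_matches_finite_difference_oracle(params, seed):
    """Internal Jacobian helper agrees with an independent central
    difference at h = 1e-7 on random states."""
    y = random_state(seed)
    p = params.as_array()
    jac = numerical_jacobian(0.0, y, p)
    h = 1e-7
    for j in [0, 7, 15, 26, 33]:  # spot columns across all three layers
        up, dn = y.copy(), y.copy()
        up[j] += h
        dn[j] -= h
        col = (rhs_core(0.0, up, p) - rhs_core(0.0, dn, p)) / (2 * h)
        assert np.allclose(jac[:, j], col, rtol=1e-5, atol=1e-8)


def test_tau_rescales_the_whole_field(params):
    y = random_state(3)
    doubled = params.with_edits({"tau": 2 * params.tau})
    assert np.allclose(rhs_full(0.0, y, doubled),
                       2.0 * rhs_full(0.0, y, params))


def test_rhs_rejects_bad_states(params):
    with pytest.raises(ValueError):
        rhs_full(0.0, np.zeros(10), params)
    bad = np.zeros(N_SPECIES)
    bad[INDEX["Mdm2"]] = np.nan
    with pytest.raises(FloatingPointError, match="Mdm2"):
        rhs_full(0.0, bad, params)


def test_derived_quantities_totals_match_brute_force(params):
    """Each reported total equals an independent sum over its members."""
    y = random_state(7)
    out = derived_quantities(y)
    assert np.allclose(out[:N_SPECIES], y)
    for k, law in enumerate(CONSERVATION_LAWS):
        brute = sum(s * y[SPECIES.index(m)] for m, s in law.members)
        assert out[N_SPECIES + k] == pytest.approx(brute, abs=1e-14)


def test_cdk1_total_is_one_on_the_normalisation_manifold(params):
    y = random_state(11)
    out = derived_quantities(y)
    assert out[N_SPECIES] == pytest.approx(1.0)  # CDK1_total is first


def test_p53_module_validates_and_maps_state(params):
    with pytest.raises(ValueError):
        rhs_p53_module(0.0, np.zeros(3), params)
    dy = rhs_p53_module(0.0, np.array([0.1, 0.02, 0.01, 0.05, 0.02]), params,
                        damage_on=False)
    assert dy.shape == (5,)
    assert np.all(np.isfinite(dy))
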