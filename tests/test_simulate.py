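import numpy as np
import pytest

from conftest import make_synthetic_result
from g2mcycle.registry import INDEX
from g2mcycle.simulate import (PhenotypeCall, SimulationResult,
                               classify_phenotype, estimate_period, integrate,
                               limit_cycle_range_scan)


def test_known_sinusoid_period_recovered():
    t = np.arange(0.0, 400.0, 0.05)
    res = make_synthetic_result(("CyclinB", 0.5 + 0.4 * np.sin(2 * np.pi * t / 24.0)), t)
    assert estimate_period(res) == pytest.approx(24.0, abs=0.1)


def test_constant_trajectory_has_no_period():
    t = np.arange(0.0, 400.0, 0.1)
    res = make_synthetic_result(("CyclinB", np.full_like(t, 0.3)), t)
    assert estimate_period(res) is None


def test_damped_ringing_rejected_by_amplitude_floor():
    t = np.arange(0.0, 400.0, 0.05)
    y = 0.5 + 0.4 * np.exp(-t / 40.0) * np.sin(2 * np.pi * t / 24.0)
    res = make_synthetic_result(("CyclinB", y), t)
    assert estimate_period(res) is None


def test_period_invariant_under_subsampling(wt_result, wt_period):
    thin = SimulationResult(wt_result.times[::2], wt_result.trajectories[:, ::2])
    assert estimate_period(thin, species="MPF") == pytest.approx(wt_period,
                                                                 rel=0.02)


def test_unknown_species_raises(wt_result):
    with pytest.raises(KeyError):
        estimate_period(wt_result, species="nonexistent")


def test_wild_type_self_comparison(wt_result, wt_period):
    call = classify_phenotype(wt_result, reference_period=wt_period)
    assert call.viable
    assert call.tm_over_t == pytest.approx(1.0, abs=0.02)
    assert call.arrest_class == "none"


def test_phenotype_call_invariants():
    with pytest.raises(ValueError):
        PhenotypeCall(viable=True, period=None)
    with pytest.raises(ValueError):
        PhenotypeCall(viable=True, period=48.0, arrest_class="early-low-MPF")


def test_arrest_classes_follow_terminal_mpf(params, wt_period, wt_result):
    mpf_peak = float(wt_result.species("MPF").max())
    high = integrate(params.with_edits({"k_s17": 0.0}), t_end=300.0)
    call_high = classify_phenotype(high, wt_period, mpf_peak)
    assert not call_high.viable and call_high.arrest_class == "M-phase-high-MPF"
    low = integrate(params.with_edits({"k_s8": 0.0}), t_end=300.0)
    call_low = classify_phenotype(low, wt_period, mpf_peak)
    assert not call_low.viable and call_low.arrest_class == "early-low-MPF"


def test_degenerate_scan_reports_the_default(params):
    default = params["k_s8"]
    lo, hi = limit_cycle_range_scan(params, "k_s8", [default], t_end=300.0)
    assert lo == hi == default


def test_result_invariants(wt_result):
    assert np.all(np.diff(wt_result.times) > 0)
    assert wt_result.trajectories.shape[0] == 34
    frame = wt_result.to_frame()
    assert set(frame.columns) == {"time", "species", "value"}
    assert len(frame) == wt_result.times.size * 34


def test_conservation_along_trajectory(wt_result):
    """Closed totals (CDK1 and separase pools) stay constant to well
    within ten times the solver tolerance."""
    cdk1 = (wt_result.species("CDK1") + wt_result.species("MPF")
            + wt_result.species("preMPF") + wt_result.species("p21:MPF"))
    assert np.abs(cdk1 - 1.0).max() < 1e-5
    sep = wt_result.species("Separase") + wt_result.species("Pttg1:Separase")
    assert np.abs(sep - sep[0]).max() < 1e-5


def test_trajectories_stay_nonnegative(wt_result):
    assert wt_result.trajectories.min() > -1e-6


def test_limit_cycle_interval_on_cdc25_synthesis_grid(params):
    """Scanning the Cdc25 synthesis rate over {0.07, 0.08, 0.09, 0.1}:
    the limit cycle exists on 0.08-0.1 but not at 0.07."""
    lo, hi = limit_cycle_range_scan(params, "k_s8", [0.07, 0.08, 0.09, 0.1])
    assert lo == pytest.approx(0.08)
    assert hi == pytest.approx(0.10)
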