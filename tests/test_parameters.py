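import pytest

from g2mcycle.parameters import (KINETIC_PARAM_NAMES, N_KINETIC, PARAM_NAMES,
                                 ConfigurationError, ParameterSet,
                                 build_default_parameters)


def test_exactly_137_kinetic_parameters_plus_tau():
    assert N_KINETIC == 137
    assert len(PARAM_NAMES) == 138
    assert PARAM_NAMES[-1] == "tau"


def test_default_table_loads_with_calibrated_timescale(params):
    assert params.tau == pytest.approx(1.65)
    assert all(params[name] >= 0 for name in KINETIC_PARAM_NAMES)


def test_missing_symbol_is_reported_by_name(params):
    broken = dict(params.values)
    del broken["k_s28"]
    with pytest.raises(ConfigurationError, match="k_s28"):
        ParameterSet(broken)


def test_negative_value_rejected(params):
    with pytest.raises(ConfigurationError, match="k_s1"):
        params.with_edits({"k_s1": -0.1})


def test_unknown_symbol_rejected(params):
    with pytest.raises(ConfigurationError, match="k_s99"):
        params.with_edits({"k_s99": 1.0})


@pytest.mark.parametrize("fmt", ["csv", "yaml"])
def test_write_then_read_round_trip(params, tmp_path, fmt):
    path = tmp_path / f"table.{fmt}"
    getattr(params, f"to_{fmt}")(path)
    reread = (ParameterSet.from_csv(path) if fmt == "csv"
              else ParameterSet.from_yaml(path))
    assert reread == params


def test_edits_do_not_mutate_the_original(params):
    before = params["k_s12"]
    mutant = params.with_edits({"k_s12": 0.0})
    assert mutant["k_s12"] == 0.0
    assert params["k_s12"] == before
    assert mutant.fingerprint() != params.fingerprint()
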