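import numpy as np
import pytest

from g2mcycle.parameters import ConfigurationError
from g2mcycle.perturb import (GENE_MAP, MODEL_GENES, PerturbationSpec,
                              load_mutant_definitions, make_mutant)


def test_gene_map_covers_model_genes_and_resolves_parameters(params):
    for gene in MODEL_GENES:
        mapping = GENE_MAP[gene]
        assert mapping.parameter in params


def test_tp53_deletion_zeroes_synthesis_and_initial_condition(params):
    ps, overrides = make_mutant(params, ["TP53"], mode="deletion")
    assert ps["k_s28"] == 0.0
    assert overrides == {"p53": 0.0}


def test_family_gene_crispr_scales_instead_of_zeroing(params):
    ps, _ = make_mutant(params, ["CCNB1"], mode="crispr")
    assert ps["k_s1"] == pytest.approx(0.5 * params["k_s1"])
    ps2, _ = make_mutant(params, ["CCNB1"], mode="deletion")
    assert ps2["k_s1"] == 0.0


def test_complex_subunit_crispr_disrupts_the_whole_complex(params):
    ps, _ = make_mutant(params, ["CDC27"], mode="crispr")
    assert ps["k_s15"] == 0.0


def test_double_deletion_composes(params):
    ps, _ = make_mutant(params, ["CDH1", "MAD2L1"], mode="deletion")
    assert ps["k_s20"] == 0.0
    assert ps["k_s33"] == 0.0


def test_deletion_order_does_not_matter(params):
    a, _ = make_mutant(params, ["CDH1", "MAD2L1"])
    b, _ = make_mutant(params, ["MAD2L1", "CDH1"])
    assert a == b


def test_unknown_gene_raises(params):
    with pytest.raises(KeyError, match="MYC"):
        make_mutant(params, ["MYC"])


def test_depletion_levels(params):
    ps, _ = make_mutant(params, ["PLK1"], mode="depletion", level=0.7)
    assert ps["k_s12"] == pytest.approx(0.3 * params["k_s12"])
    ps0, _ = make_mutant(params, ["PLK1"], mode="depletion", level=0.0)
    assert ps0["k_s12"] == params["k_s12"]
    with pytest.raises(ValueError):
        make_mutant(params, ["PLK1"], mode="depletion", level=1.5)


def test_contradictory_edits_rejected(params):
    spec = PerturbationSpec(edits=[("k_s12", "set_zero", 0.0),
                                   ("k_s12", "set_value", 0.5)])
    with pytest.raises(ValueError, match="contradictory"):
        spec.apply(params)


def test_scale_factor_range_enforced(params):
    spec = PerturbationSpec(edits=[("k_s12", "scale", 1.4)])
    with pytest.raises(ValueError):
        spec.apply(params)


def test_bundled_mutant_panel_is_well_formed(params):
    panel = load_mutant_definitions()
    assert len(panel) == 23
    for genes in panel["genes"]:
        for gene in str(genes).split(";"):
            assert gene in GENE_MAP
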