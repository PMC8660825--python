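import numpy as np
import pytest
from scipy import stats

from g2mcycle.celllines import (DEFAULT_MUTATION_RATES, CellLineGroup,
                                generate_cellline_fixture, group_cell_lines,
                                mutation_edits)


def test_fixture_is_deterministic_under_a_seed():
    a = generate_cellline_fixture(200, seed=42)
    b = generate_cellline_fixture(200, seed=42)
    assert a.equals(b)
    c = generate_cellline_fixture(200, seed=43)
    assert not a.equals(c)


def test_tp53_is_the_most_frequent_mutation():
    matrix = generate_cellline_fixture(1000, seed=0)
    counts = matrix[matrix["mutation_flag"] == 1]["gene"].value_counts()
    assert counts.idxmax() == "TP53"


def test_comutation_counts_within_exact_binomial_bounds():
    """Independent genes co-mutate at rate p1*p2; the observed pair count
    must fall inside the exact binomial 99% interval."""
    n = 2000
    matrix = generate_cellline_fixture(n, seed=7)
    rates = DEFAULT_MUTATION_RATES
    mutated = matrix[matrix["mutation_flag"] == 1]
    by_line = mutated.groupby("cell_line_id")["gene"].apply(set)
    for a, b in [("ATM", "TP53"), ("CDH1", "TP53")]:
        observed = sum(1 for genes in by_line if a in genes and b in genes)
        p = rates[a] * rates[b]
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= observed <= hi


def test_rate_validation():
    with pytest.raises(ValueError):
        generate_cellline_fixture(10, rates={"TP53": 1.5}, seed=0)
    with pytest.raises(KeyError):
        generate_cellline_fixture(10, rates={"NOTAGENE": 0.1}, seed=0)
    with pytest.raises(ValueError):
        generate_cellline_fixture(0, seed=0)


def test_grouping_produces_single_gene_and_pair_groups():
    matrix = generate_cellline_fixture(800, seed=3)
    groups = group_cell_lines(matrix, pair_groups=[("ATM", "TP53")])
    labels = {g.label for g in groups}
    assert "TP53" in labels and "ATM+TP53" in labels
    tp53 = next(g for g in groups if g.label == "TP53")
    assert max(groups, key=lambda g: g.size).label == "TP53"
    pair = next(g for g in groups if g.label == "ATM+TP53")
    assert set(pair.members) <= set(tp53.members)


def test_group_requires_mutations():
    with pytest.raises(ValueError):
        CellLineGroup("empty", ("SYN-0000",), ())


def test_mutation_edits_keep_essential_genes_partially_active(params):
    ps, overrides = mutation_edits(params, ["PLK1", "TP53"])
    assert ps["k_s12"] == pytest.approx(0.8 * params["k_s12"])
    assert ps["k_s28"] == 0.0
    assert overrides == {"p53": 0.0}
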