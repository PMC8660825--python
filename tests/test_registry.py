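import numpy as np
import pytest

from g2mcycle.registry import (CONSERVATION_LAWS, DEFAULT_REGISTRY,
                               DERIVED_NAMES, INDEX, REPORTED_NAMES, SPECIES,
                               SpeciesRegistry, load_conservation_table,
                               write_conservation_table)


def test_species_counts_and_uniqueness():
    assert len(SPECIES) == 34
    assert len(set(SPECIES)) == 34
    assert len(DERIVED_NAMES) == 16
    assert len(REPORTED_NAMES) == 50


def test_every_conservation_member_resolves():
    for law in CONSERVATION_LAWS:
        for member, stoich in law.members:
            assert member in INDEX
            assert stoich > 0


def test_registry_rejects_inconsistent_definitions():
    with pytest.raises(ValueError):
        SpeciesRegistry(names=SPECIES[:-1] + ("MPF",))  # duplicate
    with pytest.raises(ValueError):
        SpeciesRegistry(names=SPECIES[:30])             # wrong count


def test_conservation_table_round_trip(tmp_path):
    path = tmp_path / "conservation.csv"
    write_conservation_table(path)
    laws = load_conservation_table(path)
    assert {l.name for l in laws} == {l.name for l in CONSERVATION_LAWS}
    by_name = {l.name: l for l in laws}
    rng = np.random.default_rng(1)
    state = rng.uniform(0, 1, 34)
    for law in CONSERVATION_LAWS:
        assert by_name[law.name].evaluate(state) == pytest.approx(
            law.evaluate(state))
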