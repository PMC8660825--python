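"""Species registry and conservation-law bookkeeping.

The model tracks 34 dynamic concentrations, all expressed relative to the
total CDK1 pool (set to 1).  Sixteen additional "total" quantities are
defined by weighted sums over the dynamic species (conservation closures),
so that 50 quantities are reported by :func:`g2mcycle.rhs.derived_quantities`
and consumed by the sensitivity analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Tuple

#: Ordered list of the 34 dynamic species.  Indices are load-bearing: the
#: ODE right-hand side and every stored initial state use this order, and
#: the degradation-constant suffixes (k_d8.x for Cdc25, k_d11.x for Plk1P,
#: k_d18.x for Cdc20P, ...) follow these positions.
SPECIES: Tuple[str, ...] = (
    "CyclinB",        # 0  free cyclin B (k_s1)
    "MPF",            # 1  active CyclinB:CDK1
    "preMPF",         # 2  Wee1-phosphorylated (Tyr15) CyclinB:CDK1
    "CDK1",           # 3  free CDK1; total CDK1 pool is conserved at 1
    "p21",            # 4  CDK inhibitor (k_s5)
    "p21:MPF",        # 5  stoichiometric inhibitor complex (3 p21 per MPF)
    "Cdc25P",         # 6  active (phosphorylated) Cdc25
    "Cdc25",          # 7  inactive Cdc25 (k_s8)
    "Wee1",           # 8  active Wee1 kinase (k_s9)
    "Wee1P",          # 9  inactive, degradation-prone Wee1
    "Plk1P",          # 10 active Plk1
    "Plk1",           # 11 inactive Plk1 (k_s12)
    "PP2A",           # 12 active PP2A phosphatase (k_s13)
    "PP2AP",          # 13 MPF-inhibited PP2A
    "APC/C",          # 14 unmodified APC/C core (k_s15)
    "APC/CP",         # 15 MPF/Plk1-phosphorylated APC/C (Cdc20-binding form)
    "Cdc20",          # 16 unphosphorylated Cdc20 (k_s17)
    "Cdc20P",         # 17 CDK-phosphorylated Cdc20 (Mad2-binding form)
    "APC/CP:Cdc20",   # 18 anaphase-promoting holoenzyme
    "Cdh1",           # 19 unphosphorylated (binding-competent) Cdh1 (k_s20)
    "Cdh1P",          # 20 CDK-phosphorylated Cdh1
    "APC/CT",         # 21 dephosphorylated APC/C form that accepts Cdh1
    "APC/CT:Cdh1",    # 22 G1 ubiquitin-ligase holoenzyme
    "Pttg1",          # 23 securin (k_s24)
    "Separase",       # 24 free separase (closed pool)
    "Pttg1:Separase", # 25 securin-inhibited separase
    "ATM/ATR",        # 26 lumped apical checkpoint kinase signal (k_s27)
    "p53",            # 27 unphosphorylated p53 (k_s28)
    "p53P",           # 28 activated (phosphorylated) p53
    "p53P:Plk1P",     # 29 Plk1-inhibited p53 complex
    "Mdm2",           # 30 p53-directed E3 ligase (k_s31)
    "Wip1",           # 31 checkpoint-silencing phosphatase (k_s32)
    "Mad2",           # 32 free Mad2 (k_s33)
    "Mad2:Cdc20P",    # 33 mitotic checkpoint complex (arrest indicator)
)

N_SPECIES = len(SPECIES)

#: name -> index for the dynamic species
INDEX: Dict[str, int] = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class ConservationLaw:
    """A reported total: ``sum(stoich * [member])`` over dynamic species."""

    name: str
    members: Tuple[Tuple[str, float], ...]
    #: True when the total carries no net synthesis or degradation flux and
    #: is therefore constant along any trajectory (checked by tests).
    closed: bool = False

    def evaluate(self, values) -> float:
        return float(sum(s * values[INDEX[m]] for m, s in self.members))


def _law(name, members, closed=False):
    return ConservationLaw(name, tuple(members), closed)


#: The 16 conservation closures.  Total CDK1 and total separase are true
#: conserved quantities (no synthesis or degradation touches the moiety);
#: the remaining totals are reported pool sizes.
CONSERVATION_LAWS: Tuple[ConservationLaw, ...] = (
    _law("CDK1_total", [("CDK1", 1), ("MPF", 1), ("preMPF", 1), ("p21:MPF", 1)], closed=True),
    _law("Separase_total", [("Separase", 1), ("Pttg1:Separase", 1)], closed=True),
    _law("CyclinB_total", [("CyclinB", 1), ("MPF", 1), ("preMPF", 1), ("p21:MPF", 1)]),
    _law("p21_total", [("p21", 1), ("p21:MPF", 3)]),
    _law("Cdc25_total", [("Cdc25", 1), ("Cdc25P", 1)]),
    _law("Wee1_total", [("Wee1", 1), ("Wee1P", 1)]),
    _law("Plk1_total", [("Plk1", 1), ("Plk1P", 1), ("p53P:Plk1P", 1)]),
    _law("PP2A_total", [("PP2A", 1), ("PP2AP", 1)]),
    _law("APC/C_total", [("APC/C", 1), ("APC/CP", 1), ("APC/CP:Cdc20", 1),
                         ("APC/CT", 1), ("APC/CT:Cdh1", 1)]),
    _law("Cdc20_total", [("Cdc20", 1), ("Cdc20P", 1), ("APC/CP:Cdc20", 1),
                         ("Mad2:Cdc20P", 1)]),
    _law("Cdh1_total", [("Cdh1", 1), ("Cdh1P", 1), ("APC/CT:Cdh1", 1)]),
    _law("Pttg1_total", [("Pttg1", 1), ("Pttg1:Separase", 1)]),
    _law("p53_total", [("p53", 1), ("p53P", 1), ("p53P:Plk1P", 1)]),
    _law("Mad2_total", [("Mad2", 1), ("Mad2:Cdc20P", 1)]),
    _law("Mdm2_total", [("Mdm2", 1)]),
    _law("Wip1_total", [("Wip1", 1)]),
)

DERIVED_NAMES: Tuple[str, ...] = tuple(law.name for law in CONSERVATION_LAWS)

#: 50 reported quantities: the 34 dynamic species followed by the 16 totals.
REPORTED_NAMES: Tuple[str, ...] = SPECIES + DERIVED_NAMES
N_REPORTED = len(REPORTED_NAMES)


@dataclass
class SpeciesRegistry:
    """Name resolution for dynamic species, totals and reported quantities."""

    names: Tuple[str, ...] = SPECIES
    derived_names: Tuple[str, ...] = DERIVED_NAMES
    laws: Tuple[ConservationLaw, ...] = CONSERVATION_LAWS
    index_of: Dict[str, int] = field(default_factory=lambda: dict(INDEX))

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate species names")
        if len(self.names) != 34:
            raise ValueError(f"expected 34 dynamic species, got {len(self.names)}")
        if len(self.names) + len(self.derived_names) != 50:
            raise ValueError("dynamic + derived quantities must total 50")
        for law in self.laws:
            for member, _ in law.members:
                if member not in self.index_of:
                    raise ValueError(f"conservation law {law.name!r} references "
                                     f"unknown species {member!r}")

    def reported_index(self, name: str) -> int:
        try:
            return REPORTED_NAMES.index(name)
        except ValueError:
            raise KeyError(f"unknown quantity {name!r}") from None


DEFAULT_REGISTRY = SpeciesRegistry()


def load_conservation_table(path) -> Tuple[ConservationLaw, ...]:
    """Read a (total_name, member_species, stoichiometry) CSV into laws."""
    rows: Dict[str, List[Tuple[str, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.setdefault(rec["total_name"], []).append(
                (rec["member_species"], float(rec["stoichiometry"])))
    by_name = {law.name: law for law in CONSERVATION_LAWS}
    laws = []
    for name, members in rows.items():
        closed = by_name[name].closed if name in by_name else False
        laws.append(_law(name, members, closed))
    return tuple(laws)


def write_conservation_table(path, laws=CONSERVATION_LAWS) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["total_name", "member_species", "stoichiometry"])
        for law in laws:
            for member, stoich in law.members:
                writer.writerow([law.name, member, stoich])
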