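"""Synthetic cancer cell-line panels and in-silico CRISPR essentiality.

The fixture generator emulates the shape of a public mutation-matrix
export (one row per cell line x mutated gene): TP53 is the most
frequently mutated gene, ATM/ATR follow, and co-mutated pairs such as
ATM+TP53 occur at the product of the marginal rates.  Lines are grouped
by mutated gene (15 single-gene groups) plus any requested pairs.

A mutation carried by a line is translated into parameter edits under
the convention that every modelled line keeps cycling: mutations in
genes that are dispensable for the cycle zero the synthesis rate, while
mutations in cycle-essential genes only reduce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .perturb import GENE_MAP, MODEL_GENES, make_mutant
from .simulate import (ASSESS_WINDOW_H, BURN_IN_H, IntegrationError,
                       classify_phenotype, estimate_period, integrate)

__all__ = ["CellLineGroup", "EssentialityMatrix", "DEFAULT_MUTATION_RATES",
           "generate_cellline_fixture", "group_cell_lines",
           "build_essentiality_heatmap", "mutation_edits"]

#: genes whose complete loss arrests the cycle; cell-line mutations in
#: these are modelled as a reduction, never a full knockout
CYCLE_ESSENTIAL = {"CCNB1", "CDC25A", "WEE1", "PLK1", "PP2A", "ANAPC1", "CDC20"}

#: synthesis fraction kept for a mutated cycle-essential gene; chosen so
#: that every modelled line keeps cycling (the Cdc25 axis tolerates only
#: modest reduction)
ESSENTIAL_MUTATION_FACTOR = 0.8

#: per-gene mutation probabilities for the synthetic panel; TP53 dominates,
#: ATM and ATR-like damage genes follow, roughly mirroring the frequency
#: ordering reported for public cancer-line panels
DEFAULT_MUTATION_RATES: Dict[str, float] = {
    "TP53": 0.62, "ATM": 0.15, "CDKN1A": 0.05, "CCNB1": 0.04,
    "CDC25A": 0.04, "WEE1": 0.04, "PLK1": 0.015, "PP2A": 0.05,
    "ANAPC1": 0.04, "CDC20": 0.03, "CDH1": 0.05, "PTTG1": 0.03,
    "MDM2": 0.05, "PPM1D": 0.04, "MAD2L1": 0.03,
}


@dataclass(frozen=True)
class CellLineGroup:
    label: str
    members: Tuple[str, ...]
    mutations: Tuple[str, ...]

    def __post_init__(self):
        if not self.mutations:
            raise ValueError("a cell-line group needs at least one mutation")
        for g in self.mutations:
            if g not in GENE_MAP:
                raise KeyError(f"unknown gene {g!r}")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EssentialityMatrix:
    """Binary knockout outcome per (target gene, cell-line group)."""

    targets: List[str]
    groups: List[str]
    essential: pd.DataFrame          # bool, index=targets, columns=groups
    calls: pd.DataFrame              # long-format phenotype calls

    def to_frame(self) -> pd.DataFrame:
        return self.essential.copy()


def generate_cellline_fixture(n_lines: int = 500,
                              rates: Optional[Dict[str, float]] = None,
                              seed: int = 0) -> pd.DataFrame:
    """Seeded synthetic mutation matrix: (cell_line_id, gene, mutation_flag).

    Genes mutate independently with the given per-gene probabilities;
    lines with no mutation are recorded with an empty gene field so the
    panel size is preserved.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rates = dict(DEFAULT_MUTATION_RATES if rates is None else rates)
    for gene, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"mutation rate for {gene} must be in [0,1]")
        if gene not in GENE_MAP:
            raise KeyError(f"unknown gene {gene!r}")
    rng = np.random.default_rng(seed)
    genes = sorted(rates)
    draws = rng.random((n_lines, len(genes)))
    rows = []
    for i in range(n_lines):
        line = f"SYN-{i:04d}"
        hit = [g for j, g in enumerate(genes) if draws[i, j] < rates[g]]
        if hit:
            for g in hit:
                rows.append((line, g, 1))
        else:
            rows.append((line, "", 0))
    return pd.DataFrame(rows, columns=["cell_line_id", "gene", "mutation_flag"])


def group_cell_lines(matrix: pd.DataFrame,
                     pair_groups: Sequence[Tuple[str, str]] = (("ATM", "TP53"),)
                     ) -> List[CellLineGroup]:
    """Single-gene groups for the 15 model genes plus requested pairs."""
    mutated = matrix[matrix["mutation_flag"] == 1]
    by_line: Dict[str, set] = {}
    for line, gene in zip(mutated["cell_line_id"], mutated["gene"]):
        by_line.setdefault(line, set()).add(gene)
    groups = []
    for gene in MODEL_GENES:
        members = tuple(sorted(l for l, gs in by_line.items() if gene in gs))
        if members:
            groups.append(CellLineGroup(gene, members, (gene,)))
    for a, b in pair_groups:
        members = tuple(sorted(l for l, gs in by_line.items()
                               if a in gs and b in gs))
        if members:
            groups.append(CellLineGroup(f"{a}+{b}", members, (a, b)))
    return groups


def mutation_edits(params: ParameterSet, mutations: Iterable[str]
                   ) -> Tuple[ParameterSet, Dict[str, float]]:
    """Parameter edits for a line's mutation profile (cycling preserved)."""
    ps = params
    overrides: Dict[str, float] = {}
    for gene in mutations:
        m = GENE_MAP[gene]
        if gene in CYCLE_ESSENTIAL:
            ps = ps.with_edits({m.parameter: params[m.parameter]
                                * ESSENTIAL_MUTATION_FACTOR})
        else:
            ps = ps.with_edits({m.parameter: 0.0})
            if m.parameter == "k_s28":
                overrides["p53"] = 0.0
    return ps, overrides


def build_essentiality_heatmap(params: ParameterSet,
                               groups: Sequence[CellLineGroup],
                               targets: Sequence[str] = MODEL_GENES,
                               t_end: float = BURN_IN_H + ASSESS_WINDOW_H
                               ) -> EssentialityMatrix:
    """CRISPR-knockout phenotype per (target, group), plus a control column.

    A knockout is *essential* in a group when the resulting simulation
    shows cell cycle arrest (no division cycle detected); the control
    column applies no knockout and must come out cycling for every group.
    """
    ref = integrate(params, t_end=t_end)
    ref_period = estimate_period(ref, species="MPF")
    mpf_peak = float(ref.species("MPF").max())
    records = []
    ess: Dict[str, Dict[str, bool]] = {}
    for group in groups:
        base, overrides = mutation_edits(params, group.mutations)
        for target in list(targets) + [None]:
            label = target if target else "control"
            try:
                if target is not None:
                    ps, io = make_mutant(base, [target], mode="crispr")
                    ov = dict(overrides)
                    ov.update(io)
                else:
                    ps, ov = base, overrides
                res = integrate(ps, t_end=t_end, init_overrides=ov)
                call = classify_phenotype(res, ref_period, mpf_peak)
                essential = not call.viable
            except IntegrationError:
                call, essential = None, True
            ess.setdefault(label, {})[group.label] = essential
            records.append(dict(
                group=group.label, target=label, essential=essential,
                viable=None if call is None else call.viable,
                tm_over_t=None if call is None else call.tm_over_t,
                arrest_class=None if call is None else call.arrest_class))
    cols = [g.label for g in groups]
    target_rows = list(targets) + ["control"]
    mat = pd.DataFrame({c: [ess[t][c] for t in target_rows] for c in cols},
                       index=target_rows)
    return EssentialityMatrix(list(target_rows), cols, mat,
                              pd.DataFrame(records))
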