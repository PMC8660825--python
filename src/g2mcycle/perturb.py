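"""Gene-level perturbations: deletions, CRISPR knockouts, depletions.

Perturbations act on synthesis rate constants.  A uniquely mapped gene is
knocked out by zeroing its synthesis rate; a gene that is one of several
paralogs encoding a model component (cyclin B, Cdc25, ATM/ATR) or one
subunit of the APC/C only reduces or disrupts the component according to
its mapping.  TP53 deletion additionally clears the p53 initial
condition, matching the p53-null simulation protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .scenarios import Scenario, make_scenario
from .simulate import (ASSESS_WINDOW_H, BURN_IN_H, IntegrationError,
                       PhenotypeCall, classify_phenotype, estimate_period,
                       integrate)

__all__ = ["GeneMapping", "GENE_MAP", "PerturbationSpec", "make_mutant",
           "plk1_depletion_scan", "response_surface", "mutant_table",
           "load_mutant_definitions", "DEFAULT_FAMILY_FACTOR"]

#: fraction of the synthesis rate kept when one of several paralogs is lost
DEFAULT_FAMILY_FACTOR = 0.5


@dataclass(frozen=True)
class GeneMapping:
    gene: str
    component: str
    parameter: str
    family: bool = False        # one of several paralogs -> scale, not zero
    complex_subunit: bool = False  # subunit loss disrupts the whole complex


def _mappings() -> Dict[str, GeneMapping]:
    entries = [
        GeneMapping("CCNB1", "Cyclin B", "k_s1", family=True),
        GeneMapping("CCNB2", "Cyclin B", "k_s1", family=True),
        GeneMapping("CDKN1A", "p21", "k_s5"),
        GeneMapping("CDC25A", "Cdc25", "k_s8", family=True),
        GeneMapping("CDC25B", "Cdc25", "k_s8", family=True),
        GeneMapping("WEE1", "Wee1", "k_s9"),
        GeneMapping("PLK1", "Plk1", "k_s12"),
        GeneMapping("PP2A", "PP2A", "k_s13"),
        GeneMapping("ANAPC1", "APC/C", "k_s15", complex_subunit=True),
        GeneMapping("CDC27", "APC/C", "k_s15", complex_subunit=True),
        GeneMapping("CDC23", "APC/C", "k_s15", complex_subunit=True),
        GeneMapping("CDC16", "APC/C", "k_s15", complex_subunit=True),
        GeneMapping("CDC20", "Cdc20", "k_s17"),
        GeneMapping("CDH1", "Cdh1", "k_s20"),
        GeneMapping("PTTG1", "Pttg1", "k_s24"),
        GeneMapping("ATM", "ATM/ATR", "k_s27", family=True),
        GeneMapping("ATR", "ATM/ATR", "k_s27", family=True),
        GeneMapping("TP53", "p53", "k_s28"),
        GeneMapping("MDM2", "Mdm2", "k_s31"),
        GeneMapping("PPM1D", "Wip1", "k_s32"),
        GeneMapping("MAD2L1", "Mad2", "k_s33"),
        # whole-component aliases used by the mutant tables ("cdc25-null"
        # removes the entire family)
        GeneMapping("CCNB", "Cyclin B", "k_s1"),
        GeneMapping("CDC25", "Cdc25", "k_s8"),
        GeneMapping("ATM/ATR", "ATM/ATR", "k_s27"),
    ]
    return {e.gene: e for e in entries}


GENE_MAP: Dict[str, GeneMapping] = _mappings()

#: the 15 model genes/components used for cell-line grouping
MODEL_GENES = ("CCNB1", "CDKN1A", "CDC25A", "WEE1", "PLK1", "PP2A", "ANAPC1",
               "CDC20", "CDH1", "PTTG1", "ATM", "TP53", "MDM2", "PPM1D",
               "MAD2L1")


@dataclass
class PerturbationSpec:
    """A named set of parameter edits plus initial-condition overrides."""

    edits: List[Tuple[str, str, float]] = field(default_factory=list)
    init_overrides: Dict[str, float] = field(default_factory=dict)
    label: str = ""

    def apply(self, base: ParameterSet) -> ParameterSet:
        merged: Dict[str, float] = {}
        for symbol, action, value in self.edits:
            if action == "set_zero":
                new = 0.0
            elif action == "scale":
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"scale factor for {symbol} must be in [0,1]")
                new = base[symbol] * value
            elif action == "set_value":
                new = value
            else:
                raise ValueError(f"unknown action {action!r}")
            if symbol in merged and not math.isclose(merged[symbol], new):
                raise ValueError(f"contradictory edits to {symbol}")
            merged[symbol] = new
        return base.with_edits(merged)


def make_mutant(base: ParameterSet, genes: Sequence[str],
                mode: str = "deletion", level: float = 0.0,
                family_factor: float = DEFAULT_FAMILY_FACTOR
                ) -> Tuple[ParameterSet, Dict[str, float]]:
    """Translate gene perturbations into a mutated parameter set.

    ``mode`` is ``deletion`` (zero the component), ``crispr`` (zero a
    uniquely mapped gene, scale a paralog-family gene by
    ``family_factor``; a complex subunit still disrupts the whole
    complex) or ``depletion`` (scale by ``1 - level``).  Edits compose
    across genes; contradictory edits to one symbol raise.
    """
    spec = PerturbationSpec(label="+".join(genes))
    for gene in genes:
        if gene not in GENE_MAP:
            raise KeyError(f"unknown gene {gene!r}")
        m = GENE_MAP[gene]
        if mode == "deletion":
            spec.edits.append((m.parameter, "set_zero", 0.0))
        elif mode == "crispr":
            if m.family and not m.complex_subunit:
                spec.edits.append((m.parameter, "scale", family_factor))
            else:
                spec.edits.append((m.parameter, "set_zero", 0.0))
        elif mode == "depletion":
            if not 0.0 <= level <= 1.0:
                raise ValueError("depletion level must be in [0, 1]")
            spec.edits.append((m.parameter, "scale", 1.0 - level))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if m.parameter == "k_s28" and mode in ("deletion", "crispr"):
            spec.init_overrides["p53"] = 0.0
    return spec.apply(base), dict(spec.init_overrides)


def _reference(params: ParameterSet, scenario: Scenario,
               t_end: float = BURN_IN_H + ASSESS_WINDOW_H):
    ps = scenario.apply(params)
    res = integrate(ps, t_end=t_end, init_overrides=scenario.init_overrides)
    period = estimate_period(res, species="MPF")
    mpf_peak = float(res.species("MPF").max())
    return period, mpf_peak


def plk1_depletion_scan(params: ParameterSet, background: str = "p53-wt",
                        levels: Iterable[int] = range(10, 101, 10),
                        t_end: float = BURN_IN_H + ASSESS_WINDOW_H
                        ) -> pd.DataFrame:
    """Phenotype vs Plk1-synthesis depletion level, one row per level.

    The normalized period is T_depleted / T_unperturbed within the same
    p53 background.
    """
    if background not in ("p53-wt", "p53-null"):
        raise ValueError("background must be 'p53-wt' or 'p53-null'")
    scen0 = make_scenario(background == "p53-null", 0.0)
    ref_period, mpf_peak = _reference(params, scen0, t_end)
    rows = []
    for level in levels:
        scen = make_scenario(background == "p53-null", level / 100.0)
        try:
            res = integrate(scen.apply(params), t_end=t_end,
                            init_overrides=scen.init_overrides)
            call = classify_phenotype(res, ref_period, mpf_peak)
            rows.append(dict(level=level, viable=call.viable,
                             period_h=call.period,
                             normalized_period=call.tm_over_t,
                             arrest_class=call.arrest_class,
                             mad2cdc20p_mean=call.mad2cdc20p_mean))
        except IntegrationError as exc:   # keep scanning past a bad row
            rows.append(dict(level=level, viable=None, period_h=None,
                             normalized_period=None,
                             arrest_class=f"integration-error: {exc}",
                             mad2cdc20p_mean=float("nan")))
    return pd.DataFrame(rows)


def response_surface(params: ParameterSet,
                     ks28_grid: Sequence[float],
                     ks12_grid: Sequence[float],
                     ks33_grid: Sequence[float],
                     t_end: float = 250.0) -> pd.DataFrame:
    """Time-averaged Mad2:Cdc20P over a (k_s28, k_s12, k_s33) grid."""
    rows = []
    for ks28 in ks28_grid:
        for ks12 in ks12_grid:
            for ks33 in ks33_grid:
                if min(ks28, ks12, ks33) < 0:
                    raise ValueError("synthesis rates must be non-negative")
                edits = {"k_s28": ks28, "k_s12": ks12, "k_s33": ks33}
                io = {"p53": 0.0} if ks28 == 0 else None
                try:
                    res = integrate(params.with_edits(edits), t_end=t_end,
                                    init_overrides=io)
                    tail = res.window(BURN_IN_H, res.times[-1])
                    value = float(tail.species("Mad2:Cdc20P").mean())
                except IntegrationError:
                    value = float("nan")
                rows.append(dict(k_s28=ks28, k_s12=ks12, k_s33=ks33,
                                 mad2cdc20p_mean=value))
    return pd.DataFrame(rows)


def load_mutant_definitions() -> pd.DataFrame:
    """The bundled mutant panel with the expected phenotype pattern."""
    ref = resources.files("g2mcycle.data").joinpath("mutant_panel.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


_BACKGROUNDS = (
    ("p53-wt", False, 0.0),
    ("p53-null", True, 0.0),
    ("p53-wt plk1-depleted", False, 0.30),
    ("p53-null plk1-depleted", True, 0.30),
)


def mutant_table(params: ParameterSet,
                 mutants: Optional[pd.DataFrame] = None,
                 depletion: float = 0.30,
                 t_end: float = BURN_IN_H + ASSESS_WINDOW_H) -> pd.DataFrame:
    """Phenotype calls for the mutant panel in all four backgrounds.

    Backgrounds cross p53 status with 30% Plk1 depletion; each T_m/T is
    computed against that background's unperturbed reference period.
    """
    if mutants is None:
        mutants = load_mutant_definitions()
    refs = {}
    for label, p53_null, depl in _BACKGROUNDS:
        scen = make_scenario(p53_null, depl if depl else 0.0)
        refs[label] = (_reference(params, scen), scen)
    rows = []
    for _, mrow in mutants.iterrows():
        genes = [g for g in str(mrow["genes"]).split(";") if g]
        for label, p53_null, depl in _BACKGROUNDS:
            (ref_period, mpf_peak), scen = refs[label]
            try:
                ps, io = make_mutant(params, genes, mode="deletion")
                ps = make_scenario(p53_null, depl).apply(ps)
                overrides = dict(scen.init_overrides or {})
                overrides.update(io)
                res = integrate(ps, t_end=t_end, init_overrides=overrides)
                call = classify_phenotype(res, ref_period, mpf_peak)
                rows.append(dict(
                    mutant=mrow["label"], genes=mrow["genes"],
                    background=label, viable=call.viable,
                    period_h=call.period, tm_over_t=call.tm_over_t,
                    arrest_class=call.arrest_class,
                    mad2cdc20p_mean=call.mad2cdc20p_mean))
            except IntegrationError as exc:
                rows.append(dict(mutant=mrow["label"], genes=mrow["genes"],
                                 background=label, viable=None, period_h=None,
                                 tm_over_t=None,
                                 arrest_class=f"integration-error: {exc}",
                                 mad2cdc20p_mean=float("nan")))
    return pd.DataFrame(rows)
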