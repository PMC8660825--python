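"""The kinetic parameter set: 137 named rate/threshold constants plus tau.

Parameters are keyed by the field's conventional symbols: ``k_s*`` synthesis
rates, ``k_f*``/``k_r*`` forward/reverse rate constants per reaction,
``k_d*`` degradation constants (``k_dn.m`` when the route is catalysed by
another factor such as APC/CP:Cdc20 or APC/CT:Cdh1), ``K_*``
Michaelis/threshold constants, the disassembly weighting ``eps`` and the
DNA-damage-signal constants.  All rates are h^-1 on the relative
concentration scale (total CDK1 = 1); ``tau`` is the dimensionless
timescale (default 1.65, which sets the wild-type cell cycle period to
48 h).

The canonical value source is the bundled two-column CSV
(``data/parameters.csv``); :func:`build_default_parameters` reads it and
fails loudly on any missing, unknown or negative entry.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Mapping, Optional

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "KINETIC_PARAM_NAMES",
    "N_KINETIC",
    "SYNTHESIS_PARAMS",
    "ParameterSet",
    "ConfigurationError",
    "build_default_parameters",
]


class ConfigurationError(ValueError):
    """Raised when a parameter table is incomplete or invalid."""


#: the 15 protein-synthesis rate constants (one per synthesised component)
SYNTHESIS_PARAMS = (
    "k_s1", "k_s5", "k_s8", "k_s9", "k_s12", "k_s13", "k_s15", "k_s17",
    "k_s20", "k_s24", "k_s27", "k_s28", "k_s31", "k_s32", "k_s33",
)

_SYNTHESIS_EXTRA = ("k_s31.1", "k_s32.1")  # p53P-induced Mdm2/Wip1 synthesis

_FORWARD_REVERSE = (
    "k_f1",                    # CyclinB + CDK1 -> MPF (binding)
    "k_f2", "k_f2.1", "k_r2",  # Wee1 (and residual Wee1P) / Cdc25P cycle on MPF
    "k_f3", "k_r3",            # Cdc25 <-> Cdc25P
    "k_f4", "k_f4.1", "k_r4", "k_r4.1",  # Wee1 <-> Wee1P (MPF/Plk1P off; PP2A/basal on)
    "k_f5", "k_r5",            # 3 p21 + MPF <-> p21:MPF (k_f5 releases)
    "k'_f6", "k_r6",           # Plk1 <-> Plk1P (MPF-driven, ATM/ATR-gated)
    "k_f7", "k_r7",            # PP2A <-> PP2AP
    "k_f8", "k_f8.1", "k_r8", "k_r8.1",  # APC/C <-> APC/CP (MPF, Plk1P; PP2A back)
    "k_f9", "k_r9",            # Cdc20 <-> Cdc20P (k_r9 phosphorylates)
    "k_f10", "k_r10",          # APC/CP + Cdc20 <-> APC/CP:Cdc20
    "k_f11", "k_r11",          # APC/C <-> APC/CT
    "k_f12", "k_r12",          # APC/CT + Cdh1 <-> APC/CT:Cdh1
    "k_f13", "k_r13", "k_r13.1",  # Cdh1 <-> Cdh1P (MPF; PP2A and basal back)
    "k_f14",                   # MPF ejects Cdh1 from APC/CT:Cdh1 (-> Cdh1P)
    "k_f15", "k_r15",          # Pttg1 + Separase <-> Pttg1:Separase
    "k_f16", "k_r16",          # p53 <-> p53P
    "k_f17", "k_r17",          # p53P + Plk1P <-> p53P:Plk1P
    "k_f18", "k'_r18",         # Mad2 + Cdc20P <-> Mad2:Cdc20P
)

_DEGRADATION = (
    "k_d1.1", "k_d1.2", "k_d1.3",     # CyclinB (basal, APC/CP:Cdc20, APC/CT:Cdh1)
    "k_d2.1", "k_d2.2", "k_d2.3",     # MPF (cyclin moiety)
    "k_d3.1", "k_d3.2", "k_d3.3",     # preMPF (cyclin moiety)
    "k_d5",                           # p21
    "k_d6",                           # p21:MPF (cyclin + p21 moieties)
    "k_d7.1", "k_d7.3",               # Cdc25P
    "k_d8.1", "k_d8.3",               # Cdc25
    "k_d9",                           # Wee1
    "k_d10.1", "k_d10.2",             # Wee1P (basal, Plk1P-promoted)
    "k_d11.1", "k_d11.3",             # Plk1P
    "k_d12.1", "k_d12.3",             # Plk1
    "k_d13",                          # PP2A
    "k_d14",                          # PP2AP
    "k_d15",                          # APC/C
    "k_d16.1", "k_d16.3",             # APC/CP
    "k_d17.1", "k_d17.2", "k_d17.3",  # Cdc20
    "k_d18.1", "k_d18.3",             # Cdc20P
    "k_d19.1", "k_d19.3",             # Cdc20 moiety inside APC/CP:Cdc20
    "k_d20",                          # Cdh1
    "k_d21",                          # Cdh1P
    "k_d22",                          # APC/CT
    "k_d23",                          # APC/CT:Cdh1
    "k_d24.1", "k_d24.2",             # Pttg1 (basal, APC/CP:Cdc20)
    "k_d26.2",                        # Pttg1 moiety inside Pttg1:Separase
    "k_d27", "k_d27.1",               # ATM/ATR (basal, Wip1-promoted)
    "k_d28", "k_d28.1",               # p53 (basal, Mdm2-promoted)
    "k_d29", "k_d29.1",               # p53P (basal, Mdm2-promoted)
    "k_d31", "k_d31.1",               # Mdm2 (basal, ATM/ATR-promoted)
    "k_d32",                          # Wip1
    "k_d33",                          # Mad2
)

_MICHAELIS = (
    "K_p53", "K_A1", "K_A2", "K_A3",
    "K_Cdc25P1", "K_Cdc25P2", "K_Cdc25",
    "K_Plk1", "K_Plk1P1", "K_Plk1P2",
    "K_Cdc20", "K_Cdc20P1", "K_Cdc20P2",
    "K_Wip1", "K_MCD", "K_DDS",
    "K_CycB1", "K_CycB2", "K_MPF1", "K_MPF2", "K_preMPF",
    "K_Pttg1", "K_Sep", "K_Wee1",
)

_DDS = ("dds_gain", "dds_act", "dds_arrest", "dds_decay")

KINETIC_PARAM_NAMES = (
    SYNTHESIS_PARAMS + _SYNTHESIS_EXTRA + _FORWARD_REVERSE + _DEGRADATION
    + _MICHAELIS + ("eps",) + _DDS
)
N_KINETIC = len(KINETIC_PARAM_NAMES)

PARAM_NAMES = KINETIC_PARAM_NAMES + ("tau",)

#: symbol -> position in the packed parameter vector used by the RHS
PARAM_INDEX: Dict[str, int] = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass
class ParameterSet:
    """Complete, validated set of the 137 kinetic constants plus tau.

    The set is the single source of truth mutated by perturbations; use
    :meth:`with_edits` to derive mutants without touching the original.
    """

    values: Dict[str, float]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        missing = [n for n in PARAM_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in PARAM_INDEX]
        if missing or extra:
            parts = []
            if missing:
                parts.append("missing symbols: " + ", ".join(sorted(missing)))
            if extra:
                parts.append("unknown symbols: " + ", ".join(sorted(extra)))
            raise ConfigurationError("; ".join(parts))
        for name, value in self.values.items():
            if not math.isfinite(value):
                raise ConfigurationError(f"parameter {name} is not finite")
            if value < 0:
                raise ConfigurationError(f"parameter {name} is negative ({value})")
        if self.values["tau"] <= 0:
            raise ConfigurationError("tau must be positive")

    # -- access --------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.values == other.values

    @property
    def tau(self) -> float:
        return self.values["tau"]

    def as_array(self) -> np.ndarray:
        """Pack values into the fixed PARAM_NAMES order for the RHS."""
        return np.array([self.values[n] for n in PARAM_NAMES], dtype=float)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values))

    def with_edits(self, edits: Mapping[str, float]) -> "ParameterSet":
        unknown = [k for k in edits if k not in PARAM_INDEX]
        if unknown:
            raise ConfigurationError("unknown symbols: " + ", ".join(sorted(unknown)))
        merged = dict(self.values)
        merged.update({k: float(v) for k, v in edits.items()})
        return ParameterSet(merged)

    def fingerprint(self) -> str:
        import hashlib

        payload = ",".join(f"{n}={self.values[n]!r}" for n in PARAM_NAMES)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- serialisation -------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["symbol", "value"])
            for name in PARAM_NAMES:
                writer.writerow([name, repr(self.values[name])])

    @classmethod
    def from_csv(cls, path) -> "ParameterSet":
        values: Dict[str, float] = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                try:
                    values[rec["symbol"]] = float(rec["value"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise ConfigurationError(f"bad row in {path}: {rec}") from exc
        return cls(values)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({n: float(self.values[n]) for n in PARAM_NAMES}, fh,
                           sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path} is not a flat symbol:value mapping")
        return cls({str(k): float(v) for k, v in raw.items()})


def _default_table_path():
    return resources.files("g2mcycle.data").joinpath("parameters.csv")


def build_default_parameters(source: Optional[object] = None) -> ParameterSet:
    """Load the calibrated parameter table (CSV or YAML by extension).

    With ``source=None`` the bundled table is used; it carries tau = 1.65
    so that the wild-type cell cycle period is 48 h.
    """
    if source is None:
        with resources.as_file(_default_table_path()) as path:
            return ParameterSet.from_csv(path)
    source = str(source)
    if source.endswith((".yml", ".yaml")):
        return ParameterSet.from_yaml(source)
    return ParameterSet.from_csv(source)
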