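"""Right-hand side of the coupled cell-cycle / G2/M-checkpoint ODE system.

The model couples three layers:

* the mitotic oscillator — cyclin B synthesis, CDK1 binding, the
  Wee1/Cdc25 phosphorylation switch on MPF, Plk1 activation by MPF, and
  cyclin destruction by the two APC/C holoenzymes (APC/CP:Cdc20 at
  mitotic exit, APC/CT:Cdh1 through G1);
* the spindle/mitotic checkpoint proxy — Mad2 binding phosphorylated
  Cdc20 into the Mad2:Cdc20P complex, whose disassembly is promoted by
  p21 and active Plk1 through the shared factor
  ``(1 + [p21]/K_MCD + eps*[Plk1P]/K_MCD)``;
* the G2/M DNA damage checkpoint — a Mad2:Cdc20P-driven damage signal
  feeding ATM/ATR synthesis, the p53-Mdm2-Wip1 negative-feedback
  oscillator, p53-induced p21, ATM/ATR repression of Cdc25 synthesis and
  of Plk1 activation, and Plk1P sequestration of active p53.

All concentrations are dimensionless (relative to total CDK1 = 1), time
is in hours, and the timescale parameter enters as ``dX/dt = tau * f(X)``
so the cell cycle period scales exactly as 1/tau.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .dds import DdsState, dds_value
from .parameters import PARAM_INDEX, ParameterSet
from .registry import CONSERVATION_LAWS, INDEX, N_REPORTED, N_SPECIES

__all__ = ["rhs_full", "rhs_core", "rhs_p53_module", "derived_quantities",
           "numerical_jacobian", "P53_MODULE_SPECIES", "P53_MODULE_DAMAGE_SIG"]

# -- packed indices ----------------------------------------------------

_PI = PARAM_INDEX


def _p(name: str) -> int:
    return _PI[name]


_SI = INDEX

iCycB, iMPF, ipreMPF, iCDK1 = _SI["CyclinB"], _SI["MPF"], _SI["preMPF"], _SI["CDK1"]
ip21, ip21MPF = _SI["p21"], _SI["p21:MPF"]
iCdc25P, iCdc25 = _SI["Cdc25P"], _SI["Cdc25"]
iWee1, iWee1P = _SI["Wee1"], _SI["Wee1P"]
iPlk1P, iPlk1 = _SI["Plk1P"], _SI["Plk1"]
iPP2A, iPP2AP = _SI["PP2A"], _SI["PP2AP"]
iAPC, iAPCP = _SI["APC/C"], _SI["APC/CP"]
iCdc20, iCdc20P, iA20 = _SI["Cdc20"], _SI["Cdc20P"], _SI["APC/CP:Cdc20"]
iCdh1, iCdh1P, iAPCT, iACdh1 = (_SI["Cdh1"], _SI["Cdh1P"], _SI["APC/CT"],
                                _SI["APC/CT:Cdh1"])
iPttg1, iSep, iPttgSep = _SI["Pttg1"], _SI["Separase"], _SI["Pttg1:Separase"]
iATM, ip53, ip53P, ip53PPlk1P = (_SI["ATM/ATR"], _SI["p53"], _SI["p53P"],
                                 _SI["p53P:Plk1P"])
iMdm2, iWip1, iMad2, iMCC = (_SI["Mdm2"], _SI["Wip1"], _SI["Mad2"],
                             _SI["Mad2:Cdc20P"])

#: order of the standalone p53-module state vector
P53_MODULE_SPECIES = ("ATM/ATR", "p53", "p53P", "Mdm2", "Wip1")

#: default damage stimulus for the standalone module: the signal strength
#: produced by a mitotic checkpoint complex level of 0.5 (mid-activation)
P53_MODULE_DAMAGE_SIG = 28.0


def rhs_core(t: float, y: np.ndarray, p: np.ndarray,
             sig_override: Optional[float] = None) -> np.ndarray:
    """Packed-array RHS; ``p`` is ``ParameterSet.as_array()``.

    The damage signal is recomputed algebraically from the instantaneous
    Mad2:Cdc20P level on every call (no delay state); ``sig_override``
    pins Sig to a constant, which the standalone p53 module and some
    scenario experiments use.
    """
    tau = p[_PI["tau"]]

    CycB, MPF, preMPF, CDK1 = y[iCycB], y[iMPF], y[ipreMPF], y[iCDK1]
    p21, p21MPF = y[ip21], y[ip21MPF]
    Cdc25P, Cdc25 = y[iCdc25P], y[iCdc25]
    Wee1, Wee1P = y[iWee1], y[iWee1P]
    Plk1P, Plk1 = y[iPlk1P], y[iPlk1]
    PP2A, PP2AP = y[iPP2A], y[iPP2AP]
    APC, APCP = y[iAPC], y[iAPCP]
    Cdc20, Cdc20P, A20 = y[iCdc20], y[iCdc20P], y[iA20]
    Cdh1, Cdh1P, APCT, ACdh1 = y[iCdh1], y[iCdh1P], y[iAPCT], y[iACdh1]
    Pttg1, Sep, PttgSep = y[iPttg1], y[iSep], y[iPttgSep]
    ATM, p53, p53P, p53PPlk1P = y[iATM], y[ip53], y[ip53P], y[ip53PPlk1P]
    Mdm2, Wip1, Mad2, MCC = y[iMdm2], y[iWip1], y[iMad2], y[iMCC]

    g = p  # brevity

    # damage signal (algebraic, from the instantaneous MCC level)
    if sig_override is None:
        dds = dds_value(max(MCC, 0.0), gain=g[_PI["dds_gain"]],
                        activation_threshold=g[_PI["dds_act"]],
                        arrest_threshold=g[_PI["dds_arrest"]])
        sig = dds * math.exp(-g[_PI["dds_decay"]] * t)
    else:
        sig = sig_override

    dy = np.empty(N_SPECIES)

    # ---- cyclin B / MPF core -----------------------------------------
    v_bind = g[_PI["k_f1"]] * CycB * CDK1
    wee_act = (g[_PI["k_f2"]] * Wee1 + g[_PI["k_f2.1"]] * Wee1P) * MPF
    cdc25_act = g[_PI["k_r2"]] * Cdc25P * preMPF
    p21_bind = g[_PI["k_r5"]] * MPF * p21 ** 3 - g[_PI["k_f5"]] * p21MPF
    deg_CycB = (g[_PI["k_d1.1"]]
                + g[_PI["k_d1.2"]] * A20 / (g[_PI["K_CycB1"]] + CycB)
                + g[_PI["k_d1.3"]] * ACdh1 / (g[_PI["K_CycB2"]] + CycB)) * CycB
    deg_MPF = (g[_PI["k_d2.1"]]
               + g[_PI["k_d2.2"]] * A20 / (g[_PI["K_MPF1"]] + MPF)
               + g[_PI["k_d2.3"]] * ACdh1 / (g[_PI["K_MPF2"]] + MPF)) * MPF
    deg_pre = (g[_PI["k_d3.1"]]
               + g[_PI["k_d3.2"]] * A20 / (g[_PI["K_preMPF"]] + preMPF)
               + g[_PI["k_d3.3"]] * ACdh1 / (g[_PI["K_preMPF"]] + preMPF)) * preMPF
    deg_p21MPF = g[_PI["k_d6"]] * p21MPF

    dy[iCycB] = g[_PI["k_s1"]] - v_bind - deg_CycB
    dy[iMPF] = v_bind - wee_act + cdc25_act - p21_bind - deg_MPF
    dy[ipreMPF] = wee_act - cdc25_act - deg_pre
    dy[iCDK1] = -v_bind + deg_MPF + deg_pre + deg_p21MPF

    # p21 (in-text equation: p53-induced synthesis, cubic MPF binding)
    dy[ip21] = (g[_PI["k_s5"]] * (1.0 + p53 / g[_PI["K_p53"]])
                + 3.0 * (g[_PI["k_f5"]] * p21MPF
                         - g[_PI["k_r5"]] * MPF * p21 ** 3)
                - g[_PI["k_d5"]] * p21)
    dy[ip21MPF] = p21_bind - deg_p21MPF

    # ---- Cdc25 switch -------------------------------------------------
    v3 = (g[_PI["k_f3"]] * Cdc25
          - g[_PI["k_r3"]] * Cdc25P / (g[_PI["K_Cdc25P1"]] + Cdc25P))
    dy[iCdc25] = (g[_PI["k_s8"]] * g[_PI["K_A2"]] / (g[_PI["K_A2"]] + ATM)
                  - v3
                  - (g[_PI["k_d8.1"]]
                     + g[_PI["k_d8.3"]] * ACdh1 / (g[_PI["K_Cdc25"]] + Cdc25))
                  * Cdc25)
    # active Cdc25 is destabilised by PP2A-bound dephosphorylation complexes,
    # so its turnover tracks interphase (high PP2A) rather than G1 only
    dy[iCdc25P] = v3 - (g[_PI["k_d7.1"]]
                        + g[_PI["k_d7.3"]] * PP2A
                        / (g[_PI["K_Cdc25P2"]] + Cdc25P)) * Cdc25P

    # ---- Wee1 ---------------------------------------------------------
    v4 = ((g[_PI["k_f4"]] * MPF + g[_PI["k_f4.1"]] * Plk1P) * Wee1
          - (g[_PI["k_r4"]] * PP2A + g[_PI["k_r4.1"]]) * Wee1P)
    dy[iWee1] = g[_PI["k_s9"]] - v4 - g[_PI["k_d9"]] * Wee1
    # inactivated Wee1 is degraded in an MPF-dependent manner, so the
    # mitotic state keeps its grip on Wee1 even when Plk1 is depleted
    dy[iWee1P] = v4 - (g[_PI["k_d10.1"]]
                       + g[_PI["k_d10.2"]] * MPF
                       / (g[_PI["K_Wee1"]] + Wee1P)) * Wee1P

    # ---- Plk1 (in-text equation for Plk1P) ----------------------------
    v6 = (g[_PI["k'_f6"]] * Plk1 * MPF
          * g[_PI["K_A1"]] / (g[_PI["K_A1"]] + ATM)
          - g[_PI["k_r6"]] * Plk1P / (g[_PI["K_Plk1P1"]] + Plk1P))
    v17 = g[_PI["k_f17"]] * p53P * Plk1P - g[_PI["k_r17"]] * p53PPlk1P
    dy[iPlk1P] = v6 - (g[_PI["k_d11.1"]]
                       + g[_PI["k_d11.3"]] * ACdh1
                       / (g[_PI["K_Plk1P2"]] + Plk1P)) * Plk1P - v17
    dy[iPlk1] = (g[_PI["k_s12"]] - v6
                 - (g[_PI["k_d12.1"]]
                    + g[_PI["k_d12.3"]] * ACdh1
                    / (g[_PI["K_Plk1"]] + Plk1)) * Plk1)

    # ---- PP2A ---------------------------------------------------------
    v7 = g[_PI["k_f7"]] * MPF * PP2A - g[_PI["k_r7"]] * PP2AP
    dy[iPP2A] = g[_PI["k_s13"]] - v7 - g[_PI["k_d13"]] * PP2A
    dy[iPP2AP] = v7 - g[_PI["k_d14"]] * PP2AP

    # ---- APC/C forms --------------------------------------------------
    v8 = ((g[_PI["k_f8"]] * MPF + g[_PI["k_f8.1"]] * Plk1P) * APC
          - (g[_PI["k_r8"]] * PP2A + g[_PI["k_r8.1"]]) * APCP)
    v11 = g[_PI["k_f11"]] * APC - g[_PI["k_r11"]] * MPF * APCT
    v10 = g[_PI["k_f10"]] * APCP * Cdc20 - g[_PI["k_r10"]] * A20
    rel_P = g[_PI["k_r9"]] * A20  # releases Cdc20P (phosphorylated in complex)
    deg_A20 = (g[_PI["k_d19.1"]] + g[_PI["k_d19.3"]] * ACdh1) * A20

    dy[iAPC] = g[_PI["k_s15"]] - v8 - v11 - g[_PI["k_d15"]] * APC
    dy[iAPCP] = (v8 - v10 + rel_P + deg_A20
                 - (g[_PI["k_d16.1"]] + g[_PI["k_d16.3"]] * ACdh1) * APCP)
    dy[iA20] = v10 - rel_P - deg_A20

    # ---- Cdc20 (in-text equation for Cdc20P) --------------------------
    mm_20P = g[_PI["k_f9"]] * Cdc20P / (g[_PI["K_Cdc20P1"]] + Cdc20P)
    D = 1.0 + p21 / g[_PI["K_MCD"]] + g[_PI["eps"]] * Plk1P / g[_PI["K_MCD"]]
    v18 = g[_PI["k_f18"]] * Mad2 * Cdc20P - g[_PI["k'_r18"]] * D * MCC
    dy[iCdc20] = (g[_PI["k_s17"]] - g[_PI["k_r9"]] * Cdc20 + mm_20P
                  - v10
                  - (g[_PI["k_d17.1"]] + g[_PI["k_d17.2"]] * A20
                     + g[_PI["k_d17.3"]] * ACdh1
                     / (g[_PI["K_Cdc20"]] + Cdc20)) * Cdc20)
    dy[iCdc20P] = (g[_PI["k_r9"]] * Cdc20 - mm_20P + rel_P - v18
                   - (g[_PI["k_d18.1"]]
                      + g[_PI["k_d18.3"]] * ACdh1
                      / (g[_PI["K_Cdc20P2"]] + Cdc20P)) * Cdc20P)

    # ---- Cdh1 ---------------------------------------------------------
    v13 = (g[_PI["k_f13"]] * MPF * Cdh1
           - (g[_PI["k_r13"]] * PP2A + g[_PI["k_r13.1"]]) * Cdh1P)
    v12 = g[_PI["k_f12"]] * APCT * Cdh1 - g[_PI["k_r12"]] * ACdh1
    eject = g[_PI["k_f14"]] * MPF * ACdh1
    dy[iCdh1] = g[_PI["k_s20"]] - v13 - v12 - g[_PI["k_d20"]] * Cdh1
    dy[iCdh1P] = v13 + eject - g[_PI["k_d21"]] * Cdh1P
    dy[iAPCT] = v11 - v12 + eject - g[_PI["k_d22"]] * APCT
    dy[iACdh1] = v12 - eject - g[_PI["k_d23"]] * ACdh1

    # ---- securin / separase ------------------------------------------
    v15 = g[_PI["k_f15"]] * Pttg1 * Sep - g[_PI["k_r15"]] * PttgSep
    rel_sep = g[_PI["k_d26.2"]] * A20 * PttgSep / (g[_PI["K_Sep"]] + PttgSep)
    dy[iPttg1] = (g[_PI["k_s24"]] - v15
                  - (g[_PI["k_d24.1"]]
                     + g[_PI["k_d24.2"]] * A20
                     / (g[_PI["K_Pttg1"]] + Pttg1)) * Pttg1)
    dy[iSep] = -v15 + rel_sep
    dy[iPttgSep] = v15 - rel_sep

    # ---- G2/M DNA damage checkpoint (in-text equations) ---------------
    w4 = Wip1 ** 4
    dy[iATM] = (g[_PI["k_s27"]] * (1.0 + g[_PI["K_DDS"]] * sig)
                - g[_PI["k_d27.1"]] * ATM * w4 / (g[_PI["K_Wip1"]] ** 4 + w4)
                - g[_PI["k_d27"]] * ATM)
    dy[ip53] = (g[_PI["k_s28"]] * (1.0 + ATM / g[_PI["K_A3"]])
                - g[_PI["k_f16"]] * p53 + g[_PI["k_r16"]] * p53P
                - g[_PI["k_d28.1"]] * p53 * Mdm2 - g[_PI["k_d28"]] * p53)
    dy[ip53P] = (g[_PI["k_f16"]] * p53 - g[_PI["k_r16"]] * p53P - v17
                 - g[_PI["k_d29.1"]] * p53P * Mdm2 - g[_PI["k_d29"]] * p53P)
    dy[ip53PPlk1P] = v17
    dy[iMdm2] = (g[_PI["k_s31"]] + g[_PI["k_s31.1"]] * p53P
                 - g[_PI["k_d31.1"]] * ATM * Mdm2 - g[_PI["k_d31"]] * Mdm2)
    dy[iWip1] = (g[_PI["k_s32"]] + g[_PI["k_s32.1"]] * p53P
                 - g[_PI["k_d32"]] * Wip1)
    dy[iMad2] = g[_PI["k_s33"]] - v18 - g[_PI["k_d33"]] * Mad2
    dy[iMCC] = v18

    dy *= tau
    return dy


def rhs_full(t: float, state: np.ndarray, params: ParameterSet,
             dds: Optional[DdsState] = None) -> np.ndarray:
    """Validated RHS taking a :class:`ParameterSet`.

    ``dds`` only carries the constants (gain/thresholds); the signal
    itself is recomputed from the instantaneous Mad2:Cdc20P level.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(f"state must have {N_SPECIES} entries, got {y.shape}")
    bad = np.flatnonzero(~np.isfinite(y))
    if bad.size:
        from .registry import SPECIES
        raise FloatingPointError(
            "non-finite state entries: " + ", ".join(SPECIES[i] for i in bad))
    return rhs_core(t, y, params.as_array())


def rhs_p53_module(t: float, state: np.ndarray, params: ParameterSet,
                   damage_on: bool = False,
                   sig: Optional[float] = None) -> np.ndarray:
    """Standalone p53-Mdm2-Wip1 checkpoint oscillator.

    State order is ``(ATM/ATR, p53, p53P, Mdm2, Wip1)``.  Plk1P and the
    cell-cycle couplings are held at zero.  With ``damage_on`` the Sig
    input is pinned to a constant (default
    :data:`P53_MODULE_DAMAGE_SIG`, the signal strength at a
    mid-activation checkpoint-complex level); without damage Sig = 0.
    """
    y5 = np.asarray(state, dtype=float)
    if y5.shape != (5,):
        raise ValueError(f"p53-module state must have 5 entries, got {y5.shape}")
    if sig is None:
        sig = P53_MODULE_DAMAGE_SIG if damage_on else 0.0
    y = np.zeros(N_SPECIES)
    for name, value in zip(P53_MODULE_SPECIES, y5):
        y[_SI[name]] = value
    dy = rhs_core(t, y, params.as_array(), sig_override=sig)
    return np.array([dy[_SI[name]] for name in P53_MODULE_SPECIES])


def derived_quantities(state: np.ndarray, params: Optional[ParameterSet] = None
                       ) -> np.ndarray:
    """Expand a 34-entry state to the 50 reported quantities.

    The first 34 entries are the dynamic species; the remaining 16 are
    the conservation-law totals (total CDK1 pool first, equal to 1 for
    any state on the normalisation manifold).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_SPECIES,):
        raise ValueError(f"state must have {N_SPECIES} entries, got {y.shape}")
    out = np.empty(N_REPORTED)
    out[:N_SPECIES] = y
    for j, law in enumerate(CONSERVATION_LAWS):
        out[N_SPECIES + j] = law.evaluate(y)
    return out


def numerical_jacobian(t: float, y: np.ndarray, p: np.ndarray,
                       h: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of :func:`rhs_core` (testing aid)."""
    y = np.asarray(y, dtype=float)
    jac = np.empty((N_SPECIES, N_SPECIES))
    for j in range(N_SPECIES):
        up = y.copy()
        dn = y.copy()
        up[j] += h
        dn[j] -= h
        jac[:, j] = (rhs_core(t, up, p) - rhs_core(t, dn, p)) / (2 * h)
    return jac
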