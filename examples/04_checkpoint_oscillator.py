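"""The isolated p53-Mdm2-Wip1 damage oscillator.

With a sustained damage signal the five-species module (ATM/ATR, p53,
p53P, Mdm2, Wip1) produces relaxation oscillations of p53 with a period
of about 5 h, driven by the delayed negative feedback p53 -> Wip1 -|
ATM/ATR.  Without damage the module sits at a low steady state, and
removing the Wip1 inhibition of ATM/ATR abolishes the rhythm.
"""

import numpy as np
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from g2mcycle import build_default_parameters
from g2mcycle.rhs import rhs_p53_module

params = build_default_parameters()
y0 = np.array([0.02, 0.01, 0.01, 0.02, 0.01])  # ATM/ATR, p53, p53P, Mdm2, Wip1


def run(ps, damage):
    sol = solve_ivp(lambda t, y: rhs_p53_module(t, y, ps, damage_on=damage),
                    (0, 400.0), y0, method="LSODA", rtol=1e-8, atol=1e-11,
                    dense_output=True)
    tt = np.arange(200.0, 400.0, 0.02)
    p53 = sol.sol(tt)[1] + sol.sol(tt)[2]
    amp = p53.max() - p53.min()
    peaks, _ = find_peaks(p53, prominence=0.2 * max(amp, 1e-9))
    period = np.mean(np.diff(tt[peaks])) if len(peaks) > 3 else None
    return period, amp


period, amp = run(params, damage=True)
print(f"damage on : p53 oscillation period {period:.2f} h, amplitude {amp:.2f}")
period0, amp0 = run(params, damage=False)
print(f"damage off: {'steady state (no oscillation)' if period0 is None else period0}")
no_wip1 = params.with_edits({"k_d27.1": 0.0})
periodw, _ = run(no_wip1, damage=True)
print(f"Wip1->ATM/ATR inhibition removed: "
      f"{'oscillation lost' if periodw is None else periodw}")
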