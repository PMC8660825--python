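"""Plk1 depletion in p53-wild-type versus p53-null cells.

Reducing the Plk1 synthesis rate weakens disassembly of the mitotic
checkpoint complex Mad2:Cdc20P.  Once its level crosses 0.36 the DNA
damage signal activates ATM/ATR; p53-proficient cells mount a p21/Wip1
response and keep dividing until 80% depletion, while p53-null cells
arrest as soon as 60%.
"""

from g2mcycle import build_default_parameters
from g2mcycle.perturb import plk1_depletion_scan

params = build_default_parameters()
for background in ("p53-wt", "p53-null"):
    table = plk1_depletion_scan(params, background)
    arrested = table[table["viable"] == False]          # noqa: E712
    first = int(arrested["level"].min()) if len(arrested) else None
    print(f"{background}: first arrest at {first}% Plk1-synthesis reduction")
    print(table[["level", "viable", "normalized_period",
                 "mad2cdc20p_mean"]].to_string(index=False))
    print()
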