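"""Delete single genes and classify the resulting phenotypes.

Knockouts zero the corresponding synthesis rate constant (TP53 deletion
also clears the p53 initial condition).  Essential regulators arrest the
cycle -- with high MPF when mitotic exit fails (Cdc20 loss) or with low
MPF when mitotic entry fails (Cdc25 loss) -- while dispensable ones keep
cycling, some with a changed period (Cdh1 loss shortens the cycle to
about a third because the G1 cyclin brake disappears).
"""

from g2mcycle import build_default_parameters
from g2mcycle.perturb import make_mutant
from g2mcycle.simulate import classify_phenotype, estimate_period, integrate

params = build_default_parameters()
reference = integrate(params, t_end=300.0)
ref_period = estimate_period(reference, species="MPF")
mpf_peak = float(reference.species("MPF").max())

for gene in ["CDKN1A", "CDC25", "CDC20", "CDH1", "PLK1", "TP53"]:
    mutant, overrides = make_mutant(params, [gene], mode="deletion")
    result = integrate(mutant, t_end=400.0, init_overrides=overrides)
    call = classify_phenotype(result, ref_period, mpf_peak)
    if call.viable:
        print(f"{gene:8s} viable,   T_m/T = {call.tm_over_t:.2f}")
    else:
        print(f"{gene:8s} inviable, arrest = {call.arrest_class}")
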