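# Model and methods

## The model

`g2mcycle` implements a deterministic kinetic model of the mammalian
mitotic cell cycle coupled to the G2/M DNA damage checkpoint.  Thirty-four
dynamic species evolve under mass-action and Michaelis–Menten kinetics;
sixteen conservation closures (pool totals such as total CDK1, total
Cdc20, total p53) expand the state to the 50 quantities that the
sensitivity analyses report.  All concentrations are dimensionless,
normalised to the total CDK1 pool (= 1); time is in hours.

The network has three layers.

**Mitotic oscillator.**  Cyclin B is synthesised (k_s1), binds CDK1 and
is inactivated by Wee1 phosphorylation (preMPF) or activated by Cdc25
(MPF).  MPF inactivates Wee1 and PP2A and, together with active Plk1,
phosphorylates the APC/C core so it can bind Cdc20; APC/CP:Cdc20
degrades cyclin at mitotic exit while APC/CT:Cdh1 keeps cyclin low
through G1.  The oscillation is a relaxation cycle: cyclin accumulates
against the Cdh1 brake through a long interphase, the Wee1/PP2A switch
flips when the preMPF reservoir pushes enough leakage MPF past the flip
threshold, mitosis runs at high MPF, and APC-mediated destruction resets
the cycle.  Securin (Pttg1) and separase ride along as a conserved
sequestration pair; p21 inhibits MPF by cubic stoichiometric binding
(three p21 per complex).

**Mitotic checkpoint complex.**  CDK-phosphorylated Cdc20 (Cdc20P) is
bound by Mad2 into Mad2:Cdc20P, the arrest indicator.  Disassembly is
promoted by p21 and by active Plk1 through the shared factor
`(1 + [p21]/K_MCD + eps [Plk1P]/K_MCD)`.

**G2/M DNA damage checkpoint.**  The damage signal is an algebraic
function of the instantaneous Mad2:Cdc20P level `m`: zero below 0.36,
`200 (m − 0.36)` on the activation branch, and `200 (m − 0.6)` above the
arrest boundary, where the simulator additionally resets free Cdc20 to
zero (a solver event with re-arming only after the complex falls below
0.6 again).  The signal `Sig = DDS · exp(−10⁻⁸ t)` drives ATM/ATR
synthesis; ATM/ATR represses Cdc25 synthesis and Plk1 activation and
stimulates p53.  p53 induces p21 (checkpoint-complex disassembly and
CDK inhibition), Mdm2 (its own degradation) and Wip1 (which silences
ATM/ATR through a fourth-order Hill term) — the classic
p53–Mdm2–Wip1 negative-feedback oscillator.  As written, the damage
signal is continuous on [0, 0.6) and drops discontinuously at the
arrest boundary; this piecewise rule is kept exactly as specified.

The timescale parameter enters as `dX/dt = τ·f(X)`, so τ rescales time
exactly; τ = 1.65 places the wild-type period at 48 h.

## Parameterisation

The bundled table (`src/g2mcycle/data/parameters.csv`) carries exactly
137 kinetic constants plus τ and is the canonical input: the loader
fails loudly on any missing, unknown, negative or non-finite entry.
The twelve checkpoint-layer equations use the field's standard
formulation of this network symbol for symbol; the twenty-two
mitotic-core equations follow the same reaction inventory style
(15 synthesis reactions, forward/reverse interaction pairs,
APC-catalysed degradation arms).  The whole set was calibrated to the
reference behaviours the package targets: the 48 h wild-type period, the ~5 h standalone p53
oscillator, single-gene deletion phenotypes, the Plk1-depletion arrest
thresholds (60% in p53-null, 80% in p53-wild-type cells), the p21
overexpression boundary near k_s5 ≈ 0.0073, and the Mad2:Cdc20P
response surface maximum at (k_s28 = 0, k_s12 = 0, k_s33 = 0.1).

Design choices made where the equation set was open:

* Cdc25P turnover carries a PP2A-assisted route, so active Cdc25 is
  unstable in interphase in every genotype (including Cdh1-null cells);
  a Cdh1-only route makes the switch collapse when Cdh1 is deleted.
* Inactivated Wee1 is degraded MPF-dependently.  This keeps the mitotic
  state's grip on Wee1 when Plk1 is depleted — with a Plk1-driven route
  the checkpoint-arrested state decays into a pseudo-interphase and the
  arrest silently resolves.
* Wee1 inactivation has both MPF and Plk1P terms (k_f4, k_f4.1), and
  cyclin–CDK1 binding is treated as irreversible.
* APC/C activation is predominantly Plk1-driven (k_f8.1 ≫ k_f8), which
  makes mitotic exit Plk1-dependent: Plk1 deletion arrests in mitosis
  with high MPF and a saturated checkpoint complex.
* The p53 module's damage stimulus for standalone runs defaults to
  Sig = 28, the signal strength at a mid-activation checkpoint-complex
  level of 0.5.  A stimulus that merely doubles basal ATM/ATR synthesis
  sits far below the oscillation threshold of this calibration.

## Simulation protocol

Integration uses LSODA (stiff-capable, variable order) at rtol 1e-6 /
atol 1e-9 with dense output resampled on a 0.1 h grid.  The arrest
event (Mad2:Cdc20P rising through 0.6) terminates the solver, applies
Cdc20 := 0, and restarts; the event re-arms only after the complex has
fallen below the threshold, so a sustained excursion fires once.

Period detection resamples a trajectory at 0.1 h after a 100 h burn-in,
finds peaks with prominence ≥ 10% of the post-burn-in amplitude, and
requires (i) at least three peaks, (ii) a peak-to-trough swing of at
least 5% of the global amplitude, and (iii) a return into the lowest
quarter of the signal's range between consecutive peaks.  The third
rule distinguishes genuine division cycles from small oscillations
around an arrested state (which occur near the depletion-arrest
boundary when the p53 oscillator modulates an otherwise stalled
mitosis).  Phenotype calls key on MPF — mitoses are MPF peaks — with a
300 h assessment window so that even a doubled period fits three
cycles.  Inviable runs are classified *M-phase arrest (high MPF)* when
the terminal MPF mean exceeds half the wild-type peak and *early arrest
(low MPF)* otherwise.

The packaged initial state (`data/initial_state.csv`) is the wild-type
attractor sampled at an early-G1 MPF minimum after a 200+ h burn-in
from a documented seed state; limit-cycle attractors make phenotype
calls insensitive to the starting point for viable conditions.

## Perturbations

Gene-level edits act on synthesis rates: deletion zeroes the parameter,
CRISPR-style knockout zeroes a uniquely mapped gene but scales a
paralog-family gene (CCNB1/2, CDC25A/B, ATM/ATR) by 0.5, and any APC/C
subunit knockout disrupts the whole complex.  TP53 loss additionally
clears the p53 initial condition.  Depletion scales the rate by
(1 − level).  Cancer cell lines are represented by their mutated model
genes under the convention that modelled lines keep cycling: mutations
in cycle-essential genes (cyclin B, Cdc25, Wee1, Plk1, PP2A, APC/C,
Cdc20) reduce synthesis to 80% of nominal — the largest common
reduction that keeps every single-mutation line cycling — and all
others are zeroed.

## The synthetic cell-line generator

`generate_cellline_fixture` emulates the *shape* of a public
mutation-matrix export: independent per-gene Bernoulli mutations with
TP53 by far the most frequent (rate 0.62), damage-pathway genes next,
and co-mutation counts that follow the product rule.  It reproduces
none of the biology of real panels — no lineage structure, no mutation
co-occurrence beyond independence, no expression data — so tests
passing on it demonstrate the perturbation pipeline and the qualitative
essentiality pattern (Plk1 universally essential, unperturbed lines
cycling), not concordance with real dependency screens.

## Sensitivity analyses

All three analyses work on time-averaged concentrations: hourly samples
over a 96 h window from the standard initial state (N = 96 plain
arithmetic mean).  Logarithmic intensities use a central difference at
±1% of each parameter; per-quantity averages are row means over the
parameters.  PRCC draws Latin-hypercube samples over a ±1% box around
nominal (a truncated-normal option maps the box to ±3σ), perturbs all
parameters simultaneously, and computes rank-based partial correlations
with t-statistic p-values on n − 2 − (k − 1) degrees of freedom,
flagged when the sample count is close to the parameter count.  The
fuzzy analysis assigns each parameter a triangular membership function
with ±1% support; the α-cut band is the spread of each averaged
quantity over the cut interval, evaluated at the interval endpoints
plus nominal (vertex method; a dense-grid mode exists for non-monotone
responses, and a grid-search test guards the shortcut).  Parameters
with a zero nominal value in a scenario (e.g. k_s28 in p53-null cells)
are excluded from variation and their sensitivities are defined as
zero.

The four canonical scenarios cross p53 status with 45% Plk1 depletion.

## Known limitations of this calibration

* Table-1-style period ratios under 30% Plk1 depletion are not
  reproduced: in this core, depletion lengthens the cycle only near the
  arrest boundary, so pre-arrest ratios sit near 1.0 rather than
  1.3–2.2.  The normalized period is also not strictly monotone in the
  depletion level below the threshold.
* Fast (1–2 h) damage-induced p53 oscillations during mitosis do not
  appear; p53 rhythms in depleted cells are locked to the cell cycle
  (tens of hours).  Their period does decrease as depletion deepens,
  matching the qualitative claim only.
* In the phenotype panel over all four backgrounds, 11 of 92 calls
  deviate (chiefly doubles in p53-null backgrounds); all 13 single-gene
  mutants match in the primary background.
* At 45% depletion the ATM/ATR time-average is parameter-independent in
  both p53 backgrounds (the damage signal does not activate below the
  arrest threshold), so the p53-null > p53-wt sensitivity contrast
  holds strictly for the checkpoint-complex, Cdc20 and Cdc25 averages
  but not for ATM/ATR itself.
* The Cdh1-null fast cycle runs with a chronically engaged checkpoint
  and strongly reduced MPF amplitude.

## Problem sizes used by the test suite and acceptance script

Depletion scans use 10% steps with 400 h runs; the mutant panel is the
full 23 × 4 grid; the response surface uses a 2 × 3 × 3 grid at 250 h;
PRCC demonstrations use 60 Latin-hypercube samples over 5 synthesis
parameters; the essentiality screen uses a 300-line synthetic panel.
These sizes keep a complete run in minutes on one CPU while exercising
every code path; all of them are function arguments and scale up
directly.
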