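# zymoflux

Constraint-based analysis of aerobic acetaldehyde production by
*Zymomonas mobilis*, plus the batch-fermentation accounting needed to
compare model predictions with culture data.

*Z. mobilis* catabolizes glucose through the Entner-Doudoroff pathway and
normally reduces the resulting acetaldehyde to ethanol. Under aeration its
energetically uncoupled respiratory chain can reoxidize NADH instead, so
acetaldehyde — a volatile commodity-chemical precursor — accumulates. This
package asks the metabolic-engineering question quantitatively: given the
stoichiometry of central metabolism, how much acetaldehyde per glucose is
possible, and which interventions (reducing alcohol dehydrogenase flux,
forcing respiration) get there?

It is aimed at people doing small-network flux balance analysis and
fermentation data analysis: a library (`src/zymoflux/`), a CLI
(`zymoflux`), and narrative analysis drivers (`analysis/`).

## The model in brief

Fluxes v (mol per mol glucose) satisfy steady state and bounds, and one
flux is optimized:

    max v_acald  s.t.  S·v = 0,  lb ≤ v ≤ ub

S covers the ED route, fermentative branches (ethanol/acetate/acetoin),
an uncoupled respiratory chain (NADH and NADPH dehydrogenases, ubiquinol
oxidase), the non-oxidative pentose phosphate branch, a biomass precursor
drain (1 R5P + 2 PG3 + 2 PEP + 4 PYR + 3 ACCOA + 22 NADPH + 30 ATP), an
ATP maintenance sink, and exchanges (negative flux = uptake). Scenarios
fix measured exchange fluxes (glucose −1.00, biomass 0.01, by-products as
observed) and every reported optimum is audited for uniqueness by flux
variability analysis.

The batch side implements molar yields as the OLS slope of product vs
consumed glucose (both mM), off-gas back-calculation of stripped
acetaldehyde, OD600→dry-weight conversion (0.24 g/l per OD), carbon-atom
distribution, exponential growth rates, and adenylate energy charge
(ATP + ½ADP)/(ATP + ADP + AMP). A synthetic batch generator with exact
closed-form ground truth makes all of it testable end to end. See
`docs/methods.md` for assumptions and design choices.

## Worked example

```python
from zymoflux import (build_reference_model, make_scenario, run_scenario,
                      adh_sweep, percent_of_theoretical)

model = build_reference_model()

best = run_scenario(model, make_scenario("B"))   # no by-products
print(best.objective_value)                      # 1.86
print(best["UO"])                                # 0.89  (mol O2 / mol glucose)

print(adh_sweep(model, [0.60, 0.40, 0.20, 0.0]))
#    adh  acetaldehyde_yield   status
#   0.6                1.07  optimal
#   0.4                1.27  optimal
#   0.2                1.47  optimal
#   0.0                1.67  optimal

print(round(percent_of_theoretical(model, 1.3)))  # 70
```

1.86 mol acetaldehyde per mol glucose is the theoretical maximum: glucose
becomes equimolar acetaldehyde and CO2 minus the biomass precursor drain.
The sweep shows the yield rising one-for-one as alcohol dehydrogenase flux
is removed (the acetaldehyde+ethanol pool is conserved), and a measured
producer-strain yield of 1.3 mol/mol is 70% of the computed maximum.

Same from the shell:

```sh
zymoflux scenario table --out table.tsv     # 7-column scenario flux table
zymoflux simulate --seed 42 --out run.tsv   # synthetic batch + ground truth
zymoflux yields --series run.tsv --product ethanol --product acetaldehyde_liquid
zymoflux ec --atp 2 --adp 2 --amp 1         # 0.6000
```

The analysis drivers run the whole study end to end and write tables under
`results/`:

```sh
python analysis/01_build_model.py      # network + structural audit
python analysis/02_flux_scenarios.py   # scenario table, ADH & O2 sweeps
python analysis/03_batch_recovery.py   # synthetic batches, yield recovery
```

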