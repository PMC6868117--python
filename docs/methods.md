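# Methods

## The network

`zymoflux` encodes the aerobic central metabolism of *Zymomonas mobilis*
as a small stoichiometric network: 24 internal reactions plus 9 exchange
reactions over 32 metabolites. Catabolism runs through the
Entner-Doudoroff (ED) route (GLK → PGI/G6PDH → PGL → EDD → KDPGA, then the
lower glycolytic reactions GAPDH…PYK), pyruvate decarboxylase feeds the
acetaldehyde node, and acetaldehyde partitions between ethanol (ADH,
reversible), acetate (NAD-dependent acetaldehyde dehydrogenase), acetoin
(a lumped carboligase, see below) and export. The respiratory chain is
deliberately minimal and energetically uncoupled — a type II NADH
dehydrogenase and an NADPH dehydrogenase both reduce ubiquinone, and a
ubiquinol oxidase consumes O2 (counted per mole O2, so its flux equals the
O2 uptake) without ATP coupling. The non-oxidative pentose phosphate
branch (TKT2, RPE, RPI) supplies ribose 5-phosphate, and pyruvate
dehydrogenase supplies acetyl-CoA, both exclusively for biosynthesis.

All fluxes are glucose-normalized (mol per mol glucose consumed).
Exchange reactions carry a single metabolite with coefficient −1, so
negative exchange flux is uptake; only the glucose and oxygen exchanges
open in that direction. Default bounds are ±1000 (reversible) or
[0, 1000]; any finite cap well above the fixed glucose uptake of 1 gives
identical optima.

Choices made where the reconstruction was open:

* **Biomass drain.** Growth is a lumped drain of
  1 R5P + 2 PG3 + 2 PEP + 4 PYR + 3 ACCOA + 22 NADPH + 30 ATP per unit of
  a BIOMASS pseudo-metabolite carrying the summed 35 precursor carbons.
  The precursor coefficients are fixed by the constant flux gaps the
  network must exhibit between glycolytic stages at a biomass export of
  0.01 (PGK−PGM = ENO−PYK = 0.02, PDH = 0.03, NADPH gap 0.22). The ATP
  coefficient (30, a typical growth-associated demand) affects no reported
  flux because the maintenance sink absorbs ATP slack.
* **Acetoin.** A lumped carboligase PYR + ACALD → ACTN + CO2 is the unique
  single-reaction stoichiometry consistent with the network's CO2 export
  and pyruvate balance; an acetolactate-synthase route (2 PYR) would shift
  CO2 export and is not used.
* **ATP maintenance.** An unbounded ATPase sink (ATPM) is required: the
  catabolic route makes net ATP at fixed biomass, and without a sink no
  steady state exists.
* **E4P export.** Biosynthetic transketolase operation makes erythrose
  4-phosphate with no consumer inside a central-carbon-only network, so an
  artificial export (EX_e4p) removes it; it carries 0.01 in every optimum.
* **Untracked species.** Protons, water, phosphate and CoA are omitted;
  no balanced flux depends on them. NAD/NADH, NADP/NADPH, Q/QH2 and
  ATP/ADP are conserved moieties (net zero in every reaction), which the
  test suite asserts.

## Flux balance and variability analysis

FBA maximizes one flux subject to S·v = 0 and bounds; the LPs are solved
with scipy's HiGHS interface at 1e−9 primal/dual feasibility with
deterministic settings (no randomized options), so repeated runs agree to
machine precision. Scenario constraints enter as fixed fluxes
(lower = upper) on top of the defaults.

Every reported scenario optimum is audited by flux variability analysis:
with the objective pinned at its optimum, each reaction is minimized and
maximized (two LPs per reaction). A distribution is reported as point
values only if every range width is ≤ 1e−6; the audit passes for all
seven reported columns, so the printed single values are legitimate and no
tie-breaking objective is needed. The engine is cross-checked in the test
suite against an independent constraint-based stack (cobrapy/GLPK) on the
same network, and against exhaustive vertex enumeration on tiny models.

## Scenarios

All scenarios fix glucose uptake at 1.00 and biomass export at 0.01 and
maximize acetaldehyde export:

| label | fixed in addition | question it answers |
|---|---|---|
| A | ethanol 0.68, acetate 0.07, acetoin 0.06 | wild-type aerobic flux pattern |
| B | ethanol = acetate = acetoin = 0 | theoretical maximum (1.86 mol/mol) |
| C | ADH ∈ {0.60, 0.40, 0.20}, acetate/acetoin wild-type | partial ADH knock-down |
| D | ADH = 0, acetate/acetoin wild-type | ADH knockout |
| E | O2 uptake = scenario-D optimum, ADH free | can aeration substitute for the knockout? |

Scenario E pins O2 at the *unrounded* D optimum (0.925): fixing the
2-decimal value instead shifts the acetaldehyde yield by one rounding unit
through the NADH balance, while the unrounded value reproduces column D
row for row — which is the scenario's point.

Two structural properties worth stating explicitly:

* **The ADH sweep has slope exactly −1.** Pyruvate supply, acetate and
  acetoin are fixed, so the acetaldehyde + ethanol pool is constant; every
  mole of flux denied to ADH is exported as acetaldehyde, and the NADH it
  would have consumed goes to respiration instead.
* **Respiration is obligatory in this network.** With glucose and biomass
  fixed, the ED route makes 0.99 NADPH per glucose but biosynthesis
  consumes only 0.22; the NADPH dehydrogenase → oxidase chain is the only
  other NADPH sink, so no steady state exists below an O2 uptake of 0.385.
  The oxygen-forcing sweep therefore runs over [0.385, 0.925], and the
  optimal yield is non-decreasing in O2 over that range.

Rounding for table output is half-away-from-zero to 2 decimals. Four
ubiquinol-oxidase optima are exact ties (0.585, 0.625, 0.725, 0.825,
0.925 halves), where either neighboring 2-decimal value is a faithful
print; tests compare those entries within ±0.005 rather than by digit.

Percent-of-theoretical always recomputes the scenario-B optimum as the
100% reference rather than caching 1.86.

## Batch accounting

* **Yields** are OLS slopes of product concentration (mM) against consumed
  glucose S0 − S(t) (mM), restricted to the consumption phase
  (glucose > 5% of its initial value) because late-phase ethanol re-uptake
  and delayed acetate formation violate the constant-yield assumption.
  Regressing against consumed rather than residual glucose gives the same
  slope magnitude with a positive sign and an interpretable intercept.
* **Off-gas back-calculation** assumes complete capture in the
  derivatization trap: gas-phase concentration = trapped amount /
  (gas flow × sampling duration). Total acetaldehyde referred to culture
  volume adds the trapezoidal integral of gas flow × gas concentration
  over the trap samples (rate extrapolated as constant before the first
  sample, cumulative amount held after the last) divided by the liquid
  volume.
* **Carbon distribution** converts molar yields to carbon fractions
  (yield × product carbons / 6) and a gravimetric biomass yield through a
  configurable biomass carbon content of 0.48 g C/g cdw (generic bacterial
  composition). Closure is reported, never forced; for model flux
  distributions it is exactly 1.
* **Growth rate** is the slope of ln(OD600) vs time over an exponential
  window — user-supplied, or auto-selected as the longest contiguous run
  of ≥3 points with r² ≥ 0.99. Specific glucose uptake uses the
  balanced-growth relation q = µ·ΔS/ΔX over the same window, with dry
  weight from OD600 × 0.24 g/l (configurable calibration).
* **Energy charge** is (ATP + ADP/2)/(ATP + ADP + AMP).

## The synthetic-data generator

The generator produces batch cultures with exactly the structure the
analysis assumes — exponential growth, yield-coupled products, first-order
stripping of liquid acetaldehyde, additive Gaussian noise truncated at
zero — with closed-form curves, so recovery tests compare against exact
ground truth. Defaults are the aerobic study conditions: µ = 0.38 1/h,
q = 40 mmol/(g cdw·h), 277.5 mM glucose (50 g/l), 0.4 l culture sparged at
1 vvm (24 l/h), wild-type yields (ethanol 0.77, acetaldehyde 0.68, acetate
0.07, acetoin 0.06 mol/mol), noise 1 mM (glucose), 0.5 mM (products), 2%
(OD600), 12 samples over 10 h (glucose runs out at ~10 h under these
parameters). The stripping constant (0.2 1/h) is a chosen moderate value:
no stripping physics is prescribed by the study conditions, only that the
product is volatile and measured in both phases; the analysis is tested at
several values.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real cultures: lag phase and growth-rate decline,
acetaldehyde toxicity feedback on growth, late-phase ethanol re-uptake and
delayed acetate onset, trap efficiency below 100%, and instrument drift.
The yield regression's 5%-glucose floor exists precisely because real
late-phase data break the linearity the generator builds in.

Recovery at the default settings, over 200 seeded replicates per yield
level (computed by the test suite and `analysis/03_batch_recovery.py`):
yield bias ≲ 0.3% (well under the 1% requirement), growth-rate errors all
< 0.01 1/h. The OLS standard error slightly understates the total error
because the consumed-glucose regressor is itself noisy
(errors-in-variables), so empirical 2-standard-error coverage sits near
90% rather than the nominal 95%; tests assert the calibration property
(typical |error|/SE well inside 2) rather than an impossible 100%
coverage.

Adenylate pools with a prescribed energy charge are generated by inverting
the EC formula: EC and the pool total leave one degree of freedom, and the
ADP share is drawn uniformly from its admissible interval.

## Numerical conventions

LP feasibility tolerances 1e−9; FVA uniqueness threshold 1e−6;
steady-state residual of a printed 2-decimal flux column accepted up to
0.015 (propagation of half-unit rounding through ≤3-term balances); carbon
closure of model solutions asserted at 1e−9. Degenerate inputs raise
rather than guess: infeasible scenarios name their fixed constraints,
empty adenylate pools, non-increasing timestamps, negative concentrations
and sub-3-point regressions are all errors.

## Scope notes

Serialization is the TSV pair (`metabolites.tsv`/`reactions.tsv`) and a
single-file JSON; SBML export is out of scope for this release. Outputs
are plain TSV/JSON tables; no plotting layer is included.
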