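# Methods

## Model structure and assumptions

The package implements a whole-body PBPK model of digoxin with 75 state
variables: venous and arterial blood, 15 perfused organs (bone, brain, fat,
gonads, heart, kidney, large and small intestine, liver, lung, muscle,
pancreas, skin, spleen, stomach), per-organ target-bound pools, and a
gastrointestinal absorption chain (stomach lumen plus eight transit
segments, each with solid, dissolved, and enterocyte pools). Amounts are
carried in µg; plasma concentration is reported in ng/mL from the venous
pool, assuming a blood:plasma ratio of 1.

Four mechanistic assumptions define the drug model:

1. **Saturable intestinal efflux.** Enterocyte-to-lumen secretion follows
   Michaelis–Menten kinetics (Vmax 20 µmol/L/min, Km 177 µmol/L), with an
   optional relative P-gp expression scalar per segment (default 1).
2. **Linear, non-saturable target binding.** Digoxin binds Na⁺/K⁺-ATPase on
   the membranes of excitable tissue. The unprinted target concentration is
   folded into the association rate, kon = koff/Kd, acting on the deep-space
   concentration, so Kd acts as an equilibrium tissue-retention constant
   (bound:free ratio 1/Kd). The binding pool is placed in heart, skeletal
   muscle, and brain. Skeletal muscle is digoxin's dominant clinical depot
   and is required to reproduce the very large, slowly filling distribution
   volume implied by the published pediatric exposures; heart-only binding
   (a ~20 mL organ in a neonate) cannot hold the published pediatric
   predictions and fails the below-window neonatal trough finding. The set
   is configurable (`build_model(binding_organs=...)`).
3. **No metabolism.** Elimination is glomerular filtration of unbound drug,
   CL = GFR_fraction · fu · GFR, with GFR_fraction 1. The filtration
   clearance is drawn from the central venous plasma pool rather than the
   kidney vascular sub-compartment: digoxin's renal extraction ratio is low,
   and this choice makes the sampled-plasma clearance exactly dose/AUC∞
   (kidney-local extraction would bias it by CL/Q_kidney ≈ 6%).
4. **Two-layer organs.** Each organ has a fast space — vascular volume plus
   tissue water, flow-limited, holding drug at unbound equilibrium with
   plasma (effective volume vasc + fu·(f_EW + r·f_IW)·V, with r the weak-acid
   pH-partition ratio) — and a deep space (cellular lipid + bound target)
   behind a permeability barrier, PS = cellular permeability × exchange
   area. Organ equilibrium is set by the Rodgers–Rowland partition
   coefficient for neutrals/weak acids (digoxin: weak acid, pKa 7.15,
   LogP 2.36, fu 0.71); the deep-space partition coefficient is the residual
   Kp·V − V_fast over the deep volume.

## Parameters

Population parameter sets (healthy adult / heart-failure adult / pediatric
heart failure) share the physicochemical block (LogP 2.36, fu 0.71,
MW 780 g/mol, pKa 7.15, solubility 0.1 mg/mL, cellular permeability
3×10⁻⁴ cm/min) and differ in Kd (0.01 / 0.5 / 0.005 µmol/L) and specific
intestinal permeability (2.3 / 2.7 / 2.7 ×10⁻⁵ cm/min). Organ blood flows
and GFR for the healthy adult, their heart-failure halving, and the
pediatric column are the published values; organ volumes, tissue
compositions (Rodgers–Rowland composition constants), and vascular fractions
are a standard published adult reference set shipped with the package.

## Population translations

- **Heart failure**: every organ flow is multiplied by exactly 0.5 (the
  published table rounds the GI-mucosa flow 0.02 → 0.012; the exact half,
  0.010, is used, a ≤20% deviation from that one rounded entry) and GFR is
  set to 43.85 mL/min.
- **Pediatric scaling**: organ flows follow weight-allometric functions
  Q ∝ (W/73)^b with organ-specific exponents backed out of the two published
  anchor columns, so a 3.5-kg, 3-day-old term neonate reproduces the
  published pediatric column exactly. Organ volumes scale linearly with
  weight except the brain, which matures early and uses its flow exponent
  (sharing the flow exponents would give a 3.5-kg neonate >5 L of organ
  volume). GFR combines a size term (W/73)^0.32 with a sigmoidal
  postmenstrual-age maturation (Hill form, TM50 55.4 weeks, γ 3.4 — the
  standard renal maturation constants), the exponent calibrated so the
  neonate anchor yields 4.2 mL/min. The same maturation sigmoid scales the
  absorptive mucosal area (villous immaturity), giving a neonatal oral
  bioavailability of ~0.76 vs ~0.80 in adults.

## Calibrated structural constants

The published parameter set does not pin down the cellular exchange surface
or the effective mucosal absorption area. Both are fixed once, by
calibrating against the published model's own reported exposures across the
three populations, and then frozen:

- deep-space exchange area = 110 000 × (deep volume, mL)^0.2 cm². The
  strongly sub-linear exponent makes exchange area per unit volume much
  larger in small organs and small individuals, consistent with the higher
  capillary density of immature tissue; it is what lets one constant serve a
  73-kg adult and a 3.3-kg neonate.
- small-intestinal mucosal amplification = 50 (colon 4) over the smooth
  cylindrical segment areas; adult oral bioavailability ≈ 0.80 with P-gp
  active, rising when efflux is disabled.

## Study-design assumptions for the validation table

The published metric table prints neither sampling schedules, AUC windows,
infusion conventions, dose counts for the multiple-dose heart-failure
studies, nor pediatric body weights. `table3_fixtures()` carries the
documented assumptions used to re-simulate each regimen: typical rich adult
sampling grids (bolus studies first sampled at 0.5 h; infusion studies at
end of infusion); single-dose AUC windows of 24–96 h chosen per study (8 h
for the two sparse-sampling oral outlier studies); once-daily dosing with
metrics over the fourth dosing interval for the heart-failure multiple-dose
studies; 1-h infusions, 48-h windows, and first samples at 1 h for the
pediatric studies; pediatric weights ~10% below age medians, reflecting the
failure to thrive typical of infants with heart failure. Predicted Cmax and
AUC are computed on the same discrete grids as the observed metrics.

## Regimen evaluation

The FDA digitalization protocol is built as two half-loading doses 6 h
apart, maintenance starting 12 h after the second loading administration,
twice daily, each maintenance dose 25% of total loading (taken literally
from the label wording; the split fractions, interval, and start are
configurable). IV administrations are modeled as 15-min infusions and are
75% of the oral dose. Simulations run to a 7-day horizon — the conventional
clinical point for digoxin steady-state trough assessment; with the
pediatric filtration clearances true steady state lies weeks away, so the
reported trough is the final-interval trough, flagged not-converged, exactly
as a 7-day TDM measurement would be. Both window bounds are inclusive.
Representative weights (neonate 3.5, infant 6, child 20 kg) are
configuration, not claims.

## Numerical choices

LSODA integration segment-wise between dose events; boluses are applied as
state discontinuities before derivative evaluation at their instant;
infusions contribute a constant venous input over their duration. Default
tolerances 1e-6/1e-9 (tests use 1e-8/1e-10, at which the mass-balance ledger
closes to <1e-6 of dose). Output grids are 0.5 h coarse, 0.05 h for 2 h
after each dose, and 2 s over the venous mixing transient so trapezoidal
AUC of a bolus is accurate. AUC∞ adds a log-linear tail extrapolation.
Steady-state troughs are detected when successive-interval troughs differ by
<1% (each trough is the minimum over the tail of its interval, so samples at
exactly a dose time are never mistaken for troughs). Degenerate inputs
(zero-dose regimens, zero clearance, zero permeability) are exercised in the
test suite.

## Synthetic data and fitting

Virtual individuals multiply every organ flow, organ volume, and GFR by
independent unit-mean log-normal factors (default CV 0.2; PCG64, explicit
seeds everywhere). Observations are C·(1+ε_prop)+ε_add truncated at zero —
emulating sparse, noisy concentration points digitized from published
figures; the generator does not emulate model misspecification, assay LLOQ
censoring, or correlated residuals, so passing recovery tests show
identifiability under the model, not robustness to structural error.
Fitting is multi-start (uniform seeded starts within bounds) bounded
trust-region least squares on log-concentrations, balancing peak and trough
residuals across digoxin's >10-fold concentration range. The noisy-recovery
check pools eight staggered sampling replicates of the representative
neonate rather than eight distinct virtual subjects, keeping one model
evaluation per objective call.

## Known limitations

- Two published validation cells sit just outside reproduction under the
  frozen conditions: the 70-day-old infant's Cmax (ratio 0.47 vs the 0.5
  band edge) and the oral neonatal low-dose trough (0.536 vs the 0.5 ng/mL
  bound, where the published finding is below-window for both routes). Both
  are per-µg-dose consequences of a single linear parameterization serving
  individuals whose observed per-dose exposures differ by ~2-fold; the
  published model shows the same strain (its infant ratios reach 0.54).
- The model is linear apart from P-gp efflux and the solubility cap; no
  enterohepatic recirculation, lymph flow, biliary excretion, saturable
  plasma-protein binding, or tubular secretion (real digoxin has a secretory
  renal component, which is why true steady-state accumulation under the
  label regimen is overstated at long horizons).
- Heart-failure severity is a single (moderate) stratum; no
  pharmacodynamics, no drug–drug interactions.
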