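# Methods

`deliq` predicts deliquescence relative humidities (DRH) of crystalline
compounds and physical crystal mixtures by solving the coupled
solid–liquid–vapor equilibrium with PC-SAFT activity coefficients.
This note records the model, the numerical choices, and the places
where the design was genuinely open.

## Phase-equilibrium model

Deliquescence is a first-order transition: above a threshold RH a
crystal converts into a saturated aqueous solution.  At the DRH three
phases coexist, so two (or, for N crystals, N + 1) equilibrium
conditions are solved simultaneously.

**Solid–liquid equilibrium.**  For an anhydrous crystal *i* the
saturation condition is

    x_i γ_i = exp[ −Δh_i^SL/(R T) (1 − T/T_i^SL)
                   − Δc_p,i^SL/R (ln(T_i^SL/T) − T_i^SL/T + 1) ]

with melting temperature `T^SL` (K), melting enthalpy `Δh^SL` (kJ/mol)
and heat-capacity change upon melting `Δc_p^SL` (J/mol/K; zero when
untabulated — note that a positive Δc_p *raises* the right-hand side
below the melting point, since ln θ − θ + 1 ≤ 0).  For a crystal
hydrate the condition is a solubility product

    (x_i γ_i)^ν_i (x_w γ_w)^ν_w = K_s(T)

where K_s is built from the anhydrate melting term, the dehydration
transition enthalpy `Δh_trans` and temperature `T_trans`, and the water
activity at the hydrate/anhydrate transition `a_w^trans`:

    K_s = [anhydrate melting term]^ν_i · a_w^trans
          · exp[ −Δh_trans/(ν_w R T)(1 − T/T_trans) ]^ν_w .

`a_w^trans` matters only for highly water-soluble hydrates (citric acid
monohydrate: 0.725); setting it to 1 recovers the familiar
sparingly-soluble form.

**Vapor–liquid equilibrium.**  The vapor is treated as an ideal gas, so
RH/100 = x_w γ_w = a_w and the pure-water vapor pressure cancels; no
vapor-pressure correlation is needed anywhere.  The DRH is then
100·a_w evaluated at the (possibly multi-solid) saturated composition,
with x_w = 1 − Σ x_i closing the mole balance.  For N crystals in
contact the solved composition is the eutectic (eutonic): the liquid
simultaneously saturated with every crystal.  Because that liquid is an
intensive state, DRH_mix is independent of the dry-basis crystal ratio.

**Raoult's-law baseline.**  The ideal-mixing variant keeps the
PC-SAFT-derived solubilities but drops liquid-phase non-ideality from
the vapor equilibrium.  For a single crystal this is 100·x_w at the
PC-SAFT saturated composition (so DRH_raoult/DRH_pcsaft = 1/γ_w
exactly).  For a mixture, ideal mixing makes each solubility
composition-independent, so the eutectic composition is the
superposition of the binary saturation mole fractions and
DRH_raoult = 100·(1 − Σ x_i^binary).  We adopted this superposition
reading (rather than idealizing only γ_w at the PC-SAFT eutectic)
because it is the self-consistent meaning of "all γ = 1" for the
solid–liquid conditions, and it is the variant the bundled regression
tables validate against.

## PC-SAFT

The residual Helmholtz energy is hard-chain + dispersion + association,
in the original perturbed-chain formulation (Gross–Sadowski universal
dispersion constants; Boublík–Mansoori hard-sphere mixture term).
Cross parameters use Lorentz–Berthelot rules for size and dispersion
energy — with a binary parameter k_ij that is constant or linear in T,
`k_ij = k_ij,T·T + k_ij,b` — and Wolbach–Sandler rules for association.

Association uses the two-site-class Wertheim treatment: a component
carries (Na, Nb) sites of two classes and only unlike classes bond,
intra- and inter-species.  The association strength is

    Δ_ij = σ_ij³ g_ij^hs(d) κ_ij [exp(ε_ij/T) − 1].

σ³ (not the temperature-dependent d³) is used as the bonding-volume
scale because the Wolbach–Sandler rule makes κ_ij σ_ij³ the geometric
mean of the pure-component κσ³ volumes; the end-to-end DRH regression
confirms this assembly.

Water uses a temperature-dependent segment diameter
σ(T) = 2.7927 + 10.11 e^(−0.01775 T) − 1.417 e^(−0.01146 T) Å,
evaluated at the state temperature on every call.  With the bundled
parameters the model reproduces the ambient liquid density of water to
about 0.1 %.

**Derivatives.**  Pressure and fugacity coefficients come from analytic
density and composition derivatives of the reduced residual Helmholtz
energy.  The association term is differentiated via the stationarity of
the bonding functional in the site fractions (only the explicit ρ- and
x-dependence survives), which keeps the expressions closed-form; the
test suite checks all derivative routes against central finite
differences of the total Helmholtz energy and a Gibbs–Duhem residual.

**Reference states.**  Activity coefficients are symmetric
(mole-fraction) ones: γ_i = φ_i(T,p,x)/φ_i^pure-liquid(T,p).  For
solutes below their melting point the pure reference is the
hypothetical subcooled liquid on the same EOS branch; a liquid density
root exists for every bundled component over the working range.  All
liquid properties are evaluated at 101,325 Pa — DRH depends only on
a_w, so the absolute pressure choice is immaterial.

## Numerical choices

* **Site fractions:** damped successive substitution (damping 0.5)
  into the Newton basin, then an analytic-Jacobian Newton polish to
  ~1e−15 residual.  The tight polish is deliberate: downstream finite
  differences and warm/cold-start reproducibility need site-fraction
  noise below ~1e−12.
* **Liquid density:** the largest packing-fraction root of
  p(η) = p, found by a descending scan over η ∈ (1e−10, 0.7404) with
  Brent refinement; successive calls warm-start from a ±0.03 bracket
  around the previous root.
* **Saturation/eutectic solve:** Powell hybrid on the solute mole
  fractions in log space, residuals on ln-activities, tolerance 1e−9.
  Initial guess: ideal solubility corrected by the infinite-dilution
  activity coefficient, damped by 0.8 for mixtures; on failure a
  four-step homotopy walks γ in from the ideal (γ = 1) solution.
  Requests above a component's melting point are rejected explicitly.
* **Hydrate initial guess:** the γ-corrected closed form
  x^ν_i (1−x)^ν_w = K_s/γ-factors solved on the dilute branch, with the
  right-hand side capped below the left side's maximum so a root always
  exists.
* **Sorption isotherms:** below DRH_mix the uptake is exactly zero; at
  DRH_mix the uptake jumps to the lever-rule value (liquid at the
  eutectic composition, first-exhausted solid fully dissolved); between
  breakpoints the state solves saturation for the remaining-solid
  subset at fixed a_w plus component mass balances (per gram of dry
  crystals); above full dissolution a one-dimensional dilution solve
  matches a_w to RH/100.  Solid-exhaustion RHs are located by marching
  the fixed-a_w state upward with warm starts and Brent-refining the
  zero crossing of the solid amount.  RH = 100 % is an asymptote
  (w_water → 1) and is never solved.  Hydrate crystals are weighed into
  the dry basis including their water of crystallization; sorbed water
  counts liquid water plus any change in crystal-bound water.
* **Solid–solid transition RH:** anhydrate/hydrate coexistence pins the
  solute activity, so a_w = (K_s/a_anh^ν_i)^(1/ν_w) in closed form —
  no activity-coefficient model enters.  Above T_trans (or if the
  closed form exceeds 1) no stable hydrate exists and a sentinel is
  returned.
* **Temperature sweeps** default to 278–368 K; failed points are
  recorded as NaN with a warning rather than aborting.

## Parameter-set decisions

* **k_ij tabulation convention.**  Both readings of a tabulated
  temperature-dependent pair — raw intercept of k_ij,T·T + k_ij,b, or
  value at 298.15 K — are supported per record.  The bundled records
  store raw intercepts: under that reading the fructose, glucose,
  sucrose and nicotinamide regression rows reproduce to 0.1 % RH,
  whereas the value-at-298 K reading is off by tens of % RH.
* **Glucose molar mass.**  The circulated parameter tabulation misprints
  118.16 g/mol for glucose; the bundled set uses the formula mass
  180.16 (C6H12O6) consistently, so the segment number is
  0.0368·180.16 = 6.63.  The misprinted value remains available as an
  override for comparison.
* **Lactose.**  With the bundled melting data (75.3 kJ/mol, 433.2 K, no
  Δc_p) the ideal saturation activity at 298.15 K is 7.7e−5 and the
  predicted solubility is x ≈ 5e−4, giving a DRH of ~99.9 % RH — far
  above the ~94 % regression value, which would require an effective
  melting term near 36.5 kJ/mol.  The tabulated inputs and the
  regression value are mutually inconsistent for this one compound; the
  package computes faithfully from the inputs and the lactose rows are
  excluded from nothing (they raise the single-component ARD from ~2.0
  to ~2.6 %).
* **Solute–solute pairs** default to k_ij = 0 (predictive convention:
  only pure-component aqueous data is consumed).
* **Association site labelling:** the tabulated "a/b" counts are stored
  as two class counts without asserting donor/acceptor identity; with
  cross-class-only bonding and class-symmetric cross parameters the
  labelling is immaterial.

## What the regression tables do and do not show

The bundled measured columns are literature values at 298.15 K
(gravimetric vapor-sorption DRH and equilibrium water activities of
saturated solutions).  Agreement there validates equilibrium
predictions for organic acids, sugars, an amide and an artificial
sweetener in water.  It says nothing about sorption *kinetics* (real
uptake near DRH is kinetically inhibited), electrolytes, polymorphs
beyond the parameterized anhydrate/hydrate forms, or organic-solvent
vapors.  Mixture predictions assume the crystals are in physical
contact and that solute–solute interactions are captured with
k_ij = 0; systems dominated by strong solute–solute complexation would
need fitted pair parameters.

## Problem sizes used in tests and the acceptance script

All regression quantities are desk-scale: nine single-component and 25
mixture equilibrium solves at 298.15 K, sorption breakpoints for one or
two compositions, and short temperature brackets around the citric-acid
transition (305–314 K).  A single-component DRH solves in well under a
second and the full regression in under a minute on one CPU.
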