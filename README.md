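# deliq

Predicting **deliquescence relative humidities (DRH)** of crystals and
physical crystal mixtures from thermodynamics alone.

Crystalline ingredients — organic acids, sugars, sweeteners, amides —
dissolve into a saturated aqueous solution as soon as the ambient
relative humidity exceeds their DRH.  Knowing that threshold (and how
it drops when different crystals touch each other in a blend) defines
the storage-stability window of pharmaceutical, food and agrochemical
products.  `deliq` computes it predictively, using only pure-component
aqueous data: no mixture measurements enter.

## Model

At the DRH, solid, saturated liquid and vapor coexist.  For each
crystal *i* the solid–liquid equilibrium

x_i γ_i = exp[ −Δh_i^SL/(RT)(1 − T/T_i^SL) − Δc_p,i^SL/R(ln(T_i^SL/T) − T_i^SL/T + 1) ]

(or a solubility product (x_i γ_i)^ν_i (x_w γ_w)^ν_w = K_s(T) for a
hydrate) is solved simultaneously with the ideal-gas vapor equilibrium
RH/100 = x_w γ_w = a_w, with x_w = 1 − Σ x_i.  For N crystals in
contact this yields the eutectic (eutonic) liquid, and DRH_mix =
100·a_w there — always at or below every member's own DRH, and
independent of the blend ratio.

Activity coefficients γ come from **PC-SAFT**: a residual
Helmholtz-energy model with hard-chain, dispersion and association
(hydrogen-bonding) contributions, five pure-component parameters per
substance, Lorentz–Berthelot and Wolbach–Sandler combining rules, and
a binary parameter k_ij(T) fitted to aqueous data only.  A complete
parameter set for water, ascorbic acid, citric acid (anhydrate and
monohydrate), fructose, glucose, nicotinamide, lactose, saccharin and
sucrose is bundled, together with literature DRH measurements for
scoring.  Setting all γ = 1 gives the Raoult's-law baseline.

## Worked example

```sh
$ deliq drh --components "fructose,glucose" --temp 298.15
DRH (pcsaft) at 298.15 K: 58.0 % RH
saturated liquid composition (mole fractions):
  water                x = 0.71661   gamma = 0.8099
  fructose             x = 0.24217   gamma = 0.5385
  glucose              x = 0.04122   gamma = 0.7077
```

A fructose/glucose blend deliquesces at 58.0 % RH although pure
fructose holds out to 61.5 % and pure glucose to 89.3 %: the eutectic
liquid (x_w γ_w = 0.580) is saturated with both sugars at once, and
water's activity coefficient of 0.81 shows why the ideal Raoult
estimate (100·x_w = 71.7 %) would be dangerously optimistic.

The same library call chain is available in Python:

```python
from deliq import builtin_components, parse_solid, predict_drh_mixture

cs = builtin_components()
res = predict_drh_mixture([parse_solid("citric acid:hydrate"),
                           parse_solid("fructose")], 298.15, cs)
print(round(res.drh, 1))        # 54.9 (% RH)
```

Other entry points: `deliq sorption` (equilibrium water uptake vs RH,
with the lever-rule jump at DRH and the full-dissolution breakpoint),
`deliq map` (DRH vs temperature, including hydrate/anhydrate lines and
the solid–solid transition), `deliq props` (γ and a_w of a liquid),
`deliq tables` (the full regression tables), and `deliq parameters
export/validate` (JSON parameter files; `--params` overrides the
builtin set everywhere).

Scoring the predictions against the bundled literature measurements:

```sh
$ deliq tables --out-dir out/
single components: ARD vs gravimetric DRH (n=8): PC-SAFT 2.6 %, Raoult 8.5 %
crystal mixtures: ARD vs gravimetric DRH (n=22): PC-SAFT 8.5 %, Raoult 15.0 %
```

The average relative deviation (ARD = 100/N·Σ|exp − pred|/exp) of the
PC-SAFT predictions is ~2.6 % for single crystals and ~8.5 % across 22
binary/ternary/quaternary crystal mixtures — a three- to two-fold
improvement over Raoult's law, obtained without any mixture data.

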