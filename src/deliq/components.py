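"""Component parameter database.

Holds the PC-SAFT pure-component parameters, melting properties, binary
interaction parameters and hydrate specifications needed for
deliquescence calculations, together with a bundled parameter set for
water and eight crystalline food/pharma compounds (organic acids,
sugars, an artificial sweetener and an amide).

Units follow the usual PC-SAFT tabulation conventions:

* ``segment_ratio`` is m_seg/M in mol/g; the segment number is
  ``segment_ratio * molar_mass``.
* ``sigma`` is the segment diameter in Angstrom.  Water uses a
  temperature-dependent diameter sigma(T) = c0 + c1*exp(c2*T) +
  c3*exp(c4*T).
* ``dispersion_energy`` (u/kB), ``assoc_energy`` (eps^AiBi/kB) in K.
* melting temperature in K, melting enthalpy in kJ/mol, heat-capacity
  change upon melting in J/(mol K).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

T_REF_KIJ = 298.15
"""Reference temperature (K) for 'value at 298.15 K' kij records."""


class ParameterError(ValueError):
    """Raised for missing, duplicate or non-physical parameter entries."""


@dataclass(frozen=True)
class SigmaT:
    """Temperature-dependent segment diameter c0 + c1*e^(c2*T) + c3*e^(c4*T)."""

    c0: float
    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0

    def __call__(self, T: float) -> float:
        return (self.c0 + self.c1 * math.exp(self.c2 * T)
                + self.c3 * math.exp(self.c4 * T))


@dataclass(frozen=True)
class ComponentRecord:
    """One crystalline compound or water.

    ``assoc_sites`` holds the counts of the two association site classes
    (the tabulated "a/b" notation).  Only unlike classes bond; the
    labelling of which class is donor and which acceptor is immaterial
    because the cross energies are class-symmetric.
    """

    name: str
    molar_mass: float                       # g/mol
    segment_ratio: float                    # mol/g  (m_seg / M)
    sigma: float | SigmaT                   # Angstrom
    dispersion_energy: float                # K
    assoc_energy: float = 0.0               # K
    assoc_volume: float = 0.0               # dimensionless
    assoc_sites: tuple[int, int] = (0, 0)
    melting_T: float | None = None          # K
    melting_enthalpy: float | None = None   # kJ/mol
    melting_cp_change: float = 0.0          # J/(mol K); 0 when untabulated

    def __post_init__(self):
        def bad(field_name, msg):
            raise ParameterError(
                f"component {self.name!r}: {field_name} {msg}")
        if self.molar_mass <= 0:
            bad("molar_mass", "must be > 0")
        if self.segment_ratio <= 0:
            bad("segment_ratio", "must be > 0")
        if self.dispersion_energy <= 0:
            bad("dispersion_energy", "must be > 0")
        if not 0.0 <= self.assoc_volume <= 1.0:
            bad("assoc_volume", "must lie in [0, 1]")
        if any(n < 0 for n in self.assoc_sites):
            bad("assoc_sites", "site counts must be nonnegative")
        for T in (273.15, 373.15, 500.0):
            s = self.sigma_at(T)
            if not 1.0 < s < 6.0:
                bad("sigma", f"evaluates to {s:.4f} A at {T} K, outside (1, 6)")
        if self.melting_T is not None and self.melting_T <= 0:
            bad("melting_T", "must be > 0")
        if self.melting_enthalpy is not None and self.melting_enthalpy <= 0:
            bad("melting_enthalpy", "must be > 0")

    @property
    def segment_number(self) -> float:
        return self.segment_ratio * self.molar_mass

    def sigma_at(self, T: float) -> float:
        """Segment diameter in Angstrom at temperature T (K)."""
        return self.sigma(T) if isinstance(self.sigma, SigmaT) else self.sigma

    @property
    def has_melting_data(self) -> bool:
        return self.melting_T is not None and self.melting_enthalpy is not None


RAW_INTERCEPT = "raw_intercept"
VALUE_AT_298K = "value_at_298K"


@dataclass(frozen=True)
class BinaryInteractionRecord:
    """Binary dispersion-energy correction kij, constant or linear in T.

    ``kij_ref`` is either the raw intercept of kij = kij_T*T + kij_b
    (``ref_convention='raw_intercept'``) or the kij value at 298.15 K
    (``ref_convention='value_at_298K'``, the common tabulation for
    parameters re-stated at ambient conditions).
    """

    pair: tuple[str, str]
    kij_ref: float
    kij_T: float = 0.0                      # 1/K
    ref_convention: str = VALUE_AT_298K

    def __post_init__(self):
        if self.ref_convention not in (RAW_INTERCEPT, VALUE_AT_298K):
            raise ParameterError(
                f"pair {self.pair}: unknown ref_convention "
                f"{self.ref_convention!r}")
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))
        for T in (273.15, 373.15):
            if abs(self.at(T)) >= 0.5:
                raise ParameterError(
                    f"pair {self.pair}: |kij| = {abs(self.at(T)):.3f} at "
                    f"{T} K, non-physical (>= 0.5)")

    def at(self, T: float) -> float:
        """kij evaluated at temperature T (K)."""
        if self.kij_T == 0.0:
            return self.kij_ref
        if self.ref_convention == VALUE_AT_298K:
            return self.kij_T * (T - T_REF_KIJ) + self.kij_ref
        return self.kij_T * T + self.kij_ref

    def matches(self, a: str, b: str) -> bool:
        return self.pair == tuple(sorted((a, b)))


def kij_at_temperature(record: BinaryInteractionRecord, T: float) -> float:
    """Evaluate a binary interaction parameter at temperature T (K)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return record.at(T)


@dataclass(frozen=True)
class HydrateSpec:
    """Stoichiometry and dehydration-transition data of a crystal hydrate.

    ``water_activity_at_transition`` is the water activity at which the
    hydrate and anhydrate are equally stable at ``transition_T``; it is
    close to 1 for sparingly soluble hydrates and below 1 for highly
    water-soluble ones.
    """

    anhydrate_name: str
    stoich_solute: float = 1.0
    stoich_water: float = 1.0
    transition_enthalpy: float = 0.0        # kJ/mol (dehydration)
    transition_T: float = 298.15            # K
    water_activity_at_transition: float = 1.0

    def __post_init__(self):
        if self.stoich_solute <= 0 or self.stoich_water <= 0:
            raise ParameterError(
                f"hydrate of {self.anhydrate_name!r}: stoichiometries "
                "must be > 0")
        if not 0.0 < self.water_activity_at_transition <= 1.0:
            raise ParameterError(
                f"hydrate of {self.anhydrate_name!r}: "
                "water_activity_at_transition must lie in (0, 1]")
        if self.transition_T <= 0:
            raise ParameterError(
                f"hydrate of {self.anhydrate_name!r}: transition_T must "
                "be > 0")


@dataclass
class ComponentSet:
    """A component database: components, binary pairs, hydrate forms."""

    components: dict[str, ComponentRecord] = field(default_factory=dict)
    binaries: list[BinaryInteractionRecord] = field(default_factory=list)
    hydrates: dict[str, HydrateSpec] = field(default_factory=dict)

    @classmethod
    def build(cls, components: Iterable[ComponentRecord],
              binaries: Iterable[BinaryInteractionRecord] = (),
              hydrates: Iterable[HydrateSpec] = ()) -> "ComponentSet":
        cs = cls()
        for c in components:
            if c.name in cs.components:
                raise ParameterError(f"duplicate component {c.name!r}")
            cs.components[c.name] = c
        for b in binaries:
            for n in b.pair:
                if n not in cs.components:
                    raise ParameterError(
                        f"binary pair {b.pair} references unknown "
                        f"component {n!r}")
            cs.binaries.append(b)
        for h in hydrates:
            if h.anhydrate_name not in cs.components:
                raise ParameterError(
                    f"hydrate spec references unknown component "
                    f"{h.anhydrate_name!r}")
            cs.hydrates[h.anhydrate_name] = h
        return cs

    def __getitem__(self, name: str) -> ComponentRecord:
        try:
            return self.components[name]
        except KeyError:
            raise ParameterError(f"unknown component {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.components

    def names(self) -> list[str]:
        return list(self.components)

    def kij(self, a: str, b: str, T: float) -> float:
        """kij(T) for a component pair; unregistered pairs default to 0.

        The zero default is the predictive convention for solute-solute
        pairs: no mixture data is consumed, only pure-component aqueous
        behaviour.
        """
        if a == b:
            return 0.0
        for rec in self.binaries:
            if rec.matches(a, b):
                return rec.at(T)
        return 0.0

    def hydrate(self, anhydrate_name: str) -> HydrateSpec:
        try:
            return self.hydrates[anhydrate_name]
        except KeyError:
            raise ParameterError(
                f"no hydrate registered for {anhydrate_name!r}") from None

    def require_melting(self, name: str) -> ComponentRecord:
        c = self[name]
        if not c.has_melting_data:
            raise ParameterError(
                f"component {name!r} lacks melting properties (melting_T / "
                "melting_enthalpy) required for a crystalline solid")
        return c


# ---------------------------------------------------------------------------
# Bundled parameter set
# ---------------------------------------------------------------------------

#: Water segment-diameter coefficients, sigma(T)/A =
#:   2.7927 + 10.11 exp(-0.01775 T) - 1.417 exp(-0.01146 T)
WATER_SIGMA = SigmaT(2.7927, 10.11, -0.01775, -1.417, -0.01146)

#: Formula mass of glucose (C6H12O6).  The commonly circulated parameter
#: table misprints 118.16 g/mol; the bundled set uses the formula mass so
#: that the segment number m_seg = 0.0368*M refers to the real molecule.
GLUCOSE_MOLAR_MASS = 180.16
GLUCOSE_MOLAR_MASS_PRINTED = 118.16


def builtin_components(glucose_molar_mass: float = GLUCOSE_MOLAR_MASS
                             ) -> ComponentSet:
    """The bundled parameter set: water plus eight crystalline compounds.

    Pure-component PC-SAFT parameters, aqueous binary interaction
    parameters, melting properties, and the citric-acid monohydrate
    specification. ``glucose_molar_mass`` may be overridden with the
    misprinted tabular value (118.16 g/mol) for comparison runs.
    """
    comps = [
        ComponentRecord("water", 18.02, 0.06687, WATER_SIGMA, 353.94,
                        2425.67, 0.0451, (1, 1)),
        ComponentRecord("ascorbic acid", 176.13, 0.06647, 2.367, 353.44,
                        2600.68, 0.039, (4, 1), 465.15, 29.12, 43.0),
        ComponentRecord("citric acid", 192.12, 0.0445, 2.723, 227.18,
                        2488.0, 0.044, (4, 4), 428.55, 41.84, 159.46),
        ComponentRecord("fructose", 180.16, 0.0410, 2.849, 237.19,
                        5000.0, 0.1, (5, 5), 353.2, 32.4, 0.0),
        ComponentRecord("glucose", glucose_molar_mass, 0.0368, 2.986, 244.53,
                        5000.0, 0.1, (5, 5), 408.2, 32.5, 0.0),
        ComponentRecord("nicotinamide", 122.12, 0.0381, 2.178, 176.69,
                        2195.3, 0.02, (2, 2), 401.15, 28.0, 78.12),
        ComponentRecord("lactose", 342.3, 0.0419, 2.811, 319.21,
                        5000.0, 0.1, (8, 8), 433.2, 75.3, 0.0),
        ComponentRecord("saccharin", 183.18, 0.02393, 4.125, 383.54,
                        853.03, 0.02, (1, 1), 502.9, 32.1, 0.0),
        ComponentRecord("sucrose", 342.30, 0.0435, 2.827, 297.39,
                        5000.0, 0.1, (8, 8), 433.2, 41.1, 0.0),
    ]
    # All temperature-dependent kij records are tabulated as raw intercepts
    # of kij = kij_T*T + kij_b; e.g. fructose/water kij(298.15 K) = -0.0555.
    binaries = [
        BinaryInteractionRecord(("ascorbic acid", "water"), -0.018),
        BinaryInteractionRecord(("citric acid", "water"), -0.07),
        BinaryInteractionRecord(("fructose", "water"), -0.097241,
                                1.40e-4, RAW_INTERCEPT),
        BinaryInteractionRecord(("glucose", "water"), -0.119186,
                                2.24e-4, RAW_INTERCEPT),
        BinaryInteractionRecord(("nicotinamide", "water"), -0.0294,
                                9.46e-5, RAW_INTERCEPT),
        BinaryInteractionRecord(("lactose", "water"), -0.08696,
                                1.84e-4, RAW_INTERCEPT),
        BinaryInteractionRecord(("saccharin", "water"), -0.01507),
        BinaryInteractionRecord(("sucrose", "water"), -0.113426,
                                2.56e-4, RAW_INTERCEPT),
    ]
    hydrates = [
        HydrateSpec("citric acid", 1.0, 1.0, 10.85, 309.45, 0.725),
    ]
    return ComponentSet.build(comps, binaries, hydrates)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

_COMPONENT_FIELDS = {
    "name", "molar_mass_g_mol", "segment_ratio_mol_g", "sigma_A",
    "sigma_A_coeffs", "dispersion_energy_K", "assoc_energy_K",
    "assoc_volume", "assoc_sites", "melting_T_K", "melting_enthalpy_kJ_mol",
    "melting_cp_change_J_mol_K",
}
_BINARY_FIELDS = {"pair", "kij_ref", "kij_T_per_K", "ref_convention"}
_HYDRATE_FIELDS = {
    "anhydrate_name", "stoich_solute", "stoich_water",
    "transition_enthalpy_kJ_mol", "transition_T_K",
    "water_activity_at_transition",
}


def component_set_to_dict(cs: ComponentSet) -> dict:
    comps = []
    for c in cs.components.values():
        d: dict = {
            "name": c.name,
            "molar_mass_g_mol": c.molar_mass,
            "segment_ratio_mol_g": c.segment_ratio,
            "dispersion_energy_K": c.dispersion_energy,
            "assoc_energy_K": c.assoc_energy,
            "assoc_volume": c.assoc_volume,
            "assoc_sites": list(c.assoc_sites),
        }
        if isinstance(c.sigma, SigmaT):
            d["sigma_A_coeffs"] = [c.sigma.c0, c.sigma.c1, c.sigma.c2,
                                   c.sigma.c3, c.sigma.c4]
        else:
            d["sigma_A"] = c.sigma
        if c.melting_T is not None:
            d["melting_T_K"] = c.melting_T
        if c.melting_enthalpy is not None:
            d["melting_enthalpy_kJ_mol"] = c.melting_enthalpy
        if c.melting_cp_change:
            d["melting_cp_change_J_mol_K"] = c.melting_cp_change
        comps.append(d)
    binaries = [{
        "pair": list(b.pair),
        "kij_ref": b.kij_ref,
        "kij_T_per_K": b.kij_T,
        "ref_convention": b.ref_convention,
    } for b in cs.binaries]
    hydrates = [{
        "anhydrate_name": h.anhydrate_name,
        "stoich_solute": h.stoich_solute,
        "stoich_water": h.stoich_water,
        "transition_enthalpy_kJ_mol": h.transition_enthalpy,
        "transition_T_K": h.transition_T,
        "water_activity_at_transition": h.water_activity_at_transition,
    } for h in cs.hydrates.values()]
    return {"components": comps, "binaries": binaries, "hydrates": hydrates}


def save_component_set(cs: ComponentSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(component_set_to_dict(cs), indent=2) + "\n")


def _warn_extras(kind: str, name: str, entry: Mapping, known: set) -> None:
    extras = set(entry) - known
    if extras:
        log.warning("%s %r: ignoring unknown fields %s",
                    kind, name, sorted(extras))


def component_set_from_dict(data: Mapping) -> ComponentSet:
    comps = []
    for entry in data.get("components", []):
        name = entry.get("name")
        if not name:
            raise ParameterError("component entry without a name")
        _warn_extras("component", name, entry, _COMPONENT_FIELDS)
        try:
            if "sigma_A_coeffs" in entry:
                sigma: float | SigmaT = SigmaT(*entry["sigma_A_coeffs"])
            else:
                sigma = float(entry["sigma_A"])
            comps.append(ComponentRecord(
                name=name,
                molar_mass=float(entry["molar_mass_g_mol"]),
                segment_ratio=float(entry["segment_ratio_mol_g"]),
                sigma=sigma,
                dispersion_energy=float(entry["dispersion_energy_K"]),
                assoc_energy=float(entry.get("assoc_energy_K", 0.0)),
                assoc_volume=float(entry.get("assoc_volume", 0.0)),
                assoc_sites=tuple(entry.get("assoc_sites", (0, 0))),
                melting_T=(float(entry["melting_T_K"])
                           if "melting_T_K" in entry else None),
                melting_enthalpy=(float(entry["melting_enthalpy_kJ_mol"])
                                  if "melting_enthalpy_kJ_mol" in entry
                                  else None),
                melting_cp_change=float(
                    entry.get("melting_cp_change_J_mol_K", 0.0)),
            ))
        except KeyError as exc:
            raise ParameterError(
                f"component {name!r}: missing field {exc.args[0]!r}") from None
    binaries = []
    for entry in data.get("binaries", []):
        pair = entry.get("pair")
        if not pair or len(pair) != 2:
            raise ParameterError("binary entry without a two-name pair")
        _warn_extras("binary", "/".join(pair), entry, _BINARY_FIELDS)
        binaries.append(BinaryInteractionRecord(
            pair=tuple(pair),
            kij_ref=float(entry["kij_ref"]),
            kij_T=float(entry.get("kij_T_per_K", 0.0)),
            ref_convention=entry.get("ref_convention", VALUE_AT_298K),
        ))
    hydrates = []
    for entry in data.get("hydrates", []):
        name = entry.get("anhydrate_name")
        if not name:
            raise ParameterError("hydrate entry without anhydrate_name")
        _warn_extras("hydrate", name, entry, _HYDRATE_FIELDS)
        hydrates.append(HydrateSpec(
            anhydrate_name=name,
            stoich_solute=float(entry.get("stoich_solute", 1.0)),
            stoich_water=float(entry.get("stoich_water", 1.0)),
            transition_enthalpy=float(
                entry.get("transition_enthalpy_kJ_mol", 0.0)),
            transition_T=float(entry.get("transition_T_K", 298.15)),
            water_activity_at_transition=float(
                entry.get("water_activity_at_transition", 1.0)),
        ))
    return ComponentSet.build(comps, binaries, hydrates)


def load_component_set(path: str | Path) -> ComponentSet:
    """Load a validated ComponentSet from a JSON parameter file."""
    with open(path) as fh:
        data = json.load(fh)
    return component_set_from_dict(data)


# ---------------------------------------------------------------------------
# Composition conversion
# ---------------------------------------------------------------------------

def composition_convert(amounts: Mapping[str, float], cs: ComponentSet,
                        direction: str) -> dict[str, float]:
    """Convert between mass and mole amounts, returning fractions.

    ``direction`` is ``'mass_to_mole'`` or ``'mole_to_mass'``; input
    amounts may be unnormalized (grams or moles).
    """
    if direction not in ("mass_to_mole", "mole_to_mass"):
        raise ValueError(f"unknown direction {direction!r}")
    if not amounts:
        raise ValueError("empty composition")
    vals = {}
    for name, q in amounts.items():
        if q < 0:
            raise ValueError(f"negative amount for {name!r}")
        M = cs[name].molar_mass
        vals[name] = q / M if direction == "mass_to_mole" else q * M
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("composition sums to zero")
    return {name: v / total for name, v in vals.items()}
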