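"""Solid-liquid-vapor equilibria: saturation, eutectics, and DRH.

The deliquescence relative humidity (DRH) of a crystal is the relative
humidity at which solid, saturated aqueous solution and vapor coexist.
It is obtained by solving the solid-liquid equilibrium for every
crystalline component simultaneously,

    x_i * gamma_i = exp[-dh_i/(R T) (1 - T/T_i)
                        - dcp_i/R (ln(T_i/T) - T_i/T + 1)]      (anhydrate)
    (x_i gamma_i)^nu_i (x_w gamma_w)^nu_w = Ks_hydrate(T)       (hydrate)

with x_water = 1 - sum(x_i), and reading off the water activity
a_w = x_w * gamma_w, which equals RH/100 under an ideal-gas vapor.  For
N crystals in contact the solved composition is the eutectic (eutonic):
the liquid simultaneously saturated with respect to every crystal, and
DRH_mix = 100 * a_w there.

Activity coefficients come from PC-SAFT.  The Raoult's-law variant
drops all liquid-phase non-ideality: each solute's saturation mole
fraction keeps its binary (solute/water) PC-SAFT value -- under ideal
mixing a solubility cannot depend on the co-solutes -- and
DRH_Raoult = 100 * (1 - sum of those binary saturation mole fractions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .components import ComponentSet, HydrateSpec, ComponentRecord
from .pcsaft import ConvergenceError, Mixture

log = logging.getLogger(__name__)

R_GAS = 8.31446261815324      # J/(mol K)

ANHYDRATE = "anhydrate"
HYDRATE = "hydrate"


@dataclass(frozen=True)
class SolidFormChoice:
    """A crystalline component together with its solid form."""

    component: str
    form: str = ANHYDRATE

    def __post_init__(self):
        if self.form not in (ANHYDRATE, HYDRATE):
            raise ValueError(f"unknown solid form {self.form!r}")

    def label(self) -> str:
        return (self.component if self.form == ANHYDRATE
                else f"{self.component} hydrate")


def parse_solid(spec: str) -> SolidFormChoice:
    """Parse 'name' or 'name:hydrate' into a SolidFormChoice."""
    name, sep, form = spec.partition(":")
    return SolidFormChoice(name.strip(), form.strip() if sep else ANHYDRATE)


@dataclass
class SaturationState:
    """Liquid composition saturated with respect to one or more solids."""

    T: float
    solids: list[SolidFormChoice]
    names: list[str]              # ordered component names, water first
    x: np.ndarray                 # mole fractions, same order
    gamma: np.ndarray
    a_water: float
    converged: bool
    residual_norm: float

    def x_of(self, name: str) -> float:
        return float(self.x[self.names.index(name)])

    def gamma_of(self, name: str) -> float:
        return float(self.gamma[self.names.index(name)])

    def mass_fractions(self, cs: ComponentSet) -> dict[str, float]:
        masses = {n: float(xi) * cs[n].molar_mass
                  for n, xi in zip(self.names, self.x)}
        tot = sum(masses.values())
        return {n: v / tot for n, v in masses.items()}


@dataclass
class DRHResult:
    """A deliquescence relative humidity with its saturation state."""

    drh: float                    # % RH
    saturation: SaturationState
    method: str                   # 'pcsaft' | 'raoult'


# ---------------------------------------------------------------------------
# Pure-solid reference activities
# ---------------------------------------------------------------------------

def ideal_solubility_activity(component: ComponentRecord, T: float) -> float:
    """Saturation activity x_i*gamma_i of an anhydrous crystal at T.

    Computed from the melting temperature, melting enthalpy and (when
    tabulated) the heat-capacity change upon melting.  Equals 1 at the
    melting point.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not component.has_melting_data:
        raise ValueError(
            f"component {component.name!r} has no melting properties")
    dh = component.melting_enthalpy * 1000.0    # J/mol
    Tm = component.melting_T
    dcp = component.melting_cp_change
    expo = (-dh / (R_GAS * T) * (1.0 - T / Tm)
            - dcp / R_GAS * (math.log(Tm / T) - Tm / T + 1.0))
    return math.exp(expo)


def hydrate_solubility_product(spec: HydrateSpec,
                               anhydrate: ComponentRecord,
                               T: float) -> float:
    """Temperature-dependent solubility product of a crystal hydrate.

    Built from the anhydrate melting properties, the dehydration
    transition enthalpy/temperature, and the water activity at the
    hydrate-anhydrate transition (important for highly water-soluble
    hydrates; 1 recovers the sparingly-soluble limit).
    """
    a_anh = ideal_solubility_activity(anhydrate, T)
    trans = math.exp(-spec.transition_enthalpy * 1000.0
                     / (spec.stoich_water * R_GAS * T)
                     * (1.0 - T / spec.transition_T))
    return (a_anh ** spec.stoich_solute
            * spec.water_activity_at_transition
            * trans ** spec.stoich_water)


# ---------------------------------------------------------------------------
# Saturation / eutectic solving
# ---------------------------------------------------------------------------

_MIX_CACHE: dict[tuple, Mixture] = {}


def get_mixture(cs: ComponentSet, names: tuple[str, ...]) -> Mixture:
    """Cached Mixture per (parameter set, ordered component names)."""
    key = (id(cs), names)
    mix = _MIX_CACHE.get(key)
    if mix is None:
        mix = Mixture(cs, list(names))
        if len(_MIX_CACHE) > 256:
            _MIX_CACHE.clear()
        _MIX_CACHE[key] = mix
    return mix


def _gamma_fn(mix: Mixture, activity_model: str):
    if activity_model == "pcsaft":
        return lambda T, x: mix.activity_coefficients(T, x)
    if activity_model == "ideal":
        return lambda T, x: np.ones(len(x))
    raise ValueError(f"unknown activity model {activity_model!r}")


def _log_targets(solids: list[SolidFormChoice], T: float,
                 cs: ComponentSet) -> list[float]:
    """ln of the saturation-condition right-hand side per solid."""
    out = []
    for s in solids:
        rec = cs.require_melting(s.component)
        if s.form == ANHYDRATE:
            out.append(math.log(ideal_solubility_activity(rec, T)))
        else:
            out.append(math.log(
                hydrate_solubility_product(cs.hydrate(s.component), rec, T)))
    return out


def _residuals(lnxs: np.ndarray, solids, T, mix, gamma_fn, log_tgt):
    xs = np.exp(lnxs)
    xw = 1.0 - xs.sum()
    if xw <= 1e-10:
        # infeasible iterate: push back with a large smooth penalty
        return np.full(len(xs), 50.0 + 100.0 * (xs.sum() - 1.0))
    x = np.concatenate([[xw], xs])
    gam = gamma_fn(T, x)
    res = np.empty(len(solids))
    for k, s in enumerate(solids):
        lng = math.log(xs[k] * gam[k + 1])
        if s.form == HYDRATE:
            spec = mix.cs.hydrate(s.component)
            lng = (spec.stoich_solute * lng
                   + spec.stoich_water * math.log(xw * gam[0]))
        res[k] = lng - log_tgt[k]
    return res


def _binary_saturation_x(solid: SolidFormChoice, T: float, cs: ComponentSet,
                         activity_model: str = "pcsaft") -> float:
    """Solute saturation mole fraction in the binary water/solute system."""
    st = solve_saturation([solid], T, cs, activity_model=activity_model)
    return float(st.x[1])


def solve_saturation(solids: list[SolidFormChoice], T: float,
                     cs: ComponentSet, activity_model: str = "pcsaft",
                     x0: np.ndarray | None = None,
                     tol: float = 1e-9) -> SaturationState:
    """Solve the liquid composition saturated with the given solids.

    For one solid this is the solubility; for several it is the
    eutectic (eutonic) composition.  Unknowns are the solute mole
    fractions in log space; water closes the mole balance.  The initial
    guess is the ideal (gamma = 1) solubility corrected by the
    infinite-dilution activity coefficient, damped by 0.8 for mixtures;
    on failure a homotopy from the ideal solution is attempted.
    """
    if not solids:
        raise ValueError("at least one solid is required")
    comp_names = [s.component for s in solids]
    if len(set(comp_names)) != len(comp_names):
        raise ValueError("solids must be distinct components")
    if "water" not in cs:
        raise ValueError("water must be present in the component set")
    for s in solids:
        if s.form == HYDRATE:
            cs.hydrate(s.component)   # raises if unregistered
    names = tuple(["water"] + comp_names)
    mix = get_mixture(cs, names)
    gamma_fn = _gamma_fn(mix, activity_model)
    log_tgt = _log_targets(solids, T, cs)

    if max(log_tgt) > 0:
        above = [s.label() for s, lt in zip(solids, log_tgt) if lt > 0]
        raise ValueError(
            f"saturation activity > 1 for {above} at {T} K (above melting); "
            "no crystal can coexist with the liquid")

    n = len(solids)
    if x0 is not None:
        lnx0 = np.log(np.asarray(x0, dtype=float))
    else:
        lnx0 = np.empty(n)
        if activity_model == "ideal":
            for k, s in enumerate(solids):
                lnx0[k] = _ideal_guess(s, log_tgt[k], cs)
        else:
            # infinite-dilution gamma correction, then 0.8 damping for
            # mixtures to avoid overshooting the eutectic
            xdil = np.full(len(names), 1e-7)
            xdil[0] = 1.0 - xdil[1:].sum()
            gam_inf = gamma_fn(T, xdil)
            for k, s in enumerate(solids):
                lnx0[k] = _ideal_guess(s, log_tgt[k], cs,
                                       float(gam_inf[k + 1]),
                                       float(gam_inf[0]))
        if n > 1:
            lnx0 += math.log(0.8)
        # keep the initial composition feasible
        while np.exp(lnx0).sum() > 0.7:
            lnx0 -= 0.3

    args = (solids, T, mix, gamma_fn, log_tgt)
    sol = optimize.root(_residuals, lnx0, args=args, method="hybr",
                        options={"xtol": 1e-12})
    res = _residuals(sol.x, *args)
    if (not sol.success or np.max(np.abs(res)) > tol) and n >= 1:
        # homotopy: walk gamma in from the ideal solution
        ideal0 = optimize.root(
            _ideal_residuals, lnx0, args=(solids, T, cs, log_tgt),
            method="hybr", options={"xtol": 1e-12})
        lnx = ideal0.x if ideal0.success else lnx0.copy()
        ok = True
        for lam in (0.25, 0.5, 0.75, 1.0):
            def fres(v, lam=lam):
                full = _residuals(v, *args)
                ideal = _ideal_residuals(v, solids, T, cs, log_tgt)
                return lam * full + (1.0 - lam) * ideal
            step = optimize.root(fres, lnx, method="hybr",
                                 options={"xtol": 1e-12})
            if not step.success:
                ok = False
                break
            lnx = step.x
        if ok:
            sol = optimize.root(_residuals, lnx, args=args, method="hybr",
                                options={"xtol": 1e-12})
            res = _residuals(sol.x, *args)
    resnorm = float(np.max(np.abs(res)))
    if resnorm > tol:
        raise ConvergenceError(
            f"saturation solve did not converge for "
            f"{[s.label() for s in solids]} at {T} K "
            f"(last iterate x={np.exp(sol.x)}, residual {resnorm:.2e})")
    xs = np.exp(sol.x)
    x = np.concatenate([[1.0 - xs.sum()], xs])
    gam = gamma_fn(T, x)
    return SaturationState(
        T=T, solids=list(solids), names=list(names), x=x, gamma=gam,
        a_water=float(x[0] * gam[0]), converged=True, residual_norm=resnorm)


def _ideal_guess(s: SolidFormChoice, log_tgt: float, cs: ComponentSet,
                 gam_inf: float = 1.0, gam_w: float = 1.0) -> float:
    """Initial ln x for one solid from the gamma-corrected ideal solve."""
    if s.form == ANHYDRATE:
        return min(log_tgt - math.log(gam_inf), math.log(0.6))
    spec = cs.hydrate(s.component)
    Ks = math.exp(log_tgt)
    # solve x^nu_i * (1-x)^nu_w = Ks/(gam_inf^nu_i * gam_w^nu_w) on the
    # dilute branch; cap the rhs below the maximum of the left-hand side
    # (at x = nu_i/(nu_i+nu_w)) so a root always exists
    ni, nw = spec.stoich_solute, spec.stoich_water
    rhs = Ks / (gam_inf ** ni * gam_w ** nw)
    x_peak = ni / (ni + nw)
    fmax = x_peak ** ni * (1.0 - x_peak) ** nw
    rhs = min(rhs, 0.98 * fmax)
    f = lambda lx: (ni * lx + nw * math.log1p(-math.exp(lx))
                    - math.log(rhs))
    lo, hi = math.log(1e-12), math.log(x_peak)
    try:
        return optimize.brentq(f, lo, hi, xtol=1e-12)
    except ValueError:
        return math.log(min(max(rhs, 1e-10), 0.5 * x_peak))


def _ideal_residuals(lnxs, solids, T, cs, log_tgt):
    xs = np.exp(lnxs)
    xw = 1.0 - xs.sum()
    if xw <= 1e-10:
        return np.full(len(xs), 50.0 + 100.0 * (xs.sum() - 1.0))
    out = np.empty(len(solids))
    for k, s in enumerate(solids):
        lng = lnxs[k]
        if s.form == HYDRATE:
            spec = cs.hydrate(s.component)
            lng = spec.stoich_solute * lng + spec.stoich_water * math.log(xw)
        out[k] = lng - log_tgt[k]
    return out


# ---------------------------------------------------------------------------
# DRH
# ---------------------------------------------------------------------------

def predict_drh(solids: list[SolidFormChoice] | SolidFormChoice, T: float,
                cs: ComponentSet, method: str = "pcsaft") -> DRHResult:
    """DRH of a single crystal (or delegate to the mixture solve).

    ``method='pcsaft'`` reports 100*x_w*gamma_w at saturation;
    ``method='raoult'`` reports 100*x_w at the same (PC-SAFT-derived)
    saturated composition, i.e. only the vapor equilibrium is
    idealized.
    """
    if isinstance(solids, SolidFormChoice):
        solids = [solids]
    if len(solids) > 1:
        return predict_drh_mixture(solids, T, cs, method)
    if method not in ("pcsaft", "raoult"):
        raise ValueError(f"unknown method {method!r}")
    st = solve_saturation(solids, T, cs)
    drh = 100.0 * (st.a_water if method == "pcsaft" else st.x[0])
    return DRHResult(drh=drh, saturation=st, method=method)


def predict_drh_mixture(solids: list[SolidFormChoice], T: float,
                        cs: ComponentSet, method: str = "pcsaft",
                        dry_basis=None) -> DRHResult:
    """DRH of a physical crystal mixture (its eutectic water activity).

    The dry-basis crystal composition is accepted for interface
    symmetry but has no influence on DRH_mix: the eutectic liquid is an
    intensive state.  Under ``method='raoult'`` the solubilities are
    composition-independent, so the eutectic composition is the
    superposition of the binary saturation mole fractions.
    """
    if method not in ("pcsaft", "raoult"):
        raise ValueError(f"unknown method {method!r}")
    if len(solids) == 1:
        return predict_drh(solids, T, cs, method)
    if method == "pcsaft":
        st = solve_saturation(solids, T, cs)
        return DRHResult(drh=100.0 * st.a_water, saturation=st,
                         method=method)
    # Raoult: superpose binary PC-SAFT solubilities
    xs = np.array([_binary_saturation_x(s, T, cs) for s in solids])
    xw = 1.0 - xs.sum()
    if xw <= 0:
        raise ValueError(
            "binary solubilities sum above 1; Raoult superposition "
            "breaks down for this system")
    x = np.concatenate([[xw], xs])
    names = ["water"] + [s.component for s in solids]
    st = SaturationState(
        T=T, solids=list(solids), names=names, x=x,
        gamma=np.ones(len(x)), a_water=xw, converged=True,
        residual_norm=0.0)
    return DRHResult(drh=100.0 * xw, saturation=st, method=method)


def solid_solid_transition_rh(anhydrate_name: str, T: float,
                              cs: ComponentSet) -> float | None:
    """RH at which anhydrate and hydrate crystals are equally stable.

    From coexistence of the two solids: the solute activity is pinned
    to the anhydrate saturation activity, so
    a_w = (Ks_hydrate / a_anh^nu_i)^(1/nu_w).  Above this RH the
    hydrate is the stable solid, below it the anhydrate.  Returns None
    when no hydrate is stable at any RH (T above the transition
    temperature).
    """
    spec = cs.hydrate(anhydrate_name)
    rec = cs.require_melting(anhydrate_name)
    if T > spec.transition_T:
        return None
    a_anh = ideal_solubility_activity(rec, T)
    Ks = hydrate_solubility_product(spec, rec, T)
    aw = (Ks / a_anh ** spec.stoich_solute) ** (1.0 / spec.stoich_water)
    if aw >= 1.0:
        return None
    return 100.0 * aw


def ard(predicted, experimental) -> float:
    """Average relative deviation in %, 100/N * sum(|exp-pred|/exp)."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("predicted and experimental must be equal-length "
                         "non-empty 1-D vectors")
    if np.any(exp <= 0):
        raise ValueError("experimental values must be positive")
    return float(100.0 * np.mean(np.abs(exp - pred) / exp))
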