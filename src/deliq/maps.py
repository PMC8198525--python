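"""Derived phase-behavior products: sorption isotherms, stability maps,
ternary diagrams and deliquescence-vs-composition curves.

Everything here is a thin layer of mass balances and root finds on top
of the saturation solver: a water-sorption isotherm follows the
equilibrium state of a crystal mixture as the ambient RH rises (all
solid below DRH_mix, lever-rule solid+liquid region, unsaturated
solution above full dissolution); a stability map traces DRH lines over
temperature; the ternary diagram traces the two solubility branches of
a pair of solutes to their eutectic.

Outputs are plain pandas DataFrames so they can be written to CSV and
plotted (or not) downstream.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .components import ComponentSet
from .equilibria import (HYDRATE, SaturationState, SolidFormChoice,
                         _gamma_fn, _log_targets, get_mixture, predict_drh,
                         solid_solid_transition_rh, solve_saturation)
from .pcsaft import ConvergenceError

log = logging.getLogger(__name__)

M_WATER = 18.02

PHASE_SOLID = "all-solid"
PHASE_SOLID_LIQUID = "solid+liquid"
PHASE_LIQUID = "liquid"


# ---------------------------------------------------------------------------
# Water sorption
# ---------------------------------------------------------------------------

@dataclass
class SorptionCurve:
    """RH-indexed equilibrium water content of a crystal mixture."""

    T: float
    dry_basis: dict[str, float]            # crystal mass fractions
    points: pd.DataFrame                   # columns: rh, w_water, phase
    drh_mix: float                         # % RH where sorption starts
    dissolution_rh: float                  # % RH where the last solid goes
    exhaustion: list[tuple[str, float]]    # (solid label, RH) per solid


def _crystal_molar_mass(s: SolidFormChoice, cs: ComponentSet) -> float:
    """Molar mass of the crystal as weighed in (hydrates include water)."""
    M = cs[s.component].molar_mass
    if s.form == HYDRATE:
        spec = cs.hydrate(s.component)
        M += spec.stoich_water / spec.stoich_solute * M_WATER
    return M


def _dry_moles(solids, dry_basis, cs) -> np.ndarray:
    """Moles of solute per gram of dry crystal mixture, solid order."""
    out = np.empty(len(solids))
    for k, s in enumerate(solids):
        w = dry_basis[s.component]
        out[k] = w / _crystal_molar_mass(s, cs)
        if s.form == HYDRATE:
            out[k] *= cs.hydrate(s.component).stoich_solute
    return out


def _solve_fixed_aw_subset(solids, remaining, T, cs, aw, n_tot, x_guess,
                           nL_guess):
    """Liquid state at fixed water activity with `remaining` solids left.

    Unknowns: all solute mole fractions plus the liquid mole amount
    (per gram dry basis); dissolved-out solutes are constrained to sit
    entirely in the liquid.  Returns (x_full, gamma, n_L) or raises.
    """
    names = tuple(["water"] + [s.component for s in solids])
    mix = get_mixture(cs, names)
    gamma_fn = _gamma_fn(mix, "pcsaft")
    log_tgt = _log_targets(solids, T, cs)
    rem_idx = [k for k, s in enumerate(solids) if s in remaining]
    out_idx = [k for k, s in enumerate(solids) if s not in remaining]
    ln_aw = math.log(aw)

    def fun(v):
        xs = np.exp(np.clip(v[:-1], -700.0, 700.0))
        nL = math.exp(min(max(v[-1], -600.0), 600.0))
        xw = 1.0 - xs.sum()
        if xw <= 1e-10:
            return np.full(len(v), 50.0 + 100.0 * xs.sum())
        x = np.concatenate([[xw], xs])
        gam = gamma_fn(T, x)
        res = np.empty(len(v))
        for i, k in enumerate(rem_idx):
            s = solids[k]
            lng = math.log(xs[k] * gam[k + 1])
            if s.form == HYDRATE:
                spec = cs.hydrate(s.component)
                lng = (spec.stoich_solute * lng
                       + spec.stoich_water * math.log(xw * gam[0]))
            res[i] = lng - log_tgt[k]
        res[len(rem_idx)] = math.log(xw * gam[0]) - ln_aw
        for i, k in enumerate(out_idx):
            res[len(rem_idx) + 1 + i] = (math.log(xs[k] * nL)
                                         - math.log(n_tot[k]))
        return res

    v0 = np.concatenate([np.log(x_guess), [math.log(nL_guess)]])
    sol = optimize.root(fun, v0, method="hybr", options={"xtol": 1e-12})
    res = fun(sol.x)
    if not sol.success and np.max(np.abs(res)) > 1e-8:
        raise ConvergenceError(
            f"fixed-aw solve failed (remaining={remaining}, aw={aw})")
    xs = np.exp(sol.x[:-1])
    nL = math.exp(sol.x[-1])
    xw = 1.0 - xs.sum()
    x = np.concatenate([[xw], xs])
    gam = gamma_fn(T, x)
    return x, gam, nL


def _sorption_state(solids, T, cs, aw, n_tot, eut: SaturationState):
    """Equilibrium state of the mixture at water activity `aw` above
    DRH_mix: returns (w_water, phase, remaining labels)."""
    nsol = len(solids)
    # candidate remaining-solid subsets, largest first
    for size in range(nsol - 1, -1, -1):
        for rem in itertools.combinations(solids, size):
            rem = list(rem)
            try:
                if size == 0:
                    x, gam, nL = _dissolved_state(solids, T, cs, aw, n_tot)
                else:
                    x_guess = np.clip(eut.x[1:], 1e-12, None)
                    nL_guess = max((n_tot[k] / max(eut.x[k + 1], 1e-12)
                                    for k, s in enumerate(solids)
                                    if s not in rem), default=1e-3)
                    x, gam, nL = _solve_fixed_aw_subset(
                        solids, rem, T, cs, aw, n_tot, x_guess, nL_guess)
            except (ConvergenceError, ValueError):
                continue
            if not _state_admissible(solids, rem, T, cs, x, gam, nL, n_tot):
                continue
            w = _w_water(solids, rem, cs, x, nL, n_tot)
            phase = PHASE_LIQUID if size == 0 else PHASE_SOLID_LIQUID
            return w, phase, [s.label() for s in rem]
    raise ConvergenceError(f"no admissible phase split at aw={aw}")


def _dissolved_state(solids, T, cs, aw, n_tot):
    """Unsaturated solution with the dry-basis solute ratio at given aw."""
    names = tuple(["water"] + [s.component for s in solids])
    mix = get_mixture(cs, names)
    gamma_fn = _gamma_fn(mix, "pcsaft")
    frac = n_tot / n_tot.sum()

    def f(ln_xtot):
        xtot = math.exp(ln_xtot)
        x = np.concatenate([[1.0 - xtot], xtot * frac])
        gam = gamma_fn(T, x)
        return math.log(x[0] * gam[0]) - math.log(aw)

    sol = optimize.brentq(f, math.log(1e-10), math.log(0.75), xtol=1e-13)
    xtot = math.exp(sol)
    x = np.concatenate([[1.0 - xtot], xtot * frac])
    gam = gamma_fn(T, x)
    nL = n_tot.sum() / xtot
    return x, gam, nL


def _state_admissible(solids, rem, T, cs, x, gam, nL, n_tot,
                      tol=1e-7) -> bool:
    log_tgt = _log_targets(solids, T, cs)
    for k, s in enumerate(solids):
        if s in rem:
            if n_tot[k] - x[k + 1] * nL < -tol * max(n_tot[k], 1e-12):
                return False     # negative solid amount
        else:
            lng = math.log(max(x[k + 1], 1e-300) * gam[k + 1])
            if s.form == HYDRATE:
                spec = cs.hydrate(s.component)
                lng = (spec.stoich_solute * lng
                       + spec.stoich_water * math.log(x[0] * gam[0]))
            if lng > log_tgt[k] + 1e-7:
                return False     # supersaturated in a dissolved solute
    return True


def _w_water(solids, rem, cs, x, nL, n_tot) -> float:
    """Mass fraction of sorbed water in (dry solids + sorbed water)."""
    water_liq = x[0] * nL * M_WATER
    bound = 0.0
    for k, s in enumerate(solids):
        if s.form == HYDRATE:
            spec = cs.hydrate(s.component)
            n_solid = (n_tot[k] - x[k + 1] * nL) if s in rem else 0.0
            # change in crystal-bound water relative to the dry basis
            bound += (n_solid - n_tot[k]) / spec.stoich_solute \
                * spec.stoich_water * M_WATER
    sorbed = water_liq + bound
    return sorbed / (1.0 + sorbed)


def sorption_breakpoints(solids, dry_basis, T, cs):
    """(DRH_mix, uptake at DRH_mix, [(label, RH)] exhaustion sequence,
    full-dissolution RH, uptake at full dissolution).

    The uptake at DRH_mix is the lever-rule water content of the state
    in which the liquid has the eutectic composition and the
    first-exhausted solid is fully dissolved.
    """
    solids = list(solids)
    n_tot = _dry_moles(solids, dry_basis, cs)
    eut = solve_saturation(solids, T, cs)
    drh_mix = 100.0 * eut.a_water
    if len(solids) == 1:
        nL = n_tot[0] / eut.x[1]
        w0 = _w_water(solids, [], cs, eut.x, nL, n_tot)
        return drh_mix, w0, [(solids[0].label(), drh_mix)], drh_mix, w0

    # at DRH_mix the liquid is eutectic; the binding solute is the one
    # exhausted first (smallest n_tot_k / x_eut_k)
    ratios = n_tot / eut.x[1:]
    first = int(np.argmin(ratios))
    nL0 = float(ratios[first])
    rem0 = [s for k, s in enumerate(solids) if k != first]
    w0 = _w_water(solids, rem0, cs, eut.x, nL0, n_tot)

    # walk the exhaustion sequence upward in RH
    exhaustion = [(solids[first].label(), drh_mix)]
    remaining = rem0
    aw_lo = eut.a_water
    while remaining:
        next_rh, gone = _next_exhaustion(solids, remaining, T, cs, n_tot,
                                         eut, aw_lo)
        exhaustion.append((gone.label(), next_rh))
        remaining = [s for s in remaining if s is not gone]
        aw_lo = next_rh / 100.0
    full_rh = exhaustion[-1][1]
    # uptake just below full dissolution == dissolved state at that aw
    x, gam, nL = _dissolved_state(solids, T, cs, full_rh / 100.0, n_tot)
    w_full = _w_water(solids, [], cs, x, nL, n_tot)
    return drh_mix, w0, exhaustion, full_rh, w_full


def _next_exhaustion(solids, remaining, T, cs, n_tot, eut, aw_lo):
    """RH at which the next solid of `remaining` is exhausted.

    Marches the fixed-a_w state upward in water activity with warm
    starts; the first remaining solid whose amount crosses zero sets
    the breakpoint.
    """
    warm = {"x": np.clip(eut.x[1:], 1e-12, None),
            "nL": max((n_tot[k] / max(eut.x[k + 1], 1e-12)
                       for k, s in enumerate(solids) if s not in remaining),
                      default=1e-3)}

    def amounts(aw):
        x, gam, nL = _solve_fixed_aw_subset(
            solids, remaining, T, cs, aw, n_tot, warm["x"], warm["nL"])
        warm["x"], warm["nL"] = np.clip(x[1:], 1e-12, None), nL
        return n_tot - x[1:] * nL

    lo = aw_lo + 1e-9
    rem_idx = [solids.index(s) for s in remaining]
    prev_aw, prev_amt = lo, amounts(lo)
    if min(prev_amt[rem_idx]) <= 0:
        k = rem_idx[int(np.argmin(prev_amt[rem_idx]))]
        return 100.0 * lo, solids[k]
    for aw in np.linspace(lo, 0.9995, 16)[1:]:
        amt = amounts(aw)
        if min(amt[rem_idx]) <= 0:
            k = rem_idx[int(np.argmin(amt[rem_idx]))]
            root = optimize.brentq(lambda a: amounts(a)[k],
                                   prev_aw, aw, xtol=1e-10)
            return 100.0 * root, solids[k]
        prev_aw, prev_amt = aw, amt
    raise ConvergenceError("could not locate the next solid exhaustion "
                           "below 99.95% RH")


def water_sorption_isotherm(solids, dry_basis: dict[str, float], T: float,
                            cs: ComponentSet,
                            rh_grid=None) -> SorptionCurve:
    """Equilibrium water sorption of a crystal mixture versus RH.

    Below DRH_mix the crystals sorb nothing; at DRH_mix the uptake
    jumps to the lever-rule value; while solids remain, the liquid sits
    on the relevant solubility boundary; above full dissolution the
    solution is diluted until a_w matches RH/100.  RH = 100 is an
    asymptote (w_water -> 1) and is never solved.
    """
    solids = [s if isinstance(s, SolidFormChoice) else SolidFormChoice(s)
              for s in solids]
    missing = [s.component for s in solids if s.component not in dry_basis]
    if missing:
        raise ValueError(f"dry_basis lacks entries for {missing}")
    tot = sum(dry_basis.values())
    dry_basis = {k: v / tot for k, v in dry_basis.items()}
    n_tot = _dry_moles(solids, dry_basis, cs)
    eut = solve_saturation(solids, T, cs)
    drh_mix, w0, exhaustion, full_rh, _ = sorption_breakpoints(
        solids, dry_basis, T, cs)
    if rh_grid is None:
        rh_grid = np.arange(0.5, 100.0, 0.5)
    rows = []
    for rh in np.asarray(rh_grid, dtype=float):
        if not 0.0 < rh < 100.0:
            raise ValueError("RH grid must lie inside (0, 100)")
        if rh < drh_mix:
            rows.append((rh, 0.0, PHASE_SOLID, ""))
            continue
        w, phase, rem = _sorption_state(solids, T, cs, rh / 100.0,
                                        n_tot, eut)
        rows.append((rh, w, phase, "+".join(rem)))
    # make the DRH jump explicit in the tabulated points
    rows.append((drh_mix, w0, PHASE_SOLID_LIQUID,
                 "+".join(s.label() for k, s in enumerate(solids)
                          if s.label() != exhaustion[0][0])))
    df = (pd.DataFrame(rows, columns=["rh", "w_water", "phase",
                                      "solids_remaining"])
          .sort_values(["rh", "w_water"]).reset_index(drop=True))
    return SorptionCurve(T=T, dry_basis=dry_basis, points=df,
                         drh_mix=drh_mix, dissolution_rh=full_rh,
                         exhaustion=exhaustion)


# ---------------------------------------------------------------------------
# Temperature sweeps
# ---------------------------------------------------------------------------

@dataclass
class StabilityMap:
    """Temperature-indexed DRH lines plus the solid-solid transition."""

    T_grid: np.ndarray
    lines: pd.DataFrame        # columns: T, line, drh


def drh_temperature_sweep(scenarios: dict[str, list[SolidFormChoice]],
                          T_grid, cs: ComponentSet,
                          include_transition_for: str | None = None
                          ) -> StabilityMap:
    """DRH of each named solid-form scenario across a temperature grid.

    Failed points are recorded as NaN with a warning rather than
    aborting the sweep.  Adjacent solutions warm-start each other.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    rows = []
    for label, solids in scenarios.items():
        x_prev = None
        for T in T_grid:
            try:
                st = solve_saturation(solids, T, cs, x0=x_prev)
                x_prev = st.x[1:]
                rows.append((T, label, 100.0 * st.a_water))
            except (ConvergenceError, ValueError) as exc:
                log.warning("sweep point %s @ %.2f K failed: %s",
                            label, T, exc)
                rows.append((T, label, np.nan))
                x_prev = None
    if include_transition_for is not None:
        for T in T_grid:
            rh = solid_solid_transition_rh(include_transition_for, T, cs)
            rows.append((T, f"{include_transition_for} solid-solid",
                         np.nan if rh is None else rh))
    return StabilityMap(T_grid=T_grid,
                        lines=pd.DataFrame(rows,
                                           columns=["T", "line", "drh"]))


# ---------------------------------------------------------------------------
# Binary-solute diagrams
# ---------------------------------------------------------------------------

def saturation_with_background(solid: SolidFormChoice, T: float,
                               cs: ComponentSet,
                               background: dict[str, float],
                               x0: float | None = None):
    """Saturation of one solid with fixed co-solute mole fractions.

    Returns the full mole-fraction vector ordered (water, solid solute,
    *background names*) and the activity-coefficient vector.
    """
    bg_names = list(background)
    names = tuple(["water", solid.component] + bg_names)
    mix = get_mixture(cs, names)
    gamma_fn = _gamma_fn(mix, "pcsaft")
    log_tgt = _log_targets([solid], T, cs)[0]
    xbg = np.array([background[n] for n in bg_names])

    def f(lnx):
        xs = math.exp(lnx)
        xw = 1.0 - xs - xbg.sum()
        if xw <= 1e-10:
            return 50.0
        x = np.concatenate([[xw, xs], xbg])
        gam = gamma_fn(T, x)
        lng = math.log(xs * gam[1])
        if solid.form == HYDRATE:
            spec = cs.hydrate(solid.component)
            lng = (spec.stoich_solute * lng
                   + spec.stoich_water * math.log(xw * gam[0]))
        return lng - log_tgt

    guess = math.log(x0) if x0 else log_tgt
    sol = optimize.root_scalar(f, x0=guess, x1=guess - 0.2,
                               method="secant", xtol=1e-12)
    if not sol.converged:
        raise ConvergenceError(
            f"background saturation failed for {solid.label()}")
    xs = math.exp(sol.root)
    x = np.concatenate([[1.0 - xs - xbg.sum(), xs], xbg])
    return x, gamma_fn(T, x)


def ternary_solubility_diagram(solute_a: str, solute_b: str, T: float,
                               cs: ComponentSet, n_branch: int = 15,
                               contour_aw_levels=()) -> dict:
    """Solubility branches, eutectic and iso-a_w contours for two solutes.

    Each branch traces the liquid saturated with one solute while the
    co-solute concentration runs from zero to the eutectic.  Contours
    are iso-water-activity lines through the unsaturated liquid region.
    """
    if solute_a == solute_b:
        raise ValueError("solutes must differ")
    sa, sb = SolidFormChoice(solute_a), SolidFormChoice(solute_b)
    eut = solve_saturation([sa, sb], T, cs)
    xa_e, xb_e = eut.x[1], eut.x[2]
    branches = []
    for solid, other, x_other_e in ((sa, solute_b, xb_e),
                                    (sb, solute_a, xa_e)):
        prev = None
        for x_other in np.linspace(0.0, x_other_e, n_branch):
            x, gam = saturation_with_background(
                solid, T, cs, {other: float(x_other)}, x0=prev)
            prev = float(x[1])
            row = {"branch": solid.label(), "x_water": x[0],
                   f"x_{solid.component}": x[1], f"x_{other}": x_other,
                   "a_water": x[0] * gam[0]}
            branches.append(row)
    branch_df = pd.DataFrame(branches)
    contours = []
    n_solutes = np.array([1.0, 1.0])
    for level in contour_aw_levels:
        for fa in np.linspace(0.0, 1.0, 21):
            frac = np.array([fa, 1.0 - fa])
            names = tuple(["water", solute_a, solute_b])
            mix = get_mixture(cs, names)
            gamma_fn = _gamma_fn(mix, "pcsaft")

            def f(ln_xtot):
                xt = math.exp(ln_xtot)
                x = np.concatenate([[1.0 - xt], xt * frac])
                gam = gamma_fn(T, x)
                return math.log(x[0] * gam[0]) - math.log(level)

            try:
                root = optimize.brentq(f, math.log(1e-10), math.log(0.75),
                                       xtol=1e-12)
            except ValueError:
                continue
            xt = math.exp(root)
            contours.append({"a_water": level, f"x_{solute_a}": xt * fa,
                             f"x_{solute_b}": xt * (1 - fa),
                             "x_water": 1.0 - xt})
    return {"branches": branch_df,
            "eutectic": eut,
            "contours": pd.DataFrame(contours)}


def deliquescence_vs_composition(solute_a: str, solute_b: str, T: float,
                                 cs: ComponentSet,
                                 w_grid=None) -> pd.DataFrame:
    """RH at which the last crystal dissolves vs dry-basis composition.

    V-shaped: both branches meet at the eutonic composition at DRH_mix;
    the endpoints are the single-crystal DRH values.
    """
    sa, sb = SolidFormChoice(solute_a), SolidFormChoice(solute_b)
    eut = solve_saturation([sa, sb], T, cs)
    drh_mix = 100.0 * eut.a_water
    # eutonic dry-basis mass fraction of solute a
    Ma, Mb = cs[solute_a].molar_mass, cs[solute_b].molar_mass
    wa_e = eut.x[1] * Ma / (eut.x[1] * Ma + eut.x[2] * Mb)
    if w_grid is None:
        w_grid = np.round(np.linspace(0.0, 1.0, 21), 6)
    rows = []
    for wa in np.asarray(w_grid, dtype=float):
        if wa in (0.0, 1.0):
            solid = sb if wa == 0.0 else sa
            rh = predict_drh([solid], T, cs).drh
        elif abs(wa - wa_e) < 1e-12:
            rh = drh_mix
        else:
            solids = [sa, sb]
            dry = {solute_a: wa, solute_b: 1.0 - wa}
            n_tot = _dry_moles(solids, dry, cs)
            *_, full_rh, _ = sorption_breakpoints(solids, dry, T, cs)
            rh = full_rh
        rows.append({"w_dry_" + solute_a: wa, "dissolution_rh": rh})
    df = pd.DataFrame(rows)
    df.attrs["drh_mix"] = drh_mix
    df.attrs["eutonic_w_" + solute_a] = wa_e
    return df
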