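"""PC-SAFT residual Helmholtz energy and liquid-phase activity coefficients.

The residual Helmholtz energy is the sum of hard-chain repulsion,
dispersion, and association contributions,

    a_res = a_hc + a_disp + a_assoc            (per molecule, units of kT)

evaluated with Lorentz-Berthelot combining rules for the segment
diameter and dispersion energy and Wolbach-Sandler rules for the cross
association energy and volume.  The hard-chain and dispersion terms
follow the original perturbed-chain formulation (Gross-Sadowski
universal constants); association uses the two-site-class Wertheim
treatment in which a component carries ``(Na, Nb)`` sites of two
classes and only unlike classes bond, with association strength

    Delta_ij = sigma_ij^3 * g_ij^hs(d) * kappa_ij * (exp(eps_ij/T) - 1).

Internal units: temperature K, lengths Angstrom, number density
molecules/A^3; pressures in Pa at the interface.

Composition and density derivatives of a_res are analytic.  The
association contribution is differentiated via the stationarity of the
site-fraction mass balance (the bonding functional is extremal in the
site fractions, so only explicit density/composition dependence
survives), which keeps the expressions closed-form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
import numpy as np
from scipy import optimize

from .components import ComponentSet

log = logging.getLogger(__name__)

KB = 1.380649e-23          # J/K
NAV = 6.02214076e23        # 1/mol
P_DEFAULT = 101_325.0      # Pa; all liquid properties evaluated here
ETA_MAX = 0.7405

# Universal dispersion-integral constants (power series in packing fraction).
A0 = np.array([0.9105631445, 0.6361281449, 2.6861347891, -26.547362491,
               97.759208784, -159.59154087, 91.297774084])
A1 = np.array([-0.3084016918, 0.1860531159, -2.5030047259, 21.419793629,
               -65.255885330, 83.318680481, -33.746922930])
A2 = np.array([-0.0906148351, 0.4527842806, 0.5962700728, -1.7241829131,
               -4.1302112531, 13.776631870, -8.6728470368])
B0 = np.array([0.7240946941, 2.2382791861, -4.0025849485, -21.003576815,
               26.855641363, 206.55133841, -355.60235612])
B1 = np.array([-0.5755498075, 0.6995095521, 3.8925673390, -17.215471648,
               192.67226447, -161.82646165, -165.20769346])
B2 = np.array([0.0976883116, -0.2557574982, -9.1558561530, 20.642075974,
               -38.804430052, 93.626774077, -29.666905585])
_POW = np.arange(7)


class ConvergenceError(RuntimeError):
    """Raised when an inner EOS solve (sites or density) fails."""


@dataclass(frozen=True)
class CrossParameters:
    """Pair matrices of combining-rule parameters at one temperature."""

    T: float
    sigma: np.ndarray        # A, (n, n)
    u: np.ndarray            # K, (n, n), includes (1 - kij(T))
    eps_assoc: np.ndarray    # K, (n, n)
    kappa_assoc: np.ndarray  # (n, n)


class Mixture:
    """An ordered list of components bound to a parameter set.

    Precomputes per-component arrays and provides the Helmholtz-energy
    machinery, density solving, fugacity and activity coefficients.
    """

    def __init__(self, cs: ComponentSet, names: list[str] | tuple[str, ...]):
        self.cs = cs
        self.names = list(names)
        recs = [cs[n] for n in self.names]
        self.n = len(recs)
        self.m = np.array([r.segment_number for r in recs])
        self.M = np.array([r.molar_mass for r in recs])
        self.eps_self = np.array([r.assoc_energy for r in recs])
        self.kap_self = np.array([r.assoc_volume for r in recs])
        self.Na = np.array([r.assoc_sites[0] for r in recs], dtype=float)
        self.Nb = np.array([r.assoc_sites[1] for r in recs], dtype=float)
        self.u_self = np.array([r.dispersion_energy for r in recs])
        self._recs = recs
        self._cross_cache: dict[float, CrossParameters] = {}
        self._site_warm: np.ndarray | None = None
        self._eta_warm: float | None = None

    def index(self, name: str) -> int:
        return self.names.index(name)

    # -- combining rules ---------------------------------------------------

    def sigma_at(self, T: float) -> np.ndarray:
        return np.array([r.sigma_at(T) for r in self._recs])

    def cross_parameters(self, T: float) -> CrossParameters:
        cp = self._cross_cache.get(T)
        if cp is not None:
            return cp
        sig = self.sigma_at(T)
        sigma_ij = 0.5 * (sig[:, None] + sig[None, :])
        kij = np.zeros((self.n, self.n))
        for i, a in enumerate(self.names):
            for j, b in enumerate(self.names):
                if i < j:
                    kij[i, j] = kij[j, i] = self.cs.kij(a, b, T)
        u_ij = np.sqrt(np.outer(self.u_self, self.u_self)) * (1.0 - kij)
        eps_ij = 0.5 * (self.eps_self[:, None] + self.eps_self[None, :])
        # Wolbach-Sandler: kappa_ij * sigma_ij^3 is the geometric mean of
        # the pure-component kappa*sigma^3 bonding volumes.
        kap_ij = (np.sqrt(np.outer(self.kap_self, self.kap_self))
                  * (np.sqrt(np.outer(sig, sig)) / sigma_ij) ** 3)
        cp = CrossParameters(T, sigma_ij, u_ij, eps_ij, kap_ij)
        if len(self._cross_cache) > 64:
            self._cross_cache.clear()
        self._cross_cache[T] = cp
        return cp

    def d_at(self, T: float) -> np.ndarray:
        """Temperature-dependent segment diameters (A)."""
        return self.sigma_at(T) * (1.0 - 0.12 * np.exp(-3.0 * self.u_self / T))

    # -- Helmholtz energy and derivatives ----------------------------------

    def _state(self, T: float, rho: float, x: np.ndarray):
        """Precompute geometry for (T, rho, x); x need not be normalized
        for derivative purposes but physically sums to 1."""
        cp = self.cross_parameters(T)
        d = self.d_at(T)
        zeta = math.pi / 6.0 * rho * np.array(
            [np.dot(x, self.m * d ** k) for k in range(4)])
        return cp, d, zeta

    @staticmethod
    def _ghs(d: np.ndarray, zeta: np.ndarray) -> np.ndarray:
        """Hard-sphere radial distribution function at contact, pair matrix."""
        z2, z3 = zeta[2], zeta[3]
        dd = np.outer(d, d) / (d[:, None] + d[None, :])
        om = 1.0 - z3
        return (1.0 / om + dd * 3.0 * z2 / om ** 2
                + dd ** 2 * 2.0 * z2 ** 2 / om ** 3)

    @staticmethod
    def _ghs_dz(d: np.ndarray, zeta: np.ndarray):
        """(dg/dzeta2, dg/dzeta3) pair matrices."""
        z2, z3 = zeta[2], zeta[3]
        dd = np.outer(d, d) / (d[:, None] + d[None, :])
        om = 1.0 - z3
        dg_dz2 = 3.0 * dd / om ** 2 + 4.0 * dd ** 2 * z2 / om ** 3
        dg_dz3 = (1.0 / om ** 2 + 6.0 * dd * z2 / om ** 3
                  + 6.0 * dd ** 2 * z2 ** 2 / om ** 4)
        return dg_dz2, dg_dz3

    @staticmethod
    def _ahs_and_dz(zeta: np.ndarray):
        """Hard-sphere free energy per segment and its zeta-gradient."""
        z0, z1, z2, z3 = zeta
        om = 1.0 - z3
        lnom = math.log(om)
        t1 = 3.0 * z1 * z2 / om
        t2 = z2 ** 3 / (z3 * om ** 2)
        t3 = (z2 ** 3 / z3 ** 2 - z0) * lnom
        a = (t1 + t2 + t3) / z0
        da0 = -(t1 + t2) / z0 ** 2 - (z2 ** 3 / (z0 ** 2 * z3 ** 2)) * lnom
        da1 = 3.0 * z2 / (z0 * om)
        da2 = (3.0 * z1 / (z0 * om) + 3.0 * z2 ** 2 / (z0 * z3 * om ** 2)
               + 3.0 * z2 ** 2 * lnom / (z0 * z3 ** 2))
        da3 = ((3.0 * z1 * z2 / om ** 2
                + z2 ** 3 * (2.0 / (z3 * om ** 3) - 1.0 / (z3 ** 2 * om ** 2)))
               / z0
               - 2.0 * z2 ** 3 * lnom / (z0 * z3 ** 3)
               - (z2 ** 3 / z3 ** 2 - z0) / (z0 * om))
        return a, np.array([da0, da1, da2, da3])

    # -- association -------------------------------------------------------

    def _delta(self, cp: CrossParameters, T: float, d: np.ndarray,
               zeta: np.ndarray):
        """Association strength matrix and its (dzeta2, dzeta3) partials."""
        g = self._ghs(d, zeta)
        dg2, dg3 = self._ghs_dz(d, zeta)
        pref = (cp.sigma ** 3 * cp.kappa_assoc
                * np.expm1(cp.eps_assoc / T))
        # pairs with no association sites never bond
        has_a = (self.Na > 0) | (self.Nb > 0)
        mask = np.outer(has_a, has_a)
        pref = np.where(mask, pref, 0.0)
        return pref * g, pref * dg2, pref * dg3

    def solve_site_fractions(self, T: float, rho: float, x: np.ndarray,
                             delta: np.ndarray | None = None,
                             zeta=None, d=None):
        """Non-bonded site fractions (XA, XB) from the mass-action balance.

        Damped successive substitution (damping 0.5, tolerance 1e-12 on
        the residual, max 500 iterations), with a Newton fallback.
        """
        if delta is None:
            cp, d, zeta = self._state(T, rho, x)
            delta, _, _ = self._delta(cp, T, d, zeta)
        if not np.any(delta):
            ones = np.ones(self.n)
            return ones, ones.copy()
        n = self.n
        warm = self._site_warm
        if warm is not None and len(warm) == 2 * n:
            XA, XB = warm[:n].copy(), warm[n:].copy()
        else:
            XA = np.full(n, 0.2)
            XB = np.full(n, 0.2)
        # damped successive substitution into the Newton basin, then a
        # Newton polish to machine precision
        damp = 0.5
        for it in range(500):
            XA_new = 1.0 / (1.0 + rho * delta @ (x * self.Nb * XB))
            XB_new = 1.0 / (1.0 + rho * delta @ (x * self.Na * XA))
            res = max(np.max(np.abs(XA_new - XA)), np.max(np.abs(XB_new - XB)))
            XA = damp * XA_new + (1.0 - damp) * XA
            XB = damp * XB_new + (1.0 - damp) * XB
            if res < 1e-12 or (it >= 15 and res < 1e-3):
                break
        converged = self._site_newton(rho, x, delta, XA, XB)
        if not converged:
            # restart Newton from a fresh SS run with heavy damping
            XA = np.full(n, 0.1)
            XB = np.full(n, 0.1)
            for _ in range(200):
                XA_new = 1.0 / (1.0 + rho * delta @ (x * self.Nb * XB))
                XB_new = 1.0 / (1.0 + rho * delta @ (x * self.Na * XA))
                XA = 0.2 * XA_new + 0.8 * XA
                XB = 0.2 * XB_new + 0.8 * XB
            converged = self._site_newton(rho, x, delta, XA, XB)
        if not converged:
            raise ConvergenceError(
                f"association site-fraction solve failed at T={T} K, "
                f"rho={rho} A^-3, x={x}")
        self._site_warm = np.concatenate([XA, XB])
        return XA, XB

    def _site_newton(self, rho, x, delta, XA, XB) -> bool:
        """In-place Newton on the stacked site balance; True on success."""
        n = self.n
        wB = rho * x * self.Nb
        wA = rho * x * self.Na
        prev_res = np.inf
        for _ in range(80):
            sA = delta @ (wB * XB)          # 1/XA - 1 target
            sB = delta @ (wA * XA)
            rA = XA * (1.0 + sA) - 1.0
            rB = XB * (1.0 + sB) - 1.0
            res = max(np.max(np.abs(rA)), np.max(np.abs(rB)))
            # polish to machine precision: warm/cold starts must agree to
            # ~1e-15 or downstream finite differences see the noise
            if res < 1e-15 or (res < 1e-12 and res >= prev_res):
                return True
            prev_res = res
            J = np.zeros((2 * n, 2 * n))
            J[:n, :n] = np.diag(1.0 + sA)
            J[:n, n:] = XA[:, None] * delta * wB[None, :]
            J[n:, :n] = XB[:, None] * delta * wA[None, :]
            J[n:, n:] = np.diag(1.0 + sB)
            try:
                step = np.linalg.solve(J, -np.concatenate([rA, rB]))
            except np.linalg.LinAlgError:
                return False
            XA_new = XA + step[:n]
            XB_new = XB + step[n:]
            if (np.any(~np.isfinite(XA_new)) or np.any(XA_new <= 0)
                    or np.any(XB_new <= 0) or np.any(XA_new > 1.2)
                    or np.any(XB_new > 1.2)):
                # halve until admissible
                lam = 1.0
                for _ in range(30):
                    lam *= 0.5
                    XA_new = XA + lam * step[:n]
                    XB_new = XB + lam * step[n:]
                    if (np.all(np.isfinite(XA_new)) and np.all(XA_new > 0)
                            and np.all(XB_new > 0)):
                        break
                else:
                    return False
            XA[:] = XA_new
            XB[:] = XB_new
        return False

    # -- full residual Helmholtz energy ------------------------------------

    def ares(self, T: float, rho: float, x: np.ndarray) -> float:
        """Reduced residual Helmholtz energy per molecule, A_res/(N kT)."""
        return self._eval(T, rho, x, derivs="none")[0]

    def _eval(self, T: float, rho: float, x: np.ndarray,
              derivs: str = "all"):
        """Return (ares, dares_drho, dares_dx) at fixed (T, rho).

        dares_dx are the raw partials treating x as independent
        (un-normalized) variables; directional sums handle the simplex
        constraint in the fugacity expression.
        """
        x = np.asarray(x, dtype=float)
        cp, d, zeta = self._state(T, rho, x)
        z0, z1, z2, z3 = zeta
        if z3 >= ETA_MAX:
            raise ValueError(f"packing fraction {z3:.4f} >= {ETA_MAX}")
        mbar = float(np.dot(x, self.m))
        # zeta partials
        dz_drho = zeta / rho
        dz_dx = math.pi / 6.0 * rho * np.stack(
            [self.m * d ** k for k in range(4)])        # (4, n)

        # hard chain ------------------------------------------------------
        ahs, dahs_dz = self._ahs_and_dz(zeta)
        g = self._ghs(d, zeta)
        dg2, dg3 = self._ghs_dz(d, zeta)
        gii = np.diag(g).copy()
        dgii_dz2 = np.diag(dg2).copy()
        dgii_dz3 = np.diag(dg3).copy()
        a_hc = mbar * ahs - float(np.dot(x, (self.m - 1.0) * np.log(gii)))

        # dispersion ------------------------------------------------------
        eta = z3
        epow = eta ** _POW
        mf1 = (mbar - 1.0) / mbar
        mf2 = mf1 * (mbar - 2.0) / mbar
        ai = A0 + mf1 * A1 + mf2 * A2
        bi = B0 + mf1 * B1 + mf2 * B2
        I1 = float(ai @ epow)
        I2 = float(bi @ epow)
        ur = cp.u / T
        mm = np.outer(x * self.m, x * self.m)
        s3 = cp.sigma ** 3
        m2es3 = float(np.sum(mm * ur * s3))
        m2e2s3 = float(np.sum(mm * ur ** 2 * s3))
        om = 1.0 - eta
        f1 = mbar * (8.0 * eta - 2.0 * eta ** 2) / om ** 4
        f2 = ((1.0 - mbar) * (20.0 * eta - 27.0 * eta ** 2
                              + 12.0 * eta ** 3 - 2.0 * eta ** 4)
              / (om * (2.0 - eta)) ** 2)
        C1 = 1.0 / (1.0 + f1 + f2)
        a_disp = (-2.0 * math.pi * rho * I1 * m2es3
                  - math.pi * rho * mbar * C1 * I2 * m2e2s3)

        # association -----------------------------------------------------
        delta, ddel_dz2, ddel_dz3 = self._delta(cp, T, d, zeta)
        XA, XB = self.solve_site_fractions(T, rho, x, delta=delta)
        with np.errstate(divide="ignore", invalid="ignore"):
            la = np.where(self.Na > 0, np.log(XA), 0.0)
            lb = np.where(self.Nb > 0, np.log(XB), 0.0)
        a_assoc = float(np.dot(x, self.Na * (la - XA / 2.0 + 0.5)
                               + self.Nb * (lb - XB / 2.0 + 0.5)))
        a = a_hc + a_disp + a_assoc
        if derivs == "none":
            return a, None, None

        # ---- density derivative -----------------------------------------
        # hard chain: zeta all scale with rho
        da_hc_drho = (mbar * float(dahs_dz @ dz_drho)
                      - float(np.dot(x, (self.m - 1.0) / gii
                                     * (dgii_dz2 * dz_drho[2]
                                        + dgii_dz3 * dz_drho[3]))))
        # dispersion
        deta_drho = eta / rho
        dI1 = float((ai * _POW) @ np.concatenate([[0.0], epow[:-1]]))
        dI2 = float((bi * _POW) @ np.concatenate([[0.0], epow[:-1]]))
        df1 = mbar * (8.0 + 20.0 * eta - 4.0 * eta ** 2) / om ** 5
        poly2 = (20.0 * eta - 27.0 * eta ** 2 + 12.0 * eta ** 3
                 - 2.0 * eta ** 4)
        dpoly2 = 20.0 - 54.0 * eta + 36.0 * eta ** 2 - 8.0 * eta ** 3
        den2 = (om * (2.0 - eta)) ** 2
        dden2 = 2.0 * om * (2.0 - eta) * (2.0 * eta - 3.0)
        df2 = (1.0 - mbar) * (dpoly2 * den2 - poly2 * dden2) / den2 ** 2
        dC1_deta = -C1 ** 2 * (df1 + df2)
        da_disp_drho = (
            -2.0 * math.pi * m2es3 * (I1 + rho * dI1 * deta_drho)
            - math.pi * mbar * m2e2s3
            * (C1 * I2 + rho * (dC1_deta * I2 + C1 * dI2) * deta_drho))
        # association via stationarity: a_assoc = sum(...) - rho*G with
        # G = u^T delta v evaluated at the solved X
        u_vec = x * self.Na * XA
        v_vec = x * self.Nb * XB
        ddel_drho = ddel_dz2 * dz_drho[2] + ddel_dz3 * dz_drho[3]
        G = float(u_vec @ delta @ v_vec)
        da_assoc_drho = -(G + rho * float(u_vec @ ddel_drho @ v_vec))
        da_drho = da_hc_drho + da_disp_drho + da_assoc_drho
        if derivs == "rho":
            return a, da_drho, None

        # ---- composition derivatives ------------------------------------
        # hard chain
        da_hs_dx = dahs_dz @ dz_dx                       # (n,)
        dgii_dx = (np.outer(dgii_dz2, dz_dx[2])
                   + np.outer(dgii_dz3, dz_dx[3]))       # (n comp_i, n x_k)
        da_hc_dx = (self.m * ahs + mbar * da_hs_dx
                    - (self.m - 1.0) * np.log(gii)
                    - (x * (self.m - 1.0) / gii) @ dgii_dx)
        # dispersion
        dmbar_dx = self.m
        dmf1 = 1.0 / mbar ** 2
        dmf2 = 3.0 / mbar ** 2 - 4.0 / mbar ** 3
        dai_dm = dmf1 * A1 + dmf2 * A2
        dbi_dm = dmf1 * B1 + dmf2 * B2
        dI1_dm = float(dai_dm @ epow)
        dI2_dm = float(dbi_dm @ epow)
        deta_dx = dz_dx[3]
        dm2es3_dx = 2.0 * self.m * ((x * self.m) @ (ur * s3))
        dm2e2s3_dx = 2.0 * self.m * ((x * self.m) @ (ur ** 2 * s3))
        dC1_dm = -C1 ** 2 * (f1 / mbar - f2 / (1.0 - mbar))
        dC1_dx = dC1_dm * dmbar_dx + dC1_deta * deta_dx
        dI1_dx = dI1_dm * dmbar_dx + dI1 * deta_dx
        dI2_dx = dI2_dm * dmbar_dx + dI2 * deta_dx
        da_disp_dx = (
            -2.0 * math.pi * rho * (dI1_dx * m2es3 + I1 * dm2es3_dx)
            - math.pi * rho * (
                dmbar_dx * C1 * I2 * m2e2s3
                + mbar * (dC1_dx * I2 * m2e2s3 + C1 * dI2_dx * m2e2s3
                          + C1 * I2 * dm2e2s3_dx)))
        # association (stationarity again)
        ddel_dx = (ddel_dz2[None, :, :] * dz_dx[2][:, None, None]
                   + ddel_dz3[None, :, :] * dz_dx[3][:, None, None])
        da_assoc_dx = (
            self.Na * (la - XA + 1.0) + self.Nb * (lb - XB + 1.0)
            - rho * (self.Na * XA * (delta @ v_vec)
                     + self.Nb * XB * (delta.T @ u_vec))
            - rho * np.einsum("i,kij,j->k", u_vec, ddel_dx, v_vec))
        da_dx = da_hc_dx + da_disp_dx + da_assoc_dx
        return a, da_drho, da_dx

    # -- pressure and density ----------------------------------------------

    def pressure(self, T: float, rho: float, x: np.ndarray) -> float:
        """Pressure in Pa at number density rho (A^-3)."""
        _, da_drho, _ = self._eval(T, rho, x, derivs="rho")
        Z = 1.0 + rho * da_drho
        return Z * rho * 1e30 * KB * T

    def compressibility(self, T: float, rho: float, x: np.ndarray) -> float:
        _, da_drho, _ = self._eval(T, rho, x, derivs="rho")
        return 1.0 + rho * da_drho

    def rho_from_eta(self, T: float, eta: float, x: np.ndarray) -> float:
        d = self.d_at(T)
        return eta / (math.pi / 6.0 * float(np.dot(x, self.m * d ** 3)))

    def eta_from_rho(self, T: float, rho: float, x: np.ndarray) -> float:
        d = self.d_at(T)
        return math.pi / 6.0 * rho * float(np.dot(x, self.m * d ** 3))

    def solve_liquid_density(self, T: float, p: float, x: np.ndarray,
                             eta_window=(1e-10, 0.7404)) -> "LiquidState":
        """Liquid-branch density root of p(eta) = p.

        Scans the packing-fraction interval for sign changes of the
        pressure residual and refines each bracket; the largest-eta root
        is the liquid branch.
        """
        x = np.asarray(x, dtype=float)
        if p <= 0:
            raise ValueError("pressure must be positive")

        def perr(eta):
            rho = self.rho_from_eta(T, eta, x)
            return self.pressure(T, rho, x) - p

        # Warm start: the liquid root moves little between successive
        # calls on the same mixture (saturation iterations, T sweeps).
        eta = None
        if self._eta_warm is not None:
            a = max(self._eta_warm - 0.03, eta_window[0])
            b = min(self._eta_warm + 0.03, eta_window[1])
            fa, fb = perr(a), perr(b)
            if fa * fb < 0:
                eta = optimize.brentq(perr, a, b, xtol=1e-14, rtol=8.9e-16)
        # Otherwise descend from dense packing; the first sign change
        # encountered brackets the largest root, i.e. the liquid branch.
        lo, hi = eta_window
        grid = np.concatenate([
            np.linspace(hi, 0.06, 80), np.geomspace(0.05, lo, 25)])
        if eta is None:
            prev_e, prev_v = None, None
            for e in grid:
                v = perr(e)
                if prev_v is not None and (v == 0.0 or prev_v * v < 0):
                    eta = optimize.brentq(perr, e, prev_e,
                                          xtol=1e-14, rtol=8.9e-16)
                    break
                prev_e, prev_v = e, v
        if eta is None:
            raise ConvergenceError(
                f"no liquid density root at T={T} K, p={p} Pa, x={x}")
        self._eta_warm = eta
        rho = self.rho_from_eta(T, eta, x)
        XA, XB = self.solve_site_fractions(T, rho, x)
        return LiquidState(mix=self, T=T, p=p, x=x, eta=eta, rho=rho,
                           site_fractions=(XA, XB))

    # -- fugacity / activity coefficients ----------------------------------

    def ln_phi(self, T: float, p: float, x: np.ndarray,
               rho: float | None = None) -> np.ndarray:
        """Log fugacity coefficients at (T, p, x) on the liquid branch."""
        x = np.asarray(x, dtype=float)
        if rho is None:
            rho = self.solve_liquid_density(T, p, x).rho
        a, da_drho, da_dx = self._eval(T, rho, x)
        Z = 1.0 + rho * da_drho
        mu_res = a + (Z - 1.0) + da_dx - float(np.dot(x, da_dx))
        return mu_res - math.log(Z)

    def _ln_phi_pure(self, T: float, p: float, i: int) -> float:
        key = (self.names[i], round(T, 9), round(p, 6))
        val = _PURE_CACHE.get(key)
        if val is None:
            sub = Mixture(self.cs, [self.names[i]])
            val = float(sub.ln_phi(T, p, np.array([1.0]))[0])
            if len(_PURE_CACHE) > 4096:
                _PURE_CACHE.clear()
            _PURE_CACHE[key] = val
        return val

    def activity_coefficients(self, T: float, x: np.ndarray,
                              p: float = P_DEFAULT) -> np.ndarray:
        """Symmetric mole-fraction activity coefficients gamma_i.

        gamma_i = phi_i(T, p, x) / phi_i^pure-liquid(T, p); the pure
        reference for a solute below its melting point is the
        hypothetical subcooled liquid on the same branch.
        """
        lnphi = self.ln_phi(T, p, x)
        lnphi0 = np.array([self._ln_phi_pure(T, p, i)
                           for i in range(self.n)])
        return np.exp(lnphi - lnphi0)

    def water_activity(self, T: float, x: np.ndarray,
                       p: float = P_DEFAULT) -> float:
        """a_w = x_water * gamma_water; equals RH/100 at equilibrium."""
        if "water" not in self.names:
            raise ValueError("water is not part of this mixture")
        iw = self.index("water")
        gam = self.activity_coefficients(T, x, p)
        return float(x[iw] * gam[iw])


_PURE_CACHE: dict = {}


@dataclass
class LiquidState:
    """A solved liquid state: density root plus association structure."""

    mix: Mixture
    T: float
    p: float
    x: np.ndarray
    eta: float
    rho: float                       # molecules / A^3
    site_fractions: tuple[np.ndarray, np.ndarray]

    @property
    def molar_density(self) -> float:
        """mol/m^3"""
        return self.rho * 1e30 / NAV

    @property
    def mass_density(self) -> float:
        """kg/m^3"""
        Mbar = float(np.dot(self.x, self.mix.M))       # g/mol
        return self.molar_density * Mbar * 1e-3


def cross_parameters(cs: ComponentSet, names, T: float) -> CrossParameters:
    """Combining-rule pair parameters for the named components at T."""
    return Mixture(cs, list(names)).cross_parameters(T)
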