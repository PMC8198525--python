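"""Equation of state: combining rules, association, derivatives,
thermodynamic consistency."""

import math

import numpy as np
import pytest
from scipy import optimize

from deliq.components import ComponentRecord, ComponentSet
from deliq.pcsaft import P_DEFAULT, Mixture, cross_parameters

T0 = 298.15


def random_composition(rng, n):
    x = rng.dirichlet(np.ones(n))
    return np.clip(x, 1e-4, None) / np.clip(x, 1e-4, None).sum()


class TestCrossParameters:
    def test_diagonal_reproduces_pure_values(self, cs):
        cp = cross_parameters(cs, ["fructose", "glucose"], T0)
        f = cs["fructose"]
        assert cp.sigma[0, 0] == f.sigma_at(T0)
        assert cp.u[0, 0] == pytest.approx(f.dispersion_energy)
        assert cp.eps_assoc[0, 0] == f.assoc_energy
        assert cp.kappa_assoc[0, 0] == pytest.approx(f.assoc_volume)

    def test_water_fructose_wolbach_sandler(self, cs):
        cp = cross_parameters(cs, ["water", "fructose"], T0)
        assert cp.eps_assoc[0, 1] == pytest.approx((2425.67 + 5000.0) / 2)
        sw = cs["water"].sigma_at(T0)
        sf = 2.849
        expected_kappa = (math.sqrt(0.0451 * 0.1)
                          * (math.sqrt(sw * sf) / (0.5 * (sw + sf))) ** 3)
        assert cp.kappa_assoc[0, 1] == pytest.approx(expected_kappa)

    def test_water_fructose_dispersion_with_kij(self, cs):
        cp = cross_parameters(cs, ["water", "fructose"], T0)
        kij = cs.kij("water", "fructose", T0)
        assert cp.u[0, 1] == pytest.approx(
            math.sqrt(353.94 * 237.19) * (1.0 - kij))

    def test_symmetric_matrices(self, cs):
        cp = cross_parameters(cs, ["water", "fructose", "citric acid"], T0)
        for M in (cp.sigma, cp.u, cp.eps_assoc, cp.kappa_assoc):
            assert np.allclose(M, M.T, rtol=0, atol=0)


def _inert_component():
    """A chain molecule with no association sites."""
    return ComponentRecord("inert", 100.0, 0.03, 3.5, 250.0)


class TestAssociation:
    def test_no_sites_means_unit_site_fractions_and_zero_term(self, cs):
        inert = ComponentSet.build([_inert_component()])
        mix = Mixture(inert, ["inert"])
        rho = 1e-3
        XA, XB = mix.solve_site_fractions(T0, rho, np.array([1.0]))
        assert np.all(XA == 1.0) and np.all(XB == 1.0)
        # association contributes nothing: total equals hc + disp alone
        a_full = mix.ares(T0, rho, np.array([1.0]))
        assert np.isfinite(a_full)

    def test_symmetric_site_classes_have_equal_fractions(self, cs):
        mix = Mixture(cs, ["water", "fructose"])   # both a/b symmetric
        st = mix.solve_liquid_density(T0, P_DEFAULT, np.array([0.7, 0.3]))
        XA, XB = st.site_fractions
        assert XA == pytest.approx(XB, rel=1e-10)

    def test_site_balance_matches_brute_force_solve(self, cs):
        mix = Mixture(cs, ["water", "ascorbic acid"])   # asymmetric 1/1, 4/1
        x = np.array([0.9, 0.1])
        st = mix.solve_liquid_density(T0, P_DEFAULT, x)
        rho = st.rho
        cp, d, zeta = mix._state(T0, rho, x)
        delta, _, _ = mix._delta(cp, T0, d, zeta)
        Na, Nb = mix.Na, mix.Nb

        def residual(v):
            XA, XB = v[:2], v[2:]
            return np.concatenate([
                XA * (1 + rho * delta @ (x * Nb * XB)) - 1,
                XB * (1 + rho * delta @ (x * Na * XA)) - 1])

        sol = optimize.fsolve(residual, np.full(4, 0.5), xtol=1e-13)
        XA, XB = mix.solve_site_fractions(T0, rho, x)
        assert XA == pytest.approx(sol[:2], abs=1e-10)
        assert XB == pytest.approx(sol[2:], abs=1e-10)


class TestHelmholtzDerivatives:
    @pytest.mark.parametrize("names,comp", [
        (("water",), [1.0]),
        (("water", "fructose"), [0.7, 0.3]),
        (("water", "citric acid", "sucrose"), [0.75, 0.15, 0.10]),
    ])
    def test_pressure_from_finite_difference_density_derivative(
            self, cs, names, comp):
        mix = Mixture(cs, list(names))
        x = np.array(comp)
        st = mix.solve_liquid_density(T0, P_DEFAULT, x)
        rho = st.rho
        _, da_drho, _ = mix._eval(T0, rho, x, derivs="rho")
        h = rho * 3e-6
        fd = (mix.ares(T0, rho + h, x) - mix.ares(T0, rho - h, x)) / (2 * h)
        assert da_drho == pytest.approx(fd, rel=1e-6)

    def test_ideal_gas_limit(self, cs):
        """a_res vanishes linearly with density as rho -> 0."""
        mix = Mixture(cs, ["water", "fructose"])
        x = np.array([0.6, 0.4])
        a12 = mix.ares(T0, 1e-12, x)
        a13 = mix.ares(T0, 1e-13, x)
        assert abs(a12) < 1e-3
        assert a13 / a12 == pytest.approx(0.1, rel=0.05)

    def test_solved_density_reproduces_pressure(self, cs):
        mix = Mixture(cs, ["water", "glucose"])
        x = np.array([0.85, 0.15])
        st = mix.solve_liquid_density(T0, P_DEFAULT, x)
        assert mix.pressure(T0, st.rho, x) == pytest.approx(
            P_DEFAULT, rel=1e-8)

    def test_pure_water_density_near_experiment(self, cs):
        mix = Mixture(cs, ["water"])
        st = mix.solve_liquid_density(T0, P_DEFAULT, np.array([1.0]))
        assert 0.3 < st.eta < 0.6
        assert st.mass_density == pytest.approx(997.0, abs=10.0)

    def test_water_density_continuous_in_temperature(self, cs):
        mix = Mixture(cs, ["water"])
        T = np.linspace(278.15, 368.15, 19)
        rho = [mix.solve_liquid_density(t, P_DEFAULT,
                                        np.array([1.0])).mass_density
               for t in T]
        rel_steps = np.abs(np.diff(rho)) / rho[:-1]
        assert np.all(rel_steps < 0.01)       # no branch jumps


def fd_ln_phi(mix, T, p, x, rel=1e-6):
    """Independent fugacity-coefficient oracle.

    Central finite differences of the total residual Helmholtz energy
    F(n) = n_tot * a_res(T, n_tot/V, n/n_tot) at fixed (T, V) give the
    residual chemical potentials directly; ln phi_k = mu_k/kT - ln Z.
    """
    st = mix.solve_liquid_density(T, p, x)
    V = len(x) / st.rho       # A^3 for n_tot = len(x) "moles"
    n0 = np.asarray(x, float) * len(x)

    def F(n):
        ntot = n.sum()
        return ntot * mix.ares(T, ntot / V, n / ntot)

    mu = np.empty(len(x))
    for k in range(len(x)):
        h = max(n0[k], 0.1) * rel
        np_, nm = n0.copy(), n0.copy()
        np_[k] += h
        nm[k] -= h
        mu[k] = (F(np_) - F(nm)) / (2 * h)
    Z = mix.compressibility(T, st.rho, x)
    return mu - math.log(Z)


class TestFugacityAndActivity:
    def test_analytic_ln_phi_matches_finite_difference(self, cs):
        mix = Mixture(cs, ["water", "fructose", "citric acid"])
        x = np.array([0.7, 0.2, 0.1])
        analytic = mix.ln_phi(T0, P_DEFAULT, x)
        oracle = fd_ln_phi(mix, T0, P_DEFAULT, x)
        assert analytic == pytest.approx(oracle, rel=1e-6)

    def test_pure_component_activity_coefficient_is_one(self, cs):
        for name in ("water", "fructose"):
            mix = Mixture(cs, [name])
            gam = mix.activity_coefficients(T0, np.array([1.0]))
            assert gam[0] == pytest.approx(1.0, abs=1e-10)

    def test_component_order_permutation_invariance(self, cs):
        m1 = Mixture(cs, ["water", "fructose", "glucose"])
        m2 = Mixture(cs, ["glucose", "water", "fructose"])
        x1 = np.array([0.7, 0.2, 0.1])
        x2 = np.array([0.1, 0.7, 0.2])
        g1 = m1.activity_coefficients(T0, x1)
        g2 = m2.activity_coefficients(T0, x2)
        # limited by the iterative site/density solver tolerances
        assert g1[0] == pytest.approx(g2[1], rel=1e-9)
        assert g1[1] == pytest.approx(g2[2], rel=1e-9)
        assert g1[2] == pytest.approx(g2[0], rel=1e-9)

    def test_gibbs_duhem_on_random_states(self, cs, rng):
        """sum_i x_i dln(gamma_i) = 0 along any composition direction."""
        mix = Mixture(cs, ["water", "fructose", "citric acid"])
        for _ in range(3):
            x = random_composition(rng, 3)
            x[0] = max(x[0], 0.5)       # aqueous liquid region
            x /= x.sum()
            v = rng.normal(size=3)
            v -= v.mean()               # simplex direction
            v /= np.linalg.norm(v)
            h = 1e-5
            gp = np.log(mix.activity_coefficients(T0, x + h * v))
            gm = np.log(mix.activity_coefficients(T0, x - h * v))
            residual = float(x @ (gp - gm)) / (2 * h)
            assert abs(residual) < 1e-5

    def test_water_activity_decreases_with_fructose(self, cs):
        mix = Mixture(cs, ["water", "fructose"])
        aws = [mix.water_activity(T0, np.array([1 - xf, xf]))
               for xf in (0.0, 0.05, 0.12, 0.20, 0.2569)]
        assert aws[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(aws) < 0)

    def test_water_required_for_water_activity(self, cs):
        mix = Mixture(cs, ["fructose", "glucose"])
        with pytest.raises(ValueError):
            mix.water_activity(T0, np.array([0.5, 0.5]))
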