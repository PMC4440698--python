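"""Coulomb potentials, drifted propagator and the numerical GF tabulator."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from fprsim.greens import PairParams, survival
from fprsim.pair_fpr import reaction_zone_radius
from fprsim.potentials import (
    GFTable,
    PotentialSpec,
    check_drift_timestep,
    coulomb,
    drift_move,
    fit_gf_tables,
    kon_coulomb,
    load_gf_table,
    longrange_entry_weight,
    longrange_force_sum,
    p_free_drift,
    save_gf_table,
    tabulate_numerical_gf,
)


class TestCoulomb:
    def test_zero_charge(self):
        v, f = coulomb(2.0, PotentialSpec(0.0))
        assert v == 0.0 and f == 0.0

    def test_values(self):
        v, f = coulomb(1.0, PotentialSpec(1.0))
        assert v == 1.0 and f == 1.0

    def test_force_is_negative_gradient(self):
        spec = PotentialSpec(1.5)
        h = 1e-6
        for r in (1.0, 2.0, 5.0):
            grad = (spec.beta_v(r + h) - spec.beta_v(r - h)) / (2 * h)
            assert float(spec.beta_f(r)) == pytest.approx(-float(grad), rel=1e-6)

    def test_rejects_nonpositive_separation(self):
        with pytest.raises(ValueError):
            coulomb(0.0, PotentialSpec(1.0))


class TestDriftMove:
    def test_zero_force_reduces_to_free(self, rng):
        n = 50_000
        moves = np.array([drift_move(np.zeros(3), 10.0, np.zeros(3), 0.1, rng)
                          for _ in range(200)])
        assert abs(moves.mean()) < 0.05

    def test_mean_displacement_is_drift(self, rng):
        n = 50_000
        D, dt = 10.0, 0.1
        bf = np.array([0.5, 0.0, 0.0])
        disp = D * bf * dt + math.sqrt(2 * D * dt) * rng.standard_normal((n, 3))
        moves = np.zeros(3) + disp  # the sampler's definition, vectorized
        se = math.sqrt(2 * D * dt / n)
        assert abs(moves[:, 0].mean() - D * 0.5 * dt) < 3 * se

    def test_single_step_radial_density_matches_drifted_form(self, rng):
        # KS test of |x'| against the drift-shifted free propagator
        spec = PotentialSpec(1.0)
        D, dt, r0 = 25.0, 0.01, 2.0
        n = 40_000
        x0 = np.array([r0, 0.0, 0.0])
        bf = float(spec.beta_f(r0)) * np.array([1.0, 0, 0])
        seps = np.linalg.norm(
            x0 + D * bf * dt + math.sqrt(2 * D * dt) * rng.standard_normal((n, 3)),
            axis=1)

        from scipy import integrate

        norm = 1.0  # full space: the drift-shifted form integrates to one over r >= 0
        def cdf(r):
            r = np.atleast_1d(r)
            return np.array([integrate.quad(
                lambda s: 4 * math.pi * s**2 * float(
                    p_free_drift(s, dt, r0, D, spec)), 1e-9, ri)[0] / norm
                for ri in r])

        d, p = stats.kstest(seps, cdf)
        assert p > 0.01


class TestKonCoulomb:
    def test_neutral_limit_value(self):
        assert kon_coulomb(0.0, 1.0, 50.0, 50.0) == pytest.approx(46.3144,
                                                                  abs=5e-4)

    def test_attractive_value(self):
        assert kon_coulomb(-1.0, 1.0, 50.0, 50.0) == pytest.approx(119.565,
                                                                   abs=5e-3)

    def test_continuous_at_zero_charge(self):
        lim = kon_coulomb(0.0, 1.0, 50.0, 50.0)
        for rc in (1e-6, -1e-6):
            assert kon_coulomb(rc, 1.0, 50.0, 50.0) == pytest.approx(lim,
                                                                     rel=1e-4)

    def test_matches_steady_state_flux_problem(self):
        # independent oracle: solve the stationary diffusion problem
        # k_on = [ integral_sigma^inf exp(beta V) / (4 pi D r^2) dr
        #          + 1/(k_a exp(-beta V(sigma))) ]^-1  (flux through a
        # partially absorbing sphere in a potential)
        from scipy import integrate

        sigma, ka, D = 1.0, 50.0, 50.0
        for rc in (1.0, -1.0, 0.4):
            outer, _ = integrate.quad(
                lambda r: math.exp(rc / r) / (4 * math.pi * D * r**2),
                sigma, 2000.0, limit=400)
            k = 1.0 / (outer + math.exp(rc / sigma) / ka)
            assert kon_coulomb(rc, sigma, ka, D) == pytest.approx(k, rel=1e-3)


class TestLongRange:
    def test_entry_weight_values(self):
        assert longrange_entry_weight(PotentialSpec(0.0), 2.5) == 1.0
        assert longrange_entry_weight(PotentialSpec(1.0), 2.5) == \
            pytest.approx(math.exp(-0.4))
        assert longrange_entry_weight(PotentialSpec(-1.0), 2.5) > 1.0

    def test_two_particles_reduce_to_pair_force(self):
        spec = PotentialSpec(1.0)
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        F = longrange_force_sum(pos, spec)
        assert F[0, 0] == pytest.approx(-0.25)  # repulsive, pushed apart
        assert F[1, 0] == pytest.approx(0.25)

    def test_newtons_third_law_and_symmetry(self, rng):
        spec = PotentialSpec(-0.7)
        pos = rng.random((20, 3)) * 10
        F = longrange_force_sum(pos, spec, box=10.0)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-12)
        # particle at the center of a symmetric cube arrangement
        cube = np.array([[i, j, k] for i in (0, 2) for j in (0, 2)
                         for k in (0, 2)], dtype=float)
        pts = np.vstack([cube, [[1.0, 1.0, 1.0]]])
        F = longrange_force_sum(pts, spec)
        assert np.allclose(F[-1], 0.0, atol=1e-12)

    def test_drift_timestep_guard_warns(self):
        par = PairParams(1.0, 25.0, 25.0, 50.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            ok = check_drift_timestep(par, PotentialSpec(5.0), 0.01)
        assert not ok and rec


class TestZhouTabulator:
    def test_rejects_absorbing(self, rng):
        par = PairParams(1.0, 25.0, 25.0, np.inf)
        with pytest.raises(ValueError):
            tabulate_numerical_gf(par, PotentialSpec(0.0), 0.01, 0.01, 100, rng)

    def test_zero_rate_survival_is_one(self, rng):
        par = PairParams(1.0, 25.0, 25.0, 0.0)
        tab = tabulate_numerical_gf(par, PotentialSpec(0.0), 0.01, 0.02, 300,
                                    rng, dr0=1.0)
        assert np.all(tab.survival_raw == 1.0)

    def test_matches_analytic_gf_without_potential(self, rng):
        # sigma=1, D=50, k_a=50, dt=0.01: survival within 3 binomial s.e.
        par = PairParams(1.0, 25.0, 25.0, 50.0)
        n_reps = 2000
        tab = tabulate_numerical_gf(par, PotentialSpec(0.0), 0.01, 0.01,
                                    n_reps, rng, dr0=0.5)
        exact = np.asarray(survival(0.01, tab.r0_grid, par))
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-12) / n_reps)
        z = (tab.survival_raw - exact) / np.maximum(se, 1e-9)
        assert np.max(np.abs(z)) < 3.5

    def test_shell_factor_convergence(self, rng):
        # finer shells converge to the analytic value; coarse minus fine
        # differences stay within Monte-Carlo resolution
        par = PairParams(1.0, 25.0, 25.0, 50.0)
        vals = {}
        for f in (0.04, 0.01):
            tab = tabulate_numerical_gf(par, PotentialSpec(0.0), 0.01, f,
                                        3000, rng, dr0=1.0, r0_max=1.5)
            vals[f] = tab.survival_raw[0]
        exact = float(survival(0.01, 1.0 + 1e-9, par))
        se = math.sqrt(exact * (1 - exact) / 3000)
        assert abs(vals[0.01] - exact) <= abs(vals[0.04] - exact) + 2 * se
        assert abs(vals[0.01] - exact) < 3.5 * se


class TestGFTableFits:
    def _synthetic_table(self, rng, n_reps=4000):
        par = PairParams(1.0, 25.0, 25.0, 50.0)
        return tabulate_numerical_gf(par, PotentialSpec(0.0), 0.01, 0.01,
                                     n_reps, rng, dr0=0.25), par

    def test_survival_fit_recovers_parameters_noise_free(self):
        # synthetic table generated from the exact closed form: the fit must
        # recover the generating (k_a, D) to within 5%
        par = PairParams(1.0, 25.0, 25.0, 50.0)
        grid = np.arange(1.0 + 1e-9, 6.2, 0.1)
        exact = np.asarray(survival(0.01, grid, par))
        edges = np.linspace(1.0, 12.0, 21)
        tab = GFTable(par, PotentialSpec(0.0), 0.01, 0.001, grid, exact,
                      np.full(grid.size, 10**6, dtype=np.int64), edges,
                      np.zeros((grid.size, 20), dtype=np.int64))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = fit_gf_tables(tab)
        ka_f, D_f = fitted.fit_params["survival"]
        assert ka_f == pytest.approx(50.0, rel=0.05)
        assert D_f == pytest.approx(50.0, rel=0.05)

    def test_fitted_survival_monotone_in_r0(self, rng):
        tab, _ = self._synthetic_table(rng)
        fitted = fit_gf_tables(tab)
        s = np.asarray(fitted.survival_at(np.linspace(1.0, 5.0, 50)))
        assert np.all(np.diff(s) >= -1e-12)

    def test_split_half_residuals_not_worse_than_global(self, rng):
        tab, _ = self._synthetic_table(rng)
        fitted = fit_gf_tables(tab)
        # fitted density must reproduce the raw histogram mass node by node
        centers = 0.5 * (tab.hist_edges[1:] + tab.hist_edges[:-1])
        widths = np.diff(tab.hist_edges)
        i = 2
        raw = tab.hist_counts[i] / (tab.n_reps[i] * widths) / (
            4 * math.pi * centers**2)
        fit_vals = fitted._density_node(i, centers)
        m = raw > 0
        resid = np.abs(fit_vals[m] - raw[m]) / raw[m].max()
        assert np.median(resid) < 0.15

    def test_round_trip_io(self, rng, tmp_path):
        tab, _ = self._synthetic_table(rng, n_reps=500)
        path = tmp_path / "table.json"
        save_gf_table(tab, path)
        back = load_gf_table(path)
        assert np.allclose(back.survival_raw, tab.survival_raw)
        assert np.array_equal(back.hist_counts, tab.hist_counts)
        assert back.params.k_a == tab.params.k_a


class TestPotentialPairEngines:
    def test_fpr_and_exactgf_agree_repulsive(self, rng):
        from fprsim.potentials import (association_curve_exactgf,
                                       association_curve_potential)

        par = PairParams(1.0, 25.0, 25.0, 50.0)
        tab = tabulate_numerical_gf(par, PotentialSpec(1.0), 0.01, 0.01,
                                    3000, rng, dr0=0.2).fit()
        n = 10_000
        c_fpr = association_curve_potential(tab, 0.01, 1.5, 50, n, rng)
        c_ex = association_curve_exactgf(tab, 0.01, 1.5, 50, n, rng)
        se = float(np.hypot(c_fpr.stderr[-1], c_ex.stderr[-1]))
        assert abs(c_fpr.cumulative[-1] - c_ex.cumulative[-1]) < 3 * se
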