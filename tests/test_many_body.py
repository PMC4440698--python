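"""Many-particle engine: neighbor search, association resolution, kinetics."""

import math

import numpy as np
import pytest
from scipy import stats

from fprsim.greens import PairParams
from fprsim.many_body import (
    Reaction,
    SimConfig,
    Species,
    TargetEquilibriumEstimator,
    _channels,
    find_reactive_pairs,
    initialize_system,
    resolve_association,
    run_simulation,
    step_system,
    suggest_timestep,
)


def _simple_config(**kw):
    defaults = dict(
        species=[Species("A", 10.0), Species("B", 10.0), Species("C", 10.0)],
        reactions=[Reaction("A", "B", sigma=1.0, k_a=10.0, k_b=0.001,
                            product="C")],
        counts={"A": 20, "B": 20, "C": 0}, box=40.0, dt=0.01, T_max=1.0,
        seed=1)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSuggestTimestep:
    def test_single_pair_type_value(self):
        # (12 pi sigma^2 sqrt(6 D_AB) rho)^-2 at sigma=1, D_AB=20, rho=1e-4
        val = suggest_timestep([Reaction("A", "B", sigma=1.0, k_a=1.0)],
                               [Species("A", 10.0), Species("B", 10.0)],
                               {"A": 0.0, "B": 1e-4})
        expect = (12 * math.pi * math.sqrt(120.0) * 1e-4) ** -2
        assert val == pytest.approx(expect, rel=1e-12)
        assert expect == pytest.approx(586.35, rel=1e-3)

    def test_zero_density_unbounded(self):
        val = suggest_timestep([Reaction("A", "A", sigma=1.0, k_a=1.0)],
                               [Species("A", 10.0)], {"A": 0.0})
        assert val == math.inf

    def test_monotone_in_density_and_diffusion(self):
        def bound(rho, D):
            return suggest_timestep(
                [Reaction("A", "A", sigma=1.0, k_a=1.0)],
                [Species("A", D / 2)], {"A": rho})

        assert bound(1e-4, 20.0) > bound(2e-4, 20.0) > bound(2e-4, 40.0)


class TestInitialization:
    def test_empty_system(self, rng):
        cfg = _simple_config(counts={"A": 0, "B": 0, "C": 0})
        state = initialize_system(cfg, rng)
        assert state.n == 0

    def test_no_reactive_overlap(self, rng):
        cfg = _simple_config(counts={"A": 150, "B": 150, "C": 0}, box=30.0,
                             dt=0.001)
        for seed in range(20):
            state = initialize_system(cfg, np.random.default_rng(seed))
            d = state.pos[:, None, :] - state.pos[None, :, :]
            d -= cfg.box * np.round(d / cfg.box)
            r = np.linalg.norm(d, axis=2)
            ab = (state.species_idx[:, None] != state.species_idx[None, :])
            np.fill_diagonal(ab, False)
            assert r[ab].min() >= 1.0

    def test_placement_uniform_radially(self, rng):
        # chi^2 on radial shells around the box center for the target fixture
        cfg = _simple_config(counts={"A": 1, "B": 10_000, "C": 0}, box=60.0,
                             dt=0.001, target_center="A", boundary="none")
        state = initialize_system(cfg, rng)
        bpos = state.pos[state.species_idx == 1] - cfg.box / 2.0
        # use the largest sphere inscribed in the box
        r = np.linalg.norm(bpos, axis=1)
        rmax = cfg.box / 2.0
        inside = r[r < rmax]
        edges = np.linspace(0.0, rmax, 11)
        counts, _ = np.histogram(inside, bins=edges)
        expect = np.diff(edges**3) / rmax**3 * inside.size
        chi2 = ((counts - expect) ** 2 / expect).sum()
        assert stats.chi2.sf(chi2, len(counts) - 1) > 0.01

    def test_target_particle_centered(self, rng):
        cfg = _simple_config(counts={"A": 1, "B": 50, "C": 0},
                             target_center="A", boundary="none")
        state = initialize_system(cfg, rng)
        assert np.allclose(state.pos[0], cfg.box / 2.0)


class TestFindReactivePairs:
    def test_matches_brute_force(self):
        cfg = _simple_config(counts={"A": 100, "B": 100, "C": 0}, box=35.0,
                             dt=0.01)
        channels = _channels(cfg)
        R_max = channels[0].R_max
        for seed in range(20):
            rng = np.random.default_rng(seed)
            state = initialize_system(cfg, rng)
            ii, jj, cc, rr = find_reactive_pairs(state, channels)
            got = {tuple(sorted((int(i), int(j)))) for i, j in zip(ii, jj)}
            d = state.pos[:, None, :] - state.pos[None, :, :]
            d -= cfg.box * np.round(d / cfg.box)
            dist = np.linalg.norm(d, axis=2)
            expect = set()
            for i in range(state.n):
                for j in range(i + 1, state.n):
                    if state.species_idx[i] != state.species_idx[j] \
                            and {state.species_idx[i], state.species_idx[j]} == {0, 1} \
                            and dist[i, j] < R_max:
                        expect.add((i, j))
            assert got == expect

    def test_empty_system(self, rng):
        cfg = _simple_config(counts={"A": 0, "B": 0, "C": 0})
        state = initialize_system(cfg, rng)
        ii, jj, cc, rr = find_reactive_pairs(state)
        assert ii.size == 0

    def test_boundary_inclusion(self, rng):
        cfg = _simple_config(counts={"A": 1, "B": 1, "C": 0}, box=50.0)
        channels = _channels(cfg)
        R_max = channels[0].R_max
        state = initialize_system(cfg, rng)
        for eps, expected in ((+1e-6, 0), (-1e-6, 1)):
            state.pos[0] = [10.0, 10.0, 10.0]
            state.pos[1] = [10.0 + R_max + eps, 10.0, 10.0]
            ii, *_ = find_reactive_pairs(state, channels)
            assert ii.size == expected


class TestResolveAssociation:
    def test_single_partner_reduces_to_bernoulli(self, rng):
        hits = sum(resolve_association([0.3], rng) is not None
                   for _ in range(20_000))
        assert hits / 20_000 == pytest.approx(0.3, abs=0.01)

    def test_zero_probabilities_never_react(self, rng):
        assert all(resolve_association([0.0, 0.0], rng) is None
                   for _ in range(100))

    def test_partner_selection_proportional(self, rng):
        p = [0.1, 0.2, 0.3]
        n = 50_000
        picks = np.array([resolve_association(p, rng) for _ in range(n)],
                         dtype=object)
        for k, pk in enumerate(p):
            frac = np.mean(picks == k)
            assert abs(frac - pk) < 3 * math.sqrt(pk * (1 - pk) / n)


class TestStepSystem:
    def test_pure_diffusion_msd(self, rng):
        cfg = _simple_config(counts={"A": 200, "B": 0, "C": 0}, box=50.0,
                             dt=0.05)
        state = initialize_system(cfg, rng)
        start = state.pos.copy()
        channels = _channels(cfg)
        state = step_system(state, rng, channels)
        d = state.pos - start
        d -= cfg.box * np.round(d / cfg.box)
        msd = (d**2).mean(axis=0)
        expect = 2 * 10.0 * 0.05
        se = expect * math.sqrt(2.0 / 200)
        assert np.all(np.abs(msd - expect) < 3 * se)

    def test_particle_number_conservation(self, rng):
        cfg = _simple_config(counts={"A": 30, "B": 20, "C": 0}, box=25.0,
                             dt=0.01, T_max=2.0,
                             reactions=[Reaction("A", "B", sigma=1.0, k_a=50.0,
                                                 k_b=0.1, product="C")])
        ts = run_simulation(cfg, rng=rng, record_every=5)
        # A - B difference invariant; A + C and B + C conserved
        assert np.all(ts.values["A"] - ts.values["B"] == 10)
        assert np.all(ts.values["A"] + ts.values["C"] == 30)

    def test_no_reactive_overlap_after_steps(self, rng):
        cfg = _simple_config(counts={"A": 80, "B": 80, "C": 0}, box=25.0,
                             dt=0.01)
        state = initialize_system(cfg, rng)
        channels = _channels(cfg)
        for _ in range(50):
            state = step_system(state, rng, channels)
        d = state.pos[:, None, :] - state.pos[None, :, :]
        d -= cfg.box * np.round(d / cfg.box)
        r = np.linalg.norm(d, axis=2)
        ab = np.zeros_like(r, dtype=bool)
        spa = state.species_idx == 0
        spb = state.species_idx == 1
        ab[np.ix_(spa, spb)] = True
        assert r[ab].min() >= 1.0 - 1e-9

    def test_pair_limit_matches_pair_engine_statistics(self, rng):
        # one A + one B far apart in a big open box behaves like the pair
        # engine: compare single-step association probability from contact
        from fprsim.greens import p_assoc

        par = PairParams(1.0, 10.0, 10.0, 50.0)
        cfg = _simple_config(
            counts={"A": 1, "B": 1, "C": 0}, box=200.0, boundary="none",
            dt=0.1, reactions=[Reaction("A", "B", sigma=1.0, k_a=50.0,
                                        k_b=0.0, product="C")])
        n = 4000
        hits = 0
        for seed in range(n):
            r = np.random.default_rng(seed + 1)
            state = initialize_system(cfg, r)
            state.pos[0] = np.full(3, 100.0)
            state.pos[1] = state.pos[0] + np.array([1.2, 0, 0])
            state = step_system(state, r, _channels(cfg))
            hits += int(state.counts()["C"] == 1)
        p = float(p_assoc(0.1, 1.2, par))
        assert hits / n == pytest.approx(p, abs=3 * math.sqrt(p * (1 - p) / n))


class TestTargetEquilibrium:
    def test_accelerated_estimator_matches_plain_engine_regime(self, rng):
        # fast parameters where theory, plain stepping and the accelerated
        # estimator can all be compared
        par = PairParams(1.0, 0.0, 20.0, 100.0, k_b=0.05)
        est = TargetEquilibriumEstimator(par, 0.1, n_B=3, box=60.0)
        res = est.run(n_cycles=6, n_replicas=48, rng=rng)
        assert abs(res.p_bound - res.p_theory) < 3 * res.stderr + 0.01

    def test_requires_dissociation(self):
        par = PairParams(1.0, 0.0, 20.0, 100.0, k_b=0.0)
        with pytest.raises(ValueError):
            TargetEquilibriumEstimator(par, 0.1, n_B=3, box=60.0)


class TestReversibleVsGillespie:
    def test_moderate_concentration_relaxation_tracks_ssa(self, rng):
        # A + B <-> C at 52 uM with slow dissociation: the spatial simulation
        # relaxes like well-mixed kinetics with the composed k_on, k_off
        from fprsim.reference_theory import RateSet, gillespie

        conc = 52e-6 * 0.6022140857
        N = 300
        V = N / conc
        L = V ** (1 / 3)
        k_a, k_b = 1000.0, 1e-6
        cfg = SimConfig(
            species=[Species("A", 1.0), Species("B", 1.0), Species("C", 1.0)],
            reactions=[Reaction("A", "B", sigma=1.0, k_a=k_a, k_b=k_b,
                                product="C")],
            counts={"A": N, "B": N, "C": 0}, box=L, dt=0.5, T_max=1000.0,
            seed=11)
        ts = run_simulation(cfg, rng=rng, record_every=40)
        rs = RateSet(k_a, k_b, 1.0, 2.0)
        grid = ts.times
        n_ssa = 300
        acc = np.zeros_like(grid)
        for _ in range(n_ssa):
            g = gillespie("reversible", {"k_on": rs.k_on, "k_off": rs.k_off},
                          {"A": N, "B": N, "C": 0}, V, grid[-1], rng,
                          record_times=grid)
            acc += g.values["A"]
        ssa_mean = acc / n_ssa
        ssa_sd = math.sqrt(max(ssa_mean[-1], 1.0))  # Poisson-scale spread
        # single spatial run vs SSA mean: allow the run-to-run spread plus
        # the SSA mean error
        band = 3 * math.sqrt(ssa_sd**2 + ssa_sd**2 / n_ssa)
        mid = len(grid) // 2
        for k in (mid, len(grid) - 1):
            assert abs(ts.values["A"][k] - ssa_mean[k]) < band + 3.0


class TestCoulombAnnihilation:
    def test_rate_ordering_and_magnitude(self, rng):
        # A + A -> 0 with attractive / neutral / repulsive Coulomb forces:
        # decay ordered by the steady-state k_on and quantitatively close to
        # the integrated rate equation (entry-weight long-range strategy)
        from fprsim.greens import PairParams
        from fprsim.potentials import (PotentialSpec, kon_coulomb,
                                       tabulate_numerical_gf)

        par = PairParams(1.0, 25.0, 25.0, 50.0)
        conc = 5.2e-6 * 0.6022140857
        N0 = 400
        V = N0 / conc
        L = V ** (1 / 3)
        T = 300.0
        reacted = {}
        for r_c in (-1.0, 0.0, 1.0):
            if r_c != 0.0:
                tab = tabulate_numerical_gf(par, PotentialSpec(r_c), 0.01,
                                            0.02, 1500, rng, dr0=0.25).fit()
                tables = {0: tab}
                strategy = "entry_weight"
            else:
                tables, strategy = None, None
            cfg = SimConfig(species=[Species("A", 25.0)],
                            reactions=[Reaction("A", "A", sigma=1.0, k_a=50.0,
                                                r_c=r_c)],
                            counts={"A": N0}, box=L, dt=0.01, T_max=T,
                            seed=31, longrange_strategy=strategy)
            ts = run_simulation(cfg, rng=rng, record_every=3000,
                                gf_tables=tables)
            n_end = ts.values["A"][-1]
            k_on = kon_coulomb(r_c, 1.0, 50.0, 50.0)
            A0 = N0 / V
            th = 1.0 / (1.0 / A0 + k_on * T) * V
            reacted[r_c] = N0 - n_end
            # Poisson-scale tolerance on the reacted count
            expect = N0 - th
            assert abs(reacted[r_c] - expect) < 3 * math.sqrt(expect) + 3.0
        # attractive vs repulsive is the ordering the run length can resolve
        # (the neutral case sits between them within Poisson noise and is
        # already pinned by its own quantitative band above)
        assert reacted[-1.0] > reacted[1.0]
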