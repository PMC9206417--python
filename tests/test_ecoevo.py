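"""Chemostat ecology, invasion analysis and adaptive-dynamics simulation."""

import numpy as np
import pytest
from scipy.optimize import brentq

from divergelab.ecoevo import (
    ChemostatEnv,
    Community,
    TREATMENT_PRESETS,
    UptakeParams,
    classify_singular,
    community_derivatives,
    ecological_equilibrium,
    evolve,
    invasion_fitness,
    run_treatment,
    selection_gradient,
    singular_strategy,
    trait_clusters,
)
from divergelab.tradeoff import TradeoffCurve


def attracting_root(roots, env, params, curve, h=0.01):
    """Pick the convergence-stable root (negative gradient slope)."""
    for r in roots:
        if not (h < r < curve.u_max - h):
            return r
        slope = (
            selection_gradient(r + h, env, params, curve)
            - selection_gradient(r - h, env, params, curve)
        ) / (2 * h)
        if slope < 0:
            return r
    return roots[0]


class TestDerivatives:
    def test_empty_community_relaxes_to_supply(self, mix_env, params, strong_curve):
        empty = Community(np.array([]), np.array([]), strong_curve)
        mix_env.R1, mix_env.R2 = 1.0, 2.0
        dR, dN = community_derivatives(empty, mix_env, params)
        assert np.allclose(dR, mix_env.D * (mix_env.supply - [1.0, 2.0]))
        assert dN.size == 0

    def test_closed_system_no_consumers_is_static(self, params, strong_curve):
        env = ChemostatEnv(S1=2.0, S2=2.0, D=0.0, R1=1.0, R2=1.5)
        empty = Community(np.array([]), np.array([]), strong_curve)
        dR, _ = community_derivatives(empty, env, params)
        assert np.allclose(dR, 0.0)

    def test_negative_state_rejected(self, mix_env, params, strong_curve):
        comm = Community(np.array([0.5]), np.array([1.0]), strong_curve)
        mix_env.R1 = -0.1
        with pytest.raises(ValueError):
            community_derivatives(comm, mix_env, params)

    def test_single_type_equilibrium_has_zero_derivatives(self, params, strong_curve):
        """Oracle: solve the monomorphic steady state by direct root-finding
        on resource concentration, then evaluate the full derivative field."""
        env = ChemostatEnv(S1=5.0, S2=0.0, D=0.3)
        u1 = 1.0  # pure specialist on resource 1

        def growth_minus_d(R1):
            return params.eps * u1 * params.phi(np.array([R1, 0.0]))[0] - env.D

        r1_star = brentq(growth_minus_d, 1e-9, env.S1)
        n_star = params.eps * (env.S1 - r1_star)
        comm = Community(np.array([u1]), np.array([n_star]), strong_curve)
        env.R1, env.R2 = r1_star, 0.0
        dR, dN = community_derivatives(comm, env, params)
        assert np.allclose(dR, 0.0, atol=1e-10)
        assert np.allclose(dN, 0.0, atol=1e-10)

    def test_mass_balance_with_unit_yield_linear_uptake(self, strong_curve):
        """With eps = 1 and linear uptake, total mass obeys the chemostat
        balance d(sum R + sum N)/dt = D (sum S - sum R - sum N)."""
        params = UptakeParams(kinetics="linear", eps=1.0)
        env = ChemostatEnv(S1=3.0, S2=2.0, D=0.4, R1=1.0, R2=0.5)
        comm = Community(np.array([0.3, 0.8]), np.array([0.7, 0.2]), strong_curve)
        dR, dN = community_derivatives(comm, env, params)
        total_flux = dR.sum() + dN.sum()
        expected = env.D * (env.supply.sum() - env.R1 - env.R2 - comm.density.sum())
        assert total_flux == pytest.approx(expected, abs=1e-12)


class TestEquilibrium:
    def test_linear_specialist_closed_form(self, strong_curve):
        """Pure specialist with linear uptake: R1* = D/(eps a u1) and
        N1* = eps (S1 - R1*), verified against long-time integration."""
        params = UptakeParams(kinetics="linear", eps=0.4, a1=1.0)
        env = ChemostatEnv(S1=5.0, S2=0.0, D=0.3)
        comm = Community(np.array([1.0]), np.array([0.01]), strong_curve)
        eq = ecological_equilibrium(comm, env, params)
        r1_expected = env.D / (params.eps * params.a1 * 1.0)
        assert eq.R[0] == pytest.approx(r1_expected, rel=1e-8)
        assert eq.N[0] == pytest.approx(params.eps * (env.S1 - r1_expected), rel=1e-8)
        assert not eq.washout

    def test_two_specialists_coexist_from_either_start(self, mix_env, params, strong_curve):
        ends = []
        for heavy in (0, 1):
            dens = np.array([1e-4, 1e-4])
            dens[heavy] = 1.0
            comm = Community(np.array([0.0, 1.0]), dens, strong_curve)
            eq = ecological_equilibrium(comm, mix_env, params)
            assert np.all(eq.N > 1e-4)
            ends.append(np.concatenate([eq.R, eq.N]))
        assert np.allclose(ends[0], ends[1], rtol=1e-6)

    def test_no_supply_washes_out(self, params, strong_curve):
        env = ChemostatEnv(S1=0.0, S2=0.0, D=0.3)
        comm = Community(np.array([0.7]), np.array([1.0]), strong_curve)
        eq = ecological_equilibrium(comm, env, params)
        assert eq.washout
        assert np.allclose(eq.N, 0.0)
        assert np.allclose(eq.R, env.supply)

    def test_resources_depleted_not_exceeded(self, mix_env, params, strong_curve):
        comm = Community(np.array([0.7]), np.array([0.5]), strong_curve)
        eq = ecological_equilibrium(comm, mix_env, params)
        assert np.all(eq.R <= mix_env.supply + 1e-9)
        assert eq.R[0] < mix_env.S1  # consumed resource strictly depleted


class TestInvasionFitness:
    @pytest.mark.parametrize("p", [0.4, 0.7, 1.5, 2.5])
    def test_resident_neutrality(self, mix_env, params, p):
        curve = TradeoffCurve(p)
        comm = Community(np.array([0.8]), np.array([0.5]), curve)
        eq = ecological_equilibrium(comm, mix_env, params)
        s = invasion_fitness(0.8, eq, mix_env, params, curve)
        assert abs(s) < 1e-6

    def test_empty_niche_invasion_positive(self, mix_env, params, strong_curve):
        """In a washout environment (R = S) any viable phenotype grows."""
        env = ChemostatEnv(S1=0.0, S2=0.0, D=0.3)
        comm = Community(np.array([0.7]), np.array([1.0]), strong_curve)
        eq = ecological_equilibrium(comm, env, params)  # washout, R* = S
        eq.R = mix_env.supply  # now offer the mix supply untouched
        s = invasion_fitness(1.0, eq, mix_env, params, strong_curve)
        expected = params.eps * 1.0 * params.phi(mix_env.supply)[0] - mix_env.D
        assert s == pytest.approx(expected)
        assert s > 0

    def test_specialist2_invades_specialist1_closed_form_linear(self, strong_curve):
        """With linear uptake the untouched resource keeps R2* = S2, so the
        opposite specialist's invasion fitness is eps*a*S2 - D exactly."""
        params = UptakeParams(kinetics="linear", eps=0.4)
        env = ChemostatEnv(S1=2.5, S2=5.0, D=0.3)
        res = Community(np.array([1.0]), np.array([0.5]), strong_curve)
        eq = ecological_equilibrium(res, env, params)
        assert eq.R[1] == pytest.approx(env.S2, rel=1e-9)
        s = invasion_fitness(0.0, eq, env, params, strong_curve)
        assert s == pytest.approx(params.eps * params.a2 * env.S2 - env.D, rel=1e-8)
        assert s > 0

    @pytest.mark.parametrize("p", [0.4, 0.7])
    def test_mutual_invasibility_strong_tradeoff(self, mix_env, params, p):
        curve = TradeoffCurve(p)
        for res_u1, mut_u1 in [(1.0, 0.0), (0.0, 1.0)]:
            res = Community(np.array([res_u1]), np.array([0.5]), curve)
            eq = ecological_equilibrium(res, mix_env, params)
            assert invasion_fitness(mut_u1, eq, mix_env, params, curve) > 0


class TestSingularStrategies:
    @pytest.mark.parametrize("p", [0.5, 1.0, 2.0])
    def test_symmetric_supply_puts_singularity_on_diagonal(self, sym_env, params, p):
        curve = TradeoffCurve(p)
        roots, _ = singular_strategy(sym_env, params, curve)
        expected = 2.0 ** (-1.0 / p)
        closest = min(roots, key=lambda r: abs(r - expected))
        assert closest == pytest.approx(expected, abs=1e-6)

    def test_strong_tradeoff_is_branching_point(self, mix_env, params, strong_curve):
        roots, _ = singular_strategy(mix_env, params, strong_curve)
        u_star = attracting_root(roots, mix_env, params, strong_curve)
        assert 0 < u_star < 1
        assert classify_singular(u_star, mix_env, params, strong_curve) == "branching_point"

    def test_weak_tradeoff_is_ess_generalist(self, mix_env, params, weak_curve):
        roots, multiple = singular_strategy(mix_env, params, weak_curve)
        assert not multiple
        u_star = roots[0]
        assert classify_singular(u_star, mix_env, params, weak_curve) == "ESS_generalist"

    def test_single_resource_supply_is_boundary_specialist(self, params, strong_curve):
        env = ChemostatEnv(S1=5.0, S2=0.0, D=0.3)
        roots, _ = singular_strategy(env, params, strong_curve)
        assert roots == [1.0]
        assert classify_singular(1.0, env, params, strong_curve) == "boundary_specialist"


class TestEvolve:
    def test_mix_strong_tradeoff_branches(self, mix_env, params, strong_curve):
        init = Community(np.array([0.7]), np.array([0.5]), strong_curve)
        traj = evolve(init, mix_env, strong_curve, params,
                      mutation_sd=0.05, epochs=150, seed=42)
        clusters = trait_clusters(traj.final.u1, traj.final.density)
        assert len(clusters) >= 2
        us = sorted(u for u, _ in clusters)
        assert us[-1] - us[0] > 0.5

    def test_mix_weak_tradeoff_stays_monomorphic(self, mix_env, params, weak_curve):
        init = Community(np.array([0.7]), np.array([0.5]), weak_curve)
        traj = evolve(init, mix_env, weak_curve, params,
                      mutation_sd=0.05, epochs=120, seed=42)
        clusters = trait_clusters(traj.final.u1, traj.final.density)
        assert len(clusters) == 1
        roots, _ = singular_strategy(mix_env, params, weak_curve)
        assert abs(clusters[0][0] - roots[0]) < 3 * 0.05

    def test_single_resource_fixes_pure_specialist(self, params, strong_curve):
        env = ChemostatEnv(S1=5.0, S2=0.0, D=0.3)
        init = Community(np.array([0.6]), np.array([0.5]), strong_curve)
        traj = evolve(init, env, strong_curve, params,
                      mutation_sd=0.05, epochs=100, seed=1)
        clusters = trait_clusters(traj.final.u1, traj.final.density)
        assert len(clusters) == 1
        assert clusters[0][0] > 0.9

    def test_deterministic_under_seed(self, mix_env, params, strong_curve):
        init = Community(np.array([0.7]), np.array([0.5]), strong_curve)
        a = evolve(init, mix_env, strong_curve, params, epochs=20, seed=5)
        b = evolve(init, mix_env, strong_curve, params, epochs=20, seed=5)
        assert np.array_equal(a.final.u1, b.final.u1)
        assert np.array_equal(a.final.density, b.final.density)

    def test_nonviable_initial_community_raises(self, params, strong_curve):
        env = ChemostatEnv(S1=0.0, S2=0.0, D=0.3)
        init = Community(np.array([0.7]), np.array([0.5]), strong_curve)
        with pytest.raises(ValueError):
            evolve(init, env, strong_curve, params, epochs=5, seed=0)

    def test_generation_accounting_constant_dilution(self, mix_env, params, strong_curve):
        init = Community(np.array([0.7]), np.array([0.5]), strong_curve)
        traj = evolve(init, mix_env, strong_curve, params, epochs=10, seed=3)
        for snap in traj.snapshots:
            assert snap.generations == pytest.approx(
                mix_env.D * snap.time_h / np.log(2.0)
            )

    @pytest.mark.parametrize("p,start,epochs,expect_branching", [
        (0.4, 0.25, 100, True),
        (0.7, 0.40, 100, True),
        (1.5, 0.50, 80, False),
        (2.5, 0.60, 80, False),
    ])
    def test_bifurcation_consistency_grid(self, sym_env, params, p, start, epochs,
                                          expect_branching):
        """classify_singular and evolve agree across the trade-off regimes."""
        curve = TradeoffCurve(p)
        roots, _ = singular_strategy(sym_env, params, curve)
        u_star = attracting_root(roots, sym_env, params, curve)
        label = classify_singular(u_star, sym_env, params, curve, tol=1e-3)
        init = Community(np.array([start]), np.array([1.0]), curve)
        traj = evolve(init, sym_env, curve, params,
                      mutation_sd=0.05, epochs=epochs, seed=11)
        n_clusters = len(trait_clusters(traj.final.u1, traj.final.density))
        if expect_branching:
            assert label == "branching_point"
            assert n_clusters >= 2
        else:
            assert label == "ESS_generalist"
            assert n_clusters == 1


class TestRunTreatment:
    def test_presets_match_experimental_setup(self):
        assert TREATMENT_PRESETS["fructose"] == {"S1": 5.0, "S2": 0.0, "D0": 0.3}
        assert TREATMENT_PRESETS["galactose"] == {"S1": 0.0, "S2": 10.0, "D0": 0.2}
        assert TREATMENT_PRESETS["mix"] == {"S1": 2.5, "S2": 5.0, "D0": 0.3}

    def test_unknown_treatment_rejected(self, strong_curve):
        with pytest.raises(ValueError):
            run_treatment("glucose", strong_curve)

    def test_controller_off_generations_are_definitional(self, params, strong_curve):
        traj = run_treatment("mix", strong_curve, params, days=5, seed=0,
                             controller=False, mutants_per_day=0)
        D0 = TREATMENT_PRESETS["mix"]["D0"]
        assert traj.final.generations == pytest.approx(D0 * 5 * 24 / np.log(2))
        assert traj.final.D == D0

    def test_fructose_treatment_reaches_specialist_corner(self, params, strong_curve):
        traj = run_treatment("fructose", strong_curve, params, days=250, seed=7)
        clusters = trait_clusters(traj.final.u1, traj.final.density)
        assert len(clusters) == 1
        assert clusters[0][0] > 0.9

    def test_mix_treatment_yields_coexisting_specialists(self, params, strong_curve):
        traj = run_treatment("mix", strong_curve, params, days=400, seed=7)
        clusters = trait_clusters(traj.final.u1, traj.final.density)
        assert len(clusters) == 2
        us = sorted(u for u, _ in clusters)
        assert us[0] < 0.2 and us[1] > 0.8

    def test_controller_log_and_bounds(self, params, strong_curve):
        traj = run_treatment("galactose", strong_curve, params, days=30, seed=2)
        assert traj.controller_log  # daily decisions recorded
        for entry in traj.controller_log:
            assert 0.01 <= entry["D_after"] <= 1.5
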