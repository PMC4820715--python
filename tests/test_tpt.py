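"""Committors, reactive fluxes, pathway decomposition and mean first passage
times, checked against closed forms and Monte-Carlo hitting simulations."""

import numpy as np
import pytest

from quadmsm.tpt import (FluxNetwork, backward_committor, committors,
                         forward_committor, mfpt, pathway_edge_times,
                         reactive_flux, top_pathways)

from conftest import model_from_T

THREE_STATE = np.array([[0.5, 0.5, 0.0],
                        [0.25, 0.5, 0.25],
                        [0.0, 0.5, 0.5]])


def random_reversible_model(rng, n):
    W = rng.uniform(0.05, 1.0, (n, n))
    W = (W + W.T) / 2.0
    return model_from_T(W / W.sum(1, keepdims=True))


def simulate_hitting(T, start, A, B, n_rep, rng):
    """Monte-Carlo fraction of chains from ``start`` reaching B before A,
    vectorized over replicas."""
    A, B = set(A), set(B)
    cum = np.cumsum(T, axis=1)
    state = np.full(n_rep, start)
    hitB = np.zeros(n_rep, dtype=bool)
    active = ~(np.isin(state, list(A)) | np.isin(state, list(B)))
    hitB |= np.isin(state, list(B))
    while active.any():
        u = rng.random(active.sum())
        nxt = (cum[state[active]] < u[:, None]).sum(axis=1)
        state[active] = nxt
        inB = np.isin(state, list(B)) & active
        hitB |= inB
        active &= ~(np.isin(state, list(A)) | np.isin(state, list(B)))
    return hitB.mean()


def simulate_mean_hitting_time(T, start, target, n_rep, rng, t_step=1.0):
    target = set(target)
    cum = np.cumsum(T, axis=1)
    state = np.full(n_rep, start)
    steps = np.zeros(n_rep)
    active = ~np.isin(state, list(target))
    while active.any():
        u = rng.random(active.sum())
        state[active] = (cum[state[active]] < u[:, None]).sum(axis=1)
        steps[active] += 1
        active &= ~np.isin(state, list(target))
    return steps.mean() * t_step, steps.std(ddof=1) / np.sqrt(n_rep) * t_step


class TestCommittors:
    def test_boundary_values(self):
        m = model_from_T(THREE_STATE)
        qp = forward_committor(m, [0], [2])
        qm = backward_committor(m, [0], [2])
        assert qp[0] == 0.0 and qp[2] == 1.0
        assert qm[0] == 1.0 and qm[2] == 0.0

    def test_symmetric_three_state_is_half(self):
        qp = forward_committor(model_from_T(THREE_STATE), [0], [2])
        assert qp[1] == pytest.approx(0.5, abs=1e-12)

    def test_reversible_identity_backward_equals_one_minus_forward(self, rng):
        m = random_reversible_model(rng, 7)
        qp = forward_committor(m, [0, 1], [5, 6])
        qm = backward_committor(m, [0, 1], [5, 6])
        assert np.allclose(qm, 1.0 - qp, atol=1e-8)

    def test_matches_hitting_simulation(self, rng):
        m = random_reversible_model(rng, 8)
        A, B = [0], [7]
        qp = forward_committor(m, A, B)
        for start in (2, 4, 6):
            frac = simulate_hitting(m.T, start, A, B, 100_000, rng)
            se = np.sqrt(qp[start] * (1 - qp[start]) / 100_000)
            assert abs(frac - qp[start]) <= 3 * se + 1e-4

    def test_nonreversible_backward_matches_reverse_simulation(self, rng):
        # 4-state non-reversible chain: check q- via the time-reversed chain
        T = np.array([[0.2, 0.5, 0.2, 0.1],
                      [0.1, 0.3, 0.5, 0.1],
                      [0.3, 0.1, 0.2, 0.4],
                      [0.25, 0.25, 0.25, 0.25]])
        m = model_from_T(T, reversible=False)
        qm = backward_committor(m, [0], [3])
        Trev = (m.pi[None, :] * m.T.T) / m.pi[:, None]
        for start in (1, 2):
            frac = simulate_hitting(Trev, start, [3], [0], 100_000, rng)
            se = np.sqrt(max(qm[start] * (1 - qm[start]), 1e-8) / 100_000)
            assert abs(frac - qm[start]) <= 3 * se + 1e-3

    def test_monotone_on_birth_death_chain(self):
        n = 9
        T = np.zeros((n, n))
        for i in range(n):
            if i > 0:
                T[i, i - 1] = 0.3
            if i < n - 1:
                T[i, i + 1] = 0.2
            T[i, i] = 1.0 - T[i].sum()
        qp = forward_committor(model_from_T(T), [0], [n - 1])
        assert np.all(np.diff(qp) >= -1e-12)

    def test_invalid_sets_rejected(self):
        m = model_from_T(THREE_STATE)
        with pytest.raises(ValueError):
            forward_committor(m, [], [2])
        with pytest.raises(ValueError):
            forward_committor(m, [0], [0])
        with pytest.raises(ValueError):
            forward_committor(m, [0], [9])


class TestReactiveFlux:
    def test_hand_arithmetic_three_state(self):
        m = model_from_T(THREE_STATE)
        assert np.allclose(m.pi, [0.25, 0.5, 0.25], atol=1e-12)
        comm = committors(m, [0], [2])
        flux = reactive_flux(m, comm)
        # f_01 = pi_0 * qminus_0 * T_01 * qplus_1 = 0.25 * 1 * 0.5 * 0.5
        assert flux.gross[0, 1] == pytest.approx(0.0625, abs=1e-12)
        assert flux.total_flux == pytest.approx(0.0625, abs=1e-12)

    def test_no_flux_into_source_interior(self, rng):
        m = random_reversible_model(rng, 6)
        comm = committors(m, [0, 1], [5])
        flux = reactive_flux(m, comm)
        # edges ending in A carry q+ = 0 -> zero gross flux
        assert np.allclose(flux.gross[:, [0, 1]], 0.0, atol=1e-15)

    def test_conservation_at_intermediates(self, rng):
        for _ in range(5):
            m = random_reversible_model(rng, 9)
            comm = committors(m, [0], [8])
            flux = reactive_flux(m, comm)
            inter = [i for i in range(9) if i not in (0, 8)]
            imbalance = (flux.net.sum(axis=1) - flux.net.sum(axis=0))[inter]
            assert np.abs(imbalance).max() < 1e-10
            assert flux.net[:, [0]].sum() == pytest.approx(0.0, abs=1e-15)


class TestTopPathways:
    def test_pure_chain_single_path_carries_all_flux(self):
        T = np.array([[0.9, 0.1, 0.0],
                      [0.1, 0.8, 0.1],
                      [0.0, 0.1, 0.9]])
        m = model_from_T(T)
        flux = reactive_flux(m, committors(m, [0], [2]))
        paths = top_pathways(flux, K=3)
        assert len(paths) == 1
        assert paths[0].states == (0, 1, 2)
        assert paths[0].fraction == pytest.approx(1.0, abs=1e-10)

    def test_two_disjoint_channels_ranked_with_exact_fractions(self):
        """Hand-built net-flux network: channels A->1->B and A->2->B carrying
        0.7 F and 0.3 F."""
        F = 0.02
        net = np.zeros((4, 4))
        net[0, 1] = net[1, 3] = 0.7 * F
        net[0, 2] = net[2, 3] = 0.3 * F
        flux = FluxNetwork(gross=net.copy(), net=net, total_flux=F, A=(0,), B=(3,))
        paths = top_pathways(flux, K=5)
        assert [p.states for p in paths] == [(0, 1, 3), (0, 2, 3)]
        assert paths[0].fraction == pytest.approx(0.7, abs=1e-10)
        assert paths[1].fraction == pytest.approx(0.3, abs=1e-10)

    def test_path_flux_sum_bounded_by_total(self, rng):
        for _ in range(5):
            m = random_reversible_model(rng, 8)
            flux = reactive_flux(m, committors(m, [0], [7]))
            paths = top_pathways(flux, K=10)
            assert sum(p.flux for p in paths) <= flux.total_flux + 1e-10
            fracs = [p.fraction for p in paths]
            assert all(f2 <= f1 + 1e-12 for f1, f2 in zip(fracs, fracs[1:]))

    def test_invalid_k_rejected(self, rng):
        m = random_reversible_model(rng, 4)
        flux = reactive_flux(m, committors(m, [0], [3]))
        with pytest.raises(ValueError):
            top_pathways(flux, K=0)


class TestMfpt:
    def test_target_state_is_zero(self, rng):
        m = random_reversible_model(rng, 5)
        res = mfpt(m, [2])
        assert res.times[2] == 0.0

    def test_two_state_closed_form_sixty_ns(self):
        T = np.array([[0.9, 0.1], [0.5, 0.5]])
        m = model_from_T(T, lag_time=6.0, reversible=False)
        res = mfpt(m, [1])
        assert res.times[0] == pytest.approx(60.0, rel=1e-9)

    def test_matches_monte_carlo_hitting_times(self, rng):
        W = rng.uniform(0.05, 1.0, (10, 10))
        W = (W + W.T) / 2.0
        m = model_from_T(W / W.sum(1, keepdims=True))
        res = mfpt(m, [9])
        for start in (0, 4):
            mc, se = simulate_mean_hitting_time(m.T, start, [9], 100_000, rng)
            assert abs(res.times[start] - mc) <= 3 * se

    def test_lag_time_scaling_is_exact(self, rng):
        m1 = random_reversible_model(rng, 6)
        res1 = mfpt(m1, [0], lag_time=1.0)
        res2 = mfpt(m1, [0], lag_time=7.5)
        assert np.allclose(res2.times, 7.5 * res1.times, rtol=1e-12)

    def test_unreachable_target_named(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        m = model_from_T(T, reversible=False)
        with pytest.raises(ValueError, match="cannot reach"):
            mfpt(m, [1])

    def test_forced_route_edge_times_match_simulation(self, rng):
        """A linear chain with one forced route: per-edge pairwise MFPTs each
        independently match Monte-Carlo estimates."""
        T = np.array([[0.8, 0.2, 0.0],
                      [0.3, 0.5, 0.2],
                      [0.0, 0.4, 0.6]])
        m = model_from_T(T, reversible=False)
        flux = reactive_flux(model_from_T(T, reversible=False),
                             committors(model_from_T(T, reversible=False), [0], [2]))
        paths = top_pathways(flux, K=1)
        edges = pathway_edge_times(m, paths[0])
        for (u, v, t_uv) in edges:
            mc, se = simulate_mean_hitting_time(m.T, u, [v], 50_000, rng)
            assert abs(t_uv - mc) <= 3 * se

    def test_path_restricted_variant_runs(self, rng):
        m = random_reversible_model(rng, 5)
        flux = reactive_flux(m, committors(m, [0], [4]))
        paths = top_pathways(flux, K=1)
        full = pathway_edge_times(m, paths[0], restrict_to_path=False)
        restricted = pathway_edge_times(m, paths[0], restrict_to_path=True)
        assert len(full) == len(restricted) == len(paths[0].states) - 1
        assert all(t >= 0 for _, _, t in restricted)
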