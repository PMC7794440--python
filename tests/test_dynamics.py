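"""Time integration, conservation-law structure, and regime labels."""

import numpy as np
import pytest

from grnstab import (
    CellParams,
    allocation,
    analyze,
    assign_parameters,
    classify_network_dynamics,
    classify_trajectory,
    gen_random,
    integrate,
    integrate_phase1,
    integrate_reduced,
    mrna_fixed_point,
    rhs_phase1,
    rhs_reduced,
    solve_fixed_point,
)
from grnstab.dynamics import Trajectory
from grnstab.regulation import RegulatoryNetwork
from grnstab.networks import EdgeSet


def _stable_solved(net, seed=80):
    ss = solve_fixed_point(net, seed=seed, tol=1e-12)
    assert ss.converged
    return ss


class TestRightHandSides:
    def test_zero_at_fixed_point(self, small_net):
        ss = _stable_solved(small_net)
        params = CellParams(tau_m=0.3, tau_p=1e5)
        c_m = mrna_fixed_point(small_net, params, ss.c)
        full = rhs_phase1(np.concatenate([c_m, ss.c]), small_net, params)
        red = rhs_reduced(ss.c, small_net, params)
        assert np.abs(full).max() < 1e-13
        assert np.abs(red).max() < 1e-13

    def test_total_protein_relaxation_law(self, small_net):
        """Summing the protein equations gives d(sum c)/dt =
        k_p c_r (1 - sum c), vanishing exactly on the simplex."""
        rng = np.random.default_rng(1)
        params = CellParams()
        rib = small_net.topology.ribosome_index
        c = rng.uniform(0.01, 0.08, small_net.n_genes)
        total = rhs_reduced(c, small_net, params).sum()
        expected = params.k_p * c[rib] * (1.0 - c.sum())
        assert total == pytest.approx(expected, rel=1e-10)
        on_simplex = c / c.sum()
        assert abs(rhs_reduced(on_simplex, small_net, params).sum()) < 1e-15

    def test_inhibitor_increase_lowers_target_transcription(self):
        es = EdgeSet(n_genes=4, tf_indices=np.array([0]), ribosome_index=3,
                     rnap_index=2, regulators=np.array([0]),
                     targets=np.array([1]), signs=np.array([-1]))
        net = RegulatoryNetwork(
            topology=es, omega=np.array([5.0]), gamma=np.array([1 / 5 - 1]),
            k_half=np.array([0.25]), hill_coeff=1.0, g0=np.ones(4))
        params = CellParams()
        c = np.full(4, 0.25)
        c_m = mrna_fixed_point(net, params, c)
        up = c.copy()
        up[0] = 0.35
        d_base = rhs_phase1(np.concatenate([c_m, c]), net, params)
        d_up = rhs_phase1(np.concatenate([c_m, up]), net, params)
        assert d_up[1] < d_base[1]  # target mRNA production drops


class TestIntegration:
    def test_returns_to_stable_fixed_point(self, small_net):
        ss = _stable_solved(small_net)
        rng = np.random.default_rng(3)
        c0 = ss.c * (1 + 1e-3 * rng.standard_normal(small_net.n_genes))
        c0 = np.abs(c0) / np.abs(c0).sum()
        traj = integrate_reduced(small_net, CellParams(), c0,
                                 t_end=5e4, n_points=50)
        assert np.abs(traj.c[-1] - ss.c).max() < 1e-6

    def test_simplex_is_attracting(self, small_net):
        ss = _stable_solved(small_net)
        params = CellParams(tau_m=0.3, tau_p=1e5)
        c0 = ss.c * 1.05  # start off the simplex
        traj = integrate_phase1(small_net, params, c0, t_end=5e4, n_points=50)
        sums = traj.c.sum(axis=1)
        assert abs(sums[-1] - 1) < 1e-6

    def test_quasi_steady_mrna_relaxation(self, small_net):
        """With proteins frozen, mRNA relaxes exponentially to its
        quasi-steady level at rate k_p c_r + 1/tau."""
        ss = _stable_solved(small_net)
        params = CellParams(tau_m=5.0, tau_p=1e5)
        c = ss.c
        target = mrna_fixed_point(small_net, params, c)
        rate = params.k_p * c[small_net.topology.ribosome_index] + params.inv_tau
        n = small_net.n_genes

        def frozen_protein_rhs(t, c_m):
            return rhs_phase1(np.concatenate([c_m, c]), small_net, params)[:n]

        c_m0 = target * 1.5
        t_end = 2.0 / rate
        _, y = integrate(frozen_protein_rhs, c_m0, (0, t_end),
                         t_eval=np.array([t_end]), rtol=1e-10)
        dev0 = np.abs(c_m0 - target).max()
        dev1 = np.abs(y[-1] - target).max()
        assert dev1 / dev0 == pytest.approx(np.exp(-rate * t_end), rel=1e-3)

    def test_no_interaction_relaxation_rate_is_beta0(self):
        """Without regulation every mode decays at beta0 = k_p c_r^ss."""
        es = gen_random(20, 0.0, 0.5, seed=90)
        net = assign_parameters(es, omega_max=2.0, seed=91)
        ss = _stable_solved(net)
        beta0 = ss.c[es.ribosome_index]
        delta = np.zeros(20)
        delta[0], delta[1] = 1e-4, -1e-4  # stay on the simplex
        t_end = 3.0 / beta0
        traj = integrate_reduced(net, CellParams(), ss.c + delta,
                                 t_end=t_end, n_points=4, rtol=1e-10)
        dev = np.abs(traj.c - ss.c)[:, 0]
        measured = -np.log(dev[-1] / dev[0]) / traj.times[-1]
        assert measured == pytest.approx(beta0, rel=1e-2)

    def test_deterministic_given_identical_inputs(self, small_net):
        c0 = np.full(small_net.n_genes, 1 / small_net.n_genes)
        a = integrate_reduced(small_net, CellParams(), c0, t_end=100.0)
        b = integrate_reduced(small_net, CellParams(), c0, t_end=100.0)
        assert np.array_equal(a.c, b.c)

    def test_invalid_t_span_raises(self, small_net):
        c0 = np.full(small_net.n_genes, 1 / small_net.n_genes)
        with pytest.raises(ValueError):
            integrate(lambda t, y: y, c0, (1.0, 0.0))


class TestReducedVersusFull:
    def test_protein_trajectories_converge_in_fast_mrna_limit(self):
        """The reduced system is the omega -> infinity limit of the full
        dynamics: the maximal protein deviation shrinks as omega grows."""
        es = gen_random(30, 0.05, 0.5, seed=95)
        net = assign_parameters(es, omega_max=1.8, h=1.0, seed=96)
        rng = np.random.default_rng(97)
        x = rng.exponential(size=30)
        c0 = x / x.sum()
        ss = solve_fixed_point(net, seed=98)
        beta0 = ss.c[es.ribosome_index]
        t_end, n_pts = 5.0 / beta0, 80  # sample the relaxation transient
        red = integrate_reduced(net, CellParams(), c0, t_end=t_end,
                                n_points=n_pts)
        devs = []
        for omega in (10.0, 100.0, 1000.0):
            tau_m = 1.0 / (omega * beta0 + 1e-6)
            params = CellParams(tau_m=tau_m, tau_p=1e6)
            full = integrate_phase1(net, params, c0, t_end=t_end,
                                    n_points=n_pts)
            devs.append(np.abs(full.c - red.c).max())
        assert devs[0] > devs[1] > devs[2]
        assert devs[-1] < 1e-3


class TestClassification:
    def test_weak_regulation_settles_to_fixed_point(self):
        es = gen_random(50, 0.02, 0.5, seed=100)
        net = assign_parameters(es, omega_max=1.1, h=1.0, seed=101)
        traj = classify_network_dynamics(net, seed=102)
        assert traj.label == "fixed_point"
        report = analyze(net, seed=103)
        assert report.stable and report.lambda_max < 1

    def test_pure_oscillation_is_labeled_oscillatory(self):
        ts = np.linspace(0, 400, 2048)
        c = 0.1 + 0.05 * np.sin(2 * np.pi * ts[:, None] / 20.0 + np.arange(3))
        traj = Trajectory(times=ts, c=c)
        twin = Trajectory(times=ts, c=c + 1e-9)
        assert classify_trajectory(traj, 0.25, twin=twin) == "oscillatory"
        assert traj.diagnostics["dominant_period"] == pytest.approx(20, rel=0.1)

    def test_flat_trajectory_is_fixed_point(self):
        ts = np.linspace(0, 100, 256)
        c = np.full((256, 4), 0.25)
        traj = Trajectory(times=ts, c=c)
        assert classify_trajectory(traj, 0.5) == "fixed_point"

    def test_exponential_twin_separation_is_chaotic(self):
        ts = np.linspace(0, 400, 2048)
        rng = np.random.default_rng(0)
        c = 0.2 + 0.05 * rng.standard_normal((2048, 3)).cumsum(axis=0) / 40
        c = np.abs(c) + 0.05
        sep = 1e-9 * np.exp(np.minimum(0.05 * ts, 18.0))
        twin = Trajectory(times=ts, c=c + sep[:, None])
        traj = Trajectory(times=ts, c=c)
        assert classify_trajectory(traj, 0.25, twin=twin) == "chaotic"

    def test_spectral_verdict_predicts_relaxation_from_small_kick(self):
        """Networks whose interaction spectrum says stable relax back from
        a 1e-6 perturbation; unstable ones wander away.  Scaled-down
        panel; one disagreement tolerated (finite kicks can escape
        weakly stable points)."""
        agree = 0
        total = 0
        for seed in range(8):
            es = gen_random(60, 0.08, 0.5, seed=110 + seed)
            net = assign_parameters(es, omega_max=6.0, h=1.0, seed=120 + seed)
            report = analyze(net, seed=130 + seed)
            if report.converged:
                ss = solve_fixed_point(net, seed=130 + seed)
                rng = np.random.default_rng(140 + seed)
                c0 = ss.c * (1 + 1e-6 * rng.standard_normal(60))
                c0 = np.abs(c0) / np.abs(c0).sum()
                traj = integrate_reduced(net, CellParams(), c0,
                                         t_end=4e4, n_points=16)
                returned = np.abs(traj.c[-1] - ss.c).max() < 1e-6
                agree += returned == report.stable
            else:
                traj = classify_network_dynamics(net, seed=140 + seed)
                agree += traj.label != "fixed_point"
            total += 1
        assert agree >= total - 1
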