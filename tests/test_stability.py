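"""Interaction matrix, TF submatrix, spectra, and the degradation mapping."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from grnstab import (
    CellParams,
    allocation,
    analyze,
    assign_parameters,
    bipartite_eigenvalue,
    classify_stability,
    full_jacobian,
    gen_bipartite,
    gen_random,
    growth_quantities,
    interaction_matrix,
    interaction_structure,
    jacobian_phase1,
    max_interaction_eigenvalue,
    mrna_fixed_point,
    rhs_phase1,
    scaled_eigenvalues,
    solve_fixed_point,
    tf_submatrix,
)
from grnstab.networks import EdgeSet
from conftest import fd_jacobian


def _solved(net, seed=50, tol=1e-12):
    ss = solve_fixed_point(net, seed=seed, tol=tol)
    assert ss.converged
    return ss


class TestInteractionMatrix:
    def test_no_interactions_give_zero_matrix(self):
        es = gen_random(15, 0.0, 0.5, seed=0)
        net = assign_parameters(es, omega_max=2.0, seed=1)
        ss = _solved(net)
        m, m1, m2 = interaction_matrix(net, ss)
        assert np.all(m == 0)
        assert max_interaction_eigenvalue(net, ss) == 0.0
        assert classify_stability(0.0, True)

    def test_m2_is_rank_one(self, small_net):
        ss = _solved(small_net)
        _, _, m2 = interaction_matrix(small_net, ss)
        svals = np.linalg.svd(m2, compute_uv=False)
        assert np.sum(svals > 1e-10 * svals[0]) == 1

    def test_matches_finite_differences_of_allocation(self, small_net):
        ss = _solved(small_net)
        m, _, _ = interaction_matrix(small_net, ss)
        fd = fd_jacobian(lambda c: allocation(small_net, c), ss.c)
        assert np.abs(m - fd).max() <= 1e-6 * np.abs(m).max()

    def test_requires_converged_steady_state(self, small_net):
        from grnstab import SteadyState

        bad = SteadyState(c=np.full(small_net.n_genes, 0.025),
                          residual=1.0, converged=False, restarts_used=3,
                          iterations=0)
        with pytest.raises(ValueError, match="converge"):
            interaction_matrix(small_net, bad)


class TestTfSubmatrix:
    def test_nonzero_spectrum_carried_by_q(self, dense_net):
        """Eigenvalues of M = eigenvalues of Q plus structural zeros."""
        ss = _solved(dense_net)
        m, m1, m2 = interaction_matrix(dense_net, ss)
        q_mat = tf_submatrix(m1, m2, ss, dense_net.topology.tf_indices)
        assert q_mat.shape == (dense_net.topology.n_tfs,) * 2
        eig_m = np.linalg.eigvals(m)
        eig_q = np.linalg.eigvals(q_mat)
        # match the well-separated (nonzero) part of the spectra
        big_m = np.sort_complex(eig_m[np.abs(eig_m) > 1e-2])
        big_q = np.sort_complex(eig_q[np.abs(eig_q) > 1e-2])
        assert big_m.size == big_q.size
        assert np.abs(big_m - big_q).max() < 1e-8

    def test_wrong_tf_set_raises_structural_error(self, dense_net):
        ss = _solved(dense_net)
        _, m1, m2 = interaction_matrix(dense_net, ss)
        with pytest.raises(ValueError, match="TF set"):
            tf_submatrix(m1, m2, ss, dense_net.topology.tf_indices[:3])

    def test_spectrum_invariant_under_nontf_relabeling(self):
        """Permuting non-TF gene labels leaves the Q spectrum unchanged."""
        es = gen_bipartite(60, 6, 120, 0.5, seed=61)
        net = assign_parameters(es, omega_max=2.0, seed=62)
        ss = _solved(net)
        m1, m2 = interaction_structure(net, ss)
        q0 = np.linalg.eigvals(tf_submatrix(m1, m2, ss, es.tf_indices))

        # permute the non-TF genes other than ribosome and RNAP
        rng = np.random.default_rng(63)
        movable = np.arange(6, 58)
        perm = np.arange(60)
        perm[movable] = rng.permutation(movable)
        inv = np.argsort(perm)
        es2 = EdgeSet(
            n_genes=60, tf_indices=es.tf_indices, ribosome_index=59,
            rnap_index=58, regulators=perm[es.regulators],
            targets=perm[es.targets], signs=es.signs,
        )
        from grnstab import RegulatoryNetwork

        net2 = RegulatoryNetwork(
            topology=es2, omega=net.omega, gamma=net.gamma,
            k_half=net.k_half, hill_coeff=net.hill_coeff, g0=net.g0[inv],
        )
        ss2 = _solved(net2)
        m1b, m2b = interaction_structure(net2, ss2)
        q1 = np.linalg.eigvals(tf_submatrix(m1b, m2b, ss2, es2.tf_indices))
        assert np.abs(np.sort_complex(q0) - np.sort_complex(q1)).max() < 1e-9


class TestBipartite:
    def test_closed_form_matches_eigendecomposition(self):
        es = gen_bipartite(400, 40, 1600, 0.5, seed=71)
        net = assign_parameters(es, omega_max=2.0, seed=72)
        ss = _solved(net)
        lam_qb, lam_mb = bipartite_eigenvalue(net, ss)
        m1, m2 = interaction_structure(net, ss)
        q_mat = tf_submatrix(m1, m2, ss, es.tf_indices)
        eig_q = np.linalg.eigvals(q_mat)
        # Q is rank one: a single eigenvalue away from zero
        nz = eig_q[np.abs(eig_q) > 1e-12]
        assert nz.size == 1
        assert abs(nz[0].imag) < 1e-12
        assert nz[0].real == pytest.approx(lam_qb, abs=1e-8)
        assert lam_mb == max(lam_qb, 0.0)

    def test_all_activating_network_is_deeply_stable(self):
        es = gen_bipartite(300, 30, 1200, 0.0, seed=73)
        net = assign_parameters(es, omega_max=2.0, seed=74)
        ss = _solved(net)
        lam_qb, lam_mb = bipartite_eigenvalue(net, ss)
        assert lam_qb < 0
        assert lam_mb == 0.0

    def test_rejects_non_bipartite_input(self, small_net):
        ss = _solved(small_net)
        with pytest.raises(ValueError, match="bipartite"):
            bipartite_eigenvalue(small_net, ss)


class TestScaledEigenvalues:
    @pytest.mark.parametrize("omega", [-0.9, -0.5, 0.0, 1.0, 10.0, 1000.0])
    def test_marginal_interaction_eigenvalue_maps_to_zero(self, omega):
        lam = scaled_eigenvalues(np.array([1.0 + 0j]), omega)
        assert np.max(lam.real) == pytest.approx(0.0, abs=1e-12)

    def test_omega_zero_square_root_form(self):
        lam_m = np.array([0.25 + 0j, -0.5 + 0.3j])
        got = scaled_eigenvalues(lam_m, 0.0)
        expected = np.concatenate([np.sqrt(lam_m) - 1, -np.sqrt(lam_m) - 1])
        assert np.allclose(got, expected)

    def test_fast_mrna_limit_recovers_protein_sector(self):
        lam_m = np.array([0.3 + 0.2j])
        got = scaled_eigenvalues(lam_m, 1e6)
        closest = got[np.argmin(np.abs(got - (lam_m[0] - 1)))]
        assert abs(closest - (lam_m[0] - 1)) < 1e-5

    def test_rejects_omega_below_minus_one(self):
        with pytest.raises(ValueError):
            scaled_eigenvalues(np.array([0.5 + 0j]), -1.5)

    def test_stability_threshold_constant_across_omega_grid(self):
        """max Re of the mapped eigenvalues crosses 0 exactly at
        lambda_M = 1 for every omega >= -1."""
        for omega in np.concatenate([[-0.9, -0.5], np.logspace(-2, 3, 12)]):
            below = scaled_eigenvalues(np.array([1 - 1e-9 + 0j]), omega)
            above = scaled_eigenvalues(np.array([1 + 1e-9 + 0j]), omega)
            assert below.real.max() < 0
            assert above.real.max() > 0


class TestFullJacobian:
    def test_matches_finite_differences(self, small_net):
        ss = _solved(small_net)
        params = CellParams(k_m=1.5, tau_m=0.5, tau_p=1e4)
        ss.c_m = mrna_fixed_point(small_net, params, ss.c)
        jac, _ = full_jacobian(small_net, params, ss)
        x0 = np.concatenate([ss.c_m, ss.c])
        fd = fd_jacobian(lambda x: rhs_phase1(x, small_net, params), x0)
        assert np.abs(jac - fd).max() <= 1e-6 * np.abs(jac).max()

    def test_rhs_vanishes_at_fixed_point(self, small_net):
        ss = _solved(small_net)
        params = CellParams()
        ss.c_m = mrna_fixed_point(small_net, params, ss.c)
        dstate = rhs_phase1(np.concatenate([ss.c_m, ss.c]), small_net, params)
        assert np.abs(dstate).max() < 1e-13

    def test_spectrum_follows_degradation_mapping(self, dense_net):
        """Away from the defective zero-cluster images, eig(J~) equals the
        two-branch mapping of eig(M); the characteristic-polynomial
        identity ties the full spectra together."""
        ss = _solved(dense_net)
        n = dense_net.n_genes
        m, _, _ = interaction_matrix(dense_net, ss)
        lam = np.linalg.eigvals(m)
        params = CellParams(tau_m=1.0, tau_p=1e4)
        ss.c_m = mrna_fixed_point(dense_net, params, ss.c)
        _, jt = full_jacobian(dense_net, params, ss)
        _, omega, _ = growth_quantities(dense_net, params, ss)
        ev = np.linalg.eigvals(jt)
        pred = scaled_eigenvalues(lam, omega)
        cost = np.abs(ev[:, None] - pred[None, :])
        rows, cols = linear_sum_assignment(cost)
        excl = np.array([-1.0, -1.0 - omega, -1.0 - omega / 2])
        far = (np.abs(pred[cols][:, None] - excl[None, :]) > 0.05).all(axis=1)
        assert far.sum() > 0
        assert cost[rows, cols][far].max() < 1e-6
        # determinant identity at probe points covers the whole spectrum
        rng = np.random.default_rng(0)
        for _ in range(5):
            z = complex(rng.normal(scale=2), rng.normal(scale=2))
            w = (z + 1) * (z + 1 + omega) / (1 + omega)
            s1, l1 = np.linalg.slogdet(jt - z * np.eye(2 * n))
            s2, l2 = np.linalg.slogdet(w * np.eye(n) - m)
            lhs = l1 + np.log(s1)
            rhs = n * np.log(complex(1 + omega)) + l2 + np.log(s2)
            assert abs(np.exp(lhs - rhs) - 1) < 1e-6


class TestGrowthQuantities:
    def test_equal_lifetimes_give_zero_omega(self, small_net):
        ss = _solved(small_net)
        beta0, omega, mu = growth_quantities(
            small_net, CellParams(tau_m=7.0, tau_p=7.0), ss)
        assert omega == 0.0
        assert beta0 == pytest.approx(ss.c[small_net.topology.ribosome_index])

    def test_growing_cell_condition(self, small_net):
        ss = _solved(small_net)
        rib = small_net.topology.ribosome_index
        phi_r = allocation(small_net, ss.c)[rib]
        params = CellParams(tau_p=1e6)
        assert params.tau_p * params.k_p * phi_r > 1
        _, _, mu = growth_quantities(small_net, params, ss)
        assert mu > 0

    def test_verdict_independent_of_degradation_rates(self, small_net):
        """Stability is decided by M alone: changing tau_m and tau_p
        leaves both lambda_max and the verdict untouched."""
        reports = [
            analyze(small_net, params=CellParams(tau_m=tm, tau_p=tp), seed=4)
            for tm, tp in [(0.1, 1e6), (5.0, 1e4), (50.0, 100.0)]
        ]
        lams = {r.lambda_max for r in reports}
        verdicts = {r.stable for r in reports}
        assert len(lams) == 1 and len(verdicts) == 1


class TestClassifyStability:
    def test_boundary_value_is_unstable(self):
        assert not classify_stability(1.0, True)
        assert classify_stability(0.999999, True)

    def test_unconverged_is_unstable(self):
        assert not classify_stability(0.0, False)
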