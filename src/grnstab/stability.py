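"""Interaction-matrix assembly, spectra, and the degradation-rate mapping.

Linearizing the reduced protein dynamics dc/dt = k_p c_r (phi(c) - c)
about its fixed point gives the Jacobian A = beta0 (M - I), with
beta0 = k_p c_r^ss the relaxation rate in the absence of interactions
and M the interaction matrix

    M_ij = d phi_i / d c_j |_ss = c_i^ss (M1_ij - M2_ij),

where M1_ij = d log g_i / d c_j carries the direct regulatory
interactions and M2 (every row equal to d log g_T / d c_j, a rank-1
matrix) the indirect global competition for the shared transcription and
translation machinery.  The system is stable iff the maximal real part
of M's eigenvalues, lambda_M,rmax, is below 1.

Because regulators are always TFs, the columns of M outside the TF set
vanish and the nonzero spectrum of M is carried by the q x q TF block

    Q_ij = c_i^ss (T1_ij - T2_ij),

which is the cheap route to lambda_M,rmax when q << N.  For strictly
bipartite networks (no TF->TF edges) T1 = 0, Q is rank-1 and has the
single closed-form eigenvalue

    lambda_Q,b = - sum_{i in TF} c_i d log g_T / d c_i,

with lambda_M,b = max(lambda_Q,b, 0) since 0 is always in M's spectrum.

Away from the fast-mRNA limit, the full 2N x 2N Jacobian J of the
coupled mRNA/protein system, scaled by beta0, has eigenvalues given by
the two-branch mapping

    lambda~ = (1/2) (-omega +/- sqrt(omega^2 + 4 lambda_M (1 + omega))) - 1,

with omega = 1/(tau beta0) >= -1 the dimensionless degradation-rate
contrast.  Both branches cross Re(lambda~) = 0 exactly at lambda_M = 1
for every admissible omega: mRNA and protein lifetimes never decide
stability, only M does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .networks import census
from .regulation import (
    CellParams,
    RegulatoryNetwork,
    allocation,
    allocation_jacobian,
    dlog_g,
)
from .steady_state import SteadyState, mrna_fixed_point, solve_fixed_point

__all__ = [
    "StabilityReport",
    "STABILITY_MARGIN",
    "interaction_matrix",
    "interaction_structure",
    "tf_submatrix",
    "max_interaction_eigenvalue",
    "bipartite_eigenvalue",
    "scaled_eigenvalues",
    "jacobian_phase1",
    "full_jacobian",
    "growth_quantities",
    "classify_stability",
    "analyze",
]

#: Margin below the lambda_M,rmax = 1 threshold guarding against spectral
#: round-off; a fixed point sitting exactly on the boundary is unstable.
STABILITY_MARGIN = 1e-8


# --------------------------------------------------------------------------
# interaction matrix and TF submatrix
# --------------------------------------------------------------------------


def _require_converged(ss: SteadyState) -> None:
    if not ss.converged:
        raise ValueError("steady state did not converge; no fixed point to linearize")


def interaction_structure(
    net: RegulatoryNetwork, ss: SteadyState
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse M1 = d log g / d c and the common row m2 of M2 at the fixed
    point (M2 = ones * m2^T)."""
    _require_converged(ss)
    m1 = dlog_g(net, ss.c)
    m2 = ss.c @ m1
    return m1, np.asarray(m2).ravel()


def interaction_matrix(
    net: RegulatoryNetwork, ss: SteadyState
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense (M, M1, M2) at a converged fixed point.

    M = diag(c^ss) (M1 - M2); M2 has every row equal to
    d log g_T / d c = c^ss M1 and is rank-1 whenever the network has at
    least one edge.
    """
    m1_sparse, m2 = interaction_structure(net, ss)
    m1 = m1_sparse.toarray()
    m2_full = np.broadcast_to(m2, m1.shape).copy()
    m = ss.c[:, None] * (m1 - m2_full)
    return m, m1, m2_full


def tf_submatrix(
    m1: np.ndarray | sp.spmatrix,
    m2: np.ndarray,
    ss: SteadyState,
    tf_indices: np.ndarray,
    atol: float = 1e-12,
) -> np.ndarray:
    """TF-sector block Q_ij = c_i^ss (T1_ij - T2_ij), shape (q, q).

    Verifies that the columns of M outside ``tf_indices`` vanish (true
    whenever every regulator is a declared TF); a nonzero non-TF column
    means the declared TF set is wrong and raises ``ValueError``.
    """
    tf_indices = np.asarray(tf_indices, dtype=np.int64)
    n = ss.c.size
    m2 = np.asarray(m2)
    m2_row = m2[0] if m2.ndim == 2 else m2  # accept full M2 or its row
    if sp.issparse(m1):
        m1 = m1.tocsc()
        col_mag = np.asarray(abs(m1).sum(axis=0)).ravel()
    else:
        m1 = np.asarray(m1)
        col_mag = np.abs(m1).sum(axis=0)
    outside = np.setdiff1d(np.arange(n), tf_indices)
    if outside.size and (
        np.abs(col_mag[outside]).max() > atol or np.abs(m2_row[outside]).max() > atol
    ):
        raise ValueError(
            "nonzero interaction-matrix column outside the declared TF set"
        )
    if sp.issparse(m1):
        t1 = m1[tf_indices][:, tf_indices].toarray()
    else:
        t1 = m1[np.ix_(tf_indices, tf_indices)]
    t2 = m2_row[tf_indices]
    return ss.c[tf_indices, None] * (t1 - t2[None, :])


def _interaction_spectrum(
    net: RegulatoryNetwork, ss: SteadyState
) -> tuple[np.ndarray, np.ndarray]:
    """(eig(Q), full spectrum of M = eig(Q) padded with zeros)."""
    m1, m2 = interaction_structure(net, ss)
    q_mat = tf_submatrix(m1, m2, ss, net.topology.tf_indices)
    eig_q = np.linalg.eigvals(q_mat) if q_mat.size else np.empty(0, complex)
    n_zero = net.n_genes - net.topology.n_tfs
    return eig_q, np.concatenate([eig_q, np.zeros(n_zero, dtype=complex)])


def max_interaction_eigenvalue(net: RegulatoryNetwork, ss: SteadyState) -> float:
    """lambda_M,rmax via the TF-submatrix shortcut.

    The spectrum of M is the spectrum of Q plus N - q zeros, so the
    maximal real part is max(max Re eig(Q), 0) whenever q < N.
    """
    eig_q, _ = _interaction_spectrum(net, ss)
    lam = eig_q.real.max() if eig_q.size else -np.inf
    if net.topology.n_tfs < net.n_genes:
        lam = max(lam, 0.0)
    return float(lam)


def bipartite_eigenvalue(
    net: RegulatoryNetwork, ss: SteadyState
) -> tuple[float, float]:
    """Closed-form (lambda_Q,b, lambda_M,b) for a strictly bipartite network.

    Requires a census with no self- and no TF->TF edges; then Q = -c T2
    is rank-1 with the unique real eigenvalue
    lambda_Q,b = - sum_{i in TF} c_i^ss (d log g_T / d c_i), and
    lambda_M,b = max(lambda_Q,b, 0).
    """
    comp = census(net.topology)
    if comp.n_self or comp.n_tf_tf:
        raise ValueError(
            "network is not strictly bipartite "
            f"(n_self={comp.n_self}, n_tf_tf={comp.n_tf_tf})"
        )
    _, m2 = interaction_structure(net, ss)
    tf = net.topology.tf_indices
    lam_qb = float(-(ss.c[tf] * m2[tf]).sum())
    return lam_qb, max(lam_qb, 0.0)


# --------------------------------------------------------------------------
# degradation-rate mapping and the full 2N Jacobian
# --------------------------------------------------------------------------


def scaled_eigenvalues(eig_m: np.ndarray, omega: float) -> np.ndarray:
    """Map interaction-matrix eigenvalues to the 2N scaled eigenvalues.

    Both branches lambda~ = (-omega +/- sqrt(omega^2 + 4 lambda_M
    (1 + omega)))/2 - 1 with the principal complex square root.  Valid
    for omega >= -1 (guaranteed for a growing cell since tau_m >= 0).
    """
    if omega < -1:
        raise ValueError(f"omega must be >= -1, got {omega}")
    eig_m = np.asarray(eig_m, dtype=complex)
    root = np.sqrt(omega**2 + 4.0 * eig_m * (1.0 + omega))
    plus = 0.5 * (-omega + root) - 1.0
    minus = 0.5 * (-omega - root) - 1.0
    return np.concatenate([plus, minus])


def jacobian_phase1(
    net: RegulatoryNetwork,
    params: CellParams,
    c_m: np.ndarray,
    c: np.ndarray,
) -> np.ndarray:
    """Analytic 2N x 2N Jacobian of the coupled mRNA/protein dynamics.

    State ordering is (c_m, c).  All dependences are differentiated,
    including those of the allocation fractions, the RNA polymerase and
    ribosome concentrations, and the total mRNA pool c_mT on the state.
    """
    es = net.topology
    n = net.n_genes
    rib, rnap = es.ribosome_index, es.rnap_index
    c_m = np.asarray(c_m, dtype=float)
    c = np.asarray(c, dtype=float)
    cmt = c_m.sum()
    if cmt <= 0:
        raise ValueError("total mRNA concentration must be positive")
    phi = allocation(net, c)
    dphi = allocation_jacobian(net, c)
    k_m, k_p, inv_tau = params.k_m, params.k_p, params.inv_tau

    j_mm = -(k_p * c[rib] + inv_tau) * np.eye(n)
    j_mc = k_m * c[rnap] * dphi
    j_mc[:, rnap] += k_m * phi
    j_mc[:, rib] -= k_p * c_m
    j_cm = (k_p * c[rib] / cmt) * (np.eye(n) - np.outer(c_m, np.ones(n)) / cmt)
    j_cc = -k_p * c[rib] * np.eye(n)
    j_cc[:, rib] += k_p * (c_m / cmt - c)
    return np.block([[j_mm, j_mc], [j_cm, j_cc]])


def full_jacobian(
    net: RegulatoryNetwork, params: CellParams, ss: SteadyState
) -> tuple[np.ndarray, np.ndarray]:
    """(J, J~ = J / beta0) at a converged fixed point with mRNA levels."""
    _require_converged(ss)
    c_m = ss.c_m if ss.c_m is not None else mrna_fixed_point(net, params, ss.c)
    j = jacobian_phase1(net, params, c_m, ss.c)
    beta0 = params.k_p * ss.c[net.topology.ribosome_index]
    return j, j / beta0


def growth_quantities(
    net: RegulatoryNetwork, params: CellParams, ss: SteadyState
) -> tuple[float, float, float]:
    """(beta0, omega, mu) at a converged fixed point.

    beta0 = k_p c_r^ss is the no-interaction relaxation rate, omega =
    (1/tau_m - 1/tau_p)/beta0 the degradation-rate contrast, and
    mu = k_p phi_r(c^ss) - 1/tau_p the exponential volume growth rate
    (positive for an admissible growing cell).
    """
    _require_converged(ss)
    rib = net.topology.ribosome_index
    beta0 = params.k_p * ss.c[rib]
    omega = params.inv_tau / beta0
    phi_r = allocation(net, ss.c)[rib]
    mu = params.k_p * phi_r - 1.0 / params.tau_p
    return float(beta0), float(omega), float(mu)


def classify_stability(
    lambda_max: float, converged: bool, margin: float = STABILITY_MARGIN
) -> bool:
    """Stable iff a fixed point was found and lambda_M,rmax < 1 - margin."""
    return bool(converged and lambda_max < 1.0 - margin)


# --------------------------------------------------------------------------
# report pipeline
# --------------------------------------------------------------------------


@dataclass
class StabilityReport:
    """Spectral stability analysis of one parameterized network."""

    lambda_max: float
    stable: bool
    converged: bool
    residual: float
    eig_m: np.ndarray
    eig_scaled: np.ndarray
    beta0: float
    omega: float
    mu: float
    lambda_qb: float | None = None
    lambda_mb: float | None = None
    m: np.ndarray | None = None
    m1: np.ndarray | None = None
    m2: np.ndarray | None = None
    q_matrix: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def pairs(z: np.ndarray) -> list[list[float]]:
            return [[float(v.real), float(v.imag)] for v in z]

        payload = {
            "lambda_max": self.lambda_max,
            "stable": self.stable,
            "converged": self.converged,
            "residual": self.residual,
            "beta0": self.beta0,
            "omega": self.omega,
            "mu": self.mu,
            "lambda_qb": self.lambda_qb,
            "lambda_mb": self.lambda_mb,
            "eig_m": pairs(self.eig_m),
            "eig_scaled": pairs(self.eig_scaled),
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def analyze(
    net: RegulatoryNetwork,
    params: CellParams | None = None,
    seed: int = 0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    n_restarts: int = 3,
    include_matrices: bool = False,
) -> StabilityReport:
    """Solve the fixed point and assemble a full stability report.

    A network whose fixed point cannot be found is reported as unstable
    with ``lambda_max = nan`` (the loss of a findable fixed point is the
    instability observable for strongly interacting networks).
    """
    if params is None:
        params = CellParams()
    ss = solve_fixed_point(
        net, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=seed
    )
    if not ss.converged:
        return StabilityReport(
            lambda_max=float("nan"),
            stable=False,
            converged=False,
            residual=ss.residual,
            eig_m=np.empty(0, complex),
            eig_scaled=np.empty(0, complex),
            beta0=float("nan"),
            omega=float("nan"),
            mu=float("nan"),
        )
    ss.c_m = mrna_fixed_point(net, params, ss.c)
    eig_q, eig_m = _interaction_spectrum(net, ss)
    lam = eig_q.real.max() if eig_q.size else -np.inf
    if net.topology.n_tfs < net.n_genes:
        lam = max(lam, 0.0)
    beta0, omega, mu = growth_quantities(net, params, ss)
    comp = census(net.topology)
    lam_qb = lam_mb = None
    if comp.n_self == 0 and comp.n_tf_tf == 0 and net.n_edges:
        lam_qb, lam_mb = bipartite_eigenvalue(net, ss)
    report = StabilityReport(
        lambda_max=float(lam),
        stable=classify_stability(float(lam), True),
        converged=True,
        residual=ss.residual,
        eig_m=eig_m,
        eig_scaled=scaled_eigenvalues(eig_m, omega),
        beta0=beta0,
        omega=omega,
        mu=mu,
        lambda_qb=lam_qb,
        lambda_mb=lam_mb,
    )
    if include_matrices:
        m, m1, m2 = interaction_matrix(net, ss)
        report.m, report.m1, report.m2 = m, m1, m2
        report.q_matrix = tf_submatrix(m1, m2, ss, net.topology.tf_indices)
    return report
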