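"""Quantitative transcriptional regulation on top of a topology.

Each gene i carries an effective copy number

    g_i(c) = g_i0 * prod_j (1 + gamma_ij * f_ij(c_j)),

the product running over i's regulators.  f_ij is a Hill function of the
regulator concentration c_j with threshold K_ij and global coefficient h,
and gamma_ij encodes the type and strength of the interaction through
the per-edge fold-change Omega_ij > 1:

    gamma_ij = Omega_ij - 1          (activation,  gamma > 0)
    gamma_ij = 1/Omega_ij - 1        (repression, -1 < gamma < 0)

so a saturated regulator scales g_i by Omega_ij (up) or 1/Omega_ij
(down).  When RNA polymerases are limiting, the transcription rate of
gene i is proportional to the allocation fraction

    phi_i(c) = g_i(c) / sum_j g_j(c),

the fraction of polymerases working on gene i.  This module evaluates
g, phi and their analytic derivatives, and draws the quantitative
parameters for a given topology.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .networks import EdgeSet, read_edge_list, write_edge_list

__all__ = [
    "RegulatoryNetwork",
    "CellParams",
    "assign_parameters",
    "gamma_from_fold_change",
    "hill",
    "hill_deriv",
    "gene_copy",
    "allocation",
    "dlog_g",
    "allocation_jacobian",
    "save_network",
    "load_network",
]


@dataclass
class CellParams:
    """Kinetic parameters of the growing cell.

    k_m / k_p are the transcription and translation rates of a single
    RNA polymerase / ribosome (1/time; time is measured in units of
    1/k_p throughout, so k_p defaults to 1).  tau_m and tau_p are the
    mRNA and protein lifetimes; ``tau_m = inf`` encodes no mRNA
    degradation.  The derived rate 1/tau = 1/tau_m - 1/tau_p may have
    either sign.

    Defaults put the cell in the fast-mRNA-degradation, growing regime
    for the gene counts used here (protein lifetime much longer than the
    doubling time, mRNA lifetime much shorter).
    """

    k_m: float = 1.0
    k_p: float = 1.0
    tau_m: float = 0.1
    tau_p: float = 1.0e6

    def __post_init__(self) -> None:
        if self.k_m <= 0 or self.k_p <= 0:
            raise ValueError("k_m and k_p must be positive")
        if self.tau_m <= 0 or self.tau_p <= 0:
            raise ValueError("tau_m and tau_p must be positive")

    @property
    def inv_tau(self) -> float:
        """1/tau = 1/tau_m - 1/tau_p (difference of degradation rates)."""
        inv_m = 0.0 if math.isinf(self.tau_m) else 1.0 / self.tau_m
        return inv_m - 1.0 / self.tau_p


@dataclass
class RegulatoryNetwork:
    """Topology plus quantitative regulation and cell-level parameters.

    Per-edge arrays (aligned with ``topology``'s edge order): fold-change
    ``omega`` in (1, Omega_max], regulation coefficient ``gamma`` (sign
    matches the edge sign), activation threshold ``k_half`` (K_ij, a
    concentration).  Per-gene: unregulated effective copy number ``g0``.
    ``hill_coeff`` is the global Hill coefficient h.
    """

    topology: EdgeSet
    omega: np.ndarray
    gamma: np.ndarray
    k_half: np.ndarray
    hill_coeff: float
    g0: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.k_half = np.asarray(self.k_half, dtype=float)
        self.g0 = np.asarray(self.g0, dtype=float)

    @property
    def n_genes(self) -> int:
        return self.topology.n_genes

    @property
    def n_edges(self) -> int:
        return self.topology.n_edges

    def validate(self) -> None:
        self.topology.validate()
        u = self.topology.n_edges
        for name in ("omega", "gamma", "k_half"):
            if getattr(self, name).shape != (u,):
                raise ValueError(f"{name} must have one entry per edge")
        if self.g0.shape != (self.n_genes,):
            raise ValueError("g0 must have one entry per gene")
        if u:
            if np.any(self.omega <= 1.0):
                raise ValueError("fold-changes must exceed 1")
            if np.any(self.k_half <= 0):
                raise ValueError("activation thresholds must be positive")
            expected = gamma_from_fold_change(self.omega, self.topology.signs)
            if not np.allclose(self.gamma, expected, rtol=1e-12, atol=0):
                raise ValueError("gamma inconsistent with omega and edge sign")
        if self.hill_coeff <= 0:
            raise ValueError("hill_coeff must be positive")
        if np.any(self.g0 <= 0):
            raise ValueError("g0 must be positive")


def gamma_from_fold_change(omega: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Regulation coefficient from fold-change and edge sign.

    gamma = Omega - 1 on activating edges, 1/Omega - 1 on repressing
    ones, so gamma -> 0 as Omega -> 1 in either case.
    """
    omega = np.asarray(omega, dtype=float)
    return np.where(np.asarray(sign) > 0, omega - 1.0, 1.0 / omega - 1.0)


def assign_parameters(
    es: EdgeSet,
    omega_max: float,
    h: float = 1.0,
    kappa: float = 1.0,
    g0_low: float = 0.5,
    g0_high: float = 1.5,
    seed: int = 0,
    omega_dist: str = "uniform",
) -> RegulatoryNetwork:
    """Draw quantitative parameters for a topology.

    Fold-changes are i.i.d. from ``omega_dist`` on (1, omega_max]
    ("uniform" or "loguniform"), gamma follows from the edge signs,
    K_ij = kappa / N for every edge (TF thresholds are comparable to TF
    concentrations, which scale as 1/N), and g_i0 is i.i.d. uniform on
    (g0_low, g0_high).
    """
    if omega_max <= 1.0:
        raise ValueError("omega_max must exceed 1")
    if g0_low <= 0 or g0_high <= g0_low:
        raise ValueError("need 0 < g0_low < g0_high")
    rng = np.random.default_rng(seed)
    u = es.n_edges
    if omega_dist == "uniform":
        omega = rng.uniform(1.0, omega_max, size=u)
    elif omega_dist == "loguniform":
        omega = np.exp(rng.uniform(0.0, np.log(omega_max), size=u))
    else:
        raise ValueError(f"unknown omega_dist {omega_dist!r}")
    net = RegulatoryNetwork(
        topology=es,
        omega=omega,
        gamma=gamma_from_fold_change(omega, es.signs),
        k_half=np.full(u, kappa / es.n_genes),
        hill_coeff=float(h),
        g0=rng.uniform(g0_low, g0_high, size=es.n_genes),
    )
    net.validate()
    return net


# --------------------------------------------------------------------------
# Hill input and regulation functions
# --------------------------------------------------------------------------


def hill(c, k, h):
    """Hill activation function c^h / (K^h + c^h), in [0, 1)."""
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # (c/K)^h / (1 + (c/K)^h) is overflow-safe for large c/K
        x = np.power(c / k, h)
        return np.where(np.isinf(x), 1.0, x / (1.0 + x))


def hill_deriv(c, k, h):
    """Analytic derivative of :func:`hill` with respect to c."""
    c = np.asarray(c, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.power(c / k, h)
        out = h * x / (c * (1.0 + x) ** 2)
    # c = 0: derivative is 0 for h > 1, 1/K for h = 1, +inf for h < 1
    if np.ndim(out) == 0:
        if c == 0:
            return float(1.0 / k) if h == 1 else (0.0 if h > 1 else np.inf)
        return float(out)
    zero = c == 0
    if np.any(zero):
        out = np.where(zero, 1.0 / k if h == 1 else (0.0 if h > 1 else np.inf), out)
    return out


def _edge_terms(net: RegulatoryNetwork, c: np.ndarray):
    """Per-edge Hill values f_ij(c_j) and factors 1 + gamma_ij f_ij."""
    cj = np.asarray(c, dtype=float)[net.topology.regulators]
    f = hill(cj, net.k_half, net.hill_coeff)
    return f, 1.0 + net.gamma * f


def gene_copy(net: RegulatoryNetwork, c: np.ndarray) -> np.ndarray:
    """Effective gene copy numbers g_i(c); strictly positive."""
    log_g = np.log(net.g0).copy()
    if net.n_edges:
        _, factors = _edge_terms(net, c)
        np.add.at(log_g, net.topology.targets, np.log(factors))
    return np.exp(log_g)


def allocation(net: RegulatoryNetwork, c: np.ndarray) -> np.ndarray:
    """RNA-polymerase allocation fractions phi_i(c) = g_i / sum_j g_j."""
    g = gene_copy(net, c)
    return g / g.sum()


def dlog_g(net: RegulatoryNetwork, c: np.ndarray) -> sp.csr_matrix:
    """Sparse matrix of direct-regulation derivatives d log g_i / d c_j.

    Nonzero only on edges, where the entry is
    gamma_ij f'_ij(c_j) / (1 + gamma_ij f_ij(c_j)); its sign equals the
    edge sign.
    """
    n = net.n_genes
    if net.n_edges == 0:
        return sp.csr_matrix((n, n))
    c = np.asarray(c, dtype=float)
    cj = c[net.topology.regulators]
    f, factors = _edge_terms(net, c)
    fprime = hill_deriv(cj, net.k_half, net.hill_coeff)
    vals = net.gamma * fprime / factors
    return sp.csr_matrix(
        (vals, (net.topology.targets, net.topology.regulators)), shape=(n, n)
    )


def allocation_jacobian(net: RegulatoryNetwork, c: np.ndarray) -> np.ndarray:
    """Dense Jacobian d phi_i / d c_j at an arbitrary concentration c.

    phi_i = g_i / g_T gives
    d phi_i / d c_j = phi_i (d log g_i / d c_j - sum_k phi_k d log g_k / d c_j).
    At a fixed point of the reduced dynamics (phi(c) = c) this is the
    interaction matrix M.
    """
    phi = allocation(net, c)
    d1 = dlog_g(net, c)
    col = phi @ d1  # row vector: d log g_T / d c_j
    return phi[:, None] * (d1.toarray() - col[None, :])


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def save_network(net: RegulatoryNetwork, prefix: str | Path) -> None:
    """Write ``<prefix>.json`` (full-precision parameters and topology
    indices) and ``<prefix>.tsv`` (human-readable edge list)."""
    prefix = Path(prefix)
    es = net.topology
    payload = {
        "n_genes": es.n_genes,
        "tf_indices": es.tf_indices.tolist(),
        "ribosome_index": es.ribosome_index,
        "rnap_index": es.rnap_index,
        "regulators": es.regulators.tolist(),
        "targets": es.targets.tolist(),
        "signs": es.signs.tolist(),
        "shortfall": es.shortfall,
        "omega": net.omega.tolist(),
        "gamma": net.gamma.tolist(),
        "k_half": net.k_half.tolist(),
        "hill_coeff": net.hill_coeff,
        "g0": net.g0.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(payload) + "\n")
    write_edge_list(es, prefix.with_suffix(".tsv"))


def load_network(prefix: str | Path) -> RegulatoryNetwork:
    """Inverse of :func:`save_network`; exact for all numeric fields."""
    payload = json.loads(Path(prefix).with_suffix(".json").read_text())
    es = EdgeSet(
        n_genes=payload["n_genes"],
        tf_indices=np.array(payload["tf_indices"], dtype=np.int64),
        ribosome_index=payload["ribosome_index"],
        rnap_index=payload["rnap_index"],
        regulators=np.array(payload["regulators"], dtype=np.int64),
        targets=np.array(payload["targets"], dtype=np.int64),
        signs=np.array(payload["signs"], dtype=np.int64),
        shortfall=payload["shortfall"],
    )
    net = RegulatoryNetwork(
        topology=es,
        omega=np.array(payload["omega"]),
        gamma=np.array(payload["gamma"]),
        k_half=np.array(payload["k_half"]),
        hill_coeff=payload["hill_coeff"],
        g0=np.array(payload["g0"]),
    )
    net.validate()
    return net
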