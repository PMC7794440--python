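"""Self-consistent fixed point of the reduced protein dynamics.

In the fast-mRNA limit the protein concentrations evolve as
dc_i/dt = k_p c_r (phi_i(c) - c_i), so a steady state is a
self-consistent point of the allocation map,

    c_i^ss = phi_i(c^ss),

which automatically lies on the probability simplex (sum_i c_i = 1).
The solver runs a damped self-consistent iteration from random simplex
points, with a Newton fallback for fixed points at which the plain
iteration spirals (complex interaction-matrix eigenvalues of large
modulus can make the damped map non-contracting even when the dynamical
fixed point is stable).  Failure to converge is reported in the result,
not raised: for strongly interacting networks the disappearance of a
findable fixed point is itself the observable of interest.

The quasi-steady mRNA concentrations at a given protein state are

    c_mi = k_m c_n / (k_p c_r + 1/tau) * phi_i(c),

with c_n and c_r the RNA polymerase and ribosome concentrations and
1/tau = 1/tau_m - 1/tau_p.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .regulation import CellParams, RegulatoryNetwork, allocation, allocation_jacobian

__all__ = ["SteadyState", "solve_fixed_point", "mrna_fixed_point"]


@dataclass
class SteadyState:
    """Fixed point of the reduced dynamics with convergence diagnostics.

    ``residual`` is max_i |phi_i(c) - c_i| at the returned ``c``;
    ``restart_seeds`` records the derived seed of every restart tried.
    ``c_m`` is filled by :func:`mrna_fixed_point` when cell parameters
    are supplied.
    """

    c: np.ndarray
    residual: float
    converged: bool
    restarts_used: int
    iterations: int
    restart_seeds: list[int] = field(default_factory=list)
    c_m: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "c": self.c.tolist(),
            "c_m": None if self.c_m is None else self.c_m.tolist(),
            "residual": self.residual,
            "converged": self.converged,
            "restarts_used": self.restarts_used,
            "iterations": self.iterations,
            "restart_seeds": self.restart_seeds,
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SteadyState":
        p = json.loads(Path(path).read_text())
        return cls(
            c=np.array(p["c"]),
            residual=p["residual"],
            converged=p["converged"],
            restarts_used=p["restarts_used"],
            iterations=p["iterations"],
            restart_seeds=p["restart_seeds"],
            c_m=None if p["c_m"] is None else np.array(p["c_m"]),
        )


def _simplex_point(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random point on the positive simplex (exponential trick)."""
    x = rng.exponential(size=n)
    return x / x.sum()


def _newton_polish(
    net: RegulatoryNetwork,
    c: np.ndarray,
    tol: float,
    max_steps: int = 25,
) -> tuple[np.ndarray, float, bool]:
    """Damped Newton on F(c) = phi(c) - c from a starting point.

    Steps are halved until the residual decreases and positivity is
    preserved; any root of F lies on the simplex automatically because
    phi sums to one.  Gives up after a few steps of slow progress so
    that networks without a findable fixed point fail fast.
    """
    f = allocation(net, c) - c
    res = float(np.abs(f).max())
    slow_steps = 0
    for _ in range(max_steps):
        if res < tol:
            return c, res, True
        jac = allocation_jacobian(net, c) - np.eye(net.n_genes)
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            return c, res, False
        scale = 1.0
        for _ in range(30):
            c_new = c + scale * step
            if np.all(c_new > 0):
                f_new = allocation(net, c_new) - c_new
                res_new = float(np.abs(f_new).max())
                if res_new < res:
                    slow_steps = slow_steps + 1 if res_new > 0.3 * res else 0
                    c, f, res = c_new, f_new, res_new
                    break
            scale *= 0.5
        else:
            return c, res, res < tol
        if slow_steps >= 3:
            break
    return c, res, res < tol


def solve_fixed_point(
    net: RegulatoryNetwork,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    n_restarts: int = 3,
    seed: int = 0,
    damping: float = 0.5,
    polish: bool = True,
    stall_window: int = 1000,
) -> SteadyState:
    """Find c with c = phi(c) by damped iteration with restarts.

    Each restart starts from an independent random point on the simplex
    and iterates c <- (1 - damping) c + damping phi(c) until the max-norm
    residual drops below ``tol``.  The iterate stays on the simplex (a
    convex combination of simplex points), so non-convergence shows up
    as a residual that stops improving; when that happens and ``polish``
    is set, a damped Newton solve is attempted from the best iterate
    seen.  The best residual across restarts is always reported.
    """
    if tol <= 0 or max_iter <= 0 or n_restarts < 1:
        raise ValueError("tol, max_iter and n_restarts must be positive")
    if not 0 < damping <= 1:
        raise ValueError("damping must lie in (0, 1]")
    seed_seq = np.random.SeedSequence(seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_restarts)]

    best_c: np.ndarray | None = None
    best_res = np.inf
    total_iter = 0
    for restart, sub_seed in enumerate(restart_seeds, start=1):
        rng = np.random.default_rng(sub_seed)
        c = _simplex_point(rng, net.n_genes)
        loc_best_c, loc_best_res = c, np.inf
        window_best = np.inf
        for it in range(1, max_iter + 1):
            phi = allocation(net, c)
            res = float(np.abs(phi - c).max())
            if res < loc_best_res:
                loc_best_res, loc_best_c = res, c
            if res < tol:
                # one undamped step: exact for constant phi, and a strict
                # improvement whenever the map is locally contracting
                res_full = float(np.abs(allocation(net, phi) - phi).max())
                if res_full < res:
                    c, res = phi, res_full
                total_iter += it
                return SteadyState(
                    c=c,
                    residual=res,
                    converged=True,
                    restarts_used=restart,
                    iterations=total_iter,
                    restart_seeds=restart_seeds[:restart],
                )
            # stall detection: no factor-2 improvement over a full window
            if it % stall_window == 0:
                if loc_best_res > 0.5 * window_best:
                    break
                window_best = loc_best_res
            c = (1.0 - damping) * c + damping * phi
        total_iter += min(it, max_iter)
        if polish:
            c_pol, res_pol, ok = _newton_polish(net, loc_best_c, tol)
            if ok and np.all(c_pol > 0):
                return SteadyState(
                    c=c_pol,
                    residual=res_pol,
                    converged=True,
                    restarts_used=restart,
                    iterations=total_iter,
                    restart_seeds=restart_seeds[:restart],
                )
            if res_pol < loc_best_res:
                loc_best_c, loc_best_res = c_pol, res_pol
        if loc_best_res < best_res:
            best_res, best_c = loc_best_res, loc_best_c
    return SteadyState(
        c=np.asarray(best_c),
        residual=best_res,
        converged=False,
        restarts_used=n_restarts,
        iterations=total_iter,
        restart_seeds=restart_seeds,
    )


def mrna_fixed_point(
    net: RegulatoryNetwork, params: CellParams, c: np.ndarray
) -> np.ndarray:
    """Quasi-steady mRNA concentrations for a given protein state.

    c_mi = k_m c_n / (k_p c_r + 1/tau) * phi_i(c); strictly positive and
    proportional to the allocation fractions.  Raises if the effective
    mRNA removal rate k_p c_r + 1/tau is not positive.
    """
    es = net.topology
    c = np.asarray(c, dtype=float)
    denom = params.k_p * c[es.ribosome_index] + params.inv_tau
    if denom <= 0:
        raise ValueError(
            "non-positive mRNA removal rate k_p*c_r + 1/tau = "
            f"{denom:.3g} (k_p={params.k_p}, c_r={c[es.ribosome_index]:.3g}, "
            f"1/tau={params.inv_tau:.3g})"
        )
    return params.k_m * c[es.rnap_index] / denom * allocation(net, c)
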