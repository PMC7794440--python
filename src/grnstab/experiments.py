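"""Ensemble experiments over network topologies, as tidy tables.

Each sweep draws replicate networks, parameterizes them, solves for the
fixed point, and measures the maximal real part of the
interaction-matrix eigenvalues (lambda_M,rmax) or the stable-fixed-point
probability P(stable).  Results come back as a tidy
:class:`pandas.DataFrame` of one row per replicate plus a per-parameter-
point summary (median and interquartile range, the statistic used for
all ensemble plots).  Every replicate's derived seed is recorded, so any
row can be recomputed bit-for-bit by re-running the sweep with the same
master seed.

The four sweeps:

* :func:`sweep_scaling` -- lambda_M,rmax versus N for random or DAG
  topologies, with the fitted log-log slope (the sqrt(N) law gives 0.5),
* :func:`sweep_pneg_bipartite` -- bipartite networks versus the
  inhibitory fraction P_neg, locating the critical P_neg above which
  lambda_M,rmax departs from 0,
* :func:`sweep_stability` -- P(stable) versus Omega_max for an empirical
  composition under different scrambling schemes,
* :func:`sweep_rho_q` -- P(stable) versus the TF->otherTF density rho_q.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .networks import (
    EdgeSet,
    NetworkComposition,
    census,
    gen_bipartite,
    gen_dag,
    gen_random,
    scramble_composition,
    scramble_fixed_q,
)
from .regulation import assign_parameters
from .stability import (
    bipartite_eigenvalue,
    classify_stability,
    max_interaction_eigenvalue,
)
from .steady_state import solve_fixed_point

__all__ = [
    "ScalingSweep",
    "PnegSweep",
    "StabilitySweep",
    "RhoQSweep",
    "scaled_composition",
    "sweep_scaling",
    "sweep_pneg_bipartite",
    "sweep_stability",
    "sweep_rho_q",
]

#: Median lambda_M,rmax above this counts as departing from exact zero
#: when locating the critical inhibitory fraction.
LAMBDA_ZERO_TOL = 1e-12


def _derive_seeds(master_seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _split_seed(rep_seed: int, n: int = 3) -> list[int]:
    return _derive_seeds(rep_seed, n)


def _measure_lambda(
    es: EdgeSet,
    omega_max: float,
    h: float,
    param_seed: int,
    solver_seed: int,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    n_restarts: int = 3,
    use_bipartite_form: bool = False,
) -> dict:
    """Parameterize a topology, solve its fixed point, measure lambda."""
    t0 = time.perf_counter()
    net = assign_parameters(es, omega_max=omega_max, h=h, seed=param_seed)
    ss = solve_fixed_point(
        net, tol=tol, max_iter=max_iter, n_restarts=n_restarts, seed=solver_seed
    )
    if ss.converged:
        if use_bipartite_form:
            _, lam = bipartite_eigenvalue(net, ss)
        else:
            lam = max_interaction_eigenvalue(net, ss)
    else:
        lam = np.nan
    return {
        "lambda_max": lam,
        "converged": ss.converged,
        "stable": classify_stability(lam, ss.converged) if ss.converged else False,
        "residual": ss.residual,
        "runtime": time.perf_counter() - t0,
    }


def _summary(records: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
    """Median / IQR of ``value`` per parameter point, failures counted."""
    def agg(group: pd.DataFrame) -> pd.Series:
        vals = group.loc[group["converged"], value]
        return pd.Series(
            {
                "median": vals.median(),
                "q25": vals.quantile(0.25),
                "q75": vals.quantile(0.75),
                "n_converged": int(group["converged"].sum()),
                "n_failed": int((~group["converged"]).sum()),
            }
        )

    return records.groupby(by, sort=True).apply(agg, include_groups=False).reset_index()


# --------------------------------------------------------------------------
# sqrt(N) scaling
# --------------------------------------------------------------------------


@dataclass
class ScalingSweep:
    records: pd.DataFrame
    medians: pd.DataFrame
    slopes: dict[float, float]


def sweep_scaling(
    n_list: list[int],
    rho: float = 0.01,
    omega_max_list: tuple[float, ...] = (1.5,),
    n_reps: int = 10,
    topology: str = "random",
    seed: int = 0,
    h: float = 1.0,
) -> ScalingSweep:
    """Median lambda_M,rmax versus N and the fitted log-log slope.

    ``topology`` is "random" or "dag".  The slope per Omega_max is the
    least-squares fit of log(median lambda) against log(N); the sqrt(N)
    law corresponds to slope 0.5.
    """
    if list(n_list) != sorted(n_list):
        raise ValueError("n_list must be increasing")
    if n_reps < 3:
        raise ValueError("need at least 3 replicates")
    gen = {"random": gen_random, "dag": gen_dag}[topology]
    grid = [(n, om) for om in omega_max_list for n in n_list]
    seeds = _derive_seeds(seed, len(grid) * n_reps)
    rows = []
    for gi, (n, om) in enumerate(grid):
        for rep in range(n_reps):
            rep_seed = seeds[gi * n_reps + rep]
            net_seed, par_seed, sol_seed = _split_seed(rep_seed)
            es = gen(n, rho, 0.5, net_seed)
            row = _measure_lambda(es, om, h, par_seed, sol_seed)
            row.update(
                experiment="scaling", topology=topology, n_genes=n,
                rho=rho, omega_max=om, h=h, replicate=rep, seed=rep_seed,
                shortfall=es.shortfall,
            )
            rows.append(row)
    records = pd.DataFrame(rows)
    medians = _summary(records, ["omega_max", "n_genes"], "lambda_max")
    slopes = {}
    for om in omega_max_list:
        sub = medians[medians["omega_max"] == om]
        ok = sub["median"] > 0
        fit = linregress(np.log(sub["n_genes"][ok]), np.log(sub["median"][ok]))
        slopes[om] = float(fit.slope)
    return ScalingSweep(records=records, medians=medians, slopes=slopes)


# --------------------------------------------------------------------------
# bipartite critical inhibitory fraction
# --------------------------------------------------------------------------


@dataclass
class PnegSweep:
    records: pd.DataFrame
    medians: pd.DataFrame
    critical_p_neg: float | None


def sweep_pneg_bipartite(
    n_genes: int = 1000,
    q: int = 100,
    rho: float = 0.01,
    omega_max: float = 2.0,
    p_neg_grid: tuple[float, ...] = tuple(np.round(np.arange(0.40, 0.71, 0.05), 2)),
    n_reps: int = 10,
    seed: int = 0,
    h: float = 1.0,
) -> PnegSweep:
    """lambda_M,rmax of strict bipartite networks versus P_neg.

    Uses the rank-1 closed form lambda_M,b = max(lambda_Q,b, 0).  The
    critical P_neg is the smallest grid value whose median lambda
    exceeds 1e-12 (None if the grid never destabilizes).
    """
    if min(p_neg_grid) < 0 or max(p_neg_grid) > 1:
        raise ValueError("p_neg grid must lie in [0, 1]")
    u = int(round(rho * n_genes**2))
    seeds = _derive_seeds(seed, len(p_neg_grid) * n_reps)
    rows = []
    for pi, p_neg in enumerate(p_neg_grid):
        for rep in range(n_reps):
            rep_seed = seeds[pi * n_reps + rep]
            net_seed, par_seed, sol_seed = _split_seed(rep_seed)
            es = gen_bipartite(n_genes, q, u, p_neg, net_seed)
            row = _measure_lambda(
                es, omega_max, h, par_seed, sol_seed, use_bipartite_form=True
            )
            row.update(
                experiment="pneg_bipartite", n_genes=n_genes, q=q, u=u,
                p_neg=p_neg, omega_max=omega_max, h=h, replicate=rep,
                seed=rep_seed,
            )
            rows.append(row)
    records = pd.DataFrame(rows)
    medians = _summary(records, ["p_neg"], "lambda_max")
    critical = None
    for _, r in medians.iterrows():
        if r["median"] > LAMBDA_ZERO_TOL:
            critical = float(r["p_neg"])
            break
    return PnegSweep(records=records, medians=medians, critical_p_neg=critical)


# --------------------------------------------------------------------------
# scrambling schemes: P(stable) versus Omega_max
# --------------------------------------------------------------------------


def _scheme_topology(
    scheme: str,
    comp: NetworkComposition,
    net_seed: int,
    edge_set: EdgeSet | None,
) -> EdgeSet:
    n, q, u = comp.n_genes, comp.n_tfs, comp.n_edges
    if scheme == "as_given":
        if edge_set is None:
            raise ValueError("scheme 'as_given' needs an explicit edge_set")
        return edge_set
    if scheme == "random_u":
        p_neg = (u - comp.n_activating) / u
        return gen_random(n, u / n**2, p_neg, net_seed)
    if scheme == "fixed_q":
        return scramble_fixed_q(n, q, u, comp.n_activating, net_seed)
    if scheme == "composition":
        return scramble_composition(comp, net_seed)
    raise ValueError(f"unknown scramble scheme {scheme!r}")


@dataclass
class StabilitySweep:
    records: pd.DataFrame
    p_stable: pd.DataFrame
    summary: pd.DataFrame


def sweep_stability(
    base: NetworkComposition,
    scheme: str,
    omega_max_list: tuple[float, ...],
    n_sets: int = 15,
    n_per_set: int = 10,
    h: float = 2.0,
    seed: int = 0,
    edge_set: EdgeSet | None = None,
    max_iter: int = 100_000,
) -> StabilitySweep:
    """P(stable) versus Omega_max for one scrambling scheme.

    Scheme "as_given" evaluates a supplied empirical edge set (only the
    quantitative parameters are re-drawn); "random_u" keeps the edge and
    activation counts; "fixed_q" additionally keeps the TF count;
    "composition" keeps the full category census.  P(stable) is the
    fraction of stable replicates within each of ``n_sets`` sets of
    ``n_per_set`` networks; the summary reports median and IQR over
    sets, mirroring the nested-ensemble statistic of the topology
    experiments.
    """
    base.validate()
    grid = [(om, s) for om in omega_max_list for s in range(n_sets)]
    seeds = _derive_seeds(seed, len(grid) * n_per_set)
    rows = []
    for gi, (om, set_idx) in enumerate(grid):
        for rep in range(n_per_set):
            rep_seed = seeds[gi * n_per_set + rep]
            net_seed, par_seed, sol_seed = _split_seed(rep_seed)
            es = _scheme_topology(scheme, base, net_seed, edge_set)
            row = _measure_lambda(es, om, h, par_seed, sol_seed, max_iter=max_iter)
            row.update(
                experiment="stability_scramble", scheme=scheme,
                n_genes=base.n_genes, q=base.n_tfs, u=base.n_edges,
                omega_max=om, h=h, set_index=set_idx, replicate=rep,
                seed=rep_seed,
            )
            rows.append(row)
    records = pd.DataFrame(rows)
    p_stable = (
        records.groupby(["omega_max", "set_index"])["stable"]
        .mean()
        .rename("p_stable")
        .reset_index()
    )
    summary = (
        p_stable.groupby("omega_max")["p_stable"]
        .agg(median="median", q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return StabilitySweep(records=records, p_stable=p_stable, summary=summary)


# --------------------------------------------------------------------------
# TF->otherTF density sweep
# --------------------------------------------------------------------------


def scaled_composition(
    comp: NetworkComposition, n_genes: int, q: int | None = None
) -> NetworkComposition:
    """Composition with all category counts scaled to a smaller network.

    Counts (and the TF number, unless given) are scaled by
    ``n_genes / comp.n_genes`` and rounded; used for desk-scale versions
    of the empirical-composition experiments.
    """
    s = n_genes / comp.n_genes
    if q is None:
        q = max(2, int(round(comp.n_tfs * s)))
    scaled = NetworkComposition(
        n_genes=n_genes,
        n_tfs=q,
        n_self=int(round(comp.n_self * s)),
        n_self_activating=int(round(comp.n_self_activating * s)),
        n_tf_tf=int(round(comp.n_tf_tf * s)),
        n_tf_tf_activating=int(round(comp.n_tf_tf_activating * s)),
        n_tf_nontf=int(round(comp.n_tf_nontf * s)),
        n_tf_nontf_activating=int(round(comp.n_tf_nontf_activating * s)),
    )
    scaled.validate()
    return scaled


@dataclass
class RhoQSweep:
    records: pd.DataFrame
    p_stable: pd.DataFrame
    summary: pd.DataFrame
    skipped: list[float]


def sweep_rho_q(
    n_genes: int,
    q: int,
    rho_q_grid: tuple[float, ...],
    base: NetworkComposition | None = None,
    u_fix: str = "total_u",
    include_self: bool = True,
    omega_max: float = 1000.0,
    h: float = 2.0,
    n_sets: int = 15,
    n_per_set: int = 10,
    seed: int = 0,
    max_iter: int = 100_000,
) -> RhoQSweep:
    """P(stable) versus the TF->otherTF density rho_q.

    At each grid point, u_t = round(rho_q q (q-1)) TF->otherTF edges are
    drawn; self-edges are taken from ``base`` (or dropped when
    ``include_self`` is false) and the TF->nonTF count either absorbs
    the difference (``u_fix="total_u"``: total edge count held fixed) or
    stays at the base value (``u_fix="u_n"``).  Up- and downregulation
    are equally likely in every category.  Infeasible grid points are
    skipped and reported.
    """
    if base is None:
        from .networks import ECOLI_COMPOSITION

        base = scaled_composition(ECOLI_COMPOSITION, n_genes, q=q)
    if u_fix not in ("total_u", "u_n"):
        raise ValueError("u_fix must be 'total_u' or 'u_n'")
    u_s = base.n_self if include_self else 0
    rows = []
    skipped: list[float] = []
    feasible: list[tuple[float, NetworkComposition]] = []
    for rho_q in rho_q_grid:
        u_t = int(round(rho_q * q * (q - 1)))
        if u_fix == "total_u":
            u_n = base.n_edges - u_s - u_t
        else:
            u_n = base.n_tf_nontf
        if u_t > q * (q - 1) or u_n < 0 or u_n > q * (n_genes - q):
            skipped.append(float(rho_q))
            continue
        comp = NetworkComposition(
            n_genes=n_genes, n_tfs=q,
            n_self=u_s, n_self_activating=u_s // 2,
            n_tf_tf=u_t, n_tf_tf_activating=u_t // 2,
            n_tf_nontf=u_n, n_tf_nontf_activating=u_n // 2,
        )
        feasible.append((float(rho_q), comp))
    grid = [(rq, comp, s) for rq, comp in feasible for s in range(n_sets)]
    seeds = _derive_seeds(seed, len(grid) * n_per_set)
    for gi, (rho_q, comp, set_idx) in enumerate(grid):
        for rep in range(n_per_set):
            rep_seed = seeds[gi * n_per_set + rep]
            net_seed, par_seed, sol_seed = _split_seed(rep_seed)
            es = scramble_composition(comp, net_seed)
            row = _measure_lambda(es, omega_max, h, par_seed, sol_seed,
                                  max_iter=max_iter)
            row.update(
                experiment="rho_q", n_genes=n_genes, q=q, rho_q=rho_q,
                u_t=comp.n_tf_tf, u_n=comp.n_tf_nontf, u_s=u_s,
                omega_max=omega_max, h=h, set_index=set_idx, replicate=rep,
                seed=rep_seed,
            )
            rows.append(row)
    records = pd.DataFrame(rows)
    p_stable = (
        records.groupby(["rho_q", "set_index"])["stable"]
        .mean()
        .rename("p_stable")
        .reset_index()
    )
    summary = (
        p_stable.groupby("rho_q")["p_stable"]
        .agg(median="median", q25=lambda s: s.quantile(0.25),
             q75=lambda s: s.quantile(0.75))
        .reset_index()
    )
    return RhoQSweep(records=records, p_stable=p_stable, summary=summary,
                     skipped=skipped)
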