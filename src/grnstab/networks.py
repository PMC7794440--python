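"""Signed, directed regulatory-network topologies and their censuses.

A transcriptional regulatory network is a directed graph on ``n_genes``
genes in which every edge runs from a regulator (a transcription factor,
TF) to a target gene and carries a sign: +1 for activation, -1 for
repression.  Two genes are distinguished by convention: the ribosome
(index ``n_genes - 1``) and the RNA polymerase (index ``n_genes - 2``).
Ribosomes are structural and never act as TFs.

This module provides the generators used throughout the package:

* :func:`gen_random` -- fully random topologies at a given density,
* :func:`gen_dag` -- random directed *acyclic* topologies (cycle-creating
  proposals are rejected),
* :func:`gen_bipartite` -- strict TF -> non-TF bipartite topologies,
* :func:`scramble_fixed_q` / :func:`scramble_composition` -- null models
  that randomize an empirical network while preserving, respectively, the
  TF count or the full category composition (self, TF->otherTF,
  TF->nonTF, with per-category activation counts),
* :func:`ecoli_like_fixture` -- a synthetic network with the exact
  interaction composition of the curated *E. coli* transcriptional
  regulatory network (2274 genes, 211 TFs),

together with :func:`census` and plain-text (TSV) edge-list I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "EdgeSet",
    "NetworkComposition",
    "ECOLI_COMPOSITION",
    "CapacityError",
    "EdgeListParseError",
    "gen_random",
    "gen_dag",
    "gen_bipartite",
    "scramble_fixed_q",
    "scramble_composition",
    "ecoli_like_fixture",
    "census",
    "read_edge_list",
    "write_edge_list",
]


class CapacityError(ValueError):
    """Requested more edges than the candidate pool can supply."""


class EdgeListParseError(ValueError):
    """A TSV edge-list file is malformed (the message names the line)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class EdgeSet:
    """Signed directed regulatory topology over ``n_genes`` genes.

    Edges are stored as parallel arrays ``regulators``, ``targets`` and
    ``signs`` (+1 activation, -1 repression).  ``tf_indices`` is the
    ordered set of genes allowed to act as regulators; the ribosome is
    never among them.

    ``shortfall`` is set by :func:`gen_dag` when the proposal budget ran
    out before the requested edge count was reached.
    """

    n_genes: int
    tf_indices: np.ndarray
    ribosome_index: int
    rnap_index: int
    regulators: np.ndarray
    targets: np.ndarray
    signs: np.ndarray
    shortfall: bool = False
    names: list[str] | None = None  # gene names, kept by the edge-list reader

    def __post_init__(self) -> None:
        self.tf_indices = np.asarray(self.tf_indices, dtype=np.int64)
        self.regulators = np.asarray(self.regulators, dtype=np.int64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        self.signs = np.asarray(self.signs, dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return int(self.regulators.size)

    @property
    def n_tfs(self) -> int:
        return int(self.tf_indices.size)

    @property
    def edges(self) -> Iterator[tuple[int, int, int]]:
        """Iterate over (regulator, target, sign) triples."""
        return zip(
            self.regulators.tolist(), self.targets.tolist(), self.signs.tolist()
        )

    def is_tf(self) -> np.ndarray:
        """Boolean membership mask of the TF set, length ``n_genes``."""
        mask = np.zeros(self.n_genes, dtype=bool)
        mask[self.tf_indices] = True
        return mask

    def validate(self) -> None:
        """Raise ``ValueError`` if any structural invariant is violated."""
        n = self.n_genes
        if n <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("regulators", "targets"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} contain indices outside [0, {n})")
        if self.tf_indices.size and (
            self.tf_indices.min() < 0 or self.tf_indices.max() >= n
        ):
            raise ValueError("tf_indices outside [0, n_genes)")
        if not (0 <= self.ribosome_index < n and 0 <= self.rnap_index < n):
            raise ValueError("ribosome/rnap index outside [0, n_genes)")
        if np.any(self.regulators == self.ribosome_index):
            raise ValueError("ribosome appears as a regulator")
        if self.ribosome_index in set(self.tf_indices.tolist()):
            raise ValueError("ribosome listed in tf_indices")
        tf_mask = self.is_tf()
        if self.regulators.size and not tf_mask[self.regulators].all():
            raise ValueError("a regulator is not in tf_indices")
        pair_codes = self.regulators * n + self.targets
        if np.unique(pair_codes).size != pair_codes.size:
            raise ValueError("duplicate (regulator, target) pair")
        if self.signs.size and not np.isin(self.signs, (-1, 1)).all():
            raise ValueError("signs must be +1 or -1")


@dataclass(frozen=True)
class NetworkComposition:
    """Interaction census of a topology, split into three categories.

    ``n_self`` counts autoregulatory edges, ``n_tf_tf`` edges from a TF to
    a *different* TF, and ``n_tf_nontf`` edges from a TF to a non-TF; the
    ``*_activating`` fields count the positive edges in each category.
    ``density`` is u/N^2 and ``tf_tf_density`` is the density of
    TF->otherTF edges, u_t / (q (q - 1)) (zero when fewer than 2 TFs).
    """

    n_genes: int
    n_tfs: int
    n_self: int
    n_self_activating: int
    n_tf_tf: int
    n_tf_tf_activating: int
    n_tf_nontf: int
    n_tf_nontf_activating: int

    @property
    def n_edges(self) -> int:
        return self.n_self + self.n_tf_tf + self.n_tf_nontf

    @property
    def n_activating(self) -> int:
        return (
            self.n_self_activating
            + self.n_tf_tf_activating
            + self.n_tf_nontf_activating
        )

    @property
    def density(self) -> float:
        return self.n_edges / self.n_genes**2

    @property
    def tf_tf_density(self) -> float:
        q = self.n_tfs
        return self.n_tf_tf / (q * (q - 1)) if q >= 2 else 0.0

    def validate(self) -> None:
        if not (0 < self.n_tfs < self.n_genes):
            raise ValueError("need 0 < n_tfs < n_genes")
        for cat, pos in (
            (self.n_self, self.n_self_activating),
            (self.n_tf_tf, self.n_tf_tf_activating),
            (self.n_tf_nontf, self.n_tf_nontf_activating),
        ):
            if cat < 0 or not (0 <= pos <= cat):
                raise ValueError("category counts inconsistent")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "NetworkComposition":
        return cls(**json.loads(Path(path).read_text()))


#: Interaction composition of the curated E. coli transcriptional
#: regulatory network: 211 TFs regulating 2274 genes; 134 self-regulations
#: (42 activating), 373 TF->otherTF edges (201 activating) and 5148
#: TF->nonTF edges (2944 activating).  The three category counts sum to
#: 5655 and are taken as authoritative.
ECOLI_COMPOSITION = NetworkComposition(
    n_genes=2274,
    n_tfs=211,
    n_self=134,
    n_self_activating=42,
    n_tf_tf=373,
    n_tf_tf_activating=201,
    n_tf_nontf=5148,
    n_tf_nontf_activating=2944,
)


# --------------------------------------------------------------------------
# sampling helpers
# --------------------------------------------------------------------------


def _sample_without_replacement(
    rng: np.random.Generator, pool_size: int, k: int
) -> np.ndarray:
    """Draw ``k`` distinct integers uniformly from ``range(pool_size)``."""
    if k > pool_size:
        raise CapacityError(
            f"requested {k} distinct edges from a pool of {pool_size}"
        )
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k > pool_size // 3:
        return rng.permutation(pool_size)[:k].astype(np.int64)
    # sparse regime: rejection on collisions, vectorized
    chosen = np.empty(0, dtype=np.int64)
    while chosen.size < k:
        need = k - chosen.size
        draw = rng.integers(0, pool_size, size=need + max(16, need // 4))
        merged = np.concatenate([chosen, draw])
        _, first = np.unique(merged, return_index=True)
        merged = merged[np.sort(first)]  # keep first-draw order
        chosen = merged[:k] if merged.size >= k else merged
    return chosen


def _exact_signs(rng: np.random.Generator, n_edges: int, n_neg: int) -> np.ndarray:
    """Sign vector with exactly ``n_neg`` entries equal to -1, shuffled."""
    signs = np.ones(n_edges, dtype=np.int64)
    signs[:n_neg] = -1
    rng.shuffle(signs)
    return signs


def _n_negative(p_neg: float, n_edges: int) -> int:
    if not 0.0 <= p_neg <= 1.0:
        raise ValueError(f"p_neg must lie in [0, 1], got {p_neg}")
    return int(round(p_neg * n_edges))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def gen_random(
    n_genes: int,
    rho: float,
    p_neg: float,
    seed: int,
    *,
    allow_self_loops: bool = False,
) -> EdgeSet:
    """Fully random topology with ``round(rho * n_genes**2)`` edges.

    Edges are sampled uniformly without replacement from all ordered
    (regulator, target) pairs with the ribosome excluded as regulator and
    (by default) self-loops excluded, so the pool has (N-1)^2 entries.
    With ``allow_self_loops=True`` the pool is the N(N-1) pairs with only
    the ribosome constraint.  Exactly ``round(p_neg * u)`` edges are
    repressing.  Every non-ribosome gene counts as a TF.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_genes
    rib, rnap = n - 1, n - 2
    u = int(round(rho * n * n))
    if allow_self_loops:
        pool = n * (n - 1)  # regulator != ribosome, any target
        flat = _sample_without_replacement(rng, pool, u)
        regulators, targets = flat // n, flat % n
    else:
        pool = (n - 1) * (n - 1)
        flat = _sample_without_replacement(rng, pool, u)
        regulators, t = flat // (n - 1), flat % (n - 1)
        targets = np.where(t < regulators, t, t + 1)
    signs = _exact_signs(rng, u, _n_negative(p_neg, u))
    es = EdgeSet(
        n_genes=n,
        tf_indices=np.arange(n - 1),
        ribosome_index=rib,
        rnap_index=rnap,
        regulators=regulators,
        targets=targets,
        signs=signs,
    )
    es.validate()
    return es


def gen_dag(
    n_genes: int,
    rho: float,
    p_neg: float,
    seed: int,
    max_attempts: int | None = None,
) -> EdgeSet:
    """Random directed acyclic topology.

    Proposals are drawn as in :func:`gen_random` (self-loops excluded);
    a proposal is rejected if it duplicates an existing edge or if adding
    it would close a directed cycle (2-cycles included).  If
    ``max_attempts`` proposals (default ``200 * u``) are exhausted before
    the target count is reached, the partial result is returned with
    ``shortfall=True``.
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_genes
    u_target = int(round(rho * n * n))
    pool = (n - 1) * (n - 1)
    if u_target > pool:
        raise CapacityError(
            f"requested {u_target} distinct edges from a pool of {pool}"
        )
    if max_attempts is None:
        max_attempts = 200 * max(u_target, 1)

    succ: list[list[int]] = [[] for _ in range(n)]
    taken: set[int] = set()
    regulators: list[int] = []
    targets: list[int] = []
    # reusable DFS scratch: "visited at stamp" trick avoids reallocation
    stamp = np.zeros(n, dtype=np.int64)
    cur = 0

    def reaches(src: int, dst: int) -> bool:
        nonlocal cur
        cur += 1
        stack = [src]
        stamp[src] = cur
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            for w in succ[v]:
                if stamp[w] != cur:
                    stamp[w] = cur
                    stack.append(w)
        return False

    attempts = 0
    while len(regulators) < u_target and attempts < max_attempts:
        attempts += 1
        flat = int(rng.integers(0, pool))
        reg, t = flat // (n - 1), flat % (n - 1)
        tgt = t if t < reg else t + 1
        if flat in taken or reaches(tgt, reg):
            continue
        taken.add(flat)
        succ[reg].append(tgt)
        regulators.append(reg)
        targets.append(tgt)

    u = len(regulators)
    signs = _exact_signs(rng, u, _n_negative(p_neg, u))
    es = EdgeSet(
        n_genes=n,
        tf_indices=np.arange(n - 1),
        ribosome_index=n - 1,
        rnap_index=n - 2,
        regulators=np.array(regulators, dtype=np.int64),
        targets=np.array(targets, dtype=np.int64),
        signs=signs,
        shortfall=u < u_target,
    )
    es.validate()
    return es


def gen_bipartite(
    n_genes: int,
    q: int | None,
    u: int,
    p_neg: float,
    seed: int,
) -> EdgeSet:
    """Strict bipartite topology: every edge runs TF -> non-TF.

    The first ``q`` gene indices are the TFs (default ``q = 0.1 * N``);
    the ribosome and RNA polymerase sit among the non-TFs.  ``u`` distinct
    edges are drawn uniformly from the q(N - q) admissible pairs, with
    exactly ``round(p_neg * u)`` repressing.
    """
    n = n_genes
    if q is None:
        q = int(round(0.1 * n))
    if not 0 < q < n - 1:
        raise ValueError("need 0 < q < n_genes - 1 (ribosome/RNAP are non-TF)")
    rng = np.random.default_rng(seed)
    pool = q * (n - q)
    flat = _sample_without_replacement(rng, pool, u)
    regulators = flat // (n - q)
    targets = q + flat % (n - q)
    signs = _exact_signs(rng, u, _n_negative(p_neg, u))
    es = EdgeSet(
        n_genes=n,
        tf_indices=np.arange(q),
        ribosome_index=n - 1,
        rnap_index=n - 2,
        regulators=regulators,
        targets=targets,
        signs=signs,
    )
    es.validate()
    return es


def scramble_fixed_q(
    n_genes: int, q: int, u: int, u_pos: int, seed: int
) -> EdgeSet:
    """Randomize a network keeping the TF count fixed.

    ``u`` distinct edges are drawn uniformly from the q*N ordered pairs
    whose regulator lies in the first ``q`` indices (self-pairs allowed),
    and exactly ``u_pos`` of them are activating.
    """
    n = n_genes
    if not 0 < q < n - 1:
        raise ValueError("need 0 < q < n_genes - 1")
    if not 0 <= u_pos <= u:
        raise ValueError("u_pos must lie in [0, u]")
    rng = np.random.default_rng(seed)
    flat = _sample_without_replacement(rng, q * n, u)
    regulators, targets = flat // n, flat % n
    signs = -_exact_signs(rng, u, u_pos)  # exactly u_pos entries +1
    es = EdgeSet(
        n_genes=n,
        tf_indices=np.arange(q),
        ribosome_index=n - 1,
        rnap_index=n - 2,
        regulators=regulators,
        targets=targets,
        signs=signs,
    )
    es.validate()
    return es


def scramble_composition(comp: NetworkComposition, seed: int) -> EdgeSet:
    """Randomize a network keeping its full interaction composition.

    Within each category -- self, TF->otherTF, TF->nonTF -- the requested
    number of (regulator, target) pairs is drawn uniformly without
    replacement from that category's candidate pool, and the category's
    activating count is preserved exactly.  TFs are the first ``q``
    indices.
    """
    comp.validate()
    n, q = comp.n_genes, comp.n_tfs
    rng = np.random.default_rng(seed)

    regs: list[np.ndarray] = []
    tgts: list[np.ndarray] = []
    signs: list[np.ndarray] = []

    # self-regulations: pool of q diagonal pairs
    flat = _sample_without_replacement(rng, q, comp.n_self)
    regs.append(flat)
    tgts.append(flat)
    signs.append(-_exact_signs(rng, comp.n_self, comp.n_self_activating))

    # TF -> other TF: pool of q(q-1) off-diagonal TF pairs
    flat = _sample_without_replacement(rng, q * (q - 1), comp.n_tf_tf)
    r, t = flat // (q - 1), flat % (q - 1)
    regs.append(r)
    tgts.append(np.where(t < r, t, t + 1))
    signs.append(-_exact_signs(rng, comp.n_tf_tf, comp.n_tf_tf_activating))

    # TF -> non-TF: pool of q(N-q) pairs
    flat = _sample_without_replacement(rng, q * (n - q), comp.n_tf_nontf)
    regs.append(flat // (n - q))
    tgts.append(q + flat % (n - q))
    signs.append(
        -_exact_signs(rng, comp.n_tf_nontf, comp.n_tf_nontf_activating)
    )

    es = EdgeSet(
        n_genes=n,
        tf_indices=np.arange(q),
        ribosome_index=n - 1,
        rnap_index=n - 2,
        regulators=np.concatenate(regs),
        targets=np.concatenate(tgts),
        signs=np.concatenate(signs),
    )
    es.validate()
    return es


def ecoli_like_fixture(seed: int) -> EdgeSet:
    """Synthetic network with the *E. coli* interaction composition.

    A composition-preserving scramble of :data:`ECOLI_COMPOSITION`:
    same gene and TF counts and the same per-category edge and activation
    counts as the curated network, with the individual pairs re-drawn at
    random.  Deterministic for a given ``seed``.
    """
    return scramble_composition(ECOLI_COMPOSITION, seed)


# --------------------------------------------------------------------------
# census
# --------------------------------------------------------------------------


def census(es: EdgeSet) -> NetworkComposition:
    """Exact interaction census of an edge set by category and sign."""
    tf_mask = es.is_tf()
    pos = es.signs > 0
    is_self = es.regulators == es.targets
    is_tf_tf = ~is_self & tf_mask[es.targets]
    is_tf_non = ~is_self & ~tf_mask[es.targets]
    return NetworkComposition(
        n_genes=es.n_genes,
        n_tfs=es.n_tfs,
        n_self=int(is_self.sum()),
        n_self_activating=int((is_self & pos).sum()),
        n_tf_tf=int(is_tf_tf.sum()),
        n_tf_tf_activating=int((is_tf_tf & pos).sum()),
        n_tf_nontf=int(is_tf_non.sum()),
        n_tf_nontf_activating=int((is_tf_non & pos).sum()),
    )


# --------------------------------------------------------------------------
# edge-list I/O
# --------------------------------------------------------------------------

_SIGN_TOKENS = {
    "+": 1,
    "1": 1,
    "+1": 1,
    "activation": 1,
    "-": -1,
    "−": -1,  # unicode minus
    "-1": -1,
    "−1": -1,
    "repression": -1,
}


def read_edge_list(path: str | Path) -> EdgeSet:
    """Load a TSV edge list (columns regulator, target, sign; with header).

    Gene names are mapped to dense 0-based indices in order of first
    appearance; the TF set is the set of observed regulators.  The
    ribosome index is assigned to the highest-index gene that never acts
    as a regulator (the RNA polymerase to the next such gene, falling
    back to any other index).
    """
    path = Path(path)
    index: dict[str, int] = {}
    regulators: list[int] = []
    targets: list[int] = []
    signs: list[int] = []
    seen_pairs: set[tuple[int, int]] = set()

    def idx(name: str) -> int:
        if name not in index:
            index[name] = len(index)
        return index[name]

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1 or not line.strip():
                continue  # header / blank
            parts = line.split("\t")
            if len(parts) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            reg_name, tgt_name, sign_tok = (p.strip() for p in parts[:3])
            if not reg_name or not tgt_name:
                raise EdgeListParseError(f"{path}:{lineno}: empty gene name")
            sign = _SIGN_TOKENS.get(sign_tok.lower())
            if sign is None:
                raise EdgeListParseError(
                    f"{path}:{lineno}: unknown sign token {sign_tok!r}"
                )
            r, t = idx(reg_name), idx(tgt_name)
            if (r, t) in seen_pairs:
                raise EdgeListParseError(
                    f"{path}:{lineno}: duplicate edge {reg_name} -> {tgt_name}"
                )
            seen_pairs.add((r, t))
            regulators.append(r)
            targets.append(t)
            signs.append(sign)

    n = len(index)
    if n == 0:
        raise EdgeListParseError(f"{path}: no edges found")
    reg_set = set(regulators)
    non_regs = [i for i in range(n - 1, -1, -1) if i not in reg_set]
    if not non_regs:
        raise EdgeListParseError(
            f"{path}: every gene acts as a regulator; no ribosome candidate"
        )
    ribosome = non_regs[0]
    rnap = non_regs[1] if len(non_regs) > 1 else next(
        i for i in range(n - 1, -1, -1) if i != ribosome
    )
    es = EdgeSet(
        n_genes=n,
        tf_indices=np.array(sorted(reg_set), dtype=np.int64),
        ribosome_index=ribosome,
        rnap_index=rnap,
        regulators=np.array(regulators, dtype=np.int64),
        targets=np.array(targets, dtype=np.int64),
        signs=np.array(signs, dtype=np.int64),
        names=list(index),
    )
    es.validate()
    return es


def write_edge_list(
    es: EdgeSet, path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write an edge set as a TSV edge list (round-trips with the reader
    up to the reader's first-appearance index relabeling)."""
    if names is None and es.names is not None:
        names = es.names
    if names is None:
        width = len(str(es.n_genes - 1))
        names = [f"g{i:0{width}d}" for i in range(es.n_genes)]
    with Path(path).open("w") as fh:
        fh.write("regulator\ttarget\tsign\n")
        for r, t, s in es.edges:
            fh.write(f"{names[r]}\t{names[t]}\t{'+' if s > 0 else '-'}\n")
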