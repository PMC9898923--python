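"""Score-based and tree structure learning for binary networks.

Two learners are provided:

* greedy hill climbing over add/delete/reverse single-edge moves maximising
  the BIC score (decomposable per node family), optionally constrained so a
  designated *root* node receives no incoming edges;
* a Chow-Liu tree: maximum spanning tree on pairwise mutual information,
  oriented away from the root.

Both are fully deterministic for fixed data: candidate moves are enumerated
in canonical (natural) node order and exact score ties prefer the earlier
move / no move at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._util import natural_key
from .bayesnet import DAG, _as_binary

logger = logging.getLogger(__name__)

_EPS = 1e-9  # score improvements below this count as ties -> no-op


def _xlogx(c: np.ndarray) -> np.ndarray:
    out = np.zeros_like(c, dtype=float)
    nz = c > 0
    out[nz] = c[nz] * np.log(c[nz])
    return out


@dataclass
class _Scorer:
    """Cached family-wise BIC scorer over a fixed binary data matrix."""

    x: np.ndarray  # (n, k) int8
    names: tuple[str, ...]
    n: int = 0

    def __post_init__(self) -> None:
        self.n = len(self.x)
        self._col = {name: j for j, name in enumerate(self.names)}
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}
        self._penalty_unit = math.log(self.n) / 2.0 if self.n else 0.0

    def family(self, node: str, parents: tuple[str, ...]) -> float:
        parents = tuple(sorted(parents, key=natural_key))
        key = (node, parents)
        if key in self._cache:
            return self._cache[key]
        k = len(parents)
        idx = np.zeros(self.n, dtype=np.int64)
        for j, p in enumerate(parents):
            idx += self.x[:, self._col[p]].astype(np.int64) << j
        n_cfg = np.bincount(idx, minlength=2**k).astype(float)
        n_one = np.bincount(
            idx, weights=self.x[:, self._col[node]].astype(float), minlength=2**k
        )
        n_zero = n_cfg - n_one
        ll = float(_xlogx(n_one).sum() + _xlogx(n_zero).sum() - _xlogx(n_cfg).sum())
        score = ll - self._penalty_unit * (2**k)
        self._cache[key] = score
        return score


def bic_score(dag: DAG, data) -> float:
    """BIC of a DAG: sum of maximized family log-likelihoods minus
    (log n / 2) * 2^|parents| per (binary) node.  Higher is better."""
    names, x = _as_binary(data)
    scorer = _Scorer(x=x, names=names)
    missing = [n for n in dag.nodes if n not in names]
    if missing:
        raise ValueError(f"data lacks columns for nodes: {missing}")
    return sum(scorer.family(node, dag.parents(node)) for node in dag.nodes)


def _constant_columns(names: tuple[str, ...], x: np.ndarray) -> set[str]:
    if not len(x):
        return set()
    const = {name for j, name in enumerate(names) if len(np.unique(x[:, j])) < 2}
    for name in sorted(const, key=natural_key):
        logger.warning("column %r is constant; leaving node isolated", name)
    return const


def learn_structure_hc(
    data,
    root: str | None = None,
    max_parents: int = 4,
    restarts: int = 0,
    seed: int = 0,
    tabu_length: int = 10,
    max_worsening_moves: int = 10,
) -> DAG:
    """BIC hill climbing from the empty graph with a tabu escape phase.

    Moves are single-edge additions, deletions and reversals; edges into
    ``root`` are forbidden when a root is given.  The search is greedy
    until no improving move exists, then takes up to
    ``max_worsening_moves`` best non-improving moves (never revisiting the
    last ``tabu_length`` graphs) to escape shallow local optima such as a
    mis-oriented collider; the best-scoring graph visited is returned.
    This phase needs no randomness, so the search is fully deterministic
    for fixed data.  ``restarts`` extra runs start from random DAGs drawn
    with the seeded generator; the best-scoring result wins (ties prefer
    the earlier run), so the learner is deterministic for fixed seed.
    """
    names, x = _as_binary(data)
    if len(names) < 2:
        raise ValueError("need at least two columns")
    if len(x) < 10:
        raise ValueError("need at least 10 rows")
    if root is not None and root not in names:
        raise ValueError(f"root {root!r} is not a data column")
    scorer = _Scorer(x=x, names=names)
    frozen = _constant_columns(names, x)
    ordered = sorted(names, key=natural_key)

    def climb(start: DAG) -> tuple[DAG, float]:
        dag = start.copy()
        total = sum(scorer.family(n, dag.parents(n)) for n in dag.nodes)
        best_dag, best_total = dag.copy(), total
        tabu: list[frozenset] = [frozenset(dag.edges)]
        worsening = 0
        for _ in range(10_000):
            best_delta: float | None = None
            best_move = None

            def consider(delta: float, move, new_edges) -> None:
                nonlocal best_delta, best_move
                if frozenset(new_edges) in tabu:
                    return
                if best_delta is None or delta > best_delta + _EPS:
                    best_delta, best_move = delta, move

            edge_set = set(dag.edges)
            # additions
            for u in ordered:
                for v in ordered:
                    if u == v or u in frozen or v in frozen or v == root:
                        continue
                    if (u, v) in edge_set or (v, u) in edge_set:
                        continue
                    pv = dag.parents(v)
                    if len(pv) >= max_parents:
                        continue
                    if _has_path(dag, v, u):
                        continue
                    delta = scorer.family(v, pv + (u,)) - scorer.family(v, pv)
                    consider(delta, ("add", u, v), edge_set | {(u, v)})
            # deletions
            for u, v in dag.edges:
                pv = dag.parents(v)
                delta = scorer.family(v, tuple(p for p in pv if p != u)) - scorer.family(v, pv)
                consider(delta, ("del", u, v), edge_set - {(u, v)})
            # reversals
            for u, v in dag.edges:
                if u == root:
                    continue
                pu, pv = dag.parents(u), dag.parents(v)
                if len(pu) >= max_parents:
                    continue
                trial = dag.copy()
                trial.remove_edge(u, v)
                if _has_path(trial, u, v):
                    continue
                delta = (
                    scorer.family(v, tuple(p for p in pv if p != u))
                    + scorer.family(u, pu + (v,))
                    - scorer.family(v, pv)
                    - scorer.family(u, pu)
                )
                consider(delta, ("rev", u, v), (edge_set - {(u, v)}) | {(v, u)})

            if best_move is None:
                break
            kind, u, v = best_move
            if kind == "add":
                dag.add_edge(u, v)
            elif kind == "del":
                dag.remove_edge(u, v)
            else:
                dag.reverse_edge(u, v)
            total += best_delta
            tabu.append(frozenset(dag.edges))
            if len(tabu) > tabu_length:
                tabu.pop(0)
            if total > best_total + _EPS:
                best_dag, best_total = dag.copy(), total
                worsening = 0
            else:
                worsening += 1
                if worsening >= max_worsening_moves:
                    break
        return best_dag, best_total

    empty = DAG(nodes=names)
    best_dag, best_score = climb(empty)
    rng = np.random.default_rng(seed)
    for _ in range(max(0, restarts)):
        start = _random_start(names, root, max_parents, frozen, rng)
        dag, score_val = climb(start)
        if score_val > best_score + _EPS:
            best_dag, best_score = dag, score_val
    return best_dag


def _has_path(dag: DAG, u: str, v: str) -> bool:
    import networkx as nx

    return nx.has_path(dag._g, u, v)


def _random_start(names, root, max_parents, frozen, rng) -> DAG:
    order = list(names)
    rng.shuffle(order)
    dag = DAG(nodes=names)
    for j, v in enumerate(order):
        if v == root or v in frozen:
            continue
        for u in order[:j]:
            if u in frozen or len(dag.parents(v)) >= max_parents:
                continue
            if rng.random() < 0.25:
                dag.add_edge(u, v)
    return dag


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (nats) of two binary vectors; 0*log 0 == 0."""
    n = len(x)
    if n == 0:
        return 0.0
    joint = np.zeros((2, 2), dtype=float)
    for a in (0, 1):
        for b in (0, 1):
            joint[a, b] = np.count_nonzero((x == a) & (y == b))
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for a in (0, 1):
        for b in (0, 1):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (px[a] * py[b]))
    return mi


def learn_structure_chowliu(data, root: str) -> DAG:
    """Chow-Liu tree: maximum spanning tree on pairwise mutual information,
    edges oriented away from ``root``.  Ties break on canonical edge order,
    so the result is deterministic for fixed data."""
    names, x = _as_binary(data)
    if len(names) < 2:
        raise ValueError("need at least two columns")
    if root not in names:
        raise ValueError(f"root {root!r} is not a data column")
    _constant_columns(names, x)
    ordered = sorted(names, key=natural_key)
    col = {name: j for j, name in enumerate(names)}
    weighted = []
    for i, u in enumerate(ordered):
        for v in ordered[i + 1 :]:
            weighted.append((mutual_information(x[:, col[u]], x[:, col[v]]), u, v))
    weighted.sort(key=lambda t: (-t[0], natural_key(t[1]), natural_key(t[2])))

    parent_uf = {n: n for n in ordered}

    def find(a: str) -> str:
        while parent_uf[a] != a:
            parent_uf[a] = parent_uf[parent_uf[a]]
            a = parent_uf[a]
        return a

    chosen: list[tuple[str, str]] = []
    for _, u, v in weighted:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent_uf[ru] = rv
            chosen.append((u, v))
        if len(chosen) == len(ordered) - 1:
            break

    adj: dict[str, list[str]] = {n: [] for n in ordered}
    for u, v in chosen:
        adj[u].append(v)
        adj[v].append(u)
    dag = DAG(nodes=ordered)
    seen = {root}
    queue = [root]
    while queue:
        u = queue.pop(0)
        for v in sorted(adj[u], key=natural_key):
            if v not in seen:
                dag.add_edge(u, v)
                seen.add(v)
                queue.append(v)
    return dag
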