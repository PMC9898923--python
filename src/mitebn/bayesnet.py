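"""Discrete (binary) Bayesian networks: DAG, CPTs, sampling, d-separation.

A network is a DAG over component names plus one conditional probability
table (CPT) per node giving P(node=1 | parent configuration).  The joint
distribution factorizes as the product of these conditionals.  Parent
configurations are encoded as bit indices with the *first* parent (in the
CPT's parent order) as the least significant bit; CPT parent order is
always the natural (catalog) order, which makes serialization and all
tie-breaks deterministic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._util import natural_key

logger = logging.getLogger(__name__)

NET_FORMAT = "mitebn-net"
NET_VERSION = 1


class CycleError(ValueError):
    """Raised when a mutation would create a directed cycle."""


class DAG:
    """Directed acyclic graph with acyclicity checked on every mutation."""

    __slots__ = ("_g",)

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._g = nx.DiGraph()
        for n in nodes:
            self._g.add_node(str(n))
        for u, v in edges:
            self.add_edge(u, v)

    # -- structure ---------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes, key=natural_key))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            sorted(self._g.edges, key=lambda e: (natural_key(e[0]), natural_key(e[1])))
        )

    def add_node(self, node: str) -> None:
        self._g.add_node(str(node))

    def add_edge(self, u: str, v: str) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop {u!r}")
        if self._g.has_edge(u, v):
            raise ValueError(f"duplicate edge {u!r}->{v!r}")
        if u in self._g and v in self._g and nx.has_path(self._g, v, u):
            raise CycleError(f"edge {u!r}->{v!r} would create a cycle")
        self._g.add_edge(u, v)

    def remove_edge(self, u: str, v: str) -> None:
        self._g.remove_edge(u, v)

    def reverse_edge(self, u: str, v: str) -> None:
        self._g.remove_edge(u, v)
        try:
            self.add_edge(v, u)
        except CycleError:
            self._g.add_edge(u, v)
            raise

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._g.predecessors(node), key=natural_key))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._g.successors(node), key=natural_key))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._g, key=natural_key))

    def copy(self) -> "DAG":
        other = DAG()
        other._g = self._g.copy()
        return other

    def skeleton(self) -> frozenset[frozenset[str]]:
        """Undirected edge set, for structure-recovery comparisons."""
        return frozenset(frozenset(e) for e in self._g.edges)

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __eq__(self, other: object) -> bool:
        return isinstance(other, DAG) and self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:  # pragma: no cover
        return f"DAG(nodes={len(self._g)}, edges={self._g.number_of_edges()})"


@dataclass(frozen=True)
class TriplePattern:
    """A classified three-node pattern: chain X->Y->Z, fork X<-Y->Z or
    collider X->Y<-Z."""

    x: str
    y: str
    z: str
    kind: str  # "chain" | "fork" | "collider"


def classify_triples(dag: DAG) -> list[TriplePattern]:
    """Classify every node triple carrying exactly two adjacent edges.

    Triples with 0, 1 or 3 internal edges are omitted.  For forks and
    colliders the interchangeable endpoints are reported in natural order;
    chains are reported tail-to-head.
    """
    out: list[TriplePattern] = []
    edge_set = set(dag.edges)
    for a, b, c in combinations(dag.nodes, 3):
        es = [(u, v) for u, v in permutations((a, b, c), 2) if (u, v) in edge_set]
        if len(es) != 2:
            continue
        (u1, v1), (u2, v2) = es
        if v1 == v2:
            x, z = sorted((u1, u2), key=natural_key)
            out.append(TriplePattern(x, v1, z, "collider"))
        elif u1 == u2:
            x, z = sorted((v1, v2), key=natural_key)
            out.append(TriplePattern(x, u1, z, "fork"))
        elif v1 == u2:
            out.append(TriplePattern(u1, v1, v2, "chain"))
        else:  # v2 == u1
            out.append(TriplePattern(u2, v2, v1, "chain"))
    return out


@dataclass
class CPT:
    """P(node=1 | parent configuration), one entry per configuration.

    ``p1[i]`` is the probability for the configuration whose bit ``j``
    (LSB = first parent) is the value of ``parents[j]``.  Entries may be
    NaN to mark *undefined* (maximum-likelihood fit on an unobserved
    configuration); such entries are rejected at query time, never
    silently treated as 0.
    """

    node: str
    parents: tuple[str, ...]
    p1: np.ndarray

    def __post_init__(self) -> None:
        self.parents = tuple(str(p) for p in self.parents)
        self.p1 = np.asarray(self.p1, dtype=float).reshape(-1)
        if len(self.p1) != 2 ** len(self.parents):
            raise ValueError(
                f"CPT for {self.node!r}: expected {2 ** len(self.parents)} entries, "
                f"got {len(self.p1)}"
            )
        finite = self.p1[~np.isnan(self.p1)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError(f"CPT for {self.node!r}: probabilities outside [0,1]")

    def cfg_index(self, cfg: Sequence[int]) -> int:
        return int(sum(int(b) << j for j, b in enumerate(cfg)))

    def prob(self, value: int, cfg: Sequence[int] = ()) -> float:
        p = float(self.p1[self.cfg_index(cfg)])
        if math.isnan(p):
            raise ValueError(f"undefined CPT entry for {self.node!r} at configuration {tuple(cfg)}")
        return p if value == 1 else 1.0 - p

    def table_shape(self) -> np.ndarray:
        """CPT as an array of shape (2,)*n_parents, axis j = parents[j]."""
        return self.p1.reshape((2,) * len(self.parents), order="F") if self.parents else self.p1


@dataclass
class BayesNet:
    """A DAG plus one CPT per node (parent sets consistent with the DAG)."""

    dag: DAG
    cpts: dict[str, CPT] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for node in self.dag.nodes:
            cpt = self.cpts.get(node)
            if cpt is None:
                raise ValueError(f"missing CPT for node {node!r}")
            if tuple(sorted(cpt.parents, key=natural_key)) != self.dag.parents(node):
                raise ValueError(
                    f"CPT parents for {node!r} disagree with DAG: "
                    f"{cpt.parents} vs {self.dag.parents(node)}"
                )
        extra = set(self.cpts) - set(self.dag.nodes)
        if extra:
            raise ValueError(f"CPTs for unknown nodes: {sorted(extra)}")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": NET_FORMAT,
            "version": NET_VERSION,
            "nodes": list(self.nodes),
            "edges": [list(e) for e in self.dag.edges],
            "cpts": {
                node: {
                    "parents": list(cpt.parents),
                    "p1": [None if math.isnan(p) else float(p) for p in cpt.p1],
                }
                for node, cpt in sorted(self.cpts.items(), key=lambda kv: natural_key(kv[0]))
            },
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "BayesNet":
        if doc.get("format") != NET_FORMAT:
            raise ValueError(f"not a {NET_FORMAT} document")
        if int(doc.get("version", -1)) != NET_VERSION:
            raise ValueError(f"unsupported {NET_FORMAT} version {doc.get('version')!r}")
        dag = DAG(nodes=doc["nodes"], edges=[tuple(e) for e in doc["edges"]])
        cpts = {
            node: CPT(
                node=node,
                parents=tuple(spec["parents"]),
                p1=np.array(
                    [math.nan if p is None else float(p) for p in spec["p1"]], dtype=float
                ),
            )
            for node, spec in doc["cpts"].items()
        }
        return cls(dag=dag, cpts=cpts)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=False) + "\n", encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "BayesNet":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def joint_probability(net: BayesNet, assignment: Mapping[str, int]) -> float:
    """Probability of a full assignment under the factorized joint."""
    missing = set(net.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)}")
    prob = 1.0
    for node in net.nodes:
        cpt = net.cpts[node]
        cfg = [int(assignment[p]) for p in cpt.parents]
        prob *= cpt.prob(int(assignment[node]), cfg)
    return prob


def sample(
    net: BayesNet,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ancestral sampling: n draws from the joint, columns in natural order."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    order = net.dag.topological_order()
    data: dict[str, np.ndarray] = {}
    for node in order:
        cpt = net.cpts[node]
        if cpt.parents:
            idx = np.zeros(n, dtype=np.int64)
            for j, p in enumerate(cpt.parents):
                idx += data[p].astype(np.int64) << j
            p1 = cpt.p1[idx]
        else:
            p1 = np.full(n, cpt.p1[0])
        if np.isnan(p1).any():
            raise ValueError(f"undefined CPT entry hit while sampling {node!r}")
        data[node] = (rng.random(n) < p1).astype(np.int8)
    return pd.DataFrame({node: data[node] for node in net.nodes})


def _as_binary(data) -> tuple[tuple[str, ...], np.ndarray]:
    """Accept a SensitizationMatrix or a 0/1 DataFrame; return names+array."""
    if hasattr(data, "components") and hasattr(data, "values"):
        return tuple(data.components), np.asarray(data.values, dtype=np.int8)
    df = pd.DataFrame(data)
    arr = df.to_numpy()
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("data must be binary 0/1")
    return tuple(str(c) for c in df.columns), arr.astype(np.int8)


def fit_cpds(dag: DAG, data, alpha: float = 1.0) -> BayesNet:
    """Estimate one CPT per node from binary data.

    P(node=1 | cfg) = (count(node=1, cfg) + alpha) / (count(cfg) + 2*alpha).
    With alpha=0 (maximum likelihood) an unobserved configuration yields a
    NaN *undefined* entry rather than 0/0.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    names, x = _as_binary(data)
    col = {name: j for j, name in enumerate(names)}
    missing = [n for n in dag.nodes if n not in col]
    if missing:
        raise ValueError(f"data lacks columns for nodes: {missing}")
    cpts: dict[str, CPT] = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        k = len(parents)
        idx = np.zeros(len(x), dtype=np.int64)
        for j, p in enumerate(parents):
            idx += x[:, col[p]].astype(np.int64) << j
        n_cfg = np.bincount(idx, minlength=2**k).astype(float)
        n_one = np.bincount(idx, weights=x[:, col[node]].astype(float), minlength=2**k)
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = (n_one + alpha) / (n_cfg + 2 * alpha)
        if alpha == 0:
            p1 = np.where(n_cfg > 0, p1, np.nan)
        cpts[node] = CPT(node=node, parents=parents, p1=p1)
    return BayesNet(dag=dag.copy(), cpts=cpts)


def d_separated(
    dag: DAG,
    x: str | Iterable[str],
    z: str | Iterable[str],
    given: Iterable[str] = (),
) -> bool:
    """Standard d-separation of node sets ``x`` and ``z`` given ``given``.

    Implemented as the reachability ("Bayes ball") algorithm: chains and
    forks are blocked by conditioning, colliders are opened by conditioning
    on the collider or any of its descendants.
    """
    xs = {x} if isinstance(x, str) else set(x)
    zs = {z} if isinstance(z, str) else set(z)
    obs = set(given)
    if xs & zs or xs & obs or zs & obs:
        raise ValueError("x, z and conditioning set must be disjoint")
    g = dag._g
    for node in xs | zs | obs:
        if node not in g:
            raise ValueError(f"unknown node {node!r}")

    an_obs = set(obs)
    for o in obs:
        an_obs |= nx.ancestors(g, o)

    visited: set[tuple[str, str]] = set()
    frontier: list[tuple[str, str]] = [(s, "up") for s in xs]
    reachable: set[str] = set()
    while frontier:
        node, direction = frontier.pop()
        if (node, direction) in visited:
            continue
        visited.add((node, direction))
        if node not in obs:
            reachable.add(node)
        if direction == "up" and node not in obs:
            frontier.extend((p, "up") for p in g.predecessors(node))
            frontier.extend((c, "down") for c in g.successors(node))
        elif direction == "down":
            if node not in obs:
                frontier.extend((c, "down") for c in g.successors(node))
            if node in an_obs:
                frontier.extend((p, "up") for p in g.predecessors(node))
    return not (reachable & zs)
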