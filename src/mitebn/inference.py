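"""Exact conditional-probability queries on binary Bayesian networks.

``query`` answers P(target | evidence) by variable elimination with a
min-degree elimination heuristic; ``brute_force_query`` enumerates the full
joint (up to 16 nodes) and serves as the independent reference
implementation.  Zero-probability evidence yields an explicitly *undefined*
result, never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._util import natural_key, round_half_away
from .bayesnet import BayesNet

MAX_BRUTE_FORCE_NODES = 16


@dataclass(frozen=True)
class QueryResult:
    """P(target | evidence) with provenance.

    ``support_count`` is the number of joint states compatible with the
    evidence (the states summed over); ``undefined`` is set when the
    evidence has probability zero, in which case ``probability`` is None.
    """

    probability: float | None
    target: dict[str, int]
    evidence: dict[str, int]
    support_count: int
    undefined: bool = False

    @property
    def percent(self) -> float | None:
        return None if self.probability is None else round_half_away(100.0 * self.probability, 2)

    def to_dict(self) -> dict:
        return {
            "target": dict(self.target),
            "evidence": dict(self.evidence),
            "probability": self.probability,
            "percent": self.percent,
            "support_count": self.support_count,
            "undefined": self.undefined,
        }


@dataclass
class _Factor:
    vars: tuple[str, ...]
    table: np.ndarray  # shape (2,)*len(vars), axis i = vars[i]

    def reduce(self, var: str, value: int) -> "_Factor":
        if var not in self.vars:
            return self
        axis = self.vars.index(var)
        table = np.take(self.table, value, axis=axis)
        return _Factor(tuple(v for v in self.vars if v != var), table)

    def marginalize(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(tuple(v for v in self.vars if v != var), self.table.sum(axis=axis))


def _multiply(f: _Factor, g: _Factor) -> _Factor:
    union = tuple(sorted(set(f.vars) | set(g.vars), key=natural_key))
    return _Factor(union, _expand(f, union) * _expand(g, union))


def _expand(f: _Factor, union: tuple[str, ...]) -> np.ndarray:
    perm = sorted(range(len(f.vars)), key=lambda i: union.index(f.vars[i]))
    table = np.transpose(f.table, perm) if f.vars else f.table
    shape = tuple(2 if v in f.vars else 1 for v in union)
    return table.reshape(shape)


def _cpt_factor(net: BayesNet, node: str) -> _Factor:
    cpt = net.cpts[node]
    if np.isnan(cpt.p1).any():
        raise ValueError(f"undefined CPT entry for node {node!r}; refit with alpha > 0")
    k = len(cpt.parents)
    # axes: parents (in CPT order) then the node itself
    p1 = cpt.p1.reshape((2,) * k, order="F") if k else np.asarray(float(cpt.p1[0]))
    table = np.stack([1.0 - p1, p1], axis=-1)
    f = _Factor(cpt.parents + (cpt.node,), table)
    order = tuple(sorted(f.vars, key=natural_key))
    return _Factor(order, _expand(f, order).reshape((2,) * len(order)))


def _validate(net: BayesNet, target: Mapping[str, int], evidence: Mapping[str, int]) -> None:
    if not target:
        raise ValueError("target must not be empty")
    overlap = set(target) & set(evidence)
    if overlap:
        raise ValueError(f"target and evidence overlap on {sorted(overlap)}")
    unknown = (set(target) | set(evidence)) - set(net.nodes)
    if unknown:
        raise ValueError(f"unknown nodes: {sorted(unknown)}")
    for name, value in list(target.items()) + list(evidence.items()):
        if value not in (0, 1):
            raise ValueError(f"{name!r}={value!r}: values must be 0 or 1")


def query(
    net: BayesNet,
    target: Mapping[str, int],
    evidence: Mapping[str, int] | None = None,
) -> QueryResult:
    """P(target | evidence) by variable elimination.

    Hidden variables are eliminated in min-degree order on the evolving
    factor graph, ties broken by natural name order (deterministic).
    """
    evidence = dict(evidence or {})
    target = dict(target)
    _validate(net, target, evidence)
    support = 2 ** (len(net.nodes) - len(evidence))

    factors = [_cpt_factor(net, node) for node in net.nodes]
    for var, val in evidence.items():
        factors = [f.reduce(var, int(val)) for f in factors]
    hidden = set(net.nodes) - set(target) - set(evidence)

    while hidden:
        degree: dict[str, set[str]] = {h: set() for h in hidden}
        for f in factors:
            for v in f.vars:
                if v in degree:
                    degree[v] |= set(f.vars) - {v}
        var = min(hidden, key=lambda h: (len(degree[h]), natural_key(h)))
        hidden.remove(var)
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        factors = rest + [prod.marginalize(var)]

    result = factors[0]
    for f in factors[1:]:
        result = _multiply(result, f)
    z = float(result.table.sum())
    if z <= 0.0:
        return QueryResult(None, target, evidence, support, undefined=True)
    idx = tuple(int(target[v]) for v in result.vars)
    prob = float(result.table[idx]) / z
    return QueryResult(min(max(prob, 0.0), 1.0), target, evidence, support)


def brute_force_query(
    net: BayesNet,
    target: Mapping[str, int],
    evidence: Mapping[str, int] | None = None,
) -> QueryResult:
    """Reference implementation: sum the explicitly enumerated joint."""
    evidence = dict(evidence or {})
    target = dict(target)
    _validate(net, target, evidence)
    nodes = net.nodes
    k = len(nodes)
    if k > MAX_BRUTE_FORCE_NODES:
        raise ValueError(f"brute force limited to {MAX_BRUTE_FORCE_NODES} nodes, net has {k}")
    pos = {node: i for i, node in enumerate(nodes)}
    states = (np.arange(2**k)[:, None] >> np.arange(k)) & 1  # (2^k, k)
    joint = np.ones(2**k)
    for node in nodes:
        cpt = net.cpts[node]
        if np.isnan(cpt.p1).any():
            raise ValueError(f"undefined CPT entry for node {node!r}; refit with alpha > 0")
        idx = np.zeros(2**k, dtype=np.int64)
        for j, p in enumerate(cpt.parents):
            idx += states[:, pos[p]].astype(np.int64) << j
        p1 = cpt.p1[idx]
        joint *= np.where(states[:, pos[node]] == 1, p1, 1.0 - p1)

    mask_ev = np.ones(2**k, dtype=bool)
    for var, val in evidence.items():
        mask_ev &= states[:, pos[var]] == int(val)
    denom = float(joint[mask_ev].sum())
    support = int(mask_ev.sum())
    if denom <= 0.0:
        return QueryResult(None, target, evidence, support, undefined=True)
    mask_t = mask_ev.copy()
    for var, val in target.items():
        mask_t &= states[:, pos[var]] == int(val)
    prob = float(joint[mask_t].sum()) / denom
    return QueryResult(min(max(prob, 0.0), 1.0), target, evidence, support)


def joint_table(net: BayesNet) -> tuple[tuple[str, ...], np.ndarray]:
    """Full joint as an array of shape (2,)*k, axis i = nodes[i] (natural
    order).  Only valid up to ``MAX_BRUTE_FORCE_NODES`` nodes."""
    nodes = net.nodes
    k = len(nodes)
    if k > MAX_BRUTE_FORCE_NODES:
        raise ValueError(f"joint table limited to {MAX_BRUTE_FORCE_NODES} nodes")
    pos = {node: i for i, node in enumerate(nodes)}
    states = (np.arange(2**k)[:, None] >> np.arange(k)) & 1
    joint = np.ones(2**k)
    for node in nodes:
        cpt = net.cpts[node]
        idx = np.zeros(2**k, dtype=np.int64)
        for j, p in enumerate(cpt.parents):
            idx += states[:, pos[p]].astype(np.int64) << j
        p1 = cpt.p1[idx]
        joint *= np.where(states[:, pos[node]] == 1, p1, 1.0 - p1)
    # states bit i is nodes[i]; axis order must put nodes[0] first
    return nodes, joint.reshape((2,) * k, order="F")
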