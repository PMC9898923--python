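"""Synthetic HDM sensitization cohorts with a known ground-truth network.

Patient-level multiplex data of the kind this package analyses is not
publicly shareable, so every pipeline stage is exercised on synthetic
cohorts drawn from ground-truth Bayesian networks.  The flagship fixture,
``paper11``, emulates a large clinical multiplex cohort (20,033 patients
tested, 5,170 of them sensitized to at least one HDM component, 68/32
children/adults): its DAG encodes the co-sensitization neighbourhoods of
the eleven components with Der p 23 and Der p 21 as parentless roots, and
its CPTs are logistic in the parent states with intercepts calibrated (by
exact enumeration) so each component's marginal matches the reference
prevalence among sensitized patients.

The generator then dresses the binary profiles in realistic magnitudes:
ages from a child/adult band mixture, sIgE for positives from shifted
log-normals matched to the reference per-stratum means (children's levels
about twice the adults'), sub-threshold values for negatives, and
log-normal total IgE.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .bayesnet import DAG, CPT, BayesNet, sample
from .catalog import COMPONENTS
from .cohort import DEFAULT_THRESHOLD
from .panel_io import PanelTable

# ---------------------------------------------------------------------------
# Reference cohort targets (counts among 5,170 sensitized of 20,033 tested;
# mean/SD of sIgE in kU/L among positives, overall / children / adults).
# ---------------------------------------------------------------------------
N_TESTED = 20033
N_SENSITIZED = 5170
N_CHILDREN = 3518
N_ADULTS = 1652

REFERENCE_COHORT: dict[str, dict[str, float]] = {
    "Der f 1": dict(n=2821, n_child=2083, n_adult=738, mean=16.16, sd=14.77,
                    mean_child=19.29, sd_child=15.10, mean_adult=7.30, sd_adult=9.21),
    "Der f 2": dict(n=3743, n_child=2568, n_adult=1175, mean=28.18, sd=17.71,
                    mean_child=32.31, sd_child=16.76, mean_adult=19.16, sd_adult=16.32),
    "Der p 1": dict(n=2720, n_child=1981, n_adult=741, mean=14.19, sd=13.20,
                    mean_child=16.71, sd_child=13.57, mean_adult=7.43, sd_adult=9.20),
    "Der p 2": dict(n=3701, n_child=2548, n_adult=1153, mean=27.45, sd=17.77,
                    mean_child=31.69, sd_child=16.90, mean_adult=18.07, sd_adult=15.95),
    "Der p 5": dict(n=1512, n_child=1065, n_adult=447, mean=16.00, sd=15.35,
                    mean_child=19.56, sd_child=15.72, mean_adult=7.54, sd_adult=10.32),
    "Der p 7": dict(n=1172, n_child=834, n_adult=338, mean=17.07, sd=15.79,
                    mean_child=20.37, sd_child=16.00, mean_adult=8.92, sd_adult=11.80),
    "Der p 10": dict(n=320, n_child=207, n_adult=114, mean=12.48, sd=15.99,
                     mean_child=13.34, sd_child=16.47, mean_adult=10.91, sd_adult=14.95),
    "Der p 11": dict(n=30, n_child=14, n_adult=16, mean=1.26, sd=2.72,
                     mean_child=0.94, sd_child=1.17, mean_adult=1.53, sd_adult=3.54),
    "Der p 20": dict(n=438, n_child=234, n_adult=204, mean=9.73, sd=13.10,
                     mean_child=11.49, sd_child=14.56, mean_adult=7.72, sd_adult=10.85),
    "Der p 21": dict(n=1422, n_child=952, n_adult=470, mean=20.26, sd=17.49,
                     mean_child=24.65, sd_child=17.57, mean_adult=11.37, sd_adult=13.50),
    "Der p 23": dict(n=2843, n_child=2011, n_adult=832, mean=15.77, sd=15.31,
                     mean_child=19.47, sd_child=15.66, mean_adult=6.81, sd_adult=9.72),
}

MEAN_TIGE_CHILDREN = 371.23  # kU/L, sensitized children
MEAN_TIGE_ADULTS = 222.51  # kU/L, sensitized adults
MEAN_TIGE_BACKGROUND = 150.0  # kU/L, allergic but not HDM-sensitized

# Age model: band mixture chosen to reproduce the reference mean ages
# (children ~8.2 y, adults ~32.2 y) with the early-school-age peak in
# children and the 18-32 peak in adults.
CHILD_AGE_BANDS = ((0.0, 1.0), (1.0, 3.0), (3.0, 6.0), (6.0, 12.0), (12.0, 18.0))
CHILD_AGE_WEIGHTS = (0.06, 0.12, 0.22, 0.35, 0.25)
ADULT_AGE_BANDS = ((18.0, 25.0), (25.0, 36.0), (36.0, 44.0), (44.0, 60.0), (60.0, 90.0))
ADULT_AGE_WEIGHTS = (0.38, 0.34, 0.13, 0.10, 0.05)

# ---------------------------------------------------------------------------
# "paper11" truth network: parent sets follow the described co-sensitization
# neighbourhoods, oriented so Der p 23 (and the unaffected Der p 21) are
# parentless; weights are fixed log-odds effects, positive for the strong
# group 1/2/5/21/23 co-sensitization cluster and negative for the
# tropomyosin Der p 10, whose carriers tend to lack the major components.
# ---------------------------------------------------------------------------
_PAPER11_PARENTS: dict[str, tuple[str, ...]] = {
    "Der p 23": (),
    "Der p 21": (),
    "Der p 5": ("Der p 21", "Der p 23"),
    "Der p 7": ("Der p 5", "Der p 21", "Der p 23"),
    "Der p 1": ("Der p 5", "Der p 7", "Der p 21", "Der p 23"),
    "Der f 2": ("Der p 1", "Der p 7", "Der p 21", "Der p 23"),
    "Der f 1": ("Der f 2", "Der p 1", "Der p 23"),
    "Der p 2": ("Der f 2", "Der p 1"),
    "Der p 11": ("Der f 2",),
    "Der p 20": ("Der f 2", "Der p 1", "Der p 5", "Der p 23"),
    "Der p 10": ("Der f 1", "Der f 2", "Der p 20", "Der p 23"),
}

_PAPER11_WEIGHTS: dict[str, dict[str, float]] = {
    "Der p 5": {"Der p 21": 1.6, "Der p 23": 0.8},
    "Der p 7": {"Der p 5": 1.2, "Der p 21": 1.0, "Der p 23": 0.8},
    "Der p 1": {"Der p 5": 0.8, "Der p 7": 0.8, "Der p 21": 0.6, "Der p 23": 1.4},
    "Der f 2": {"Der p 1": 1.2, "Der p 7": 0.8, "Der p 21": 0.8, "Der p 23": 1.2},
    "Der f 1": {"Der f 2": 1.2, "Der p 1": 1.6, "Der p 23": 1.2},
    "Der p 2": {"Der f 2": 2.2, "Der p 1": 1.2},
    "Der p 11": {"Der f 2": 0.7},
    # Der p 20 and Der p 10 carriers tend to lack the dominant group
    # 1/2/23 components, so their parent effects are negative
    "Der p 20": {"Der f 2": -0.8, "Der p 1": -0.8, "Der p 5": -0.4, "Der p 23": -0.8},
    "Der p 10": {"Der f 1": -0.7, "Der f 2": -0.7, "Der p 20": 1.5, "Der p 23": -0.5},
}

FIXTURE_NAMES = ("paper11", "chain3", "collider3", "strong5")


def _axis_bits(axis: int, ndim: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis] = 2
    return np.arange(2).reshape(shape)


@lru_cache(maxsize=1)
def _build_paper11() -> BayesNet:
    """Calibrate the paper11 CPT intercepts against the reference marginals.

    Nodes are processed in topological order while the exact joint over the
    processed prefix is maintained as a (2,)*m array; for each node the
    logistic intercept is solved with Brent's method so the node's marginal
    equals its reference prevalence (count / 5,170).
    """
    order = list(_PAPER11_PARENTS)
    processed: list[str] = []
    joint = np.ones(())
    cpts: dict[str, CPT] = {}
    for node in order:
        parents = _PAPER11_PARENTS[node]
        weights = [_PAPER11_WEIGHTS.get(node, {}).get(p, 0.0) for p in parents]
        target = REFERENCE_COHORT[node]["n"] / N_SENSITIZED
        ndim = len(processed)
        logit_wo_b = np.zeros((2,) * ndim) if ndim else np.zeros(())
        for w, p in zip(weights, parents):
            logit_wo_b = logit_wo_b + w * _axis_bits(processed.index(p), ndim)

        def marginal_gap(b: float) -> float:
            return float((joint * expit(b + logit_wo_b)).sum()) - target

        b = brentq(marginal_gap, -35.0, 35.0, xtol=1e-13)
        cond = expit(b + logit_wo_b)
        joint = np.stack([joint * (1.0 - cond), joint * cond], axis=-1)
        processed.append(node)
        cfgs = (np.arange(2 ** len(parents))[:, None] >> np.arange(len(parents))) & 1
        p1 = expit(b + cfgs @ np.array(weights)) if len(parents) else np.array([expit(b)])
        cpts[node] = CPT(node=node, parents=parents, p1=p1)
    dag = DAG(nodes=order, edges=[(p, n) for n in order for p in _PAPER11_PARENTS[n]])
    return BayesNet(dag=dag, cpts=cpts)


def _build_chain3() -> BayesNet:
    dag = DAG(
        nodes=("Der p 23", "Der p 1", "Der f 1"),
        edges=[("Der p 23", "Der p 1"), ("Der p 1", "Der f 1")],
    )
    cpts = {
        "Der p 23": CPT("Der p 23", (), np.array([0.7])),
        "Der p 1": CPT("Der p 1", ("Der p 23",), np.array([0.2, 0.9])),
        "Der f 1": CPT("Der f 1", ("Der p 1",), np.array([0.2, 0.9])),
    }
    return BayesNet(dag=dag, cpts=cpts)


def _build_collider3() -> BayesNet:
    dag = DAG(
        nodes=("Der p 1", "Der f 1", "Der f 2"),
        edges=[("Der p 1", "Der f 1"), ("Der f 2", "Der f 1")],
    )
    cpts = {
        "Der p 1": CPT("Der p 1", (), np.array([0.5])),
        "Der f 2": CPT("Der f 2", (), np.array([0.5])),
        # parents in natural order: (Der f 2, Der p 1); LSB = Der f 2
        "Der f 1": CPT("Der f 1", ("Der f 2", "Der p 1"), np.array([0.05, 0.85, 0.85, 0.98])),
    }
    return BayesNet(dag=dag, cpts=cpts)


def _build_strong5() -> BayesNet:
    """Five components with strong effects, for structure-recovery tests."""
    dag = DAG(
        nodes=("Der p 23", "Der p 21", "Der p 1", "Der f 2", "Der f 1"),
        edges=[
            ("Der p 23", "Der p 1"),
            ("Der p 21", "Der p 1"),
            ("Der p 1", "Der f 2"),
            ("Der f 2", "Der f 1"),
        ],
    )
    cpts = {
        "Der p 23": CPT("Der p 23", (), np.array([0.55])),
        "Der p 21": CPT("Der p 21", (), np.array([0.40])),
        # parents in natural order: (Der p 21, Der p 23); LSB = Der p 21
        "Der p 1": CPT("Der p 1", ("Der p 21", "Der p 23"), np.array([0.08, 0.75, 0.75, 0.95])),
        "Der f 2": CPT("Der f 2", ("Der p 1",), np.array([0.15, 0.85])),
        "Der f 1": CPT("Der f 1", ("Der f 2",), np.array([0.20, 0.80])),
    }
    return BayesNet(dag=dag, cpts=cpts)


_BUILDERS = {
    "paper11": _build_paper11,
    "chain3": _build_chain3,
    "collider3": _build_collider3,
    "strong5": _build_strong5,
}


def make_truth_net(name: str, overrides: dict[str, dict[int, float]] | None = None) -> BayesNet:
    """Return a deep copy of a named fixture network.

    ``overrides`` maps node -> {configuration index: new P(node=1|cfg)};
    the copy is revalidated after applying them.
    """
    if name not in _BUILDERS:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    net = copy.deepcopy(_BUILDERS[name]())
    if overrides:
        for node, edits in overrides.items():
            if node not in net.cpts:
                raise ValueError(f"override for unknown node {node!r}")
            p1 = net.cpts[node].p1.copy()
            for idx, value in edits.items():
                p1[int(idx)] = float(value)
            net.cpts[node] = CPT(node=node, parents=net.cpts[node].parents, p1=p1)
        net.validate()
    return net


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------
@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults reproduce the reference cohort scale: 20,033 patients of whom
    ~25.81% are sensitized to at least one component, 68.05% of the
    sensitized being children (< 18 y).  Sensitized patients' binary
    profiles are drawn from ``truth_net`` (all-negative draws are
    resampled so a "sensitized" patient always carries >= 1 positive);
    everyone else is negative throughout.
    """

    n_patients: int = N_TESTED
    seed: int = 0
    fixture: str = "paper11"
    truth_net: BayesNet | None = None
    sensitized_fraction: float = N_SENSITIZED / N_TESTED
    require_positive: bool = True
    child_fraction: float = N_CHILDREN / N_SENSITIZED
    threshold: float = DEFAULT_THRESHOLD
    sige_sigma: float = 0.9  # log-scale SD of positive sIgE magnitudes
    tige_sigma: float = 1.2
    hard_zeros: bool = False  # negatives exactly 0 instead of sub-threshold

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.sensitized_fraction <= 1.0:
            raise ValueError("sensitized_fraction must lie in [0, 1]")
        if not 0.0 < self.child_fraction < 1.0:
            raise ValueError("child_fraction must lie in (0, 1)")
        if self.sige_sigma <= 0 or self.tige_sigma <= 0:
            raise ValueError("scale parameters must be positive")

    def resolve_net(self) -> BayesNet:
        return self.truth_net if self.truth_net is not None else make_truth_net(self.fixture)


def _lognormal_mu(mean: float, shift: float, sigma: float) -> float:
    if mean <= shift:
        raise ValueError(f"positive-stratum mean {mean} must exceed threshold {shift}")
    return float(np.log(mean - shift) - sigma**2 / 2.0)


def _draw_ages(child: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    ages = np.empty(len(child))
    for mask, bands, weights in (
        (child, CHILD_AGE_BANDS, CHILD_AGE_WEIGHTS),
        (~child, ADULT_AGE_BANDS, ADULT_AGE_WEIGHTS),
    ):
        m = int(mask.sum())
        if not m:
            continue
        idx = rng.choice(len(bands), size=m, p=np.array(weights) / sum(weights))
        lo = np.array([bands[i][0] for i in idx])
        hi = np.array([bands[i][1] for i in idx])
        ages[mask] = rng.uniform(lo, hi)
    return ages


def generate_cohort(config: CohortConfig) -> PanelTable:
    """Generate a panel table under the configured study conditions.

    Reproducible for a fixed seed.  By construction every positive sIgE is
    >= threshold and every negative is < threshold, so binarizing at the
    same threshold recovers the sampled binary matrix exactly.
    """
    rng = np.random.default_rng(config.seed)
    net = config.resolve_net()
    unknown = set(net.nodes) - set(COMPONENTS)
    if unknown:
        raise ValueError(f"truth net has non-catalog nodes: {sorted(unknown)}")
    n = config.n_patients
    thr = config.threshold

    sensitized = rng.random(n) < config.sensitized_fraction
    n_s = int(sensitized.sum())
    profiles = sample(net, n_s, rng=rng)
    if config.require_positive and n_s:
        for _ in range(1000):
            empty = profiles.sum(axis=1).to_numpy() == 0
            if not empty.any():
                break
            profiles.loc[empty] = sample(net, int(empty.sum()), rng=rng).to_numpy()

    binary = np.zeros((n, len(COMPONENTS)), dtype=np.int8)
    for j, comp in enumerate(COMPONENTS):
        if comp in profiles.columns:
            binary[sensitized, j] = profiles[comp].to_numpy()

    child = rng.random(n) < config.child_fraction
    ages = _draw_ages(child, rng)

    sige = np.empty((n, len(COMPONENTS)))
    if config.hard_zeros:
        sige[:] = 0.0
    else:
        # sub-threshold background, kept clear of the threshold so that
        # 4-decimal serialization cannot round a negative up to positive
        sige[:] = rng.uniform(0.0, thr - 5e-4, size=sige.shape)
    sigma = config.sige_sigma
    for j, comp in enumerate(COMPONENTS):
        ref = REFERENCE_COHORT[comp]
        for mean, mask in (
            (ref["mean_child"], child),
            (ref["mean_adult"], ~child),
        ):
            sel = (binary[:, j] == 1) & mask
            m = int(sel.sum())
            if m:
                mu = _lognormal_mu(mean, thr, sigma)
                sige[sel, j] = thr + rng.lognormal(mu, sigma, size=m)

    tige = np.empty(n)
    for mean, mask in (
        (MEAN_TIGE_CHILDREN, sensitized & child),
        (MEAN_TIGE_ADULTS, sensitized & ~child),
        (MEAN_TIGE_BACKGROUND, ~sensitized),
    ):
        m = int(mask.sum())
        if m:
            mu = float(np.log(mean) - config.tige_sigma**2 / 2.0)
            tige[mask] = rng.lognormal(mu, config.tige_sigma, size=m)

    df = pd.DataFrame({"id": [f"P{i:06d}" for i in range(n)], "age": ages, "tIgE": tige})
    for j, comp in enumerate(COMPONENTS):
        df[comp] = sige[:, j]
    return PanelTable(df)


def simulate(
    fixture: str = "paper11", n: int = 20000, seed: int = 0, **overrides
) -> PanelTable:
    """Convenience wrapper: generate a cohort from a named fixture."""
    return generate_cohort(CohortConfig(n_patients=n, seed=seed, fixture=fixture, **overrides))


def random_net(
    nodes: int | tuple[str, ...],
    seed: int = 0,
    edge_prob: float = 0.35,
    max_parents: int = 3,
    p_low: float = 0.05,
    p_high: float = 0.95,
) -> BayesNet:
    """Random DAG + strictly positive random CPTs (for fuzz/oracle tests)."""
    rng = np.random.default_rng(seed)
    names = tuple(f"X{i}" for i in range(nodes)) if isinstance(nodes, int) else tuple(nodes)
    order = list(names)
    rng.shuffle(order)
    dag = DAG(nodes=names)
    for j, v in enumerate(order):
        for u in order[:j]:
            if len(dag.parents(v)) >= max_parents:
                break
            if rng.random() < edge_prob:
                dag.add_edge(u, v)
    cpts = {
        node: CPT(
            node=node,
            parents=dag.parents(node),
            p1=rng.uniform(p_low, p_high, size=2 ** len(dag.parents(node))),
        )
        for node in names
    }
    return BayesNet(dag=dag, cpts=cpts)
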