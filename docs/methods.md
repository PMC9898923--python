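# Methods

This note documents the statistical model, the numerical choices and the
known limitations of `mitebn`, the way a maintainer (rather than a user)
needs them.

## Problem setting

Component-resolved diagnostics (CRD) for house dust mite (HDM) allergy
measures allergen-specific IgE (sIgE, kU/L) against individual
Dermatophagoides molecules rather than whole-mite extract. The package
analyses panels of eleven components (Der f 1, Der f 2, Der p 1, Der p 2,
Der p 5, Der p 7, Der p 10, Der p 11, Der p 20, Der p 21, Der p 23) with
two goals:

1. **descriptive epidemiology** — who is sensitized to what, at which age;
2. **co-sensitization structure** — which components tend to appear
   together in an individual profile, modelled as a discrete Bayesian
   network over the binary sensitization indicators.

## Binarization and descriptive statistics

A patient is sensitized to component *j* when sIgE_j >= 0.31 kU/L, the
multiplex assay's reference cut-off. The boundary is inclusive: values are
discarded only when *below* the threshold. All downstream statistics are
computed on patients sensitized to at least one component ("the sensitized
sample").

Per-component **shares** are percentages of the whole sensitized sample —
also for the children (< 18 y) and adult strata, so the three shares of a
component relate as overall = children + adults. A within-stratum
denominator is available via `stratum_denominator=True`. Percentages and
ratios are rounded half-away-from-zero to two decimals (spreadsheet
convention), which reproduces published tables of this kind cell-for-cell;
Python's default banker's rounding does not.

Mean ± SD of sIgE is computed among positives only (values >= threshold),
with the sample SD (ddof = 1); an SD over fewer than two values, or any
statistic over an empty stratum, is NaN ("undefined"), never silently 0.

**Age bands** are half-open intervals [0,1), [1,3), [3,6), [6,12),
[12,18), [18,25), [25,36), [36,44), [44,60), [60,inf) — half-open so the
bands partition [0, inf) unambiguously at the cut ages. Age profiles are
emitted with both denominators (band size, and whole sensitized sample)
because either convention is defensible for such figures.

## The Bayesian network model

A network is a DAG over component names plus one CPT per binary node:
P(node = 1 | parent configuration). The joint factorizes as
`prod_i P(X_i | pa(X_i))`. Configurations are encoded as bit indices with
the first parent (CPT parent order = natural/catalog order) as the least
significant bit; this fixes serialization and every tie-break.

**CPT estimation** uses add-alpha smoothing,
`P(X=1|cfg) = (n_1(cfg) + alpha) / (n(cfg) + 2 alpha)`, alpha = 1
(Laplace) by default so every entry is defined even for parent
configurations unobserved among 2^11 profile states; alpha = 0 gives
maximum likelihood with unobserved configurations flagged NaN and refused
at query time.

**Inference** (`query`) is exact variable elimination: evidence is fixed
by factor reduction, hidden variables eliminated in min-degree order on
the evolving factor graph (ties by natural name order), and the result
normalized over the target assignment. Evidence of probability zero is
returned as an explicit *undefined* result. `brute_force_query`
enumerates the full joint (<= 16 nodes) and is the independent oracle the
test suite holds `query` to at 1e-12.

**d-separation** uses the standard reachability ("Bayes ball")
algorithm: chains/forks block when the middle node is observed; colliders
open when the collider or a descendant is observed. Note the three-node
pattern *names* used here are the standard ones — chain X->Y->Z, fork
X<-Y->Z ("common cause"), collider X->Y<-Z ("common effect") — because
part of the applied literature swaps the latter two labels; the semantics,
not the labels, drive all code paths.

## Structure learning

**BIC hill climbing.** Score = sum over nodes of the maximized multinomial
log-likelihood given parents minus (log n / 2) * 2^|parents| free
parameters per binary node; decomposable per family, cached per
(node, parent-set). Moves are single-edge add/delete/reverse, enumerated
in canonical node order; acyclicity is checked per move; edges into the
designated root (default Der p 23, the component whose prevalence is
stable across all ages) are forbidden unless the constraint is disabled.
Greedy ascent prefers no move on exact ties. Because the 2^p penalty is
*not* score-equivalent across orientations, plain greedy search can lock
in a mis-oriented collider early and then "patch" it with an extra edge —
a local optimum one single-edge move cannot leave. The search therefore
finishes with a deterministic tabu phase: up to 10 best non-improving
moves are taken, never revisiting the last 10 graphs, and the best graph
visited is returned. This needs no randomness, so results are exactly
reproducible for fixed data; optional random restarts (seeded, default 0)
remain available for harder instances.

**Chow–Liu tree.** Pairwise mutual information (natural log, 0 log 0 = 0)
from the 2x2 contingency tables, maximum spanning tree by Kruskal with
ties broken on canonical edge order, edges oriented away from the root by
BFS. Deterministic; every non-root node has exactly one parent.

Constant columns cannot carry information; they are left isolated with a
logged warning.

## The synthetic cohort generator

Real CRD cohorts of this kind are not publicly shareable, so the
generator produces panels with the statistical features the analysis
relies on. Reference targets (embedded as the `REFERENCE_COHORT` constants):
20,033 patients tested, 5,170 (25.81%) sensitized to >= 1 component,
68.05% of the sensitized being children; per-component prevalence among
the sensitized from 0.58% (Der p 11) to 72.40% (Der f 2); per-stratum
mean sIgE among positives, with children's levels roughly double the
adults' for most components.

**Truth network `paper11`.** Parent sets follow the described
co-sensitization neighbourhoods: Der p 23 and Der p 21 are parentless
roots; the group 5/21 pair feeds Der p 7 and Der p 1; Der p 1, Der p 7,
Der p 21, Der p 23 feed Der f 2; group 1/2 cascade into Der f 1, Der p 2,
Der p 11; Der p 20 and Der p 10 have *negative* dependence on the major
components (their carriers tend to lack group 1/2/23 sensitization).
CPTs are logistic in the parent states with fixed effect sizes
(|log-odds| 0.4–2.2); the intercepts are solved by Brent's method against
exact enumeration of the partial joint so every component's marginal
equals its reference prevalence to machine precision. Smaller fixtures
(`chain3`, `collider3`, `strong5`) have hand-set CPTs with strong effects
for recovery and pattern tests.

**Cohort assembly.** Each of n patients is sensitized with probability
0.2581; sensitized patients draw a binary profile from the truth net
(all-zero draws are resampled, so "sensitized" always means >= 1
positive), everyone else is negative throughout. Ages come from a
child/adult two-stage band mixture tuned to the reference mean ages
(8.2 y / 32.2 y); profiles and ages are independent. Positive sIgE values
are threshold + LogNormal(mu_jc, 0.9) with mu matched to the per-stratum
reference mean; negatives are uniform sub-threshold (capped at 0.3095 so
4-decimal serialization cannot cross the threshold), or exactly zero with
`hard_zeros`. Total IgE is log-normal by stratum. Everything is driven by
one seeded generator; a fixed seed reproduces the cohort bit-for-bit.

What the generator does **not** emulate: age-dependent prevalence drift
(the reference cohort's group-2 shares rise with age), correlation
between profile and age, assay censoring at the upper measuring range,
and any region structure. Tests passing on synthetic data therefore
demonstrate correctness of the machinery under the modelled conditions,
not fidelity of the truth net to the real joint distribution, which is
unknown beyond the described neighbourhoods.

Because sensitized profiles are conditioned on >= 1 positive, the
among-sensitized prevalence in generated cohorts exceeds the truth-net
marginal by a factor 1/(1-P0), P0 = P(all-zero profile) ≈ 0.054 — up to
~3.6 percentage points for the most prevalent components. Calibrating the
conditional marginal instead would detach the net's own marginals from
the reference shares; the package keeps the net calibration exact and
documents the inflation (the acceptance script reports it).

## Problem sizes used in the checks

The recovery and equivalence experiments use sizes at which the effects
they demonstrate are clearly resolved while the whole suite stays fast:
50,000 profiles for CPT/query recovery, 20,000 for structure recovery
(10 seeds), 200 fuzzed queries over 11-node random networks for the
variable-elimination/enumeration equivalence, 20 random 7-node networks
with all ~8,000 d-separated triples verified against the enumerated
joint.

## Known limitations

- Entry-wise CPT recovery to ±0.02 at n = 50,000 is not achievable for
  the `paper11` truth net: its 4-parent families (forced by the described
  neighbourhoods) contain parent configurations with mass of order
  0.1–1%, i.e. ~50–500 samples and a binomial standard error of
  0.02–0.07. The observed max-abs entry error is ~0.03–0.06 across seeds;
  the corresponding acceptance test states the ±0.02 condition and is
  expected to fail on the entry clause. Conditional-probability *queries*
  concentrate on well-supported regions and recover to ~0.01–0.02.
- BIC with the 2^p-parameter penalty is not score-equivalent, so learned
  edge *orientations* are not identified; only skeletons are compared in
  recovery experiments.
- The generator's lognormal magnitude model reproduces means, not the
  full shape (reference SDs suggest heavy censoring at the assay's upper
  range); magnitude-level analyses beyond means should not rely on it.
- Variable elimination is exponential in treewidth; fine for 11 nodes,
  not intended for large panels.
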