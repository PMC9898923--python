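# mitebn

Analysis toolkit for **molecular sensitization to house dust mite (HDM)
allergens**: threshold binarization of multiplex sIgE panels, descriptive
and age-stratified sensitization statistics, and discrete **Bayesian
network** modelling of co-sensitization between the eleven
Dermatophagoides components measured by modern component-resolved
diagnostics (Der f 1, Der f 2, Der p 1, Der p 2, Der p 5, Der p 7,
Der p 10, Der p 11, Der p 20, Der p 21, Der p 23).

It is written for allergy epidemiologists and biostatisticians who have
per-patient panel tables (`id, age, tIgE, Der f 1, ..., Der p 23` in
kU/L) and want reproducible answers to questions like *"what share of
sensitized children carry Der p 23?"* or *"how probable is Der f 1
sensitization in a profile that already contains Der f 2, Der p 1 and
Der p 23?"*. Because patient-level CRD data is rarely shareable, the
package also ships a synthetic cohort generator with a known ground-truth
network, so every stage of the pipeline is testable end to end.

## Model

A patient is *sensitized* to component j when sIgE_j >= 0.31 kU/L (the
assay's reference cut-off, boundary inclusive). Over the binary
indicators X_1..X_11 the package fits a Bayesian network — a DAG G plus
one conditional probability table per node — factorizing the joint as

    P(x_1, ..., x_11) = prod_i P(x_i | pa_G(x_i))

Structure is learned by BIC-scored hill climbing (single-edge
add/delete/reverse moves, deterministic tabu escape, optional root
constraint, default root Der p 23) or by a Chow–Liu tree (maximum
spanning tree on pairwise mutual information, oriented away from the
root). CPTs use Laplace smoothing, P(X=1|cfg) = (n_1 + a)/(n + 2a) with
a = 1. Conditional probabilities P(target | evidence) are computed by
exact variable elimination, validated against a brute-force enumeration
oracle; d-separation queries and the canonical chain / fork / collider
triple patterns are provided for structural reasoning.

## Worked example

```python
from mitebn import (simulate, binarize, filter_sensitized, cohort_summary,
                    share, query, RunConfig)
from mitebn.pipeline import learn_network

table = simulate(fixture="paper11", n=20033, seed=42)   # synthetic cohort
matrix = filter_sensitized(binarize(table, 0.31))
s = cohort_summary(table, matrix)
print(s.n_sensitized, share(s.n_sensitized, s.n_total_tested), s.child_adult_ratio)
# 5193 25.92 2.17

net = learn_network(matrix, RunConfig(input="-", outdir="-", seed=42))
print(query(net, {"Der f 1": 1},
            {"Der f 2": 1, "Der p 1": 1, "Der p 23": 1}).percent)
# 87.56
```

The cohort of 20,033 synthetic patients contains 5,193 (25.92%)
HDM-sensitized individuals with a 2.17 child:adult ratio; group 2
components lead the prevalence table (Der f 2 76.60%, Der p 2 74.79% of
the sensitized), followed by Der f 1, Der p 23 and Der p 1 — the shape
real CRD cohorts show. The learned 21-edge network then quantifies
individual co-sensitization: a profile already positive for Der f 2,
Der p 1 and Der p 23 carries Der f 1 with 87.56% probability.

The same analysis runs from the shell:

```bash
mitebn simulate --fixture paper11 --n 20033 --seed 42 --out panel.csv
mitebn summarize --input panel.csv --out summary.json --tsv table1.tsv
mitebn learn --input panel.csv --root "Der p 23" --seed 42 \
             --out net.json --dot net.dot
mitebn cpd --net net.json --target "Der f 1=1" \
           --evidence "Der f 2=1,Der p 1=1,Der p 23=1"
```

or end to end via `mitebn run --config run.yaml`, which writes a
deterministic report bundle (summary JSON/TSV, age profiles, the network
as JSON and Graphviz DOT, all conditional-probability query results, the
resolved config and a log) — byte-identical for identical config and
seed.

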