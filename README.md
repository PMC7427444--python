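# ergmix

ERGM-based audit of selective-mixing inference in binary brain graphs.

`ergmix` fits four nested exponential random graph model (ERGM)
specifications to binary functional-connectivity graphs with node
attributes derived from structural connectivity, and quantifies how
omitting triadic-closure (GWESP) and structural terms changes the
significance of selective-mixing (label-pair) parameters.  Each mixing
parameter in a full-vs-base model comparison is classified as a false
positive, false negative, true positive, or true negative; error rates
are then modeled with a multinomial logistic regression across subject
groups.  A seeded synthetic-cohort generator stands in for clinical data,
so the entire pipeline is testable end to end.

## Model specifications

| name         | terms                                                                |
|--------------|----------------------------------------------------------------------|
| `base`       | edges + selective mixing (one reference cell dropped)                |
| `structural` | base + nodal covariates (degree, local efficiency, clustering) + latent-cluster homophily |
| `gwesp`      | base + fixed-decay geometrically weighted edgewise shared partners   |
| `complete`   | all of the above                                                     |

Estimation is maximum pseudo-likelihood (exact MLE for the
dyad-independent specs) with an optional Geyer–Thompson MCMC-MLE
refinement; simulation uses a Metropolis sampler over uniform dyad
toggles with the adjacency held as integer bitmasks.  An exhaustive
enumeration over graphs on ≤ 5 nodes serves as an exact oracle in the
test suite.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the binding end-to-end criteria
(published GWESP worked example, 192-fit design census, change-statistic
oracle equivalence, sampler total-variation check against exact
enumeration, parameter recovery with CI coverage, the misspecification
direction experiment, and multinomial closed forms).  The full suite
takes several minutes; the heavy tests are the recovery and
misspecification experiments.

## Command line

```sh
# generate a seeded synthetic cohort (structural + functional graphs)
ergmix simulate --n-subjects 12 --n-nodes 154 --seed 7 --out out/cohort

# fit one specification to one session
ergmix fit --adjacency out/cohort/S001_ses1_functional.csv \
           --attributes out/cohort/S001_attributes.tsv \
           --spec complete --decay 0.5 --out out/fit.json

# simulation goodness of fit (model terms + edgewise-shared-partner bins)
ergmix gof --adjacency ... --attributes ... --spec complete --n-sims 1000 \
           --out out/gof.csv

# four fits + three full-vs-base comparisons for one session
ergmix audit --adjacency ... --attributes ... --out out/records.csv

# multinomial error-rate models from pooled records
ergmix rates --records out/records.csv --sessions sessions.csv --out out/rates

# everything: cohorts -> fits -> comparisons -> tallies -> rate models
ergmix run-all --seed 7 --out out/full
```

Adjacency I/O accepts dense CSV/TSV (header row of node ids) and
GraphML; attribute tables are TSV with `node_id`, `rsn_label`,
`cortical_group` and optional covariate columns.

## Library entry points

```python
from ergmix import (
    validate_graph, compute_statistics, ModelSpec,
    mple_fit, mcmcmle_fit, sample_graphs, enumerate_exact,
    gof_report, classify_pe, tally_errors, fit_multinomial,
    CohortConfig, gen_functional_cohort, run_pipeline,
)
```
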