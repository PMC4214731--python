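# drugnet

Network-based prediction of drug–disease associations for drug
repositioning.

Most approved drugs act on several protein targets, and most diseases arise
from several susceptibility genes. When a drug's targets sit close — in a
gene/protein interaction network — to the targets of drugs already known to
treat a disease, or to the disease's own genes, that proximity is evidence
for a new indication. `drugnet` turns this guilt-by-association idea into a
supervised link-prediction pipeline for computational biologists and
cheminformaticians: it scores network proximity, converts the scores into
features, trains classifiers on known associations, and ranks novel
drug–disease candidates.

## The model

Let `T(d)` be drug *d*'s target proteins and `T(p)` disease *p*'s
susceptibility genes, both restricted to the nodes of an integrative network
(experimental PPIs, regulatory interactions, complex-inferred PPIs; only
entities with ≥ 2 in-network nodes are kept). A shortest path of length
ℓ between two nodes scores `ω(ℓ) = base^(ℓ+1)` for ℓ ∈ {0, 1, 2} (paths
R0, R1, R2) and 0 beyond; `base` defaults to 1/6, the reciprocal median
degree of large integrative human networks, or may be recomputed from the
loaded network.

**Adjacency-based inference.** The adjacency of two node sets is the
normalized scored-path sum

    A(S1, S2) = Σ_{x∈S1, y∈S2} ω(dist(x, y)) / (|S1|·|S2|)

For a candidate pair (d, p), the drug-side feature is
`max_{d' known for p} A(T(d), T(d'))`, the disease-side feature is the
symmetric maximum over the diseases known for *d*, and the combined feature
is their weighted geometric mean — 3 features.

**Module-distance-based inference.** The *d-module* of two drugs at level
*v* is the intersection of the *v*-step neighborhoods of their target sets —
the gene module topologically common to both. Its distance to a disease at
exact path length *k* is

    M_k(mod, T(p)) = Σ_{t∈mod, g∈T(p)} ω_k(t, g) / (|mod|·|T(p)|),
    ω_k(t, g) = base^(k+1) if dist(t, g) = k exactly, else 0

maximized over the drugs known for *p*; *p-modules* are the symmetric
construction on disease pairs, measured against `T(d)`. Over the
(v, k) ∈ {0,1,2}² grid and the three variants (d-module, p-module,
combined) this yields 27 features, 30 in total per pair.

**Learning.** Known associations are the positives; an equal number of
negatives is drawn uniformly from the positives' drugs × diseases. 10-fold
stratified cross-validation is repeated 10 times with a fresh negative
sample each repeat, scored by the rank-based (Mann–Whitney) AUC, with
decision-tree, random-forest and multilayer-perceptron backends. Predictions
are validated post hoc by coverage enrichment against an external
association list (one-sided Fisher exact test) and a Tanimoto
fingerprint screen confirming predictions are not structural look-alikes.

## Worked example

Everything runs on self-contained synthetic benchmarks with a planted
proximity signal, so no external databases are needed:

```sh
drugnet simulate --out bench --nodes 300 --drugs 30 --diseases 10 \
    --positives 80 --seed 7
drugnet train-eval --network bench/network.tsv --drugs bench/drug_targets.tsv \
    --diseases bench/disease_genes.tsv --associations bench/associations.tsv \
    --backend forest --folds 10 --repeats 5 --seed 0 --out cv.json
drugnet predict --network bench/network.tsv --drugs bench/drug_targets.tsv \
    --diseases bench/disease_genes.tsv --associations bench/associations.tsv \
    --backend forest --seed 0 --out predictions.tsv
```

prints

```
wrote benchmark to bench
grand mean AUC (forest): 0.6584
predicted 55 of 220 candidate pairs
```

The grand mean AUC is the average over 5 repeats of 10-fold CV (individual
repeats here: 0.671, 0.710, 0.636, 0.657, 0.618) — well above the 0.5 of an
uninformative classifier, showing the planted drug-target/disease-gene
proximity is recovered from the features alone. `predictions.tsv` ranks the
220 never-seen drug–disease pairs by classifier score; the 55 pairs with
score ≥ 0.5 are the proposed repositioning candidates. `cv.json` also
records a per-feature information-gain ranking (here led by `dmod_v0_k1`,
the drug-module distance at v = 0, k = 1) and every seed needed to
reproduce the run. The same feature matrices can be exported as CSV or ARFF
via `drugnet build-features`, and `drugnet validate` / `drugnet ablate`
cover coverage-enrichment validation and the method/path-type/network-source
ablation grids.

The Python API mirrors the CLI (`drugnet.pair_set_adjacency`,
`drugnet.build_feature_vector`, `drugnet.repeated_cv`, ...); see the module
docstrings and `docs/methods.md` for the full model description.

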