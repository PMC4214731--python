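# Methods

## Model and assumptions

The package treats drug repositioning as supervised link prediction on a
bipartite drug–disease graph, with all evidence derived from an integrative
gene/protein network. The core assumption is *guilt by association*: if
(d', p) is a known therapeutic association and drug d's targets are
network-proximal to d''s targets, then (d, p) is a plausible association;
symmetrically for diseases known to respond to the same drug. Proximity is
only trusted over very short ranges — identical nodes (R0), direct
interactions (R1) and one-intermediate paths (R2) — because longer paths in
dense interactomes connect almost everything and carry little specific
signal. Everything at distance ≥ 3 therefore contributes exactly zero, which
also keeps the computation local (depth-2 truncated BFS, cached per node;
no all-pairs shortest paths).

The network is undirected and simple. Regulatory edges are directed in
typical source data, but none of the scores use direction, so edges keep
their source tags (ppi, regulation_activation, regulation_inhibition,
complex_inferred) and direction is ignored; the tags exist so that
per-source ablations can filter the network at load time. Protein complexes
are assumed to be already expanded to binary interactions by the data
provider.

Entity filtering mirrors curated-catalog practice: node identifiers absent
from the network are dropped first, then drugs with fewer than two remaining
targets and diseases with fewer than two remaining susceptibility genes,
then associations referencing a dropped entity. The two pruning steps
commute, so filtering is order-independent.

## Scores

A path of length ℓ scores `base^(ℓ+1)`. The default `base = 1/6` is the
reciprocal of the median node degree of large integrative human networks;
`auto` mode recomputes it as 1/median-degree of the loaded network (median
taken as the lower middle value for even node counts, keeping the base a
unit fraction).

*Set adjacency* (drug–drug or disease–disease) is the scored-path sum over
all cross pairs divided by `|S1|·|S2|`. Note the attainable maximum is
`base`, not 1, since each pair contributes at most the R0 score; scores are
used as-is, with no renormalization.

*Topological modules*: the module common to two entities at level v is the
intersection of the v-step neighborhoods of their node sets (at v = 0,
exactly the shared nodes). Expansion happens before intersection. *Module
distance* to an entity at parameter k uses an exact-distance indicator —
a (module member, entity node) pair contributes `base^(k+1)` iff its
shortest-path distance equals k — normalized by `|module|·|entity set|`.
The exact-distance buckets are disjoint across k, so the three k-features
decompose the ≤ 2 neighborhood rather than re-counting it. An empty module
or an empty candidate maximum scores 0.

Both feature families take the *maximum* over the anchor entity's known
partners, and drug-side and disease-side maxima are merged by a weighted
geometric mean (default weights 0.5/0.5; the mean is zero whenever either
side is zero, so a completely absent signal on one side cannot be averaged
away). Although the d-module and p-module scores are described with opposite
verbal orientations (higher vs shorter = better), both are implemented as
the same maximized similarity-style score (larger = closer) and the
classifier is left to learn the signs.

## Features and leakage policy

Each pair yields 30 features: 3 adjacency features and 27 module features
(3 variants × v ∈ {0,1,2} × k ∈ {0,1,2}), in a fixed documented column
order (`drugnet-features-v1`). When a *known positive* pair is scored for
training, the pair itself is removed from the known-association indices
(`exclude_self`), otherwise its own label leaks into the maxima. By default
no further exclusion is applied during cross-validation — features are
computed once against the full association set — matching the most literal
reading of the evaluation protocol; a stricter `strict_cv` mode that
recomputes features per fold with the test-fold positives removed from the
indices is available but off by default. Features are not standardized: the
reference backends are dominated by trees, and backends that need scaling
can apply it internally.

## Training and evaluation

Negatives are drawn uniformly *without replacement* from (drugs appearing in
positives) × (diseases appearing in positives) minus the positives, with
`#negatives = #positives` (with-replacement sampling could duplicate rows).
Each of the 10 CV repeats draws a fresh negative set, partitions the
balanced matrix into 10 *stratified* folds (plain random folds can go
single-class at small n), trains on nine and scores one. A repeat's AUC is
the mean of its fold AUCs (score pooling across folds is available as
`pooled`); the grand mean averages the repeats. The AUC is the Mann–Whitney
statistic (ties count ½), checked in the tests against trapezoidal ROC
integration. Backends use scikit-learn library defaults with fixed seeds:
`DecisionTreeClassifier` (a CART stand-in for C4.5), `RandomForestClassifier`
and `MLPClassifier`, plus a constant baseline; any `seed -> backend`
callable honoring the fit/score contract can be substituted. All
sub-seeds (negative draws, fold shuffles, per-fold classifier seeds) derive
from one master seed via `SeedSequence`, so identical configuration implies
bit-identical artifacts. Candidate prediction scores every
(drug, disease) pair outside the known set and thresholds at 0.5 by
default. A per-feature mutual-information ranking is reported as a
diagnostic only; no feature selection is performed.

Coverage validation builds the 2×2 predicted-by-validated table over the
candidate universe (all candidate pairs by default; the external list is
intersected with the universe first), reports coverage =
|predicted ∩ validated| / |validated|, and tests enrichment with a
one-sided (upper-tail) Fisher exact test. The Tanimoto screen flags drug
pairs with fingerprint Jaccard similarity *strictly* above 0.7.

## Synthetic benchmarks

The generator emulates the *shape* of real inputs, not their biology: a
preferential-attachment backbone (mimicking interactome degree
heterogeneity; Erdős–Rényi available), with the attachment parameter chosen
so the realized median degree lands closest to the target (default 6);
disease gene sets as local neighborhood patches (a non-leaf seed node plus
sampled neighbors); uniformly sampled known associations; and drug target
sets planted with strength s — each target of an associated drug is drawn
from within distance 1 of a randomly chosen one of its diseases' gene
modules with probability s, uniformly otherwise. Fingerprints are
independent random bitsets (32 of 256 bits), so the structural-similarity
screen is expected to report ~0 on synthetic data. Default study
conditions: 500 nodes, 60 drugs (2–6 targets), 20 diseases (3–8 genes),
200 positives, s = 0.8, seed 1 — set sizes are scaled-down versions of
typical curated catalogs.

What passing tests on these benchmarks do and do not show: they demonstrate
that the scoring features recover planted network proximity and that the
full pipeline is deterministic and internally consistent; they say nothing
about performance on real curated data, whose pathway structure, annotation
bias and label noise the generator does not model. Two intrinsic properties
of the protocol are visible even synthetically. First, with 200 positives
on a 60×20 grid each drug carries ~3.3 associations, so per-target planting
necessarily splits a drug's targets across its diseases; per-pair signal is
diluted by roughly 1/|diseases(d)| and the achievable forest AUC under the
default conditions sits near 0.70 (≈ 0.74 even at s = 1; ≈ 0.87 when
positives are sparse enough for one disease per drug). Second, the null
benchmark (s = 0) evaluates slightly above chance (~0.6) because positives
over-represent high-degree entities relative to uniformly drawn negatives,
inflating max-over-known-partner features — the familiar degree bias of
uniform negative sampling, which the mirrored evaluation protocol shares.

## Numerical and degenerate-input conventions

Distances beyond the bound return an `UNREACHABLE` sentinel (infinity), so
comparisons behave naturally. Empty candidate maxima, empty modules, and a
zero on either side of a geometric mean all score 0; empty node sets,
out-of-range v/k, negative scores and single-class AUC inputs raise
parameter errors rather than returning conventions. Fisher p-values use
scipy's exact hypergeometric implementation (stable for large margins) and
are oracle-checked against direct enumeration. Feature CSVs are written
with `%.17g` floats, so round-trips and determinism checks are bitwise.

## Known limitations

- Identifier mapping (UniProt/Entrez/MeSH/OMIM) is out of scope; all
  identifiers are opaque strings and must already be consistent across
  inputs.
- Activation vs inhibition is not interpreted; no signed-path logic.
- The negative-sampling protocol treats unknown pairs as negative, so
  reported AUCs are optimistic in the usual way for this family of methods.
- Module members are not required to induce a connected subgraph.
- `strict_cv` recomputes features per fold and is markedly slower; it is
  provided for leakage-sensitivity analyses rather than routine use.
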