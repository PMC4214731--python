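"""30-dimensional feature vectors for drug-disease pairs and labeled
training matrices with balanced random negative sampling.

Feature layout (fixed canonical order, schema ``drugnet-features-v1``):

* 3 adjacency features: ``adj_drug``, ``adj_disease``, ``adj_combined`` —
  the maximized drug-side and disease-side set adjacencies and their
  geometric-mean combination.
* 27 module features: ``{dmod,pmod,mod_combined}_v{v}_k{k}`` for the full
  (v, k) grid with v, k in {0,1,2} — maximized d-module and p-module
  distance scores and their combination, at module expansion level v and
  exact path length k.

Known positive pairs are scored with *self-exclusion*: the pair itself is
removed from the known-association indices, otherwise its own label leaks
into the maxima.  Negatives are drawn uniformly without replacement from the
drugs x diseases of the positive set, minus the positives, with the same
cardinality as the positive set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .adjacency import best_known_adjacency, combine_geometric
from .entities import AssociationSet, Catalogs
from .exceptions import ParameterError, UnknownEntityError
from .modules import D_MODULE, P_MODULE, best_known_module_distance
from .network import GeneNetwork, PathScoreConfig

FEATURE_SCHEMA_VERSION = "drugnet-features-v1"

ADJACENCY_FEATURES = ("adj_drug", "adj_disease", "adj_combined")

MODULE_FEATURES = tuple(
    f"{m}_v{v}_k{k}"
    for m in ("dmod", "pmod", "mod_combined")
    for v in (0, 1, 2)
    for k in (0, 1, 2)
)

FEATURE_NAMES = ADJACENCY_FEATURES + MODULE_FEATURES

LABEL_POSITIVE = "positive"
LABEL_NEGATIVE = "negative"


def feature_names() -> tuple:
    """The 30 feature names in canonical column order."""
    return FEATURE_NAMES


def build_feature_vector(
    drug: str,
    disease: str,
    catalogs: Catalogs,
    assoc: AssociationSet,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    exclude_self: bool = True,
) -> pd.Series:
    """Score one (drug, disease) pair into its 30 named features."""
    if drug not in catalogs.drugs:
        raise UnknownEntityError(drug)
    if disease not in catalogs.diseases:
        raise UnknownEntityError(disease)
    t_d = catalogs.drugs[drug]
    t_p = catalogs.diseases[disease]
    excl_drug = drug if exclude_self else None
    excl_disease = disease if exclude_self else None

    values = {}
    adj_drug = best_known_adjacency(
        t_d, disease, "drug", catalogs, assoc, net, cfg, exclude=excl_drug
    )
    adj_disease = best_known_adjacency(
        t_p, drug, "disease", catalogs, assoc, net, cfg, exclude=excl_disease
    )
    values["adj_drug"] = adj_drug
    values["adj_disease"] = adj_disease
    values["adj_combined"] = combine_geometric(adj_drug, adj_disease, cfg.combine_weights)

    dmod = {}
    pmod = {}
    for v in (0, 1, 2):
        for k in (0, 1, 2):
            dmod[v, k] = best_known_module_distance(
                drug, disease, D_MODULE, v, k, catalogs, assoc, net, cfg,
                exclude=excl_drug,
            )
            pmod[v, k] = best_known_module_distance(
                disease, drug, P_MODULE, v, k, catalogs, assoc, net, cfg,
                exclude=excl_disease,
            )
    for v in (0, 1, 2):
        for k in (0, 1, 2):
            values[f"dmod_v{v}_k{k}"] = dmod[v, k]
    for v in (0, 1, 2):
        for k in (0, 1, 2):
            values[f"pmod_v{v}_k{k}"] = pmod[v, k]
    for v in (0, 1, 2):
        for k in (0, 1, 2):
            values[f"mod_combined_v{v}_k{k}"] = combine_geometric(
                dmod[v, k], pmod[v, k], cfg.combine_weights
            )
    return pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES),
                     name=(drug, disease), dtype=float)


def sample_negatives(positives: AssociationSet, n: int, seed: int) -> list:
    """Draw *n* presumed-negative pairs uniformly without replacement.

    The candidate pool is (drugs appearing in positives) x (diseases
    appearing in positives) minus the positive pairs themselves.  The draw is
    reproducible given *seed*; the returned list is sorted for stable output.
    """
    if n < 1:
        raise ParameterError(f"need n >= 1 negatives, got {n}")
    drugs = sorted(positives.drugs())
    diseases = sorted(positives.diseases())
    pool = [
        (d, p) for d in drugs for p in diseases if (d, p) not in positives
    ]
    if len(pool) < n:
        raise ParameterError(
            f"negative pool has only {len(pool)} pairs, cannot draw {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return sorted(pool[i] for i in idx)


def build_training_matrix(
    positives: AssociationSet,
    catalogs: Catalogs,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    seed: int,
    assoc: AssociationSet | None = None,
    feature_cache: dict | None = None,
) -> pd.DataFrame:
    """Balanced labeled feature matrix: all positives + equally many negatives.

    Positives are scored with self-exclusion on; sampled negatives are not in
    the association set, so exclusion is moot for them.  *assoc* lets callers
    score features against a different (e.g. fold-restricted) known set than
    the labeling positives; it defaults to the positives themselves.
    *feature_cache* (pair -> Series) amortizes repeated scoring across CV
    repeats that share the association set.
    """
    if len(positives) == 0:
        raise ParameterError("positive association set is empty")
    known = positives if assoc is None else assoc
    negatives = sample_negatives(positives, len(positives), seed)

    rows = []
    index = []
    cache = feature_cache if feature_cache is not None else {}
    for pair, label in [((d, p), LABEL_POSITIVE) for d, p in positives] + [
        (pair, LABEL_NEGATIVE) for pair in negatives
    ]:
        vec = cache.get(pair)
        if vec is None:
            vec = build_feature_vector(
                pair[0], pair[1], catalogs, known, net, cfg, exclude_self=True
            )
            cache[pair] = vec
        rows.append(vec.to_numpy())
        index.append((*pair, label))
    mat = pd.DataFrame(
        np.asarray(rows, dtype=float),
        columns=list(FEATURE_NAMES),
        index=pd.MultiIndex.from_tuples(index, names=["drug", "disease", "label"]),
    )
    return mat.reset_index()[["drug", "disease", *FEATURE_NAMES, "label"]]


def write_feature_matrix(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """CSV export with '#'-prefixed provenance header (schema version, seeds)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# schema={FEATURE_SCHEMA_VERSION}\n")
        for key in sorted(provenance or {}):
            fh.write(f"# {key}={provenance[key]}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.17g")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_arff(df: pd.DataFrame, path, relation: str = "drug_disease_features") -> None:
    """ARFF export (nominal class {positive,negative}) for Weka-style tools."""
    has_label = "label" in df.columns
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        fh.write("@ATTRIBUTE drug STRING\n@ATTRIBUTE disease STRING\n")
        for name in FEATURE_NAMES:
            fh.write(f"@ATTRIBUTE {name} NUMERIC\n")
        if has_label:
            fh.write("@ATTRIBUTE class {positive,negative}\n")
        fh.write("\n@DATA\n")
        for _, row in df.iterrows():
            fields = [str(row["drug"]), str(row["disease"])]
            fields += [f"{row[n]:.17g}" for n in FEATURE_NAMES]
            if has_label:
                fields.append(str(row["label"]))
            fh.write(",".join(fields) + "\n")
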