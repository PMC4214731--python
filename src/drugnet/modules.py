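"""Module-distance-based inference: common topological modules and their
distance to an entity's node set.

A d-module is the gene module topologically common to two drugs: the
intersection of the v-step network neighborhoods of their target sets
(v in {0,1,2}; at v=0 it is exactly the shared targets).  Its distance to a
disease is the normalized sum, over (module member, disease gene) pairs, of
an exact-length path score: a pair at shortest-path distance exactly k
contributes base**(k+1), other pairs contribute nothing.  p-modules are the
symmetric construction on two diseases, measured against a drug's targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .adjacency import combine_geometric
from .entities import AssociationSet, Catalogs
from .exceptions import ParameterError
from .network import GeneNetwork, PathScoreConfig, neighborhood

D_MODULE = "d-module"
P_MODULE = "p-module"


@dataclass(frozen=True)
class TopologicalModule:
    """Gene module common to two entities at expansion level v."""

    members: frozenset
    level: int
    seed_entities: tuple = ("", "")
    kind: str = D_MODULE


def common_module(
    s1: Iterable,
    s2: Iterable,
    v: int,
    net: GeneNetwork,
    seed_entities: tuple = ("", ""),
    kind: str = D_MODULE,
) -> TopologicalModule:
    """Intersection of the v-step neighborhoods of two seed node sets.

    May be empty; monotone nondecreasing in v for fixed seeds.
    """
    s1, s2 = frozenset(s1), frozenset(s2)
    if not s1 or not s2:
        raise ParameterError("common module of an empty seed set is undefined")
    members = neighborhood(net, s1, v) & neighborhood(net, s2, v)
    return TopologicalModule(members, v, seed_entities, kind)


def module_entity_distance(
    mod: TopologicalModule,
    entity_nodes: Iterable,
    k: int,
    net: GeneNetwork,
    cfg: PathScoreConfig,
) -> float:
    """Exact-length-k path score between a module and an entity's node set.

    value = sum over (t in module, g in entity_nodes) of base**(k+1) if
    dist(t, g) == k exactly, else 0, divided by |module| * |entity_nodes|.
    An empty module scores 0 at every k.
    """
    if k not in (0, 1, 2):
        raise ParameterError(f"distance parameter k must be in {{0,1,2}}, got {k}")
    genes = frozenset(entity_nodes)
    if not genes:
        raise ParameterError("module distance to an empty node set is undefined")
    if not mod.members:
        return 0.0
    w = cfg.weight(k)
    if w == 0.0:
        return 0.0
    hits = sum(len(mod.members & net.shells(g)[k]) for g in genes)
    return w * hits / (len(mod.members) * len(genes))


def best_known_module_distance(
    query: str,
    anchor: str,
    kind: str,
    v: int,
    k: int,
    catalogs: Catalogs,
    assoc: AssociationSet,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    exclude: str | None = None,
) -> float:
    """Maximum module-to-entity distance score over the anchor's known partners.

    kind='d-module' scores a (drug=query, disease=anchor) pair: for each drug
    d' known to treat the anchor disease, build the common module of T(query)
    and T(d') at level v and measure it against the anchor's gene set at
    distance k.  kind='p-module' is symmetric: query is a disease, the anchor
    a drug, candidates its known diseases, measured against the anchor's
    target set.  *exclude* drops the query itself from the candidates; an
    empty candidate set scores 0.
    """
    if kind == D_MODULE:
        candidates = assoc.drugs_for(anchor)
        seed_sets = catalogs.drugs
        query_set = catalogs.drugs[query]
        against = catalogs.diseases[anchor]
    elif kind == P_MODULE:
        candidates = assoc.diseases_for(anchor)
        seed_sets = catalogs.diseases
        query_set = catalogs.diseases[query]
        against = catalogs.drugs[anchor]
    else:
        raise ParameterError(f"kind must be {D_MODULE!r} or {P_MODULE!r}, got {kind!r}")
    best = 0.0
    for cand in candidates:
        if cand == exclude or cand not in seed_sets:
            continue
        mod = common_module(query_set, seed_sets[cand], v, net, (query, cand), kind)
        score = module_entity_distance(mod, against, k, net, cfg)
        if score > best:
            best = score
    return best


def combined_module_score(dmod: float, pmod: float, cfg: PathScoreConfig) -> float:
    """Weighted geometric mean of the d-module and p-module maxima."""
    return combine_geometric(dmod, pmod, cfg.combine_weights)


def write_module(mod: TopologicalModule, path) -> None:
    """Export a module as one node per line (for inspection/visualization)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kind={mod.kind} level={mod.level} seeds={','.join(mod.seed_entities)}\n")
        for node in sorted(mod.members):
            fh.write(f"{node}\n")
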