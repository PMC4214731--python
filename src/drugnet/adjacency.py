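"""Adjacency-based inference: scored bounded paths between node sets.

The drug-drug (disease-disease) adjacency of two entities is the normalized
sum of path scores over all cross pairs of their node sets: a pair at
distance l contributes base**(l+1) for l in {0,1,2} and nothing beyond, and
the sum is divided by |S1|*|S2|.  For a candidate (drug d, disease p) the
drug-side feature is the maximum adjacency between T(d) and the target set of
any drug already known to treat p; the disease-side feature is symmetric; the
combined feature is their weighted geometric mean.
"""

from __future__ import annotations

import math
from typing import Iterable

from .entities import AssociationSet, Catalogs
from .exceptions import ParameterError, UnknownEntityError
from .network import GeneNetwork, PathScoreConfig


def pair_set_adjacency(
    s1: Iterable, s2: Iterable, net: GeneNetwork, cfg: PathScoreConfig
) -> float:
    """Normalized scored-path adjacency between two non-empty node sets.

    Symmetric in (s1, s2); bounded by cfg.base (each cross pair contributes at
    most the length-0 score).
    """
    s1, s2 = frozenset(s1), frozenset(s2)
    if not s1 or not s2:
        raise ParameterError("adjacency of an empty node set is undefined")
    for n in (s1 | s2):
        if n not in net:
            raise UnknownEntityError(n)
    # Iterate the smaller side; each shell intersection counts the cross
    # pairs at that exact distance.
    if len(s2) < len(s1):
        s1, s2 = s2, s1
    total = 0.0
    for node in s1:
        shells = net.shells(node)
        for length in (0, 1, 2):
            w = cfg.weight(length)
            if w:
                total += w * len(s2 & shells[length])
    return total / (len(s1) * len(s2))


def best_known_adjacency(
    query_set: Iterable,
    anchor_entity: str,
    side: str,
    catalogs: Catalogs,
    assoc: AssociationSet,
    net: GeneNetwork,
    cfg: PathScoreConfig,
    exclude: str | None = None,
) -> float:
    """Maximum adjacency between *query_set* and any known partner of the anchor.

    side='drug': the anchor is a disease; candidates are its known drugs and
    the adjacency is measured against their target sets.  side='disease': the
    anchor is a drug; candidates are its known diseases, measured against
    their gene sets.  *exclude* removes the query entity itself from the
    candidates (label-leak guard when scoring a known positive pair).
    Returns 0 when no candidate remains.
    """
    if side == "drug":
        candidates = assoc.drugs_for(anchor_entity)
        node_sets = catalogs.drugs
    elif side == "disease":
        candidates = assoc.diseases_for(anchor_entity)
        node_sets = catalogs.diseases
    else:
        raise ParameterError(f"side must be 'drug' or 'disease', got {side!r}")
    best = 0.0
    for cand in candidates:
        if cand == exclude or cand not in node_sets:
            continue
        score = pair_set_adjacency(query_set, node_sets[cand], net, cfg)
        if score > best:
            best = score
    return best


def combine_geometric(a: float, b: float, weights: tuple = (0.5, 0.5)) -> float:
    """Weighted geometric mean a**w1 * b**w2 with w1 + w2 normalized to 1.

    Zero if either score is zero (an absent signal on one side annihilates
    the combination).
    """
    if a < 0 or b < 0:
        raise ParameterError("scores must be non-negative")
    w1, w2 = weights
    if w1 < 0 or w2 < 0 or w1 + w2 <= 0:
        raise ParameterError("weights must be non-negative, not both zero")
    if a == 0.0 or b == 0.0:
        return 0.0
    s = w1 + w2
    return math.exp((w1 / s) * math.log(a) + (w2 / s) * math.log(b))
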