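"""Drug/disease catalogs and the known drug-disease association set.

Catalogs map each drug to its target-protein node set T(d) and each disease
to its susceptibility-gene node set T(p).  Because real target and gene
annotations are incomplete, only entities with at least two nodes present in
the loaded network are retained; associations referencing a dropped entity
are dropped with them.  Filtering is a fixpoint of two monotone pruning
steps (drop out-of-network nodes, drop under-sized entities) and is therefore
order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator, Mapping, NamedTuple

from .exceptions import ParseError
from .network import GeneNetwork

MIN_NODES_PER_ENTITY = 2


class Catalogs(NamedTuple):
    """Filtered drug and disease catalogs (entity id -> frozenset of nodes)."""

    drugs: dict
    diseases: dict


class AssociationSet:
    """Known (drug, disease) pairs with per-entity partner indices."""

    def __init__(self, pairs: Iterable[tuple]):
        self._pairs = frozenset((str(d), str(p)) for d, p in pairs)
        self._by_disease: dict = {}
        self._by_drug: dict = {}
        for d, p in self._pairs:
            self._by_disease.setdefault(p, set()).add(d)
            self._by_drug.setdefault(d, set()).add(p)

    @property
    def pairs(self) -> frozenset:
        return self._pairs

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def __iter__(self) -> Iterator[tuple]:
        return iter(sorted(self._pairs))

    def __eq__(self, other) -> bool:
        return isinstance(other, AssociationSet) and self._pairs == other._pairs

    def __hash__(self) -> int:
        return hash(self._pairs)

    def drugs_for(self, disease) -> frozenset:
        """Drugs with a known association to *disease* (empty if none)."""
        return frozenset(self._by_disease.get(disease, ()))

    def diseases_for(self, drug) -> frozenset:
        """Diseases with a known association to *drug* (empty if none)."""
        return frozenset(self._by_drug.get(drug, ()))

    def drugs(self) -> frozenset:
        return frozenset(self._by_drug)

    def diseases(self) -> frozenset:
        return frozenset(self._by_disease)

    def difference(self, pairs: Iterable[tuple]) -> "AssociationSet":
        """A new association set with the given pairs removed (for strict CV)."""
        drop = frozenset(tuple(p) for p in pairs)
        return AssociationSet(self._pairs - drop)


@dataclass
class FilterReport:
    """Counts of what the in-network filters removed, step by step."""

    drug_nodes_in: int = 0
    drug_nodes_dropped: int = 0
    drugs_in: int = 0
    drugs_dropped: int = 0
    disease_nodes_in: int = 0
    disease_nodes_dropped: int = 0
    diseases_in: int = 0
    diseases_dropped: int = 0
    associations_in: int = 0
    associations_dropped: int = 0

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def read_pair_table(path) -> Iterator[tuple]:
    """Yield (col1, col2) rows from a two-column TSV with optional '#' header."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            a, b = (f.strip() for f in fields)
            if not a or not b:
                raise ParseError(f"{path}: line {lineno}: empty identifier")
            yield a, b


def _collect(pairs: Iterable[tuple]) -> dict:
    """Entity -> node set, silently deduplicating repeated rows."""
    out: dict = {}
    for entity, node in pairs:
        out.setdefault(str(entity), set()).add(str(node))
    return out


def _filter_catalog(raw: Mapping, net: GeneNetwork) -> tuple[dict, int, int]:
    """Drop out-of-network nodes, then entities with < 2 remaining nodes."""
    kept: dict = {}
    nodes_dropped = 0
    for entity in sorted(raw):
        in_net = frozenset(n for n in raw[entity] if n in net)
        nodes_dropped += len(raw[entity]) - len(in_net)
        if len(in_net) >= MIN_NODES_PER_ENTITY:
            kept[entity] = in_net
    return kept, nodes_dropped, len(raw) - len(kept)


def build_catalogs(
    drug_pairs: Iterable[tuple],
    disease_pairs: Iterable[tuple],
    assoc_pairs: Iterable[tuple],
    net: GeneNetwork,
) -> tuple[Catalogs, AssociationSet, FilterReport]:
    """Assemble filtered catalogs and the association set from raw rows.

    Returns the retained catalogs, the associations restricted to retained
    entities, and a :class:`FilterReport` of everything dropped on the way.
    An association set that filters down to empty is legal (a warning-level
    situation for callers, not an error).
    """
    report = FilterReport()

    raw_drugs = _collect(drug_pairs)
    report.drugs_in = len(raw_drugs)
    report.drug_nodes_in = sum(len(v) for v in raw_drugs.values())
    drugs, report.drug_nodes_dropped, report.drugs_dropped = _filter_catalog(raw_drugs, net)

    raw_dis = _collect(disease_pairs)
    report.diseases_in = len(raw_dis)
    report.disease_nodes_in = sum(len(v) for v in raw_dis.values())
    diseases, report.disease_nodes_dropped, report.diseases_dropped = _filter_catalog(
        raw_dis, net
    )

    raw_assoc = frozenset((str(d), str(p)) for d, p in assoc_pairs)
    report.associations_in = len(raw_assoc)
    kept_assoc = frozenset(
        (d, p) for d, p in raw_assoc if d in drugs and p in diseases
    )
    report.associations_dropped = len(raw_assoc) - len(kept_assoc)

    return Catalogs(drugs, diseases), AssociationSet(kept_assoc), report


def load_catalogs(
    drug_path, disease_path, assoc_path, net: GeneNetwork
) -> tuple[Catalogs, AssociationSet, FilterReport]:
    """File-based convenience wrapper around :func:`build_catalogs`."""
    return build_catalogs(
        read_pair_table(drug_path),
        read_pair_table(disease_path),
        read_pair_table(assoc_path),
        net,
    )
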