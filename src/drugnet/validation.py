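"""Post-hoc validation statistics.

Two independent checks on a prediction run:

* coverage enrichment — how many externally validated associations (e.g. a
  clinical-trial list) fall inside the predicted set, with a one-sided
  (upper-tail) Fisher exact test on the 2x2 predicted-by-validated table
  over the candidate universe;
* a structural-similarity screen — the fraction of (known drug, predicted
  drug) pairs whose fingerprint Tanimoto coefficient exceeds a threshold,
  verifying that predictions are not just structural look-alikes of known
  treatments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import fisher_exact

from .entities import AssociationSet
from .exceptions import ParameterError, ParseError, UnknownEntityError


def fisher_exact_one_sided(table) -> float:
    """Upper-tail Fisher exact p-value of a 2x2 contingency table.

    The probability, under fixed margins, of an overlap at least as large as
    observed (hypergeometric upper tail).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError(f"need a 2x2 table, got shape {t.shape}")
    if np.any(t < 0):
        raise ParameterError("contingency table entries must be non-negative")
    if not np.all(t == t.astype(int)):
        raise ParameterError("contingency table entries must be integers")
    return float(fisher_exact(t.astype(int), alternative="greater").pvalue)


@dataclass
class CoverageReport:
    """2x2 predicted-by-validated table, coverage fraction, Fisher p-value."""

    table: tuple  # ((a, b), (c, d)): rows predicted/not, cols validated/not
    coverage: float
    p_value: float
    n_predicted: int
    n_validation: int
    n_universe: int

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "table": [list(r) for r in self.table],
                    "coverage": self.coverage,
                    "p_value": self.p_value,
                    "n_predicted": self.n_predicted,
                    "n_validation": self.n_validation,
                    "n_universe": self.n_universe,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def coverage_report(
    predicted: Iterable, validation: Iterable, universe: Iterable
) -> CoverageReport:
    """Enrichment of an external validation set inside the predicted set.

    coverage = |predicted ∩ validation| / |validation| — the fraction of
    validated associations the prediction recovered.  The p-value is the
    one-sided Fisher exact test of the 2x2 table over the universe.
    """
    universe = frozenset(tuple(x) for x in universe)
    predicted = frozenset(tuple(x) for x in predicted)
    validation = frozenset(tuple(x) for x in validation)
    if not predicted <= universe:
        raise ParameterError("predicted set must be contained in the universe")
    if not validation <= universe:
        raise ParameterError("validation set must be contained in the universe")
    a = len(predicted & validation)
    b = len(predicted) - a
    c = len(validation) - a
    d = len(universe) - a - b - c
    coverage = a / len(validation) if validation else float("nan")
    p = fisher_exact_one_sided([[a, b], [c, d]])
    return CoverageReport(
        table=((a, b), (c, d)),
        coverage=coverage,
        p_value=p,
        n_predicted=len(predicted),
        n_validation=len(validation),
        n_universe=len(universe),
    )


# -- fingerprint similarity ------------------------------------------------


def tanimoto(a: Iterable, b: Iterable) -> float:
    """Tanimoto (Jaccard) coefficient |a ∩ b| / |a ∪ b| of two bitsets."""
    a, b = frozenset(a), frozenset(b)
    if not a and not b:
        raise ParameterError("Tanimoto of two empty bitsets is undefined")
    return len(a & b) / len(a | b)


def fraction_similar(
    pairs: Iterable, fingerprints: Mapping, threshold: float = 0.7
) -> float:
    """Fraction of drug pairs with Tanimoto coefficient strictly above threshold."""
    pairs = list(pairs)
    if not pairs:
        raise ParameterError("no drug pairs to compare")
    hits = 0
    for d1, d2 in pairs:
        for d in (d1, d2):
            if d not in fingerprints:
                raise UnknownEntityError(f"no fingerprint for drug {d!r}")
        if tanimoto(fingerprints[d1], fingerprints[d2]) > threshold:
            hits += 1
    return hits / len(pairs)


def known_vs_predicted_drug_pairs(
    predicted: Iterable, assoc: AssociationSet
) -> list:
    """(known drug, predicted drug) pairs sharing a disease.

    For every predicted (drug, disease) association, pair the predicted drug
    with each drug already known to treat that disease.  These are the pairs
    screened for structural similarity.
    """
    out = set()
    for d, p in predicted:
        for known in assoc.drugs_for(p):
            if known != d:
                out.add(tuple(sorted((known, d))))
    return sorted(out)


def read_fingerprints(path, hex_mode: bool = False) -> dict:
    """Load drug fingerprints from TSV: drug_id TAB bit spec.

    Default dialect: comma-separated indices of set bits.  ``hex_mode``: a
    hex string whose set bits (MSB first) are the fingerprint.
    """
    fps: dict = {}
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
            drug, spec = fields[0].strip(), fields[1].strip()
            try:
                if hex_mode:
                    width = len(spec) * 4
                    value = int(spec, 16)
                    bits = frozenset(
                        width - 1 - i for i in range(width) if value >> i & 1
                    )
                else:
                    bits = frozenset(int(x) for x in spec.split(",") if x.strip())
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad bit spec: {exc}") from exc
            fps[drug] = bits
    return fps


def write_fingerprints(fps: Mapping, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#drug\tbits\n")
        for drug in sorted(fps):
            fh.write(f"{drug}\t{','.join(str(b) for b in sorted(fps[drug]))}\n")
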