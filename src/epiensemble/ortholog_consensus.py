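"""Consensus ortholog calling under the two-of-three evidence rule.

Three independent ortholog-assignment methods (a reciprocal-best-hit search
plus two external database call tables) each either name an ortholog for an
ensemble gene or stay silent.  A gene receives a consensus ortholog only
when at least two methods name the *same* target gene — agreement at the
identifier level, not mere detection.  Genes where two methods disagree on
the target are flagged rather than called.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_formats import InputError

METHODS = ("mrbb", "db1", "db2")


class ConfigError(ValueError):
    pass


@dataclass
class EvidenceMatrix:
    """Per-gene ortholog calls from each of exactly three methods.

    ``calls[method][gene]`` is the called ortholog id; a missing key means
    the method made no call for that gene.
    """

    genes: list[str]
    calls: dict[str, dict[str, str]]  # method -> gene -> ortholog id

    def __post_init__(self) -> None:
        unknown = set(self.calls) - set(METHODS)
        if unknown:
            raise InputError(f"unknown evidence methods: {sorted(unknown)}")
        for m in METHODS:
            self.calls.setdefault(m, {})
        stray = {
            g for m in METHODS for g in self.calls[m] if g not in set(self.genes)
        }
        if stray:
            raise InputError(f"calls for genes not in the ensemble: {sorted(stray)[:5]}")

    def gene_calls(self, gene: str) -> dict[str, str]:
        return {m: self.calls[m][gene] for m in METHODS if gene in self.calls[m]}


@dataclass
class GeneConsensus:
    gene: str
    support_count: int            # number of methods making any call
    consensus_ortholog: str | None
    candidates: tuple[str, ...]   # all ids tied at the winning agreement level
    agreement: bool               # >= 2 supporting methods named the same id
    ambiguous: bool               # more than one id reached the threshold
    functional_class: str | None = None


@dataclass
class ConsensusCatalog:
    """Per-gene consensus results over the whole ensemble."""

    entries: dict[str, GeneConsensus]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_with_consensus(self) -> int:
        return sum(1 for e in self.entries.values() if e.consensus_ortholog)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": e.gene,
                "support_count": e.support_count,
                "consensus_ortholog": e.consensus_ortholog or "",
                "agreement": e.agreement,
                "ambiguous": e.ambiguous,
                "functional_class": e.functional_class or "",
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)


def call_consensus(
    evidence: EvidenceMatrix,
    min_support: int = 2,
    require_agreement: bool = True,
) -> ConsensusCatalog:
    """Apply the two-of-three rule (or ``min_support``-of-three).

    With ``require_agreement`` (default), at least ``min_support`` methods
    must name the same ortholog id; otherwise mere detection by
    ``min_support`` methods suffices and the majority id is reported.
    Genes tied between several ids at the threshold are kept with all
    candidates and flagged ambiguous.
    """
    if min_support not in (1, 2, 3):
        raise ConfigError(f"min_support must be 1, 2 or 3, got {min_support}")
    entries: dict[str, GeneConsensus] = {}
    for gene in evidence.genes:
        calls = evidence.gene_calls(gene)
        support = len(calls)
        counts = Counter(calls.values())
        top = counts.most_common()
        consensus: str | None = None
        candidates: tuple[str, ...] = ()
        agreement = False
        ambiguous = False
        if top:
            best_n = top[0][1]
            agreement = best_n >= 2
            threshold_met = (
                best_n >= min_support if require_agreement else support >= min_support
            )
            if threshold_met:
                winners = sorted(o for o, n in counts.items() if n == best_n)
                candidates = tuple(winners)
                ambiguous = len(winners) > 1
                consensus = winners[0]
        entries[gene] = GeneConsensus(
            gene=gene,
            support_count=support,
            consensus_ortholog=consensus,
            candidates=candidates,
            agreement=agreement,
            ambiguous=ambiguous,
        )
    return ConsensusCatalog(entries=entries)


def support_distribution(catalog: ConsensusCatalog) -> dict[int, int]:
    """Counts of genes by evidence-support level {3, 2, 1, 0}."""
    dist = {3: 0, 2: 0, 1: 0, 0: 0}
    for entry in catalog.entries.values():
        dist[entry.support_count] += 1
    return dist


def assign_classes(catalog: ConsensusCatalog, classes: dict[str, str]) -> None:
    """Attach a functional class to every gene (in place)."""
    for gene, entry in catalog.entries.items():
        if gene not in classes:
            raise InputError(f"gene {gene!r} has no functional class")
        entry.functional_class = classes[gene]


def class_accounting(
    catalog: ConsensusCatalog,
    class_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-functional-class counts: ensemble members vs consensus calls.

    Returns a DataFrame indexed by class with columns ``n_reference`` (genes
    in the reference-species ensemble) and ``n_with_consensus``, plus a
    ``TOTAL`` row.
    """
    counts: dict[str, list[int]] = {}
    for entry in catalog.entries.values():
        if entry.functional_class is None:
            raise InputError(f"gene {entry.gene!r} has no functional class assigned")
        row = counts.setdefault(entry.functional_class, [0, 0])
        row[0] += 1
        if entry.consensus_ortholog:
            row[1] += 1
    order = class_order if class_order is not None else sorted(counts)
    unknown = set(counts) - set(order)
    if unknown:
        raise InputError(f"classes outside the given order: {sorted(unknown)}")
    df = pd.DataFrame(
        [(c, *counts.get(c, [0, 0])) for c in order],
        columns=["functional_class", "n_reference", "n_with_consensus"],
    ).set_index("functional_class")
    df.loc["TOTAL"] = [df["n_reference"].sum(), df["n_with_consensus"].sum()]
    return df


def conservation_rate(catalog: ConsensusCatalog) -> tuple[float, int]:
    """Percent of ensemble genes with a consensus ortholog.

    Returns ``(full_precision_percent, nearest_integer_percent)``.
    """
    if len(catalog) == 0:
        raise InputError("empty catalog")
    pct = 100.0 * catalog.n_with_consensus / len(catalog)
    return pct, round(pct)


def read_call_table(path: str | Path) -> dict[str, str]:
    """Read an external ortholog-call TSV (ensemble_gene, called_ortholog).

    Absent rows mean no call.  A header line is permitted.
    """
    calls: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in {"gene", "ensemble_gene"}:
                continue
            calls[parts[0]] = parts[1]
    return calls
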