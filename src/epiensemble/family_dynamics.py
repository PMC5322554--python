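"""Gene-family copy-number dynamics across a species panel.

Tabulates ortholog copy numbers per family and species against a reference
species, excludes apparent expansions whose extra copies sit on the
unplaced "UNKN" chromosome (likely assembly artifacts rather than real
duplications), calls expansion/contraction events, summarizes per-species
1:1 copy-number conservation, and flags retrocopies — intronless
(single-exon) paralogs of multi-exon genes, the signature of duplication by
retrotransposition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .homology import ScoringScheme, local_align
from .io_formats import GeneModel, InputError

logger = logging.getLogger("epiensemble")


@dataclass
class CopyNumberTable:
    """family x species integer copy counts with a designated reference."""

    copies: pd.DataFrame  # rows = families, columns = species
    reference_species: str

    def __post_init__(self) -> None:
        if self.reference_species not in self.copies.columns:
            raise InputError(
                f"reference species {self.reference_species!r} absent from table"
            )
        if (self.copies.to_numpy() < 0).any():
            raise InputError("negative copy counts")

    @property
    def families(self) -> list[str]:
        return list(self.copies.index)

    @property
    def species(self) -> list[str]:
        return list(self.copies.columns)


@dataclass(frozen=True)
class EventCall:
    family: str
    species: str
    direction: str  # "expansion" | "contraction"
    delta: int      # copies(species) - copies(reference)

    def __post_init__(self) -> None:
        if self.delta == 0:
            raise InputError("EventCall with delta == 0")
        expected = "expansion" if self.delta > 0 else "contraction"
        if self.direction != expected:
            raise InputError("direction does not match sign of delta")


@dataclass
class FamilyEventSummary:
    """Per-family dominant direction over the panel (ties flagged)."""

    directions: dict[str, str]          # family -> expansion|contraction|tie
    n_event_families: int
    n_expansions: int
    n_contractions: int
    n_ties: int


@dataclass
class ConservationSummary:
    per_species_pct: dict[str, float]
    min_pct: float
    mean_pct: float
    n_families: int


def build_copy_table(
    per_species_counts: dict[str, dict[str, int]],
    reference: str,
) -> CopyNumberTable:
    """Assemble the copy-number table from per-species family counts.

    ``per_species_counts[species][family]`` is the number of ortholog calls;
    families absent from a species get 0 copies.
    """
    if reference not in per_species_counts:
        raise InputError(f"reference species {reference!r} missing from catalogs")
    families = sorted({f for c in per_species_counts.values() for f in c})
    df = pd.DataFrame(
        {
            sp: [counts.get(f, 0) for f in families]
            for sp, counts in per_species_counts.items()
        },
        index=families,
    )
    return CopyNumberTable(copies=df, reference_species=reference)


def filter_unkn(
    table: CopyNumberTable,
    gene_models: dict[str, GeneModel],
    genes_by_family: dict[str, dict[str, list[str]]],
) -> tuple[CopyNumberTable, list[tuple[str, str]]]:
    """Discount above-reference copies whose gene models sit on "UNKN".

    ``genes_by_family[family][species]`` lists the counted gene ids.  For
    every (family, species) cell above the reference count, copies on the
    UNKN chromosome are removed from the count (down to at most the
    reference value is *not* enforced: every UNKN copy above reference is
    simply not counted).  Returns the filtered table and a removal log of
    (family, species) pairs.
    """
    df = table.copies.copy()
    removed: list[tuple[str, str]] = []
    for family in table.families:
        ref_count = int(df.loc[family, table.reference_species])
        for species in table.species:
            count = int(df.loc[family, species])
            if count <= ref_count:
                continue
            gene_ids = genes_by_family.get(family, {}).get(species, [])
            unkn = []
            for gid in gene_ids:
                gm = gene_models.get(gid)
                if gm is None:
                    raise InputError(f"no gene model for counted gene {gid!r}")
                if gm.chromosome == "UNKN":
                    unkn.append(gid)
            n_remove = min(len(unkn), count - ref_count)
            if n_remove:
                df.loc[family, species] = count - n_remove
                removed.append((family, species))
                logger.info(
                    "UNKN filter: %s in %s reduced by %d copy(ies)",
                    family, species, n_remove,
                )
    return CopyNumberTable(copies=df, reference_species=table.reference_species), removed


def detect_events(table: CopyNumberTable) -> tuple[list[EventCall], FamilyEventSummary]:
    """Call per-(family, species) events and classify families.

    A family's summary direction is the dominant one across species
    (relative to the reference); equal numbers of expansions and
    contractions are flagged as ties and counted in neither column.
    """
    events: list[EventCall] = []
    directions: dict[str, str] = {}
    for family in table.families:
        ref = int(table.copies.loc[family, table.reference_species])
        n_exp = n_con = 0
        for species in table.species:
            if species == table.reference_species:
                continue
            delta = int(table.copies.loc[family, species]) - ref
            if delta > 0:
                events.append(EventCall(family, species, "expansion", delta))
                n_exp += 1
            elif delta < 0:
                events.append(EventCall(family, species, "contraction", delta))
                n_con += 1
        if n_exp or n_con:
            if n_exp > n_con:
                directions[family] = "expansion"
            elif n_con > n_exp:
                directions[family] = "contraction"
            else:
                directions[family] = "tie"
    summary = FamilyEventSummary(
        directions=directions,
        n_event_families=len(directions),
        n_expansions=sum(1 for d in directions.values() if d == "expansion"),
        n_contractions=sum(1 for d in directions.values() if d == "contraction"),
        n_ties=sum(1 for d in directions.values() if d == "tie"),
    )
    return events, summary


def conservation_stats(
    table: CopyNumberTable,
    n_ensemble_families: int,
) -> ConservationSummary:
    """Per-species 1:1 copy-number conservation over the whole ensemble.

    For species s: pct(s) = 100 * (F - d(s)) / F where F is the ensemble
    family count and d(s) the number of table families whose copy count
    differs from the reference (families absent from the table are 1:1 by
    definition).
    """
    if n_ensemble_families < len(table.families):
        raise InputError(
            "n_ensemble_families smaller than the number of table families"
        )
    per_species: dict[str, float] = {}
    ref_col = table.copies[table.reference_species]
    for species in table.species:
        if species == table.reference_species:
            continue
        d = int((table.copies[species] != ref_col).sum())
        if d > n_ensemble_families:
            raise InputError("more differing families than ensemble families")
        per_species[species] = 100.0 * (n_ensemble_families - d) / n_ensemble_families
    values = list(per_species.values())
    return ConservationSummary(
        per_species_pct=per_species,
        min_pct=min(values),
        mean_pct=sum(values) / len(values),
        n_families=n_ensemble_families,
    )


def detect_retrocopies(
    paralog_pairs: list[tuple[str, str]],
    gene_models: dict[str, GeneModel],
    proteins: dict[str, str],
    min_identity: float = 0.5,
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, str]]:
    """Flag (parent, retrocopy) pairs among candidate paralog pairs.

    A pair qualifies when one gene has exactly one exon, the other at least
    two, and protein identity over the locally aligned region is at least
    ``min_identity``.  The single-exon member is the retrocopy.
    """
    scheme = scheme or ScoringScheme()
    out: list[tuple[str, str]] = []
    for g1, g2 in paralog_pairs:
        for g in (g1, g2):
            if g not in gene_models:
                raise InputError(f"missing gene model for {g!r}")
            if g not in proteins:
                raise InputError(f"missing protein sequence for {g!r}")
        n1, n2 = gene_models[g1].n_exons, gene_models[g2].n_exons
        if n1 == 1 and n2 >= 2:
            retro, parent = g1, g2
        elif n2 == 1 and n1 >= 2:
            retro, parent = g2, g1
        else:
            continue
        aln = local_align(proteins[parent], proteins[retro], scheme)
        if aln.n_aligned == 0:
            continue
        identity = aln.n_identical / aln.n_aligned
        if identity >= min_identity:
            out.append((parent, retro))
    return out
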