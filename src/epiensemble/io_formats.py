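"""Readers and writers for the external formats the pipeline touches.

Supported formats: FASTA (via Biopython), GFF3 gene models (gene/mRNA/exon
features), BLAST tabular hit tables (classic 12-column ``outfmt 6``), and
expression matrices as TSV.  All coordinates are 1-based inclusive, matching
the GFF3 and BLAST conventions; no conversions happen internally.

Validation is strict: duplicate sequence ids, residues outside the declared
alphabet, overlapping exons, and malformed hit-table lines raise
:class:`FormatError` naming the offending record or line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("epiensemble")

# IUPAC alphabets, ambiguity codes included.  Gaps are not sequence residues.
DNA_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}


class FormatError(ValueError):
    """A file violated the format contract (who/where is in the message)."""


class InputError(ValueError):
    """Semantically invalid input to an operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record with a declared alphabet."""

    id: str
    description: str
    residues: str
    alphabet: str  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.alphabet not in _ALPHABETS:
            raise InputError(f"unknown alphabet {self.alphabet!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        allowed = _ALPHABETS[self.alphabet]
        for pos, ch in enumerate(self.residues, start=1):
            if ch.upper() not in allowed:
                raise FormatError(
                    f"record {self.id!r}: illegal {self.alphabet} residue "
                    f"{ch!r} at position {pos}"
                )


@dataclass(frozen=True)
class GeneModel:
    """A gene with exon structure on a (possibly unplaced) chromosome.

    ``chromosome`` is taken verbatim from the source, so the literal
    ``"UNKN"`` used for unplaced contigs survives parsing — duplicates
    mapping there may be assembly artifacts rather than real expansions.
    """

    gene_id: str
    species: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_length: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if len(self.exons) < 1:
            raise FormatError(f"gene {self.gene_id!r}: no exons")
        if self.cds_length < 3:
            raise FormatError(f"gene {self.gene_id!r}: cds_length < 3")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise FormatError(
                    f"gene {self.gene_id!r}: exon start {start} > end {end}"
                )
            if start <= prev_end:
                raise FormatError(
                    f"gene {self.gene_id!r}: overlapping or unsorted exons"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column BLAST tabular hit table."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"hit {self.query_id}->{self.subject_id}: E < 0")
        if self.aln_length < 1:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: alignment length < 1"
            )
        if self.q_start > self.q_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: query coordinates unordered"
            )


@dataclass
class ExpressionMatrix:
    """Gene × condition abundance matrix (FPKM-like, non-negative)."""

    species: str
    values: pd.DataFrame  # rows = genes, columns = conditions

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            raise FormatError(f"{self.species}: duplicate gene ids")
        if df.columns.duplicated().any():
            raise FormatError(f"{self.species}: duplicate condition ids")
        if (df.to_numpy() < 0).any():
            raise FormatError(f"{self.species}: negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file, validating residues against *alphabet*.

    Record order is preserved.  Duplicate ids and illegal residues raise
    :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                description=rec.description,
                residues=str(rec.seq),
                alphabet=alphabet,
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def _gff3_attributes(col9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col9.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue  # unknown attribute shapes are ignored
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3_gene_models(path: str | Path, species: str = "") -> list[GeneModel]:
    """Parse gene/mRNA/exon features from a GFF3 file into :class:`GeneModel`.

    One mRNA per gene is expected; if several are present the first one (by
    file order) is used and a warning is logged.  The parse is insensitive to
    feature order within the file: exons are collected by Parent id and
    sorted before assembly.
    """
    genes: dict[str, dict] = {}          # gene_id -> {chrom, strand}
    mrna_parent: dict[str, str] = {}     # mrna_id -> gene_id
    mrna_order: dict[str, list[str]] = {}  # gene_id -> [mrna ids in file order]
    exons: dict[str, list[tuple[int, int]]] = {}  # mrna_id -> [(start, end)]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            if ftype not in {"gene", "mRNA", "exon"}:
                continue
            attrs = _gff3_attributes(attrs_s)
            if ftype == "gene":
                if "ID" not in attrs:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                genes[attrs["ID"]] = {"chromosome": chrom, "strand": strand}
            elif ftype == "mRNA":
                if "ID" not in attrs or "Parent" not in attrs:
                    raise FormatError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_parent[attrs["ID"]] = attrs["Parent"]
                mrna_order.setdefault(attrs["Parent"], []).append(attrs["ID"])
            else:  # exon
                if "Parent" not in attrs:
                    raise FormatError(f"{path}:{lineno}: exon feature without Parent")
                exons.setdefault(attrs["Parent"], []).append(
                    (int(start_s), int(end_s))
                )

    models: list[GeneModel] = []
    for gene_id, info in genes.items():
        mrnas = mrna_order.get(gene_id, [])
        if not mrnas:
            raise FormatError(f"{path}: gene {gene_id!r} has no mRNA")
        if len(mrnas) > 1:
            logger.warning(
                "%s: gene %s has %d mRNAs; using the first (%s)",
                path, gene_id, len(mrnas), mrnas[0],
            )
        mrna_id = mrnas[0]
        exon_list = sorted(exons.get(mrna_id, []))
        if not exon_list:
            raise FormatError(f"{path}: mRNA {mrna_id!r} has no exons")
        cds_length = sum(end - start + 1 for start, end in exon_list)
        models.append(
            GeneModel(
                gene_id=gene_id,
                species=species,
                chromosome=info["chromosome"],
                strand=info["strand"],
                exons=tuple(exon_list),
                cds_length=cds_length,
            )
        )
    return models


def write_gff3_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back out as gene/mRNA/exon GFF3 (simulator output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            g_start = gm.exons[0][0]
            g_end = gm.exons[-1][1]
            base = f"{gm.chromosome}\tepiensemble\t"
            tail = f"\t.\t{gm.strand}\t."
            fh.write(f"{base}gene\t{g_start}\t{g_end}{tail}\tID={gm.gene_id}\n")
            mrna_id = f"{gm.gene_id}.t1"
            fh.write(
                f"{base}mRNA\t{g_start}\t{g_end}{tail}\tID={mrna_id};Parent={gm.gene_id}\n"
            )
            for start, end in gm.exons:
                fh.write(f"{base}exon\t{start}\t{end}{tail}\tParent={mrna_id}\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6) hit tables
# ---------------------------------------------------------------------------

_HIT_COLUMNS = 12


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Read a classic 12-column BLAST tabular file."""
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(cols)}"
                )
            try:
                records.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        e_value=float(cols[10]),
                        bit_score=float(cols[11]),
                    )
                )
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        f"{r.pct_identity:.2f}",
                        str(r.aln_length),
                        str(r.mismatches),
                        str(r.gap_opens),
                        str(r.q_start),
                        str(r.q_end),
                        str(r.s_start),
                        str(r.s_end),
                        f"{r.e_value:.6g}",
                        f"{r.bit_score:.6g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, species: str) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column gene id, header row of
    condition ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(species=species, values=df)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
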