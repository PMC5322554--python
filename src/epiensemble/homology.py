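"""Desk-scale protein similarity search and reciprocal-best ortholog calling.

The search engine performs optimal Smith-Waterman local alignment with
affine gaps (via Biopython's PairwiseAligner) over all query x subject
pairs, converts raw scores to E-values with the ungapped Karlin-Altschul
formula (E = K*m*n*exp(-lambda*S)), and keeps hits below an E-value
threshold (default 1e-10).  The E-values are approximate — the acceptance
checks rely on planted relative contrasts, never on absolute agreement with
NCBI BLAST.

Ortholog calling implements the "modified" reciprocal-best rule: a pair
(a, b) is called when hits exist in both directions below the threshold and
either b is a's best forward hit or a is b's best reverse hit.  This
relaxation permits many-to-one calls for genes with multiple homologs in
the other species; a ``strict`` mode requires both conditions (classic
reciprocal best hit).  "Best" means the numerically lowest E-value, with
ties broken by descending bit score, then lexicographic subject id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import HitRecord, InputError, SequenceRecord

# Karlin-Altschul parameters for BLOSUM62 with typical gapped defaults.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = DEFAULT_LAMBDA
    karlin_k: float = DEFAULT_K
    matrix: object = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise InputError("Karlin-Altschul parameters must be positive")
        if self.matrix is None:
            self.matrix = substitution_matrices.load(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])


@dataclass(frozen=True)
class OrthologPair:
    """One called ortholog pair with the supporting E-values."""

    gene_a: str
    gene_b: str
    source: str = "mrbb"
    e_ab: float = float("nan")
    e_ba: float = float("nan")


@dataclass(frozen=True)
class AlignmentResult:
    raw_score: float
    q_span: tuple[int, int]   # 1-based inclusive on query; (0, 0) if empty
    s_span: tuple[int, int]
    n_aligned: int            # aligned columns (including gaps)
    n_identical: int
    n_mismatches: int
    n_gap_opens: int


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def local_align(query: str, subject: str, scheme: ScoringScheme | None = None
                ) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns the raw score and the aligned spans/statistics of one optimal
    alignment.  All-negative scoring pairs score 0 with empty spans.
    """
    if not query or not subject:
        raise InputError("empty sequence")
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme)
    score = float(aligner.score(query, subject))
    if score <= 0:
        return AlignmentResult(0.0, (0, 0), (0, 0), 0, 0, 0, 0)
    aln = next(iter(aligner.align(query, subject)))
    q_blocks, s_blocks = aln.aligned
    n_identical = n_mismatch = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for qi, si in zip(range(qs, qe), range(ss, se)):
            if query[qi] == subject[si]:
                n_identical += 1
            else:
                n_mismatch += 1
    q_start = int(q_blocks[0][0]) + 1
    q_end = int(q_blocks[-1][1])
    s_start = int(s_blocks[0][0]) + 1
    s_end = int(s_blocks[-1][1])
    n_gap_opens = 2 * (len(q_blocks) - 1)  # each block break opens one gap
    # columns = matched residues + gapped columns
    gap_cols = (q_end - q_start + 1 - sum(qe - qs for qs, qe in q_blocks)) + (
        s_end - s_start + 1 - sum(se - ss for ss, se in s_blocks)
    )
    n_aligned = n_identical + n_mismatch + gap_cols
    return AlignmentResult(
        raw_score=score,
        q_span=(q_start, q_end),
        s_span=(s_start, s_end),
        n_aligned=n_aligned,
        n_identical=n_identical,
        n_mismatches=n_mismatch,
        n_gap_opens=n_gap_opens,
    )


def evalue(raw_score: float, query_len: int, db_len: int,
           scheme: ScoringScheme | None = None) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    if raw_score < 0:
        raise InputError("raw_score must be >= 0")
    scheme = scheme or ScoringScheme()
    return scheme.karlin_k * query_len * db_len * math.exp(
        -scheme.karlin_lambda * raw_score
    )


def bit_score(raw_score: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_k)) / math.log(2)


def search(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-10,
) -> list[HitRecord]:
    """All-pairs local-alignment search, reporting hits with E < ``e_max``.

    Output is sorted by (query id, ascending E-value).  The database length
    for the E-value is the total residue count of the subject set.
    """
    if not queries or not subjects:
        raise InputError("empty sequence set")
    scheme = scheme or ScoringScheme()
    aligner = _make_aligner(scheme)
    db_len = sum(len(s.residues) for s in subjects)
    hits: list[HitRecord] = []
    for q in queries:
        for s in subjects:
            score = float(aligner.score(q.residues, s.residues))
            if score <= 0:
                continue
            e = evalue(score, len(q.residues), db_len, scheme)
            if not (e < e_max):
                continue
            aln = local_align(q.residues, s.residues, scheme)
            pct = 100.0 * aln.n_identical / aln.n_aligned if aln.n_aligned else 0.0
            hits.append(
                HitRecord(
                    query_id=q.id,
                    subject_id=s.id,
                    pct_identity=pct,
                    aln_length=max(aln.n_aligned, 1),
                    mismatches=aln.n_mismatches,
                    gap_opens=aln.n_gap_opens,
                    q_start=aln.q_span[0],
                    q_end=aln.q_span[1],
                    s_start=aln.s_span[0],
                    s_end=aln.s_span[1],
                    e_value=e,
                    bit_score=bit_score(score, scheme),
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.e_value, -h.bit_score, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# MRBB
# ---------------------------------------------------------------------------

def _hit_sort_key(h: HitRecord) -> tuple:
    # "best" = most significant: ascending E, then descending bit score,
    # then lexicographic subject id — deterministic
    return (h.e_value, -h.bit_score, h.subject_id)


def _best_by_query(hits: list[HitRecord]) -> dict[str, str]:
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or _hit_sort_key(h) < _hit_sort_key(cur):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def mrbb(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    mode: str = "modified",
    species_of: dict[str, str] | None = None,
) -> list[OrthologPair]:
    """Call ortholog pairs from two directional hit tables.

    ``hits_ab`` are species-A queries against species-B subjects and
    ``hits_ba`` the reverse; both must already satisfy the E-value cutoff.
    In ``modified`` mode (default) a pair is called when hits exist in both
    directions and at least one direction is a best hit; ``strict`` mode is
    classic reciprocal best hit.  If ``species_of`` is given, within-species
    pairs in either table raise an error.
    """
    if mode not in {"modified", "strict"}:
        raise InputError(f"unknown MRBB mode {mode!r}")
    if species_of is not None:
        for h in hits_ab + hits_ba:
            if species_of.get(h.query_id) == species_of.get(h.subject_id):
                raise InputError(
                    f"within-species hit {h.query_id} -> {h.subject_id}"
                )
    forward: dict[tuple[str, str], float] = {}
    for h in hits_ab:
        key = (h.query_id, h.subject_id)
        if key not in forward or h.e_value < forward[key]:
            forward[key] = h.e_value
    reverse: dict[tuple[str, str], float] = {}
    for h in hits_ba:
        key = (h.query_id, h.subject_id)
        if key not in reverse or h.e_value < reverse[key]:
            reverse[key] = h.e_value
    best_fwd = _best_by_query(hits_ab)   # a -> best b
    best_rev = _best_by_query(hits_ba)   # b -> best a

    pairs: set[tuple[str, str]] = set()
    for (a, b) in forward:
        if (b, a) not in reverse:
            continue
        fwd_best = best_fwd.get(a) == b
        rev_best = best_rev.get(b) == a
        if (mode == "modified" and (fwd_best or rev_best)) or (
            mode == "strict" and fwd_best and rev_best
        ):
            pairs.add((a, b))
    return [
        OrthologPair(
            gene_a=a, gene_b=b, source="mrbb",
            e_ab=forward[(a, b)], e_ba=reverse[(b, a)],
        )
        for a, b in sorted(pairs)
    ]


def mrbb_all_pairs(
    proteins: dict[str, list[SequenceRecord]],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-10,
    mode: str = "modified",
) -> list[OrthologPair]:
    """Run search + MRBB over every unordered species pair."""
    species = sorted(proteins)
    out: list[OrthologPair] = []
    for i, sp_a in enumerate(species):
        for sp_b in species[i + 1 :]:
            hits_ab = search(proteins[sp_a], proteins[sp_b], scheme, e_max)
            hits_ba = search(proteins[sp_b], proteins[sp_a], scheme, e_max)
            out.extend(mrbb(hits_ab, hits_ba, mode=mode))
    return out
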