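"""Pairwise dN/dS estimation with saturation filtering.

Rates are estimated with the Nei-Gojobori (1986) counting method: per-codon
synonymous/nonsynonymous site fractions (averaged over the two sequences,
with changes to stop codons excluded from the site denominators),
difference counts averaged over all single-step mutational paths that avoid
stop codons, and Jukes-Cantor correction d = -(3/4)ln(1 - (4/3)p).  This is
a counting estimator, not a maximum-likelihood codon model: it is fully
specifiable and checkable against exhaustive enumeration at desk scale, and
all reported rates are labeled as NG86 estimates.

Estimates are excluded from downstream averages when synonymous divergence
is saturated (dS > 1, or the Jukes-Cantor correction diverges at
p >= 3/4) or absent (dS = 0), mirroring standard practice for comparisons
at moderate divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
from Bio.Align import PairwiseAligner
from scipy import stats

from .homology import ScoringScheme
from .io_formats import InputError
from .synthetic_data import STOP_CODONS, translate_cds, translate_codon

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Aligned CDS rows with gaps in whole-codon units."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise InputError("codon alignment rows differ in length")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise InputError("codon alignment length not divisible by 3")
        for rid, row in zip(self.ids, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != "---":
                    raise InputError(
                        f"{rid}: gap not in whole-codon units at column {i // 3}"
                    )

    @property
    def n_codon_columns(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon_column(self, j: int) -> list[str]:
        return [row[3 * j : 3 * j + 3] for row in self.rows]


def thread_codon_alignment(
    protein_alignment: list[tuple[str, str]],
    cds_by_id: dict[str, str],
) -> CodonAlignment:
    """Back-thread a protein alignment onto the coding sequences.

    Each protein row must translate exactly from its CDS (a trailing stop on
    the CDS is trimmed); every amino-acid column maps to one codon column
    and protein gaps become whole-codon gaps.
    """
    ids: list[str] = []
    rows: list[str] = []
    for seq_id, aligned in protein_alignment:
        if seq_id not in cds_by_id:
            raise InputError(f"no CDS for aligned sequence {seq_id!r}")
        cds = cds_by_id[seq_id]
        protein = translate_cds(cds)
        if protein.endswith("*"):
            protein = protein[:-1]
            cds = cds[:-3]
        ungapped = aligned.replace("-", "")
        if len(ungapped) != len(protein):
            raise InputError(
                f"{seq_id}: aligned protein has {len(ungapped)} residues, "
                f"CDS translates to {len(protein)}"
            )
        for pos, (a, b) in enumerate(zip(ungapped, protein), start=1):
            if a != b:
                raise InputError(
                    f"{seq_id}: translation mismatch at residue {pos} "
                    f"({a!r} in alignment vs {b!r} from CDS)"
                )
        out = []
        k = 0
        for ch in aligned:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        ids.append(seq_id)
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=rows)


def filter_columns(aln: CodonAlignment, min_occupancy: float = 0.6) -> CodonAlignment:
    """Drop codon columns with non-gap occupancy below ``min_occupancy``.

    A column exactly at the threshold is kept ("at least" semantics); column
    order is preserved.
    """
    n_rows = len(aln.rows)
    kept: list[int] = []
    for j in range(aln.n_codon_columns):
        present = sum(1 for codon in aln.codon_column(j) if codon != "---")
        if present / n_rows >= min_occupancy:
            kept.append(j)
    if not kept:
        raise InputError("occupancy filter removed every column")
    rows = [
        "".join(row[3 * j : 3 * j + 3] for j in kept) for row in aln.rows
    ]
    return CodonAlignment(ids=list(aln.ids), rows=rows)


def align_proteins_global(
    protein_a: str,
    protein_b: str,
    scheme: ScoringScheme | None = None,
) -> tuple[str, str]:
    """Global (Needleman-Wunsch) protein alignment, gapped strings out."""
    scheme = scheme or ScoringScheme()
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    aln = next(iter(aligner.align(protein_a, protein_b)))
    a, b = str(aln[0]), str(aln[1])
    return a, b


# ---------------------------------------------------------------------------
# NG86 counting machinery
# ---------------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@lru_cache(maxsize=None)
def codon_site_fractions(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each position contributes the fraction of its non-stop single-nucleotide
    changes that are synonymous; changes to stop codons are excluded from
    the denominator, so the two counts always sum to exactly 3.  With the
    default ``kappa=1`` this is the classic NG86 count; ``kappa > 1``
    weights transitions by the transition/transversion ratio (in the spirit
    of yn00's mutational-opportunity correction), for use when the
    underlying mutation bias is known.
    """
    if codon in STOP_CODONS:
        raise InputError(f"stop codon {codon!r} has no site counts")
    aa = translate_codon(codon)
    s = 0.0
    for i in range(3):
        syn_w = valid_w = 0.0
        for b in _BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if alt in STOP_CODONS:
                continue
            w = kappa if b == _TRANSITION[codon[i]] else 1.0
            valid_w += w
            if translate_codon(alt) == aa:
                syn_w += w
        if valid_w:
            s += syn_w / valid_w
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_path_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Averaged over all orderings of the differing positions whose
    intermediate codons avoid stops; if every path passes through a stop the
    average falls back to all paths.  Symmetric in its arguments.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid_paths: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff):
        current = codon_a
        syn = non = 0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if translate_codon(current) == translate_codon(nxt):
                syn += 1
            else:
                non += 1
            current = nxt
        all_paths.append((syn, non))
        if not through_stop:
            valid_paths.append((syn, non))
    paths = valid_paths or all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; diverges at p >= 3/4."""
    if p < 0:
        raise InputError("proportion below 0")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class RateEstimate:
    """NG86 pairwise rate estimate with exclusion flags."""

    dn: float
    ds: float
    omega: float | None
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int
    excluded: str  # "none" | "ds_saturated" | "ds_zero"

    @property
    def usable(self) -> bool:
        return self.excluded == "none"


def _comparable(codon: str) -> bool:
    return (
        len(codon) == 3
        and all(b in _BASES for b in codon)
        and codon not in STOP_CODONS
    )


def ng86_pairwise(codons_a: str, codons_b: str,
                  kappa: float = 1.0) -> RateEstimate:
    """NG86 dN/dS between two equal-length coding sequences.

    Codon pairs where either side is gapped, ambiguous or a stop codon are
    skipped pairwise.  Saturation (dS > 1 or a diverging correction) and
    absent synonymous divergence (dS = 0) set the exclusion flag; omega is
    defined only when no exclusion applies.  ``kappa`` feeds the optional
    transition-weighted site counting (1 = classic NG86).
    """
    if len(codons_a) != len(codons_b):
        raise InputError("sequences differ in length")
    if len(codons_a) % 3 != 0:
        raise InputError("sequence length not divisible by 3")
    s_sites = n_sites = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(codons_a), 3):
        ca, cb = codons_a[i : i + 3], codons_b[i : i + 3]
        if not (_comparable(ca) and _comparable(cb)):
            continue
        n_codons += 1
        sa, na = codon_site_fractions(ca, kappa)
        sb, nb = codon_site_fractions(cb, kappa)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        dsd, dnd = codon_path_differences(ca, cb)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        raise InputError("no comparable codons")

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)

    if math.isinf(ds) or ds > 1.0:
        excluded = "ds_saturated"
    elif ds == 0.0:
        excluded = "ds_zero"
    else:
        excluded = "none"
    omega = dn / ds if excluded == "none" and not math.isinf(dn) else None
    return RateEstimate(
        dn=dn, ds=ds, omega=omega,
        n_sites=n_sites, s_sites=s_sites, nd=nd, sd=sd,
        n_codons=n_codons, excluded=excluded,
    )


def rate_for_cds_pair(
    cds_a: str,
    cds_b: str,
    min_occupancy: float = 0.6,
    scheme: ScoringScheme | None = None,
    kappa: float = 1.0,
) -> RateEstimate:
    """Protein-align, back-thread, occupancy-filter, then NG86."""
    pa = translate_cds(cds_a).rstrip("*")
    pb = translate_cds(cds_b).rstrip("*")
    ga, gb = align_proteins_global(pa, pb, scheme)
    aln = thread_codon_alignment([("a", ga), ("b", gb)], {"a": cds_a, "b": cds_b})
    aln = filter_columns(aln, min_occupancy)
    return ng86_pairwise(aln.rows[0], aln.rows[1], kappa=kappa)


# ---------------------------------------------------------------------------
# Paralog contrast and group comparison
# ---------------------------------------------------------------------------

@dataclass
class ParalogContrast:
    estimate_1: RateEstimate
    estimate_2: RateEstimate
    more_diverged: str  # "paralog1" | "paralog2" | "tie"


def paralog_rate_contrast(
    reference_cds: str,
    paralog1_cds: str,
    paralog2_cds: str,
    min_occupancy: float = 0.6,
) -> ParalogContrast:
    """Rates of two paralogs against a common reference ortholog.

    Mirrors the pairwise comparison used to contrast a retrotransposed copy
    (typically saturated in dS) with its spliced sibling.
    """
    est1 = rate_for_cds_pair(reference_cds, paralog1_cds, min_occupancy)
    est2 = rate_for_cds_pair(reference_cds, paralog2_cds, min_occupancy)
    if est1.ds > est2.ds:
        more = "paralog1"
    elif est2.ds > est1.ds:
        more = "paralog2"
    else:
        more = "tie"
    return ParalogContrast(estimate_1=est1, estimate_2=est2, more_diverged=more)


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    ns: tuple[int, int]
    n_excluded: tuple[int, int]
    t_statistic: float
    p_value: float


def compare_groups(
    estimates_a: list[RateEstimate],
    estimates_b: list[RateEstimate],
    labels: tuple[str, str] = ("group_a", "group_b"),
) -> GroupComparison:
    """Welch two-sample t-test on usable omega values of two gene sets."""
    omegas_a = [e.omega for e in estimates_a if e.usable and e.omega is not None]
    omegas_b = [e.omega for e in estimates_b if e.usable and e.omega is not None]
    if len(omegas_a) < 2 or len(omegas_b) < 2:
        raise InputError("each group needs >= 2 usable omega values")
    a = np.asarray(omegas_a, dtype=float)
    b = np.asarray(omegas_b, dtype=float)
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        t_stat, p_val = 0.0, 1.0  # degenerate identical groups
    else:
        t_stat, p_val = stats.ttest_ind(a, b, equal_var=False)
    sem_a = float(stats.sem(a)) if len(a) > 1 else 0.0
    sem_b = float(stats.sem(b)) if len(b) > 1 else 0.0
    return GroupComparison(
        labels=labels,
        means=(float(a.mean()), float(b.mean())),
        sems=(sem_a, sem_b),
        ns=(len(a), len(b)),
        n_excluded=(len(estimates_a) - len(a), len(estimates_b) - len(b)),
        t_statistic=float(t_stat),
        p_value=float(p_val),
    )
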