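"""Synthetic multi-species gene families with known ground truth.

The generator emulates a small panel of dipteran genomes carrying a curated
gene ensemble: families evolve along a user-supplied species tree with
duplication, loss and retrotransposition events; coding sequences evolve
under an accept/reject codon process with a controllable dN/dS (omega); and
per-species expression matrices carry a planted two-class (high/low)
structure with lognormal noise.  Every stochastic draw flows from a single
integer seed, so fixed-seed runs are bit-identical.

The module also bundles hard-coded fixtures transcribing the published
ensemble accounting (functional-class catalog, family copy-number table
across twelve mosquito species, and the per-gene evidence-support
distribution), which downstream bookkeeping is tested against.

The codon process is deliberately simple: per-site nucleotide proposals with
a transition/transversion weight kappa, synonymous proposals always
accepted, nonsynonymous accepted with probability min(1, omega), proposals
creating stop codons rejected.  This is an accept/reject scheme, not a full
codon rate matrix; its realized substitution counts are recorded so rate
estimators can be checked against the simulation truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import (
    ExpressionMatrix,
    GeneModel,
    InputError,
    SequenceRecord,
    write_fasta,
    write_gff3_gene_models,
)
from .ortholog_consensus import EvidenceMatrix

logger = logging.getLogger("epiensemble")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))  # 61 codons

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

_CHROMOSOMES = ("2L", "2R", "3L", "3R", "X")


def translate_codon(codon: str) -> str:
    """Translate one codon; '*' for stops."""
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def translate_cds(cds: str) -> str:
    if len(cds) % 3 != 0:
        raise InputError("CDS length not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


class ConfigError(ValueError):
    """Simulation configuration is unusable (e.g. unreadable tree)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExpressionConfig:
    """Two-class expression model: lognormal abundances around class means.

    Defaults emulate a four-stage developmental series (two larval stages,
    adult male, adult female) with FPKM-like units: the high class at a
    median of 100, the low class at 1, lognormal noise sd 0.5 (natural-log
    scale).  ``swap_fraction`` is the fraction of orthologs whose class
    differs between species, emulating the minority of genes observed to
    change expression group between fly and mosquito.
    """

    n_stages: int = 4
    high_mean: float = 100.0
    low_mean: float = 1.0
    lognormal_sd: float = 0.5
    swap_fraction: float = 0.0
    #: Amplitude (natural-log scale) of the class-specific temporal
    #: signature.  Genes of a class share a stage profile (the high class
    #: declining across stages, the low class rising); without this shared
    #: shape, correlation-based clustering would carry no class signal at
    #: all, since Pearson distance is location-invariant.  The signature is
    #: mean-zero across stages, so the geometric mean stays at the class
    #: mean.
    stage_amplitude: float = 1.0


@dataclass
class SimulationConfig:
    """Parameters of the gene-family simulator.

    Rates are events per unit branch length (substitutions/site).  ``omega``
    is the family dN/dS; the default 0.1 matches the strong purifying regime
    typical of chromatin-modifier ensembles.
    """

    species_tree: str = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);"
    n_families: int = 50
    dup_rate: float = 0.0
    loss_rate: float = 0.0
    retro_rate: float = 0.0
    omega: float = 0.1
    kappa: float = 2.0
    codons_per_gene: int = 100
    exons_per_gene: int = 4
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    unkn_fraction: float = 0.0  # fraction of extra copies placed on "UNKN"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.expression, dict):
            self.expression = ExpressionConfig(**self.expression)
        for name in ("dup_rate", "loss_rate", "retro_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.omega <= 0:
            raise ConfigError("omega must be > 0")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        if self.codons_per_gene < 50:
            raise ConfigError("codons_per_gene must be >= 50")
        if self.exons_per_gene < 2:
            raise ConfigError("exons_per_gene must be >= 2")
        if not (0.0 <= self.expression.swap_fraction <= 1.0):
            raise ConfigError("swap_fraction must be in [0, 1]")
        if not (0.0 <= self.unkn_fraction <= 1.0):
            raise ConfigError("unkn_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonEvolutionResult:
    """Descendant CDS plus the realized substitution record."""

    descendant: str
    n_syn_subs: int
    n_nonsyn_subs: int
    n_proposals: int


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Uniform random sense codons (no stops), GC bias 0.5."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def evolve_codons(
    ancestor_cds: str,
    branch_length: float,
    omega: float,
    kappa: float,
    seed: int | np.random.Generator,
) -> CodonEvolutionResult:
    """Evolve a CDS along a branch under the accept/reject codon process.

    Proposals arrive as a Poisson process at rate 1 per nucleotide site per
    unit branch length; the alternative base is a transition with weight
    ``kappa`` and each transversion with weight 1.  Synonymous proposals are
    always accepted, so the expected synonymous divergence approximately
    equals ``branch_length``; nonsynonymous proposals are accepted with
    probability min(1, omega); proposals creating stop codons are rejected.
    """
    if len(ancestor_cds) % 3 != 0:
        raise InputError("ancestor CDS length not divisible by 3")
    protein = translate_cds(ancestor_cds)
    if "*" in protein:
        raise InputError("ancestor CDS contains an internal stop codon")
    if branch_length < 0:
        raise InputError("branch_length must be >= 0")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = list(ancestor_cds)
    n_nt = len(seq)
    n_proposals = int(rng.poisson(n_nt * branch_length))
    p_transition = kappa / (kappa + 2.0)
    n_syn = n_nonsyn = 0

    for _ in range(n_proposals):
        pos = int(rng.integers(0, n_nt))
        old = seq[pos]
        if rng.random() < p_transition:
            new = _TRANSITION[old]
        else:
            choices = [b for b in _BASES if b != old and b != _TRANSITION[old]]
            new = choices[int(rng.integers(0, 2))]
        codon_start = (pos // 3) * 3
        codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = codon[: pos - codon_start] + new + codon[pos - codon_start + 1 :]
        if new_codon in STOP_CODONS:
            continue
        if translate_codon(codon) == translate_codon(new_codon):
            seq[pos] = new
            n_syn += 1
        elif rng.random() < min(1.0, omega):
            seq[pos] = new
            n_nonsyn += 1

    return CodonEvolutionResult(
        descendant="".join(seq),
        n_syn_subs=n_syn,
        n_nonsyn_subs=n_nonsyn,
        n_proposals=n_proposals,
    )


# ---------------------------------------------------------------------------
# Gene-tree simulation along the species tree
# ---------------------------------------------------------------------------

@dataclass
class _GeneNode:
    """Node of the simulated gene tree.

    ``kind`` is ``speciation``, ``duplication`` or ``leaf``; duplication
    nodes created by a retro event carry ``retro_child`` pointing at the
    newborn (intronless) subtree.
    """

    kind: str
    children: list["_GeneNode"] = field(default_factory=list)
    gene_id: str = ""
    species: str = ""
    is_retro: bool = False
    retro_child: "_GeneNode | None" = None

    def leaves(self) -> list["_GeneNode"]:
        if self.kind == "leaf":
            return [self]
        out: list[_GeneNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class GroundTruth:
    """The planted answer key for one simulation run."""

    # family -> species -> list of gene ids present at the tips
    families: dict[str, dict[str, list[str]]]
    # all cross-species gene pairs whose last common ancestor was a
    # speciation (co-orthology included); pairs stored sorted
    ortholog_pairs: set[tuple[str, str]]
    # expected tip-level event calls relative to the reference species,
    # UNKN-placed copies excluded: (family, species, direction)
    events: list[tuple[str, str, str]]
    # (parent_gene, retro_gene, species)
    retrocopies: list[tuple[str, str, str]]
    true_omega: dict[str, float]          # family -> omega
    expression_class: dict[str, str]      # gene id -> "high" | "low"
    reference_species: str
    copy_counts: pd.DataFrame             # family x species, UNKN excluded

    def ortholog_map_one_to_one(self) -> dict[tuple[str, str], str]:
        """(family, species) -> gene id; defined only for 1:1 simulations."""
        out: dict[tuple[str, str], str] = {}
        for fam, by_sp in self.families.items():
            for sp, genes in by_sp.items():
                if len(genes) != 1:
                    raise InputError("one-to-one map undefined with events")
                out[(fam, sp)] = genes[0]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "families": self.families,
            "ortholog_pairs": sorted(map(list, self.ortholog_pairs)),
            "events": self.events,
            "retrocopies": self.retrocopies,
            "true_omega": self.true_omega,
            "expression_class": self.expression_class,
            "reference_species": self.reference_species,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimulationOutput:
    """In-memory result of :func:`simulate_families`."""

    sequences: dict[str, list[SequenceRecord]]   # species -> CDS records
    proteins: dict[str, list[SequenceRecord]]    # species -> protein records
    gene_models: dict[str, list[GeneModel]]      # species -> gene models
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in sorted(self.sequences):
            write_fasta(self.sequences[sp], outdir / f"{sp}.cds.fasta")
            write_fasta(self.proteins[sp], outdir / f"{sp}.protein.fasta")
            write_gff3_gene_models(self.gene_models[sp], outdir / f"{sp}.gff3")
        self.ground_truth.to_json(outdir / "ground_truth.json")


def _parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise ConfigError(f"unreadable species tree: {exc}") from exc
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise ConfigError("species tree needs at least 2 leaves")
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ConfigError("species tree has an unlabeled leaf")
    return tree


def _simulate_family_tree(
    family_id: str,
    tree: dendropy.Tree,
    cfg: SimulationConfig,
    omega: float,
    rng: np.random.Generator,
    sequences: dict[str, str],
    counter: list[int],
) -> _GeneNode | None:
    """Recursively grow one family's gene tree over the species tree.

    Extra copies born on an edge (duplications, retrocopies) inherit the
    evolved sequence at the end of the edge verbatim; their divergence
    accrues on the branches below.  A loss event removes the whole lineage
    below that edge.
    """

    def at_node(sp_node, seq: str, is_retro: bool) -> _GeneNode | None:
        if sp_node.is_leaf():
            species = sp_node.taxon.label
            counter[0] += 1
            gid = f"{family_id}_{species}_g{counter[0]}"
            sequences[gid] = seq
            return _GeneNode(kind="leaf", gene_id=gid, species=species,
                             is_retro=is_retro)
        kids = []
        for child in sp_node.child_nodes():
            sub = along_edge(child, seq, is_retro)
            if sub is not None:
                kids.append(sub)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return _GeneNode(kind="speciation", children=kids)

    def along_edge(sp_child, seq: str, is_retro: bool) -> _GeneNode | None:
        length = sp_child.edge.length or 0.0
        if cfg.loss_rate > 0 and rng.poisson(cfg.loss_rate * length) >= 1:
            return None
        res = evolve_codons(seq, length, omega, cfg.kappa, rng)
        evolved = res.descendant
        n_dup = int(rng.poisson(cfg.dup_rate * length)) if cfg.dup_rate else 0
        n_retro = int(rng.poisson(cfg.retro_rate * length)) if cfg.retro_rate else 0
        top = at_node(sp_child, evolved, is_retro)
        for _ in range(n_dup):
            extra = at_node(sp_child, evolved, is_retro)
            top = _join_duplication(top, extra)
        for _ in range(n_retro):
            extra = at_node(sp_child, evolved, True)
            top = _join_duplication(top, extra, retro=True)
        return top

    def _join_duplication(top, extra, retro: bool = False):
        if extra is None:
            return top
        if top is None:
            return extra
        node = _GeneNode(kind="duplication", children=[top, extra])
        if retro:
            node.retro_child = extra
        return node

    return at_node(tree.seed_node, random_cds(cfg.codons_per_gene, rng), False)


def _ortholog_pairs(root: _GeneNode) -> set[tuple[str, str]]:
    """Cross-species leaf pairs whose LCA is a speciation node."""
    pairs: set[tuple[str, str]] = set()

    def walk(node: _GeneNode) -> list[_GeneNode]:
        if node.kind == "leaf":
            return [node]
        child_leaves = [walk(c) for c in node.children]
        if node.kind == "speciation":
            for i in range(len(child_leaves)):
                for j in range(i + 1, len(child_leaves)):
                    for a in child_leaves[i]:
                        for b in child_leaves[j]:
                            if a.species != b.species:
                                pairs.add(tuple(sorted((a.gene_id, b.gene_id))))
        return [leaf for sub in child_leaves for leaf in sub]

    walk(root)
    return pairs


def _retrocopy_pairs(root: _GeneNode) -> list[tuple[str, str, str]]:
    """(parent, retrocopy, species) pairs from retro-birth duplication nodes."""
    out: list[tuple[str, str, str]] = []

    def walk(node: _GeneNode) -> None:
        if node.kind == "leaf":
            return
        if node.retro_child is not None:
            retro_leaves = [l for l in node.retro_child.leaves() if l.is_retro]
            parent_side = [c for c in node.children if c is not node.retro_child]
            parent_leaves = [
                l for c in parent_side for l in c.leaves() if not l.is_retro
            ]
            by_species: dict[str, _GeneNode] = {}
            for l in parent_leaves:
                by_species.setdefault(l.species, l)
            for rl in retro_leaves:
                pl = by_species.get(rl.species)
                if pl is not None:
                    out.append((pl.gene_id, rl.gene_id, rl.species))
        for c in node.children:
            walk(c)

    walk(root)
    return out


def simulate_families(config: SimulationConfig) -> SimulationOutput:
    """Simulate the whole gene panel; deterministic for a fixed seed."""
    tree = _parse_tree(config.species_tree)
    rng = np.random.default_rng(config.seed)
    species = [l.taxon.label for l in tree.leaf_node_iter()]
    reference = species[0]

    families: dict[str, dict[str, list[str]]] = {}
    ortholog_pairs: set[tuple[str, str]] = set()
    retrocopies: list[tuple[str, str, str]] = []
    true_omega: dict[str, float] = {}
    expression_class: dict[str, str] = {}
    sequences: dict[str, str] = {}
    leaf_info: dict[str, _GeneNode] = {}

    for i in range(config.n_families):
        fam = f"fam{i:03d}"
        counter = [0]
        root = _simulate_family_tree(fam, tree, config, config.omega, rng,
                                     sequences, counter)
        true_omega[fam] = config.omega
        by_sp: dict[str, list[str]] = {sp: [] for sp in species}
        if root is not None:
            for leaf in root.leaves():
                by_sp[leaf.species].append(leaf.gene_id)
                leaf_info[leaf.gene_id] = leaf
            ortholog_pairs |= _ortholog_pairs(root)
            retrocopies.extend(_retrocopy_pairs(root))
        families[fam] = by_sp

        # two-class expression with per-species swaps relative to reference
        fam_class = "high" if rng.random() < 0.5 else "low"
        for sp in species:
            for gid in by_sp[sp]:
                cls = fam_class
                if sp != reference and rng.random() < config.expression.swap_fraction:
                    cls = "low" if cls == "high" else "high"
                expression_class[gid] = cls

    for sp in species:
        if all(not families[f][sp] for f in families):
            logger.warning("species %s lost every family", sp)

    # chromosome placement and gene models
    gene_models: dict[str, list[GeneModel]] = {sp: [] for sp in species}
    cds_records: dict[str, list[SequenceRecord]] = {sp: [] for sp in species}
    protein_records: dict[str, list[SequenceRecord]] = {sp: [] for sp in species}
    on_unkn: set[str] = set()
    offsets: dict[tuple[str, str], int] = {}

    for fam in families:
        for sp in species:
            for k, gid in enumerate(families[fam][sp]):
                leaf = leaf_info[gid]
                extra_copy = k > 0 or leaf.is_retro
                if extra_copy and rng.random() < config.unkn_fraction:
                    chrom = "UNKN"
                    on_unkn.add(gid)
                else:
                    chrom = _CHROMOSOMES[int(rng.integers(0, len(_CHROMOSOMES)))]
                cds = sequences[gid]
                n_exons = 1 if leaf.is_retro else config.exons_per_gene
                start = offsets.get((sp, chrom), 1000) + int(rng.integers(0, 500))
                exons = _split_exons(start, len(cds), n_exons)
                offsets[(sp, chrom)] = exons[-1][1] + 5000
                gene_models[sp].append(
                    GeneModel(
                        gene_id=gid,
                        species=sp,
                        chromosome=chrom,
                        strand="+",
                        exons=tuple(exons),
                        cds_length=len(cds),
                    )
                )
                cds_records[sp].append(
                    SequenceRecord(id=gid, description="", residues=cds,
                                   alphabet="dna")
                )
                protein_records[sp].append(
                    SequenceRecord(id=gid, description="",
                                   residues=translate_cds(cds),
                                   alphabet="protein")
                )

    # ground-truth copy counts after UNKN discounting: copies above the
    # reference count that sit on UNKN are not counted (the artifact
    # filter's semantics), so event recovery under perfect calls is exact
    counts = pd.DataFrame(0, index=sorted(families), columns=species)
    for fam in families:
        for sp in species:
            counts.loc[fam, sp] = len(families[fam][sp])
    for fam in families:
        ref_n = int(counts.loc[fam, reference])
        for sp in species:
            if sp == reference:
                continue
            c = int(counts.loc[fam, sp])
            if c > ref_n:
                n_unkn = sum(1 for g in families[fam][sp] if g in on_unkn)
                counts.loc[fam, sp] = c - min(n_unkn, c - ref_n)
    events: list[tuple[str, str, str]] = []
    for fam in sorted(families):
        ref_n = int(counts.loc[fam, reference])
        for sp in species:
            if sp == reference:
                continue
            delta = int(counts.loc[fam, sp]) - ref_n
            if delta > 0:
                events.append((fam, sp, "expansion"))
            elif delta < 0:
                events.append((fam, sp, "contraction"))

    truth = GroundTruth(
        families=families,
        ortholog_pairs=ortholog_pairs,
        events=events,
        retrocopies=retrocopies,
        true_omega=true_omega,
        expression_class=expression_class,
        reference_species=reference,
        copy_counts=counts,
    )
    return SimulationOutput(
        sequences=cds_records,
        proteins=protein_records,
        gene_models=gene_models,
        ground_truth=truth,
    )


def _split_exons(start: int, cds_len: int, n_exons: int) -> list[tuple[int, int]]:
    """Split a CDS into n contiguous exons separated by 100-nt introns."""
    base = cds_len // n_exons
    sizes = [base] * n_exons
    sizes[-1] += cds_len - base * n_exons
    exons = []
    pos = start
    for size in sizes:
        exons.append((pos, pos + size - 1))
        pos += size + 100
    return exons


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    ground_truth: GroundTruth,
    config: SimulationConfig,
    seed: int,
) -> dict[str, ExpressionMatrix]:
    """Per-species expression matrices realizing the planted classes.

    Values are lognormal around the class median (``high_mean`` or
    ``low_mean``); with ``lognormal_sd == 0`` every value equals its class
    mean exactly.
    """
    rng = np.random.default_rng(seed)
    expr = config.expression
    stages = [f"stage{i+1}" for i in range(expr.n_stages)]
    # mean-zero temporal signature shared within a class; the two classes
    # get opposite shapes so profile correlation separates them
    t_idx = np.arange(expr.n_stages)
    signature = expr.stage_amplitude * np.cos(
        np.pi * t_idx / max(expr.n_stages - 1, 1)
    )
    out: dict[str, ExpressionMatrix] = {}
    species = list(ground_truth.copy_counts.columns)
    for sp in species:
        genes = [
            g
            for fam in sorted(ground_truth.families)
            for g in ground_truth.families[fam][sp]
        ]
        rows = []
        for g in genes:
            if ground_truth.expression_class[g] == "high":
                log_means = np.log(expr.high_mean) + signature
            else:
                log_means = np.log(expr.low_mean) - signature
            if expr.lognormal_sd == 0:
                vals = np.exp(log_means)
            else:
                vals = np.exp(
                    rng.normal(log_means, expr.lognormal_sd)
                )
            rows.append(vals)
        df = pd.DataFrame(rows, index=genes, columns=stages)
        out[sp] = ExpressionMatrix(species=sp, values=df)
    return out


# ---------------------------------------------------------------------------
# Printed-table fixtures
# ---------------------------------------------------------------------------

#: Functional-class catalog: (class, ensemble members in the fly reference,
#: orthologous members called in the mosquito reference), 17 classes.
ENSEMBLE_CATALOG: tuple[tuple[str, int, int], ...] = (
    ("Acetylation", 26, 22),
    ("Deacetylation", 7, 7),
    ("Methylation", 34, 31),
    ("Demethylation", 7, 7),
    ("DNA methylation", 2, 1),
    ("Ino80 complex", 9, 7),
    ("ACF complex", 4, 3),
    ("NURF complex", 3, 3),
    ("NuRD complex", 6, 6),
    ("Other complexes", 6, 6),
    ("Heterochromatin", 13, 8),
    ("Centromeric heterochromatin", 6, 4),
    ("Intercalary heterochromatin", 5, 3),
    ("Nuclear heterochromatin", 4, 3),
    ("Other heterochromatin", 14, 12),
    ("Ubiquitylation/phosphorylation", 14, 12),
    ("Set-N proteins and Misc.", 55, 34),
)

#: The twelve mosquito species of the copy-number table, reference first.
TABLE2_SPECIES: tuple[str, ...] = (
    "A. gambiae", "A. epiroticus", "A. stephensi", "A. funestus",
    "A. arabiensis", "A. albimanus", "A. dirus", "A. minimus",
    "A. quadriannulatus", "A. atroparvus", "A. merus", "A. farauti",
)

#: Family copy numbers across the twelve species (reference = A. gambiae).
TABLE2_COPIES: dict[str, tuple[int, ...]] = {
    "Cap-G":   (1, 1, 1, 1, 1, 1, 2, 1, 1, 1, 1, 1),
    "Parg":    (1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 1, 1),
    "CG18004": (1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 1, 1),
    "Orc2":    (1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 1, 1),
    "GRO":     (2, 1, 2, 2, 2, 2, 2, 2, 2, 2, 1, 2),
    "Effete":  (1, 1, 1, 2, 1, 2, 2, 2, 1, 2, 1, 2),
    "CC14":    (2, 2, 1, 1, 2, 1, 1, 1, 2, 1, 2, 1),
}

#: Evidence-support distribution over the 215-gene ensemble:
#: support level -> number of genes.
EVIDENCE_SUPPORT_COUNTS: dict[int, int] = {3: 146, 2: 23, 1: 10, 0: 36}

#: Multigene Set-N subfamily accounting: members in the fly reference and
#: how many lack a mosquito ortholog call (17/40 = 42.5% missing).
SET_N_TOTAL = 40
SET_N_MISSING = 17


@dataclass
class TableFixtures:
    """Hard-coded transcriptions of the published ensemble accounting."""

    ensemble_catalog: pd.DataFrame   # 17 classes x (n_dmel, n_agam)
    copy_table: pd.DataFrame         # 7 families x 12 species
    evidence_support: list[int]      # 215 per-gene support levels
    n_set_n: int = SET_N_TOTAL
    n_set_n_missing: int = SET_N_MISSING

    @property
    def set_n_missing_fraction(self) -> float:
        return 100.0 * self.n_set_n_missing / self.n_set_n


def make_table_fixtures() -> TableFixtures:
    """Return the printed-table fixtures used by the bookkeeping tests."""
    catalog = pd.DataFrame(
        [(c, d, a) for c, d, a in ENSEMBLE_CATALOG],
        columns=["functional_class", "n_dmel", "n_agam"],
    ).set_index("functional_class")
    copy_table = pd.DataFrame.from_dict(
        TABLE2_COPIES, orient="index", columns=list(TABLE2_SPECIES)
    )
    support: list[int] = []
    for level in (3, 2, 1, 0):
        support.extend([level] * EVIDENCE_SUPPORT_COUNTS[level])
    return TableFixtures(
        ensemble_catalog=catalog,
        copy_table=copy_table,
        evidence_support=support,
    )


def make_standard_evidence() -> tuple[EvidenceMatrix, dict[str, str]]:
    """Build the 215-gene evidence fixture and its class assignment.

    Gene order follows the functional-class catalog; within each class the
    called genes come first.  Support levels are distributed so that the
    ensemble-wide distribution is {3:146, 2:23, 1:10, 0:36}: the first 146
    called genes get support 3 and the rest support 2; the first 10 uncalled
    genes get a single (non-consensus) call and the rest none.
    """
    genes: list[str] = []
    classes: dict[str, str] = {}
    called_flags: list[bool] = []
    idx = 0
    for cls, n_dmel, n_agam in ENSEMBLE_CATALOG:
        for j in range(n_dmel):
            idx += 1
            gid = f"CG{idx:05d}"
            genes.append(gid)
            classes[gid] = cls
            called_flags.append(j < n_agam)

    calls: dict[str, dict[str, str]] = {"mrbb": {}, "db1": {}, "db2": {}}
    n_called_seen = 0
    n_uncalled_seen = 0
    for gid, called in zip(genes, called_flags):
        target = f"AGAP{gid[2:]}"
        if called:
            n_called_seen += 1
            if n_called_seen <= EVIDENCE_SUPPORT_COUNTS[3]:
                for m in ("mrbb", "db1", "db2"):
                    calls[m][gid] = target
            else:
                calls["mrbb"][gid] = target
                calls["db1"][gid] = target
        else:
            n_uncalled_seen += 1
            if n_uncalled_seen <= EVIDENCE_SUPPORT_COUNTS[1]:
                calls["mrbb"][gid] = target
    return EvidenceMatrix(genes=genes, calls=calls), classes
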