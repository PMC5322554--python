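# Methods

This note documents the models and procedures implemented in
`epiensemble`, the assumptions behind them, the parameters that matter, and
the limits of what the synthetic-data validation shows.

## Homology search and E-values

Protein similarity is computed by optimal Smith–Waterman local alignment
with affine gap penalties (BLOSUM62, gap open 11, extend 1), delegated to
Biopython's `PairwiseAligner`.  Raw scores are converted to E-values with
the ungapped Karlin–Altschul formula E = K·m·n·exp(−λS) using the typical
gapped BLOSUM62 parameters λ = 0.267, K = 0.041, where m is the query
length and n the total residue count of the subject set.  These E-values
are approximate — no edge-effect or length corrections — and are used only
to rank hits and to apply the significance cutoff (default E < 1e-10).
Nothing downstream depends on absolute agreement with NCBI BLAST; tests
rely on planted relative contrasts.

## Modified reciprocal-best ortholog calling (MRBB)

Classic reciprocal best hit (RBH) declares orthologs when two genes are
each other's most significant cross-species hit, which forces 1:1 calls.
The *modified* rule implemented here keeps the reciprocal-evidence
requirement (hits must exist in both directions below the E cutoff) but
calls the pair when **either** direction is a best hit.  This admits
many-to-one calls for genes with multiple homologs in the other species —
the behaviour needed when duplications are present.  "Best" means lowest
E-value, with ties broken by descending bit score and then lexicographic
subject id, so output is deterministic and invariant to hit-table row
order.  A `strict` mode restores plain RBH; every strict pair is provably
contained in the modified output.  Within-species and self hits are
rejected before calling.

## Consensus orthology (two-of-three rule)

Three evidence sources — the MRBB search and two external call tables
standing in for curated orthology databases — each either name an ortholog
for an ensemble gene or stay silent.  A consensus requires at least two
sources to name the *same* target identifier (agreement, not mere
detection); genes where two sources disagree are flagged rather than
called, and genes tied between several candidates are kept with all
candidates and marked ambiguous.  A `require_agreement=False` switch
relaxes this to presence-only support.  The support level of a gene is the
number of sources making any call (0–3).  The conservation rate is the
percentage of ensemble genes with a consensus, reported both at full
precision and rounded to the nearest integer.

## Family dynamics

Copy numbers are tabulated per family and species against a designated
reference species; families absent from a species count zero (a loss is a
contraction).  Apparent expansions whose extra copies sit on the unplaced
"UNKN" chromosome are discounted copy-by-copy down to the reference count
— unplaced contigs can duplicate sequence already present on placed
chromosomes, so such copies are treated as probable assembly artifacts,
and the filter logs each affected (family, species) cell.  Event calls are
per (family, species) with nonzero delta; the family-level summary uses
the dominant direction across species, with exact ties flagged separately
rather than counted in either column.

Per-species 1:1 conservation over an ensemble of F families is
100·(F − d)/F, where d counts table families whose copy number differs
from the reference (families absent from the table are 1:1 by
definition).  This formula is a reconstruction — validated against the
published per-species extremes (100% and 97.6%) — and one published
intermediate value (98.8% for the most divergent species pair) is not
reproducible from the printed copy-number table under any obvious variant
of the formula (the table implies three differing families, i.e. 98.2%);
that value is therefore not asserted anywhere.

Retrocopies are detected structurally: a candidate paralog pair is flagged
when one gene has exactly one exon, the other at least two, and protein
identity over the locally aligned region is at least 50%.  The single-exon
member is the retrocopy.  Identity is computed over aligned columns, not
global length, so a truncated retrocopy of a long parent still qualifies.

## Pairwise dN/dS (NG86)

Rates are estimated with the Nei–Gojobori (1986) counting method rather
than a maximum-likelihood codon model: the counting estimator is fully
specifiable, fast at desk scale, and exhaustively checkable (site and
difference counts are verified against independent path enumeration over
all 61×61 sense-codon pairs).  Conventions:

- **Sites.**  Each codon position contributes the fraction of its
  single-nucleotide changes that are synonymous; changes producing stop
  codons are excluded from the denominator.  Site counts are averaged over
  the two sequences, so n_sites + s_sites = 3 × compared codons exactly.
- **Differences.**  Codons differing at k positions are averaged over all
  k! single-step mutational paths that avoid stop codons; if every path
  passes through a stop (rare), the average falls back to all paths.
- **Correction.**  Proportions are corrected with Jukes–Cantor
  d = −(3/4)·ln(1 − (4/3)p), which diverges at p ≥ 3/4.
- **Exclusions.**  Estimates with dS > 1 (or a diverging correction) are
  flagged saturated; dS = 0 is flagged uninformative; ω is defined only
  for unflagged estimates.  Gapped, ambiguous or stop codons are skipped
  pairwise, not column-wise.
- **Transition bias.**  Classic NG86 weights all mutational opportunities
  equally, which under a transition/transversion bias κ > 1 systematically
  understates synonymous site counts and hence ω (about 12% relative at
  κ = 2).  An optional κ parameter weights the site counting by the
  mutational opportunity (in the spirit of yn00); the default κ = 1 is the
  classic estimator, and the κ-aware variant is used where the true
  mutation bias is known (e.g. against the simulator).

Codon alignments are produced by globally aligning the translated
proteins (Needleman–Wunsch, BLOSUM62) and back-threading the codons, with
exact translation validation; columns below 60% non-gap occupancy are then
removed ("at least" semantics: a column exactly at the threshold is kept).

Group rate comparisons report per-group mean and SEM of ω over usable
estimates and a Welch (unequal-variance) two-sample *t*-test; excluded
estimates are dropped and counted.  Degenerate identical groups are
reported as t = 0, p = 1 explicitly.

## Expression

Abundances can be mapped to the ordinal 0–6 scale via seven configurable
breakpoints (defaults log-spaced at 0, 1, 4, 16, 64, 256, 1024
FPKM-equivalents; no analysis depends on the defaults).  Two-class
clustering operates on log10(value + 0.01) profiles with 1 − Pearson *r*
distance and complete linkage, cutting the dendrogram into exactly two
clusters; the cluster with the higher grand-mean raw expression is "high".
Zero-variance profiles have no defined correlation distance and are
assigned to the "low" class directly (logged, not dropped).  On an exact
grand-mean tie the cluster holding the lexicographically first gene takes
"low", keeping labels deterministic.

Concordance counts ortholog pairs sharing their class across species;
n_same + n_diff always equals the map size.  Tissue comparisons normalize
each gene to a housekeeping reference gene per tissue (log10 ratio,
pseudocount 0.01) before PCA; PCA stacks the species-tagged gene rows as
observations over shared tissue columns, centres columns without scaling
(a `scale` flag exists), and takes variance fractions from squared
singular values.  The fold-change ANOVA is a one-way test across tissues
on per-pair log10 fold-changes, with the zero-within-variance degenerate
cases handled explicitly.

## Synthetic data generator

The generator emulates a small panel of related genomes carrying a curated
gene ensemble.  Families evolve along a user-supplied Newick species tree
(branch lengths in substitutions/site): on each branch, per-lineage
Poisson events duplicate the gene, delete the lineage, or create a
retrocopy; extra copies inherit the evolved sequence at the end of the
branch verbatim and diverge below it.  Retrocopies are emitted as
single-exon gene models; all other genes get a configurable multi-exon
structure.  A configurable fraction of extra copies is placed on "UNKN" to
exercise the artifact filter.  Ancestral sequences are uniform random
sense codons.

Codon evolution is an accept/reject scheme, not a full codon rate matrix:
proposals arrive at rate 1 per nucleotide site per unit branch length,
transitions weighted κ against transversions, synonymous proposals always
accepted, nonsynonymous accepted with probability min(1, ω), stop-creating
proposals rejected.  Expected synonymous divergence therefore
approximately equals branch length, and realized synonymous/nonsynonymous
substitution counts are recorded so estimators can be checked against the
simulation truth.

Expression profiles are lognormal around class medians (high 100, low 1,
sd 0.5 on the natural-log scale over four stages by default), with a
class-specific mean-zero temporal signature (high class declining across
stages, low class rising; amplitude 1.0 in log units).  The signature is
essential, not cosmetic: Pearson correlation distance is
location-invariant, so without a shared within-class profile shape the
two-class structure would be invisible to correlation clustering — as it
is in real data, where expression classes are coherent temporal patterns,
not just offsets.  A configurable fraction of orthologs swaps class
between species to emulate cross-species discordance.

The ground truth records the gene tree per family, every cross-species
gene pair whose last common ancestor is a speciation node (so co-orthologs
of duplicates are included), expected tip-level event calls (with
UNKN-placed copies discounted under the same semantics as the filter),
retrocopy parent/child pairs, per-gene expression classes, and the true ω.
All draws flow from one `numpy` generator, so fixed-seed runs are
byte-identical.

**What the generator does not emulate:** indels (orthology is exercised at
the hit-table level, alignments of simulated sequences are effectively
ungapped), intron sequence content, rate variation across sites and
branches, codon usage and GC bias, assembly and annotation error beyond
the UNKN placement, and correlated gene loss.  Recovery tests therefore
demonstrate internal consistency of the estimators under the generative
model, not performance on real genomes.

## Fixtures

Bookkeeping stages are additionally exercised on hard-coded fixtures
transcribing the published ensemble accounting: a 17-class functional
catalog (215 reference genes, 169 with mosquito orthologs), a
seven-family × twelve-species copy-number table, a 215-gene
evidence-support vector (146/23/10/36 at support 3/2/1/0), and the Set-N
subfamily tallies (17 of 40 members without an ortholog call, 42.5%).
These fixtures are inputs, not outputs: the tests verify that the
package's own consensus caller, event detector and conservation statistics
reproduce the published counts *from* them.

## Problem sizes and defaults

Default simulations use 50 families of 100 codons over a four-species
tree (total height ≈ 0.15–0.3 substitutions/site), chosen as the smallest
sizes at which ortholog calling, event detection and clustering behave
stably; ω-recovery checks use 3000-codon sequences at dS ≈ 0.3 so counting
noise is small against the 0.05 acceptance band.  Key defaults: E cutoff
1e-10, consensus support 2 of 3, occupancy 0.6, dS exclusion bounds
(0, 1], retrocopy identity 0.5, pseudocount 0.01, κ = 2 in the generator.

## Known limitations

- The counting estimator is not codeml: absolute ω values on real data
  would differ from maximum-likelihood estimates, particularly at high
  divergence or strong codon bias.
- E-values are ungapped-theory approximations applied to gapped scores.
- The modified-RBH rule's either-direction reading is one of two defensible
  interpretations; both are implemented, and the strict mode is the other.
- The per-species conservation formula is reconstructed from its published
  extremes (see above); one published intermediate value is inconsistent
  with the printed table and is not asserted.
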