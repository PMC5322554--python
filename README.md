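# epiensemble

Comparative analysis of an epigenetic gene ensemble across dipteran
genomes.  The package implements, as a tested desk-scale pipeline, the
workflow used to characterize the chromatin-modifier gene complement of
malaria mosquitoes against the fruit-fly reference:

- **Consensus orthology.** A modified reciprocal-best-hit search (MRBB)
  over protein similarity hit tables, combined with two external
  ortholog-call tables under a two-of-three evidence rule: a gene receives
  a consensus ortholog only when at least two of the three methods name the
  same target gene.
- **Gene-family dynamics.** Copy-number tabulation across a species panel,
  expansion/contraction event calling relative to a reference species, a
  filter discounting apparent duplicates on the unplaced "UNKN" chromosome
  (likely assembly artifacts), per-species 1:1 conservation statistics, and
  retrocopy detection (intronless paralogs of multi-exon genes).
- **Evolutionary rates.** Pairwise dN/dS by the Nei–Gojobori (NG86)
  counting method with Jukes–Cantor correction and the standard exclusion
  filters (dS > 1 saturated; dS = 0 uninformative), plus Welch *t*-test
  group comparisons of ω = dN/dS between gene sets.
- **Expression.** Two-class (high/low) hierarchical clustering of
  developmental expression profiles (1 − Pearson *r* distance, complete
  linkage), cross-species class concordance over an ortholog map,
  reference-gene-normalized tissue PCA, and tissue fold-change ANOVA.

Because the original genome-scale inputs (genome assemblies, RNA-seq,
ortholog databases) are not required, a first-class synthetic-data module
generates multi-species gene families with planted duplication, loss and
retrotransposition events, codon sequences evolved at a controlled ω, and
two-class expression profiles — every downstream stage is validated against
this planted ground truth.  Hard-coded fixtures additionally transcribe the
published ensemble accounting (functional-class catalog, family copy-number
table over twelve mosquito species, evidence-support distribution) so the
bookkeeping stages reproduce the published numbers exactly.

## Worked example

```python
from epiensemble import (
    call_consensus, support_distribution, conservation_rate,
    CopyNumberTable, detect_events, conservation_stats,
)
from epiensemble.synthetic_data import make_standard_evidence, make_table_fixtures

evidence, classes = make_standard_evidence()
catalog = call_consensus(evidence, min_support=2)
print(catalog.n_with_consensus)            # 169
print(support_distribution(catalog))       # {3: 146, 2: 23, 1: 10, 0: 36}
print(conservation_rate(catalog))          # (78.6046511627907, 79)

fx = make_table_fixtures()
table = CopyNumberTable(copies=fx.copy_table, reference_species="A. gambiae")
events, summary = detect_events(table)
print(summary.n_event_families,            # 7
      summary.n_expansions,                # 4
      summary.n_contractions)              # 3
stats = conservation_stats(table, n_ensemble_families=169)
print(stats.per_species_pct["A. arabiensis"])   # 100.0
print(round(stats.min_pct, 1))                  # 97.6
```

Reading: of the 215-gene reference ensemble, 169 genes receive a consensus
ortholog (79% conservation), with 146 genes supported by all three methods
and 36 by none.  Across the twelve-species panel, seven gene families show
copy-number events (four expansions, three contractions); one species pair
is perfectly 1:1 conserved and the least-conserved comparison still retains
97.6% of families at identical copy number.

A simulation-driven run of the whole pipeline:

```bash
epiensemble run --config config.yaml
```

with a YAML config selecting either `mode: fixtures` (the worked example
above) or `mode: simulation` (synthetic genomes with planted events and a
recovery-style report).  Individual stages are exposed as `epiensemble
search`, `mrbb`, `consensus`, `rates` and `cluster`.

## Documentation

`docs/methods.md` describes the models and estimators, the synthetic-data
generator and its limitations, all numerical choices, and the tunable
parameters with their defaults.
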