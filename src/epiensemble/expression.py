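"""Expression binning, two-class clustering, cross-species concordance,
reference-normalized PCA, and tissue fold-change ANOVA.

Genes are clustered on their developmental expression profiles with
1 - Pearson correlation distance and complete linkage, and the dendrogram
is cut into exactly two clusters; the cluster with the higher grand-mean
raw expression is the "high" class.  Concordance counts orthologs that fall
in the same class in both species.  Tissue comparisons first normalize each
gene to a reference gene (an actin housekeeping standard) per tissue and
work on log10 ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix, InputError

logger = logging.getLogger("epiensemble")

#: Default FPKM -> 0-6 scale breakpoints (log-spaced upper edges of bins
#: 0..5; values above the last edge map to 6).  Fully configurable.
DEFAULT_BREAKPOINTS = (0.0, 1.0, 4.0, 16.0, 64.0, 256.0, 1024.0)

DEFAULT_PSEUDOCOUNT = 0.01


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Binning to the 0-6 scale
# ---------------------------------------------------------------------------

def bin_expression(
    matrix: ExpressionMatrix,
    breakpoints: tuple[float, ...] = DEFAULT_BREAKPOINTS,
) -> pd.DataFrame:
    """Map abundances onto the ordinal 0-6 expression scale.

    ``breakpoints`` are the 7 ascending interval edges covering [0, inf):
    a value v falls in bin i when breakpoints[i] <= v < breakpoints[i+1],
    and in bin 6 when v >= breakpoints[6].  Larger values never get a
    smaller bin.
    """
    if len(breakpoints) != 7:
        raise ConfigError("exactly 7 breakpoints required")
    bp = np.asarray(breakpoints, dtype=float)
    if not np.all(np.diff(bp) > 0):
        raise ConfigError("breakpoints must be strictly increasing")
    values = matrix.values.to_numpy()
    bins = np.searchsorted(bp, values, side="right") - 1
    bins = np.clip(bins, 0, 6)
    return pd.DataFrame(bins, index=matrix.values.index,
                        columns=matrix.values.columns)


# ---------------------------------------------------------------------------
# Two-class hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ExpressionClassLabels:
    labels: dict[str, str]  # gene -> "high" | "low"
    linkage_method: str = "complete"
    distance: str = "pearson"


def cluster_two_class(
    matrix: ExpressionMatrix,
    log_transform: bool = True,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ExpressionClassLabels:
    """Cut a complete-linkage, correlation-distance dendrogram into the
    high/low expression classes.

    Profiles are log10(value + pseudocount) by default.  Zero-variance
    profiles have no defined Pearson distance; they are assigned to the
    "low" class directly and logged.  The cluster with the higher grand
    mean of raw expression is labeled "high"; on an exact tie the cluster
    holding the lexicographically first gene takes "low".
    """
    df = matrix.values
    if len(df) < 2:
        raise InputError("need at least 2 genes to cluster")
    if df.shape[1] < 2:
        raise InputError("need at least 2 conditions to cluster")
    data = np.log10(df.to_numpy(dtype=float) + pseudocount) if log_transform \
        else df.to_numpy(dtype=float)
    variances = data.var(axis=1)
    usable = variances > 0
    labels: dict[str, str] = {}
    degenerate = [g for g, ok in zip(df.index, usable) if not ok]
    for g in degenerate:
        labels[g] = "low"
    if degenerate:
        logger.info("assigned %d zero-variance profiles to the low class",
                    len(degenerate))
    sub = data[usable]
    genes = [g for g, ok in zip(df.index, usable) if ok]
    if len(genes) < 2:
        raise InputError("fewer than 2 genes with variable profiles")
    dist = pdist(sub, metric="correlation")  # 1 - Pearson r
    tree = linkage(dist, method="complete")
    assignment = fcluster(tree, t=2, criterion="maxclust")
    raw = df.to_numpy(dtype=float)[usable]
    means = {
        c: raw[assignment == c].mean() for c in np.unique(assignment)
    }
    if len(means) == 1:
        high_cluster = None  # degenerate single cluster: everyone low
    else:
        (c1, m1), (c2, m2) = sorted(means.items())
        if m1 == m2:
            # exact tie: the cluster holding the lexicographically first
            # gene is "low", the other "high" (deterministic)
            first = min(zip(genes, assignment))[1]
            high_cluster = c2 if first == c1 else c1
        else:
            high_cluster = c1 if m1 > m2 else c2
    for g, c in zip(genes, assignment):
        labels[g] = "high" if high_cluster is not None and c == high_cluster else "low"
    return ExpressionClassLabels(labels=labels)


# ---------------------------------------------------------------------------
# Cross-species concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    n_same: int
    n_diff: int
    n_same_high: int
    n_same_low: int
    discordant_by_class: dict[str, int]  # functional class -> count


def concordance(
    labels_a: ExpressionClassLabels,
    labels_b: ExpressionClassLabels,
    ortholog_map: list[tuple[str, str]],
    functional_classes: dict[str, str] | None = None,
) -> ConcordanceResult:
    """Count ortholog pairs sharing or swapping expression class.

    ``ortholog_map`` pairs genes of species A with genes of species B; the
    optional functional-class map (keyed by the species-A gene) breaks the
    discordant set down by category.
    """
    n_same = n_diff = n_hi = n_lo = 0
    by_class: dict[str, int] = {}
    for ga, gb in ortholog_map:
        if ga not in labels_a.labels:
            raise InputError(f"gene {ga!r} unlabeled in species A")
        if gb not in labels_b.labels:
            raise InputError(f"gene {gb!r} unlabeled in species B")
        la, lb = labels_a.labels[ga], labels_b.labels[gb]
        if la == lb:
            n_same += 1
            if la == "high":
                n_hi += 1
            else:
                n_lo += 1
        else:
            n_diff += 1
            if functional_classes is not None:
                cls = functional_classes.get(ga, "unclassified")
                by_class[cls] = by_class.get(cls, 0) + 1
    return ConcordanceResult(
        n_same=n_same, n_diff=n_diff,
        n_same_high=n_hi, n_same_low=n_lo,
        discordant_by_class=by_class,
    )


# ---------------------------------------------------------------------------
# Reference-gene normalization and PCA
# ---------------------------------------------------------------------------

def normalize_to_reference(
    matrix: ExpressionMatrix,
    ref_gene: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-tissue log10 ratios to a reference gene's expression.

    value(g, t) -> log10((value(g, t) + pseudocount) /
    (value(ref, t) + pseudocount)); the reference row maps to zeros.
    """
    df = matrix.values
    if ref_gene not in df.index:
        raise InputError(f"reference gene {ref_gene!r} absent")
    ref = df.loc[ref_gene].to_numpy(dtype=float)
    if pseudocount == 0 and (ref == 0).any():
        raise InputError(
            f"reference gene {ref_gene!r} has zero expression in a tissue "
            "and no pseudocount was given"
        )
    return np.log10((df + pseudocount).div(ref + pseudocount, axis=1))


@dataclass
class PCAResult:
    variance_fractions: np.ndarray   # descending, sums to 1
    loadings: pd.DataFrame           # tissues x components
    scores: pd.DataFrame             # observations x components


def pca_tissue(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    scale: bool = False,
) -> PCAResult:
    """PCA of pooled, species-tagged gene rows over shared tissue columns.

    Rows of the two (already normalized) matrices are stacked as
    observations with tissues as variables; columns are centred (and
    optionally scaled to unit variance); variance fractions come from the
    squared singular values.
    """
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise InputError("the two matrices must share tissue columns")
    if matrix_a.shape[1] < 2:
        raise InputError("need at least 2 tissues")
    stacked = pd.concat(
        [
            matrix_a.set_index("A:" + matrix_a.index.astype(str)),
            matrix_b.set_index("B:" + matrix_b.index.astype(str)),
        ]
    )
    x = stacked.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    comps = [f"PC{i+1}" for i in range(len(s))]
    return PCAResult(
        variance_fractions=fractions,
        loadings=pd.DataFrame(vt.T, index=stacked.columns, columns=comps),
        scores=pd.DataFrame(u * s, index=stacked.index, columns=comps),
    )


# ---------------------------------------------------------------------------
# Tissue fold-change ANOVA
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeAnova:
    per_tissue_mean: dict[str, float]  # mean log10(a/b) per tissue
    f_statistic: float
    p_value: float
    n_pairs: int


def tissue_fold_change_anova(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    ortholog_map: list[tuple[str, str]],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeAnova:
    """Per-tissue mean log10 fold-change over ortholog pairs plus a one-way
    ANOVA across tissues on the per-pair fold-changes."""
    tissues = list(matrix_a.values.columns)
    if tissues != list(matrix_b.values.columns):
        raise InputError("matrices must share tissue columns")
    if len(tissues) < 2:
        raise InputError("need at least 2 tissues")
    if len(ortholog_map) < 2:
        raise InputError("need at least 2 ortholog pairs")
    if pseudocount == 0:
        vb = matrix_b.values
        for _, gb in ortholog_map:
            if (vb.loc[gb] == 0).any():
                raise InputError(
                    f"zero denominator for {gb!r} and no pseudocount"
                )
    per_tissue: dict[str, list[float]] = {t: [] for t in tissues}
    for ga, gb in ortholog_map:
        a = matrix_a.values.loc[ga].to_numpy(dtype=float)
        b = matrix_b.values.loc[gb].to_numpy(dtype=float)
        fc = np.log10((a + pseudocount) / (b + pseudocount))
        for t, v in zip(tissues, fc):
            per_tissue[t].append(float(v))
    groups = [np.asarray(per_tissue[t]) for t in tissues]
    within_const = all(np.allclose(g, g.mean()) for g in groups)
    means_equal = np.allclose([g.mean() for g in groups],
                              groups[0].mean())
    if within_const:
        # degenerate cases scipy cannot express: no within-group variance
        f_stat, p_val = (0.0, 1.0) if means_equal else (math.inf, 0.0)
    else:
        f_stat, p_val = stats.f_oneway(*groups)
    return FoldChangeAnova(
        per_tissue_mean={t: float(np.mean(per_tissue[t])) for t in tissues},
        f_statistic=float(f_stat),
        p_value=float(p_val),
        n_pairs=len(ortholog_map),
    )
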