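"""Multivariate summaries and set statistics for differential-expression sets.

Covers the post-ANOVA toolkit: PCA variance partition over design factors,
k-means and Ward clustering of gene profiles, Venn region accounting,
hypergeometric overlap with a representation factor, term enrichment with
slim-ancestor mapping, two-count proportion tests, Fisher's exact test, and
relative-quantification statistics for qPCR validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .io_design import AnnotationMap
from .mixed_models import bh_adjust


def sample_gene_matrix(expr, design, transcripts=None) -> pd.DataFrame:
    """Samples x transcripts matrix of expression (or residual) values.

    Each hybridized sample is one channel; a transcript's value for a sample
    is the mean over its duplicate spots on that channel.  Missing cells
    yield NaN.
    """
    df = expr.values.join(design.spots.set_index("spot")["transcript"],
                          on="spot")
    ch = design.channels.set_index(["array", "dye"])["sample"]
    df = df.join(ch, on=["array", "dye"])
    mat = df.pivot_table(index="sample", columns="transcript",
                         values="intensity", aggfunc="mean")
    if transcripts is not None:
        mat = mat[[t for t in transcripts if t in mat.columns]]
    order = [s for s in design.channels["sample"] if s in mat.index]
    return mat.loc[order]


# --------------------------------------------------------------------------
# PCA variance partition
# --------------------------------------------------------------------------

@dataclass
class PCAPartition:
    variance_percent: np.ndarray       # % of total variance per component
    scores: np.ndarray                 # samples x components
    factor_r2: pd.DataFrame            # components x factors, R^2 of scores
    factor_assignment: list            # best factor per component
    sample_ids: list


def pca_partition(matrix: pd.DataFrame, design_labels: pd.DataFrame,
                  factors: list, n_components: int | None = None) -> PCAPartition:
    """Principal components of samples over a gene set, associated to factors.

    *matrix* is samples x genes (one row per sample); *design_labels* maps
    each sample (same row order) to factor levels.  Components are computed
    from the covariance of the mean-centered matrix, and each retained
    component is assigned the factor whose one-way dummy regression on its
    scores has the largest R^2.
    """
    X = np.asarray(matrix, dtype=float)
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    for f in factors:
        counts = design_labels[f].value_counts()
        if (counts < 2).any():
            raise ValueError(f"factor {f!r} has a level with fewer than 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    # SVD of the centered matrix == eigendecomposition of the covariance
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("matrix has zero variance")
    k = min(n_components or (n_samples - 1), len(s))
    scores = U[:, :k] * s[:k]
    pct = 100.0 * var[:k] / total

    r2 = np.zeros((k, len(factors)))
    for j, f in enumerate(factors):
        labels = pd.Categorical(design_labels[f])
        G = pd.get_dummies(labels).to_numpy(dtype=float)
        H = G @ np.linalg.pinv(G)          # projection onto group means
        for i in range(k):
            y = scores[:, i]
            ss_tot = float(((y - y.mean()) ** 2).sum())
            fitted = H @ y
            ss_fit = float(((fitted - y.mean()) ** 2).sum())
            r2[i, j] = ss_fit / ss_tot if ss_tot > 0 else 0.0
    r2_df = pd.DataFrame(r2, columns=list(factors),
                         index=[f"PC{i+1}" for i in range(k)])
    assignment = [factors[int(np.argmax(r2[i]))] for i in range(k)]
    index = list(matrix.index) if isinstance(matrix, pd.DataFrame) else list(
        range(n_samples))
    return PCAPartition(variance_percent=pct, scores=scores, factor_r2=r2_df,
                        factor_assignment=assignment, sample_ids=index)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def kmeans_clusters(matrix, k: int = 2, seed: int = 0,
                    n_restarts: int = 10, standardize: bool = True):
    """K-means on (optionally row-standardized) gene profiles.

    Returns (labels, inertia).  Rows with zero variance standardize to zero
    profiles; with all-identical rows every gene lands in one cluster and
    the remaining labels are unused.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows {X.shape[0]}")
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if np.allclose(X, X[0]):
        return np.zeros(X.shape[0], dtype=int), 0.0
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(X)
    return labels, float(km.inertia_)


def ward_tree(matrix) -> np.ndarray:
    """Ward-linkage dendrogram (scipy linkage matrix) over rows."""
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to build a tree")
    if np.isnan(X).any():
        raise ValueError("NaN rows are not allowed in hierarchical clustering")
    return hierarchy.linkage(X, method="ward")


# --------------------------------------------------------------------------
# set accounting
# --------------------------------------------------------------------------

def venn_counts(*sets) -> dict:
    """Disjoint region cardinalities for 2 or 3 labeled sets.

    Region keys are tuples of member flags, e.g. ('A',), ('A','B').  Sets
    are labeled A, B[, C] in argument order; regions sum to |union|.
    """
    if len(sets) not in (2, 3):
        raise ValueError("venn_counts takes 2 or 3 sets")
    labels = "ABC"[: len(sets)]
    sets = [set(s) for s in sets]
    universe = set().union(*sets)
    counts: dict = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            inside = set.intersection(*(sets[i] for i in combo))
            outside = set().union(*(sets[i] for i in range(len(sets))
                                    if i not in combo)) if len(combo) < len(
                                        sets) else set()
            counts[tuple(labels[i] for i in combo)] = len(inside - outside)
    assert sum(counts.values()) == len(universe)
    return counts


@dataclass
class OverlapResult:
    n1: int
    n2: int
    overlap: int
    universe: int
    representation_factor: float
    p_value: float


def hypergeom_overlap(n1: int, n2: int, overlap: int, universe: int) -> OverlapResult:
    """Upper-tail hypergeometric test of a two-list overlap.

    The representation factor RF = overlap / (n1*n2/N) is the observed
    overlap divided by its expectation under independent draws; the p-value
    is P(X >= overlap) for X ~ Hypergeom(N, n1, n2).
    """
    if not (0 <= n1 <= universe and 0 <= n2 <= universe):
        raise ValueError("list sizes must lie within the universe")
    if not (0 <= overlap <= min(n1, n2)):
        raise ValueError("overlap cannot exceed the smaller list")
    if overlap > universe or n1 + n2 - overlap > universe:
        raise ValueError("impossible overlap for this universe")
    expected = n1 * n2 / universe if universe > 0 else np.nan
    rf = overlap / expected if expected > 0 else np.nan
    p = float(stats.hypergeom.sf(overlap - 1, universe, n1, n2))
    return OverlapResult(n1=n1, n2=n2, overlap=overlap, universe=universe,
                         representation_factor=rf, p_value=p)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def proportion_test(count_a: int, count_b: int) -> dict:
    """Equal-split test for two counts (e.g. up- vs down-regulated genes).

    Returns the likelihood-ratio G statistic (headline), the Pearson
    chi-square variant, df=1, and p-values for both.  G is
    2*[a ln(2a/(a+b)) + b ln(2b/(a+b))].
    """
    a, b = int(count_a), int(count_b)
    if a < 0 or b < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0:
        raise ValueError("at least one count must be positive")
    n = a + b
    g = 0.0
    for c in (a, b):
        if c > 0:
            g += c * np.log(2.0 * c / n)
    g *= 2.0
    pearson = (a - n / 2) ** 2 / (n / 2) + (b - n / 2) ** 2 / (n / 2)
    return {
        "G": float(g), "p_G": float(stats.chi2.sf(g, 1)),
        "pearson_chi2": float(pearson),
        "p_pearson": float(stats.chi2.sf(pearson, 1)),
        "df": 1,
    }


# --------------------------------------------------------------------------
# enrichment and ancestor mapping
# --------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: pd.DataFrame                # term, k, n, K, N, p, q
    query_size: int
    background_size: int
    ease: bool = False

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> list:
        col = "q" if adjusted else "p"
        return list(self.table.loc[self.table[col] < alpha, "term"])


def enrich_terms(query, annotation: AnnotationMap, background,
                 ease: bool = False) -> EnrichmentResult:
    """Per-term upper-tail hypergeometric enrichment of *query* in *background*.

    With ease=True the conservative variant is used: the tail probability is
    computed with one observed hit removed (k-1), so single-gene hits are
    never significant.
    """
    background = set(background)
    query = set(query)
    if not background:
        raise ValueError("empty background")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    N = len(background)
    n = len(query)
    rows = []
    for term in sorted(annotation.terms):
        members = annotation.genes_for_term(term) & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        k_eff = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": p})
    table = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    table["q"] = bh_adjust(table["p"]) if len(table) else []
    return EnrichmentResult(table=table, query_size=n, background_size=N,
                            ease=ease)


@dataclass
class AncestorCounts:
    counts: dict                       # ancestor -> number of input terms
    n_assigned: int
    n_unassigned: int


def map_to_ancestors(terms, annotation: AnnotationMap) -> AncestorCounts:
    """Single-count slim mapping: each input term adds 1 to each ancestor.

    Input has list semantics — a term appearing twice is counted twice.
    Terms with no slim entry go to the unassigned bucket.
    """
    counts: dict = {}
    n_assigned = 0
    n_unassigned = 0
    for term in terms:
        ancestors = annotation.slim.get(term, set())
        if not ancestors:
            n_unassigned += 1
            continue
        n_assigned += 1
        for anc in ancestors:
            counts[anc] = counts.get(anc, 0) + 1
    return AncestorCounts(counts=counts, n_assigned=n_assigned,
                          n_unassigned=n_unassigned)


# --------------------------------------------------------------------------
# qPCR statistics
# --------------------------------------------------------------------------

def qpcr_relative(target, housekeeping, groups=None, reference_group=None):
    """Housekeeping-normalized relative expression.

    Each sample's target value is divided by the geometric mean of its
    housekeeping genes; when *groups* and *reference_group* are given, all
    values are rescaled so the reference group's mean is 1.
    """
    target = np.asarray(target, dtype=float)
    hk = np.asarray(housekeeping, dtype=float)
    if hk.ndim == 1:
        hk = hk[None, :] if hk.shape[0] != target.shape[0] else hk[:, None]
    if (hk <= 0).any():
        raise ValueError("housekeeping values must be positive")
    geo = np.exp(np.mean(np.log(hk), axis=1))
    rel = target / geo
    if reference_group is not None:
        groups = np.asarray(groups)
        ref_mean = rel[groups == reference_group].mean()
        if ref_mean == 0:
            raise ValueError("reference group mean is zero")
        rel = rel / ref_mean
    return rel


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis rank-sum H (tie-corrected) and its chi-square p."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) and all(
            len(set(a)) == 1 for a in arrays):
        return 0.0, 1.0
    try:
        h, p = stats.kruskal(*arrays)
    except ValueError:
        # scipy rejects the all-identical case; H is 0 by definition
        return 0.0, 1.0
    return float(h), float(p)
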