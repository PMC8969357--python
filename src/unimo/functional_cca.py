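"""Morphology–function network construction.

Starting from a mutants x features matrix of Wald Z values and a gene →
annotation-term mapping, this module:

1. filters the Boolean annotation matrix (terms annotating < 3 or > 199
   genes dropped; duplicate term columns collapsed; unannotated genes
   removed);
2. reduces both sides by PCA to the smallest number of components whose
   cumulative contribution ratio (CCR) reaches a threshold (default 95%
   phenotype / 99% function);
3. runs canonical correlation analysis between phenotype and function
   components, with Bartlett's sequential chi-squared test selecting the
   number of significant canonical pairs;
4. clusters genes into functional groups by complete-linkage hierarchical
   clustering on the binary (Jaccard) distance between annotation vectors,
   cut just below height 1, and assigns each group a representative term by
   Fisher's exact enrichment (Bonferroni-corrected);
5. tests every unordered group pair by a CCA of the groups' phenotype
   canonical-variable (pCV) score profiles (Bartlett test on the first
   canonical dimension, Bonferroni over all pairs);
6. builds the gene correlation network: Pearson r between pCV score
   vectors, cross-group edges kept only for significant group pairs and
   only at the maximum |r| of that pair (all other cross-group cells
   zero-filled), with a seeded force-directed 2-D embedding;
7. flags *core* groups (high network degree, split by a two-component
   Poisson mixture) and *dense* groups (small mean within-group embedding
   distance, split by a two-component gamma mixture) — the thresholds are
   data-derived mixture boundaries, not constants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "AnnotationMatrix",
    "PCAReduction",
    "CCAResult",
    "GeneGroup",
    "CorrelationNetwork",
    "build_annotation_matrix",
    "pca_reduce",
    "fit_cca",
    "cluster_gene_groups",
    "enrich_groups",
    "pairwise_group_cca",
    "build_correlation_network",
    "classify_core_dense",
    "n_unordered_pairs",
]


def n_unordered_pairs(n_groups: int) -> int:
    """Number of unordered group pairs, C(n, 2)."""
    return n_groups * (n_groups - 1) // 2


# ---------------------------------------------------------------------------
# annotation matrix

@dataclass
class AnnotationMatrix:
    matrix: pd.DataFrame               # genes x terms, bool
    filter_log: dict = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def terms(self) -> list[str]:
        return list(self.matrix.columns)


def build_annotation_matrix(gene_terms, min_genes: int = 3,
                            max_genes: int = 199) -> AnnotationMatrix:
    """Build and filter the genes x terms Boolean matrix.

    ``gene_terms`` is a {gene: iterable of terms} mapping or an iterable of
    (gene, term) pairs.  Terms annotating fewer than ``min_genes`` genes
    (unique terms) or more than ``max_genes`` (global terms) are dropped;
    duplicate term columns (identical gene sets) are collapsed keeping the
    first; genes left with no annotation are removed.
    """
    if hasattr(gene_terms, "items"):
        pairs = [(g, t) for g, ts in gene_terms.items() for t in ts]
    else:
        pairs = list(gene_terms)
    if not pairs:
        raise ValueError("empty gene->term mapping")
    df = pd.DataFrame(pairs, columns=["gene", "term"]).drop_duplicates()
    mat = pd.crosstab(df["gene"], df["term"]).astype(bool)
    log: dict = {}

    sizes = mat.sum(axis=0)
    too_small = sizes[sizes < min_genes].index.tolist()
    too_big = sizes[sizes > max_genes].index.tolist()
    log["terms_dropped_unique"] = too_small
    log["terms_dropped_global"] = too_big
    mat = mat.drop(columns=too_small + too_big)

    dup_drop = []
    seen: dict[bytes, str] = {}
    for t in list(mat.columns):
        key = mat[t].to_numpy().tobytes()
        if key in seen:
            dup_drop.append(t)
        else:
            seen[key] = t
    log["terms_dropped_duplicate"] = dup_drop
    mat = mat.drop(columns=dup_drop)

    unannotated = mat.index[~mat.any(axis=1)].tolist()
    log["genes_dropped_unannotated"] = unannotated
    mat = mat.drop(index=unannotated)
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError("annotation matrix is empty after filtering")
    return AnnotationMatrix(matrix=mat, filter_log=log)


def read_gene_terms(path) -> list[tuple[str, str]]:
    """Read a gene->term mapping from a two-column TSV or a GMT file."""
    pairs = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gmt = len(first.rstrip("\n").split("\t")) > 2 or str(path).endswith(".gmt")
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            if len(cells) < 2 or not cells[0]:
                continue
            if is_gmt:
                term = cells[0]
                for g in cells[2:]:
                    if g:
                        pairs.append((g, term))
            else:
                pairs.append((cells[0], cells[1]))
    return pairs


# ---------------------------------------------------------------------------
# PCA with CCR cutoff

@dataclass
class PCAReduction:
    loadings: np.ndarray               # variables x components (all)
    scores: np.ndarray                 # observations x retained components
    explained_ratio: np.ndarray
    ccr_threshold: float
    n_retained: int
    center: np.ndarray

    def project(self, X) -> np.ndarray:
        """Project new rows onto the retained components."""
        Xc = np.asarray(X, dtype=float) - self.center
        return Xc @ self.loadings[:, : self.n_retained]


def pca_reduce(matrix, ccr_threshold: float = 0.95) -> PCAReduction:
    """Column-centered PCA retaining the smallest number of components whose
    cumulative contribution ratio reaches ``ccr_threshold``."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a matrix with >= 2 rows and columns")
    if not 0 < ccr_threshold <= 1:
        raise ValueError("ccr_threshold must be in (0, 1]")
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has rank 0 (no variance)")
    ratio = var / total
    ccr = np.cumsum(ratio)
    rank = int(np.sum(s > s[0] * 1e-12))
    k = int(np.searchsorted(ccr, ccr_threshold - 1e-12) + 1)
    k = min(k, rank)
    return PCAReduction(loadings=Vt.T, scores=(U * s)[:, :k],
                        explained_ratio=ratio, ccr_threshold=ccr_threshold,
                        n_retained=k, center=center)


# ---------------------------------------------------------------------------
# canonical correlation analysis

@dataclass
class CCAResult:
    rho: np.ndarray
    x_weights: np.ndarray
    y_weights: np.ndarray
    x_scores: np.ndarray
    y_scores: np.ndarray
    bartlett_stat: np.ndarray
    bartlett_df: np.ndarray
    bartlett_p: np.ndarray
    n_significant: int
    n: int


def _inv_sqrt(S, eps=1e-8):
    w, V = np.linalg.eigh(S)
    w = np.maximum(w, 0.0) + eps
    return V @ np.diag(1.0 / np.sqrt(w)) @ V.T


def fit_cca(X, Y, alpha: float = 0.05, eps: float = 1e-8) -> CCAResult:
    """Canonical correlations via SVD of the whitened cross-covariance.

    A ridge ``eps`` stabilizes singular covariances.  Bartlett's sequential
    chi-squared statistic for dimension k (0-based) is
    ``-(n - 1 - (p + q + 1)/2) * sum_{i>k} ln(1 - rho_i^2)`` with
    ``(p - k)(q - k)`` degrees of freedom; the number of significant pairs
    is the largest K such that tests 1..K all reject at ``alpha``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share the observation dimension")
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 observations")
    for M, nm in ((X, "X"), (Y, "Y")):
        sd = M.std(axis=0)
        if np.any(sd == 0):
            raise ValueError(
                f"constant column(s) in {nm}: {np.where(sd == 0)[0].tolist()}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)
    Wx = _inv_sqrt(Sxx, eps)
    Wy = _inv_sqrt(Syy, eps)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    d = min(p, q)
    rho = np.clip(s[:d], 0.0, 1.0)
    A = Wx @ U[:, :d]
    B = Wy @ Vt.T[:, :d]
    stat = np.empty(d)
    dfs = np.empty(d, dtype=int)
    pvals = np.empty(d)
    factor = n - 1 - (p + q + 1) / 2.0
    log1m = np.log(np.clip(1.0 - rho ** 2, 1e-300, None))
    for k in range(d):
        stat[k] = -factor * np.sum(log1m[k:])
        dfs[k] = (p - k) * (q - k)
        pvals[k] = stats.chi2.sf(max(stat[k], 0.0), dfs[k])
    n_sig = 0
    for k in range(d):
        if pvals[k] < alpha:
            n_sig += 1
        else:
            break
    return CCAResult(rho=rho, x_weights=A, y_weights=B,
                     x_scores=Xc @ A, y_scores=Yc @ B,
                     bartlett_stat=stat, bartlett_df=dfs, bartlett_p=pvals,
                     n_significant=n_sig, n=n)


# ---------------------------------------------------------------------------
# gene groups

@dataclass
class GeneGroup:
    group_id: int
    members: list[str]
    enriched_terms: list[tuple[str, float]] = field(default_factory=list)
    representative_term: Optional[str] = None
    representative_p: float = math.nan
    degree: int = 0
    mean_within_distance: float = math.nan
    core: bool = False
    dense: bool = False


def binary_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed pairwise binary (Jaccard) distance: discordant coordinates
    over coordinates where at least one vector is 1."""
    return pdist(np.asarray(matrix, dtype=bool), metric="jaccard")


def cluster_gene_groups(annotation: AnnotationMatrix,
                        cut_height: float = 0.999) -> list[GeneGroup]:
    """Complete-linkage hierarchical clustering of genes on the binary
    distance between annotation vectors, cut at ``cut_height`` (< 1);
    singleton groups are discarded."""
    mat = annotation.matrix
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    d = binary_distance(mat.to_numpy())
    Z = linkage(d, method="complete")
    labels = fcluster(Z, t=cut_height, criterion="distance")
    genes = np.asarray(mat.index)
    groups = []
    for gid in np.unique(labels):
        members = genes[labels == gid].tolist()
        if len(members) >= 2:
            groups.append(GeneGroup(group_id=int(gid), members=members))
    return groups


def enrich_groups(groups: Sequence[GeneGroup], annotation: AnnotationMatrix,
                  alpha: float = 0.05) -> list[GeneGroup]:
    """Fisher's exact enrichment of each term in each group against the
    annotated-gene universe, Bonferroni-corrected over all (group, term)
    tests; the representative term is the enriched term with lowest P."""
    mat = annotation.matrix
    universe = len(mat)
    term_counts = mat.sum(axis=0)
    n_tests = len(groups) * mat.shape[1]
    for g in groups:
        sub = mat.loc[g.members]
        g_size = len(g.members)
        in_term = sub.sum(axis=0)
        enriched = []
        for term in mat.columns:
            a = int(in_term[term])
            if a == 0:
                continue
            b = g_size - a
            c = int(term_counts[term]) - a
            dd = universe - g_size - c
            _, p = stats.fisher_exact([[a, b], [c, dd]], alternative="two-sided")
            p_adj = min(1.0, p * n_tests)
            if p_adj < alpha:
                enriched.append((term, float(p)))
        enriched.sort(key=lambda t: t[1])
        g.enriched_terms = enriched
        if enriched:
            g.representative_term, g.representative_p = enriched[0]
    return list(groups)


# ---------------------------------------------------------------------------
# pairwise group CCA

def pairwise_group_cca(groups: Sequence[GeneGroup], pcv_scores: pd.DataFrame,
                       alpha: float = 0.0005,
                       bonferroni: bool = True) -> pd.DataFrame:
    """Test each unordered group pair for a shared phenotype signature.

    Observations are the pCV dimensions; the variables of each side are the
    member genes' pCV profiles.  Sides with at least as many genes as half
    the pCV dimensions are PCA-reduced so the Bartlett approximation stays
    valid.  The first canonical dimension's Bartlett P is Bonferroni-
    multiplied by the number of tested pairs and compared to ``alpha``.

    Returns a DataFrame (group_a, group_b, rho1, p_raw, p_adj, significant).
    """
    usable = [g for g in groups if len(g.members) >= 2]
    skipped = [g.group_id for g in groups if len(g.members) < 2]
    if skipped:
        warnings.warn(f"groups skipped (fewer than 2 members): {skipped}")
    n_obs = pcv_scores.shape[1]            # pCV dimensions as observations
    if n_obs < 4:
        raise ValueError(
            f"need >= 4 pCV dimensions for pairwise CCA, got {n_obs}")
    # cap each side's variable count so the Bartlett factor
    # n - 1 - (p + q + 1)/2 stays positive
    max_vars = max(1, (n_obs - 1) // 2)
    profiles = {}
    for g in usable:
        M = pcv_scores.loc[g.members].to_numpy().T     # n_obs x n_genes
        if M.shape[1] > max_vars:
            M = pca_reduce(M, ccr_threshold=1.0).scores[:, :max_vars]
        profiles[g.group_id] = M
    rows = []
    ids = [g.group_id for g in usable]
    m = n_unordered_pairs(len(ids))
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            X, Y = profiles[ids[i]], profiles[ids[j]]
            try:
                res = fit_cca(X, Y, alpha=alpha)
                rho1 = float(res.rho[0])
                p_raw = float(res.bartlett_p[0])
            except (ValueError, np.linalg.LinAlgError):
                rho1, p_raw = math.nan, 1.0
            p_adj = min(1.0, p_raw * m) if bonferroni else p_raw
            rows.append((ids[i], ids[j], rho1, p_raw, p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "rho1",
                                       "p_raw", "p_adj", "significant"])


# ---------------------------------------------------------------------------
# correlation network

@dataclass
class CorrelationNetwork:
    edges: pd.DataFrame                # gene_a, gene_b, r, kind
    coordinates: pd.DataFrame          # gene -> x, y
    degrees: dict[int, int]            # group -> number of significant partners
    graph: nx.Graph


def build_correlation_network(pcv_scores: pd.DataFrame,
                              groups: Sequence[GeneGroup],
                              significant_pairs: pd.DataFrame,
                              layout_seed: int = 0) -> CorrelationNetwork:
    """Assemble the phenotype-correlation network.

    Gene–gene similarity is the Pearson correlation of pCV score vectors.
    All within-group correlations are kept; a cross-group edge between two
    groups exists only when their pair is significant and only for the gene
    pair with the maximum |r| of that group pair — every other cross-group
    cell is zero-filled.  Node positions come from a seeded
    Fruchterman–Reingold layout weighted by |r|.
    """
    gmap = {g.group_id: g.members for g in groups}
    genes = [m for g in groups for m in g.members]
    if not genes:
        raise ValueError("no genes in any group")
    S = pcv_scores.loc[genes].to_numpy()
    R = np.corrcoef(S)
    gi = {g: i for i, g in enumerate(genes)}
    edges = []
    for g in groups:
        mem = g.members
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                edges.append((mem[i], mem[j],
                              float(R[gi[mem[i]], gi[mem[j]]]), "within"))
    sig = significant_pairs[significant_pairs["significant"]]
    degrees: dict[int, int] = {g.group_id: 0 for g in groups}
    for _, row in sig.iterrows():
        a, b = int(row["group_a"]), int(row["group_b"])
        if a not in gmap or b not in gmap:
            continue
        degrees[a] += 1
        degrees[b] += 1
        best, best_abs = None, -1.0
        for ga in gmap[a]:
            for gb in gmap[b]:
                r = float(R[gi[ga], gi[gb]])
                if abs(r) > best_abs:
                    best, best_abs = (ga, gb, r), abs(r)
        if best is not None:
            edges.append((best[0], best[1], best[2], "between"))
    edf = pd.DataFrame(edges, columns=["gene_a", "gene_b", "r", "kind"])
    if len(edf) == 0:
        raise ValueError("network has no edges")
    G = nx.Graph()
    G.add_nodes_from(genes)
    for _, e in edf.iterrows():
        G.add_edge(e["gene_a"], e["gene_b"], weight=abs(float(e["r"])))
    pos = nx.spring_layout(G, seed=layout_seed, weight="weight")
    coords = pd.DataFrame(
        [(g, xy[0], xy[1]) for g, xy in pos.items()],
        columns=["gene", "x", "y"]).set_index("gene")
    for g in groups:
        g.degree = degrees[g.group_id]
        pts = coords.loc[g.members, ["x", "y"]].to_numpy()
        if len(pts) >= 2:
            g.mean_within_distance = float(np.mean(pdist(pts)))
    return CorrelationNetwork(edges=edf, coordinates=coords, degrees=degrees,
                              graph=G)


# ---------------------------------------------------------------------------
# core / dense classification by two-component mixtures

def _two_component_split_1d(x: np.ndarray, family: str, max_iter: int = 200
                            ) -> Optional[np.ndarray]:
    """Best two-component mixture assignment of 1-d data, EM refined from
    every sorted-split initialization.  Returns a Boolean mask of the
    higher-mean component, or None when no split beats degeneracy."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    best_ll, best_assign = -np.inf, None

    def comp_logpdf(xs, lab):
        out = np.empty((n, 2))
        for j in (0, 1):
            sub = xs[lab == j]
            m = sub.mean()
            if family == "poisson":
                lam = max(m, 1e-9)
                out[:, j] = stats.poisson.logpmf(xs.astype(int), lam)
            else:  # gamma
                v = sub.var()
                if v <= 0:
                    v = max(1e-6 * m * m, 1e-12)
                a = max(m * m / v, 1e-3)
                out[:, j] = stats.gamma.logpdf(xs, a, scale=m / a)
        return out

    for split in range(1, n):
        lab = np.zeros(n, dtype=int)
        lab[order[split:]] = 1
        pi = np.array([split / n, 1 - split / n])
        resp = None
        ll = -np.inf
        for _ in range(max_iter):
            lp = comp_logpdf(x, lab) + np.log(pi)
            from scipy.special import logsumexp
            norm = logsumexp(lp, axis=1)
            ll_new = float(norm.sum())
            resp = np.exp(lp - norm[:, None])
            lab_new = resp.argmax(axis=1)
            pi = np.clip(resp.mean(axis=0), 1e-9, None)
            if len(np.unique(lab_new)) < 2:
                ll_new = -np.inf
                break
            if abs(ll_new - ll) < 1e-10 * max(abs(ll_new), 1.0):
                ll = ll_new
                lab = lab_new
                break
            ll = ll_new
            lab = lab_new
        if np.isfinite(ll) and ll > best_ll:
            best_ll, best_assign = ll, lab.copy()
    if best_assign is None:
        return None
    m0 = x[best_assign == 0].mean()
    m1 = x[best_assign == 1].mean()
    hi = 1 if m1 > m0 else 0
    return best_assign == hi


def classify_core_dense(degrees, mean_distances
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Flag core and dense groups by two-component mixture splits.

    ``degrees`` (significant-partner counts per group) are split by a
    Poisson mixture; the higher-mean cluster is *core*.  ``mean_distances``
    (average within-group 2-D embedding distances) are split by a gamma
    mixture; the lower-mean cluster is *dense*.  The implied boundary
    values (min core degree, max dense distance) are reported.  Degenerate
    input (all values equal) yields no flags and a warning.
    """
    deg = np.asarray(degrees, dtype=float)
    dist = np.asarray(mean_distances, dtype=float)
    if len(deg) < 4 or len(dist) < 4:
        raise ValueError("need at least 4 groups")
    info: dict = {}
    if np.ptp(deg) == 0:
        warnings.warn("all degrees equal; no core split")
        core = np.zeros(len(deg), dtype=bool)
        info["core_boundary"] = math.nan
    else:
        hi = _two_component_split_1d(deg, "poisson")
        core = hi if hi is not None else np.zeros(len(deg), dtype=bool)
        info["core_boundary"] = float(deg[core].min()) if core.any() else math.nan
    ok = np.isfinite(dist)
    dist_pos = np.where(dist <= 0, 1e-6, dist)
    if np.ptp(dist_pos[ok]) == 0 or ok.sum() < 4:
        warnings.warn("degenerate distances; no dense split")
        dense = np.zeros(len(dist), dtype=bool)
        info["dense_boundary"] = math.nan
    else:
        hi = _two_component_split_1d(dist_pos[ok], "gamma")
        dense = np.zeros(len(dist), dtype=bool)
        if hi is not None:
            dense[np.where(ok)[0]] = ~hi       # lower-mean component
        info["dense_boundary"] = float(dist[dense].max()) if dense.any() else math.nan
    return core, dense, info
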