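"""Comparative analysis modes: gene-vs-gene divergence, gene-vs-gene-list
permutation testing, and gene-list topology.

* **Gene vs gene** contrasts two correlation vectors by the two-point sample
  variance of each paired coefficient, ``(r1 - r2)^2 / 2`` (n-1 denominator),
  so the genes whose co-expression diverges most between the two queries (or
  conditions) rise to the top; the same variance metric applied to per-set
  NES values ranks diverging enrichments.
* **Gene vs gene list** asks whether a secondary gene list is more correlated
  with the query gene than chance: the observed mean r over the list is
  compared with the mean r of random same-size lists, giving an empirical
  tail probability; the per-replicate Welch t-test p-values (whose density is
  the classic readout of this test) are retained alongside.
* **Topology** embeds each input gene by its genome-wide correlation profile
  (PCA, optionally t-SNE) and cuts a complete-linkage hierarchy into
  clusters, exposing de-novo sub-groups within a gene list; the variant-genes
  view instead keeps the correlate columns with the highest variance across
  the input list for heatmap-style inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import AnalysisError, ParameterError
from .gsea import GeneSetCollection, corgsea
from .store import CorrelationStore, CorrelationVector, correlation_pvalue, group_key

TOPOLOGY_MAX_FULL_INPUT = 100  # above this many input genes, restrict feature columns
TOPOLOGY_N_VARIANT_COLUMNS = 2500
VARIANT_GENES_DEFAULT_K = 1500

_STAR_THRESHOLDS = [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")]


def significance_stars(p: float) -> str:
    for thr, stars in _STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


# ---------------------------------------------------------------------------
# gene vs gene


@dataclass
class DivergenceResult:
    """Paired correlations/NES with their two-point variances, sorted descending."""

    genes: pd.DataFrame  # gene, r1, r2, variance
    sets: pd.DataFrame | None  # set, nes1, nes2, variance
    n_dropped: int


def gene_vs_gene(
    vec1: CorrelationVector,
    vec2: CorrelationVector,
    collection: GeneSetCollection | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DivergenceResult:
    """Top diverging correlations (and optionally enrichments) between two vectors.

    Both query genes are removed from the shared universe; missing
    correlations in either vector are dropped (the count is reported).
    The ranking is symmetric in the two vectors.
    """
    common = np.intersect1d(vec1.genes, vec2.genes)
    if len(common) == 0:
        raise AnalysisError("correlation vectors have disjoint gene universes")
    common = common[(common != vec1.query_gene) & (common != vec2.query_gene)]
    i1 = {g: i for i, g in enumerate(vec1.genes)}
    i2 = {g: i for i, g in enumerate(vec2.genes)}
    r1 = np.array([vec1.r[i1[g]] for g in common])
    r2 = np.array([vec2.r[i2[g]] for g in common])
    keep = np.isfinite(r1) & np.isfinite(r2)
    n_dropped = int((~keep).sum())
    genes_df = pd.DataFrame(
        {
            "gene": common[keep],
            "r1": r1[keep],
            "r2": r2[keep],
            "variance": (r1[keep] - r2[keep]) ** 2 / 2.0,
        }
    ).sort_values(["variance", "gene"], ascending=[False, True], kind="stable")
    genes_df = genes_df.reset_index(drop=True)

    sets_df = None
    if collection is not None:
        res1 = corgsea(vec1, collection, n_perm=n_perm, seed=seed)
        res2 = corgsea(vec2, collection, n_perm=n_perm, seed=seed)
        merged = res1[["set", "NES"]].merge(res2[["set", "NES"]], on="set", suffixes=("1", "2"))
        sets_df = pd.DataFrame(
            {
                "set": merged["set"],
                "nes1": merged["NES1"],
                "nes2": merged["NES2"],
                "variance": (merged["NES1"] - merged["NES2"]) ** 2 / 2.0,
            }
        ).sort_values(["variance", "set"], ascending=[False, True], kind="stable")
        sets_df = sets_df.reset_index(drop=True)
    return DivergenceResult(genes=genes_df, sets=sets_df, n_dropped=n_dropped)


def gene_vs_gene_groups(store: CorrelationStore, gene1: str, gene2: str) -> pd.DataFrame:
    """Group-mode comparison of two genes (or one gene across conditions).

    * ``gene1 != gene2``: per tissue-disease group, r(gene1, gene2) and its
      analytic p-value.
    * ``gene1 == gene2``: per tissue with both cancer and normal present, the
      Pearson correlation between the gene's two correlation profiles plus a
      two-sided Wilcoxon rank-sum contrast of its VST expression between
      conditions, star-coded at .05/.01/.001/.0001.
    """
    gene1, gene2 = str(gene1).upper(), str(gene2).upper()
    if gene1 != gene2:
        rows = []
        for grp in store.group_keys():
            vec = store.get_vector(gene1, grp)
            idx = store._gene_index(gene2)
            rows.append(
                {
                    "tissue": grp[0],
                    "disease": grp[1],
                    "r": vec.r[idx],
                    "p": vec.p[idx],
                    "n": vec.n,
                }
            )
        return pd.DataFrame(rows)

    if store.expression is None:
        raise AnalysisError(
            "same-gene condition contrast needs the expression matrix; "
            "rebuild or save the store with expression included"
        )
    tissues = sorted(
        {t for (t, d) in store.group_keys()}
        & {t for (t, d) in store.group_keys() if d == "cancer"}
        & {t for (t, d) in store.group_keys() if d == "normal"}
    )
    if not tissues:
        raise AnalysisError("no tissue has both cancer and normal groups in the store")
    gi = store._gene_index(gene1)
    expr = store.expression
    col_of = {str(s): j for j, s in enumerate(expr.sample_ids)}
    rows = []
    for tissue in tissues:
        cancer = store.groups[(tissue, "cancer")]
        normal = store.groups[(tissue, "normal")]
        rc = cancer.matrix[gi].astype(float)
        rn = normal.matrix[gi].astype(float)
        keep = np.isfinite(rc) & np.isfinite(rn)
        keep[gi] = False
        profile_r = float(np.corrcoef(rc[keep], rn[keep])[0, 1]) if keep.sum() >= 3 else np.nan
        xc = expr.values[gi, [col_of[str(s)] for s in cancer.sample_ids]]
        xn = expr.values[gi, [col_of[str(s)] for s in normal.sample_ids]]
        p = float(stats.ranksums(xc, xn).pvalue)
        rows.append(
            {
                "tissue": tissue,
                "profile_r": profile_r,
                "mean_vst_cancer": float(np.mean(xc)),
                "mean_vst_normal": float(np.mean(xn)),
                "ranksum_p": p,
                "stars": significance_stars(p),
                "n_cancer": cancer.n,
                "n_normal": normal.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene vs gene list


@dataclass
class PermTestResult:
    """Permutation comparison of a secondary gene list against random lists."""

    observed_stat: float
    null_stats: np.ndarray
    empirical_p: float
    replicate_pvalues: np.ndarray
    n_secondary_used: int
    n_dropped: int


def gene_vs_genelist(
    vector: CorrelationVector,
    secondary: list[str],
    B: int = 1000,
    seed: int | None = None,
) -> PermTestResult:
    """Is the secondary list more correlated with the query than random lists?

    ``observed_stat`` is the mean r over the secondary genes; each of B
    replicates draws a random same-size list from the rest of the universe,
    records its mean r (the null) and the Welch t-test p between secondary
    and replicate r-values (the plotted density).  ``empirical_p`` is the
    one-sided tail ``(1 + #{null >= observed}) / (B + 1)``.
    """
    keep = np.isfinite(vector.r) & (vector.genes != vector.query_gene)
    genes, r = vector.genes[keep], vector.r[keep]
    requested = {str(g).upper() for g in secondary} - {vector.query_gene}
    in_universe = np.isin(genes, sorted(requested))
    m = int(in_universe.sum())
    n_dropped = len(requested) - m
    if m < 2:
        raise AnalysisError(f"secondary list needs >= 2 genes in the universe, got {m}")
    if len(genes) < 2 * m:
        raise AnalysisError(
            f"universe of {len(genes)} genes is too small for a secondary list of {m} "
            "(need at least 2m)"
        )
    sec_r = np.sort(r[in_universe])  # sorted: order-invariance of the input list
    comp_r = r[~in_universe]
    observed = float(sec_r.mean())

    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((B, len(comp_r))), axis=1)[:, :m]
    null_draws = comp_r[idx]
    null_stats = null_draws.mean(axis=1)
    rep_p = stats.ttest_ind(
        np.broadcast_to(sec_r, (B, m)), null_draws, axis=1, equal_var=False
    ).pvalue
    empirical_p = float((1.0 + np.sum(null_stats >= observed)) / (B + 1.0))
    return PermTestResult(
        observed_stat=observed,
        null_stats=null_stats,
        empirical_p=empirical_p,
        replicate_pvalues=np.asarray(rep_p),
        n_secondary_used=m,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# topology


@dataclass
class TopologyResult:
    """2-D embedding and cluster assignment per input gene."""

    embedding: pd.DataFrame  # index gene, columns x, y
    cluster_id: pd.Series  # index gene, contiguous ints from 1
    n_features: int
    n_dropped: int
    k: int


@dataclass
class VariantGenesResult:
    """High-variance correlate submatrix with dendrogram orders."""

    submatrix: pd.DataFrame  # input genes x selected correlates
    row_order: np.ndarray
    col_order: np.ndarray
    selected_correlates: np.ndarray


def _feature_matrix(
    store: CorrelationStore, group: tuple[str, str], genes: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Rows = usable input genes, columns = valid-universe correlates."""
    gd = store.matrix(group)
    wanted = list(dict.fromkeys(str(g).upper() for g in genes))
    rows, used = [], []
    for g in wanted:
        if not store.has_gene(g):
            continue
        row = gd.matrix[store._gene_index(g)].astype(float)
        if np.all(np.isnan(row)):
            continue
        rows.append(row)
        used.append(g)
    n_dropped = len(wanted) - len(used)
    if not used:
        raise AnalysisError("no input gene present in the correlation store")
    X = np.vstack(rows)
    valid_cols = ~np.any(np.isnan(X), axis=0)
    return X[:, valid_cols], np.asarray(used), store.gene_ids[valid_cols], n_dropped


def topology_dimred(
    store: CorrelationStore,
    group: tuple[str, str],
    genes: list[str],
    use_tsne: bool = False,
    seed: int | None = None,
    k: int | None = None,
) -> TopologyResult:
    """Embed and cluster a gene list by its correlation profiles.

    Feature matrix: input genes x correlates (all correlates, or the 2500
    highest-variance columns when the input list exceeds 100 genes); rows
    centered; PCA to min(50, rank) components; complete-linkage Euclidean
    clustering on the scores, with k chosen by maximum mean silhouette over
    2..min(12, n-1) unless given.  The embedding is the first two PCs, or a
    t-SNE of the scores when ``use_tsne`` (perplexity min(30, (n-1)/3)).
    """
    X, used, correlates, n_dropped = _feature_matrix(store, group, genes)
    n = len(used)
    if n < 5:
        raise AnalysisError(f"topology needs >= 5 usable input genes, got {n}")
    if n > TOPOLOGY_MAX_FULL_INPUT and X.shape[1] > TOPOLOGY_N_VARIANT_COLUMNS:
        var = X.var(axis=0, ddof=1)
        cols = np.argsort(-var, kind="stable")[:TOPOLOGY_N_VARIANT_COLUMNS]
        X = X[:, np.sort(cols)]
    X = X - X.mean(axis=1, keepdims=True)

    n_comp = min(50, n - 1, X.shape[1])
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)

    degenerate = np.allclose(scores, scores[0], atol=1e-12)
    if degenerate:
        warnings.warn(
            "all input genes have identical correlation profiles; single cluster returned",
            stacklevel=2,
        )
        labels = np.ones(n, dtype=int)
        chosen_k = 1
    else:
        Z = hierarchy.linkage(scores, method="complete", metric="euclidean")
        if k is not None:
            if k < 1:
                raise ParameterError("k must be >= 1")
            labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
            chosen_k = k
        else:
            best, best_sil = None, -np.inf
            for kk in range(2, min(12, n - 1) + 1):
                lab = hierarchy.fcluster(Z, t=kk, criterion="maxclust")
                if len(np.unique(lab)) < 2:
                    continue
                sil = silhouette_score(scores, lab)
                if sil > best_sil:
                    best, best_sil = lab, sil
            if best is None:
                labels, chosen_k = np.ones(n, dtype=int), 1
            else:
                labels, chosen_k = best, len(np.unique(best))
        # relabel contiguous from 1 in order of first appearance
        remap = {}
        for lab in labels:
            if lab not in remap:
                remap[lab] = len(remap) + 1
        labels = np.array([remap[lab] for lab in labels])

    if use_tsne:
        from sklearn.manifold import TSNE

        perplexity = min(30.0, (n - 1) / 3.0)
        emb = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=None if seed is None else int(seed),
            init="pca",
        ).fit_transform(scores)
    else:
        emb = scores[:, :2] if scores.shape[1] >= 2 else np.column_stack([scores[:, 0], np.zeros(n)])

    embedding = pd.DataFrame(emb, index=pd.Index(used, name="gene"), columns=["x", "y"])
    cluster_id = pd.Series(labels, index=pd.Index(used, name="gene"), name="cluster_id")
    return TopologyResult(
        embedding=embedding,
        cluster_id=cluster_id,
        n_features=X.shape[1],
        n_dropped=n_dropped,
        k=chosen_k,
    )


def variant_genes(
    store: CorrelationStore,
    group: tuple[str, str],
    genes: list[str],
    k: int = VARIANT_GENES_DEFAULT_K,
) -> VariantGenesResult:
    """Select the k correlate columns with highest variance across the input list.

    Input genes themselves are excluded as columns; rows and columns are
    hierarchically clustered (Euclidean, complete linkage) and returned with
    their dendrogram leaf orders, heatmap-style.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    X, used, correlates, _ = _feature_matrix(store, group, genes)
    if len(used) < 2:
        raise AnalysisError(f"variant-genes needs >= 2 usable input genes, got {len(used)}")
    col_keep = ~np.isin(correlates, used)
    X, correlates = X[:, col_keep], correlates[col_keep]
    var = X.var(axis=0, ddof=1)
    take = np.argsort(-var, kind="stable")[: min(k, len(correlates))]
    take = np.sort(take)
    sub, selected = X[:, take], correlates[take]

    row_order = hierarchy.leaves_list(
        hierarchy.linkage(sub, method="complete", metric="euclidean")
    )
    col_order = hierarchy.leaves_list(
        hierarchy.linkage(sub.T, method="complete", metric="euclidean")
    )
    submatrix = pd.DataFrame(sub, index=pd.Index(used, name="gene"), columns=selected)
    return VariantGenesResult(
        submatrix=submatrix,
        row_order=row_order,
        col_order=col_order,
        selected_correlates=selected,
    )
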