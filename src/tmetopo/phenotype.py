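"""Cell phenotyping: the count-matrix chain and graph clustering.

The transcriptomic arm runs on an :class:`anndata.AnnData` of raw counts
(cells x genes) and follows the conventional single-cell recipe with strict
quality-control inequalities: genes covered by fewer than 3 cells are
dropped, then cells expressing < 500 or > 5000 genes, containing < 400 or
> 25 000 total counts, or with mitochondrial content > 15% are removed.
Counts are library-size normalized to a fixed target and ln(1+x)
transformed; 2000 highly variable genes are ranked by the clipped
standardized variance of a mean-variance trend fit (the "vst" ranking); the
scaled HVG matrix is reduced to 20 principal components; and cells are
clustered on a shared-nearest-neighbor (Jaccard) graph by Leiden modularity
at a fixed resolution.

The same :func:`cluster_graph` operation serves the imaging arm
(PhenoGraph-style clustering of normalized marker means at k = 100).

Marker ranking uses the two-sided Wilcoxon rank-sum test with detection
fraction and log-fold-change pre-filters. Log fold change is
``ln((mean(expm1 x) + 1) / (mean(expm1 x) + 1))`` between the cluster and
the rest, computed on the log-normalized matrix — i.e. on de-logged
normalized expression with a pseudocount of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterAssignment", "qc_filter", "lognormalize", "select_hvg",
    "embed_pca", "cluster_graph", "rank_markers", "annotate",
]


@dataclass
class ClusterAssignment:
    """Per-cell cluster ids (contiguous, 0-based, ordered by size)."""

    labels: np.ndarray
    means: pd.DataFrame | None = None       # cluster x feature mean profile
    annotation: dict[int, str] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def annotated_labels(self) -> np.ndarray:
        return np.array([self.annotation.get(int(c), str(c)) for c in self.labels])


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


# ======================================================================== QC

def qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell totals, genes detected and mitochondrial count fraction."""
    X = adata.X
    if sp.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        total = X.sum(axis=1)
        n_genes = (X > 0).sum(axis=1)
    is_mito = adata.var_names.str.startswith(mito_prefix)
    if is_mito.any():
        sub = X[:, np.where(is_mito)[0]]
        mito = np.asarray(sub.sum(axis=1)).ravel()
    else:
        mito = np.zeros_like(total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame({"total_counts": total, "n_genes": n_genes,
                         "mito_fraction": frac}, index=adata.obs_names)


def qc_filter(adata: ad.AnnData, min_genes: int = 500, max_genes: int = 5000,
              min_umi: int = 400, max_umi: int = 25000, max_mito: float = 0.15,
              min_cells_per_gene: int = 3, mito_prefix: str = "MT-",
              drop_doublets: bool = False) -> ad.AnnData:
    """Filter genes then cells with strict boundary semantics.

    Genes detected in fewer than ``min_cells_per_gene`` cells are removed
    first; then cells expressing < ``min_genes`` or > ``max_genes`` genes,
    containing < ``min_umi`` or > ``max_umi`` total counts, or with
    mitochondrial fraction > ``max_mito`` are removed (all inequalities
    strict, so boundary cells survive). With ``drop_doublets`` cells whose
    ``obs['is_doublet']`` flag is set are also removed.
    """
    if min_genes >= max_genes or min_umi >= max_umi:
        raise ValueError("require min_genes < max_genes and min_umi < max_umi")
    X = adata.X
    if sp.issparse(X):
        cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        cells_per_gene = (np.asarray(X) > 0).sum(axis=0)
    adata = adata[:, cells_per_gene >= min_cells_per_gene]

    m = qc_metrics(adata, mito_prefix)
    keep = ((m["n_genes"] >= min_genes) & (m["n_genes"] <= max_genes)
            & (m["total_counts"] >= min_umi) & (m["total_counts"] <= max_umi)
            & (m["mito_fraction"] <= max_mito)).to_numpy()
    if drop_doublets and "is_doublet" in adata.obs:
        keep &= ~adata.obs["is_doublet"].to_numpy(dtype=bool)
    if not keep.any():
        warnings.warn("qc_filter removed every cell; returning an empty matrix")
    out = adata[keep].copy()
    out.obs = out.obs.drop(columns=m.columns, errors="ignore").join(m.loc[out.obs_names])
    return out


def lognormalize(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Scale each cell to ``target_sum`` counts, then ln(1 + x).

    Raw counts are preserved in ``layers['counts']``. A zero-count cell
    cannot be scaled and raises.
    """
    adata = adata.copy()
    X = adata.X
    if sp.issparse(X):
        total = np.asarray(X.sum(axis=1)).ravel()
    else:
        total = np.asarray(X).sum(axis=1)
    if (total == 0).any():
        raise ValueError("cannot normalize: matrix contains zero-count cells")
    adata.layers["counts"] = X.copy()
    if sp.issparse(X):
        Xn = sp.diags(target_sum / total) @ X
        Xn = Xn.tocsr()
        Xn.data = np.log1p(Xn.data)
    else:
        Xn = np.log1p(np.asarray(X, dtype=float) * (target_sum / total)[:, None])
    adata.X = Xn
    return adata


# ======================================================================= HVG

def select_hvg(adata: ad.AnnData, n: int = 2000, span: float = 0.3) -> list[str]:
    """Rank genes by clipped standardized variance of the mean-variance trend.

    On raw counts (``layers['counts']`` if present): a lowess trend of
    log10(variance) on log10(mean) predicts each gene's expected standard
    deviation; counts are standardized by it, clipped at sqrt(N), and genes
    are ranked by the variance of the clipped values. The top ``n`` gene
    names are returned (also flagged in ``var['highly_variable']``), in a
    deterministic order.
    """
    if n > adata.n_vars:
        raise ValueError(f"requested {n} HVGs but matrix has {adata.n_vars} genes")
    counts = _dense(adata.layers["counts"] if "counts" in adata.layers else adata.X)
    counts = counts.astype(float)
    N = counts.shape[0]
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)

    std_var = np.zeros(adata.n_vars)
    fit_mask = (mean > 0) & (var > 0)
    if fit_mask.sum() >= 2:
        lx = np.log10(mean[fit_mask])
        ly = np.log10(var[fit_mask])
        pred = lowess(ly, lx, frac=span, xvals=lx, return_sorted=False)
        sd_exp = np.sqrt(10.0 ** pred)
        clip_val = np.sqrt(N)
        sub = counts[:, fit_mask]
        z = (sub - mean[fit_mask]) / sd_exp
        np.clip(z, -clip_val, clip_val, out=z)
        std_var[fit_mask] = z.var(axis=0, ddof=1)

    order = np.lexsort((np.arange(adata.n_vars), -std_var))
    top = order[:n]
    hv = np.zeros(adata.n_vars, dtype=bool)
    hv[top] = True
    adata.var["highly_variable"] = hv
    adata.var["hvg_rank_statistic"] = std_var
    return [adata.var_names[i] for i in sorted(top)]


# ======================================================================= PCA

def embed_pca(adata: ad.AnnData, n_pcs: int = 20, clip: float = 10.0) -> np.ndarray:
    """Principal components of the scaled HVG matrix.

    Genes are z-scored across cells (clipped at ``clip``), then reduced by
    SVD. The sign convention makes the largest-magnitude loading of each
    component positive, so the embedding is fully deterministic. If the
    matrix rank is below ``n_pcs`` the embedding is truncated with a
    warning. Stored in ``obsm['X_pca']``.
    """
    if "highly_variable" in adata.var:
        sub = adata[:, adata.var["highly_variable"].to_numpy(dtype=bool)]
    else:
        sub = adata
    X = _dense(sub.X).astype(float)
    if n_pcs > min(X.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(cells, genes)={min(X.shape)}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -clip, clip)
    Z = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = max(Z.shape) * np.finfo(float).eps * (s[0] if s.size else 0)
    rank = int((s > tol).sum())
    m = min(n_pcs, rank)
    if m < n_pcs:
        warnings.warn(f"matrix rank {rank} < n_pcs={n_pcs}; truncating embedding")
    emb = U[:, :m] * s[:m]
    for j in range(m):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            emb[:, j] = -emb[:, j]
    adata.obsm["X_pca"] = emb
    adata.uns["pca_variance"] = (s ** 2) / max(Z.shape[0] - 1, 1)
    return emb


# ================================================================ clustering

def cluster_graph(X: np.ndarray, k_neighbors: int = 20, resolution: float = 1.0,
                  seed: int = 0, prune: float = 1.0 / 15.0) -> ClusterAssignment:
    """Shared-nearest-neighbor Leiden clustering (PhenoGraph-style).

    A Euclidean kNN graph is reweighted by the Jaccard similarity of the
    neighborhoods (each cell's neighborhood includes itself), edges below
    ``prune`` are dropped, and communities are found by Leiden modularity
    (RB configuration) at the given resolution with a fixed seed. Serves
    both the transcriptomic embedding (k from config) and the imaging
    marker table (k = 100).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < n cells ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    rows = np.repeat(np.arange(n), idx.shape[1])
    A = sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())), shape=(n, n))
    A = A.maximum(sp.eye(n, format="csr"))       # ensure self-membership
    A.data[:] = 1.0
    inter = (A @ A.T).tocoo()                    # |N_i & N_j| on candidate pairs
    sizes = np.asarray(A.sum(axis=1)).ravel()
    mask = inter.row < inter.col
    r, c, iv = inter.row[mask], inter.col[mask], inter.data[mask]
    jac = iv / (sizes[r] + sizes[c] - iv)
    keep = jac >= prune
    edges = list(zip(r[keep].tolist(), c[keep].tolist()))
    weights = jac[keep].tolist()
    g = igraph.Graph(n=n, edges=edges, edge_attrs={"weight": weights})
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights="weight",
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    labels = np.asarray(part.membership)
    return ClusterAssignment(labels=_relabel_by_size(labels))


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == i) for i in ids])
    order = np.lexsort((first, -counts))
    remap = {int(ids[o]): new for new, o in enumerate(order)}
    return np.array([remap[int(l)] for l in labels], dtype=int)


# ==================================================================== markers

def rank_markers(adata: ad.AnnData, labels: np.ndarray, min_pct: float = 0.25,
                 logfc_threshold: float = 0.25) -> pd.DataFrame:
    """Per-cluster marker table: one-vs-rest Wilcoxon rank-sum.

    Genes are pre-filtered by detection fraction >= ``min_pct`` in either
    group and |log fold change| >= ``logfc_threshold``; surviving genes get
    a two-sided rank-sum p-value (exact when both groups have <= 10 cells
    and no ties, normal approximation with tie correction otherwise) and a
    Benjamini-Hochberg adjusted p across the genes tested per cluster.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("rank_markers requires at least 2 clusters")
    X = _dense(adata.X).astype(float)
    expm1 = np.expm1(X)
    out = []
    for cl in clusters:
        in_mask = labels == cl
        if in_mask.sum() < 2:
            warnings.warn(f"cluster {cl} has fewer than 2 cells; skipped")
            continue
        xin, xout = X[in_mask], X[~in_mask]
        pct_in = (xin > 0).mean(axis=0)
        pct_out = (xout > 0).mean(axis=0)
        lfc = np.log((expm1[in_mask].mean(axis=0) + 1.0)
                     / (expm1[~in_mask].mean(axis=0) + 1.0))
        cand = np.where(((pct_in >= min_pct) | (pct_out >= min_pct))
                        & (np.abs(lfc) >= logfc_threshold))[0]
        rows = []
        for g in cand:
            a, b = xin[:, g], xout[:, g]
            exact = (a.size <= 10 and b.size <= 10
                     and np.unique(np.concatenate([a, b])).size == a.size + b.size)
            res = mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
            rows.append({"cluster": cl, "gene": adata.var_names[g],
                         "log_fc": lfc[g], "pct_in": pct_in[g],
                         "pct_out": pct_out[g], "pvalue": res.pvalue})
        if rows:
            df = pd.DataFrame(rows)
            df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
            out.append(df)
    if not out:
        return pd.DataFrame(columns=["cluster", "gene", "log_fc", "pct_in",
                                     "pct_out", "pvalue", "padj"])
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["cluster", "padj", "pvalue", "gene"],
                           kind="stable").reset_index(drop=True)


# ================================================================= annotation

def annotate(X: "pd.DataFrame | ad.AnnData", labels: np.ndarray,
             marker_map: dict[str, list[str]]) -> dict[int, str]:
    """Label clusters by their best-matching canonical marker set.

    ``X`` is a cells x features expression table (DataFrame or AnnData of
    normalized values). Features are z-scored across cells; each cluster is
    assigned the ``marker_map`` entry with the highest mean scaled
    expression of its (present) markers, ties broken alphabetically with a
    warning. Markers absent from the matrix are skipped with a warning.
    """
    if not marker_map:
        raise ValueError("marker_map must be non-empty")
    if isinstance(X, ad.AnnData):
        X = pd.DataFrame(_dense(X.X), index=X.obs_names, columns=X.var_names)
    labels = np.asarray(labels)
    z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0).replace(0, 1.0)
    usable: dict[str, list[str]] = {}
    for lab, markers in marker_map.items():
        present = [m for m in markers if m in X.columns]
        absent = [m for m in markers if m not in X.columns]
        if absent:
            warnings.warn(f"markers absent from matrix for {lab!r}: {absent}")
        if present:
            usable[lab] = present
    if not usable:
        raise ValueError("no marker in marker_map is present in the matrix")
    result: dict[int, str] = {}
    for cl in np.unique(labels):
        zc = z.loc[np.asarray(labels) == cl].mean(axis=0)
        scores = {lab: float(zc[m].mean()) for lab, m in usable.items()}
        best = max(scores.values())
        winners = sorted(lab for lab, s in scores.items() if s == best)
        if len(winners) > 1:
            warnings.warn(f"cluster {cl}: tie between {winners}; "
                          "choosing alphabetically first")
        result[int(cl)] = winners[0]
    return result
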