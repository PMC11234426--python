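"""Spatial topology: kNN cell graphs, cellular neighborhoods, interaction
tests and TLS-like patch detection.

A *cellular neighborhood* (CN) is the multiset of phenotypes among a center
cell and its k nearest neighbors (k = 20 by default, window of k+1 cells);
CN composition vectors are clustered by K-means (k = 15 in the reference
configuration, over the cell clusters along with collagen I) into recurring
tissue motifs.

Pairwise *interaction / avoidance* between phenotypes is tested per image
against a label-permutation null: the graph is kept fixed, phenotype labels
are shuffled across cells, and the observed statistic (mean number of
B-phenotype neighbors per A-phenotype cell) is compared to the permutation
distribution with add-one p-value estimators, so p in (0, 1] always.

*TLS-like patches* are dense aggregates of the lymphoid target phenotypes
(B cells and memory CD4 T cells by default), found by density-based spatial
clustering (DBSCAN semantics) with patch area measured by an alpha-shape of
the member centroids.

All graph construction is scoped per image: neighbors never cross image
boundaries. Distances are Euclidean in micrometres (pixel coordinates
scaled by the ROI pixel size); ties are broken by cell id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree
from sklearn.cluster import DBSCAN, KMeans

__all__ = [
    "NeighborGraph", "CNModel", "PatchSet", "Patch",
    "build_graph", "cn_compose", "cn_cluster", "interaction_test",
    "detect_patches", "patch_profile", "alpha_shape_area",
]


@dataclass
class ImageGraph:
    """Neighborhood structure of one image."""

    cell_ids: np.ndarray                       # original cell_id values
    neighbors: list[np.ndarray]                # per cell: neighbor positions (not ids)
    distances: list[np.ndarray]


@dataclass
class NeighborGraph:
    """Per-image neighbor lists; ``mode`` is 'knn' (k) or 'radius' (r um)."""

    mode: str
    k: int | None
    radius: float | None
    images: dict[str, ImageGraph] = field(default_factory=dict)

    def to_edge_list(self) -> pd.DataFrame:
        rows = []
        for img, g in self.images.items():
            for i, (nbrs, dists) in enumerate(zip(g.neighbors, g.distances)):
                for j, d in zip(nbrs, dists):
                    rows.append((img, int(g.cell_ids[i]), int(g.cell_ids[j]), float(d)))
        return pd.DataFrame(rows, columns=["image", "source", "target", "distance"])


def build_graph(cells: pd.DataFrame, mode: str = "knn", k: int = 20,
                radius: float | None = None, image_col: str = "roi_id",
                pixel_size: float = 1.0) -> NeighborGraph:
    """Exact per-image Euclidean kNN or fixed-radius neighbor graph.

    ``cells`` needs columns ``cell_id, x, y`` plus ``image_col``.
    Coordinates are multiplied by ``pixel_size`` (um/px) before distance
    computation. In knn mode each cell gets exactly min(k, n-1) neighbors
    (self excluded, ties broken by cell id); if k >= n in an image it is
    capped at n-1 with a warning.
    """
    if mode not in ("knn", "radius"):
        raise ValueError("mode must be 'knn' or 'radius'")
    if mode == "radius" and (radius is None or radius <= 0):
        raise ValueError("radius mode requires radius > 0")
    graph = NeighborGraph(mode=mode, k=k if mode == "knn" else None,
                          radius=radius if mode == "radius" else None)
    for img, sub in cells.groupby(image_col, sort=True):
        sub = sub.sort_values("cell_id", kind="stable")
        ids = sub["cell_id"].to_numpy()
        pts = sub[["x", "y"]].to_numpy(dtype=float) * pixel_size
        n = len(sub)
        if mode == "knn" and n < 2:
            raise ValueError(f"image {img!r} has {n} cells; knn needs >= 2")
        neighbors: list[np.ndarray] = []
        distances: list[np.ndarray] = []
        if mode == "knn":
            kk = k
            if kk >= n:
                warnings.warn(f"image {img!r}: k={k} >= n={n}; capped at {n - 1}")
                kk = n - 1
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            np.fill_diagonal(d2, np.inf)
            for i in range(n):
                order = np.lexsort((ids, d2[i]))[:kk]
                neighbors.append(order.astype(np.intp))
                distances.append(np.sqrt(d2[i, order]))
        else:
            tree = cKDTree(pts)
            for i in range(n):
                hits = tree.query_ball_point(pts[i], r=radius)
                hits = np.array([h for h in hits if h != i], dtype=np.intp)
                d = np.sqrt(((pts[hits] - pts[i]) ** 2).sum(-1)) if hits.size else np.empty(0)
                order = np.lexsort((ids[hits], d)) if hits.size else np.empty(0, dtype=np.intp)
                neighbors.append(hits[order])
                distances.append(d[order])
        graph.images[str(img)] = ImageGraph(cell_ids=ids, neighbors=neighbors,
                                            distances=distances)
    return graph


# =============================================================== neighborhoods

def cn_compose(cells: pd.DataFrame, graph: NeighborGraph,
               category_col: str = "phenotype",
               categories: list[str] | None = None,
               include_center: bool = True,
               image_col: str = "roi_id") -> pd.DataFrame:
    """Per-cell neighborhood composition over phenotype categories.

    Each row is the fraction of each category among the window formed by
    the center cell and its neighbors (k + 1 cells when
    ``include_center``, the default reading). Rows sum to 1. Index is
    (image, cell_id).
    """
    if categories is None:
        categories = sorted(cells[category_col].astype(str).unique())
    cat_idx = {c: i for i, c in enumerate(categories)}
    unknown = set(cells[category_col].astype(str)) - set(categories)
    if unknown:
        raise ValueError(f"unknown category labels: {sorted(unknown)}")
    blocks = []
    index = []
    for img, g in graph.images.items():
        sub = cells[cells[image_col].astype(str) == img].sort_values(
            "cell_id", kind="stable")
        codes = np.array([cat_idx[c] for c in sub[category_col].astype(str)])
        n = len(sub)
        comp = np.zeros((n, len(categories)))
        for i, nbrs in enumerate(g.neighbors):
            if nbrs.size == 0:
                raise ValueError(f"cell {g.cell_ids[i]} in image {img!r} has no neighbors")
            window = np.concatenate([[i], nbrs]) if include_center else nbrs
            cnt = np.bincount(codes[window], minlength=len(categories))
            comp[i] = cnt / cnt.sum()
        blocks.append(comp)
        index.extend((img, int(cid)) for cid in g.cell_ids)
    return pd.DataFrame(np.vstack(blocks) if blocks else np.empty((0, len(categories))),
                        index=pd.MultiIndex.from_tuples(index, names=["image", "cell_id"]),
                        columns=categories)


@dataclass
class CNModel:
    """K-means model over the CN composition simplex."""

    centroids: pd.DataFrame                    # cn x category, rows sum to 1
    labels: np.ndarray                         # per cell, 0..k_cn-1
    inertia: float

    @property
    def k_cn(self) -> int:
        return len(self.centroids)


def cn_cluster(compositions: pd.DataFrame, k_cn: int = 15, seed: int = 0,
               n_init: int = 10) -> CNModel:
    """K-means (k-means++ init, fixed seed, best of ``n_init``) on CN rows."""
    X = compositions.to_numpy(dtype=float)
    n_distinct = np.unique(X, axis=0).shape[0]
    if k_cn > n_distinct:
        raise ValueError(f"k_cn={k_cn} exceeds {n_distinct} distinct composition rows")
    km = KMeans(n_clusters=k_cn, init="k-means++", n_init=n_init,
                random_state=seed).fit(X)
    cent = pd.DataFrame(km.cluster_centers_, columns=compositions.columns)
    cent = cent.clip(lower=0)
    cent = cent.div(cent.sum(axis=1), axis=0)       # renormalize fp drift
    return CNModel(centroids=cent, labels=km.labels_.astype(int),
                   inertia=float(km.inertia_))


# ================================================================ interaction

def _neighbor_matrix(g: ImageGraph) -> tuple[np.ndarray, np.ndarray]:
    """Pad neighbor lists to (n, kmax) with -1; also return a validity mask."""
    n = len(g.neighbors)
    kmax = max((len(x) for x in g.neighbors), default=0)
    out = np.full((n, kmax), -1, dtype=np.intp)
    for i, nbrs in enumerate(g.neighbors):
        out[i, :len(nbrs)] = nbrs
    return out, out >= 0


def interaction_test(cells: pd.DataFrame, graph: NeighborGraph,
                     n_perm: int = 1000, alpha: float = 0.01, seed: int = 0,
                     category_col: str = "phenotype",
                     image_col: str = "roi_id",
                     chunk: int = 100) -> pd.DataFrame:
    """Permutation test for pairwise spatial interaction / avoidance.

    Per image and ordered phenotype pair (A, B), the observed statistic is
    the mean number of B neighbors per A cell. The null shuffles phenotype
    labels over the cells of that image with the graph fixed, matching the
    tissue's connectivity and cell-type abundances. Add-one estimators:
    ``p_interact = (1 + #{perm >= obs}) / (n_perm + 1)`` and ``p_avoid``
    analogously with <=. Classification: interaction if p_interact <=
    alpha, else avoidance if p_avoid <= alpha, else none. Pairs involving a
    phenotype absent from an image are recorded with classification
    'absent'.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    all_types = sorted(cells[category_col].astype(str).unique())
    rows = []
    for img, g in sorted(graph.images.items()):
        sub = cells[cells[image_col].astype(str) == img].sort_values(
            "cell_id", kind="stable")
        labels = sub[category_col].astype(str).to_numpy()
        present = sorted(set(labels))
        if len(present) < 2 and len(all_types) >= 2:
            pass  # single-phenotype images are still testable for (A, A)
        nbr, valid = _neighbor_matrix(g)
        n = len(labels)
        t_index = {t: i for i, t in enumerate(present)}
        codes = np.array([t_index[l] for l in labels])
        T = len(present)
        onehot = np.zeros((n, T))
        onehot[np.arange(n), codes] = 1.0
        # neighbor counts per cell per type (invalid slots contribute 0)
        safe = np.where(valid, nbr, 0)
        counts = np.where(valid[..., None], onehot[safe], 0.0).sum(axis=1)  # n x T
        group_n = onehot.sum(axis=0)                                        # cells per type
        obs = (onehot.T @ counts) / group_n[:, None]                        # T x T

        ge = np.zeros((T, T), dtype=np.int64)
        le = np.zeros((T, T), dtype=np.int64)
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perm = rng.permuted(np.tile(codes, (m, 1)), axis=1)             # m x n
            perm_nbr = perm[:, safe]                                        # m x n x kmax
            for b in range(T):
                nb = np.where(valid[None, :, :], perm_nbr == b, False).sum(axis=2)
                for a in range(T):
                    stat = ((perm == a) * nb).sum(axis=1) / group_n[a]
                    ge[a, b] += int((stat >= obs[a, b]).sum())
                    le[a, b] += int((stat <= obs[a, b]).sum())
            done += m

        p_int = (1.0 + ge) / (n_perm + 1.0)
        p_avo = (1.0 + le) / (n_perm + 1.0)
        for a_name in all_types:
            for b_name in all_types:
                if a_name not in t_index or b_name not in t_index:
                    rows.append({"image": img, "phenotype_a": a_name,
                                 "phenotype_b": b_name, "observed": np.nan,
                                 "p_interact": np.nan, "p_avoid": np.nan,
                                 "classification": "absent", "n_perm": n_perm})
                    continue
                a, b = t_index[a_name], t_index[b_name]
                if p_int[a, b] <= alpha:
                    cls = "interaction"
                elif p_avo[a, b] <= alpha:
                    cls = "avoidance"
                else:
                    cls = "none"
                rows.append({"image": img, "phenotype_a": a_name,
                             "phenotype_b": b_name, "observed": float(obs[a, b]),
                             "p_interact": float(p_int[a, b]),
                             "p_avoid": float(p_avo[a, b]),
                             "classification": cls, "n_perm": n_perm})
    return pd.DataFrame(rows)


def interaction_statistic(cells: pd.DataFrame, graph: NeighborGraph,
                          category_col: str = "phenotype",
                          image_col: str = "roi_id") -> pd.DataFrame:
    """Observed mean-neighbor statistic per image and ordered pair (A, B)."""
    res = []
    for img, g in sorted(graph.images.items()):
        sub = cells[cells[image_col].astype(str) == img].sort_values(
            "cell_id", kind="stable")
        labels = sub[category_col].astype(str).to_numpy()
        types = sorted(set(labels))
        for a in types:
            a_cells = np.where(labels == a)[0]
            for b in types:
                cnt = [np.sum(labels[g.neighbors[i]] == b) for i in a_cells]
                res.append({"image": img, "phenotype_a": a, "phenotype_b": b,
                            "observed": float(np.mean(cnt))})
    return pd.DataFrame(res)


# ==================================================================== patches

@dataclass
class Patch:
    patch_id: int
    image: str
    member_cell_ids: np.ndarray
    area_um2: float
    composition: pd.Series                     # phenotype fractions, sum 1


@dataclass
class PatchSet:
    """Detected TLS-like patches for one image, plus per-image density."""

    image: str
    patches: list[Patch]
    density_per_mm2: float | None = None       # patches / ROI area

    @property
    def n_patches(self) -> int:
        return len(self.patches)


def alpha_shape_area(points: np.ndarray, alpha: float) -> float:
    """Area of the alpha-shape of 2-D points.

    Delaunay triangles whose circumradius is at most ``alpha`` are kept and
    their areas summed. Fewer than 3 points (or a degenerate triangulation)
    give area 0.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        return 0.0
    try:
        tri = Delaunay(pts)
    except Exception:
        return 0.0
    total = 0.0
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        ab, ac, bc = b - a, c - a, c - b
        area2 = abs(ab[0] * ac[1] - ab[1] * ac[0])        # 2 * triangle area
        if area2 <= 0:
            continue
        la, lb, lc = np.linalg.norm(bc), np.linalg.norm(ac), np.linalg.norm(ab)
        circum_r = la * lb * lc / (2.0 * area2)
        if circum_r <= alpha:
            total += area2 / 2.0
    return total


def detect_patches(cells: pd.DataFrame, target_phenotypes: "set[str] | list[str]",
                   eps: float = 20.0, min_size: int = 20,
                   pixel_size: float = 1.0, image_col: str = "roi_id",
                   category_col: str = "phenotype",
                   roi_area_mm2: float | None = None) -> dict[str, PatchSet]:
    """Density-based detection of TLS-like patches, per image.

    Cells whose phenotype is in ``target_phenotypes`` are clustered with
    DBSCAN semantics (core point: >= ``min_size`` target cells within
    ``eps`` um, the point itself included; border cells join the first
    core cluster reaching them in cell-id order). Each cluster is a patch
    with member ids, alpha-shape area (alpha = eps) and phenotype
    composition. Images without target cells yield 0 patches.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    targets = set(map(str, target_phenotypes))
    out: dict[str, PatchSet] = {}
    for img, sub in cells.groupby(image_col, sort=True):
        sub = sub.sort_values("cell_id", kind="stable")
        tc = sub[sub[category_col].astype(str).isin(targets)]
        patches: list[Patch] = []
        if len(tc) >= 1:
            pts = tc[["x", "y"]].to_numpy(dtype=float) * pixel_size
            db = DBSCAN(eps=eps, min_samples=min_size).fit(pts)
            for pid in sorted(set(db.labels_) - {-1}):
                sel = db.labels_ == pid
                members = tc.loc[sel]
                comp = (members[category_col].astype(str).value_counts(normalize=True)
                        .sort_index())
                patches.append(Patch(
                    patch_id=int(pid), image=str(img),
                    member_cell_ids=members["cell_id"].to_numpy(),
                    area_um2=alpha_shape_area(pts[sel], alpha=eps),
                    composition=comp))
        density = None
        if roi_area_mm2 is not None and roi_area_mm2 > 0:
            density = len(patches) / roi_area_mm2
        out[str(img)] = PatchSet(image=str(img), patches=patches,
                                 density_per_mm2=density)
    return out


def patch_profile(patch_sets: "dict[str, PatchSet] | PatchSet",
                  cells: pd.DataFrame, markers: list[str],
                  phenotype_filter: "set[str] | list[str] | None" = None,
                  category_col: str = "phenotype") -> pd.DataFrame:
    """Per-patch phenotype composition and mean marker expression.

    Marker means are taken over member cells, optionally restricted to a
    phenotype filter (e.g. exhaustion markers over T cells only). Missing
    markers raise.
    """
    for mk in markers:
        if mk not in cells.columns:
            raise ValueError(f"marker {mk!r} absent from the cell table")
    if isinstance(patch_sets, PatchSet):
        patch_sets = {patch_sets.image: patch_sets}
    indexed = cells.set_index("cell_id")
    rows = []
    for img, ps in sorted(patch_sets.items()):
        for patch in ps.patches:
            members = indexed.loc[patch.member_cell_ids]
            row = {"image": img, "patch_id": patch.patch_id,
                   "n_cells": len(members), "area_um2": patch.area_um2}
            comp = members[category_col].astype(str).value_counts(normalize=True)
            for phen, frac in comp.items():
                row[f"frac_{phen}"] = float(frac)
            sel = members
            if phenotype_filter is not None:
                sel = members[members[category_col].astype(str)
                              .isin(set(map(str, phenotype_filter)))]
            for mk in markers:
                row[mk] = float(sel[mk].mean()) if len(sel) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
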