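"""Synthetic multiplexed-tissue and single-nucleus data with planted truth.

Real acquisitions of this kind (40-plex imaging of FFPE tumor sections,
droplet single-nucleus total-RNA counts) are rarely deposited, so every
downstream stage of the pipeline is validated against data generated here
with known ground truth: cell layouts with site-specific phenotype
composition and planted lymphoid-aggregate ("TLS-like") structure, rendered
ROI images with spillover / shot noise / hot pixels, and negative-binomial
count matrices with marker genes, mitochondrial content and doublets.

Conventions
-----------
* One ``numpy.random.Generator`` per generation call, seeded explicitly;
  the seed is recorded in the returned :class:`GroundTruth`.
* ``generate_layout`` draws background phenotypes as a single multinomial
  over the composition mapping in its iteration order — the first draw from
  the generator — so an oracle with the same seed reproduces the counts.
* Coordinates are pixel units, origin top-left, x = column, y = row; all
  geometry half-open [0, W) x [0, H).
* ``n_cells`` counts background cells; aggregate members are additional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .roi import Channel, Panel, ROIImage, SpilloverMatrix

__all__ = [
    "AggregateSpec", "GroundTruth", "NoiseSpec", "PackingError",
    "generate_layout", "render_roi", "generate_counts",
    "default_panel", "default_intensity_profiles", "default_site_composition",
    "default_count_profiles", "DEFAULT_MARKER_MAP",
    "write_layout", "read_layout", "write_counts_mtx", "read_counts_mtx",
    "disk_offsets",
]


class PackingError(RuntimeError):
    """Raised when a layout cannot be packed at the minimum separation."""


@dataclass(frozen=True)
class AggregateSpec:
    """A planted circular cell aggregate (e.g. a TLS-like B/T follicle)."""

    center: tuple[float, float]  # (x, y) pixels
    radius: float                # pixels
    n_cells: int
    composition: "str | dict[str, float]" = "B"

    def member_probs(self) -> tuple[list[str], np.ndarray]:
        if isinstance(self.composition, str):
            return [self.composition], np.array([1.0])
        names = list(self.composition)
        p = np.array([self.composition[k] for k in names], dtype=float)
        return names, p / p.sum()

    def to_dict(self) -> dict:
        return {"center": list(self.center), "radius": self.radius,
                "n_cells": self.n_cells, "composition": self.composition}

    @classmethod
    def from_dict(cls, d: dict) -> "AggregateSpec":
        comp = d["composition"]
        return cls(tuple(d["center"]), d["radius"], d["n_cells"], comp)


@dataclass
class NoiseSpec:
    """Acquisition noise: Poisson shot noise and isolated hot pixels."""

    poisson: bool = False
    hot_pixel_rate: float = 0.0
    hot_value: float = 100.0


@dataclass
class GroundTruth:
    """Planted truth for one generated artifact (layout, image, or counts).

    ``composition`` columns (sites) sum to 1. Every aggregate member's
    centroid lies within that aggregate's radius of its center.
    """

    seed: int
    phenotypes: list[str] = field(default_factory=list)          # per cell
    centroids: np.ndarray | None = None                          # (n, 2) x, y
    aggregates: list[AggregateSpec] = field(default_factory=list)
    aggregate_of: np.ndarray | None = None                       # per cell, -1 = background
    composition: pd.DataFrame | None = None                      # phenotype x site
    site: str | None = None
    spillover: np.ndarray | None = None
    doublet: np.ndarray | None = None                            # bool per barcode

    def __post_init__(self) -> None:
        if self.composition is not None:
            colsums = np.asarray(self.composition.sum(axis=0), dtype=float)
            if not np.allclose(colsums, 1.0, atol=1e-9):
                raise ValueError("composition matrix columns must sum to 1")

    # -------------------------------------------------------------- IO
    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "seed": int(self.seed),
            "phenotypes": list(self.phenotypes),
            "centroids": None if self.centroids is None else np.asarray(self.centroids).tolist(),
            "aggregates": [a.to_dict() for a in self.aggregates],
            "aggregate_of": None if self.aggregate_of is None
            else np.asarray(self.aggregate_of).tolist(),
            "composition": None if self.composition is None
            else {"index": list(self.composition.index),
                  "columns": list(self.composition.columns),
                  "values": self.composition.to_numpy().tolist()},
            "site": self.site,
            "spillover": None if self.spillover is None else np.asarray(self.spillover).tolist(),
            "doublet": None if self.doublet is None else np.asarray(self.doublet).astype(bool).tolist(),
        }
        text = json.dumps(d, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and source.endswith(".json")):
            source = Path(source).read_text()
        d = json.loads(source)
        comp = d["composition"]
        return cls(
            seed=d["seed"],
            phenotypes=d["phenotypes"],
            centroids=None if d["centroids"] is None else np.asarray(d["centroids"], dtype=float),
            aggregates=[AggregateSpec.from_dict(a) for a in d["aggregates"]],
            aggregate_of=None if d["aggregate_of"] is None
            else np.asarray(d["aggregate_of"], dtype=int),
            composition=None if comp is None else pd.DataFrame(
                np.asarray(comp["values"], dtype=float), index=comp["index"],
                columns=comp["columns"]),
            site=d["site"],
            spillover=None if d["spillover"] is None else np.asarray(d["spillover"], dtype=float),
            doublet=None if d["doublet"] is None else np.asarray(d["doublet"], dtype=bool),
        )

    def equals(self, other: "GroundTruth") -> bool:
        def _arr_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(np.asarray(a), np.asarray(b))

        comp_eq = (self.composition is None and other.composition is None) or (
            self.composition is not None and other.composition is not None
            and self.composition.equals(other.composition))
        return (self.seed == other.seed
                and self.phenotypes == other.phenotypes
                and _arr_eq(self.centroids, other.centroids)
                and self.aggregates == other.aggregates
                and _arr_eq(self.aggregate_of, other.aggregate_of)
                and comp_eq
                and self.site == other.site
                and _arr_eq(self.spillover, other.spillover)
                and _arr_eq(self.doublet, other.doublet))


# ===================================================================== layout

def generate_layout(
    n_cells: int,
    site: str = "lung",
    composition: dict[str, float] | None = None,
    aggregates: "list[AggregateSpec] | tuple[AggregateSpec, ...]" = (),
    shape: tuple[int, int] = (512, 512),
    min_separation: float = 6.0,
    seed: int = 0,
    max_attempts_per_cell: int = 2000,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Place cells in a field with planted aggregates and composition.

    Parameters
    ----------
    n_cells
        Number of *background* (non-aggregate) cells; aggregate members are
        drawn on top of these, so the total is ``n_cells + sum(agg.n_cells)``.
    composition
        Background phenotype probabilities (must sum to 1); drawn as one
        multinomial in the mapping's iteration order.
    aggregates
        Planted disks; member centroids are uniform within each disk.
    shape
        Field (H, W) in pixels.
    min_separation
        Minimum pairwise centroid distance, enforced globally by rejection
        sampling (dart throwing). Default 6 px = 2x the default nucleus
        radius so segmentation ground truth is unambiguous.

    Returns
    -------
    (cells, truth)
        ``cells`` has columns cell_id, x, y, phenotype, aggregate (index of
        the planted aggregate, -1 for background) and site.

    Raises
    ------
    PackingError
        If a centroid cannot be placed within ``max_attempts_per_cell``
        rejection-sampling attempts (infeasible packing).
    """
    H, W = shape
    if H <= 0 or W <= 0:
        raise ValueError("field dimensions must be positive")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    composition = dict(composition or {})
    if n_cells > 0:
        total_p = sum(composition.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"composition probabilities sum to {total_p}, expected 1")
    for a in aggregates:
        if a.radius <= 0:
            raise ValueError("aggregate radii must be > 0")

    rng = np.random.default_rng(seed)
    # First draw: background phenotype counts (multinomial over mapping order).
    names = list(composition)
    if n_cells > 0 and names:
        counts = rng.multinomial(n_cells, [composition[k] for k in names])
        bg_labels = np.repeat(names, counts).tolist()
    else:
        bg_labels = []

    xs: list[float] = []
    ys: list[float] = []
    labels: list[str] = []
    agg_of: list[int] = []

    cell_w = max(min_separation, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    min_sq = min_separation ** 2

    def _ok(x: float, y: float) -> bool:
        gx, gy = int(x // cell_w), int(y // cell_w)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), ()):
                    if (xs[j] - x) ** 2 + (ys[j] - y) ** 2 < min_sq:
                        return False
        return True

    def _add(x: float, y: float, lab: str, agg: int) -> None:
        idx = len(xs)
        xs.append(x)
        ys.append(y)
        labels.append(lab)
        agg_of.append(agg)
        grid.setdefault((int(x // cell_w), int(y // cell_w)), []).append(idx)

    # Aggregate members first (uniform in each disk, clipped to the field).
    for ai, agg in enumerate(aggregates):
        anames, aprobs = agg.member_probs()
        acounts = rng.multinomial(agg.n_cells, aprobs)
        member_labels = np.repeat(anames, acounts)
        cx, cy = agg.center
        for lab in member_labels:
            for _ in range(max_attempts_per_cell):
                r = agg.radius * np.sqrt(rng.random())
                th = rng.random() * 2 * np.pi
                x, y = cx + r * np.cos(th), cy + r * np.sin(th)
                if 0 <= x < W and 0 <= y < H and _ok(x, y):
                    _add(x, y, str(lab), ai)
                    break
            else:
                raise PackingError(
                    f"could not place aggregate {ai} member at separation "
                    f">= {min_separation} after {max_attempts_per_cell} attempts")

    # Background cells by rejection sampling over the whole field.
    for lab in bg_labels:
        for _ in range(max_attempts_per_cell):
            x, y = rng.random() * W, rng.random() * H
            if _ok(x, y):
                _add(x, y, str(lab), -1)
                break
        else:
            raise PackingError(
                f"could not place background cell at separation >= {min_separation} "
                f"after {max_attempts_per_cell} attempts ({len(xs)} placed)")

    cells = pd.DataFrame({
        "cell_id": np.arange(len(xs)),
        "x": np.asarray(xs, dtype=float),
        "y": np.asarray(ys, dtype=float),
        "phenotype": labels,
        "aggregate": np.asarray(agg_of, dtype=int),
        "site": site,
    })

    phen_all = sorted(set(labels)) or sorted(composition)
    comp_col = pd.Series({p: composition.get(p, 0.0) for p in phen_all}, dtype=float)
    if comp_col.sum() > 0:
        comp_df = pd.DataFrame({site: comp_col / comp_col.sum()})
    else:
        comp_df = None
    truth = GroundTruth(
        seed=seed,
        phenotypes=labels,
        centroids=cells[["x", "y"]].to_numpy(),
        aggregates=list(aggregates),
        aggregate_of=np.asarray(agg_of, dtype=int),
        composition=comp_df,
        site=site,
    )
    return cells, truth


# ==================================================================== imaging

def disk_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer (dy, dx) offsets of a rasterized disk of the given radius."""
    r = int(np.floor(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return dy[keep], dx[keep]


def render_roi(
    cells: pd.DataFrame,
    panel: Panel,
    profiles: pd.DataFrame,
    spillover: SpilloverMatrix | None = None,
    noise: NoiseSpec | None = None,
    shape: tuple[int, int] = (512, 512),
    nucleus_radius: float = 1.5,
    cell_radius: float = 4.0,
    roi_id: str = "roi",
    site: str | None = None,
    pixel_size: float = 1.0,
    seed: int = 0,
    return_truth: bool = False,
) -> "ROIImage | tuple[ROIImage, np.ndarray]":
    """Render a cell layout into a multi-channel ROI image.

    Each cell contributes a rasterized nucleus disk on the nucleus channel
    and a whole-cell disk on every other channel, scaled by its phenotype's
    intensity profile (``profiles``: phenotype x channel-name). The observed
    image is the true rendering mixed through the spillover matrix, with
    optional Poisson shot noise and a configured rate of hot pixels.

    With ``return_truth=True`` also returns the pre-spillover, pre-noise
    true image (C x H x W).
    """
    noise = noise or NoiseSpec()
    H, W = shape
    C = len(panel)
    if spillover is not None and spillover.n != C:
        raise ValueError(
            f"spillover matrix dimension {spillover.n} != panel size {C}")
    missing = set(cells["phenotype"]) - set(profiles.index)
    if missing:
        raise ValueError(f"no intensity profile for phenotypes: {sorted(missing)}")
    missing_ch = [n for n in panel.names if n not in profiles.columns]
    if missing_ch:
        raise ValueError(f"profiles missing panel channels: {missing_ch}")

    prof = profiles.loc[:, panel.names]
    nuc_idx = panel.nucleus_index
    true = np.zeros((C, H, W), dtype=float)
    nuc_dy, nuc_dx = disk_offsets(nucleus_radius)
    cel_dy, cel_dx = disk_offsets(cell_radius)

    cx = np.rint(cells["x"].to_numpy()).astype(int)
    cy = np.rint(cells["y"].to_numpy()).astype(int)
    phen = cells["phenotype"].to_numpy()
    for i in range(len(cells)):
        p = prof.loc[phen[i]].to_numpy(dtype=float)
        for ch in range(C):
            if p[ch] == 0:
                continue
            dy, dx = (nuc_dy, nuc_dx) if ch == nuc_idx else (cel_dy, cel_dx)
            rr, cc = cy[i] + dy, cx[i] + dx
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            true[ch, rr[keep], cc[keep]] += p[ch]

    if spillover is not None:
        observed = np.einsum("ihw,ij->jhw", true, spillover.values)
    else:
        observed = true.copy()

    rng = np.random.default_rng(seed)
    if noise.poisson:
        observed = rng.poisson(observed).astype(float)
    if noise.hot_pixel_rate > 0:
        total = observed.size
        n_hot = rng.binomial(total, noise.hot_pixel_rate)
        if n_hot:
            flat = rng.choice(total, size=n_hot, replace=False)
            observed.reshape(-1)[flat] += noise.hot_value

    roi = ROIImage(observed, panel, roi_id=roi_id,
                   site=site if site is not None else str(cells["site"].iloc[0]) if len(cells) else "",
                   pixel_size=pixel_size,
                   meta={"seed": seed,
                         "spillover": None if spillover is None else spillover.values,
                         "nucleus_radius": nucleus_radius, "cell_radius": cell_radius})
    return (roi, true) if return_truth else roi


# ===================================================================== counts

def generate_counts(
    n_cells: int,
    composition: "pd.DataFrame | dict[str, float]",
    profiles: pd.DataFrame,
    site_probs: dict[str, float] | None = None,
    dispersion: float = 2.0,
    mito_fraction: float = 0.05,
    n_mito_genes: int = 10,
    doublet_rate: float = 0.0,
    mito_prefix: str = "MT-",
    patients_per_site: int = 2,
    seed: int = 0,
) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a negative-binomial gene-by-cell count matrix with planted truth.

    Parameters
    ----------
    composition
        phenotype x site probabilities (columns sum to 1), or a plain
        mapping for a single site.
    profiles
        genes x phenotype matrix of NB means; marker genes are simply genes
        with elevated means in their phenotype.
    dispersion
        NB shape ``theta`` (> 0): var = mu + mu^2 / theta. Large theta
        approaches the Poisson limit.
    mito_fraction
        Target expected fraction of counts from mitochondrial genes, which
        are appended with ``mito_prefix`` names.
    doublet_rate
        Fraction of barcodes that receive the summed counts of a second,
        randomly chosen parent cell; flagged in the returned GroundTruth
        and in ``obs['is_doublet']``.
    """
    if isinstance(composition, dict):
        composition = pd.DataFrame({"site0": pd.Series(composition, dtype=float)})
    comp = composition.astype(float)
    if not np.allclose(comp.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("composition columns must each sum to 1")
    if (profiles.to_numpy() < 0).any():
        raise ValueError("NB means must be >= 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    if not (0 <= doublet_rate < 1):
        raise ValueError("doublet_rate must lie in [0, 1)")
    missing = set(comp.index) - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles missing phenotypes: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    sites = list(comp.columns)
    if site_probs is None:
        sp_vec = np.full(len(sites), 1.0 / len(sites))
    else:
        sp_vec = np.array([site_probs[s] for s in sites], dtype=float)
        sp_vec = sp_vec / sp_vec.sum()
    site_idx = rng.choice(len(sites), size=n_cells, p=sp_vec)

    phen_names = list(comp.index)
    cum = comp.to_numpy().T.cumsum(axis=1)          # site x phenotype
    u = rng.random(n_cells)
    phen_idx = np.array([np.searchsorted(cum[s], v) for s, v in zip(site_idx, u)])
    phenotypes = [phen_names[i] for i in phen_idx]

    mu_base = profiles.loc[:, phen_names].to_numpy(dtype=float).T  # phenotype x gene
    # Mitochondrial genes: means chosen so the expected mito fraction of
    # counts matches ``mito_fraction`` for every phenotype.
    totals = mu_base.sum(axis=1)
    mito_total = mito_fraction / (1.0 - mito_fraction) * totals
    mito_mu = np.repeat(mito_total[:, None] / n_mito_genes, n_mito_genes, axis=1)
    mu_all = np.hstack([mu_base, mito_mu])           # phenotype x (genes + mito)
    genes = list(profiles.index) + [f"{mito_prefix}{i + 1}" for i in range(n_mito_genes)]

    mu = mu_all[phen_idx]                            # cells x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        p = dispersion / (dispersion + mu)
    counts = np.zeros_like(mu, dtype=np.int64)
    nz = mu > 0
    counts[nz] = rng.negative_binomial(dispersion, p[nz])

    doublet = np.zeros(n_cells, dtype=bool)
    n_dbl = int(round(doublet_rate * n_cells))
    if n_dbl:
        idx = rng.choice(n_cells, size=n_dbl, replace=False)
        partners = rng.integers(0, n_cells, size=n_dbl)
        clash = partners == idx
        while clash.any():
            partners[clash] = rng.integers(0, n_cells, size=int(clash.sum()))
            clash = partners == idx
        counts[idx] += counts[partners]
        doublet[idx] = True

    obs = pd.DataFrame({
        "site": [sites[s] for s in site_idx],
        "patient": [f"{sites[s]}-P{rng.integers(1, patients_per_site + 1)}"
                    for s in site_idx],
        "phenotype": phenotypes,
        "is_doublet": doublet,
    }, index=[f"cell{i:06d}" for i in range(n_cells)])
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs,
                       var=pd.DataFrame(index=genes))
    adata.uns["seed"] = int(seed)

    truth = GroundTruth(seed=seed, phenotypes=phenotypes, composition=comp,
                        doublet=doublet)
    return adata, truth


# =================================================================== defaults
# The defaults below define the study conditions the generator emulates: a
# compact lineage panel, per-phenotype marker intensity profiles, and a
# site-composition matrix in which B/plasma/T cells are enriched at the
# "immunogenic" sites (primary lung, adrenal) while collagen I dominates the
# immunosuppressive ones (brain, liver).

def default_panel() -> Panel:
    return Panel(tuple(Channel(n, r) for n, r in [
        ("DNA1", "nucleus"),
        ("CD20", "lineage"),
        ("CD138", "lineage"),
        ("CD3", "lineage"),
        ("CD4", "lineage"),
        ("CD8a", "lineage"),
        ("CD68", "lineage"),
        ("PanCK", "membrane"),
        ("CD31", "membrane"),
        ("TIM3", "membrane"),
        ("CollagenI", "structure"),
    ]))


IMC_PHENOTYPES = ("B", "plasma", "memory CD4 T", "CD8 T", "macrophage",
                  "epithelial", "endothelial", "collagen I")


def default_intensity_profiles(panel: Panel | None = None) -> pd.DataFrame:
    """Phenotype x channel mean intensities (arbitrary counts units)."""
    panel = panel or default_panel()
    rows = {
        "B":            {"DNA1": 10, "CD20": 8, "CD3": 0.2},
        "plasma":       {"DNA1": 10, "CD138": 8, "CD20": 0.5},
        "memory CD4 T": {"DNA1": 10, "CD3": 8, "CD4": 6},
        "CD8 T":        {"DNA1": 10, "CD3": 8, "CD8a": 6},
        "macrophage":   {"DNA1": 10, "CD68": 8},
        "epithelial":   {"DNA1": 10, "PanCK": 9},
        "endothelial":  {"DNA1": 10, "CD31": 8},
        "collagen I":   {"DNA1": 10, "CollagenI": 9},
    }
    prof = pd.DataFrame(0.0, index=list(rows), columns=panel.names)
    for phen, d in rows.items():
        for ch, v in d.items():
            prof.loc[phen, ch] = float(v)
    return prof


def default_site_composition() -> pd.DataFrame:
    """Phenotype x site probabilities (columns sum to 1).

    Plasma cells are 3x over-represented in the adrenal site relative to
    primary lung, and collagen I is deposited in brain/liver.
    """
    data = {
        #                lung  brain  liver adrenal
        "B":            [0.12, 0.02, 0.03, 0.15],
        "plasma":       [0.06, 0.02, 0.03, 0.18],
        "memory CD4 T": [0.14, 0.05, 0.05, 0.15],
        "CD8 T":        [0.10, 0.05, 0.06, 0.12],
        "macrophage":   [0.15, 0.16, 0.15, 0.10],
        "epithelial":   [0.30, 0.40, 0.35, 0.20],
        "endothelial":  [0.05, 0.10, 0.13, 0.05],
        "collagen I":   [0.08, 0.20, 0.20, 0.05],
    }
    return pd.DataFrame(data, index=["lung", "brain", "liver", "adrenal"]).T


RNA_PHENOTYPES = ("B", "plasma", "T", "macrophage", "epithelial")

DEFAULT_MARKER_MAP: dict[str, list[str]] = {
    "B cells": ["EBF1", "BCL11A", "BANK1", "MS4A1", "CD79A"],
    "plasma cells": ["IGHA1", "IGHG1", "JCHAIN", "MZB1", "XBP1"],
    "T cells": ["CD3E", "SKAP1", "IKZF1", "CD2", "IL7R"],
    "macrophages": ["CTSB", "SPP1", "MRC1", "CD68", "C1QB"],
    "epithelial cells": ["MUC1", "SFTPB", "EPCAM", "KRT8", "KRT18"],
}

_RNA_MARKERS = {
    "B": ["EBF1", "BCL11A", "BANK1", "MS4A1", "CD79A", "CD19", "PAX5", "CD37"],
    "plasma": ["IGHA1", "IGHG1", "JCHAIN", "MZB1", "XBP1", "IGHG3", "SDC1", "PRDM1"],
    "T": ["CD3E", "SKAP1", "IKZF1", "CD2", "IL7R", "TRAC", "CD3D", "THEMIS"],
    "macrophage": ["CTSB", "SPP1", "MRC1", "CD68", "C1QB", "LYZ", "CSF1R", "AIF1"],
    "epithelial": ["MUC1", "SFTPB", "EPCAM", "KRT8", "KRT18", "MUC16", "NAPSA", "SFTPC"],
}


def default_count_profiles(
    phenotypes: tuple[str, ...] = RNA_PHENOTYPES,
    n_background_genes: int = 300,
    marker_mean: float = 20.0,
    marker_background_mean: float = 0.2,
    seed: int = 12345,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Genes x phenotype NB-mean profiles with named marker genes.

    Background gene means are log-normal draws shared across phenotypes;
    each phenotype's markers have mean ``marker_mean`` in that phenotype and
    ``marker_background_mean`` elsewhere (a 100-fold planted contrast).
    Returns the profile matrix and the phenotype -> marker-gene map.
    """
    rng = np.random.default_rng(seed)
    bg_names = [f"G{i:04d}" for i in range(n_background_genes)]
    bg_means = np.exp(rng.normal(-0.7, 1.0, size=n_background_genes))
    rows = []
    index = []
    for g, m in zip(bg_names, bg_means):
        index.append(g)
        rows.append({p: m for p in phenotypes})
    markers = {p: list(_RNA_MARKERS[p]) for p in phenotypes}
    for p in phenotypes:
        for g in markers[p]:
            index.append(g)
            rows.append({q: (marker_mean if q == p else marker_background_mean)
                         for q in phenotypes})
    prof = pd.DataFrame(rows, index=index)
    return prof, markers


def default_rna_site_composition() -> pd.DataFrame:
    data = {
        #             lung  brain  liver adrenal
        "B":          [0.15, 0.04, 0.05, 0.18],
        "plasma":     [0.08, 0.03, 0.04, 0.24],
        "T":          [0.20, 0.08, 0.08, 0.22],
        "macrophage": [0.22, 0.25, 0.28, 0.16],
        "epithelial": [0.35, 0.60, 0.55, 0.20],
    }
    return pd.DataFrame(data, index=["lung", "brain", "liver", "adrenal"]).T


# ======================================================================== IO

def write_layout(cells: pd.DataFrame, truth: GroundTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells.to_csv(outdir / "cells.csv", index=False)
    truth.to_json(outdir / "groundtruth.json")


def read_layout(outdir: str | Path) -> tuple[pd.DataFrame, GroundTruth]:
    outdir = Path(outdir)
    cells = pd.read_csv(outdir / "cells.csv")
    truth = GroundTruth.from_json((outdir / "groundtruth.json").read_text())
    return cells, truth


def write_counts_mtx(adata: ad.AnnData, outdir: str | Path) -> None:
    """MTX (genes x cells) + genes.tsv / barcodes.tsv / metadata.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if sp.issparse(X):
        mat = X.T.tocoo()
    else:
        mat = sp.coo_matrix(np.asarray(X).T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    adata.obs.to_csv(outdir / "metadata.csv")


def read_counts_mtx(outdir: str | Path) -> ad.AnnData:
    outdir = Path(outdir)
    mat = scipy.io.mmread(str(outdir / "matrix.mtx")).tocsr().T.tocsr()
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=mat.astype(np.int64),
                       obs=pd.DataFrame(index=barcodes.to_list()),
                       var=pd.DataFrame(index=genes.to_list()))
    meta_path = outdir / "metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        adata.obs = meta.loc[adata.obs_names]
    return adata
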