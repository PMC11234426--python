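"""Tissue enrichment and signature scoring.

*Ro/e* quantifies preferential tissue enrichment of a cell cluster: the
ratio of observed to expected cell numbers per (cluster, site), with the
expected counts from the chi-squared independence model
``E(c, s) = rowtotal(c) * coltotal(s) / grandtotal``. Ro/e > 1 flags
enrichment, < 1 depletion.

*ssGSEA* scores the coordinate up-regulation of a gene set in a single
sample with a rank-weighted running sum: genes are ranked by expression,
and the score is the summed difference between the |rank|^alpha-weighted
ECDF over set members and the unweighted ECDF over non-members. Being
rank-based, scores are invariant under strictly monotone transforms of the
expression values.

Site-wise frequency comparisons use the two-sided Wilcoxon rank-sum test
for two groups (exact when both groups have <= 10 samples and no ties) and
the Kruskal-Wallis test for more, with Benjamini-Hochberg adjustment
across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RoeTable", "GeneSet", "roe", "ssgsea", "score_signature",
    "compare_site_frequencies", "read_gmt", "TRM_SIGNATURE",
]

# Core tissue-resident-macrophage signature. The "MHC-II" family member is
# expanded to a configurable default of four classical class-II genes.
# TIMD4 occasionally appears in the literature with the transposed symbol
# "TIDM4"; the HGNC symbol is TIMD4 and that is what ships here.
MHC_II_DEFAULT = ["HLA-DRA", "HLA-DRB1", "HLA-DPA1", "HLA-DPB1"]
TRM_SIGNATURE = ["TIMD4", "LYVE1", "FOLR2", "CCR2", *MHC_II_DEFAULT]


@dataclass
class RoeTable:
    """Observed, expected and ratio matrices for clusters x sites.

    Entries with zero expected count are undefined and reported as NaN
    (flagged in ``undefined``), never as infinity.
    """

    observed: pd.DataFrame
    expected: pd.DataFrame
    ratio: pd.DataFrame
    undefined: pd.DataFrame


@dataclass(frozen=True)
class GeneSet:
    """Named gene set with a rank-weight exponent alpha (default 0.25)."""

    name: str
    genes: tuple[str, ...]
    alpha: float = 0.25

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        object.__setattr__(self, "genes", tuple(self.genes))


def roe(observed: pd.DataFrame) -> RoeTable:
    """Observed / expected tissue enrichment under independence.

    ``observed`` is a clusters x sites count table (all entries >= 0,
    grand total > 0). The conservation identity
    ``sum_s E(c, s) * Roe(c, s) / rowtotal(c) = 1`` holds for every
    cluster with a positive row total.
    """
    obs = observed.astype(float)
    vals = obs.to_numpy()
    if (vals < 0).any():
        raise ValueError("observed counts must be >= 0")
    total = vals.sum()
    if total <= 0:
        raise ValueError("grand total must be > 0")
    row = vals.sum(axis=1, keepdims=True)
    col = vals.sum(axis=0, keepdims=True)
    expected = row @ col / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, vals / np.where(expected > 0, expected, 1.0),
                         np.nan)
    undefined = expected <= 0
    mk = lambda a: pd.DataFrame(a, index=obs.index, columns=obs.columns)
    return RoeTable(observed=obs, expected=mk(expected), ratio=mk(ratio),
                    undefined=mk(undefined))


def ssgsea(expression: pd.DataFrame, gene_set: GeneSet,
           alpha: float | None = None, normalize: bool = False) -> pd.Series:
    """Single-sample gene-set enrichment scores (running-sum statistic).

    ``expression`` is genes x samples. Per sample, genes are ranked by
    expression (descending walk; ties get their average rank), and the
    score is ``sum_i [P_in^w(i) - P_out(i)]`` where ``P_in^w`` is the
    |rank|^alpha-weighted ECDF over set members and ``P_out`` the
    unweighted ECDF over non-members. With ``normalize`` the raw scores are
    divided by their range across the supplied samples.
    """
    a = gene_set.alpha if alpha is None else alpha
    if a < 0:
        raise ValueError("alpha must be >= 0")
    genes = expression.index
    member = genes.isin(gene_set.genes)
    m = int(member.sum())
    if m == 0:
        raise ValueError(f"gene set {gene_set.name!r} has no member in the matrix")
    N = len(genes)
    if m == N:
        raise ValueError(f"gene set {gene_set.name!r} covers every gene; "
                         "no outside ECDF exists")
    scores = {}
    for col in expression.columns:
        v = expression[col].to_numpy(dtype=float)
        r = rankdata(v)                                   # ascending, ties averaged
        order = np.lexsort((np.arange(N), -r))            # descending, stable
        in_set = member[order]
        w = np.zeros(N)
        w[in_set] = np.abs(r[order][in_set]) ** a
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~in_set) / (N - m)
        scores[col] = float(np.sum(p_in - p_out))
    s = pd.Series(scores, name=gene_set.name)
    if normalize:
        rng = s.max() - s.min()
        if rng > 0:
            s = s / rng
    return s


def score_signature(expression: pd.DataFrame, genes: list[str],
                    method: str = "mean_z", alpha: float = 0.25,
                    name: str = "signature") -> pd.Series:
    """Per-sample signature score: mean z-score or ssGSEA.

    ``expression`` is genes x samples. ``mean_z`` averages per-gene
    z-scores (across samples); ``ssgsea`` delegates to :func:`ssgsea`.
    Signature genes missing from the matrix are dropped with a warning;
    if all are missing, an error is raised.
    """
    present = [g for g in genes if g in expression.index]
    missing = [g for g in genes if g not in expression.index]
    if missing:
        warnings.warn(f"signature genes absent from matrix: {missing}")
    if not present:
        raise ValueError(f"no gene of signature {name!r} is present in the matrix")
    if method == "mean_z":
        sub = expression.loc[present]
        sd = sub.std(axis=1, ddof=0).replace(0, 1.0)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        return z.mean(axis=0).rename(name)
    if method == "ssgsea":
        return ssgsea(expression, GeneSet(name, tuple(present), alpha=alpha))
    raise ValueError(f"unknown method {method!r}; expected 'mean_z' or 'ssgsea'")


def compare_site_frequencies(freqs: pd.DataFrame, groups: pd.Series,
                             ) -> pd.DataFrame:
    """Compare per-sample frequencies between site groups, per feature.

    ``freqs`` is samples x features (e.g. cell-type or CN fractions per
    image); ``groups`` maps each sample to its site. Two groups use the
    two-sided Wilcoxon rank-sum test (exact for <= 10 samples per group
    without ties, normal approximation with tie correction otherwise);
    more than two use Kruskal-Wallis. P-values are BH-adjusted across
    features.
    """
    groups = pd.Series(groups)
    groups = groups.loc[freqs.index]
    levels = [g for g in pd.unique(groups)]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    per_group = [freqs.loc[groups == g] for g in levels]
    for g, sub in zip(levels, per_group):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} has 0 samples")
    rows = []
    for feat in freqs.columns:
        samples = [sub[feat].to_numpy(dtype=float) for sub in per_group]
        if len(levels) == 2:
            a, b = samples
            exact = (a.size <= 10 and b.size <= 10
                     and np.unique(np.concatenate([a, b])).size == a.size + b.size)
            res = mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
            rows.append({"feature": feat, "test": "wilcoxon-rank-sum",
                         "statistic": float(res.statistic),
                         "pvalue": float(res.pvalue)})
        else:
            if all(np.all(s == samples[0][0]) for s in samples):
                rows.append({"feature": feat, "test": "kruskal-wallis",
                             "statistic": 0.0, "pvalue": 1.0})
                continue
            res = kruskal(*samples)
            rows.append({"feature": feat, "test": "kruskal-wallis",
                         "statistic": float(res.statistic),
                         "pvalue": float(res.pvalue)})
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def read_gmt(path: str | Path, alpha: float = 0.25) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        name = parts[0]
        genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
        sets[name] = GeneSet(name, genes, alpha=alpha)
    return sets
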