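"""Shared synthetic fixtures for the test suite.

Everything is generated programmatically with fixed seeds; nothing is read
from disk except what the tests themselves write to tmp paths.
"""

import numpy as np
import pandas as pd
import pytest

from tmetopo import syndata
from tmetopo.roi import Channel, Panel


@pytest.fixture(scope="session")
def panel() -> Panel:
    return syndata.default_panel()


@pytest.fixture(scope="session")
def profiles(panel) -> pd.DataFrame:
    return syndata.default_intensity_profiles(panel)


@pytest.fixture(scope="session")
def two_channel_panel() -> Panel:
    return Panel((Channel("DNA", "nucleus"), Channel("CD20", "lineage")))


@pytest.fixture(scope="session")
def small_layout():
    """~200-cell two-phenotype layout on a 220x220 field."""
    cells, truth = syndata.generate_layout(
        200, site="lung", composition={"B": 0.3, "epithelial": 0.7},
        shape=(220, 220), seed=7)
    return cells, truth


@pytest.fixture(scope="session")
def rna_dataset():
    """~1200-cell five-phenotype negative-binomial count matrix."""
    prof, markers = syndata.default_count_profiles()
    adata, truth = syndata.generate_counts(
        1200, syndata.default_rna_site_composition(), prof,
        doublet_rate=0.02, seed=11)
    return adata, truth, markers


def brute_force_interaction(cells: pd.DataFrame, graph, category_col="phenotype"):
    """Independent all-pairs oracle for the mean-neighbor statistic."""
    rows = []
    for img, g in sorted(graph.images.items()):
        sub = cells[cells["roi_id"].astype(str) == img].sort_values(
            "cell_id", kind="stable").reset_index(drop=True)
        labels = sub[category_col].astype(str).to_numpy()
        nbr_sets = [set(g.cell_ids[n] for n in nbrs) for nbrs in g.neighbors]
        ids = g.cell_ids
        for a in sorted(set(labels)):
            for b in sorted(set(labels)):
                counts = []
                for i in range(len(sub)):
                    if labels[i] != a:
                        continue
                    c = 0
                    for j in range(len(sub)):
                        if i != j and labels[j] == b and ids[j] in nbr_sets[i]:
                            c += 1
                    counts.append(c)
                rows.append({"image": img, "phenotype_a": a, "phenotype_b": b,
                             "observed": float(np.mean(counts))})
    return pd.DataFrame(rows)
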