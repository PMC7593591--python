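"""Multi-sample comparison of taxonomic profiles.

Profiles are compared on a taxonomy tree in which every taxon at depth
1..d is a node carrying a branch of unit length.  With ``A_i`` the
number of pairs in sample A classified to node i or its descendants and
``A_T`` the sample total, the raw abundance-weighted distance is

    u = sum_i | A_i/A_T - B_i/B_T |

and, because the tree is ultrametric with unit branches, the normalised
UniFrac-like metric is ``u' = u / (2 d)`` where d is the comparison
level (e.g. 4 for order).  u' lies in [0, 1]: 0 for identical
normalised cumulative counts and 1 for domain-disjoint samples.

Also builds the barplot / heatmap matrices (percent of classified pairs
per taxon and sample, minor taxa pooled as "Other") with hierarchical
ordering of samples by the UniFrac-like distance.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from ssuflash import config
from ssuflash.taxprofile import TaxPath, TaxProfile, render_label


@dataclass
class TaxTree:
    """Cumulative per-sample counts on taxonomy-prefix nodes up to depth d."""

    level: int
    sample_ids: tuple[str, ...]
    # node (non-empty path prefix) -> per-sample cumulative counts
    node_counts: dict[TaxPath, np.ndarray] = field(default_factory=dict)
    totals: np.ndarray = field(default_factory=lambda: np.zeros(0))


def build_taxtree(
    profiles: Sequence[Mapping[TaxPath, int] | TaxProfile],
    level: int,
    sample_ids: Sequence[str] | None = None,
) -> TaxTree:
    """Cumulative node counts for each sample on the shared taxonomy tree.

    ``profiles`` are per-sample taxon counts (a mapping from taxonomy
    path to pair count, or a :class:`TaxProfile`).  Every non-empty
    prefix of each path, truncated to ``level``, is a node; a path
    contributes its count to all of its ancestor nodes.  Pairs
    classified above ``level`` contribute to their ancestors only.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    counts_list = []
    ids = []
    for i, p in enumerate(profiles):
        if isinstance(p, TaxProfile):
            counts_list.append(p.counts)
            ids.append(p.sample_id)
        else:
            counts_list.append(dict(p))
            ids.append(f"S{i}")
    if sample_ids is not None:
        ids = list(sample_ids)
    ns = len(counts_list)
    nodes: dict[TaxPath, np.ndarray] = defaultdict(lambda: np.zeros(ns))
    totals = np.zeros(ns)
    for si, counts in enumerate(counts_list):
        for path, n in counts.items():
            path = tuple(path[:level])
            totals[si] += n
            for depth in range(1, len(path) + 1):
                nodes[path[:depth]][si] += n
    return TaxTree(level=level, sample_ids=tuple(ids),
                   node_counts=dict(nodes), totals=totals)


def unifrac_like(tree: TaxTree, sample_a: str, sample_b: str,
                 level: int | None = None) -> float:
    """Normalised abundance-weighted taxonomic UniFrac-like distance u'.

    ``u' = u / (2 d)`` with u the sum over tree nodes of the absolute
    difference in the samples' normalised cumulative counts.
    """
    d = tree.level if level is None else level
    ia = tree.sample_ids.index(sample_a)
    ib = tree.sample_ids.index(sample_b)
    at, bt = tree.totals[ia], tree.totals[ib]
    if at == 0 or bt == 0:
        raise ValueError("UniFrac-like distance undefined for an empty sample")
    u = 0.0
    for counts in tree.node_counts.values():
        u += abs(counts[ia] / at - counts[ib] / bt)
    return u / (2 * d)


@dataclass
class DistanceMatrix:
    level: int
    frame: pd.DataFrame  # symmetric, zero diagonal, entries in [0, 1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)


def distance_matrix(profiles: Sequence[TaxProfile],
                    level: int | None = None) -> DistanceMatrix:
    """Pairwise u' over a set of profiles summarised at one level."""
    lvl = level if level is not None else profiles[0].level
    tree = build_taxtree(profiles, level=lvl)
    ids = list(tree.sample_ids)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = unifrac_like(tree, ids[i], ids[j])
    return DistanceMatrix(level=lvl,
                          frame=pd.DataFrame(mat, index=ids, columns=ids))


# --------------------------------------------------------------------------
# Barplot / heatmap matrices
# --------------------------------------------------------------------------

def _leaf_order(dist: np.ndarray, labels: list[str]) -> list[str]:
    if len(labels) <= 2:
        return labels
    z = linkage(squareform(dist, checks=False), method="average")
    return [labels[i] for i in leaves_list(z)]


def comparison_matrices(
    profiles: Sequence[TaxProfile],
    level: int | None = None,
    top_n: int = config.COMPARE_TOP_N,
) -> tuple[pd.DataFrame, pd.DataFrame, DistanceMatrix]:
    """Barplot table, clustered heatmap table, and u' distance matrix.

    Heatmap rows are taxa as percent of classified pairs per sample
    (columns); taxa outside the overall ``top_n`` are pooled as
    "Other".  Samples are ordered by average-linkage clustering on the
    UniFrac-like distance, taxa by clustering on the Euclidean distance
    of their percentage rows ("Other" appended last, excluded from
    clustering).  Per-sample percentages sum to 100.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two samples to compare")
    lvl = level if level is not None else profiles[0].level
    dm = distance_matrix(profiles, level=lvl)
    ids = dm.sample_ids
    pct = pd.DataFrame({
        p.sample_id: {render_label(k, lvl): 100.0 * v
                      for k, v in p.fractions().items()}
        for p in profiles
    }).fillna(0.0)
    # long-format barplot table before pooling
    barplot = (pct.rename_axis("taxon").reset_index()
               .melt(id_vars="taxon", var_name="sample", value_name="percent"))
    # pool minor taxa
    order = pct.sum(axis=1).sort_values(ascending=False)
    major = list(order.index[:top_n])
    minor = [t for t in pct.index if t not in major]
    heat = pct.loc[major]
    # cluster samples on u', taxa on Euclidean distance of their rows
    col_order = _leaf_order(dm.frame.values, ids)
    if len(major) > 2:
        zt = linkage(heat.values, method="average", metric="euclidean")
        row_order = [major[i] for i in leaves_list(zt)]
    else:
        row_order = major
    heat = heat.loc[row_order, col_order]
    if minor:
        heat.loc["Other"] = pct.loc[minor, col_order].sum(axis=0)
    return barplot, heat, dm
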