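"""Hierarchically clustered heat maps of log-PRR signal matrices.

Three resolutions support drill-down exploration of class signals:

1. all drug classes x all ADE classes (class-level PRR);
2. the member drugs of one focal class x ADE classes (drug-level PRR);
3. the member drugs x the individual ADE terms of selected ADE classes.

Both axes are ordered by agglomerative clustering with Euclidean distance
and complete linkage, so rows/columns with similar signal profiles sit
together; a uniform class effect then shows as a solid elevated column in
the level-2 map, a subset effect as an incomplete column, and a
single-drug association as an isolated spot.  The exported TSV of the
permuted matrix is the testable artifact; rendering (low = red, through
yellow, high = white) is optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .signals import AnalysisUniverse, SignalMatrix, signal_scan, to_matrix

__all__ = ["ClusteredMatrix", "cluster_axis", "build_heatmap", "export", "render"]


def cluster_axis(
    matrix: SignalMatrix, axis: int
) -> tuple[np.ndarray, list[int]]:
    """Complete-linkage / Euclidean clustering of one matrix axis.

    Returns the linkage table and the leaf order (left-first dendrogram
    traversal).  A single item yields a trivial tree and order [0].
    """
    X = matrix.values if axis == 0 else matrix.values.T
    n = X.shape[0]
    if n == 0:
        raise ValueError("cannot cluster an empty axis")
    if n == 1:
        return np.empty((0, 4)), [0]
    Z = linkage(X, method="complete", metric="euclidean")
    return Z, [int(i) for i in leaves_list(Z)]


@dataclass
class ClusteredMatrix:
    """A signal matrix with clustering-derived row and column orders."""

    matrix: SignalMatrix
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray

    def permuted(self) -> SignalMatrix:
        """The matrix with rows/columns in dendrogram leaf order."""
        return SignalMatrix(
            [self.matrix.row_ids[i] for i in self.row_order],
            [self.matrix.col_ids[j] for j in self.col_order],
            self.matrix.values[np.ix_(self.row_order, self.col_order)],
        )


def _cluster(matrix: SignalMatrix) -> ClusteredMatrix:
    rZ, r_order = cluster_axis(matrix, axis=0)
    cZ, c_order = cluster_axis(matrix, axis=1)
    return ClusteredMatrix(matrix, r_order, c_order, rZ, cZ)


def build_heatmap(
    universe: AnalysisUniverse,
    class_members: Mapping[str, set[str]],
    level: int,
    focal_class: str | None = None,
    focal_ade_classes: Sequence[str] | None = None,
    min_class_prr: float | None = None,
) -> ClusteredMatrix:
    """Assemble and cluster the signal matrix for one drill-down level.

    Level 1 plots class-level log-PRR for every class against every ADE
    class.  Level 2 needs ``focal_class`` and plots its member drugs
    (drug-level log-PRR) against ADE classes — optionally only those whose
    class-level PRR for the focal class exceeds ``min_class_prr``.  Level 3
    additionally needs ``focal_ade_classes`` and descends to individual ADE
    terms of those classes.  Non-co-occurring cells are neutral (0).
    """
    members = dict(class_members)
    if level == 1:
        recs = signal_scan(
            universe, "class_x_ade_class", class_members=members, include_neutral=True
        )
        mat = to_matrix(recs, sorted(members), universe.ade_class_ids)
    elif level in (2, 3):
        if focal_class is None:
            raise ValueError("levels 2 and 3 require a focal drug class")
        if focal_class not in members:
            raise ValueError(f"unknown or ineligible class {focal_class!r}")
        rows = sorted(members[focal_class])
        if level == 2:
            cols = list(universe.ade_class_ids)
            if min_class_prr is not None:
                keep = []
                for rec in signal_scan(
                    universe,
                    "class_x_ade_class",
                    class_members={focal_class: members[focal_class]},
                ):
                    if rec.prr >= min_class_prr:
                        keep.append(rec.col_id)
                cols = [c for c in cols if c in set(keep)]
            if not cols:
                raise ValueError("no ADE-class columns selected")
            recs = signal_scan(
                universe,
                "drug_x_ade_class",
                row_ids=rows,
                col_ids=cols,
                include_neutral=True,
            )
            mat = to_matrix(recs, rows, cols)
        else:
            if not focal_ade_classes:
                raise ValueError("level 3 requires focal ADE classes")
            terms_by_class = universe.ade_vocab.class_terms()
            cols = sorted(
                {
                    t
                    for ac in focal_ade_classes
                    for t in terms_by_class.get(ac, set())
                    if t in set(universe.ade_term_ids)
                }
            )
            if not cols:
                raise ValueError("no ADE-term columns selected")
            recs = signal_scan(
                universe,
                "drug_x_ade",
                row_ids=rows,
                col_ids=cols,
                include_neutral=True,
            )
            mat = to_matrix(recs, rows, cols)
    else:
        raise ValueError(f"unknown heat-map level {level!r}; expected 1, 2 or 3")
    return _cluster(mat)


def export(clustered: ClusteredMatrix, path: str | Path) -> None:
    """Write the permuted log-PRR matrix as TSV with row/column headers."""
    m = clustered.permuted()
    df = pd.DataFrame(m.values, index=m.row_ids, columns=m.col_ids)
    df.to_csv(path, sep="\t", index_label="id")


def render(clustered: ClusteredMatrix, path: str | Path) -> None:
    """Render the clustered matrix as a raster heat map.

    Low signals are red, intermediate yellow, strong white, matching the
    convention that strong safety signals stand out bright.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    m = clustered.permuted()
    cmap = LinearSegmentedColormap.from_list("prr", ["red", "yellow", "white"])
    h = max(2.0, 0.25 * len(m.row_ids) + 1.5)
    w = max(2.5, 0.25 * len(m.col_ids) + 2.0)
    fig, ax = plt.subplots(figsize=(w, h))
    im = ax.imshow(m.values, aspect="auto", cmap=cmap)
    ax.set_xticks(range(len(m.col_ids)))
    ax.set_xticklabels(m.col_ids, rotation=90, fontsize=6)
    ax.set_yticks(range(len(m.row_ids)))
    ax.set_yticklabels(m.row_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="log PRR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
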