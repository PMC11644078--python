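"""Replicate-level variability fingerprints.

At each sampling day, every unordered metabolite pair gets the Canberra
distance between the two metabolites' vectors of values across the
biological replicates.  The resulting day x pair matrix captures the
pattern of coordinated replicate-to-replicate variability — a
fingerprint of the physiological state — and the days are then
hierarchically clustered in that pair-distance space, again with the
Canberra metric.

Canberra is scale-sensitive (|u - v| / (|u| + |v|) per coordinate) and
is conventionally applied to non-negative data; here it is applied to
standardized values by default, matching the preprocessing chain, with
an option to compute on the positive normalized-stage data instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .table import MetaboliteTable, Stage

__all__ = [
    "canberra",
    "FingerprintMatrix",
    "TimepointClustering",
    "pair_distance_matrix",
    "cluster_timepoints",
]


def canberra(u, v) -> float:
    """Canberra distance: sum_i |u_i - v_i| / (|u_i| + |v_i|).

    Coordinates where both entries are zero contribute 0.  Vectors must
    have equal length >= 2.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if u.size < 2:
        raise ValueError("vectors must have length >= 2")
    num = np.abs(u - v)
    den = np.abs(u) + np.abs(v)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(terms.sum())


@dataclass
class FingerprintMatrix:
    """Days x metabolite-pairs matrix of per-day Canberra distances."""

    values: pd.DataFrame      # index days, columns "metA|metB"
    pairs: list[tuple[str, str]]
    source_stage: str

    @property
    def days(self) -> list[int]:
        return list(self.values.index)


def pair_distance_matrix(
    table: MetaboliteTable, stage: Stage | str = Stage.SCALED
) -> FingerprintMatrix:
    """Per-day Canberra distance between every metabolite pair.

    For each day, each metabolite's values across the replicates form a
    vector; the Canberra distance between the vectors of metabolites i
    and j (i < j, lexicographic by column position) fills column "i|j".
    Days with fewer than 2 replicates are skipped with a warning.
    """
    table.require_stage(stage)
    if table.values.isna().to_numpy().any():
        raise ValueError("fingerprints require an imputed (no-missing) table")
    names = table.metabolite_names
    pairs = [
        (names[i], names[j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]
    day_col = table.samples["day"].to_numpy()
    rep_col = table.samples["replicate"].to_numpy()
    rows, kept_days = [], []
    for d in table.days:
        mask = day_col == d
        if mask.sum() < 2:
            warnings.warn(f"day {d} has fewer than 2 replicates; skipped")
            continue
        order = np.argsort(rep_col[mask], kind="stable")
        block = table.values.to_numpy(dtype=float)[mask][order]  # reps x mets
        rows.append(pdist(block.T, metric="canberra"))
        kept_days.append(int(d))
    values = pd.DataFrame(
        np.vstack(rows), index=kept_days, columns=[f"{a}|{b}" for a, b in pairs]
    )
    return FingerprintMatrix(values=values, pairs=pairs, source_stage=Stage(stage).value)


@dataclass
class TimepointClustering:
    linkage: np.ndarray
    days: list[int]
    metric: str
    linkage_method: str
    leaf_order: list[int]

    def distance_matrix(self) -> np.ndarray:
        return squareform(self._condensed)

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.days[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def cluster_timepoints(
    fp: FingerprintMatrix, linkage: str = "average"
) -> TimepointClustering:
    """Cluster days by Canberra distance between their pair-distance rows."""
    if fp.values.shape[0] < 2:
        raise ValueError("need at least 2 time points")
    condensed = pdist(fp.values.to_numpy(dtype=float), metric="canberra")
    Z = hierarchy.linkage(condensed, method=linkage)
    days = [int(d) for d in fp.values.index]
    leaves = [days[i] for i in hierarchy.leaves_list(Z)]
    out = TimepointClustering(
        linkage=Z,
        days=days,
        metric="canberra",
        linkage_method=linkage,
        leaf_order=leaves,
    )
    out._condensed = condensed
    return out
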