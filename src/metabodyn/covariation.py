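"""Correlation-network mapping of metabolite temporal profiles.

Metabolites are nodes; pairs whose mean temporal profiles correlate
strongly (|r| above a threshold, default 0.85) are joined by signed
edges.  A force-directed layout in which positive correlations attract
and negative correlations (and non-edges) repel places co-varying
metabolites together; k-means on the 2-D coordinates then yields the
temporal clusters, summarized per cluster by median dynamics, an
interquartile band and chemical-class composition.  A separate contrast
compares the correlation distributions of metabolite pairs sharing a
pathway ("inside") against annotated pairs sharing none ("outside").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .table import MeanProfileMatrix, PathwayAnnotation

__all__ = [
    "CorrelationNetwork",
    "ClusterDynamics",
    "PairCorrelationContrast",
    "correlation_matrix",
    "build_network",
    "layout_signed",
    "cluster_nodes",
    "cluster_dynamics",
    "pathway_pair_correlations",
]


def correlation_matrix(
    profiles: MeanProfileMatrix, method: str = "pearson"
) -> pd.DataFrame:
    """Metabolite x metabolite correlation of mean temporal profiles.

    Constant profiles (undefined correlation) yield 0 off-diagonal
    entries; the diagonal is always 1.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = profiles.values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.where(np.isnan(r), 0.0, r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    idx = profiles.values.index
    return pd.DataFrame(r, index=idx, columns=idx)


@dataclass
class CorrelationNetwork:
    corr: pd.DataFrame
    graph: nx.Graph
    threshold: float
    method: str = "pearson"
    layout: pd.DataFrame | None = None      # nodes x (x, y)
    clusters: pd.Series | None = None       # node -> label

    @property
    def nodes(self) -> list[str]:
        return list(self.corr.index)


def build_network(
    corr: pd.DataFrame, threshold: float = 0.85, method: str = "pearson"
) -> CorrelationNetwork:
    """Threshold a correlation matrix into a signed undirected graph."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    names = list(corr.index)
    g = nx.Graph()
    g.add_nodes_from(names)
    r = corr.to_numpy()
    iu, ju = np.triu_indices(len(names), k=1)
    strong = np.abs(r[iu, ju]) > threshold
    for i, j in zip(iu[strong], ju[strong]):
        rij = float(r[i, j])
        g.add_edge(names[i], names[j], r=rij, sign=1 if rij > 0 else -1)
    return CorrelationNetwork(corr=corr.copy(), graph=g, threshold=threshold, method=method)


def layout_signed(
    network: CorrelationNetwork, seed: int = 0, iterations: int = 100
) -> pd.DataFrame:
    """Deterministic attraction/repulsion layout of the signed graph.

    Nodes start at a 2-D spectral embedding of the correlation matrix
    (plus seeded jitter to break symmetry) and are refined by a
    Fruchterman-Reingold-style loop: every pair repels as k^2/d, edges
    with positive r attract as r * d^2 / k, and negative edges repel
    twice as strongly as non-edges.  Coordinates are centered at the
    origin.
    """
    names = network.nodes
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    R = network.corr.to_numpy()
    # spectral warm start: top-2 eigenvectors of the similarity matrix
    evals, evecs = np.linalg.eigh(R)
    pos = evecs[:, -2:] * np.sqrt(np.clip(evals[-2:], 0.0, None))
    spread = max(pos.std(), 1e-3)
    pos = pos + rng.normal(scale=0.05 * spread, size=pos.shape)

    A = np.zeros((n, n))  # signed attraction weights from edges
    index = {name: i for i, name in enumerate(names)}
    for u, v, data in network.graph.edges(data=True):
        i, j = index[u], index[v]
        A[i, j] = A[j, i] = data["r"]
    k = 1.0 / np.sqrt(n)
    pos = pos / (np.abs(pos).max() + 1e-12)
    step = 0.1
    for it in range(iterations):
        delta = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(delta, axis=-1)
        np.fill_diagonal(dist, 1.0)
        unit = delta / dist[..., None]
        rep = (k * k) / dist
        rep = rep * (1.0 + np.where(A < 0, 2.0 * np.abs(A), 0.0))
        att = np.where(A > 0, A, 0.0) * dist**2 / k
        force = ((rep - att)[..., None] * unit).sum(axis=1)
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        temp = step * (1.0 - it / iterations)
        pos = pos + force / norm * np.minimum(norm, temp)
    pos = pos - pos.mean(axis=0)
    layout = pd.DataFrame(pos, index=names, columns=["x", "y"])
    network.layout = layout
    return layout


def cluster_nodes(
    network: CorrelationNetwork, k: int = 4, seed: int = 0, n_init: int = 50
) -> pd.Series:
    """k-means on the layout coordinates; labels renumbered by size.

    The best of ``n_init`` restarts (by within-cluster sum of squares) is
    kept; labels 0..k-1 are assigned in order of decreasing cluster size
    so the labelling is deterministic given the seed.
    """
    if network.layout is None:
        raise ValueError("layout must be computed before clustering")
    n = len(network.nodes)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k exceeds the number of nodes")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(network.layout.to_numpy())
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda lbl: (-sizes[lbl], lbl))
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series([remap[l] for l in raw], index=network.layout.index)
    network.clusters = labels
    return labels


@dataclass
class ClusterDynamics:
    cluster: int
    days: list[int]
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    composition: dict[str, int] = field(default_factory=dict)
    size: int = 0


def cluster_dynamics(
    labels: pd.Series, profiles: MeanProfileMatrix, classes: pd.Series
) -> list[ClusterDynamics]:
    """Per-cluster median trajectory, IQR band and class composition."""
    missing = set(profiles.values.index) - set(labels.index)
    if missing:
        raise ValueError(f"labels missing for metabolites: {sorted(missing)[:5]}...")
    out = []
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        sub = profiles.values.loc[members].to_numpy()
        comp = classes.reindex(members).value_counts().to_dict()
        out.append(
            ClusterDynamics(
                cluster=int(cl),
                days=list(profiles.days),
                median=np.median(sub, axis=0),
                q25=np.percentile(sub, 25, axis=0),
                q75=np.percentile(sub, 75, axis=0),
                composition=comp,
                size=len(members),
            )
        )
    return out


@dataclass
class PairCorrelationContrast:
    all_pairs: np.ndarray
    inside: np.ndarray
    outside: np.ndarray
    per_pathway: dict[str, np.ndarray]
    median_all: float
    median_inside: float
    median_outside: float
    median_shift: float


def pathway_pair_correlations(
    corr: pd.DataFrame, annotation: PathwayAnnotation
) -> PairCorrelationContrast:
    """Contrast correlations of within-pathway vs between-pathway pairs.

    "inside" pairs share at least one pathway, "outside" pairs are
    annotated on both ends but share none; pairs with an unannotated
    member count only toward "all".  The summary statistic is
    median(inside) - median(outside).
    """
    names = list(corr.index)
    n = len(names)
    index = {m: i for i, m in enumerate(names)}
    membership = np.zeros((n, len(annotation.sets)), dtype=bool)
    for jp, pid in enumerate(annotation.pathway_ids()):
        for m in annotation.members(pid):
            if m in index:
                membership[index[m], jp] = True
    annotated = membership.any(axis=1)
    shared = membership @ membership.T  # counts of shared pathways
    r = corr.to_numpy()
    iu, ju = np.triu_indices(n, k=1)
    all_pairs = r[iu, ju]
    both_annot = annotated[iu] & annotated[ju]
    if not both_annot.any():
        raise ValueError("no metabolite pair with pathway annotation on both ends")
    inside_mask = both_annot & (shared[iu, ju] > 0)
    outside_mask = both_annot & (shared[iu, ju] == 0)
    per_pathway = {}
    for jp, pid in enumerate(annotation.pathway_ids()):
        mem = membership[:, jp]
        mask = mem[iu] & mem[ju]
        if mask.any():
            per_pathway[pid] = all_pairs[mask]
    inside = all_pairs[inside_mask]
    outside = all_pairs[outside_mask]
    med_in = float(np.median(inside)) if inside.size else np.nan
    med_out = float(np.median(outside)) if outside.size else np.nan
    return PairCorrelationContrast(
        all_pairs=all_pairs,
        inside=inside,
        outside=outside,
        per_pathway=per_pathway,
        median_all=float(np.median(all_pairs)),
        median_inside=med_in,
        median_outside=med_out,
        median_shift=med_in - med_out,
    )
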