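"""Preranked metabolite-set enrichment (MSEA).

Metabolites are ranked by a score (by default the OPLS-DA predictive
loading) and each pathway is tested with the weighted Kolmogorov-Smirnov
running-sum statistic: walking down the ranked list, members increment
the sum by their |score|^weight (normalized over members) and
non-members decrement it by 1/(N - n_members); the enrichment score (ES)
is the signed extremum of the walk.  The null distribution comes from
random member sets of equal size drawn from the profile; the normalized
enrichment score (NES) is ES divided by the mean |null ES| of matching
sign, and p-values are taken from the matching-sign tail with
Benjamini-Hochberg adjustment across pathways.

The permutation unit is the metabolite label, not the sample: scores
come from a single fitted model, so sample-level permutation is not
available for a preranked analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .table import PathwayAnnotation

__all__ = ["RankedList", "enrichment_score", "msea"]


@dataclass
class RankedList:
    """Metabolite names with ranking scores, sorted non-increasing."""

    names: np.ndarray
    scores: np.ndarray

    @classmethod
    def from_series(cls, scores: pd.Series) -> "RankedList":
        if scores.index.duplicated().any():
            raise ValueError("ranked list names must be unique")
        s = scores.sort_values(ascending=False, kind="stable")
        return cls(names=s.index.to_numpy(), scores=s.to_numpy(dtype=float))

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.names) != len(set(self.names)):
            raise ValueError("ranked list names must be unique")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be sorted non-increasing")

    def __len__(self) -> int:
        return len(self.names)


def _es_from_positions(positions: np.ndarray, abs_weights: np.ndarray, N: int) -> float:
    """ES for one set given sorted 0-based hit positions.

    The running sum is piecewise linear between hits, so its extrema are
    attained just before or just after a hit; both candidate sets are
    evaluated in closed form.
    """
    pos = np.sort(positions)
    s = pos.size
    hit_w = abs_weights[pos]
    total = hit_w.sum()
    if total <= 0:
        hit_w = np.ones(s)  # degenerate all-zero scores: unweighted steps
        total = float(s)
    cum = np.cumsum(hit_w) / total
    miss = 1.0 / (N - s)
    misses_before = pos - np.arange(s)
    after = cum - misses_before * miss
    before = np.concatenate([[0.0], cum[:-1]]) - misses_before * miss
    top = after.max()
    bottom = before.min()
    return float(top if top >= -bottom else bottom)


def enrichment_score(ranked: RankedList, members, weight: float = 1.0) -> float:
    """Weighted KS enrichment score of a member set in a ranked list.

    Raises if no member is present or if the set covers the whole list
    (no misses: the statistic is degenerate).
    """
    N = len(ranked)
    index = {n: i for i, n in enumerate(ranked.names)}
    positions = np.array([index[m] for m in members if m in index], dtype=int)
    if positions.size == 0:
        raise ValueError("no member of the set is present in the ranked list")
    if positions.size >= N:
        raise ValueError("set covers the entire ranked list (no misses)")
    abs_w = np.abs(ranked.scores) ** weight
    return _es_from_positions(positions, abs_w, N)


def _null_es(
    rng: np.random.Generator, n_perm: int, size: int, abs_w: np.ndarray, N: int
) -> np.ndarray:
    keys = rng.random((n_perm, N))
    positions = np.argpartition(keys, size, axis=1)[:, :size]
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = _es_from_positions(positions[i], abs_w, N)
    return out


def msea(
    ranked: RankedList,
    annotation: PathwayAnnotation,
    n_perm: int = 1000,
    min_size: int = 3,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run preranked enrichment for every pathway in the annotation.

    Pathways with fewer than ``min_size`` members in the profile are
    skipped and reported in a warning.  Returns a DataFrame with columns
    pathway_id, description, size, es, nes, p_raw, p_adj, direction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    N = len(ranked)
    abs_w = np.abs(ranked.scores) ** weight
    present = set(ranked.names)
    rng = np.random.default_rng(seed)

    rows, skipped = [], []
    null_cache: dict[int, np.ndarray] = {}
    for pid in annotation.pathway_ids():
        desc, members = annotation.sets[pid]
        inset = [m for m in members if m in present]
        if len(inset) < min_size or len(inset) >= N:
            skipped.append(pid)
            continue
        es = enrichment_score(ranked, inset, weight=weight)
        size = len(inset)
        if size not in null_cache:
            null_cache[size] = _null_es(rng, n_perm, size, abs_w, N)
        null = null_cache[size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and not np.isnan(denom) else 0.0
        p = (1.0 + (np.abs(same) >= abs(es)).sum()) / (1.0 + same.size)
        rows.append((pid, desc, size, es, nes, float(p)))
    if skipped:
        warnings.warn(f"skipped pathways below min_size or degenerate: {skipped}")
    out = pd.DataFrame(
        rows, columns=["pathway_id", "description", "size", "es", "nes", "p_raw"]
    )
    if not out.empty:
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
        out["direction"] = np.where(out["nes"] >= 0, "up", "down")
    else:
        out["p_adj"] = []
        out["direction"] = []
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)
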