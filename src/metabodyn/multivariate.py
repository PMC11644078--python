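"""Ordination and supervised contrast analysis.

PCA (SVD on the centered matrix) with chi-square confidence ellipses,
hierarchical clustering of profiles by Pearson distance with Ward
linkage, OPLS-DA — a PLS1 model with orthogonal signal correction so a
single predictive component carries all between-group variation — with
VIP scores, and per-metabolite Mann-Whitney/Welch tests with
Benjamini-Hochberg adjustment.

The quantity quoted from OPLS-DA models throughout is ``r2x_pred``, the
fraction of total (centered) X-variance captured by the predictive
component; orthogonal components each carry their own fraction and the
three kinds (predictive, orthogonal, residual) sum to one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .table import MeanProfileMatrix, MetaboliteTable, Stage

__all__ = [
    "PcaResult",
    "OplsdaModel",
    "fit_pca",
    "confidence_ellipse",
    "ward_correlation_cluster",
    "fit_oplsda",
    "vip_scores",
    "univariate_tests",
    "differential_table",
    "vip_band",
]

STAR_LEVELS = (0.001, 0.01, 0.05, 0.1)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # metabolites x components
    explained_fraction: np.ndarray
    column_means: pd.Series


def fit_pca(table: MetaboliteTable, n_components: int = 2) -> PcaResult:
    """SVD-based PCA of the mean-centered, imputed table.

    Deterministic up to sign; the sign of each component is fixed so its
    largest-magnitude loading is positive.
    """
    table.require_stage(Stage.SCALED)
    X = table.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("PCA requires an imputed table (no missing values)")
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)={min(n, p)}")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float((S**2).sum())
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(n_components)]
    scores = pd.DataFrame(
        U[:, :n_components] * S[:n_components], index=table.values.index, columns=comps
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T, index=table.values.columns, columns=comps
    )
    frac = (S[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    means = pd.Series(mu, index=table.values.columns)
    return PcaResult(scores, loadings, frac, means)


@dataclass
class Ellipse:
    center: np.ndarray
    semi_axes: np.ndarray   # lengths, descending
    angle: float            # radians, orientation of the major axis
    degenerate: bool = False


def confidence_ellipse(scores: np.ndarray, level: float = 0.90) -> Ellipse:
    """Normal-theory confidence ellipse of a 2-column score cloud.

    The boundary is the set of points at squared Mahalanobis distance
    equal to the chi-square(2) quantile at ``level`` from the group mean.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be an n x 2 array")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points for a covariance ellipse")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    q = stats.chi2.ppf(level, df=2) if level > 0 else 0.0
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(np.min(evals) <= 1e-12 or q == 0.0)
    semi = np.sqrt(np.clip(evals, 0.0, None) * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(center=center, semi_axes=semi, angle=angle, degenerate=degenerate)


# ----------------------------------------------------------------------
# hierarchical clustering of profiles
# ----------------------------------------------------------------------

def ward_correlation_cluster(profiles: MeanProfileMatrix):
    """Ward-linkage tree over profiles with Pearson distance 1 - r.

    Constant profiles (undefined correlation) get the maximal distance 2
    to every other profile and are reported.  Returns ``(linkage,
    leaf_order, flagged)`` where ``leaf_order`` lists row names in
    dendrogram order.
    """
    X = profiles.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    sd = X.std(axis=1)
    flagged = [profiles.values.index[i] for i in np.flatnonzero(sd == 0)]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    d[np.isnan(d)] = 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    Z = hierarchy.linkage(squareform(d, checks=False), method="ward")
    leaves = [profiles.values.index[i] for i in hierarchy.leaves_list(Z)]
    if flagged:
        warnings.warn(f"constant profiles at maximal distance: {flagged}")
    return Z, leaves, flagged


# ----------------------------------------------------------------------
# OPLS-DA
# ----------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """Two-group OPLS-DA fit.

    ``t_pred``/``p_pred``/``w_pred`` are the predictive scores, loadings
    and (unit-norm) weights; orthogonal components are stored as columns
    of ``t_orth``/``p_orth``.  ``r2x_pred`` and ``r2x_orth`` are
    fractions of the total centered X-variance; with the residual they
    sum to 1.  The sign convention puts the second day-set of the
    contrast at positive predictive scores.
    """

    contrast: tuple[tuple[int, ...], tuple[int, ...]]
    sample_ids: list[str]
    y: np.ndarray
    t_pred: np.ndarray
    p_pred: pd.Series
    w_pred: pd.Series
    t_orth: np.ndarray          # n x n_ortho (possibly 0 columns)
    p_orth: np.ndarray          # p x n_ortho
    r2x_pred: float
    r2x_orth: np.ndarray
    r2x_resid: float
    vip: pd.Series = field(default=None)

    @property
    def n_ortho(self) -> int:
        return self.t_orth.shape[1]


def fit_oplsda(
    table: MetaboliteTable,
    contrast: tuple,
    n_ortho: int | str = 1,
    min_orth_fraction: float = 0.01,
) -> OplsdaModel:
    """Fit a two-group OPLS-DA on the samples of two disjoint day-sets.

    NIPALS-style PLS1 with orthogonal signal correction: y-orthogonal
    X-components are removed iteratively (``n_ortho`` of them, or
    ``"auto"`` to stop when a component would explain less than
    ``min_orth_fraction`` of X-variance), then a single predictive
    component is fitted to the filtered matrix.
    """
    table.require_stage(Stage.SCALED)
    days_a, days_b = (tuple(contrast[0]), tuple(contrast[1]))
    if set(days_a) & set(days_b):
        raise ValueError("contrast day-sets must be disjoint")
    known = set(table.days)
    absent = (set(days_a) | set(days_b)) - known
    if absent:
        raise ValueError(f"contrast references days not in the data: {sorted(absent)}")
    mask_a = table.day_mask(days_a)
    mask_b = table.day_mask(days_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("both contrast groups need at least 3 samples")
    sel = mask_a | mask_b
    X = table.values.to_numpy(dtype=float)[sel]
    if np.isnan(X).any():
        raise ValueError("OPLS-DA requires an imputed table")
    y = np.where(mask_b[sel], 1.0, -1.0)
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    auto = n_ortho == "auto"
    max_ortho = X.shape[0] - 2 if auto else int(n_ortho)
    if not auto and X.shape[0] < max_ortho + 1:
        raise ValueError("fewer samples than n_ortho + 1")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    ss_total = float((Xc**2).sum())
    if ss_total == 0:
        raise ValueError("X has no variance")

    Xf = Xc.copy()
    t_orth_list, p_orth_list, r2o = [], [], []
    for _ in range(max_ortho):
        w = Xf.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w /= nw
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10:
            break  # no y-orthogonal structure left
        w_o /= n_wo
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        frac = float((t_o @ t_o) * (p_o @ p_o)) / ss_total
        if auto and frac < min_orth_fraction:
            break
        t_orth_list.append(t_o)
        p_orth_list.append(p_o)
        r2o.append(frac)
        Xf = Xf - np.outer(t_o, p_o)

    w = Xf.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("no y-covarying X-variation to fit")
    w /= nw
    t_pred = Xf @ w
    p_pred = Xf.T @ t_pred / (t_pred @ t_pred)
    if t_pred[y > 0].mean() < 0:  # second group listed scores positive
        w, t_pred, p_pred = -w, -t_pred, -p_pred
    r2x_pred = float((t_pred @ t_pred) * (p_pred @ p_pred)) / ss_total

    t_orth = np.column_stack(t_orth_list) if t_orth_list else np.empty((X.shape[0], 0))
    p_orth = np.column_stack(p_orth_list) if p_orth_list else np.empty((X.shape[1], 0))
    r2x_orth = np.asarray(r2o)
    mets = table.values.columns
    model = OplsdaModel(
        contrast=(days_a, days_b),
        sample_ids=list(table.values.index[sel]),
        y=y,
        t_pred=t_pred,
        p_pred=pd.Series(p_pred, index=mets),
        w_pred=pd.Series(w, index=mets),
        t_orth=t_orth,
        p_orth=p_orth,
        r2x_pred=r2x_pred,
        r2x_orth=r2x_orth,
        r2x_resid=float(1.0 - r2x_pred - r2x_orth.sum()),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: OplsdaModel) -> pd.Series:
    """Variable importance in projection for the predictive component.

    With a single predictive component, VIP_j = sqrt(J * w_j^2 / sum w^2),
    so the mean squared VIP is exactly 1 and VIP > 1 flags metabolites
    contributing more than an average share.
    """
    w = model.w_pred.to_numpy()
    J = w.size
    vip = np.sqrt(J * w**2 / (w**2).sum())
    return pd.Series(vip, index=model.w_pred.index)


def vip_band(v: float) -> str:
    if v > 1.0:
        return "strong"
    if v > 0.9:
        return "weak"
    return "none"


# ----------------------------------------------------------------------
# univariate testing
# ----------------------------------------------------------------------

def _stars(p: float) -> str:
    for i, level in enumerate(STAR_LEVELS):
        if p < level:
            return "*" * (len(STAR_LEVELS) - i)
    return ""


def univariate_tests(
    table: MetaboliteTable, contrast: tuple, test: str = "MWW"
) -> pd.DataFrame:
    """Per-metabolite two-group tests with Benjamini-Hochberg adjustment.

    ``test`` is ``"MWW"`` (two-sided Mann-Whitney, exact when sample
    sizes and ties permit) or ``"t"`` (Welch).  All-tied metabolites get
    p = 1 and a flag.  Star bands follow adjusted p < 0.001/0.01/0.05/0.1.
    """
    if test not in ("MWW", "t"):
        raise ValueError("test must be 'MWW' or 't'")
    days_a, days_b = (tuple(contrast[0]), tuple(contrast[1]))
    mask_a, mask_b = table.day_mask(days_a), table.day_mask(days_b)
    if mask_a.sum() < 3 or mask_b.sum() < 3:
        raise ValueError("both groups need at least 3 samples")
    X = table.values.to_numpy(dtype=float)
    rows = []
    for j, name in enumerate(table.values.columns):
        a = X[mask_a, j]
        b = X[mask_b, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        tied = np.ptp(np.concatenate([a, b])) == 0
        if tied:
            p = 1.0
        elif test == "MWW":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        direction = "up in B" if b.mean() > a.mean() else "up in A"
        rows.append((name, direction, p, tied))
    out = pd.DataFrame(rows, columns=["metabolite", "direction", "p_raw", "all_tied"])
    out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")[1]
    out["stars"] = [_stars(p) for p in out["p_adj"]]
    out["test"] = test
    return out


def differential_table(model: OplsdaModel, tests: pd.DataFrame) -> pd.DataFrame:
    """Join OPLS-DA loadings/VIPs with univariate calls per metabolite."""
    out = tests.set_index("metabolite").copy()
    out["loading_p"] = model.p_pred
    out["vip"] = model.vip
    out["vip_band"] = [vip_band(v) for v in out["vip"]]
    cols = ["loading_p", "vip", "vip_band", "direction", "test", "p_raw", "p_adj", "stars"]
    return out[cols].reset_index()
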