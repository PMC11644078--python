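"""Preprocessing chain for GC-MS peak-area tables.

The chain mirrors standard metabolomics practice for normalized peak
areas: per-sample median normalization, natural-log transform with a
half-minimum floor for zeros, per-metabolite autoscaling (z-scoring),
then k-nearest-neighbour imputation of sporadically missing cells in
metabolite (feature) space.  Each step checks and advances the table's
stage tag, so the chain can only be applied in order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .table import MeanProfileMatrix, MetaboliteTable, Stage

__all__ = [
    "median_normalize",
    "log_transform",
    "autoscale",
    "knn_impute",
    "preprocess",
    "aggregate_means",
    "ratio_index",
]


def median_normalize(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample by its median, preserving the grand scale.

    Each sample's values are divided by that sample's median over
    observed metabolites and re-multiplied by the grand median of the
    per-sample medians, so the output stays on the input's scale.
    """
    table.require_stage(Stage.RAW)
    med = table.values.median(axis=1, skipna=True)
    if med.isna().any():
        empty = table.values.index[med.isna()].tolist()
        raise ValueError(f"samples with no observed values: {empty}")
    zero = med == 0
    if zero.any():
        raise ValueError(
            f"sample median is zero for: {table.values.index[zero].tolist()}"
        )
    grand = float(np.median(med.to_numpy()))
    values = table.values.div(med, axis=0) * grand
    return table.advanced(values, Stage.NORMALIZED)


def log_transform(table: MetaboliteTable, zero_policy: str = "half-min") -> MetaboliteTable:
    """Element-wise natural log.

    Zeros are floored to half the metabolite's smallest positive value
    (``zero_policy="half-min"``, the default) or rejected
    (``zero_policy="strict"``).  Negative values are always an error.
    """
    table.require_stage(Stage.NORMALIZED)
    values = table.values.copy()
    arr = values.to_numpy()
    if np.nanmin(arr, initial=np.inf) < 0:
        raise ValueError("negative values cannot be log-transformed")
    zeros = values == 0
    if zeros.to_numpy().any():
        if zero_policy == "strict":
            raise ValueError("zero values present and zero_policy='strict'")
        floored = []
        for col in values.columns[zeros.any(axis=0)]:
            pos = values[col][values[col] > 0]
            if pos.empty:
                raise ValueError(f"metabolite {col!r} has no positive value to floor zeros")
            values.loc[zeros[col], col] = pos.min() / 2.0
            floored.append(col)
        warnings.warn(f"floored zeros in {len(floored)} metabolite(s) to half-minimum")
    return table.advanced(np.log(values), Stage.LOGGED)


def autoscale(table: MetaboliteTable) -> MetaboliteTable:
    """Standardize each metabolite to mean 0, sample SD 1 over observed values.

    Constant columns become all-zero and are recorded in
    ``flags["constant_columns"]``.
    """
    table.require_stage(Stage.LOGGED)
    values = table.values.copy()
    mean = values.mean(axis=0, skipna=True)
    sd = values.std(axis=0, ddof=1, skipna=True)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    sd_safe = sd.replace(0, np.nan)
    scaled = (values - mean) / sd_safe
    for col in constant:
        observed = values[col].notna()
        scaled.loc[observed, col] = 0.0
    if constant:
        warnings.warn(f"{len(constant)} constant metabolite column(s) set to zero")
    return table.advanced(scaled, Stage.SCALED, constant_columns=constant)


def knn_impute(table: MetaboliteTable, k: int | None = None) -> MetaboliteTable:
    """Impute missing cells from the k nearest metabolite rows.

    Neighbour space is metabolite (feature) rows: for each metabolite
    with missing cells, distances to every *complete* metabolite row are
    computed as Euclidean distance over the samples where the target is
    observed, and each missing cell is filled with the mean of the k
    nearest rows' values at that sample.  Observed cells are never
    altered.  Metabolites with no observed value at all are left missing
    and reported in ``flags["unimputable"]``.
    """
    table.require_stage(Stage.SCALED)
    values = table.values.copy()
    mask = values.isna()
    if not mask.to_numpy().any():
        out = table.advanced(values, Stage.SCALED)
        out.flags["unimputable"] = []
        return out

    X = values.to_numpy().T  # metabolites x samples
    obs = ~np.isnan(X)
    complete = obs.all(axis=1)
    n_complete = int(complete.sum())
    if k is None:
        k = min(10, max(n_complete - 1, 1))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_complete:
        raise ValueError(
            f"k={k} exceeds the {n_complete} complete metabolite rows available"
        )
    donors = X[complete]  # rows with no missing values
    donor_idx = np.flatnonzero(complete)

    unimputable: list[str] = []
    cols = list(values.columns)
    for j in np.flatnonzero(~obs.all(axis=1)):
        row = X[j]
        seen = obs[j]
        if not seen.any():
            unimputable.append(cols[j])
            continue
        diff = donors[:, seen] - row[seen]
        dist = np.sqrt((diff * diff).sum(axis=1))
        # a complete row cannot be the target itself (target has missing cells)
        order = np.argsort(dist, kind="stable")[:k]
        fill = donors[order][:, ~seen].mean(axis=0)
        missing_samples = np.flatnonzero(~seen)
        for s, v in zip(missing_samples, fill):
            values.iloc[s, j] = v
    if unimputable:
        warnings.warn(f"metabolites left missing (no observed value): {unimputable}")
    out = table.advanced(values, Stage.SCALED)
    out.flags["unimputable"] = unimputable
    return out


def preprocess(
    table: MetaboliteTable, k: int | None = None, zero_policy: str = "half-min"
) -> MetaboliteTable:
    """Run the full chain: median-normalize, log, autoscale, KNN-impute."""
    return knn_impute(
        autoscale(log_transform(median_normalize(table), zero_policy=zero_policy)), k=k
    )


def aggregate_means(table: MetaboliteTable) -> MeanProfileMatrix:
    """Average replicates per day: metabolites x time-points matrix."""
    table.require_stage(Stage.SCALED)
    if table.values.isna().to_numpy().any():
        raise ValueError("aggregate_means requires an imputed (no-missing) table")
    days = table.days
    by_day = table.values.groupby(table.samples["day"].to_numpy()).mean()
    profiles = by_day.T.reindex(columns=days)
    return MeanProfileMatrix(values=profiles, days=days)


def ratio_index(
    table: MetaboliteTable, numerator: str, denominator: str
) -> pd.DataFrame:
    """Per-day mean and SD of a metabolite abundance ratio.

    Computed on normalized (pre-log) positive values; the classic use is
    the stigmasterol/beta-sitosterol membrane-activity index.  Days where
    the denominator's mean is zero are reported as undefined (NaN).
    """
    table.require_stage(Stage.NORMALIZED)
    for name in (numerator, denominator):
        if name not in table.values.columns:
            raise KeyError(f"metabolite {name!r} not in table")
    num = table.values[numerator].to_numpy(dtype=float)
    den = table.values[denominator].to_numpy(dtype=float)
    day = table.samples["day"].to_numpy()
    rows = []
    for d in table.days:
        m = day == d
        den_mean = np.nanmean(den[m])
        if den_mean == 0 or np.isnan(den_mean):
            rows.append((d, np.nan, np.nan, False))
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = num[m] / den[m]
        ratios = ratios[np.isfinite(ratios)]
        rows.append(
            (
                d,
                float(np.mean(ratios)),
                float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0,
                True,
            )
        )
    return pd.DataFrame(rows, columns=["day", "ratio_mean", "ratio_sd", "defined"])
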