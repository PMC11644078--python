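"""Tabular containers and file I/O for metabolite profiling data.

The central object is :class:`MetaboliteTable`, a samples x metabolites
abundance matrix with sample metadata (day after inoculation, biological
replicate) and metabolite annotations (chemical class, identification
level).  The table carries a *stage* tag recording where it sits in the
preprocessing chain; stages only move forward in the order
``raw -> normalized -> logged -> scaled``.

File layouts
------------
* feature table: CSV, rows = samples, first columns ``sample_id, day,
  replicate``, remaining columns = metabolites; empty cells are missing.
* annotation: TSV with columns ``metabolite, class, id_level``.
* pathway sets: GMT-like TSV, ``pathway_id<TAB>description<TAB>member...``.
"""

from __future__ import annotations

import enum
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Stage",
    "MetaboliteTable",
    "PathwayAnnotation",
    "MeanProfileMatrix",
    "read_feature_table",
    "write_feature_table",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
]

ID_LEVELS = ("identified", "class-annotated", "unknown")

SAMPLE_COLUMNS = ("sample_id", "day", "replicate")


class Stage(str, enum.Enum):
    """Preprocessing stage of a :class:`MetaboliteTable`."""

    RAW = "raw"
    NORMALIZED = "normalized"
    LOGGED = "logged"
    SCALED = "scaled"

    @property
    def order(self) -> int:
        return _STAGE_ORDER[self]


_STAGE_ORDER = {Stage.RAW: 0, Stage.NORMALIZED: 1, Stage.LOGGED: 2, Stage.SCALED: 3}


class StageError(ValueError):
    """Raised when an operation is applied at the wrong preprocessing stage."""


@dataclass
class MetaboliteTable:
    """Samples x metabolites abundance matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by ``sample_id`` with one column per metabolite.
        Missing measurements are NaN.
    samples
        DataFrame with columns ``sample_id, day, replicate``, one row per
        row of ``values`` (same order).
    metabolites
        DataFrame with columns ``metabolite, class, id_level`` aligned with
        the columns of ``values``.
    stage
        Position in the preprocessing chain.
    flags
        Free-form diagnostics accumulated by operations (e.g. names of
        constant columns zeroed during autoscaling).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    metabolites: pd.DataFrame
    stage: Stage = Stage.RAW
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dups))}")
        if list(self.values.index) != list(self.samples["sample_id"]):
            raise ValueError("values index must equal samples.sample_id in order")
        if list(self.values.columns) != list(self.metabolites["metabolite"]):
            raise ValueError("values columns must equal metabolites.metabolite in order")

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    @property
    def days(self) -> list[int]:
        return sorted(self.samples["day"].unique().tolist())

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def day_mask(self, days: Iterable[int]) -> np.ndarray:
        return self.samples["day"].isin(list(days)).to_numpy()

    def classes(self) -> pd.Series:
        return pd.Series(
            self.metabolites["class"].to_numpy(),
            index=self.metabolites["metabolite"].to_numpy(),
        )

    # -- stage machine -------------------------------------------------
    def require_stage(self, stage: Stage) -> None:
        if self.stage is not Stage(stage):
            raise StageError(
                f"operation requires stage={Stage(stage).value!r}, "
                f"table is at {self.stage.value!r}"
            )

    def advanced(self, values: pd.DataFrame, stage: Stage, **new_flags) -> "MetaboliteTable":
        """Return a copy with new values at a later (or equal) stage."""
        stage = Stage(stage)
        if stage.order < self.stage.order:
            raise StageError(
                f"stage may only advance: {self.stage.value!r} -> {stage.value!r}"
            )
        flags = dict(self.flags)
        flags.update(new_flags)
        return MetaboliteTable(
            values=values,
            samples=self.samples.copy(),
            metabolites=self.metabolites.copy(),
            stage=stage,
            flags=flags,
        )

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            values=self.values.copy(),
            samples=self.samples.copy(),
            metabolites=self.metabolites.copy(),
            stage=self.stage,
            flags=dict(self.flags),
        )


@dataclass
class PathwayAnnotation:
    """Named metabolite sets (KEGG-style pathways).

    ``sets`` maps a pathway id to ``(description, tuple of member names)``.
    """

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for pid, (_, members) in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"pathway {pid!r} has no members")

    def members(self, pathway_id: str) -> tuple[str, ...]:
        return self.sets[pathway_id][1]

    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def annotated_metabolites(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out.update(members)
        return out

    def apply_overrides(self, overrides: pd.DataFrame) -> "PathwayAnnotation":
        """Apply a manual-correction table with columns action/pathway_id/metabolite.

        ``action`` is ``add`` or ``remove``.  Adding to an unknown pathway
        creates it with an empty description.
        """
        sets = {pid: (desc, list(members)) for pid, (desc, members) in self.sets.items()}
        for _, row in overrides.iterrows():
            action = str(row["action"]).strip().lower()
            pid = str(row["pathway_id"])
            met = str(row["metabolite"])
            if action == "add":
                desc, members = sets.setdefault(pid, ("", []))
                if met not in members:
                    members.append(met)
            elif action == "remove":
                if pid in sets and met in sets[pid][1]:
                    sets[pid][1].remove(met)
            else:
                raise ValueError(f"unknown override action {action!r}")
        sets = {pid: (d, tuple(m)) for pid, (d, m) in sets.items() if m}
        return PathwayAnnotation(sets=sets)


@dataclass
class MeanProfileMatrix:
    """Metabolites x time-points matrix of replicate means."""

    values: pd.DataFrame  # index metabolites, columns days (ints)
    days: list[int]

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.days):
            raise ValueError("columns of values must equal days")


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_feature_table(path, annotation_path=None) -> MetaboliteTable:
    """Read a raw feature table (CSV) plus optional annotation TSV.

    Unparseable or negative abundance cells become missing with a warning.
    Missing mandatory columns or duplicate sample ids are errors.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"feature table missing mandatory columns: {missing_cols}")
    if df["sample_id"].duplicated().any():
        dups = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise ValueError(f"duplicate sample_id(s): {dups}")

    samples = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "day": df["day"].astype(int),
            "replicate": df["replicate"].astype(int),
        }
    )
    met_cols = [c for c in df.columns if c not in SAMPLE_COLUMNS]
    raw = df[met_cols].replace("", np.nan)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        warnings.warn(f"{int(bad.to_numpy().sum())} unparseable cells set to missing")
    neg = values < 0
    if neg.to_numpy().any():
        warnings.warn(f"{int(neg.to_numpy().sum())} negative cells set to missing")
        values = values.mask(neg)
    values.index = samples["sample_id"].to_numpy()

    if annotation_path is not None:
        ann = read_annotation(annotation_path)
        ann = ann.set_index("metabolite").reindex(met_cols).reset_index()
        ann["class"] = ann["class"].fillna("other")
        ann["id_level"] = ann["id_level"].fillna("unknown")
    else:
        ann = pd.DataFrame(
            {"metabolite": met_cols, "class": "other", "id_level": "unknown"}
        )
    return MetaboliteTable(values=values, samples=samples, metabolites=ann, stage=Stage.RAW)


def write_feature_table(table: MetaboliteTable, path) -> None:
    """Write a table as CSV; round-trips values to full float precision."""
    out = table.samples.copy()
    vals = table.values.reset_index(drop=True)
    out = pd.concat([out, vals], axis=1)
    out.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"metabolite", "class", "id_level"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    bad = set(ann["id_level"].dropna()) - set(ID_LEVELS)
    if bad:
        raise ValueError(f"unknown id_level values: {sorted(bad)}")
    return ann


def write_annotation(table: MetaboliteTable, path) -> None:
    table.metabolites.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_gmt(path) -> PathwayAnnotation:
    """Read GMT-like TSV: pathway_id<TAB>description<TAB>member..."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    text = Path(path).read_text(encoding="utf-8")
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs id, description, >=1 member: {line!r}")
        pid, desc, members = parts[0], parts[1], tuple(p for p in parts[2:] if p)
        if pid in sets:
            raise ValueError(f"duplicate pathway id {pid!r}")
        sets[pid] = (desc, members)
    return PathwayAnnotation(sets=sets)


def write_gmt(annotation: PathwayAnnotation, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid, (desc, members) in annotation.sets.items():
            fh.write("\t".join([pid, desc, *members]) + "\n")
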