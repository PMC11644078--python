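"""End-to-end orchestration of the batch-culture metabolome analysis.

A single :class:`PipelineConfig` (usually loaded from YAML) drives:
simulation or ingestion, the preprocessing chain, PCA, a schedule of
sequential OPLS-DA contrasts with univariate tests, loading-ranked
enrichment per contrast, the correlation-network map with k-means
clusters and dynamics, and the replicate-variability fingerprints.
Every stage writes its artifacts under the output directory and
contributes a section to a machine-readable JSON report; given fixed
seeds the whole run is reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariation import (
    build_network,
    cluster_dynamics,
    cluster_nodes,
    correlation_matrix,
    layout_signed,
    pathway_pair_correlations,
)
from .enrichment import RankedList, msea
from .fingerprint import cluster_timepoints, pair_distance_matrix
from .multivariate import differential_table, fit_oplsda, fit_pca, univariate_tests
from .preprocess import aggregate_means, median_normalize, preprocess
from .simulate import SimulationConfig, simulate_metabolome
from .table import (
    MetaboliteTable,
    PathwayAnnotation,
    Stage,
    read_feature_table,
    read_gmt,
    write_feature_table,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "DEFAULT_CONTRASTS"]

log = logging.getLogger("metabodyn")

# the study's sequential comparison schedule across the culture cycle:
# subculturing vs lag, lag vs proliferation, elongation onset/offset,
# stationary transition, aging steps, and death
DEFAULT_CONTRASTS: tuple = (
    ((21, 23), (1, 2)),
    ((1, 2), (4, 7)),
    ((7,), (14,)),
    ((14,), (18,)),
    ((18,), (21,)),
    ((21,), (23,)),
    ((23,), (26,)),
)


@dataclass
class PipelineConfig:
    """Fully materialized pipeline configuration."""

    outdir: str = "metabodyn_out"
    seed: int = 0
    # input: either file paths or a simulation block
    feature_table: str | None = None
    annotation: str | None = None
    pathways: str | None = None
    pathway_overrides: str | None = None
    simulation: dict | None = None
    # preprocessing
    knn_k: int | None = None
    zero_policy: str = "half-min"
    # contrasts
    contrasts: tuple = DEFAULT_CONTRASTS
    n_ortho: int | str = 1
    tests: str = "MWW"
    # msea
    n_perm: int = 1000
    msea_weight: float = 1.0
    min_size: int = 3
    # network
    corr_method: str = "pearson"
    contrast_corr_method: str = "spearman"
    threshold: float = 0.85
    n_clusters: int = 4
    n_init: int = 50
    layout_iterations: int = 100
    # fingerprint
    fingerprint_stage: str = "normalized"
    fingerprint_linkage: str = "average"
    # pca
    n_components: int = 2


def validate_config(source) -> PipelineConfig:
    """Validate a YAML path or dict into a :class:`PipelineConfig`.

    All structural problems are aggregated into a single error listing
    every offending field.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    elif isinstance(source, dict):
        raw = dict(source)
    elif isinstance(source, PipelineConfig):
        raw = None
    else:
        raise TypeError("source must be a path, dict or PipelineConfig")

    if raw is not None:
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(raw) - known
        errors = [f"unknown field: {u}" for u in sorted(unknown)]
        cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    else:
        cfg, errors = source, []

    if isinstance(cfg.contrasts, list):
        cfg.contrasts = tuple(
            (tuple(a), tuple(b)) for a, b in (tuple(c) for c in cfg.contrasts)
        )
    for a, b in cfg.contrasts:
        if set(a) & set(b):
            errors.append(f"contrast day-sets overlap: {a} vs {b}")
    if cfg.n_perm < 100:
        errors.append(f"n_perm must be >= 100, got {cfg.n_perm}")
    if not (0 < cfg.threshold < 1):
        errors.append(f"threshold must be in (0, 1), got {cfg.threshold}")
    if cfg.n_clusters < 2:
        errors.append(f"n_clusters must be >= 2, got {cfg.n_clusters}")
    if cfg.min_size < 1:
        errors.append(f"min_size must be >= 1, got {cfg.min_size}")
    if cfg.tests not in ("MWW", "t"):
        errors.append(f"tests must be 'MWW' or 't', got {cfg.tests!r}")
    if cfg.fingerprint_stage not in ("normalized", "scaled"):
        errors.append(f"fingerprint_stage must be normalized|scaled, got {cfg.fingerprint_stage!r}")
    if cfg.feature_table is None and cfg.simulation is None:
        cfg.simulation = {}
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return cfg


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulation is not None:
        sim = dict(cfg.simulation)
        sim.setdefault("seed", cfg.seed)
        if "sampling_days" in sim:
            sim["sampling_days"] = tuple(sim["sampling_days"])
        ds = simulate_metabolome(SimulationConfig(**sim))
        ds.write(outdir / "simulated")
        return ds.table, ds.truth_pathways, ds
    table = read_feature_table(cfg.feature_table, cfg.annotation)
    pathways = read_gmt(cfg.pathways) if cfg.pathways else None
    if pathways is not None and cfg.pathway_overrides:
        overrides = pd.read_csv(cfg.pathway_overrides, sep="\t")
        pathways = pathways.apply_overrides(overrides)
    return table, pathways, None


def run_pipeline(config) -> dict:
    """Execute every stage and return (and write) the JSON report."""
    cfg = validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": []}
    t_start = time.time()

    def stage(name):
        log.info("stage %s", name)
        report["stages"].append(name)

    try:
        stage("input")
        table, pathways, dataset = _load_inputs(cfg, outdir)
        known_days = set(table.days)
        for a, b in cfg.contrasts:
            absent = (set(a) | set(b)) - known_days
            if absent:
                raise ValueError(
                    f"contrast {a} vs {b} references days absent from data: {sorted(absent)}"
                )

        stage("preprocess")
        normalized = median_normalize(table)
        processed = preprocess(table, k=cfg.knn_k, zero_policy=cfg.zero_policy)
        write_feature_table(processed, outdir / "processed.csv")
        profiles = aggregate_means(processed)
        profiles.values.to_csv(outdir / "mean_profiles.tsv", sep="\t")

        stage("pca")
        pca = fit_pca(processed, n_components=cfg.n_components)
        pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        report["pca"] = {
            "explained_fraction": [float(f) for f in pca.explained_fraction]
        }

        stage("contrasts")
        report["contrasts"] = []
        rankings = {}
        for a, b in cfg.contrasts:
            model = fit_oplsda(processed, (a, b), n_ortho=cfg.n_ortho)
            tests = univariate_tests(processed, (a, b), test=cfg.tests)
            diff = differential_table(model, tests)
            tag = f"{'-'.join(map(str, a))}_vs_{'-'.join(map(str, b))}"
            diff.to_csv(outdir / f"contrast_{tag}.tsv", sep="\t", index=False)
            rankings[tag] = model.p_pred
            bands = diff["vip_band"].value_counts().to_dict()
            report["contrasts"].append(
                {
                    "contrast": [list(a), list(b)],
                    "r2x_pred": model.r2x_pred,
                    "r2x_orth": [float(f) for f in model.r2x_orth],
                    "n_ortho": model.n_ortho,
                    "n_vip_strong": int(bands.get("strong", 0)),
                    "n_vip_weak": int(bands.get("weak", 0)),
                    "n_significant": int((diff["p_adj"] < 0.05).sum()),
                }
            )

        if pathways is not None:
            stage("msea")
            report["msea"] = {}
            for tag, loadings in rankings.items():
                ranked = RankedList.from_series(loadings)
                res = msea(
                    ranked,
                    pathways,
                    n_perm=cfg.n_perm,
                    min_size=cfg.min_size,
                    weight=cfg.msea_weight,
                    seed=cfg.seed,
                )
                res.to_csv(outdir / f"msea_{tag}.tsv", sep="\t", index=False)
                report["msea"][tag] = {
                    "n_pathways": int(len(res)),
                    "n_significant": int((res["p_adj"] < 0.05).sum()),
                }

        stage("covariation")
        corr = correlation_matrix(profiles, method=cfg.corr_method)
        net = build_network(corr, threshold=cfg.threshold, method=cfg.corr_method)
        layout_signed(net, seed=cfg.seed, iterations=cfg.layout_iterations)
        labels = cluster_nodes(net, k=cfg.n_clusters, seed=cfg.seed, n_init=cfg.n_init)
        dyn = cluster_dynamics(labels, profiles, processed.classes())
        nx.write_graphml(net.graph, outdir / "network.graphml")
        net.layout.assign(cluster=labels).to_csv(outdir / "layout.tsv", sep="\t")
        edges = nx.to_pandas_edgelist(net.graph)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        report["covariation"] = {
            "n_edges": net.graph.number_of_edges(),
            "cluster_sizes": [d.size for d in dyn],
        }
        if dataset is not None:
            from sklearn.metrics import adjusted_rand_score

            truth = [dataset.truth_clusters[m] for m in labels.index]
            report["covariation"]["archetype_ari"] = float(
                adjusted_rand_score(truth, labels.to_numpy())
            )
        if pathways is not None:
            ccorr = correlation_matrix(profiles, method=cfg.contrast_corr_method)
            pc = pathway_pair_correlations(ccorr, pathways)
            report["covariation"]["median_inside"] = pc.median_inside
            report["covariation"]["median_outside"] = pc.median_outside
            report["covariation"]["median_shift"] = pc.median_shift

        stage("fingerprint")
        fp_table = normalized if cfg.fingerprint_stage == "normalized" else processed
        if fp_table.values.isna().to_numpy().any():
            # normalized-stage fingerprints need observed values everywhere;
            # fall back to replicate means for the few missing cells
            vals = fp_table.values.copy()
            day_arr = fp_table.samples["day"].to_numpy()
            for d in fp_table.days:
                m = day_arr == d
                block = vals.loc[m]
                vals.loc[m] = block.fillna(block.mean())
            fp_table = MetaboliteTable(
                values=vals,
                samples=fp_table.samples.copy(),
                metabolites=fp_table.metabolites.copy(),
                stage=fp_table.stage,
                flags=dict(fp_table.flags),
            )
        fp = pair_distance_matrix(fp_table, stage=fp_table.stage)
        tc = cluster_timepoints(fp, linkage=cfg.fingerprint_linkage)
        fp.values.to_csv(outdir / "fingerprint.tsv", sep="\t")
        (outdir / "timepoint_tree.nwk").write_text(tc.to_newick(), encoding="utf-8")
        report["fingerprint"] = {
            "stage": fp.source_stage,
            "leaf_order": tc.leaf_order,
            "newick": tc.to_newick(),
        }
    except Exception as exc:  # annotate the failing stage, keep partial output
        failed = report["stages"][-1] if report["stages"] else "setup"
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    report["runtime_s"] = round(time.time() - t_start, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=1), encoding="utf-8")
    return report
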