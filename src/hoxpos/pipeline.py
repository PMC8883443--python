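"""End-to-end pipeline orchestration: QC → HVG → normalization → reference →
mapping → spatial genes → clustering → association, with a run manifest.

Every stage writes TSV artifacts into the output directory; the manifest
records the package version, the full parameter set, its hash, and every
defaulted parameter that upstream protocols leave unspecified, so runs are
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import class_association_fisher, cluster_association_ftest, ig_cluster_map
from .clustering import covariate_check, homeo_clustering, top_variable_clustering
from .containers import CountMatrix, ReferenceMap
from .mapping import MappingParams, estimate_rg, map_cells
from .normalization import near_binary_matrix
from .qc import annotate_hox, filter_cells, filter_genes
from .reference import IntensityTrace, build_reference
from .spatial import cluster_patterns, select_spatial_genes, smooth_profiles
from .synthetic import DEFAULT_HOX_SPECS, add_spatial_genes, make_reference, simulate_cells
from .variability import fit_technical_noise, scale_expression, size_factors, test_variable_genes

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, parameters and seed for one pipeline run."""

    counts_path: str | None = None
    counts_format: str | None = None
    traces_path: str | None = None
    out_dir: str = "hoxpos_out"
    # QC
    min_genes: int = 500
    min_reads: int = 10
    gene_min_cells: int = 5
    gene_min_reads: int = 10
    filter_order: str = "cells_first"
    # HVG
    fdr: float = 0.1
    min_mean_quantile: float = 0.3
    # normalization
    k: float = 1e6
    # reference / mapping
    grid_size: int = 201
    background_quantile: float = 0.1
    lambda_bg: float = 0.1
    hox_genes: list[str] = field(
        default_factory=lambda: [s.gene for s in DEFAULT_HOX_SPECS]
    )
    # spatial genes
    spline_df: int = 3
    decay: float = 10.0
    n_patterns: int = 10
    # clustering
    n_top_genes: int = 20
    n_major: int = 3
    n_homeo: int = 60
    # association
    alpha: float = 0.05
    # simulation fallback (used when counts_path is None)
    sim_cells: int = 500
    sim_r: float = 20.0
    sim_spatial: int = 20
    sim_flat: int = 20
    sim_effect: float = 8.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, cfg_hash: str, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# hoxpos config={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _load_inputs(cfg: PipelineConfig) -> tuple[CountMatrix, ReferenceMap]:
    if cfg.counts_path is not None:
        m = io.load_counts(cfg.counts_path, cfg.counts_format)
    else:
        ref = make_reference(DEFAULT_HOX_SPECS, cfg.grid_size)
        m, truth = simulate_cells(
            ref, cfg.sim_cells, r=cfg.sim_r, lambda_bg=cfg.lambda_bg, seed=cfg.seed
        )
        if cfg.sim_spatial or cfg.sim_flat:
            m, truth = add_spatial_genes(
                m, truth, cfg.sim_spatial, cfg.sim_flat, cfg.sim_effect, seed=cfg.seed + 1
            )
        log.info("no counts_path given: simulated %d cells", cfg.sim_cells)
        return m, ref
    if cfg.traces_path is not None:
        traces_df = io.load_traces(cfg.traces_path)
        traces = [
            IntensityTrace(g, grp["position"].to_numpy(), grp["intensity"].to_numpy())
            for g, grp in traces_df.groupby("gene", sort=False)
        ]
        ref = build_reference(traces, cfg.grid_size, cfg.background_quantile)
    else:
        ref = make_reference(DEFAULT_HOX_SPECS, cfg.grid_size)
        log.info("no traces_path given: using the built-in stripe reference")
    return m, ref


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages and write artifacts; returns the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    m, ref = _load_inputs(cfg)

    # --- QC --------------------------------------------------------------
    log.info("filter order: %s", cfg.filter_order)
    if cfg.filter_order == "cells_first":
        m, report = filter_cells(m, cfg.min_genes, cfg.min_reads)
        m = filter_genes(m, cfg.gene_min_cells, cfg.gene_min_reads)
    elif cfg.filter_order == "genes_first":
        m = filter_genes(m, cfg.gene_min_cells, cfg.gene_min_reads)
        m, report = filter_cells(m, cfg.min_genes, cfg.min_reads)
    else:
        raise ValueError(f"unknown filter_order {cfg.filter_order!r}")
    if m.n_cells == 0 or m.n_genes == 0:
        raise RuntimeError("qc stage: no cells or genes survive the filters")
    _write(report.per_cell, out / "qc_report.tsv", h)

    # --- variability ------------------------------------------------------
    sf = size_factors(m)
    fit = fit_technical_noise(m, sf, cfg.min_mean_quantile)
    hvg = test_variable_genes(m, fit, cfg.fdr)
    _write(hvg, out / "hvg.tsv", h)
    scaled = scale_expression(m, fit)

    # --- normalization ----------------------------------------------------
    nb = near_binary_matrix(m, size_factors=sf, params=cfg.k)
    _write(nb, out / "near_binary.tsv", h)

    # --- mapping ----------------------------------------------------------
    io.write_reference(ref, out / "reference.tsv")
    hox_present = [g for g in cfg.hox_genes if g in m.gene_ids]
    if len(hox_present) < 2:
        raise RuntimeError("mapping stage: fewer than 2 Hox genes in the matrix")
    hox_info = annotate_hox(m, hox_present)
    ref_used = (
        ref
        if list(ref.gene_ids) == hox_present
        else ReferenceMap(
            ref.grid,
            ref.curves[[ref.gene_ids.index(g) for g in hox_present]],
            hox_present,
        )
    )
    r = estimate_rg(m, hox_present)
    params = MappingParams(r=r.to_numpy(), lambda_bg=cfg.lambda_bg)
    positions_df = map_cells(m, ref_used, params)
    _write(positions_df, out / "positions.tsv", h)

    mapped = positions_df["mapped"] & ~hox_info["hox_negative"]
    pos = positions_df.loc[mapped, "x_hat"]

    # --- spatial genes ----------------------------------------------------
    svg = select_spatial_genes(
        scaled.loc[:, pos.index], pos.to_numpy(), df=cfg.spline_df
    )
    spatial_ids = svg.index[svg["is_spatial"]]
    if len(spatial_ids) >= cfg.n_patterns:
        profiles = smooth_profiles(
            scaled.loc[spatial_ids, pos.index], pos.to_numpy(), cfg.decay
        )
        svg["pattern_cluster"] = cluster_patterns(profiles, cfg.n_patterns).reindex(
            svg.index
        )
        _write(profiles, out / "smoothed_profiles.tsv", h)
    _write(svg, out / "spatial_genes.tsv", h)

    # --- clustering -------------------------------------------------------
    major, panel = top_variable_clustering(
        scaled, hvg, min(cfg.n_top_genes, m.n_genes), cfg.n_major
    )
    clusters = pd.DataFrame({"major_cluster": major})
    homeobox_panel = [
        g for g in m.genes_in_class("homeobox") if hvg.loc[g, "is_variable"]
    ] or m.genes_in_class("homeobox")
    homeo = None
    if homeobox_panel:
        n_homeo = min(cfg.n_homeo, int(mapped.sum()))
        homeo = homeo_clustering(
            nb.loc[homeobox_panel],
            hox_mask=hox_info["hox_negative"],
            n_clusters=n_homeo,
            positions=pos,
        )
        clusters["homeo_cluster"] = homeo.reindex(clusters.index)
        depth = pd.Series(m.counts.sum(axis=0), index=m.cell_ids)
        _write(covariate_check(homeo, depth), out / "covariate_check.tsv", h)
    _write(clusters, out / "clusters.tsv", h)

    # --- association ------------------------------------------------------
    labels = homeo if homeo is not None else major
    assoc = cluster_association_ftest(scaled.loc[:, labels.index], labels)
    class_sets = {}
    if m.gene_classes:
        for label in sorted({c for s in m.gene_classes.values() for c in s}):
            class_sets[label] = set(m.genes_in_class(label))
    if class_sets:
        assoc_classes = class_association_fisher(assoc, class_sets, cfg.alpha)
        _write(assoc_classes, out / "class_association.tsv", h)
        ig = class_sets.get("Ig-domain")
        if ig:
            norm = pd.DataFrame(
                np.log1p(m.counts / sf[None, :]), index=m.gene_ids, columns=m.cell_ids
            )
            igmap = ig_cluster_map(norm, labels, ig, positions=pos)
            _write(igmap, out / "ig_cluster_map.tsv", h, index=False)
    _write(assoc, out / "association.tsv", h)

    manifest = {
        "hoxpos_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": h,
        "n_cells": m.n_cells,
        "n_genes": m.n_genes,
        "n_mapped": int(mapped.sum()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
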