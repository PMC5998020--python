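"""End-to-end orchestration of the analysis pipeline.

Stages: merge -> tile -> per-ROI multi-threshold features -> population
statistics -> random-null filtering -> blob segmentation -> descriptors
-> unsupervised group discovery and matching.  Per-ROI stages share no
state and run through a worker-pool abstraction, so parallel and serial
runs produce identical results.  Every randomized stage takes its seed
from the config, and a provenance snapshot (config, seeds, registry
versions) is written next to the outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import blobs as blobs_mod
from . import filtering, identify, merge, partition, roi_analysis
from .io_events import EventList, LocalizationSet, read_event_list, \
    write_localization_set
from .registry import BLOB_REGISTRY_VERSION, ROI_REGISTRY_VERSION

__all__ = ["PipelineConfig", "CellInput", "PipelineResult", "run_pipeline",
           "load_config"]


@dataclass
class PipelineConfig:
    merge_T: float = 20.0
    roi_size: tuple[float, float, float] = (3000.0, 3000.0, 1000.0)
    filter_T: float = 80.0
    filter_alpha: float = 4.0
    filter_measure: str = "uwDeg"
    null_replicates: int = 10
    bandwidth: float = 80.0
    min_blob_size: int = 3
    k_max: int = 10
    beta: float = 30.0
    seed: int = 0
    n_workers: int = 1
    compute_roi_features: bool = True
    roi_registry_version: str = ROI_REGISTRY_VERSION
    blob_registry_version: str = BLOB_REGISTRY_VERSION


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config; unknown keys are rejected, missing keys
    fall back to (logged) defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "roi_size" in raw:
        raw["roi_size"] = tuple(float(v) for v in raw["roi_size"])
    return PipelineConfig(**raw)


@dataclass
class CellInput:
    events: EventList
    cell_id: str
    population: str

    @classmethod
    def from_file(cls, path, cell_id: str, population: str,
                  dialect=None) -> "CellInput":
        return cls(events=read_event_list(path, dialect=dialect),
                   cell_id=cell_id, population=population)


@dataclass
class PipelineResult:
    merged: dict[str, LocalizationSet]
    merge_stats: pd.DataFrame
    features: Optional[pd.DataFrame]
    significance: Optional[roi_analysis.SignificanceMap]
    filtered: dict[str, LocalizationSet]
    blob_table: pd.DataFrame
    blob_objects: dict[str, list]
    models: dict[str, identify.GroupModel]
    matching: Optional[identify.MatchResult]
    provenance: dict


def _process_roi(roi, cfg: PipelineConfig, want_features: bool):
    fv = roi_analysis.roi_features(roi) if want_features else None
    params = filtering.FilterParams(
        T_filter=cfg.filter_T, alpha=cfg.filter_alpha,
        measure=cfg.filter_measure, null_replicates=cfg.null_replicates)
    # stable per-ROI seed (crc32: independent of PYTHONHASHSEED)
    seed = cfg.seed + 7919 * roi.roi_index + (
        zlib.crc32(roi.cell_id.encode()) % 10_000)
    if len(roi) >= 2:
        res = filtering.degree_filter(roi, params, seed=seed)
        retained = res.retained
    else:
        retained = roi.points
    return fv, retained


def run_pipeline(inputs: Sequence[CellInput], cfg: PipelineConfig,
                 outdir=None) -> PipelineResult:
    """Run the whole pipeline over labeled cells.

    When ``outdir`` is given, stage outputs are written as plain-text
    tables plus a ``provenance.json`` snapshot.
    """
    if not inputs:
        raise ValueError("need at least one input cell")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    merged: dict[str, LocalizationSet] = {}
    merge_rows = []
    all_fvs: dict[str, list] = {}
    filtered: dict[str, LocalizationSet] = {}
    blob_objects: dict[str, list] = {}
    blob_rows = []

    pool = Parallel(n_jobs=cfg.n_workers, backend="loky") if (
        cfg.n_workers > 1) else None

    for cell in inputs:
        locs = merge.merge_blinks(cell.events,
                                  merge.MergeParams(threshold_T=cfg.merge_T))
        locs.source_label = cell.cell_id
        merged[cell.cell_id] = locs
        n_in, n_out = len(cell.events), len(locs)
        merge_rows.append({
            "cell_id": cell.cell_id, "population": cell.population,
            "n_blinks": n_in, "n_localizations": n_out,
            "percent_reduction": 100.0 * (n_in - n_out) / n_in if n_in else 0.0,
        })

        rois = partition.tile(locs, cfg.roi_size, cell_id=cell.cell_id)
        nonempty = [r for r in rois if not r.empty]
        if pool is not None:
            results = pool(delayed(_process_roi)(r, cfg,
                                                 cfg.compute_roi_features)
                           for r in nonempty)
        else:
            results = [_process_roi(r, cfg, cfg.compute_roi_features)
                       for r in nonempty]
        fvs = [fv for fv, _ in results if fv is not None]
        all_fvs[cell.cell_id] = fvs
        kept = [r for _, r in results if len(r)]
        if kept:
            filtered[cell.cell_id] = LocalizationSet(
                points=np.vstack([k.points for k in kept]),
                merged_from=np.concatenate([k.merged_from for k in kept]),
                source_label=cell.cell_id)
        else:
            filtered[cell.cell_id] = LocalizationSet(
                points=np.zeros((0, 3)),
                merged_from=np.zeros(0, dtype=np.int64),
                source_label=cell.cell_id)

        cell_blobs, _ = blobs_mod.segment_blobs(
            filtered[cell.cell_id], bandwidth=cfg.bandwidth,
            min_size=cfg.min_blob_size, roi_ref=cell.cell_id)
        blob_objects[cell.cell_id] = cell_blobs
        for b in cell_blobs:
            desc = blobs_mod.blob_descriptor(b, network_T=cfg.filter_T)
            row = {"cell_id": cell.cell_id,
                   "population": cell.population,
                   "blob_id": b.blob_id,
                   "degenerate": desc.degenerate}
            row.update(desc.as_dict())
            blob_rows.append(row)

    merge_stats = pd.DataFrame(merge_rows)
    blob_table = pd.DataFrame(blob_rows)

    populations = sorted({c.population for c in inputs})
    features = None
    significance = None
    if cfg.compute_roi_features:
        features = roi_analysis.features_frame(
            [fv for fvs in all_fvs.values() for fv in fvs])
        pop_of_cell = {c.cell_id: c.population for c in inputs}
        features.insert(1, "population",
                        features["cell_id"].map(pop_of_cell))
        if len(populations) == 2:
            fa = features[features["population"] == populations[0]]
            fb = features[features["population"] == populations[1]]
            if len(fa) and len(fb):
                pmat = roi_analysis.mw_map(fa, fb)
                significance = roi_analysis.aggregate_pvalues([pmat])

    models: dict[str, identify.GroupModel] = {}
    matching = None
    if len(blob_table):
        feat_cols = list(blobs_mod.BLOB_FEATURES)
        for pop in populations:
            sub = blob_table[blob_table["population"] == pop]
            if len(sub) >= 4:
                models[pop] = identify.discover_groups(
                    sub[feat_cols].to_numpy(), k_max=cfg.k_max,
                    seed=cfg.seed, population_tag=pop)
        if len(models) == 2:
            a, b = (models[p] for p in populations)
            matching = identify.match_groups(a, b, beta=cfg.beta)

    provenance = {
        "config": asdict(cfg),
        "cells": [{"cell_id": c.cell_id, "population": c.population,
                   "n_blinks": len(c.events)} for c in inputs],
        "roi_registry_version": cfg.roi_registry_version,
        "blob_registry_version": cfg.blob_registry_version,
    }

    if outdir is not None:
        merge_stats.to_csv(outdir / "merge_report.csv", index=False)
        for cid, locs in merged.items():
            write_localization_set(locs, outdir / f"locs_{cid}.csv")
        for cid, locs in filtered.items():
            write_localization_set(locs, outdir / f"filtered_{cid}.csv")
        if features is not None:
            features.to_csv(outdir / "roi_features.csv", index=False)
        if significance is not None:
            pd.DataFrame(significance.p_combined,
                         index=list(significance.measure_names),
                         columns=[int(t) for t in significance.thresholds_nm]
                         ).to_csv(outdir / "significance.csv")
        blob_table.to_csv(outdir / "blobs.csv", index=False)
        for pop, model in models.items():
            model.to_json(outdir / f"model_{pop}.json")
        if matching is not None:
            (outdir / "matching.json").write_text(json.dumps({
                "pairs": matching.pairs,
                "unmatched_a": matching.unmatched_a,
                "beta": matching.beta,
                "distances": matching.distances.tolist(),
            }, indent=2))
        (outdir / "provenance.json").write_text(
            json.dumps(provenance, indent=2))

    return PipelineResult(merged=merged, merge_stats=merge_stats,
                          features=features, significance=significance,
                          filtered=filtered, blob_table=blob_table,
                          blob_objects=blob_objects, models=models,
                          matching=matching, provenance=provenance)
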