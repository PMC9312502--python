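"""End-to-end pipeline: simulate → index → temporal → map → overlay → validate.

Each stage reads the on-disk outputs of the previous one, so any stage can
be re-run in isolation.  A :class:`RunManifest` records the config
snapshot, the seed, per-stage timings and a SHA-256 digest of every output
file; deterministic stages reproduce their digests under an identical
seed/config.

Configuration is a flat, human-editable key-value mapping (YAML on disk);
unknown keys are rejected before any stage runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .datatypes import IndexResult
from .index import compute_index, key_species
from .overlay import overlay as overlay_op
from .raster import read_ascii_grid, read_stack, write_ascii_grid
from .sediment import SystemRule, classify, grain_class
from .spatial import SpatialModel, predict_raster
from .synth import (
    CommunityData,
    GeneratorConfig,
    gen_communities,
    gen_landscape,
    gen_measurements,
    gen_scores,
    loop_bipc,
    stratified_cores,
)
from .temporal import system_contrast, tukey_letters
from .validation import corr_matrix

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "scores_path": None,               # use simulated scores when None
    "community_path": None,
    "sediment_threshold_um": 177.0,
    "sediment_overrides": {},
    "rf_trees": 1000,
    "rf_mtry_min": 1,
    "rf_mtry_max": 5,
    "rf_importance_repeats": 10,
    "bpc_rf_trees": 500,
    "bpc_rf_mtry": 3,
    "overlay_hot_quantile": 0.75,
    "overlay_delta_quantile": 0.10,
    "sim_n_taxa": 120,
    "sim_n_stations": 8,
    "sim_years": 5,
    "sim_advective_multiplier": 5.0,
    "sim_community_cv": 0.3,
    "sim_landscape_stations": 200,
    "sim_landscape_shape": [40, 40],
    "sim_landscape_noise_sigma": 0.3,
    "sim_n_cores": 14,
    "sim_measurement_sigma": 0.3,
}


class ConfigError(ValueError):
    """The pipeline configuration violates the schema."""


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge defaults, an optional YAML file and explicit overrides."""
    cfg = dict(DEFAULTS)
    loaded: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
    for src in (loaded, overrides or {}):
        for key, val in src.items():
            if key not in DEFAULTS:
                raise ConfigError(f"unknown configuration key {key!r}")
            cfg[key] = val
    return cfg


def _generator_config(cfg: Mapping[str, Any]) -> GeneratorConfig:
    return GeneratorConfig(
        seed=cfg["seed"],
        n_taxa=cfg["sim_n_taxa"],
        n_stations=cfg["sim_n_stations"],
        years=cfg["sim_years"],
        advective_multiplier=cfg["sim_advective_multiplier"],
        community_cv=cfg["sim_community_cv"],
        landscape_stations=cfg["sim_landscape_stations"],
        landscape_shape=tuple(cfg["sim_landscape_shape"]),
        landscape_noise_sigma=cfg["sim_landscape_noise_sigma"],
        n_cores=cfg["sim_n_cores"],
        measurement_sigma=cfg["sim_measurement_sigma"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict[str, Any]
    seed: int
    stages: list[str] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)   # path → sha256

    def record(self, stage: str, t0: float, files: list[Path]) -> None:
        self.stages.append(stage)
        self.timings_s[stage] = round(time.perf_counter() - t0, 3)
        for f in files:
            self.outputs[f.name] = _sha256(f)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _samples_to_frame(data: CommunityData) -> pd.DataFrame:
    rows = []
    for sample in data.samples:
        for rec in sample.records:
            rows.append(
                {
                    "station": sample.station_id,
                    "date": sample.date,
                    "taxon": rec.taxon,
                    "abundance_ind_m2": rec.abundance,
                    "biomass_afdw_g_m2": rec.biomass_afdw,
                    "depth_cm": rec.depth_measured,
                    "median_grain_um": sample.median_grain_um,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> RunManifest:
    """Execute all stages on (simulated or supplied) inputs.

    Failures abort with the stage named; outputs of completed stages are
    preserved.  Returns the manifest, which is also written to
    ``manifest.json`` in ``out_dir``.
    """
    cfg = dict(config)
    unknown = set(cfg) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    for key, default in DEFAULTS.items():
        cfg.setdefault(key, default)
    if cfg["scores_path"] is not None and not Path(cfg["scores_path"]).exists():
        raise ConfigError(f"scores_path {cfg['scores_path']!r} does not exist")
    if cfg["community_path"] is not None and not Path(cfg["community_path"]).exists():
        raise ConfigError(f"community_path {cfg['community_path']!r} does not exist")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]))
    gcfg = _generator_config(cfg)

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    scores = gen_scores(gcfg)
    land = gen_landscape(gcfg)
    files: list[Path] = []
    if cfg["scores_path"] is None:
        scores_path = out / "scores.csv"
        bio.write_score_table(scores, scores_path)
        files.append(scores_path)
    else:
        scores_path = Path(cfg["scores_path"])
        scores = bio.read_score_table(scores_path)
    if cfg["community_path"] is None:
        comm = gen_communities(gcfg, scores)
        community_path = out / "community.csv"
        _samples_to_frame(comm).to_csv(community_path, index=False)
        files.append(community_path)
    else:
        community_path = Path(cfg["community_path"])
    raster_dir = out / "rasters"
    raster_dir.mkdir(exist_ok=True)
    for name, layer in land.stack.layers.items():
        p = raster_dir / f"{name}.asc"
        write_ascii_grid(layer, p)
        files.append(p)
    stations_path = out / "landscape_stations.csv"
    pd.DataFrame(
        {
            "station": [f"L{i:03d}" for i in range(land.station_x.size)],
            "x": land.station_x,
            "y": land.station_y,
            "log_bipc_obs": land.station_log_bipc,
            "log_bpc_obs": land.station_log_bpc,
        }
    ).to_csv(stations_path, index=False)
    files.append(stations_path)
    manifest.record("simulate", t0, files)

    # --- index ----------------------------------------------------------
    t0 = time.perf_counter()
    samples = bio.read_community_table(community_path)
    rule = SystemRule(
        advective_min_grain_um=float(cfg["sediment_threshold_um"]),
        overrides=dict(cfg["sediment_overrides"]),
    )
    results: list[IndexResult] = []
    systems: list[str] = []
    for sample in samples:
        system = classify(sample, rule)
        systems.append(system)
        results.append(compute_index(sample, scores, system))
    index_path = out / "index.csv"
    bio.write_index_table(results, index_path)
    classes = [grain_class(s.median_grain_um) for s in samples]
    shares = key_species(samples, scores, systems, classes)
    key_path = out / "key_species.csv"
    pd.concat(
        [df.assign(group=g) for g, df in sorted(shares.items())], ignore_index=True
    ).to_csv(key_path, index=False)
    manifest.record("index", t0, [index_path, key_path])

    # --- temporal -------------------------------------------------------
    t0 = time.perf_counter()
    idx = bio.read_index_table(index_path)
    cmpres = tukey_letters(idx["bipc"], idx["station"])
    letters_path = out / "letters.csv"
    cmpres.summary().to_csv(letters_path, index=False)
    ratio, p = system_contrast(idx["bipc"], idx["system"])
    contrast_path = out / "system_contrast.json"
    contrast_path.write_text(
        json.dumps({"advective_diffusive_ratio": ratio, "tukey_p": p}, indent=2)
    )
    manifest.record("temporal", t0, [letters_path, contrast_path])

    # --- map ------------------------------------------------------------
    t0 = time.perf_counter()
    st = pd.read_csv(stations_path)
    stack = read_stack({p.stem: p for p in sorted(raster_dir.glob("*.asc"))})
    pred = pd.DataFrame(
        stack.extract(st["x"].to_numpy(), st["y"].to_numpy()), columns=stack.names
    )
    y_bipc = np.power(10.0, st["log_bipc_obs"].to_numpy()) - 1.0
    fit = SpatialModel(y_bipc, pred).fit(
        n_trees=int(cfg["rf_trees"]),
        mtry_values=range(int(cfg["rf_mtry_min"]), int(cfg["rf_mtry_max"]) + 1),
        seed=int(cfg["seed"]),
        importance_repeats=int(cfg["rf_importance_repeats"]),
    )
    bipc_map = predict_raster(fit, stack)
    map_path = out / "bipc_map.asc"
    write_ascii_grid(bipc_map, map_path)
    report_path = out / "fit_report.json"
    report_path.write_text(
        json.dumps(
            {
                "predictors": fit.predictors,
                "dropped": [d.name for d in fit.dropped],
                "n_trees": fit.n_trees,
                "mtry": fit.mtry,
                "oob_variance_explained_pct": fit.oob_variance_explained_pct,
                "importance_pct_inc_mse": fit.importance_pct_inc_mse,
                "kendall_tau": fit.kendall_tau,
                "kendall_p": fit.kendall_p,
                "seed": fit.seed,
            },
            indent=2,
            sort_keys=True,
        )
    )
    # reference BPc map: same pipeline, 500 trees / 3 variables per split
    y_bpc = np.power(10.0, st["log_bpc_obs"].to_numpy()) - 1.0
    fit_bpc = SpatialModel(y_bpc, pred).fit(
        n_trees=int(cfg["bpc_rf_trees"]),
        mtry_values=[int(cfg["bpc_rf_mtry"])],
        seed=int(cfg["seed"]),
        importance_repeats=int(cfg["rf_importance_repeats"]),
    )
    bpc_map = predict_raster(fit_bpc, stack)
    bpc_map_path = out / "bpc_map.asc"
    write_ascii_grid(bpc_map, bpc_map_path)
    manifest.record("map", t0, [map_path, report_path, bpc_map_path])

    # --- overlay --------------------------------------------------------
    t0 = time.perf_counter()
    ov = overlay_op(
        read_ascii_grid(map_path),
        read_ascii_grid(bpc_map_path),
        hot_quantile=float(cfg["overlay_hot_quantile"]),
        delta_quantile=float(cfg["overlay_delta_quantile"]),
    )
    overlay_path = out / "overlay.asc"
    write_ascii_grid(ov.classes, overlay_path)
    legend_path = out / "overlay_legend.txt"
    legend_path.write_text(ov.legend() + "\n")
    manifest.record("overlay", t0, [overlay_path, legend_path])

    # --- validate -------------------------------------------------------
    t0 = time.perf_counter()
    core_samples = stratified_cores(samples, int(cfg["sim_n_cores"]))
    core_truth = {
        s.sample_id: loop_bipc(s.records, scores, classify(s, rule))
        for s in core_samples
    }
    meas = gen_measurements(gcfg, core_truth)
    meas_path = out / "measurements.csv"
    pd.DataFrame(
        [
            {"core_id": m.core_id, "quantity": m.quantity, "value": m.value}
            for m in meas
        ]
    ).to_csv(meas_path, index=False)
    irr = {m.core_id: m.value for m in meas if m.quantity == "irrigation_l_m2_d"}
    table = pd.DataFrame(
        {
            "bipc": [
                compute_index(s, scores, classify(s, rule)).bipc
                for s in core_samples
            ],
            "bpc": [compute_index(s, scores, "diffusive").bpc for s in core_samples],
            "irrigation": [irr[s.sample_id] for s in core_samples],
        }
    )
    cm = corr_matrix(table, method="spearman")
    validation_path = out / "validation.csv"
    cm.matrix_layout().to_csv(validation_path)
    manifest.record("validate", t0, [meas_path, validation_path])

    manifest.write(out / "manifest.json")
    return manifest
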