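"""Config-driven end-to-end runs with deterministic, auditable outputs.

A run configuration is a plain dict (YAML/JSON on disk). Outputs of a
run are a function of the configuration and the input files only: all
randomness flows from the configured seed, and the provenance sidecar
records the resolved configuration and its hash so a run can be
re-executed bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, InputError
from .io_formats import (
    CellOutline,
    read_localizations,
    read_movie,
    read_outline,
    save_config,
    write_localizations,
    write_movie,
)
from .coloc import cbc, cbc_by_class, estimate_affine, apply_affine
from .dynamics import (
    TrackingParams,
    bleach_correct,
    ccs_mask,
    detect_centroids,
    enrichment_series,
    link_tracks,
    temporal_filter,
    track_stats,
    tracks_to_table,
)
from .sr_quant import ClassifierParams, analyze_scene
from .synthetic import SimulationConfig, simulate_ccs_movie, simulate_scene

log = logging.getLogger("ccsquant")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def write_provenance(outdir: Path, config: dict) -> None:
    """Resolved config + hash + version; deliberately no timestamp so
    that repeated runs stay byte-identical."""
    prov = {"config": config, "config_hash": config_hash(config), "version": __version__}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))


def objects_table(objects) -> pd.DataFrame:
    rows = []
    for o in objects:
        rows.append(
            {
                "label": o.label,
                "class": o.cls,
                "centroid_x_nm": o.centroid_nm[0],
                "centroid_y_nm": o.centroid_nm[1],
                "area_um2": o.area_um2,
                "perimeter_um": o.perimeter_um,
                "circularity": o.circularity,
                "equivalent_diameter_nm": o.equivalent_diameter_nm,
                "feret_max_nm": o.feret_max_nm,
                "feret_min_nm": o.feret_min_nm,
                "hole_count": o.hole_count,
                "mean_brightness": o.mean_brightness,
                "brightness_ratio": o.brightness_ratio,
            }
        )
    cols = [
        "label", "class", "centroid_x_nm", "centroid_y_nm", "area_um2", "perimeter_um",
        "circularity", "equivalent_diameter_nm", "feret_max_nm", "feret_min_nm",
        "hole_count", "mean_brightness", "brightness_ratio",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_sr_pipeline(config: dict, outdir) -> dict:
    """Render, segment, classify and measure one SR scene (+ optional CBC)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sr = config.get("sr", {})
    locs_path = sr.get("localizations")
    if not locs_path:
        raise ConfigurationError("sr.localizations is required")
    if not Path(locs_path).exists():
        raise InputError(f"stage sr: input not found: {locs_path}")
    table = read_localizations(locs_path, sr.get("dialect", "thunderstorm"))
    outline = read_outline(sr["outline"]) if sr.get("outline") else None
    params = ClassifierParams(**sr.get("classifier", {}))
    log.info("sr: %d localizations", len(table))
    result = analyze_scene(
        table,
        outline=outline,
        params=params,
        pixel_size_nm=sr.get("pixel_size_nm", 20.0),
        band_width_um=sr.get("band_width_um", 3.0),
        bounds_nm=tuple(sr["bounds_nm"]) if sr.get("bounds_nm") else None,
    )
    objects_table(result["objects"]).to_csv(outdir / "objects.csv", index=False)
    m = result["metrics"]
    metrics = {
        "n_pits": m.n_pits,
        "pit_density_per_um2": m.pit_density_per_um2,
        "n_plaques": m.n_plaques,
        "plaque_area_fraction": m.plaque_area_fraction,
        "roi_area_um2": m.roi_area_um2,
        "background_brightness": result["background_brightness"],
    }
    pd.DataFrame([metrics]).to_csv(outdir / "metrics.csv", index=False)
    cbc_cfg = config.get("cbc")
    if cbc_cfg:
        other = read_localizations(cbc_cfg["localizations"], cbc_cfg.get("dialect", "thunderstorm"))
        if cbc_cfg.get("beads_a") and cbc_cfg.get("beads_b"):
            a = np.loadtxt(cbc_cfg["beads_a"], delimiter=",")
            b = np.loadtxt(cbc_cfg["beads_b"], delimiter=",")
            t, rms = estimate_affine(b, a)  # map channel B onto channel A
            other = apply_affine(t, other)
            metrics["registration_rms_nm"] = rms
        by_class = cbc_by_class(
            other, result["objects"], table, result["image"].pixels.shape,
            r_max_nm=cbc_cfg.get("r_max_nm", 300.0), n_radii=cbc_cfg.get("n_radii", 10),
        )
        res = cbc(other, table, cbc_cfg.get("r_max_nm", 300.0), cbc_cfg.get("n_radii", 10))
        summary = {"mean": res.mean, "median": res.median, "by_class": by_class}
        (outdir / "cbc.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    write_provenance(outdir, config)
    return metrics


def run_dynamics_pipeline(config: dict, outdir) -> dict:
    """Preprocess a CCS movie, build masks, track and summarize."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dyn = config.get("dynamics", {})
    movie_path = dyn.get("movie")
    if not movie_path:
        raise ConfigurationError("dynamics.movie is required")
    if not Path(movie_path).exists():
        raise InputError(f"stage dynamics: input not found: {movie_path}")
    movie = read_movie(
        movie_path,
        frame_interval_s=dyn.get("frame_interval_s"),
        pixel_size_nm=dyn.get("pixel_size_nm"),
    )
    mean_w = min(dyn.get("mean_window_frames", 3), movie.n_frames)
    if mean_w % 2 == 0:
        mean_w -= 1
    smoothed = temporal_filter(movie, max(mean_w, 1), "mean")
    corrected = bleach_correct(smoothed)
    median_w = min(dyn.get("median_window_frames", 9), movie.n_frames)
    if median_w % 2 == 0:
        median_w -= 1
    denoised = temporal_filter(corrected, median_w, "median") if median_w > 1 else corrected
    masks = ccs_mask(denoised)
    detections = detect_centroids(denoised, masks)
    params = TrackingParams(max_link_distance_nm=dyn.get("max_link_distance_nm", 300.0))
    tracks = link_tracks(detections, params)
    tracks_to_table(tracks).to_csv(outdir / "tracks.csv", index=False)
    stats = track_stats(
        tracks, movie.frame_interval_s,
        full_length_only=dyn.get("full_length_only", False), movie_T=movie.n_frames,
    )
    stats.to_csv(outdir / "track_stats.csv", index=False)
    summary = {
        "n_tracks": int(len(stats)),
        "mean_duration_s": float(stats["duration_s"].mean()) if len(stats) else float("nan"),
    }
    if dyn.get("signal_movie") and dyn.get("stim_frame") is not None:
        sig = read_movie(
            dyn["signal_movie"],
            frame_interval_s=dyn.get("frame_interval_s"),
            pixel_size_nm=dyn.get("pixel_size_nm"),
        )
        series = enrichment_series(sig, masks, int(dyn["stim_frame"]))
        pd.DataFrame({"time_s": series.time_s, "enrichment": series.values}).to_csv(
            outdir / "enrichment.csv", index=False
        )
        post = series.values[series.stim_frame:]
        summary["enrichment_final"] = float(post[np.isfinite(post)][-1])
    write_provenance(outdir, config)
    return summary


def run_simulation(config: dict, outdir) -> dict:
    """Write a synthetic dataset bundle (scene + movie + truth sidecars)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.get("simulation", {})
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim_cfg) - fields - {"n_pits", "n_plaques", "n_structures"}
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    kwargs = {k: v for k, v in sim_cfg.items() if k in fields}
    for key in ("field_size_nm", "movie_shape", "pit_diameter_range_nm", "plaque_radius_range_nm"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    sim = SimulationConfig(**kwargs)
    n_pits = sim_cfg.get("n_pits", 50)
    n_plaques = sim_cfg.get("n_plaques", 5)
    table, scene = simulate_scene(sim, n_pits, n_plaques)
    write_localizations(table, outdir / "scene.csv", dialect="thunderstorm")
    (outdir / "scene_truth.json").write_text(scene.to_json())
    movies, truth = simulate_ccs_movie(sim, n_structures=sim_cfg.get("n_structures", 20))
    for name, mv in movies.items():
        write_movie(mv, outdir / f"movie_{name}.tif")
    (outdir / "movie_truth.json").write_text(truth.to_json())
    write_provenance(outdir, config)
    return {
        "n_structures_scene": len(scene.structures),
        "n_localizations": len(table),
        "n_tracks": len(truth.tracks),
    }
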