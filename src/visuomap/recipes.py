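"""Experiment recipes: end-to-end synthetic runs of the pipeline.

Each recipe bundles the stimulus configuration, GLM settings (high-pass
cutoff, contrasts) and rendering caps of one experiment:

- ``diamond``: bistable occluded-diamond display, variable-epoch
  percept GLM (HPF 128 s), render caps 25 (vs-fixation) / 15
  (differential).
- ``dots``: four central dot apertures, alternating 30 s blocks
  (HPF 185 s), caps 35 / 25.
- ``dots_quadrant``: small upper-right-quadrant configuration
  (HPF 185 s), caps 25 / 15.
- ``mapping``: wedge-and-ring retinotopic mapping and pRF estimation
  (HPF 155 s).

``run_recipe`` executes simulate -> (optionally) fit pRFs -> GLM ->
smooth/filter -> back-project -> RSA -> render, writing every product
plus a reproducibility manifest to an output directory.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import pyplot as plt

from . import io as vio
from .backprojection import backproject, render_heatmap
from .glm import FMRIGLM, build_design, parse_percept_stream
from .grid import VisualFieldGrid
from .hrf import double_gamma_hrf
from .prf import PRFEstimator, filter_vertices, smooth_vertex_values
from .rsa import ClassicalMDS, dissimilarity_matrix, loso_maps, ordination_plot
from .stimuli import diamond_region_masks, dots_aperture_masks, wedge_ring_apertures
from .synth import (DEFAULT_AREA_PROFILES, generate_percept_stream,
                    sample_vertex_population, simulate_differential_betas,
                    simulate_timeseries)

__all__ = ["RECIPES", "recipe_config", "run_recipe"]

RECIPES = {
    "diamond": {
        "hpf_cutoff": 128.0,
        "contrasts": {"global_vs_fix": {"global": 1.0},
                      "local_vs_fix": {"local": 1.0},
                      "global_vs_local": {"global": 1.0, "local": -1.0}},
        "caps": {"global_vs_fix": 25.0, "local_vs_fix": 25.0,
                 "global_vs_local": 15.0},
        "stimulus": "diamond",
        "display_window": (15.0, 415.0),
        "run_length_s": 430.0,
    },
    "dots": {
        "hpf_cutoff": 185.0,
        "contrasts": {"global_vs_fix": {"global": 1.0},
                      "local_vs_fix": {"local": 1.0},
                      "global_vs_local": {"global": 1.0, "local": -1.0}},
        "caps": {"global_vs_fix": 35.0, "local_vs_fix": 35.0,
                 "global_vs_local": 25.0},
        "stimulus": "dots_central",
        "run_length_s": 375.0,
    },
    "dots_quadrant": {
        "hpf_cutoff": 185.0,
        "contrasts": {"global_vs_fix": {"global": 1.0},
                      "local_vs_fix": {"local": 1.0},
                      "global_vs_local": {"global": 1.0, "local": -1.0}},
        "caps": {"global_vs_fix": 25.0, "local_vs_fix": 25.0,
                 "global_vs_local": 15.0},
        "stimulus": "dots_quadrant",
        "run_length_s": 375.0,
    },
    "mapping": {
        "hpf_cutoff": 155.0,
        "stimulus": "wedge_ring",
    },
}

_DEFAULTS = {
    "n_participants": 5,
    "n_vertices_per_area": 250,
    "areas": ["V1", "V2", "V3", "VLOC"],
    "tr": 1.0,
    "noise_sd": 1.0,
    "effect_size": 0.5,
    "mean_percept_durations": [8.0, 8.0],
    "smoothing_fwhm_mm": 3.0,
    "ar_model": "ar1",
    "fit_prfs": False,
    "n_prf_fit_vertices": 20,
    "render": True,
}


def recipe_config(name: str, overrides: dict | None = None) -> dict:
    """Fully resolved configuration for a named recipe."""
    if name not in RECIPES:
        raise ValueError(
            f"unknown recipe {name!r}; valid recipes: "
            f"{', '.join(sorted(RECIPES))}")
    cfg = dict(_DEFAULTS)
    cfg.update(RECIPES[name])
    cfg["recipe"] = name
    if overrides:
        cfg.update(overrides)
    return cfg


def _region_masks(cfg):
    grid = VisualFieldGrid(-8.5, 8.5, -8.5, 8.5, 0.1)
    stim = cfg["stimulus"]
    if stim == "diamond":
        return diamond_region_masks(grid)
    if stim == "dots_central":
        return dots_aperture_masks("central", grid)
    if stim == "dots_quadrant":
        return dots_aperture_masks("quadrant", grid)
    raise ValueError(f"no region masks for stimulus {stim!r}")


def _effects(cfg):
    delta = cfg["effect_size"]
    if cfg["stimulus"] == "diamond":
        return {"segments": -delta, "corners": -delta / 2,
                "center": delta / 2, "background": delta}
    # dots variants: suppression inside the apertures, enhancement outside
    eff = {f"aperture_{i}": -delta for i in range(1, 5)}
    eff["background"] = delta
    return eff


def _percept_events(cfg, seed):
    stream = generate_percept_stream(
        tuple(cfg["mean_percept_durations"]),
        tuple(cfg["display_window"]), seed=seed)
    return parse_percept_stream(stream)


def _block_events(cfg, seed):
    """Alternating 30 s condition blocks with 15 s fixation gaps."""
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    state = "local" if seed % 2 else "global"
    while t + 45.0 <= cfg["run_length_s"] - 15.0 + 1e-9:
        onset = t + 15.0
        rows.append({"onset": onset, "duration": 30.0, "condition": state})
        n_flicker = rng.choice([3, 6, 9])
        for ft in np.sort(rng.uniform(onset, onset + 30.0, n_flicker)):
            rows.append({"onset": float(ft), "duration": 0.0,
                         "condition": "flicker"})
        state = "global" if state == "local" else "local"
        t += 45.0
    return pd.DataFrame(rows)


def _simulate_participant_run(table, events, cfg, seed):
    """Per-vertex series with condition amplitudes set by region effects.

    Each vertex responds to the ``global`` epochs with
    ``1 + effect/2`` and to ``local`` epochs with ``1 - effect/2``
    (effect = its ground-truth regional amplitude), so the
    global-minus-local contrast recovers the injected pattern.
    """
    tr = cfg["tr"]
    n_vol = int(round(cfg["run_length_s"] / tr))
    design = build_design(events, tr, n_vol, hpf_cutoff=None)
    X = design.frame()
    rng = np.random.default_rng(seed)
    eff = table["true_effect"].to_numpy()
    amp = {"global": 1.0 + eff / 2.0, "local": 1.0 - eff / 2.0}
    Y = np.zeros((n_vol, len(table)))
    for cond in X.columns:
        if cond in amp:
            Y += np.outer(X[cond].to_numpy(), amp[cond])
        elif cond not in ("constant",):
            Y += np.outer(X[cond].to_numpy(), np.full(len(table), 0.3))
    Y += rng.normal(0.0, cfg["noise_sd"], Y.shape)
    return Y


def run_recipe(name: str, config: dict | None = None, seed: int = 0,
               outdir: str | Path = "visuomap_out") -> dict:
    """Execute one experiment recipe end to end on synthetic data.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory): seed, configuration, per-stage timings, vertex
    counts surviving each filter, and the paths of every output file.
    """
    cfg = recipe_config(name, config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"recipe": name, "seed": seed, "config": _jsonable_cfg(cfg),
                "stages": {}, "outputs": [], "filter_counts": {}}
    rng_root = np.random.default_rng(seed)
    stage_start = time.perf_counter()

    def _stage_done(stage):
        nonlocal stage_start
        manifest["stages"][stage] = round(time.perf_counter() - stage_start, 3)
        stage_start = time.perf_counter()

    try:
        # -- simulate: populations and ground-truth patterns -------------
        profiles = {a: DEFAULT_AREA_PROFILES[a] for a in cfg["areas"]}
        participants = [f"P{i + 1}" for i in range(cfg["n_participants"])]
        tables = {}
        for i, pid in enumerate(participants):
            tables[pid] = sample_vertex_population(
                profiles, cfg["n_vertices_per_area"],
                seed=int(rng_root.integers(2 ** 31)), participant=pid)
        if name == "mapping":
            return _run_mapping(cfg, tables, manifest, outdir, rng_root,
                                _stage_done)
        masks = _region_masks(cfg)
        for pid in participants:
            tables[pid] = simulate_differential_betas(
                tables[pid], masks, _effects(cfg), noise_sd=0.0,
                seed=int(rng_root.integers(2 ** 31)))
        _stage_done("simulate")

        # -- GLM per participant -----------------------------------------
        contrast_maps = {c: {} for c in cfg["contrasts"]}
        for pid in participants:
            ev_seed = int(rng_root.integers(2 ** 31))
            if cfg["stimulus"] == "diamond":
                events = _percept_events(cfg, ev_seed)
            else:
                events = _block_events(cfg, ev_seed)
            vio.write_event_table(events, outdir / f"events_{pid}.tsv")
            manifest["outputs"].append(str(outdir / f"events_{pid}.tsv"))
            Y = _simulate_participant_run(
                tables[pid], events, cfg, int(rng_root.integers(2 ** 31)))
            n_vol = Y.shape[0]
            design = build_design(events, cfg["tr"], n_vol,
                                  hpf_cutoff=cfg["hpf_cutoff"])
            glm = FMRIGLM(ar_model=cfg["ar_model"]).fit(design, Y)
            for cname, weights in cfg["contrasts"].items():
                usable = {k: v for k, v in weights.items()
                          if k in glm.names_}
                tables[pid][cname] = glm.contrast(usable).effect
        _stage_done("glm")

        # -- smooth and filter -------------------------------------------
        for pid in participants:
            t = filter_vertices(tables[pid], "pre_smoothing")
            coords = t[["cx", "cy"]].to_numpy()
            for cname in cfg["contrasts"]:
                t[cname] = smooth_vertex_values(
                    t[cname].to_numpy(), coords, cfg["smoothing_fwhm_mm"])
            n_pre = len(t)
            t = filter_vertices(t, "pre_backprojection")
            manifest["filter_counts"][pid] = {
                "raw": len(tables[pid]), "pre_smoothing": n_pre,
                "pre_backprojection": len(t)}
            tables[pid] = t
        _stage_done("smooth_filter")

        # -- back-projection per area and contrast ------------------------
        for area in cfg["areas"]:
            area_tables = {pid: t[t["area"] == area]
                           for pid, t in tables.items()}
            area_tables = {p: t for p, t in area_tables.items() if len(t)}
            for cname in cfg["contrasts"]:
                bp = backproject(area_tables, value_column=cname)
                prefix = outdir / f"map_{area}_{cname}"
                vio.save_backprojection_map(bp, prefix)
                manifest["outputs"].append(str(prefix) + "_t.tsv")
                if cfg["render"]:
                    fig, ax = plt.subplots(figsize=(4, 4))
                    render_heatmap(bp, cap=cfg["caps"][cname], ax=ax)
                    ax.set_title(f"{area} {cname}")
                    png = outdir / f"map_{area}_{cname}.png"
                    fig.savefig(png, dpi=120)
                    plt.close(fig)
                    manifest["outputs"].append(str(png))
        _stage_done("backproject")

        # -- RSA on the differential contrast ------------------------------
        diff = "global_vs_local"
        area = cfg["areas"][0]
        area_tables = {pid: t[t["area"] == area]
                       for pid, t in tables.items()}
        area_tables = {p: t for p, t in area_tables.items() if len(t) >= 2}
        if len(area_tables) >= 3:
            maps = loso_maps(area_tables, value_column=diff)
            D = dissimilarity_matrix(maps)
            D.to_csv(outdir / f"rdm_{area}_{diff}.tsv", sep="\t")
            manifest["outputs"].append(str(outdir / f"rdm_{area}_{diff}.tsv"))
            mds = ClassicalMDS(2)
            coords = mds.fit_transform(D)
            pd.DataFrame(coords, index=D.index,
                         columns=["dim1", "dim2"]).to_csv(
                outdir / f"ordination_{area}_{diff}.tsv", sep="\t")
            manifest["outputs"].append(
                str(outdir / f"ordination_{area}_{diff}.tsv"))
            if cfg["render"]:
                fig, ax = plt.subplots(figsize=(5, 5))
                ordination_plot(coords, list(D.index), ax=ax)
                fig.savefig(outdir / f"ordination_{area}_{diff}.png", dpi=120)
                plt.close(fig)
        _stage_done("rsa")
    except Exception as exc:  # annotate which stage failed
        stage = f"after {list(manifest['stages'])[-1]}" if manifest["stages"] \
            else "simulate"
        raise RuntimeError(f"recipe {name!r} failed in stage {stage}: {exc}") \
            from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _run_mapping(cfg, tables, manifest, outdir, rng_root, stage_done):
    """Mapping recipe: forward-simulate and re-fit pRFs for a subset."""
    apertures = wedge_ring_apertures()
    n_fit = cfg["n_prf_fit_vertices"]
    pid = next(iter(tables))
    sub = tables[pid].iloc[:n_fit].copy()
    Y = simulate_timeseries(sub, apertures, noise_sd=cfg.get("noise_sd", 0.0),
                            seed=int(rng_root.integers(2 ** 31)))
    stage_done("simulate")
    est = PRFEstimator(apertures, hrf=double_gamma_hrf(
        apertures.frame_duration)).fit(Y)
    fitted = est.params_.copy()
    fitted["vertex_id"] = sub["vertex_id"].to_numpy()
    fitted["participant"] = pid
    fitted["area"] = sub["area"].to_numpy()
    out = outdir / "prf_fits.tsv"
    vio.write_vertex_table(
        fitted[["vertex_id", "participant", "area", "x", "y", "sigma",
                "beta", "r2"]], out)
    manifest["outputs"].append(str(out))
    stage_done("fit_prf")
    manifest["prf_recovery"] = {
        "median_abs_dx": float(np.median(np.abs(
            fitted["x"].to_numpy() - sub["x"].to_numpy()))),
        "median_abs_dy": float(np.median(np.abs(
            fitted["y"].to_numpy() - sub["y"].to_numpy()))),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _jsonable_cfg(cfg):
    out = {}
    for k, v in cfg.items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out
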