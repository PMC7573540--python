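"""File formats: vertex tables, event tables, aperture stacks, maps,
configuration, and the GIfTI surface-data adapter.

Vertex and event tables are tab-delimited text; aperture sequences are
stored as a compressed array container plus a small JSON text header
with the grid metadata; back-projection maps are written as one
delimited matrix per field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .backprojection import BackProjectionMap
from .grid import VisualFieldGrid
from .stimuli import ApertureSequence

__all__ = [
    "VERTEX_TABLE_COLUMNS",
    "read_vertex_table",
    "write_vertex_table",
    "read_event_table",
    "write_event_table",
    "save_aperture_sequence",
    "load_aperture_sequence",
    "export_aperture_frames",
    "save_backprojection_map",
    "load_backprojection_map",
    "load_config",
    "save_config",
    "write_gifti_vertex_data",
    "read_gifti_vertex_data",
]

VERTEX_TABLE_COLUMNS = [
    "vertex_id", "participant", "area", "x", "y", "sigma", "beta", "r2",
]
_NUMERIC_COLUMNS = ["x", "y", "sigma", "beta", "r2"]
EVENT_TABLE_COLUMNS = ["onset", "duration", "condition"]


class SchemaError(ValueError):
    """A delimited file is missing required columns or has bad types."""


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} is missing required column(s): {', '.join(missing)}")


def read_vertex_table(path) -> pd.DataFrame:
    """Read a tab-delimited per-vertex pRF table."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, VERTEX_TABLE_COLUMNS, f"vertex table {path}")
    for col in _NUMERIC_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise SchemaError(f"column {col!r} in {path} is not numeric")
    return df


def write_vertex_table(table: pd.DataFrame, path) -> None:
    _check_columns(table, VERTEX_TABLE_COLUMNS, "vertex table")
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_event_table(path) -> pd.DataFrame:
    """Read a tab-delimited BIDS-style events table."""
    df = pd.read_csv(path, sep="\t")
    _check_columns(df, EVENT_TABLE_COLUMNS, f"event table {path}")
    return df


def write_event_table(events: pd.DataFrame, path) -> None:
    _check_columns(events, EVENT_TABLE_COLUMNS, "event table")
    events.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Aperture sequences
# ---------------------------------------------------------------------------

def save_aperture_sequence(seq: ApertureSequence, path) -> None:
    """Write frames as ``<path>.npz`` plus a ``<path>.json`` text header."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"),
                        frames=seq.frames.astype(np.uint8))
    g = seq.grid
    header = {
        "x_min": g.x_min, "x_max": g.x_max, "y_min": g.y_min,
        "y_max": g.y_max, "step": g.step,
        "frame_duration": seq.frame_duration,
        "n_frames": seq.n_frames,
        "meta": {k: _jsonable(v) for k, v in seq.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_aperture_sequence(path) -> ApertureSequence:
    path = Path(path)
    header = json.loads(path.with_suffix(".json").read_text())
    frames = np.load(path.with_suffix(".npz"))["frames"].astype(bool)
    grid = VisualFieldGrid(header["x_min"], header["x_max"],
                           header["y_min"], header["y_max"], header["step"])
    return ApertureSequence(frames, grid, header["frame_duration"],
                            header.get("meta", {}))


def export_aperture_frames(seq: ApertureSequence, directory,
                           stride: int = 1) -> list[Path]:
    """Dump frames as PNGs for visual inspection."""
    from matplotlib import pyplot as plt

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(0, seq.n_frames, stride):
        p = directory / f"frame_{i:04d}.png"
        plt.imsave(p, seq.frames[i], cmap="gray", origin="lower")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Back-projection maps
# ---------------------------------------------------------------------------

_MAP_FIELDS = ("t", "n", "w_raw", "w", "valid", "traversed")


def save_backprojection_map(bp_map: BackProjectionMap, prefix) -> None:
    """Write one delimited matrix per field plus a JSON grid header."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    for name in _MAP_FIELDS:
        arr = getattr(bp_map, name)
        np.savetxt(f"{prefix}_{name}.tsv", np.asarray(arr, float),
                   delimiter="\t", fmt="%.10g")
    g = bp_map.grid
    header = {"x_min": g.x_min, "x_max": g.x_max, "y_min": g.y_min,
              "y_max": g.y_max, "step": g.step,
              "meta": {k: _jsonable(v) for k, v in bp_map.meta.items()}}
    Path(f"{prefix}_grid.json").write_text(json.dumps(header, indent=1))


def load_backprojection_map(prefix) -> BackProjectionMap:
    prefix = Path(prefix)
    header = json.loads(Path(f"{prefix}_grid.json").read_text())
    grid = VisualFieldGrid(header["x_min"], header["x_max"],
                           header["y_min"], header["y_max"], header["step"])
    arrays = {name: np.loadtxt(f"{prefix}_{name}.tsv", delimiter="\t",
                               ndmin=2)
              for name in _MAP_FIELDS}
    return BackProjectionMap(
        grid, arrays["t"], arrays["n"].astype(int), arrays["w_raw"],
        arrays["w"], arrays["valid"].astype(bool),
        arrays["traversed"].astype(bool), header.get("meta", {}))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# GIfTI adapter
# ---------------------------------------------------------------------------

def write_gifti_vertex_data(table: pd.DataFrame, path) -> None:
    """Store the numeric vertex-table columns in a GIfTI functional file.

    One data array per numeric column, named via GIfTI metadata;
    string columns (participant, area) are stored as file-level
    metadata when constant.
    """
    import nibabel as nib

    img = nib.gifti.GiftiImage()
    for col in ["vertex_id"] + _NUMERIC_COLUMNS:
        arr = nib.gifti.GiftiDataArray(
            table[col].to_numpy(np.float32),
            intent="NIFTI_INTENT_NONE")
        arr.meta["Name"] = col
        img.add_gifti_data_array(arr)
    meta = {}
    for col in ("participant", "area"):
        if col in table.columns and table[col].nunique() == 1:
            meta[col] = str(table[col].iloc[0])
    img.meta = nib.gifti.GiftiMetaData(**meta)
    nib.save(img, str(path))


def read_gifti_vertex_data(path) -> pd.DataFrame:
    """Read a vertex table written by :func:`write_gifti_vertex_data`."""
    import nibabel as nib

    img = nib.load(str(path))
    data = {}
    for arr in img.darrays:
        name = arr.meta.get("Name", f"col{len(data)}")
        data[name] = np.asarray(arr.data, float)
    df = pd.DataFrame(data)
    if "vertex_id" in df:
        df["vertex_id"] = df["vertex_id"].astype(int)
    meta = dict(img.meta)
    df["participant"] = meta.get("participant", "P?")
    df["area"] = meta.get("area", "?")
    return df[[c for c in VERTEX_TABLE_COLUMNS if c in df.columns]]


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
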