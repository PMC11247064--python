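"""CSV/JSON serialization of cross-sections, fields, contours and results.

Only sites that belong to the vessel (non-exterior) are written, which keeps
the files compact; readers restore full grids.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (EXTERIOR, LABEL_NAMES, Contour, CrossSection, HexGrid)

__all__ = [
    "write_cross_section_csv", "read_cross_section_csv",
    "write_damage_csv", "read_damage_csv",
    "write_mask_csv", "read_mask_csv",
    "write_contour_csv", "read_contour_csv",
    "damage_to_json", "damage_from_json",
    "write_manifest",
]

_NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}


def write_cross_section_csv(cs: CrossSection, path) -> None:
    sites = np.flatnonzero(cs.labels != EXTERIOR)
    rows, cols = cs.grid.rowcol(sites)
    df = pd.DataFrame({
        "plane_id": cs.plane_id, "row": rows, "col": cols,
        "label": [LABEL_NAMES[int(l)] for l in cs.labels[sites]],
        "damage": (np.zeros(sites.size) if cs.damage is None
                   else cs.damage[sites]),
    })
    df.to_csv(path, index=False)


def read_cross_section_csv(path, grid: HexGrid,
                           axial_pos: float = 0.0) -> CrossSection:
    df = pd.read_csv(path)
    required = {"plane_id", "row", "col", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"cross-section CSV needs columns {sorted(required)}")
    labels = np.full(grid.n_sites, EXTERIOR, dtype=np.int8)
    damage = np.zeros(grid.n_sites)
    sites = grid.site_index(df["row"].to_numpy(), df["col"].to_numpy())
    labels[sites] = [_NAME_TO_LABEL[l] for l in df["label"]]
    if "damage" in df.columns:
        damage[sites] = df["damage"].to_numpy(float)
    plane_id = int(df["plane_id"].iloc[0]) if len(df) else 0
    return CrossSection(grid, labels, plane_id=plane_id,
                        axial_pos=axial_pos, damage=damage)


def write_damage_csv(damage: np.ndarray, grid: HexGrid, path,
                     plane_id: int = 0, threshold: float = 0.0) -> None:
    """Columns plane_id, row, col, damage; sites above ``threshold`` only."""
    sites = np.flatnonzero(np.asarray(damage) > threshold)
    rows, cols = grid.rowcol(sites)
    pd.DataFrame({"plane_id": plane_id, "row": rows, "col": cols,
                  "damage": np.asarray(damage)[sites]}).to_csv(path,
                                                               index=False)


def read_damage_csv(path, grid: HexGrid) -> np.ndarray:
    df = pd.read_csv(path)
    required = {"plane_id", "row", "col", "damage"}
    if not required.issubset(df.columns):
        raise ValueError(f"damage CSV needs columns {sorted(required)}")
    out = np.zeros(grid.n_sites)
    sites = grid.site_index(df["row"].to_numpy(), df["col"].to_numpy())
    vals = df["damage"].to_numpy(float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("damage values must lie in [0, 1]")
    out[sites] = vals
    return out


def write_mask_csv(mask: np.ndarray, grid: HexGrid, path,
                   plane_id: int = 0) -> None:
    sites = np.flatnonzero(np.asarray(mask, bool))
    rows, cols = grid.rowcol(sites)
    pd.DataFrame({"plane_id": plane_id, "row": rows, "col": cols,
                  "deleted": True}).to_csv(path, index=False)


def read_mask_csv(path, grid: HexGrid) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.zeros(grid.n_sites, bool)
    if len(df):
        out[grid.site_index(df["row"].to_numpy(), df["col"].to_numpy())] = \
            df["deleted"].to_numpy(bool)
    return out


def write_contour_csv(contour: Contour, path, plane_id: int = 0) -> None:
    pd.DataFrame({"plane_id": plane_id,
                  "x_mm": contour.points[:, 0],
                  "y_mm": contour.points[:, 1]}).to_csv(path, index=False)


def read_contour_csv(path) -> Contour:
    df = pd.read_csv(path)
    return Contour(df[["x_mm", "y_mm"]].to_numpy(float))


def damage_to_json(damage: np.ndarray, grid: HexGrid, path,
                   plane_id: int = 0) -> None:
    sites = np.flatnonzero(np.asarray(damage) > 0)
    rows, cols = grid.rowcol(sites)
    payload = {"plane_id": plane_id,
               "sites": {f"{r},{c}": float(v) for r, c, v
                         in zip(rows, cols, np.asarray(damage)[sites])}}
    Path(path).write_text(json.dumps(payload))


def damage_from_json(path, grid: HexGrid) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    out = np.zeros(grid.n_sites)
    for key, v in payload["sites"].items():
        r, c = (int(t) for t in key.split(","))
        out[grid.site_index(r, c)] = v
    return out


def write_manifest(path, config, seed: int, extra: dict | None = None) -> None:
    """Deterministic run manifest: config dump, seed, package versions."""
    import hashlib
    import restenosim

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "versions": {"restenosim": restenosim.__version__,
                     "numpy": np.__version__},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
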