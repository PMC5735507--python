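"""Scene serialization: TIFF channels, ground-truth CSV, JSON sidecar.

A scene directory holds one 16-bit grayscale TIFF per channel
(``phase.tif``, ``nuclei_all.tif``, ``nuclei_dead.tif``,
``live_cyto.tif``), the cell table as ``cells.csv`` and a
``scene.json`` sidecar recording layout, condition and seeds so a run
can be reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .conditions import SeedingCondition
from .layout import ArrayLayout
from .scene import GROUND_TRUTH_COLUMNS, ImageSet, SceneGroundTruth

CHANNEL_FILES = {
    "phase": "phase.tif",
    "nuclei_all": "nuclei_all.tif",
    "nuclei_dead": "nuclei_dead.tif",
    "live_cyto": "live_cyto.tif",
}
CELLS_FILE = "cells.csv"
SIDECAR_FILE = "scene.json"


def _layout_to_dict(layout: ArrayLayout) -> dict:
    d = dataclasses.asdict(layout)
    d["well_centers"] = np.asarray(layout.well_centers).tolist()
    d["footprint_um"] = list(layout.footprint_um)
    return d


def _layout_from_dict(d: dict) -> ArrayLayout:
    d = dict(d)
    d["well_centers"] = np.asarray(d["well_centers"], dtype=float)
    d["footprint_um"] = tuple(d["footprint_um"])
    return ArrayLayout(**d)


def _condition_to_dict(condition: SeedingCondition) -> dict:
    d = dataclasses.asdict(condition)
    if d.get("occupancy_dist") is not None:
        d["occupancy_dist"] = {str(k): v for k, v in d["occupancy_dist"].items()}
    return d


def _condition_from_dict(d: dict) -> SeedingCondition:
    d = dict(d)
    if d.get("occupancy_dist") is not None:
        d["occupancy_dist"] = {int(k): v for k, v in d["occupancy_dist"].items()}
    return SeedingCondition(**d)


def write_scene(
    image_set: ImageSet,
    ground_truth: SceneGroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one scene to ``out_dir``; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, fname in CHANNEL_FILES.items():
        path = out / fname
        tifffile.imwrite(path, image_set.channels[name])
        written[name] = path

    cells_path = out / CELLS_FILE
    # %.17g guarantees exact float64 round-trip through text
    ground_truth.cells.to_csv(cells_path, index=False, float_format="%.17g")
    written["cells"] = cells_path

    sidecar = {
        "layout": _layout_to_dict(ground_truth.layout),
        "condition": _condition_to_dict(ground_truth.condition),
        "pixel_scale_um_per_px": image_set.pixel_scale_um_per_px,
        "n_cells": int(ground_truth.n_cells),
        "channels": {k: v for k, v in CHANNEL_FILES.items()},
    }
    sidecar_path = out / SIDECAR_FILE
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written["sidecar"] = sidecar_path
    return written


def read_scene(scene_dir: str | Path) -> tuple[ImageSet, SceneGroundTruth]:
    """Read a scene directory written by :func:`write_scene`."""
    d = Path(scene_dir)
    sidecar = json.loads((d / SIDECAR_FILE).read_text())
    layout = _layout_from_dict(sidecar["layout"])
    condition = _condition_from_dict(sidecar["condition"])
    channels = {
        name: tifffile.imread(d / fname) for name, fname in CHANNEL_FILES.items()
    }
    image_set = ImageSet(
        pixel_scale_um_per_px=float(sidecar["pixel_scale_um_per_px"]), **channels
    )
    cells = pd.read_csv(d / CELLS_FILE, float_precision="round_trip")
    if len(cells) == 0:
        cells = cells.astype(
            {"cell_id": int, "x_um": float, "y_um": float, "well_id": int}
        )
    cells = cells[GROUND_TRUTH_COLUMNS]
    cells["is_interior"] = cells["is_interior"].astype(bool)
    cells["is_dead"] = cells["is_dead"].astype(bool)
    gt = SceneGroundTruth(cells=cells, condition=condition, layout=layout)
    return image_set, gt
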