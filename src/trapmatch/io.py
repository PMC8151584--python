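"""Readers and writers: images, detections, ground truth, correlation maps."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detection import Detection
from .imaging_core import to_grayscale
from .synthetic_scenes import Annotation


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as a float64 grayscale array."""
    return to_grayscale(iio.imread(path))


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a grayscale array as an 8-bit image (rounded, clipped)."""
    arr = np.clip(np.round(np.asarray(image)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def detections_to_frame(
    detections: list[Detection], image_id: str = ""
) -> pd.DataFrame:
    rows = []
    for i, d in enumerate(detections):
        f = d.features
        rows.append({
            "image_id": image_id, "detection_id": i,
            "center_x": d.center_x, "center_y": d.center_y,
            "score": d.score, "label": d.label or "",
            "perimeter": f.perimeter if f is not None else "",
            "area": f.area if f is not None else "",
            "ratio1": f.ratio1 if f is not None else "",
            "ratio2": f.ratio2 if f is not None else "",
        })
    return pd.DataFrame(rows, columns=[
        "image_id", "detection_id", "center_x", "center_y", "score",
        "label", "perimeter", "area", "ratio1", "ratio2",
    ])


def write_detections_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def write_detections_json(
    detections: list[Detection], path: str | Path, image_id: str = ""
) -> None:
    records = [{
        "image_id": image_id,
        "center_x": d.center_x, "center_y": d.center_y,
        "score": d.score, "label": d.label,
        "roi_box": list(d.roi_box),
    } for d in detections]
    Path(path).write_text(json.dumps(records, indent=1))


def read_truth_json(path: str | Path) -> list[Annotation]:
    """Ground-truth annotations from a JSON list of insect records."""
    return [Annotation.from_dict(r) for r in json.loads(Path(path).read_text())]


def write_truth_json(annotations: list[Annotation], path: str | Path) -> None:
    Path(path).write_text(json.dumps([a.to_dict() for a in annotations], indent=1))


def save_correlation_map(rmap: np.ndarray, path: str | Path) -> None:
    """Export a correlation map as float32 TIFF (.tif) or CSV (anything else)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(rmap, dtype=np.float32))
    else:
        np.savetxt(path, np.asarray(rmap), delimiter=",")


def overlay_detections(
    image: np.ndarray, detections: list[Detection], color_mosquito_only: bool = True
) -> np.ndarray:
    """RGB copy of the image with rectangles on detections.

    Mosquito-labeled detections are framed in red; others (when drawn) in
    gray, mirroring the colored-classification display of the pipeline.
    """
    gray = np.clip(np.round(np.asarray(image)), 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for d in detections:
        if color_mosquito_only and d.label != "mosquito":
            continue
        color = (255, 40, 40) if d.label == "mosquito" else (160, 160, 160)
        x0, y0, w, h = d.roi_box
        x1, y1 = x0 + w - 1, y0 + h - 1
        rgb[y0, x0:x1 + 1] = color
        rgb[y1, x0:x1 + 1] = color
        rgb[y0:y1 + 1, x0] = color
        rgb[y0:y1 + 1, x1] = color
    return rgb
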