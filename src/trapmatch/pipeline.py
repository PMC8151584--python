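"""End-to-end batch runner: detect, classify, and (optionally) evaluate.

Ties the stages together for a list of input images: grayscale load,
padded template matching with covering, ROI shape classification, CSV/JSON
output, and — when ground truth is supplied — confusion counts and metrics.
Unreadable files are logged and skipped; the rest of the batch continues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .classification import classify_roi, roi_pipeline_stages
from .config import PipelineConfig
from .detection import Detection, detect, extract_roi
from .evaluation import ConfusionCounts, Metrics, compute_metrics, match_to_ground_truth

logger = logging.getLogger("trapmatch")


@dataclass
class PipelineResult:
    detections: dict[str, list[Detection]] = field(default_factory=dict)
    frame: pd.DataFrame | None = None
    counts: ConfusionCounts | None = None
    metrics: Metrics | None = None
    failures: list[str] = field(default_factory=list)


def process_image(
    image: np.ndarray,
    template: np.ndarray,
    config: PipelineConfig,
) -> list[Detection]:
    """Detect targets in one grayscale image and label each ROI."""
    detections = detect(image, template, config.detection_config())
    for d in detections:
        roi = extract_roi(image, d, template)
        result = classify_roi(roi, config.theta1, config.theta2, config.morph_size)
        d.label = result.label
        d.features = result.features
    return detections


def run_pipeline(
    images: list[str | Path],
    config: PipelineConfig,
    template: np.ndarray | None = None,
    truth: dict[str, list] | None = None,
    out_dir: str | Path | None = None,
    debug_stages: bool = False,
) -> PipelineResult:
    """Run the full pipeline over a batch of image files.

    ``truth`` maps image ids (file stems) to annotation lists; when given,
    per-batch confusion counts and metrics are computed.  With ``out_dir``
    set, per-image detection CSV/JSON and an aggregate CSV are written; with
    ``debug_stages`` also the per-ROI intermediate images.
    """
    config.validate()
    if not images:
        raise ValueError("empty input list")
    if template is None:
        if not config.template_path:
            raise ValueError("no template: pass one or set template.path in the config")
        template = tio.load_image(config.template_path)

    result = PipelineResult()
    frames = []
    total_counts = ConfusionCounts(0, 0, 0)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for path in images:
        path = Path(path)
        image_id = path.stem
        try:
            image = tio.load_image(path)
        except Exception as exc:  # unreadable frame: log and continue
            logger.error("skipping %s: %s", path, exc)
            result.failures.append(str(path))
            continue
        detections = process_image(image, template, config)
        result.detections[image_id] = detections
        frames.append(tio.detections_to_frame(detections, image_id))
        logger.info("%s: %d detections, %d labeled mosquito", image_id,
                    len(detections),
                    sum(d.label == "mosquito" for d in detections))
        if out is not None:
            tio.write_detections_json(detections, out / f"{image_id}.json", image_id)
            tio.save_image(tio.overlay_detections(image, detections),
                           out / f"{image_id}_overlay.png")
            if debug_stages:
                for i, d in enumerate(detections):
                    stages = roi_pipeline_stages(extract_roi(image, d, template),
                                                 config.morph_size)
                    for name, arr in stages.items():
                        img8 = arr * 255.0 if arr.dtype == bool else arr
                        tio.save_image(img8, out / f"{image_id}_det{i}_{name}.png")
        if truth is not None and image_id in truth:
            c = match_to_ground_truth(detections, truth[image_id], config.match_tol)
            total_counts = ConfusionCounts(
                total_counts.tp + c.tp, total_counts.fn + c.fn, total_counts.fp + c.fp
            )

    if not result.detections and result.failures:
        raise ValueError("no readable input images")
    result.frame = (pd.concat(frames, ignore_index=True) if frames
                    else pd.DataFrame())
    if truth is not None:
        result.counts = total_counts
        if total_counts.tp + total_counts.fn > 0 and total_counts.tp + total_counts.fp > 0:
            result.metrics = compute_metrics(total_counts)
    if out is not None and result.frame is not None:
        tio.write_detections_csv(result.frame, out / "detections.csv")
    return result
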