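"""Iterative multi-target extraction from a correlation map.

A single correlation map yields only one target (its global maximum).  The
multi-target procedure thresholds the map and extracts maxima one at a time:
after a peak is accepted, the template-sized region of the map centered on it
is *covered* — overwritten with the map's global minimum, recorded once
before any covering — so the next global maximum finds a different target.
The loop stops when the maximum falls below the threshold (default 0.4).

With covering disabled the detector degrades to single-template matching (at
most one detection); with padding disabled, targets near the image border
lack full correlation support and are typically missed.  Both switches exist
so the three operating modes can be compared on the same scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from . import imaging_core
from .errors import ConfigError


@dataclass
class DetectionConfig:
    """Operating point of the detector.

    threshold: minimum correlation for an accepted peak, in (-1, 1).
    cover_width, cover_height: size of the covered map region around an
        accepted peak; ``None`` means the template's own width/height.
    enable_padding: pad the image by the template size before matching.
    enable_covering: iterate beyond the first peak.
    max_detections: hard cap on the extraction loop.
    pad_fill: border fill policy, "median" | "edge" | numeric constant.
    """

    threshold: float = 0.4
    cover_width: Optional[int] = None
    cover_height: Optional[int] = None
    enable_padding: bool = True
    enable_covering: bool = True
    max_detections: int = 100
    pad_fill: str | float = "median"

    def validate(self) -> None:
        if not (-1.0 < self.threshold < 1.0):
            raise ConfigError(f"threshold must lie in (-1, 1), got {self.threshold}")
        for name in ("cover_width", "cover_height"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.max_detections < 1:
            raise ConfigError(f"max_detections must be >= 1, got {self.max_detections}")


@dataclass
class Detection:
    """One detected target.

    ``peak_x``/``peak_y`` are correlation-map coordinates of the accepted
    maximum (template top-left placement); ``center_x``/``center_y`` are the
    corresponding target center in original-image coordinates; ``roi_box`` is
    the template-sized analysis window ``(x0, y0, w, h)``, shifted inward
    where necessary so it lies entirely within the image.
    """

    peak_x: int
    peak_y: int
    center_x: int
    center_y: int
    score: float
    roi_box: tuple[int, int, int, int]
    label: Optional[str] = None
    features: Optional[object] = None


def _clamped_box(cx: int, cy: int, tw: int, th: int,
                 width: int, height: int) -> tuple[int, int, int, int]:
    x0 = min(max(cx - tw // 2, 0), width - tw)
    y0 = min(max(cy - th // 2, 0), height - th)
    return (x0, y0, tw, th)


def detect(
    image: np.ndarray,
    template: np.ndarray,
    config: DetectionConfig | None = None,
) -> list[Detection]:
    """Run threshold–extract–cover matching and return detections.

    Returns detections in decreasing score order (the extraction order).
    Equal maxima break ties in raster order (smallest y, then smallest x).
    Map peak coordinates convert to original-image centers by adding half the
    template size and, when padding is on, subtracting the padding offsets;
    with the symmetric padding used here the two corrections cancel, so a
    padded-map peak at (x, y) is the target center (x, y) directly (clamped
    to the image bounds for peaks inside the padded border).
    """
    config = config or DetectionConfig()
    config.validate()
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    tpl = np.asarray(template, dtype=np.float64)
    th, tw = tpl.shape
    height, width = img.shape

    work = imaging_core.pad_image(img, tpl, fill=config.pad_fill) \
        if config.enable_padding else img
    rmap = imaging_core.match_template(work, tpl).copy()
    ox, oy = (tw // 2, th // 2) if config.enable_padding else (0, 0)

    cover_w = config.cover_width if config.cover_width is not None else tw
    cover_h = config.cover_height if config.cover_height is not None else th
    # "the minimum value from Step five": captured once, before any covering.
    floor = float(rmap.min())

    detections: list[Detection] = []
    while len(detections) < config.max_detections:
        flat_idx = int(np.argmax(rmap))  # raster order breaks ties
        py, px = (int(v) for v in np.unravel_index(flat_idx, rmap.shape))
        score = float(rmap[py, px])
        if score < config.threshold:
            break
        cx = min(max(px + tw // 2 - ox, 0), width - 1)
        cy = min(max(py + th // 2 - oy, 0), height - 1)
        detections.append(Detection(
            peak_x=int(px), peak_y=int(py),
            center_x=int(cx), center_y=int(cy),
            score=score,
            roi_box=_clamped_box(cx, cy, tw, th, width, height),
        ))
        if not config.enable_covering:
            break
        y0 = max(py - cover_h // 2, 0)
        x0 = max(px - cover_w // 2, 0)
        rmap[y0:py + cover_h - cover_h // 2, x0:px + cover_w - cover_w // 2] = floor
    return detections


def detect_boundary_case(
    image: np.ndarray,
    template: np.ndarray,
    config: DetectionConfig | None = None,
) -> tuple[int, int]:
    """Detection counts on the same scene with padding off, then on.

    Supports the padding ablation: a target straddling the border gains full
    correlation support only when the image is padded.
    """
    config = config or DetectionConfig()
    n_off = len(detect(image, template, replace(config, enable_padding=False)))
    n_on = len(detect(image, template, replace(config, enable_padding=True)))
    return n_off, n_on


def extract_roi(
    image: np.ndarray,
    detection: Detection,
    template: np.ndarray,
) -> np.ndarray:
    """Template-sized sub-image centered on the detection.

    The box is shifted inward at borders so the returned window always has
    the full template dimensions (downstream shape features need a complete
    window).
    """
    img = np.asarray(image, dtype=np.float64)
    th, tw = np.asarray(template).shape[:2]
    x0, y0, _, _ = _clamped_box(detection.center_x, detection.center_y,
                                tw, th, img.shape[1], img.shape[0])
    return img[y0:y0 + th, x0:x0 + tw]
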