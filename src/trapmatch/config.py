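"""Pipeline configuration: a flat TOML file that round-trips losslessly.

All tunable constants of the pipeline (frame and template geometry, the
correlation threshold, classification thresholds, matching tolerance, scene
photometry) live in one config object loaded from TOML; the packaged
``default_config.toml`` holds the defaults.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields
from importlib import resources
from pathlib import Path

from .detection import DetectionConfig
from .errors import ConfigError


@dataclass
class PipelineConfig:
    image_width: int = 1280
    image_height: int = 960
    template_width: int = 200
    template_height: int = 144
    threshold: float = 0.4
    enable_padding: bool = True
    enable_covering: bool = True
    max_detections: int = 100
    pad_fill: str | float = "median"
    theta1: float = 0.2165
    theta2: float = 38.0
    morph_size: int = 3
    match_tol: float = 100.0
    background_intensity: float = 30.0
    illumination_gradient: float = 40.0
    noise_sigma: float = 5.0
    contrast: float = 140.0
    template_path: str = ""
    output_dir: str = "trapmatch_out"
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        if not (-1.0 < self.threshold < 1.0):
            raise ConfigError(f"detection.threshold must be in (-1, 1), got {self.threshold}")
        for name in ("image_width", "image_height", "template_width",
                     "template_height", "morph_size", "max_detections"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.template_width > self.image_width or self.template_height > self.image_height:
            raise ConfigError("template dimensions must not exceed image dimensions")
        if self.match_tol <= 0:
            raise ConfigError(f"evaluation.match_tol must be > 0, got {self.match_tol}")
        if self.noise_sigma < 0:
            raise ConfigError(f"scene.noise_sigma must be >= 0, got {self.noise_sigma}")

    def detection_config(self) -> DetectionConfig:
        return DetectionConfig(
            threshold=self.threshold,
            enable_padding=self.enable_padding,
            enable_covering=self.enable_covering,
            max_detections=self.max_detections,
            pad_fill=self.pad_fill,
        )


_SECTIONS = {
    "image": {"width": "image_width", "height": "image_height"},
    "template": {"width": "template_width", "height": "template_height",
                 "path": "template_path"},
    "detection": {"threshold": "threshold", "enable_padding": "enable_padding",
                  "enable_covering": "enable_covering",
                  "max_detections": "max_detections", "pad_fill": "pad_fill"},
    "classification": {"theta1": "theta1", "theta2": "theta2",
                       "morph_size": "morph_size"},
    "evaluation": {"match_tol": "match_tol"},
    "scene": {"background_intensity": "background_intensity",
              "illumination_gradient": "illumination_gradient",
              "noise_sigma": "noise_sigma", "contrast": "contrast"},
    "run": {"output_dir": "output_dir", "log_level": "log_level", "seed": "seed"},
}


def _from_mapping(data: dict) -> PipelineConfig:
    known = {f.name for f in fields(PipelineConfig)}
    kwargs = {}
    for section, entries in data.items():
        mapping = _SECTIONS.get(section)
        if mapping is None:
            raise ConfigError(f"unknown config section [{section}]")
        if not isinstance(entries, dict):
            raise ConfigError(f"section [{section}] must be a table")
        for key, value in entries.items():
            attr = mapping.get(key)
            if attr is None or attr not in known:
                raise ConfigError(f"unknown config field {section}.{key}")
            kwargs[attr] = value
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a TOML config; with no path, the packaged defaults."""
    if path is None:
        text = resources.files("trapmatch").joinpath("default_config.toml").read_text()
    else:
        text = Path(path).read_text()
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"invalid TOML: {exc}") from exc
    return _from_mapping(data)


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config as flat TOML; ``load_config`` recovers it exactly."""
    values = asdict(config)
    lines: list[str] = []
    for section, mapping in _SECTIONS.items():
        lines.append(f"[{section}]")
        for key, attr in mapping.items():
            lines.append(f"{key} = {_format_value(values[attr])}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
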