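"""Seeded generator of trap-like scenes with ground truth.

Emulates the imaging geometry of a suction trap photographing insects
against a dark cloth: a low-intensity background with a linear top-to-bottom
illumination gradient (the illuminator sits above the camera's field of
view), small high-contrast insect silhouettes, and additive Gaussian sensor
noise clipped to the 8-bit range.

Two parametric silhouette classes are rendered:

* **mosquito** — a slender body ellipse (60x8 px at scale 1) with six thin
  one-pixel legs and two narrow wing ellipses;
* **bee** — a compact thick body ellipse (44x28 px) with a round head.

The classes are built so the contour descriptors the classifier uses
(perimeter/area, perimeter^2/area) separate them by construction, the same
way the real insects' processed masks differ.  The generator does not
emulate motion blur, partial occlusion, specular glints, or non-insect
debris; detection/classification results on these scenes bound what the
pipeline can do on clean trap frames, not on arbitrary field imagery.

Every scene is a pure function of its spec (including the seed): identical
specs produce bit-identical images and annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse, line

from .errors import SceneError

#: Nominal frame and template sizes of the trap camera setup.
DEFAULT_FRAME = (1280, 960)     # (width, height)
DEFAULT_TEMPLATE = (200, 144)   # (width, height)

#: Default photometric conditions: dark-cloth background, top illumination
#: gradient, bright insects, mild sensor noise (8-bit intensity units).
DEFAULT_BACKGROUND = 30.0
DEFAULT_GRADIENT = 40.0
DEFAULT_NOISE_SIGMA = 5.0
DEFAULT_CONTRAST = 140.0

#: Mosquito fraction used when sampling mixed benchmarks (the trap study's
#: own image mix was 71 mosquitoes to 51 bees).
DEFAULT_MIX = 71 / 122


@dataclass
class InsectSpec:
    """One insect to render: species, placement, pose and contrast."""

    species: str                      # "mosquito" | "bee"
    center: tuple[float, float]       # (x, y) in scene pixels
    orientation: float = 0.0          # degrees, counter-clockwise
    scale: float = 1.0
    intensity_contrast: float = DEFAULT_CONTRAST  # delta vs. background; may be < 0
    allow_edge: bool = False          # permit a silhouette straddling the frame


@dataclass
class SceneSpec:
    """A full scene: frame geometry, photometry, insects and the RNG seed."""

    width: int = DEFAULT_FRAME[0]
    height: int = DEFAULT_FRAME[1]
    background_intensity: float = DEFAULT_BACKGROUND
    illumination_gradient: float = DEFAULT_GRADIENT
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    insects: list[InsectSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class Annotation:
    """Ground truth for one rendered insect."""

    species: str
    center_x: float
    center_y: float
    bbox: tuple[int, int, int, int]   # (x0, y0, x1, y1), exclusive upper bounds

    def to_dict(self) -> dict:
        return {"species": self.species, "center_x": self.center_x,
                "center_y": self.center_y, "bbox": list(self.bbox)}

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        return cls(d["species"], d["center_x"], d["center_y"], tuple(d["bbox"]))


def _mosquito_mask(scale: float) -> np.ndarray:
    """Axis-aligned mosquito silhouette on a local canvas, body along x."""
    half = max(int(round(48 * scale)), 8)
    n = 2 * half + 1
    m = np.zeros((n, n), dtype=bool)
    c = half
    rr, cc = ellipse(c, c, max(4 * scale, 1.5), max(30 * scale, 3), shape=m.shape)
    m[rr, cc] = True
    for dy, rot in ((-6, 0.35), (6, -0.35)):  # two narrow wings
        rr, cc = ellipse(c + dy * scale, c - 3 * scale,
                         max(4 * scale, 1.2), max(16 * scale, 2),
                         shape=m.shape, rotation=rot)
        m[rr, cc] = True
    leg_len = 30 * scale
    for ax in (-14, 0, 14):  # three leg pairs
        for side in (-1, 1):
            for ang in (55.0,):
                x0 = int(round(c + ax * scale))
                y0 = int(round(c + side * 3 * scale))
                x1 = int(round(x0 + leg_len * np.cos(np.deg2rad(ang)) * np.sign(ax + 7)))
                y1 = int(round(y0 + side * leg_len * np.sin(np.deg2rad(ang))))
                x1 = int(np.clip(x1, 0, n - 1))
                y1 = int(np.clip(y1, 0, n - 1))
                rr, cc = line(y0, x0, y1, x1)
                m[rr, cc] = True
    return m


def _bee_mask(scale: float) -> np.ndarray:
    """Axis-aligned bee silhouette: compact body ellipse plus round head."""
    half = max(int(round(36 * scale)), 8)
    n = 2 * half + 1
    m = np.zeros((n, n), dtype=bool)
    c = half
    rr, cc = ellipse(c, c, max(14 * scale, 3), max(22 * scale, 4), shape=m.shape)
    m[rr, cc] = True
    rr, cc = disk((c, c + 26 * scale), max(7 * scale, 2), shape=m.shape)
    m[rr, cc] = True
    return m


def insect_mask(species: str, scale: float = 1.0, orientation: float = 0.0) -> np.ndarray:
    """Boolean silhouette of one insect, rotated to ``orientation`` degrees."""
    if species == "mosquito":
        m = _mosquito_mask(scale)
    elif species == "bee":
        m = _bee_mask(scale)
    else:
        raise SceneError(f"unknown species {species!r}")
    if orientation % 360.0:
        m = ndimage.rotate(m.astype(np.uint8), orientation,
                           reshape=True, order=0).astype(bool)
    ys, xs = np.nonzero(m)
    return m[ys.min():ys.max() + 1, xs.min():xs.max() + 1]


def _background(spec: SceneSpec) -> np.ndarray:
    rows = np.arange(spec.height, dtype=np.float64)
    denom = max(spec.height - 1, 1)
    column = spec.background_intensity + spec.illumination_gradient * (1.0 - rows / denom)
    return np.repeat(column[:, None], spec.width, axis=1)


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, list[Annotation]]:
    """Render a scene and its ground truth.

    Returns the image as float64 in [0, 255] (what an 8-bit capture would
    quantize) and one :class:`Annotation` per insect.  Raises
    :class:`SceneError` if a silhouette extends beyond the frame without
    ``allow_edge``.
    """
    img = _background(spec)
    annotations: list[Annotation] = []
    for insect in spec.insects:
        mask = insect_mask(insect.species, insect.scale, insect.orientation)
        mh, mw = mask.shape
        cx, cy = insect.center
        x0 = int(round(cx)) - mw // 2
        y0 = int(round(cy)) - mh // 2
        inside = (x0 >= 0 and y0 >= 0 and
                  x0 + mw <= spec.width and y0 + mh <= spec.height)
        if not inside and not insect.allow_edge:
            raise SceneError(
                f"{insect.species} at ({cx}, {cy}) extends outside the "
                f"{spec.width}x{spec.height} frame; set allow_edge to permit it"
            )
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x0 + mw, spec.width), min(y0 + mh, spec.height)
        if sx1 <= sx0 or sy1 <= sy0:
            raise SceneError(f"{insect.species} at ({cx}, {cy}) lies fully outside the frame")
        sub = mask[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0]
        region = img[sy0:sy1, sx0:sx1]
        region[sub] += insect.intensity_contrast
        ys, xs = np.nonzero(sub)
        annotations.append(Annotation(
            species=insect.species, center_x=float(cx), center_y=float(cy),
            bbox=(sx0 + int(xs.min()), sy0 + int(ys.min()),
                  sx0 + int(xs.max()) + 1, sy0 + int(ys.max()) + 1),
        ))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img += rng.normal(0.0, spec.noise_sigma, img.shape)
    return np.clip(img, 0.0, 255.0), annotations


def make_template(
    spec: InsectSpec | None = None,
    template_size: tuple[int, int] = DEFAULT_TEMPLATE,
) -> np.ndarray:
    """Render the matching template: a canonical mosquito centered in frame.

    The silhouette is drawn noise-free on a uniform background at the scene's
    mid-gradient intensity, mimicking a template cut out of a clean capture.
    """
    tw, th = template_size
    spec = spec or InsectSpec("mosquito", center=(0, 0))
    bg = DEFAULT_BACKGROUND + DEFAULT_GRADIENT / 2.0
    img = np.full((th, tw), bg, dtype=np.float64)
    mask = insect_mask(spec.species, spec.scale, spec.orientation)
    mh, mw = mask.shape
    if mh > th or mw > tw:
        raise SceneError(f"insect ({mw}x{mh}) does not fit the {tw}x{th} template frame")
    y0, x0 = (th - mh) // 2, (tw - mw) // 2
    img[y0:y0 + mh, x0:x0 + mw][mask] += spec.intensity_contrast
    return np.clip(img, 0.0, 255.0)


def _sample_insects(
    rng: np.random.Generator,
    k: int,
    mix: float,
    width: int,
    height: int,
    insect_scale: float,
    template_size: tuple[int, int],
    difficulty: str,
    contrast: float,
) -> list[InsectSpec]:
    tw, th = template_size
    diag = float(np.hypot(tw, th))
    margin_x, margin_y = tw // 2 + 8, th // 2 + 8
    insects: list[InsectSpec] = []
    centers: list[tuple[float, float]] = []

    def sample_interior() -> tuple[float, float]:
        for _ in range(200):
            x = float(rng.uniform(margin_x, width - margin_x))
            y = float(rng.uniform(margin_y, height - margin_y))
            if all(np.hypot(x - px, y - py) >= diag for px, py in centers):
                return x, y
        raise SceneError("could not place insects with the required separation")

    for i in range(k):
        species = "mosquito" if rng.uniform() < mix else "bee"
        scale = insect_scale * float(rng.uniform(0.9, 1.1))
        orientation = float(rng.uniform(0.0, 360.0))
        if difficulty == "edge-cases" and i == 0:
            side = int(rng.integers(4))
            d = float(rng.uniform(5, 25)) * insect_scale
            if side == 0:
                x, y = d, float(rng.uniform(margin_y, height - margin_y))
            elif side == 1:
                x, y = width - d, float(rng.uniform(margin_y, height - margin_y))
            elif side == 2:
                x, y = float(rng.uniform(margin_x, width - margin_x)), d
            else:
                x, y = float(rng.uniform(margin_x, width - margin_x)), height - d
            insects.append(InsectSpec(species, (x, y), orientation, scale,
                                      contrast, allow_edge=True))
        else:
            x, y = sample_interior()
            insects.append(InsectSpec(species, (x, y), orientation, scale, contrast))
        centers.append((x, y))
    return insects


def make_benchmark(
    n_scenes: int,
    mix: float = DEFAULT_MIX,
    difficulty: str = "easy",
    seed: int = 0,
    width: int = DEFAULT_FRAME[0],
    height: int = DEFAULT_FRAME[1],
    insect_scale: float = 1.0,
    template_size: tuple[int, int] = DEFAULT_TEMPLATE,
    insects_per_scene: tuple[int, int] = (1, 3),
    out_dir: str | Path | None = None,
) -> list[tuple[np.ndarray, list[Annotation]]]:
    """Generate a seeded batch of annotated scenes.

    ``difficulty`` selects the regime: ``"easy"`` places every insect in the
    interior with center separation at least the template diagonal;
    ``"edge-cases"`` makes the first insect of every scene straddle a frame
    border; ``"noisy"`` uses easy placement with noise sigma 12 and contrast
    90.  ``mix`` is the mosquito fraction.  With ``out_dir`` set, scenes are
    also written as PNG plus a ``manifest.json`` of the annotations.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    if difficulty not in ("easy", "edge-cases", "noisy"):
        raise ValueError(f"unknown difficulty {difficulty!r}")
    noise = 12.0 if difficulty == "noisy" else DEFAULT_NOISE_SIGMA
    contrast = 90.0 if difficulty == "noisy" else DEFAULT_CONTRAST
    rng = np.random.default_rng(seed)
    scenes: list[tuple[np.ndarray, list[Annotation]]] = []
    for _ in range(n_scenes):
        k = int(rng.integers(insects_per_scene[0], insects_per_scene[1] + 1))
        insects = _sample_insects(rng, k, mix, width, height, insect_scale,
                                  template_size, difficulty, contrast)
        spec = SceneSpec(width=width, height=height, noise_sigma=noise,
                         insects=insects, seed=int(rng.integers(2 ** 31)))
        scenes.append(render_scene(spec))
    if out_dir is not None:
        write_benchmark(scenes, out_dir)
    return scenes


def write_benchmark(
    scenes: list[tuple[np.ndarray, list[Annotation]]],
    out_dir: str | Path,
) -> Path:
    """Write scenes as 8-bit PNGs plus a JSON manifest; returns manifest path."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (img, anns) in enumerate(scenes):
        name = f"scene_{i:04d}.png"
        iio.imwrite(out / name, np.round(img).astype(np.uint8))
        manifest.append({"image": name, "insects": [a.to_dict() for a in anns]})
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def read_manifest(path: str | Path) -> list[dict]:
    """Load a benchmark manifest; annotations become :class:`Annotation`."""
    records = json.loads(Path(path).read_text())
    return [
        {"image": r["image"],
         "insects": [Annotation.from_dict(a) for a in r["insects"]]}
        for r in records
    ]
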