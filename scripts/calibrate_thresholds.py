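"""Reproduce the default classification thresholds theta1, theta2.

Renders 100 mosquitoes and 100 bees at the generator's default parameters
(scale jitter 0.9-1.1, random orientation, default photometry), pushes each
through the ROI shape pipeline, and prints the midpoint between the
per-class mean ratio1 (perimeter/area) and ratio2 (perimeter^2/area).
These midpoints are the packaged defaults in default_config.toml.

Usage: python scripts/calibrate_thresholds.py [--seed 42]
"""

import argparse

import numpy as np

from trapmatch.classification import roi_pipeline_stages, shape_features
from trapmatch.synthetic_scenes import InsectSpec, SceneSpec, render_scene


def class_features(species: str, n: int, rng: np.random.Generator) -> np.ndarray:
    out = []
    for _ in range(n):
        spec = SceneSpec(
            width=200, height=144,
            insects=[InsectSpec(species, (100, 72),
                                orientation=float(rng.uniform(0, 360)),
                                scale=float(rng.uniform(0.9, 1.1)))],
            seed=int(rng.integers(2 ** 31)),
        )
        img, _ = render_scene(spec)
        f = shape_features(roi_pipeline_stages(img)["contour"])
        out.append((f.ratio1, f.ratio2))
    return np.asarray(out)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n", type=int, default=100, help="samples per class")
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    mosq = class_features("mosquito", args.n, rng)
    bee = class_features("bee", args.n, rng)
    for name, col in (("ratio1", 0), ("ratio2", 1)):
        m, b = mosq[:, col], bee[:, col]
        print(f"{name}: mosquito mean {m.mean():.4f} [{m.min():.4f}, {m.max():.4f}]  "
              f"bee mean {b.mean():.4f} [{b.min():.4f}, {b.max():.4f}]  "
              f"midpoint {(m.mean() + b.mean()) / 2:.4f}")


if __name__ == "__main__":
    main()
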