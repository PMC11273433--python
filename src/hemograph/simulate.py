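"""Synthetic two-class blood-smear image generator.

The clinical smear dataset behind this pipeline is private, so this module
produces a stand-in: pale-background images containing dark elliptical
"nuclei" whose count, size, boundary irregularity and intensity differ
between the two classes, mimicking the morphological axes an oncologist uses
to tell lymphoblasts (ALL: many, small, round, dark) from myeloblasts
(AML: fewer, larger, irregular, paler). A single ``separation`` knob in
[0, 1] interpolates both classes between identical generative parameters
(separation 0) and the full configured gap (separation 1).

All randomness flows through numpy Generators seeded from a master seed, so
datasets are bit-reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import polygon as _draw_polygon

from .preprocess import ImageSample

#: Per-class morphology defaults. Values are simulator parameters, not
#: measurements of real cells.
DEFAULT_CLASS_MORPHOLOGY = {
    "ALL": {
        "n_cells_mean": 10.0,
        "cell_radius_mean": 9.0,
        "cell_irregularity": 0.06,
        "nucleus_intensity": 0.15,
    },
    "AML": {
        "n_cells_mean": 4.0,
        "cell_radius_mean": 30.0,
        "cell_irregularity": 0.5,
        "nucleus_intensity": 0.25,
    },
}


@dataclass
class SimParams:
    """Generative parameters for the synthetic smear simulator.

    ``separation`` scales every between-class parameter gap about its
    midpoint: 0 makes the classes statistically identical, 1 applies the
    full configured difference.
    """

    side: int = 226
    background_intensity: float = 0.92
    texture_noise_sd: float = 0.03
    separation: float = 1.0
    class_morphology: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_CLASS_MORPHOLOGY.items()
        }
    )
    seed: int = 0

    def effective_morphology(self, label: str) -> dict:
        """Class parameters after applying the separation scaling."""
        if label not in self.class_morphology:
            raise ValueError(f"unknown class label {label!r}")
        keys = self.class_morphology[label].keys()
        out = {}
        for key in keys:
            vals = [self.class_morphology[c][key] for c in self.class_morphology]
            mid = float(np.mean(vals))
            v = self.class_morphology[label][key]
            out[key] = mid + self.separation * (v - mid)
        return out


def _blob_mask(
    side: int,
    center: tuple[float, float],
    radius: float,
    irregularity: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one elliptical nucleus with a smoothly perturbed
    boundary (low-order Fourier modes of amplitude ``irregularity``)."""
    n_vert = 64
    theta = np.linspace(0.0, 2 * np.pi, n_vert, endpoint=False)
    aspect = rng.uniform(0.75, 1.0)
    rot = rng.uniform(0.0, np.pi)
    # radial perturbation: 3 random low-frequency harmonics
    r_mod = np.ones(n_vert)
    for harmonic in (2, 3, 5):
        amp = irregularity * rng.uniform(0.2, 0.5)
        r_mod += amp * np.sin(harmonic * theta + rng.uniform(0, 2 * np.pi))
    # cap the outward bulge so nuclei stay within their placement envelope
    r_mod = np.clip(r_mod, 0.3, 1.0 + 0.6 * irregularity)
    rr = radius * r_mod * np.sin(theta) * aspect
    cc = radius * r_mod * np.cos(theta)
    rows = center[0] + rr * np.cos(rot) - cc * np.sin(rot)
    cols = center[1] + rr * np.sin(rot) + cc * np.cos(rot)
    return _draw_polygon(rows, cols, shape=(side, side))


def generate_image(
    label: str, params: SimParams, seed: int | None = None
) -> ImageSample:
    """Draw one synthetic smear image of the requested class.

    Background at ``background_intensity`` plus Gaussian texture noise; a
    Poisson-distributed number of nuclei placed by rejection sampling so no
    two fully overlap; values clipped to [0, 1].
    """
    if params.side < 32:
        raise ValueError(f"side must be >= 32, got {params.side}")
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    morph = params.effective_morphology(label)
    side = params.side

    img = np.full((side, side), params.background_intensity, dtype=float)
    if params.texture_noise_sd > 0:
        img += rng.normal(0.0, params.texture_noise_sd, size=img.shape)

    n_cells = int(rng.poisson(morph["n_cells_mean"]))
    # keep centers inside the frame, but never demand more margin than the
    # raster can give (large nuclei on small rasters are clipped at edges)
    margin = min(morph["cell_radius_mean"] + 2, side / 2 - 2)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    placed = 0
    attempts = 0
    while placed < n_cells and attempts < 500 * max(n_cells, 1):
        attempts += 1
        c = (
            rng.uniform(margin, side - margin),
            rng.uniform(margin, side - margin),
        )
        r = morph["cell_radius_mean"] * rng.uniform(0.8, 1.2)
        # keep the bulge envelopes disjoint so nuclei stay countable
        r_env = r * (1.0 + 0.6 * morph["cell_irregularity"])
        if any(
            np.hypot(c[0] - c0, c[1] - c0c) < 1.02 * (r_env + r0)
            for (c0, c0c), r0 in zip(centers, radii)
        ):
            continue
        rr, cc = _blob_mask(side, c, r, morph["cell_irregularity"], rng)
        depth = morph["nucleus_intensity"] + rng.normal(0.0, 0.02)
        img[rr, cc] = depth + rng.normal(
            0.0, params.texture_noise_sd, size=rr.shape
        )
        centers.append(c)
        radii.append(r_env)
        placed += 1

    np.clip(img, 0.0, 1.0, out=img)
    return ImageSample(
        pixels=img,
        label=label,
        source_id=f"sim-{label}-{seed}",
        meta={"n_cells": placed},
    )


def generate_dataset(
    n_per_class: int,
    params: SimParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[ImageSample]:
    """Generate a balanced labeled dataset (and optionally write PNGs + a
    ``path,label`` manifest CSV under ``out_dir``).

    Per-image seeds are derived deterministically from the master seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if params is None:
        params = SimParams()
    ss = np.random.SeedSequence(seed)
    labels = sorted(params.class_morphology)
    child_seeds = ss.generate_state(len(labels) * n_per_class)
    samples: list[ImageSample] = []
    idx = 0
    for label in labels:
        for _ in range(n_per_class):
            child = int(child_seeds[idx]) % (2**31)
            samples.append(generate_image(label, params, seed=child))
            idx += 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(samples):
            name = f"{s.label}_{i:04d}.png"
            arr8 = np.round(s.pixels * 255).astype(np.uint8)
            Image.fromarray(arr8, mode="L").save(out_dir / name)
            rows.append((name, s.label))
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["path", "label"])
            writer.writerows(rows)
    return samples
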