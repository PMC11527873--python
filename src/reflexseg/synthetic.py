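"""Seeded generator of eye-like scenes with tiny bright reflex targets.

The clinical regime this emulates: a corneal light reflex occupying on the
order of 17 pixels of a 512x512 eye crop — about 0.0066% of the image —
surrounded by iris, sclera, eyelid skin and sensor noise.  Rendering is
parametric (skin background, elliptical palpebral opening, iris and pupil
disks, optional upper-lid droop, one anti-aliased bright reflex disk), not
photorealistic: the point is controllable difficulty (target area,
contrast, occlusion) with exact ground truth, so that every other module
is testable without any clinical data.

Determinism: each sample is a pure function of ``(seed, index)`` — the
random stream is keyed, not shared — so datasets are reproducible and
samples independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


class GenerationError(RuntimeError):
    """Raised when no feasible scene exists for the drawn parameters."""


@dataclass(frozen=True)
class SceneParams:
    """Distributional parameters of the synthetic scenes.

    Lengths are in pixels at ``image_size``; intensities in [0, 1].  The
    default reflex radius range (1.6, 3.0) yields disk areas of roughly
    8-30 px with a mean near 17 px at size 512, matching the clinical
    foreground statistic of ~0.0066% of the image.
    """

    image_size: int = 512
    iris_radius_range: tuple[float, float] | None = None  # default 0.11-0.165 * size
    iris_center_jitter: float = 10.0
    reflex_radius_range: tuple[float, float] = (1.6, 3.0)
    reflex_intensity: float = 0.97
    eyelid_droop_range: tuple[float, float] = (0.0, 0.35)
    background_noise_sigma: float = 0.02
    skin_tone: tuple[float, float, float] = (0.80, 0.62, 0.52)
    sclera_tone: tuple[float, float, float] = (0.93, 0.91, 0.89)
    iris_tone: tuple[float, float, float] = (0.36, 0.26, 0.18)
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.reflex_radius_range
        if not 0.75 <= lo <= hi:
            raise ValueError("reflex radii must satisfy 0.75 <= lo <= hi "
                             "(smaller disks can rasterise to an empty mask)")
        if hi >= min(self.iris_radii):
            raise ValueError("reflex radius must be smaller than iris radius")
        dlo, dhi = self.eyelid_droop_range
        if not 0.0 <= dlo <= dhi:
            raise ValueError("invalid eyelid_droop_range")

    @property
    def iris_radii(self) -> tuple[float, float]:
        if self.iris_radius_range is not None:
            return self.iris_radius_range
        return (0.11 * self.image_size, 0.165 * self.image_size)

    def expected_mask_area(self) -> float:
        """Mean rasterised reflex area, E[pi r^2] for r ~ U(lo, hi)."""
        lo, hi = self.reflex_radius_range
        return math.pi * (lo * lo + lo * hi + hi * hi) / 3.0

    def max_mask_area(self) -> float:
        """Upper bound on a single mask's area (anti-aliasing slack 0.5 px)."""
        return math.pi * (self.reflex_radius_range[1] + 0.5) ** 2 + 4.0


@dataclass
class Sample:
    """One rendered scene: image, exact reflex mask, drawn parameters."""

    image: np.ndarray       # (S, S, 3) float32 in [0, 1]
    mask: np.ndarray        # (S, S) uint8 in {0, 1}
    metadata: dict = field(default_factory=dict)


def _disk_coverage(shape: tuple[int, int], cx: float, cy: float,
                   r: float) -> np.ndarray:
    """Approximate pixel coverage of a disk: clip(r + 0.5 - dist, 0, 1)."""
    h, w = shape
    y0, y1 = max(0, int(cy - r - 2)), min(h, int(cy + r + 3))
    x0, x1 = max(0, int(cx - r - 2)), min(w, int(cx + r + 3))
    cov = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    cov[y0:y1, x0:x1] = np.clip(r + 0.5 - dist, 0.0, 1.0)
    return cov


def generate_sample(params: SceneParams, index: int,
                    max_retries: int = 20) -> Sample:
    """Render one scene; a pure function of ``(params.seed, index)``."""
    rng = np.random.default_rng([params.seed, index])
    s = params.image_size
    last_err = "no attempt made"
    for _ in range(max_retries):
        sample = _try_render(params, rng, s)
        if isinstance(sample, Sample):
            sample.metadata["index"] = index
            sample.metadata["seed"] = params.seed
            return sample
        last_err = sample
    raise GenerationError(
        f"no feasible scene after {max_retries} retries: {last_err}")


def _try_render(params: SceneParams, rng: np.random.Generator,
                s: int) -> Sample | str:
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)

    # skin background with a gentle vertical shading gradient
    tone = np.asarray(params.skin_tone, np.float32) \
        * rng.uniform(0.92, 1.05)
    image = np.empty((s, s, 3), np.float32)
    grad = (0.95 + 0.1 * yy / s)[..., None]
    image[:] = np.clip(tone[None, None, :] * grad, 0, 1)

    # elliptical palpebral opening filled with sclera
    ocx = s / 2 + rng.uniform(-0.04, 0.04) * s
    ocy = s / 2 + rng.uniform(-0.04, 0.04) * s
    ax = rng.uniform(0.28, 0.38) * s
    ay = rng.uniform(0.15, 0.21) * s
    opening = ((xx - ocx) / ax) ** 2 + ((yy - ocy) / ay) ** 2 <= 1.0
    sclera = np.asarray(params.sclera_tone, np.float32) \
        * rng.uniform(0.96, 1.02)
    image[opening] = sclera

    # iris and pupil disks
    ir = rng.uniform(*params.iris_radii)
    icx = ocx + rng.uniform(-1, 1) * params.iris_center_jitter
    icy = ocy + rng.uniform(-1, 1) * params.iris_center_jitter
    dist_iris = np.hypot(yy - icy, xx - icx)
    iris_region = (dist_iris <= ir) & opening
    itone = np.asarray(params.iris_tone, np.float32) * rng.uniform(0.85, 1.15)
    image[iris_region] = np.clip(itone, 0, 1)
    pupil_region = (dist_iris <= 0.45 * ir) & opening
    image[pupil_region] = np.asarray((0.08, 0.07, 0.07), np.float32)

    # upper-lid droop: skin covers everything above the lid line, which
    # sits `droop` of the iris diameter below the iris top
    droop = rng.uniform(*params.eyelid_droop_range)
    y_lid = icy - ir + droop * 2.0 * ir
    lid_rows = yy < y_lid
    image[lid_rows] = np.clip(tone[None, :] * grad[lid_rows], 0, 1)
    visible_iris = iris_region & ~lid_rows

    # one bright reflex disk inside the visible iris, clear of the lid
    r = rng.uniform(*params.reflex_radius_range)
    margin = r + 1.5
    placed = False
    for _ in range(30):
        rcx = icx + rng.uniform(-0.5, 0.5) * ir
        rcy = icy + rng.uniform(-0.5, 0.5) * ir
        if np.hypot(rcx - icx, rcy - icy) > ir - margin:
            continue
        if rcy - r - 1.0 < y_lid:
            continue
        if ((rcx - ocx) / ax) ** 2 + ((rcy - ocy) / ay) ** 2 > 0.85:
            continue
        placed = True
        break
    if not placed:
        return (f"reflex does not fit (droop={droop:.2f}, "
                f"iris_radius={ir:.1f})")

    cov = _disk_coverage((s, s), rcx, rcy, r)
    glint = params.reflex_intensity
    image = image * (1.0 - cov[..., None]) + glint * cov[..., None]
    mask = (cov >= 0.5).astype(np.uint8)
    if mask.sum() < 1:
        return "reflex rasterised to an empty mask"

    if params.background_noise_sigma > 0:
        image = image + rng.normal(
            0.0, params.background_noise_sigma, image.shape).astype(np.float32)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)

    meta = {"reflex_radius": r, "reflex_cx": rcx, "reflex_cy": rcy,
            "mask_area": int(mask.sum()), "iris_radius": ir,
            "iris_cx": icx, "iris_cy": icy, "droop": droop,
            "lid_y": y_lid}
    return Sample(image=image, mask=mask, metadata=meta)


def generate_dataset(params: SceneParams, n: int
                     ) -> tuple[list[Sample], pd.DataFrame]:
    """Generate ``n`` independent samples plus a per-sample manifest."""
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = [generate_sample(params, i) for i in range(n)]
    manifest = pd.DataFrame([s.metadata for s in samples])
    return samples, manifest


def save_dataset(samples: list[Sample], manifest: pd.DataFrame,
                 out_dir: str | Path) -> None:
    """Write ``images/NNNN.png``, ``masks/NNNN.png`` and ``manifest.csv``."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        img8 = (s.image * 255.0 + 0.5).astype(np.uint8)
        Image.fromarray(img8).save(out / "images" / f"{i:04d}.png")
        Image.fromarray(s.mask * 255).save(out / "masks" / f"{i:04d}.png")
    manifest.to_csv(out / "manifest.csv", index=False)


def foreground_fraction(mean_area: float, image_size: int) -> float:
    """Mean foreground area as a percentage of the image, to 2 s.f.

    ``foreground_fraction(17.27, 512)`` gives 0.0066 (percent).
    """
    if mean_area <= 0 or image_size <= 0:
        raise ValueError("inputs must be positive")
    pct = 100.0 * mean_area / float(image_size * image_size)
    ndigits = 1 - int(math.floor(math.log10(abs(pct))))
    return round(pct, ndigits)


__all__ = ["SceneParams", "Sample", "GenerationError", "generate_sample",
           "generate_dataset", "save_dataset", "foreground_fraction"]
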