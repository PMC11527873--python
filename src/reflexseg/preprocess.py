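"""Deterministic preprocessing of facial photographs into network inputs.

The fixed chain mirrors the clinical acquisition protocol: a 1200x797
photograph is cut in half (one eye per half, removing eye interdependence),
cropped by fixed offsets (200 px off the top, 450 px off the right),
resized preserving aspect ratio so the longer side is 512, zero-padded to
512x512 at the top-left anchor, and scaled to [0, 1].  Every step is
recorded in a :class:`PreprocessRecord` so predicted masks can be mapped
back to original pixel coordinates.

Conventions: arrays are indexed (row, col) with the origin top-left;
"1200 x 797" reads width x height.  Right-eye halves are mirrored
horizontally before cropping (configurable) so a single crop box serves
both sides.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

TARGET_SIZE = 512
DEFAULT_CROP_TOP = 200
DEFAULT_CROP_RIGHT = 450


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    crop_top: int = DEFAULT_CROP_TOP
    crop_right: int = DEFAULT_CROP_RIGHT
    target_size: int = TARGET_SIZE
    mirror_right_eye: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**data)


@dataclass(frozen=True)
class RawPhotograph:
    """An RGB photograph with integer intensities in [0, 255]."""

    pixels: np.ndarray

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise PreprocessError(f"expected HxWx3 pixels, got shape {p.shape}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise PreprocessError("image must be non-empty")
        if p.min() < 0 or p.max() > 255:
            raise PreprocessError("intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class EyeHalf:
    """One half of a photograph; ``origin_x`` locates it in the raw frame."""

    pixels: np.ndarray
    side: str  # "left" | "right"
    origin_x: int
    mirrored: bool = False

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise PreprocessError(f"side must be 'left' or 'right', got {self.side!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PreprocessRecord:
    """Bookkeeping for inverting the preprocessing chain, per image."""

    crop_top: int
    crop_right: int
    scale: float
    pad_right: int
    pad_bottom: int
    side: str
    origin_x: int
    raw_width: int
    raw_height: int
    half_width: int
    half_height: int
    content_width: int
    content_height: int
    mirrored: bool
    target_size: int = TARGET_SIZE

    def __post_init__(self):
        if self.scale <= 0:
            raise PreprocessError("scale must be positive")
        if self.pad_right < 0 or self.pad_bottom < 0:
            raise PreprocessError("pads must be nonnegative")


@dataclass(frozen=True)
class ModelInput:
    """A 512x512x3 float image in [0, 1] with zero-valued padding."""

    pixels: np.ndarray

    def __post_init__(self):
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise PreprocessError(f"expected HxWx3, got {p.shape}")
        if p.shape[0] != p.shape[1]:
            raise PreprocessError("model input must be square")
        if p.min() < 0.0 or p.max() > 1.0:
            raise PreprocessError("model input intensities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# individual operations
# ---------------------------------------------------------------------------

def split_halves(photo: RawPhotograph) -> tuple[EyeHalf, EyeHalf]:
    """Cut the photograph into left/right halves of equal width.

    Each half has width floor(W/2); for odd raw widths the centre column
    is dropped so the halves stay symmetric.  The subject's right eye
    appears in the image's left half.
    """
    if photo.width < 2:
        raise PreprocessError("photograph must be at least 2 pixels wide")
    hw = photo.width // 2
    left = EyeHalf(photo.pixels[:, :hw], side="left", origin_x=0)
    right = EyeHalf(photo.pixels[:, photo.width - hw:], side="right",
                    origin_x=photo.width - hw)
    return left, right


def crop_top_right(half: EyeHalf, crop_top: int = DEFAULT_CROP_TOP,
                   crop_right: int = DEFAULT_CROP_RIGHT) -> EyeHalf:
    """Remove ``crop_top`` rows from the top and ``crop_right`` columns
    from the right."""
    if crop_top < 0 or crop_right < 0:
        raise PreprocessError("crop values must be nonnegative")
    if crop_top >= half.height or crop_right >= half.width:
        raise PreprocessError(
            f"crop ({crop_top}, {crop_right}) consumes the whole "
            f"{half.height}x{half.width} half")
    return replace(half, pixels=half.pixels[crop_top:, :half.width - crop_right])


def _pil_resize(arr: np.ndarray, new_h: int, new_w: int,
                nearest: bool) -> np.ndarray:
    mode = Image.Resampling.NEAREST if nearest else Image.Resampling.BILINEAR
    if arr.ndim == 2:
        img = Image.fromarray(arr.astype(np.uint8))
    else:
        img = Image.fromarray(arr.astype(np.uint8), mode="RGB")
    return np.asarray(img.resize((new_w, new_h), mode))


def resize_and_pad(img: np.ndarray, target: int = TARGET_SIZE,
                   ) -> tuple[np.ndarray, dict]:
    """Resize so the longer side equals ``target`` (bilinear, aspect
    preserved), anchor at the top-left, zero-pad the rest, scale to [0, 1].

    Returns the padded float image and a dict with ``scale``, ``pad_right``,
    ``pad_bottom``, ``content_width``, ``content_height``.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise PreprocessError("cannot resize an empty image")
    h, w = img.shape[:2]
    scale = target / float(max(h, w))
    new_h, new_w = int(round(h * scale)), int(round(w * scale))
    content = _pil_resize(img, new_h, new_w, nearest=False)
    out = np.zeros((target, target, 3), dtype=np.float32)
    out[:new_h, :new_w] = content.astype(np.float32) / 255.0
    geometry = {"scale": scale, "pad_right": target - new_w,
                "pad_bottom": target - new_h,
                "content_width": new_w, "content_height": new_h}
    return out, geometry


def preprocess_pipeline(photo: RawPhotograph, side: str,
                        config: PreprocessConfig = PreprocessConfig()
                        ) -> tuple[ModelInput, PreprocessRecord]:
    """split -> (mirror right half) -> crop -> resize/pad, with bookkeeping."""
    left, right = split_halves(photo)
    half = left if side == "left" else right
    mirrored = side == "right" and config.mirror_right_eye
    if mirrored:
        half = replace(half, pixels=half.pixels[:, ::-1], mirrored=True)
    half_h, half_w = half.height, half.width
    cropped = crop_top_right(half, config.crop_top, config.crop_right)
    pixels, geom = resize_and_pad(cropped.pixels, config.target_size)
    record = PreprocessRecord(
        crop_top=config.crop_top, crop_right=config.crop_right,
        scale=geom["scale"], pad_right=geom["pad_right"],
        pad_bottom=geom["pad_bottom"], side=side, origin_x=half.origin_x,
        raw_width=photo.width, raw_height=photo.height,
        half_width=half_w, half_height=half_h,
        content_width=geom["content_width"],
        content_height=geom["content_height"], mirrored=mirrored,
        target_size=config.target_size)
    return ModelInput(pixels), record


def preprocess_mask(mask: np.ndarray, record: PreprocessRecord) -> np.ndarray:
    """Carry a raw-frame binary mask through the same chain as its image
    (nearest-neighbour resize keeps it binary)."""
    mask = _check_binary(mask)
    if mask.shape != (record.raw_height, record.raw_width):
        raise PreprocessError(
            f"mask shape {mask.shape} does not match the raw frame "
            f"({record.raw_height}, {record.raw_width})")
    half = mask[:, record.origin_x:record.origin_x + record.half_width]
    if record.mirrored:
        half = half[:, ::-1]
    cropped = half[record.crop_top:,
                   :record.half_width - record.crop_right]
    content = _pil_resize(cropped * 255, record.content_height,
                          record.content_width, nearest=True)
    out = np.zeros((record.target_size, record.target_size), dtype=np.uint8)
    out[:record.content_height, :record.content_width] = content > 127
    return out


def map_mask_to_original(mask: np.ndarray,
                         record: PreprocessRecord) -> np.ndarray:
    """Map a predicted 512x512 mask back to raw-photograph coordinates.

    Inverse of the pipeline: drop padding, nearest-neighbour resize back to
    the crop box, undo the crop offsets, undo mirroring, and place the half
    at its origin in the raw frame.  Padding pixels map nowhere.
    """
    mask = _check_binary(mask)
    t = record.target_size
    if mask.shape != (t, t):
        raise PreprocessError(
            f"expected a {t}x{t} mask, got shape {mask.shape}")
    content = mask[:record.content_height, :record.content_width]
    crop_h = record.half_height - record.crop_top
    crop_w = record.half_width - record.crop_right
    unresized = _pil_resize(content * 255, crop_h, crop_w, nearest=True) > 127
    half = np.zeros((record.half_height, record.half_width), dtype=np.uint8)
    half[record.crop_top:, :crop_w] = unresized
    if record.mirrored:
        half = half[:, ::-1]
    out = np.zeros((record.raw_height, record.raw_width), dtype=np.uint8)
    out[:, record.origin_x:record.origin_x + record.half_width] = half
    return out


def _check_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise PreprocessError(f"mask must be 2-d, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise PreprocessError("mask must contain only 0 and 1")
    return mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> RawPhotograph:
    """Read a JPEG/PNG photograph as RGB."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"))
    return RawPhotograph(arr)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG, binarised at intensity > 127."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return (arr > 127).astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(_check_binary(mask) * 255).save(path)


def save_record(record: PreprocessRecord, path: str | Path) -> None:
    Path(path).write_text(json.dumps(record.__dict__, indent=2))


def load_record(path: str | Path) -> PreprocessRecord:
    return PreprocessRecord(**json.loads(Path(path).read_text()))


__all__ = [
    "PreprocessConfig", "PreprocessError", "RawPhotograph", "EyeHalf",
    "PreprocessRecord", "ModelInput", "split_halves", "crop_top_right",
    "resize_and_pad", "preprocess_pipeline", "preprocess_mask",
    "map_mask_to_original", "load_image", "load_mask", "save_mask",
    "save_record", "load_record", "TARGET_SIZE", "DEFAULT_CROP_TOP",
    "DEFAULT_CROP_RIGHT",
]
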