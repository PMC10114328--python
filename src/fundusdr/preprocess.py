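"""Standard operating procedure (SOP) for fundus-image preprocessing.

Camera hardware leaves retinal photographs framed in uninformative black
borders and letterboxes. The SOP normalizes geometry and contrast before
grading:

1. auto-crop the black border (clipping mask at a gray tolerance, default 7);
2. re-frame the retina as a centered disc inside a square (circular crop),
   so resizing cannot deform it;
3. gate image quality (see :mod:`fundusdr.quality_gate`);
4. equalize the hue and value histograms in HSV space;
5. resize to the network input side.

Images are plain ``HxWx3`` uint8 numpy arrays throughout ("PixelImage");
grayscale intermediates are ``HxW`` uint8 ("GrayImage").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage import color

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

HSV_CHANNELS = ("hue", "saturation", "value")


@dataclass
class SOPConfig:
    """Knobs of the preprocessing SOP.

    tolerance: gray level at or below which a pixel counts as border (> is
        content); the auto-crop default is 7.
    output_side: side of the final square image fed to the network.
    equalize_channels: which HSV channels to equalize; hue and value by
        default, saturation untouched.
    """

    tolerance: int = 7
    output_side: int = 224
    equalize_channels: tuple[str, ...] = ("hue", "value")

    def __post_init__(self):
        if self.tolerance < 0:
            raise InvalidInputError("tolerance must be >= 0")
        if self.output_side < 8:
            raise InvalidInputError("output_side must be >= 8")
        bad = set(self.equalize_channels) - set(HSV_CHANNELS)
        if bad:
            raise InvalidInputError(f"unknown HSV channels: {sorted(bad)}")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError(f"expected HxWx3 image, got shape {img.shape}")
    return img


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Luma grayscale: round(0.299 R + 0.587 G + 0.114 B), uint8."""
    img = _check_image(img)
    gray = (
        0.299 * img[:, :, 0].astype(np.float64)
        + 0.587 * img[:, :, 1].astype(np.float64)
        + 0.114 * img[:, :, 2].astype(np.float64)
    )
    return np.round(gray).astype(np.uint8)


def build_clip_mask(gray: np.ndarray, tolerance: int = 7) -> np.ndarray:
    """Binary mask: 1 where gray is strictly above tolerance, else 0."""
    if tolerance < 0:
        raise InvalidInputError("tolerance must be >= 0")
    return (np.asarray(gray) > tolerance).astype(np.uint8)


def content_bbox(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """Tightest half-open box (r0, r1, c0, c1) covering all 1s; None if empty."""
    mask = np.asarray(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return None
    return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def autocrop(img: np.ndarray, tolerance: int = 7) -> np.ndarray:
    """Crop the black border: keep the bounding box of above-tolerance gray.

    A fully dark image (empty mask) is returned unchanged with a warning —
    there is nothing informative to crop to.
    """
    img = _check_image(img)
    bbox = content_bbox(build_clip_mask(rgb_to_gray(img), tolerance))
    if bbox is None:
        logger.warning("autocrop: image entirely at or below tolerance; returned as-is")
        return img
    r0, r1, c0, c1 = bbox
    return img[r0:r1, c0:c1]


def resize(img: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize to (height, width)."""
    return np.array(
        Image.fromarray(img).resize((width, height), Image.BILINEAR), dtype=np.uint8
    )


def circular_mask(side: int) -> np.ndarray:
    """Boolean disc of radius side/2 centered in a side x side square.

    A pixel (i, j) is inside iff the distance from its center
    (i + 0.5, j + 0.5) to the square's center (side/2, side/2) is <= side/2.
    """
    c = side / 2.0
    yy = np.arange(side) + 0.5 - c
    xx = np.arange(side) + 0.5 - c
    return (yy[:, None] ** 2 + xx[None, :] ** 2) <= c**2


def circular_crop(img: np.ndarray, tolerance: int = 7) -> np.ndarray:
    """Re-frame the retina as a centered disc inside a square.

    Steps: take L = max(H, W); resize to L x L; zero everything outside the
    inscribed disc of radius L/2; auto-crop the border once more; pad with
    black to square if that crop was asymmetric.
    """
    img = _check_image(img)
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise InvalidInputError("empty image")
    side = max(h, w)
    sq = resize(img, side, side) if (h, w) != (side, side) else img.copy()
    sq[~circular_mask(side)] = 0
    out = autocrop(sq, tolerance)
    oh, ow = out.shape[:2]
    if oh != ow:
        target = max(oh, ow)
        padded = np.zeros((target, target, 3), dtype=np.uint8)
        r = (target - oh) // 2
        c = (target - ow) // 2
        padded[r : r + oh, c : c + ow] = out
        out = padded
    return out


def equalize_channel(channel: np.ndarray) -> np.ndarray:
    """Histogram-equalize one uint8 channel.

    T(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255) with cdf in pixel
    counts and cdf_min the count at the lowest occupied level. A single-level
    channel has N == cdf_min; that level maps to 0 by convention.
    """
    channel = np.asarray(channel, dtype=np.uint8)
    hist = np.bincount(channel.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.argmax(hist > 0)]
    n = channel.size
    if n == cdf_min:
        lut = np.zeros(256, dtype=np.uint8)
    else:
        lut = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0)
        lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[channel]


def equalize_hsv(
    img: np.ndarray, channels: tuple[str, ...] = ("hue", "value")
) -> np.ndarray:
    """Equalize selected HSV channels and convert back to RGB.

    Channels are quantized to a full 0-255 scale before equalization — hue
    included, so behavior does not depend on any 0-179 hue dialect. An empty
    channel selection returns the input bit-identically (no color-space
    round trip).
    """
    img = _check_image(img)
    if not channels:
        return img.copy()
    bad = set(channels) - set(HSV_CHANNELS)
    if bad:
        raise InvalidInputError(f"unknown HSV channels: {sorted(bad)}")
    hsv = color.rgb2hsv(img)  # floats in [0, 1]
    quant = np.round(hsv * 255.0).astype(np.uint8)
    for name in channels:
        idx = HSV_CHANNELS.index(name)
        quant[:, :, idx] = equalize_channel(quant[:, :, idx])
    rgb = color.hsv2rgb(quant.astype(np.float64) / 255.0)
    return np.round(rgb * 255.0).astype(np.uint8)


@dataclass
class SOPResult:
    """Output of the full SOP on one image."""

    image: np.ndarray
    steps: list[str] = field(default_factory=list)
    quality_label: str = "good"
    metrics: dict = field(default_factory=dict)
    rejected: bool = False


def run_sop(img: np.ndarray, cfg: SOPConfig = SOPConfig(), thresholds=None) -> SOPResult:
    """Full preprocessing pipeline on one image.

    Order: auto-crop -> circular crop -> quality gate -> HSV equalization ->
    resize to cfg.output_side. Images gated ``reject`` come back flagged,
    unequalized, so callers can exclude them from datasets while still
    auditing the metrics.
    """
    from .quality_gate import QualityThresholds, assess_quality

    img = _check_image(img)
    steps: list[str] = []
    out = autocrop(img, cfg.tolerance)
    steps.append("autocrop")
    out = circular_crop(out, cfg.tolerance)
    steps.append("circular_crop")
    label, metrics = assess_quality(
        out, thresholds if thresholds is not None else QualityThresholds(),
        tolerance=cfg.tolerance,
    )
    steps.append(f"quality:{label}")
    rejected = label == "reject"
    if not rejected:
        out = equalize_hsv(out, cfg.equalize_channels)
        steps.append("equalize_hsv")
    out = resize(out, cfg.output_side, cfg.output_side)
    steps.append(f"resize:{cfg.output_side}")
    return SOPResult(
        image=out,
        steps=steps,
        quality_label=label,
        metrics=metrics.__dict__.copy(),
        rejected=rejected,
    )
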