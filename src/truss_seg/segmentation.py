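"""Growing-truss extraction from a depth-colormap image.

The chain is classical image processing, tuned to one fact about the data:
in a near-red / far-blue depth colormap of a managed greenhouse row, the
growing truss is the red thing.  Stages:

1. **HSV gate** — keep pixels whose hue/saturation/value fall inside a
   configured interval (hue on the 0-179 scale, S and V on 0-255, the
   byte-scaled convention the gate ranges are written in).  Three named
   presets,
   ``a``/``b``/``c``, are shipped; ``c`` (H 0-30, S 248-255, V 240-255)
   is the production choice.
2. **Otsu binarization** of the luma of the gated image (gated-out pixels
   contribute zeros), thresholding at the 256-level histogram's
   between-class-variance maximum.
3. **Morphological cleanup** — closing to fill small fragments, external
   contours filled, one 3x3 erosion to shave noise, small components
   dropped.

The same chain serves both the real depth camera's colormap and the
learned RGB-to-depth translation's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

__all__ = [
    "HsvRange",
    "SegmentationConfig",
    "HSV_PRESETS",
    "rgb_to_hsv8",
    "hsv_gate",
    "otsu_threshold",
    "morph_clean",
    "segment_truss",
    "segmentation_score",
]


@dataclass(frozen=True)
class HsvRange:
    """Closed HSV intervals; hue 0-179, saturation and value 0-255."""

    h_lo: int
    h_hi: int
    s_lo: int
    s_hi: int
    v_lo: int
    v_hi: int

    def __post_init__(self) -> None:
        for lo, hi, top, name in (
            (self.h_lo, self.h_hi, 179, "h"),
            (self.s_lo, self.s_hi, 255, "s"),
            (self.v_lo, self.v_hi, 255, "v"),
        ):
            if not 0 <= lo <= hi <= top:
                raise ValueError(
                    f"{name} bounds must satisfy 0 <= lo <= hi <= {top}, "
                    f"got ({lo}, {hi})"
                )


#: The three gate candidates evaluated during development; ``c`` won.
HSV_PRESETS: dict[str, HsvRange] = {
    "a": HsvRange(0, 65, 150, 255, 150, 255),
    "b": HsvRange(0, 30, 180, 245, 250, 255),
    "c": HsvRange(0, 30, 248, 255, 240, 255),
}


@dataclass(frozen=True)
class SegmentationConfig:
    """Pipeline knobs.  Defaults are the production settings.

    ``closing_kernel`` is the diameter of the elliptical closing footprint
    (it must exceed the 3x3 erosion for the cleanup to net-fill);
    ``erosion_kernel``/``erosion_iterations`` are fixed by the protocol at
    3x3, one pass.
    """

    hsv_range: HsvRange = field(default_factory=lambda: HSV_PRESETS["c"])
    closing_kernel: int = 5
    erosion_kernel: int = 3
    erosion_iterations: int = 1
    min_component_area: int = 25

    def __post_init__(self) -> None:
        if self.closing_kernel < 1 or self.closing_kernel % 2 == 0:
            raise ValueError("closing_kernel must be odd and >= 1")
        if self.erosion_kernel < 1 or self.erosion_kernel % 2 == 0:
            raise ValueError("erosion_kernel must be odd and >= 1")
        if self.erosion_iterations < 0 or self.min_component_area < 0:
            raise ValueError("erosion_iterations/min_component_area must be >= 0")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an (H, W, 3) uint8 image")
    return image


def rgb_to_hsv8(image: np.ndarray) -> np.ndarray:
    """8-bit RGB to HSV on the uint8 scales (H 0-179, S 0-255, V 0-255).

    Standard hexcone transform with each channel rounded to integers,
    hue halved (so 0-360 degrees fit a byte) and wrapped mod 180.
    """
    image = _check_image(image)
    rgb = image.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = rgb.max(axis=2)
    mn = rgb.min(axis=2)
    diff = mx - mn
    v = mx
    s = np.where(mx > 0, 255.0 * diff / np.where(mx > 0, mx, 1.0), 0.0)
    hdeg = np.zeros_like(mx)
    nz = diff > 0
    safe = np.where(nz, diff, 1.0)
    rmax = nz & (mx == r)
    gmax = nz & ~rmax & (mx == g)
    bmax = nz & ~rmax & ~gmax
    hdeg = np.where(rmax, (60.0 * (g - b) / safe) % 360.0, hdeg)
    hdeg = np.where(gmax, 60.0 * (b - r) / safe + 120.0, hdeg)
    hdeg = np.where(bmax, 60.0 * (r - g) / safe + 240.0, hdeg)
    h = np.round(hdeg / 2.0) % 180
    return np.stack([h, np.round(s), np.round(v)], axis=-1).astype(np.uint8)


def hsv_gate(image: np.ndarray, hsv_range: HsvRange) -> np.ndarray:
    """Boolean mask: true iff the pixel's HSV lies inside all three intervals."""
    hsv = rgb_to_hsv8(image).astype(np.int32)
    r = hsv_range
    return (
        (hsv[..., 0] >= r.h_lo)
        & (hsv[..., 0] <= r.h_hi)
        & (hsv[..., 1] >= r.s_lo)
        & (hsv[..., 1] <= r.s_hi)
        & (hsv[..., 2] >= r.v_lo)
        & (hsv[..., 2] <= r.v_hi)
    )


def otsu_threshold(gray: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's threshold over the 256-level histogram, plus ``gray > t``.

    The returned level maximizes the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2`` of the split ``{<= t} / {> t}``; ties break
    to the lowest level.  A constant image thresholds at its own value, so
    the binary image is the all-background class.
    """
    gray = np.asarray(gray)
    if gray.size == 0:
        raise ValueError("empty image")
    if gray.dtype != np.uint8:
        raise ValueError("expected an 8-bit single-channel image")
    if gray.min() == gray.max():
        t = int(gray.flat[0])
        return t, gray > t
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)
    m0 = np.cumsum(p * levels)
    mt = m0[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mt - m0) / w1
        var_b = w0 * w1 * (mu0 - mu1) ** 2
    var_b = np.nan_to_num(var_b, nan=0.0)
    t = int(np.argmax(var_b))
    return t, gray > t


def _luma8(image: np.ndarray) -> np.ndarray:
    rgb = image.astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.round(y).astype(np.uint8)


def _ellipse_footprint(size: int) -> np.ndarray:
    return skmorph.disk((size - 1) // 2) if size > 1 else np.ones((1, 1), bool)


def morph_clean(mask: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Closing, contour fill, one small erosion, small-object removal.

    Closing (dilate-then-erode with the elliptical ``closing_kernel``
    footprint) bridges the small gaps left by binarization; external
    contours are filled to solid regions; a single 3x3 erosion shaves the
    1-pixel noise rim; connected components below ``min_component_area``
    pixels are discarded.
    """
    if config is None:
        config = SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    out = ndi.binary_closing(
        mask, structure=_ellipse_footprint(config.closing_kernel)
    )
    out = ndi.binary_fill_holes(out)
    if config.erosion_iterations > 0:
        out = ndi.binary_erosion(
            out,
            structure=np.ones((config.erosion_kernel, config.erosion_kernel), bool),
            iterations=config.erosion_iterations,
        )
    if config.min_component_area > 0:
        labels, n = ndi.label(out, structure=np.ones((3, 3), bool))
        if n:
            sizes = np.bincount(labels.ravel())
            keep = sizes >= config.min_component_area
            keep[0] = False
            out = keep[labels]
    return out


def segment_truss(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Full chain: HSV gate -> gated luma -> Otsu -> morphological cleanup.

    ``image`` is any 3-channel 8-bit depth-colormap-like image — the depth
    camera's own colorized view or the learned converter's output; the
    chain is identical for both.
    """
    if config is None:
        config = SegmentationConfig()
    image = _check_image(image)
    gate = hsv_gate(image, config.hsv_range)
    gated = np.where(gate[..., None], image, 0).astype(np.uint8)
    gray = _luma8(gated)
    _, binary = otsu_threshold(gray)
    return morph_clean(binary, config)


def segmentation_score(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Continuous per-pixel truss score: the gated luma the chain thresholds.

    This is the quantity a threshold sweep (ROC analysis) should scan,
    because it is the axis the pipeline itself decides on.
    """
    if config is None:
        config = SegmentationConfig()
    image = _check_image(image)
    gate = hsv_gate(image, config.hsv_range)
    gated = np.where(gate[..., None], image, 0).astype(np.uint8)
    return _luma8(gated).astype(np.float64)
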