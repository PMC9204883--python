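"""Depth-to-colormap rendering.

A consumer depth camera presents its range image through a color table in
which nearby surfaces are warm (red) and distant surfaces cold (blue).  The
growing-truss pipeline exploits exactly that encoding: the truss is the
object nearest the lens, so it is the reddest thing in the frame.

The table here is an explicit 256-entry jet-like ramp,
``red -> yellow -> green -> cyan -> blue``, with index 0 (= ``near``) at pure
red ``(255, 0, 0)`` and index 255 (= ``far``) at pure blue ``(0, 0, 255)``.
Storing it as a concrete array lets tests do exact lookups and lets
:func:`decode_depth_colormap` invert rendering by nearest-entry search.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DEPTH_COLOR_TABLE",
    "render_depth_colormap",
    "decode_depth_colormap",
]


def _build_table() -> np.ndarray:
    """256 RGB entries, piecewise-linear through the four jet anchors."""
    anchors = np.array(
        [
            [255, 0, 0],  # near: red
            [255, 255, 0],  # yellow
            [0, 255, 0],  # green
            [0, 255, 255],  # cyan
            [0, 0, 255],  # far: blue
        ],
        dtype=np.float64,
    )
    # 4 segments of 64 steps each -> indices 0..255, endpoints exact.
    t = np.linspace(0.0, 4.0, 256)
    seg = np.minimum(t.astype(int), 3)
    frac = t - seg
    table = anchors[seg] * (1.0 - frac[:, None]) + anchors[seg + 1] * frac[:, None]
    return np.round(table).astype(np.uint8)


DEPTH_COLOR_TABLE: np.ndarray = _build_table()
DEPTH_COLOR_TABLE.setflags(write=False)


def render_depth_colormap(
    depth: "np.ndarray | DepthMap",
    near: float,
    far: float,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Render a metric depth map as an 8-bit near-red / far-blue color image.

    Depth is clipped to ``[near, far]`` and mapped through
    :data:`DEPTH_COLOR_TABLE`.  Pixels where the sensor failed
    (``valid_mask`` false) are rendered black, mimicking the holes a
    stereo depth camera leaves where it cannot match.

    Parameters
    ----------
    depth
        ``(H, W)`` float array of distances in meters, or a
        :class:`~truss_seg.synthetic.DepthMap` (its ``valid_mask`` is used
        unless one is passed explicitly).
    near, far
        Fixed colorization range in meters; ``near < far`` required.

    Returns
    -------
    ``(H, W, 3)`` uint8 RGB image.
    """
    values = getattr(depth, "values", depth)
    if valid_mask is None:
        valid_mask = getattr(depth, "valid_mask", None)
    values = np.asarray(values, dtype=np.float64)
    if not near < far:
        raise ValueError(f"need near < far, got near={near}, far={far}")
    clipped = np.clip(values, near, far)
    idx = np.round((clipped - near) / (far - near) * 255.0).astype(np.intp)
    out = DEPTH_COLOR_TABLE[idx]
    if valid_mask is not None:
        out = out.copy()
        out[~np.asarray(valid_mask, dtype=bool)] = 0
    return out


def decode_depth_colormap(
    image: np.ndarray, near: float, far: float
) -> tuple[np.ndarray, np.ndarray]:
    """Invert :func:`render_depth_colormap` by nearest-table-entry lookup.

    Returns ``(depth, valid)`` where ``valid`` is false for black
    (sensor-failure) pixels.  Exact on rendered images; on arbitrary images
    it returns the depth of the nearest table color.  Quantization limits
    accuracy to one table step, ``(far - near) / 255``.
    """
    if not near < far:
        raise ValueError(f"need near < far, got near={near}, far={far}")
    img = np.asarray(image, dtype=np.int64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    flat = img.reshape(-1, 3)
    # squared distance to each of the 256 entries; argmin tie-breaks low.
    d2 = (
        (flat[:, None, :].astype(np.int64) - DEPTH_COLOR_TABLE[None, :, :]) ** 2
    ).sum(axis=2)
    idx = d2.argmin(axis=1)
    depth = near + idx / 255.0 * (far - near)
    valid = ~(flat == 0).all(axis=1)
    shape = img.shape[:2]
    return depth.reshape(shape), valid.reshape(shape)
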