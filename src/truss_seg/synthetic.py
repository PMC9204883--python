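"""Synthetic paired RGB / depth / ground-truth greenhouse scenes.

The imaging regime being emulated: a camera rig drives along a tomato row
and photographs the *growing truss* — the young stem-plus-leaves tip of the
plant — which the grower's line works keep nearest the lens (tens of
centimeters away), against a dense, cluttered canopy background a meter or
more behind it.  A stereo depth camera sees the same scene as a metric
range image, conventionally displayed through a near-red / far-blue color
table, so the truss is the red object in the depth colormap.

The generator reproduces exactly the properties the downstream pipeline
exploits, and nothing more:

* the truss is a connected, branching, plant-like silhouette drawn in
  unsaturated greens (so plain RGB color gating cannot find it);
* its depth lies inside a near band, everything else in a far band, with a
  clear gap between the two (the camera-to-gutter geometry of a managed
  greenhouse row);
* the background is cluttered with leaf-like blobs at assorted far depths;
* with some probability a frame simulates a depth-camera defocus failure:
  a contiguous region of the range image becomes invalid, which is the
  real-world failure mode that motivates translating RGB to depth with a
  learned model instead of trusting the sensor.

Ground-truth masks are filled silhouettes (no interior holes), matching
the character of a manually traced polygon ROI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

from .colormap import render_depth_colormap

__all__ = [
    "SceneConfig",
    "DepthMap",
    "SceneTriplet",
    "generate_scene",
    "export_dataset",
    "default_split",
]

# Acquisition-protocol proportion: 276 of 356 collected frames train, 80 test.
_TRAIN_FRAMES = 276
_TOTAL_FRAMES = 356


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic greenhouse imaging regime.

    ``image_size`` may be one square dimension or an ``(height, width)``
    pair (e.g. ``(900, 1600)`` to exercise the aspect-distorting resize
    path of the converter).  Depth ranges are meters; the near band must
    lie entirely below the far band.
    """

    image_size: int | tuple[int, int] = 512
    n_trusses: int = 1
    near_depth_range: tuple[float, float] = (0.4, 0.9)
    far_depth_range: tuple[float, float] = (1.5, 4.0)
    clutter_density: float = 0.35
    defocus_prob: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if min(h, w) < 64:
            raise ValueError(f"image_size must be >= 64 pixels, got {self.shape}")
        for name, (lo, hi) in (
            ("near_depth_range", self.near_depth_range),
            ("far_depth_range", self.far_depth_range),
        ):
            if not 0 < lo < hi:
                raise ValueError(f"{name} must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if not self.near_depth_range[1] < self.far_depth_range[0]:
            raise ValueError(
                "near_depth_range must lie entirely below far_depth_range"
            )
        if not 0.0 <= self.defocus_prob <= 1.0:
            raise ValueError("defocus_prob must be in [0, 1]")
        if not 0.0 <= self.clutter_density <= 1.0:
            raise ValueError("clutter_density must be in [0, 1]")
        if self.n_trusses < 0:
            raise ValueError("n_trusses must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        if isinstance(self.image_size, (tuple, list)):
            h, w = self.image_size
            return int(h), int(w)
        return int(self.image_size), int(self.image_size)

    @property
    def colorize_range(self) -> tuple[float, float]:
        """Fixed colorizer range: nearest expected to farthest expected."""
        return self.near_depth_range[0], self.far_depth_range[1]


@dataclass
class DepthMap:
    """Metric range image: per-pixel distance plus a sensor-validity mask."""

    values: np.ndarray  # (H, W) float64 meters
    valid_mask: np.ndarray  # (H, W) bool, False where the sensor failed

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must share shape")
        if np.any(self.values[self.valid_mask] <= 0):
            raise ValueError("valid depth values must be positive")


@dataclass
class SceneTriplet:
    """One paired observation: RGB frame, range image, truss ground truth."""

    rgb: np.ndarray  # (H, W, 3) uint8
    depth: DepthMap
    truth: np.ndarray  # (H, W) bool
    index: int
    colorize_range: tuple[float, float]

    def __post_init__(self) -> None:
        shp = self.rgb.shape[:2]
        if not (self.depth.values.shape == shp and self.truth.shape == shp):
            raise ValueError("rgb, depth and truth must share dimensions")

    def depth_colormap(self) -> np.ndarray:
        """The scene as the depth camera's color view (invalid -> black)."""
        near, far = self.colorize_range
        return render_depth_colormap(self.depth, near, far)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Low-frequency noise in [-1, 1], for gentle texture/depth variation."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def _stamp_disks(mask: np.ndarray, pts: np.ndarray, radius: int) -> None:
    h, w = mask.shape
    for r, c in pts:
        rr, cc = skdraw.disk((r, c), radius, shape=(h, w))
        mask[rr, cc] = True


def _bezier_points(rng: np.random.Generator, p0, p1, p2, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    return pts


def _draw_truss(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Silhouette of one truss: a curved main stem, side branches, leaf blobs.

    Geometry is proportional to frame size, matching a truss tens of
    centimeters from the lens: stem ~1 cm wide, leaves several cm across.
    """
    h, w = shape
    s = min(h, w)
    mask = np.zeros(shape, dtype=bool)

    top = np.array([rng.uniform(0.05, 0.25) * h, rng.uniform(0.3, 0.7) * w])
    length = rng.uniform(0.4, 0.55) * h
    bottom = top + np.array([length, rng.uniform(-0.12, 0.12) * w])
    ctrl = (top + bottom) / 2 + np.array([0.0, rng.uniform(-0.1, 0.1) * w])
    stem_r = max(1, round(0.011 * s))
    stem_pts = _bezier_points(rng, top, ctrl, bottom, max(40, int(length)))
    _stamp_disks(mask, stem_pts, stem_r)

    branch_ends = []
    for _ in range(rng.integers(3, 6)):
        t0 = rng.uniform(0.15, 0.95)
        start = stem_pts[int(t0 * (len(stem_pts) - 1))]
        ang = rng.uniform(0, 2 * np.pi)
        blen = rng.uniform(0.08, 0.18) * s
        end = start + blen * np.array([np.sin(ang), np.cos(ang)])
        bctrl = (start + end) / 2 + rng.uniform(-0.03, 0.03, size=2) * s
        bpts = _bezier_points(rng, start, bctrl, end, max(10, int(blen)))
        _stamp_disks(mask, bpts, max(1, round(0.007 * s)))
        branch_ends.append(end)

    # leaf blobs: at branch ends plus a few along the stem, heavily
    # overlapping so the silhouette is compact like a leafy truss tip
    anchors = branch_ends + [
        stem_pts[int(rng.uniform(0.2, 1.0) * (len(stem_pts) - 1))]
        for _ in range(rng.integers(3, 6))
    ]
    for r, c in anchors:
        a = rng.uniform(0.05, 0.07) * s
        b = rng.uniform(0.03, 0.045) * s
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(r, c, a, b, shape=shape, rotation=rot)
        mask[rr, cc] = True

    # a manual ROI polygon is a filled outline: close small gaps and fill
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3)), iterations=2)
    mask = ndi.binary_fill_holes(mask)
    return mask


def _add_clutter(
    rng: np.random.Generator,
    rgb: np.ndarray,
    depth: np.ndarray,
    config: SceneConfig,
) -> None:
    """Leaf-like blobs of the far canopy, painted into rgb and depth."""
    h, w = depth.shape
    s = min(h, w)
    mean_area = np.pi * (0.045 * s) ** 2
    n_items = int(round(config.clutter_density * h * w / mean_area))
    flo, fhi = config.far_depth_range
    palette = np.array(
        [[60, 95, 45], [40, 70, 35], [90, 105, 60], [70, 60, 40], [55, 80, 65]],
        dtype=np.float64,
    )
    for _ in range(n_items):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(0.02, 0.07) * s
        b = rng.uniform(0.015, 0.05) * s
        rr, cc = skdraw.ellipse(r0, c0, a, b, shape=(h, w), rotation=rng.uniform(0, np.pi))
        color = palette[rng.integers(len(palette))] * rng.uniform(0.7, 1.3)
        rgb[rr, cc] = np.clip(color + rng.normal(0, 6, size=3), 0, 255)
        depth[rr, cc] = rng.uniform(flo, fhi)


def generate_scene(config: SceneConfig, index: int) -> SceneTriplet:
    """Deterministically generate scene ``index`` under ``config``.

    The same ``(config.rng_seed, index)`` always yields bit-identical
    rasters; different indices are statistically independent draws.
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    rng = np.random.default_rng([config.rng_seed, index])
    h, w = config.shape
    nlo, nhi = config.near_depth_range
    flo, fhi = config.far_depth_range

    # --- background canopy ---
    base_col = np.array([45, 60, 38], dtype=np.float64) * rng.uniform(0.8, 1.2)
    grad = np.linspace(0.85, 1.15, h)[:, None, None]
    rgb = base_col[None, None, :] * grad * (1 + 0.15 * _smooth_field(rng, (h, w), 8)[:, :, None])
    depth = np.full((h, w), rng.uniform(flo + 0.3 * (fhi - flo), fhi))
    depth += 0.15 * (fhi - flo) * _smooth_field(rng, (h, w), 16)
    _add_clutter(rng, rgb, depth, config)
    depth = np.clip(depth, flo, fhi)

    # --- near-camera trusses ---
    truth = np.zeros((h, w), dtype=bool)
    for _ in range(config.n_trusses):
        tmask = _draw_truss(rng, (h, w))
        truth |= tmask
        # unsaturated plant greens with smooth per-pixel variation
        tex = _smooth_field(rng, (h, w), 4)
        col = np.stack(
            [
                60 + 20 * tex + rng.normal(0, 4, (h, w)),
                115 + 30 * tex + rng.normal(0, 4, (h, w)),
                48 + 14 * tex + rng.normal(0, 4, (h, w)),
            ],
            axis=-1,
        )
        rgb[tmask] = np.clip(col, 0, 255)[tmask]
        margin = 0.08 * (nhi - nlo)
        d0 = rng.uniform(nlo + margin, nhi - margin)
        dvar = 0.06 * (nhi - nlo) * _smooth_field(rng, (h, w), 8)
        depth[tmask] = np.clip(d0 + dvar[tmask], nlo, nhi)

    rgb = np.clip(rgb + rng.normal(0, 2.5, rgb.shape), 0, 255).astype(np.uint8)
    valid = np.ones((h, w), dtype=bool)

    # --- depth-camera defocus failure (Bernoulli per frame) ---
    if rng.uniform() < config.defocus_prob:
        r0 = rng.uniform(0.2, 0.8) * h
        c0 = rng.uniform(0.2, 0.8) * w
        rr, cc = skdraw.ellipse(
            r0,
            c0,
            rng.uniform(0.18, 0.32) * h,
            rng.uniform(0.18, 0.32) * w,
            shape=(h, w),
            rotation=rng.uniform(0, np.pi),
        )
        blob = np.zeros((h, w), dtype=bool)
        blob[rr, cc] = True
        valid &= ~blob
        # the sensor reports garbage far-range values in the failed region;
        # true truss geometry is unchanged, the *measurement* is lost
        corrupt = blob & ~truth
        depth[corrupt] = rng.uniform(flo, fhi, size=int(corrupt.sum()))

    return SceneTriplet(
        rgb=rgb,
        depth=DepthMap(values=depth, valid_mask=valid),
        truth=truth,
        index=index,
        colorize_range=config.colorize_range,
    )


def default_split(n_scenes: int) -> tuple[int, int]:
    """Train/test sizes at the acquisition protocol's 276:80 proportion."""
    n_train = round(n_scenes * _TRAIN_FRAMES / _TOTAL_FRAMES)
    return n_train, n_scenes - n_train


def export_dataset(
    config: SceneConfig,
    n_scenes: int,
    out_dir: str | Path,
    n_train: int | None = None,
) -> dict:
    """Write ``n_scenes`` PNG triplets plus a train/test manifest.

    Per scene: ``rgb/<id>.png`` (color frame), ``depthcm/<id>.png`` (depth
    colormap as the camera would display it), ``depth/<id>.png`` (16-bit
    millimeters, 0 = invalid), ``mask/<id>.png`` (0/255 ground truth).
    Returns the manifest, also written to ``manifest.json``.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    if n_train is None:
        n_train, _ = default_split(n_scenes)
    manifest: dict = {"n_scenes": n_scenes, "n_train": n_train, "items": []}
    if n_scenes > 0:
        for sub in ("rgb", "depthcm", "depth", "mask"):
            (out_dir / sub).mkdir(parents=True, exist_ok=True)
    for i in range(n_scenes):
        scene = generate_scene(config, i)
        sid = f"scene_{i:04d}"
        split = "train" if i < n_train else "test"
        paths = {
            "rgb": f"rgb/{sid}.png",
            "depthcm": f"depthcm/{sid}.png",
            "depth": f"depth/{sid}.png",
            "mask": f"mask/{sid}.png",
        }
        try:
            iio.imwrite(out_dir / paths["rgb"], scene.rgb)
            iio.imwrite(out_dir / paths["depthcm"], scene.depth_colormap())
            mm = np.where(
                scene.depth.valid_mask,
                np.round(scene.depth.values * 1000.0),
                0,
            ).astype(np.uint16)
            iio.imwrite(out_dir / paths["depth"], mm)
            iio.imwrite(
                out_dir / paths["mask"], scene.truth.astype(np.uint8) * 255
            )
        except OSError as exc:
            raise OSError(f"failed writing scene {sid} under {out_dir}: {exc}") from exc
        manifest["items"].append({"id": sid, "split": split, "paths": paths})
    if n_scenes > 0:
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
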