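"""End-to-end experiment driver.

Mirrors the full protocol on synthetic data: simulate paired scenes,
train the RGB-to-depth translator on the training split, then on the test
split segment (a) the real depth camera's colormap and (b) the translated
RGB frames with the identical chain, and evaluate both against ground
truth.  A third, baseline path segments the raw RGB frames directly,
quantifying what the translation buys.  Every artifact lands in a
self-describing run directory: the exact config, seeds, per-stage logs,
loss curves, masks, per-image CSVs and a comparison summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cyclegan import (
    CycleGANResults,
    CycleGanState,
    GeneratorConfig,
    TrainConfig,
    convert,
    train,
)
from .evaluation import evaluate_dataset
from .segmentation import SegmentationConfig, segment_truss, segmentation_score, HSV_PRESETS
from .synthetic import SceneConfig, default_split, generate_scene

__all__ = ["ExperimentConfig", "run_experiment", "scan_sequence"]

log = logging.getLogger("truss_seg")


@dataclass(frozen=True)
class ExperimentConfig:
    """One reproducible simulate/train/convert/segment/evaluate run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    gen: GeneratorConfig = field(default_factory=GeneratorConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seg: SegmentationConfig = field(default_factory=SegmentationConfig)
    n_scenes: int = 30
    run_cyclegan: bool = True
    run_depth_direct: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d.pop("version", None)
        scene = d.pop("scene", {})
        if isinstance(scene.get("image_size"), list):
            scene["image_size"] = tuple(scene["image_size"])
        for key in ("near_depth_range", "far_depth_range"):
            if key in scene:
                scene[key] = tuple(scene[key])
        seg = d.pop("seg", {})
        if isinstance(seg.get("hsv_range"), str):
            seg["hsv_range"] = HSV_PRESETS[seg["hsv_range"]]
        elif isinstance(seg.get("hsv_range"), dict):
            from .segmentation import HsvRange

            seg["hsv_range"] = HsvRange(**seg["hsv_range"])
        return cls(
            scene=SceneConfig(**scene),
            gen=GeneratorConfig(**d.pop("gen", {})),
            train=TrainConfig(**d.pop("train", {})),
            seg=SegmentationConfig(**seg),
            **d,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, mask.astype(np.uint8) * 255)


def _stage(name: str):
    log.info("stage %s: start", name)
    return time.time()


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Execute the full protocol; returns the run directory.

    Stages: simulate -> train -> convert -> segment -> evaluate -> compare.
    Deterministic given the config (single-threaded numerics assumed for
    the training path).  Any stage failure is re-raised annotated with the
    stage name and offending item.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        n_train, n_test = default_split(config.n_scenes)
        if n_test == 0:
            raise ValueError("config.n_scenes leaves an empty test split")
        log.info(
            "run: %d scenes (%d train / %d test), seeds scene=%d train=%d, v%s",
            config.n_scenes, n_train, n_test,
            config.scene.rng_seed, config.train.rng_seed, __version__,
        )

        t = _stage("simulate")
        try:
            scenes = [generate_scene(config.scene, i) for i in range(config.n_scenes)]
        except Exception as exc:
            raise RuntimeError(f"stage simulate failed: {exc}") from exc
        train_scenes, test_scenes = scenes[:n_train], scenes[n_train:]
        log.info("stage simulate: done in %.1fs", time.time() - t)

        results: CycleGANResults | None = None
        if config.run_cyclegan:
            t = _stage("train")
            xs = np.stack([s.rgb for s in train_scenes])
            ys = np.stack([s.depth_colormap() for s in train_scenes])
            try:
                state = train(xs, ys, config.train, gen_config=config.gen)
            except Exception as exc:
                raise RuntimeError(f"stage train failed: {exc}") from exc
            results = CycleGANResults(state, config.train)
            results.save(out / "checkpoint.npz")
            results.write_loss_csv(out / "loss_history.csv")
            log.info("stage train: %d iterations in %.1fs",
                     state.iteration, time.time() - t)

        paths: dict[str, dict] = {}
        if config.run_depth_direct:
            paths["depth_direct"] = {
                "image": lambda s: s.depth_colormap(),
                "masks": [], "scores": [],
            }
        if config.run_cyclegan:
            paths["cyclegan"] = {
                "image": lambda s: convert(results.state, s.rgb),
                "masks": [], "scores": [],
            }
            paths["rgb_baseline"] = {
                "image": lambda s: s.rgb,
                "masks": [], "scores": [],
            }

        t = _stage("segment")
        ids = [f"scene_{s.index:04d}" for s in test_scenes]
        for pname, p in paths.items():
            pdir = out / "masks" / pname
            pdir.mkdir(parents=True, exist_ok=True)
            for s, sid in zip(test_scenes, ids):
                try:
                    img = p["image"](s)
                    mask = segment_truss(img, config.seg)
                    p["scores"].append(segmentation_score(img, config.seg))
                except Exception as exc:
                    raise RuntimeError(
                        f"stage segment failed on path {pname}, scene {sid}: {exc}"
                    ) from exc
                p["masks"].append(mask)
                _write_mask_png(pdir / f"{sid}.png", mask)
        log.info("stage segment: done in %.1fs", time.time() - t)

        t = _stage("evaluate")
        comparison: dict = {"n_test": n_test, "paths": {}}
        for pname, p in paths.items():
            truth_at = {
                "depth_direct": lambda s: s.truth,
                "cyclegan": lambda s: _resized_truth(s, config.gen.input_size),
                "rgb_baseline": lambda s: s.truth,
            }[pname]
            pairs = [(m, truth_at(s)) for m, s in zip(p["masks"], test_scenes)]
            report = evaluate_dataset(pairs, ids=ids, scores=p["scores"])
            report.write(out / "reports", stem=pname)
            comparison["paths"][pname] = {
                "aggregate": report.aggregate,
                "auc": report.auc,
            }
            for line in report.summary_lines():
                log.info("%s %s", pname, line)
        (out / "comparison.json").write_text(json.dumps(comparison, indent=2))
        log.info("stage evaluate: done in %.1fs", time.time() - t)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()


def _resized_truth(scene, size: int) -> np.ndarray:
    """Ground truth at the converter's working resolution (nearest)."""
    if scene.truth.shape == (size, size):
        return scene.truth
    from skimage.transform import resize

    return resize(scene.truth.astype(float), (size, size), order=0) > 0.5


def scan_sequence(
    state: CycleGanState,
    frames,
    seg_config: SegmentationConfig | None = None,
) -> list[np.ndarray | None]:
    """Per-frame convert + segment over an ordered frame sequence.

    Frames are processed independently, in order, with no inter-frame
    registration.  Each frame is an ``(H, W, 3)`` uint8 array or a path
    to an image file; an unreadable frame yields ``None`` in its slot and
    a warning, preserving positional correspondence.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("scan_sequence needs at least one frame")
    seg_config = seg_config or SegmentationConfig()
    masks: list[np.ndarray | None] = []
    for i, frame in enumerate(frames):
        try:
            if isinstance(frame, (str, Path)):
                import imageio.v3 as iio

                frame = np.asarray(iio.imread(frame))[..., :3]
            fake = convert(state, np.asarray(frame))
            masks.append(segment_truss(fake, seg_config))
        except (OSError, ValueError) as exc:
            log.warning("frame %d skipped: %s", i, exc)
            masks.append(None)
    return masks
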