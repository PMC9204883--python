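"""Unpaired RGB-to-depth-colormap translation (CycleGAN).

Two generators and two discriminators learn a pair of mappings between
unpaired image domains: G takes a greenhouse RGB frame (domain X) to a
depth-colormap-style image (domain Y), F goes the other way.  Training
combines least-squares adversarial losses with cycle-consistency — the
mean absolute deviation of the round trips ``F(G(x)) ≈ x`` and
``G(F(y)) ≈ y`` — so neither domain needs pixel-aligned counterparts.
Only G is of downstream interest: its output feeds the truss segmentation
chain in place of the (failure-prone) depth camera; F exists to close the
cycle.

Each generator is encoder (one 7x7 conv then two stride-2 convs),
transformer (eight residual blocks by default), decoder (two transposed
convs and a 7x7 output conv).  Hidden layers use instance normalization
and ReLU; the output layer alone uses tanh, since a one-sided rectifier
cannot emit the full color range.  Discriminators are 70x70-receptive-
field patch classifiers.  Images are scaled to [-1, 1] for the networks.

The module follows a model/results idiom: build a :class:`CycleGAN` from
the two domains, call :meth:`~CycleGAN.fit`, and get a
:class:`CycleGANResults` carrying the trained state, the per-iteration
loss history and a ``summary()``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from skimage import transform as sktransform

from . import nn
from .nn import relu, relu_grad  # re-exported scalar activation  # noqa: F401

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "TrainConfig",
    "TrainingDivergedError",
    "build_generator",
    "build_discriminator",
    "patch_output_size",
    "normalize_images",
    "denormalize_image",
    "cycle_losses",
    "CycleGanState",
    "CycleGAN",
    "CycleGANResults",
    "train",
    "convert",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Generator shape.  ``input_size`` must be divisible by 4 so the two
    stride-2 encoder stages are exactly inverted by the two transposed
    convolutions.  ``base_channels`` is the encoder's first width; the
    default 64 matches the reference translation architecture, and tests
    scale it down."""

    input_size: int = 512
    base_channels: int = 64
    transformer_blocks: int = 8

    def __post_init__(self) -> None:
        if self.input_size % 4 != 0 or self.input_size < 4:
            raise ValueError(
                f"input_size must be a positive multiple of 4, got {self.input_size}"
            )
        if self.base_channels < 1 or self.transformer_blocks < 0:
            raise ValueError("base_channels >= 1 and transformer_blocks >= 0 required")


@dataclass(frozen=True)
class DiscriminatorConfig:
    base_channels: int = 64


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.  The full-scale protocol is 9600 iterations
    at batch size 5; tests and the bundled experiments run scaled-down
    versions of the same loop."""

    iterations: int = 9600
    batch_size: int = 5
    learning_rate: float = 2e-4
    cycle_weight: float = 10.0
    identity_weight: float = 0.0
    beta1: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.cycle_weight <= 0:
            raise ValueError("cycle_weight must be > 0")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


class TrainingDivergedError(RuntimeError):
    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


def _conv_in_relu(c_in, c_out, k, stride, pad, rng, dtype):
    return [
        nn.Conv2d(c_in, c_out, k, stride=stride, pad=pad, rng=rng, dtype=dtype),
        nn.InstanceNorm2d(c_out, dtype=dtype),
        nn.ReLU(),
    ]


def _res_block(c, rng, dtype):
    return nn.Residual(
        nn.Sequential(
            nn.Conv2d(c, c, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(c, dtype=dtype),
            nn.ReLU(),
            nn.Conv2d(c, c, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            nn.InstanceNorm2d(c, dtype=dtype),
        )
    )


def build_generator(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> nn.Sequential:
    """Encoder / residual transformer / decoder generator, 3ch -> 3ch."""
    rng = rng or np.random.default_rng(0)
    ngf = config.base_channels
    layers: list[nn.Module] = []
    layers += _conv_in_relu(3, ngf, 7, 1, 3, rng, dtype)
    layers += _conv_in_relu(ngf, ngf * 2, 3, 2, 1, rng, dtype)
    layers += _conv_in_relu(ngf * 2, ngf * 4, 3, 2, 1, rng, dtype)
    for _ in range(config.transformer_blocks):
        layers.append(_res_block(ngf * 4, rng, dtype))
    layers += [
        nn.ConvTranspose2d(ngf * 4, ngf * 2, 3, stride=2, pad=1, output_pad=1, rng=rng, dtype=dtype),
        nn.InstanceNorm2d(ngf * 2, dtype=dtype),
        nn.ReLU(),
        nn.ConvTranspose2d(ngf * 2, ngf, 3, stride=2, pad=1, output_pad=1, rng=rng, dtype=dtype),
        nn.InstanceNorm2d(ngf, dtype=dtype),
        nn.ReLU(),
        nn.Conv2d(ngf, 3, 7, stride=1, pad=3, rng=rng, dtype=dtype),
        nn.Tanh(),
    ]
    return nn.Sequential(*layers)


def build_discriminator(
    config: DiscriminatorConfig | None = None,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> nn.Sequential:
    """70x70-receptive-field patch discriminator: image -> real/fake field."""
    config = config or DiscriminatorConfig()
    rng = rng or np.random.default_rng(0)
    ndf = config.base_channels
    return nn.Sequential(
        nn.Conv2d(3, ndf, 4, stride=2, pad=1, rng=rng, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv2d(ndf, ndf * 2, 4, stride=2, pad=1, rng=rng, dtype=dtype),
        nn.InstanceNorm2d(ndf * 2, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv2d(ndf * 2, ndf * 4, 4, stride=2, pad=1, rng=rng, dtype=dtype),
        nn.InstanceNorm2d(ndf * 4, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv2d(ndf * 4, ndf * 8, 4, stride=1, pad=1, rng=rng, dtype=dtype),
        nn.InstanceNorm2d(ndf * 8, dtype=dtype),
        nn.LeakyReLU(0.2),
        nn.Conv2d(ndf * 8, 1, 4, stride=1, pad=1, rng=rng, dtype=dtype),
    )


def patch_output_size(n: int) -> int:
    """Spatial extent of the discriminator's prediction field for an
    n-pixel input edge (three stride-2 then two stride-1 4x4 convs)."""
    for stride in (2, 2, 2, 1, 1):
        n = (n + 2 - 4) // stride + 1
    return n


def normalize_images(images) -> np.ndarray:
    """uint8 HWC image(s) -> float32 NCHW in [-1, 1]."""
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected (H, W, 3) or (N, H, W, 3) images")
    return (arr.astype(np.float32) / 127.5 - 1.0).transpose(0, 3, 1, 2)


def denormalize_image(batch: np.ndarray) -> np.ndarray:
    """float NCHW in [-1, 1] -> uint8 NHWC."""
    out = (np.clip(batch, -1.0, 1.0) + 1.0) * 127.5
    return np.round(out).astype(np.uint8).transpose(0, 2, 3, 1)


@dataclass
class CycleGanState:
    """Generators, discriminators and the training trace."""

    G: nn.Sequential
    F: nn.Sequential
    Dx: nn.Sequential
    Dy: nn.Sequential
    gen_config: GeneratorConfig
    disc_config: DiscriminatorConfig
    loss_history: list[dict] = field(default_factory=list)
    iteration: int = 0

    def modules(self) -> dict[str, nn.Sequential]:
        return {"G": self.G, "F": self.F, "Dx": self.Dx, "Dy": self.Dy}

    def save(self, path: str | Path) -> None:
        """Checkpoint: npz of all parameters + JSON sidecar of configs."""
        path = Path(path)
        arrays = {}
        for mname, module in self.modules().items():
            for i, p in enumerate(module.parameters()):
                arrays[f"{mname}_{i}"] = p.value
        np.savez(path, **arrays)
        sidecar = {
            "gen_config": asdict(self.gen_config),
            "disc_config": asdict(self.disc_config),
            "iteration": self.iteration,
            "loss_history": self.loss_history,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "CycleGanState":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        gen_config = GeneratorConfig(**sidecar["gen_config"])
        disc_config = DiscriminatorConfig(**sidecar["disc_config"])
        state = _init_state(gen_config, disc_config, np.random.default_rng(0))
        state.iteration = sidecar["iteration"]
        state.loss_history = sidecar["loss_history"]
        with np.load(path) as data:
            for mname, module in state.modules().items():
                for i, p in enumerate(module.parameters()):
                    arr = data[f"{mname}_{i}"]
                    p.value = arr.astype(p.value.dtype)
                    p.grad = np.zeros_like(p.value)
        return state


def _init_state(
    gen_config: GeneratorConfig,
    disc_config: DiscriminatorConfig,
    rng: np.random.Generator,
    dtype=np.float32,
) -> CycleGanState:
    return CycleGanState(
        G=build_generator(gen_config, rng, dtype),
        F=build_generator(gen_config, rng, dtype),
        Dx=build_discriminator(disc_config, rng, dtype),
        Dy=build_discriminator(disc_config, rng, dtype),
        gen_config=gen_config,
        disc_config=disc_config,
    )


def cycle_losses(x: np.ndarray, y: np.ndarray, state: CycleGanState):
    """Mean-absolute-deviation round-trip losses for a batch pair.

    ``forward = mean |F(G(x)) - x|``, ``reverse = mean |G(F(y)) - y|``.
    Inputs are float NCHW in the networks' [-1, 1] range (uint8 HWC images
    are normalized automatically).
    """
    if x.dtype == np.uint8:
        x = normalize_images(x)
    if y.dtype == np.uint8:
        y = normalize_images(y)
    if x.shape[1:] != y.shape[1:]:
        raise ValueError(f"domain shapes differ: {x.shape} vs {y.shape}")
    fake_y, _ = state.G.forward(x)
    rec_x, _ = state.F.forward(fake_y)
    fake_x, _ = state.F.forward(y)
    rec_y, _ = state.G.forward(fake_x)
    return float(np.abs(rec_x - x).mean()), float(np.abs(rec_y - y).mean())


def _as_domain(images, name: str) -> np.ndarray:
    arr = np.asarray(images)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.size == 0 or arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"domain {name} must be a non-empty (N, H, W, 3) stack")
    return arr


def train(
    dataset_x,
    dataset_y,
    config: TrainConfig,
    gen_config: GeneratorConfig | None = None,
    disc_config: DiscriminatorConfig | None = None,
    callback=None,
) -> CycleGanState:
    """Run the adversarial + cycle-consistency optimization.

    ``dataset_x`` / ``dataset_y`` are stacks of uint8 HWC images of the
    two domains; they need not be paired or equally sized in count, and
    each iteration draws an independent batch from each.  All randomness
    (init, batch sampling) derives from ``config.rng_seed``.  Raises
    :class:`TrainingDivergedError` on a non-finite loss.
    """
    xs = _as_domain(dataset_x, "X")
    ys = _as_domain(dataset_y, "Y")
    size = xs.shape[1]
    if gen_config is None:
        gen_config = GeneratorConfig(input_size=size)
    if patch_output_size(gen_config.input_size) < 1:
        raise ValueError(
            f"input_size {gen_config.input_size} too small for the patch "
            "discriminator; need at least 32"
        )
    if xs.shape[1:3] != (gen_config.input_size,) * 2 or ys.shape[1:3] != (
        gen_config.input_size,
    ) * 2:
        raise ValueError("domain images must match gen_config.input_size (square)")
    disc_config = disc_config or DiscriminatorConfig(
        base_channels=gen_config.base_channels
    )
    rng = np.random.default_rng([config.rng_seed, 0xC6C1E])
    state = _init_state(gen_config, disc_config, rng)
    xs_n = normalize_images(xs)
    ys_n = normalize_images(ys)

    g_params = state.G.parameters() + state.F.parameters()
    d_params = state.Dx.parameters() + state.Dy.parameters()
    opt_g = nn.Adam(g_params, lr=config.learning_rate, beta1=config.beta1)
    opt_d = nn.Adam(d_params, lr=config.learning_rate, beta1=config.beta1)
    lam = config.cycle_weight

    for it in range(config.iterations):
        bx = xs_n[rng.integers(0, len(xs_n), size=config.batch_size)]
        by = ys_n[rng.integers(0, len(ys_n), size=config.batch_size)]

        # ---- generator update (adversarial + cycle [+ identity]) ----
        fake_y, cG1 = state.G.forward(bx)
        rec_x, cF1 = state.F.forward(fake_y)
        fake_x, cF2 = state.F.forward(by)
        rec_y, cG2 = state.G.forward(fake_x)
        py, cDy = state.Dy.forward(fake_y)
        px, cDx = state.Dx.forward(fake_x)

        fwd_cyc = float(np.abs(rec_x - bx).mean())
        rev_cyc = float(np.abs(rec_y - by).mean())
        g_adv = float(((py - 1.0) ** 2).mean() + ((px - 1.0) ** 2).mean())
        g_loss = g_adv + lam * (fwd_cyc + rev_cyc)

        d_fake_y = state.Dy.backward(2.0 * (py - 1.0) / py.size, cDy)
        d_rec_x = lam * np.sign(rec_x - bx).astype(rec_x.dtype) / rec_x.size
        d_fake_y = d_fake_y + state.F.backward(d_rec_x, cF1)
        d_rec_y = lam * np.sign(rec_y - by).astype(rec_y.dtype) / rec_y.size
        d_fake_x = state.G.backward(d_rec_y, cG2)
        d_fake_x = d_fake_x + state.Dx.backward(2.0 * (px - 1.0) / px.size, cDx)
        state.G.backward(d_fake_y, cG1)
        state.F.backward(d_fake_x, cF2)

        if config.identity_weight > 0:
            idt_y, cGi = state.G.forward(by)
            idt_x, cFi = state.F.forward(bx)
            wi = config.identity_weight * lam
            g_loss += wi * float(np.abs(idt_y - by).mean() + np.abs(idt_x - bx).mean())
            state.G.backward(wi * np.sign(idt_y - by).astype(by.dtype) / idt_y.size, cGi)
            state.F.backward(wi * np.sign(idt_x - bx).astype(bx.dtype) / idt_x.size, cFi)

        opt_g.step()
        opt_g.zero_grad()
        state.Dx.zero_grad()  # grads leaked through the adversarial terms
        state.Dy.zero_grad()

        # ---- discriminator update (fakes detached by construction) ----
        dx_loss = _disc_step(state.Dx, bx, fake_x)
        dy_loss = _disc_step(state.Dy, by, fake_y)
        opt_d.step()
        opt_d.zero_grad()

        losses = {
            "iteration": it,
            "g_loss": g_loss,
            "dx_loss": dx_loss,
            "dy_loss": dy_loss,
            "fwd_cycle": fwd_cyc,
            "rev_cycle": rev_cyc,
        }
        if not all(np.isfinite(v) for v in losses.values()):
            raise TrainingDivergedError(it)
        state.loss_history.append(losses)
        state.iteration = it + 1
        if callback is not None:
            callback(losses)
    return state


def _disc_step(disc: nn.Sequential, real: np.ndarray, fake: np.ndarray) -> float:
    p_real, c_real = disc.forward(real)
    p_fake, c_fake = disc.forward(fake)
    loss = 0.5 * float(((p_real - 1.0) ** 2).mean() + (p_fake**2).mean())
    disc.backward((p_real - 1.0) / p_real.size, c_real)
    disc.backward(p_fake / p_fake.size, c_fake)
    return loss


def convert(state: CycleGanState, rgb: np.ndarray) -> np.ndarray:
    """Translate one RGB image to the depth-colormap domain via G.

    The input is resized (bilinear, aspect-distorting, e.g. 1600x900 to
    512x512) to the generator's input size, mapped, and de-normalized to
    an 8-bit image.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    size = state.gen_config.input_size
    if rgb.shape[:2] != (size, size):
        resized = sktransform.resize(
            rgb, (size, size), order=1, preserve_range=True, anti_aliasing=False
        )
        rgb = np.round(resized).astype(np.uint8)
    x = normalize_images(rgb)
    y, _ = state.G.forward(x)
    return denormalize_image(y)[0]


class CycleGAN:
    """Unpaired translation model between two image domains.

    Parameters
    ----------
    domain_x, domain_y
        uint8 image stacks ``(N, S, S, 3)`` — RGB frames and depth
        colormaps.  They need not be paired.
    gen_config, disc_config, train_config
        Architecture and optimization settings; defaults are the
        full-scale protocol.
    """

    def __init__(
        self,
        domain_x,
        domain_y,
        gen_config: GeneratorConfig | None = None,
        disc_config: DiscriminatorConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.domain_x = _as_domain(domain_x, "X")
        self.domain_y = _as_domain(domain_y, "Y")
        self.gen_config = gen_config or GeneratorConfig(
            input_size=self.domain_x.shape[1]
        )
        self.disc_config = disc_config or DiscriminatorConfig(
            base_channels=self.gen_config.base_channels
        )
        self.train_config = train_config or TrainConfig()

    def fit(self, callback=None) -> "CycleGANResults":
        state = train(
            self.domain_x,
            self.domain_y,
            self.train_config,
            gen_config=self.gen_config,
            disc_config=self.disc_config,
            callback=callback,
        )
        return CycleGANResults(state, self.train_config)


class CycleGANResults:
    """Fitted translation model: trained state, loss trace, inference."""

    def __init__(self, state: CycleGanState, train_config: TrainConfig | None = None):
        self.state = state
        self.train_config = train_config

    @property
    def loss_history(self) -> list[dict]:
        return self.state.loss_history

    def convert(self, rgb: np.ndarray) -> np.ndarray:
        return convert(self.state, rgb)

    def save(self, path: str | Path) -> None:
        self.state.save(path)

    @classmethod
    def load(cls, path: str | Path) -> "CycleGANResults":
        return cls(CycleGanState.load(path))

    def loss_table(self) -> np.ndarray:
        """(iterations, 6) array: iteration, g, dx, dy, fwd_cycle, rev_cycle."""
        cols = ("iteration", "g_loss", "dx_loss", "dy_loss", "fwd_cycle", "rev_cycle")
        return np.array([[rec[c] for c in cols] for rec in self.loss_history])

    def write_loss_csv(self, path: str | Path) -> None:
        import csv

        cols = ("iteration", "g_loss", "dx_loss", "dy_loss", "fwd_cycle", "rev_cycle")
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for rec in self.loss_history:
                w.writerow([rec[c] for c in cols])

    def summary(self) -> str:
        n = len(self.loss_history)
        lines = [
            "CycleGAN translation results",
            "============================",
            f"iterations:          {self.state.iteration}",
            f"generator input:     {self.state.gen_config.input_size}x"
            f"{self.state.gen_config.input_size}, "
            f"{self.state.gen_config.base_channels} base channels, "
            f"{self.state.gen_config.transformer_blocks} residual blocks",
            f"parameters (G+F):    {sum(p.value.size for p in self.state.G.parameters()) + sum(p.value.size for p in self.state.F.parameters())}",
        ]
        if n:
            head = max(1, n // 10)
            first = np.mean(
                [r["fwd_cycle"] + r["rev_cycle"] for r in self.loss_history[:head]]
            )
            last = np.mean(
                [r["fwd_cycle"] + r["rev_cycle"] for r in self.loss_history[-head:]]
            )
            rec = self.loss_history[-1]
            lines += [
                f"cycle loss (fwd+rev), first {head} its: {first:.4f}",
                f"cycle loss (fwd+rev), last {head} its:  {last:.4f}",
                f"final losses: g={rec['g_loss']:.4f} dx={rec['dx_loss']:.4f} "
                f"dy={rec['dy_loss']:.4f}",
            ]
        else:
            lines.append("(untrained: empty loss history)")
        return "\n".join(lines)
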