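"""Nested-U-Net generator, 3D conv discriminator, losses, and training.

The generator is a U-Net++: encoder nodes ``X[i][0]`` feed a triangle of
nested decoder nodes ``X[i][j]`` where each node receives dense skips from
all same-scale predecessors plus a trilinear ×2 upsampling of the node one
scale below.  Downsampling is 2×2×2 max-pooling; every conv block is
``convs_per_block`` repetitions of (3³ conv → instance norm → PReLU); the
output head is a linear 1×1×1 convolution.

The default widths (18, 36, 72, 144, 352) were frozen by exact parameter
counting so the generator totals 10.3 million trainable parameters and the
default discriminator (convs 32-64-128-256, FC 256-128-64-1) totals
1.2 million, both rounded to one decimal.

Generator loss: SmoothL1(X, Y) + alpha * (−log D(X)); discriminator loss:
−(log D(Y) + log(1 − D(X))), with D emitting a sigmoid probability clamped
to [eps, 1−eps] inside the logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from mapgan.errors import ConfigError
from mapgan.nn import autograd as ag
from mapgan.nn.autograd import Tensor
from mapgan.nn.layers import Conv3d, InstanceNorm3d, Linear, Module, PReLU
from mapgan.nn.optim import NAdam
from mapgan.simulator import SimulationParams, grid_from_model, simulate_map
from mapgan.tiling import pad_and_tile, reassemble
from mapgan.volume_io import AtomicModel, DensityMap, minmax_normalize

EPS_PROB = 1e-7  # clamp for log D(.)

#: frozen by parameter-count calibration against the 10.3 M budget
DEFAULT_GENERATOR_WIDTHS = (18, 36, 72, 144, 352)
DEFAULT_DISCRIMINATOR_WIDTHS = (32, 64, 128, 256)
DEFAULT_FC_WIDTHS = (256, 128, 64, 1)


@dataclass
class GanConfig:
    generator_widths: tuple[int, ...] = DEFAULT_GENERATOR_WIDTHS
    convs_per_block: int = 2
    alpha: float = 0.01
    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0
    use_smooth_l1: bool = True
    discriminator_widths: tuple[int, ...] = DEFAULT_DISCRIMINATOR_WIDTHS
    fc_widths: tuple[int, ...] = DEFAULT_FC_WIDTHS
    tile_size: int = 32

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigError(f"alpha must be non-negative, got {self.alpha}")
        if any(w <= 0 for w in self.generator_widths):
            raise ConfigError(f"generator widths must be positive: {self.generator_widths}")
        if any(w <= 0 for w in self.discriminator_widths):
            raise ConfigError(
                f"discriminator widths must be positive: {self.discriminator_widths}"
            )
        if self.fc_widths[-1] != 1:
            raise ConfigError("final fully connected width must be 1")
        depth = len(self.generator_widths) - 1
        if self.tile_size // (2**depth) < 2:
            raise ConfigError(
                f"depth {depth} reduces a {self.tile_size}³ tile below 2³ at the "
                "bottleneck"
            )

    @property
    def depth(self) -> int:
        return len(self.generator_widths) - 1

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("generator_widths", "discriminator_widths", "fc_widths"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GanConfig":
        d = dict(d)
        for key in ("generator_widths", "discriminator_widths", "fc_widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def toy_config(**overrides) -> GanConfig:
    """A reduced-width configuration for desk-scale experiments and tests."""
    defaults = dict(
        generator_widths=(4, 8, 16),
        convs_per_block=1,
        discriminator_widths=(4, 8, 16, 32),
        fc_widths=(32, 16, 8, 1),
        batch_size=8,
        epochs=10,
    )
    defaults.update(overrides)
    return GanConfig(**defaults)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class _ConvBlock(Module):
    def __init__(self, in_ch: int, width: int, n_convs: int, rng: np.random.Generator):
        self.convs = []
        self.norms = []
        self.acts = []
        c = in_ch
        for _ in range(n_convs):
            self.convs.append(Conv3d(c, width, 3, rng=rng))
            self.norms.append(InstanceNorm3d(width))
            self.acts.append(PReLU(width))
            c = width

    def forward(self, x: Tensor) -> Tensor:
        for conv, norm, act in zip(self.convs, self.norms, self.acts):
            x = act(norm(conv(x)))
        return x


class Generator(Module):
    """U-Net++ with dense nested skips; linear 1×1×1 output head."""

    def __init__(self, config: GanConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        widths = config.generator_widths
        depth = config.depth
        self.depth = depth
        self.blocks: list[list[_ConvBlock]] = []
        for i in range(depth + 1):
            row: list[_ConvBlock] = []
            for j in range(depth - i + 1):
                if j == 0:
                    in_ch = 1 if i == 0 else widths[i - 1]
                else:
                    in_ch = j * widths[i] + widths[i + 1]
                row.append(_ConvBlock(in_ch, widths[i], config.convs_per_block, rng))
            self.blocks.append(row)
        self.head = Conv3d(widths[0], 1, kernel_size=1, padding=0, rng=rng)
        self.n_forward = 0  # diagnostic counter

    def forward(self, x: Tensor) -> Tensor:
        self.n_forward += 1
        depth = self.depth
        nodes: dict[tuple[int, int], Tensor] = {}
        nodes[(0, 0)] = self.blocks[0][0](x)
        for i in range(1, depth + 1):
            nodes[(i, 0)] = self.blocks[i][0](ag.maxpool3d(nodes[(i - 1, 0)]))
        for j in range(1, depth + 1):
            for i in range(0, depth - j + 1):
                skips = [nodes[(i, k)] for k in range(j)]
                up = ag.upsample3d(nodes[(i + 1, j - 1)])
                nodes[(i, j)] = self.blocks[i][j](ag.concat(skips + [up], axis=1))
        return self.head(nodes[(0, depth)])


class Discriminator(Module):
    """Four stride-2 conv stages → global average pool → 3 FC layers → sigmoid."""

    def __init__(self, config: GanConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.convs = []
        self.norms = []
        self.acts = []
        c = 1
        for w in config.discriminator_widths:
            self.convs.append(Conv3d(c, w, 3, stride=2, rng=rng))
            self.norms.append(InstanceNorm3d(w))
            self.acts.append(PReLU(w))
            c = w
        fc = config.fc_widths
        if fc[0] != config.discriminator_widths[-1]:
            raise ConfigError(
                f"first fully connected width {fc[0]} must match the last conv "
                f"width {config.discriminator_widths[-1]}"
            )
        self.fcs = [Linear(fc[i], fc[i + 1], rng=rng) for i in range(len(fc) - 1)]
        self.n_forward = 0

    def forward(self, x: Tensor) -> Tensor:
        self.n_forward += 1
        for conv, norm, act in zip(self.convs, self.norms, self.acts):
            x = act(norm(conv(x)))
        x = ag.global_mean_pool(x)
        for fc in self.fcs[:-1]:
            x = ag.relu(fc(x))
        return ag.sigmoid(self.fcs[-1](x))


def build_generator(config: GanConfig, rng: np.random.Generator | None = None) -> Generator:
    return Generator(config, rng)


def build_discriminator(
    config: GanConfig, rng: np.random.Generator | None = None
) -> Discriminator:
    return Discriminator(config, rng)


def count_parameters(module: Module) -> int:
    return module.n_parameters()


# ---------------------------------------------------------------------------
# losses (closed-form numpy; the training loop uses autograd equivalents)
# ---------------------------------------------------------------------------


def smooth_l1(x: np.ndarray, y: np.ndarray) -> float:
    """Mean Huber loss: 0.5 (x−y)² where |x−y| < 1, else |x−y| − 0.5."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    d = x - y
    absd = np.abs(d)
    return float(np.where(absd < 1.0, 0.5 * d * d, absd - 0.5).mean())


def adversarial_loss(d_of_fake) -> float:
    """−log D(X), with D(X) clamped away from {0, 1}."""
    d = np.clip(np.asarray(d_of_fake, dtype=np.float64), EPS_PROB, 1.0 - EPS_PROB)
    return float(np.mean(-np.log(d)))


def generator_loss(x, y, d_of_fake, alpha: float, use_smooth_l1: bool = True) -> float:
    """SmoothL1(X, Y) + alpha · (−log D(X)); either term can be ablated."""
    total = 0.0
    if use_smooth_l1:
        total += smooth_l1(x, y)
    if alpha != 0.0:
        total += alpha * adversarial_loss(d_of_fake)
    return float(total)


def discriminator_loss(d_of_real, d_of_fake) -> float:
    """−(log D(Y) + log(1 − D(X)))."""
    dr = np.clip(np.asarray(d_of_real, dtype=np.float64), EPS_PROB, 1.0 - EPS_PROB)
    df = np.clip(np.asarray(d_of_fake, dtype=np.float64), EPS_PROB, 1.0 - EPS_PROB)
    return float(-(np.mean(np.log(dr)) + np.mean(np.log(1.0 - df))))


# autograd versions -------------------------------------------------------


def _adv_loss_t(d_fake: Tensor) -> Tensor:
    return ag.neg(ag.mean(ag.log(ag.clamp(d_fake, EPS_PROB, 1.0 - EPS_PROB))))


def _disc_loss_t(d_real: Tensor, d_fake: Tensor) -> Tensor:
    lr_ = ag.mean(ag.log(ag.clamp(d_real, EPS_PROB, 1.0 - EPS_PROB)))
    one_minus = ag.sub(ag.neg(d_fake), -1.0)  # 1 - d_fake
    lf = ag.mean(ag.log(ag.clamp(one_minus, EPS_PROB, 1.0 - EPS_PROB)))
    return ag.neg(ag.add(lr_, lf))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    config: GanConfig
    generator_state: dict[str, np.ndarray]
    discriminator_state: dict[str, np.ndarray]
    optimizer_g_state: dict | None = None
    optimizer_d_state: dict | None = None
    epoch: int = 0
    loss_history: dict[str, list[float]] = field(
        default_factory=lambda: {"generator": [], "discriminator": []}
    )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "epoch": self.epoch,
            "loss_history": self.loss_history,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for prefix, state in (("G.", self.generator_state), ("D.", self.discriminator_state)):
            for name, arr in state.items():
                arrays[prefix + name] = arr
        np.savez_compressed(directory / "weights.npz", **arrays)
        opt = {}
        for prefix, state in (
            ("optG.", self.optimizer_g_state),
            ("optD.", self.optimizer_d_state),
        ):
            if state is None:
                continue
            opt[prefix + "t"] = np.asarray(state["t"])
            opt[prefix + "mu_product"] = np.asarray(state["mu_product"])
            for i, m in enumerate(state["m"]):
                opt[f"{prefix}m.{i}"] = m
            for i, v in enumerate(state["v"]):
                opt[f"{prefix}v.{i}"] = v
        if opt:
            np.savez_compressed(directory / "optimizer.npz", **opt)

    @classmethod
    def load(cls, directory: str | Path) -> "Checkpoint":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        config = GanConfig.from_dict(meta["config"])
        g_state: dict[str, np.ndarray] = {}
        d_state: dict[str, np.ndarray] = {}
        with np.load(directory / "weights.npz") as npz:
            for key in npz.files:
                if key.startswith("G."):
                    g_state[key[2:]] = npz[key]
                elif key.startswith("D."):
                    d_state[key[2:]] = npz[key]
        opt_g = opt_d = None
        opt_path = directory / "optimizer.npz"
        if opt_path.exists():
            with np.load(opt_path) as npz:
                def unpack(prefix: str):
                    keys = [k for k in npz.files if k.startswith(prefix)]
                    if not keys:
                        return None
                    n = len([k for k in keys if k.startswith(prefix + "m.")])
                    return {
                        "t": int(npz[prefix + "t"]),
                        "mu_product": float(npz[prefix + "mu_product"]),
                        "m": [npz[f"{prefix}m.{i}"] for i in range(n)],
                        "v": [npz[f"{prefix}v.{i}"] for i in range(n)],
                    }

                opt_g = unpack("optG.")
                opt_d = unpack("optD.")
        return cls(
            config=config,
            generator_state=g_state,
            discriminator_state=d_state,
            optimizer_g_state=opt_g,
            optimizer_d_state=opt_d,
            epoch=int(meta["epoch"]),
            loss_history={k: list(v) for k, v in meta["loss_history"].items()},
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _as_pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        sims, exps = pairs
    else:
        sims = np.stack([p[0] for p in pairs])
        exps = np.stack([p[1] for p in pairs])
    sims = np.asarray(sims, dtype=np.float32)
    exps = np.asarray(exps, dtype=np.float32)
    if sims.shape != exps.shape:
        raise ValueError(f"paired tiles disagree in shape: {sims.shape} vs {exps.shape}")
    if sims.ndim != 4:
        raise ValueError(f"expected (n, d, h, w) tile stacks, got ndim={sims.ndim}")
    return sims, exps


def train(
    train_pairs,
    val_pairs,
    config: GanConfig,
    log=None,
) -> Checkpoint:
    """Adversarial training on paired (sim tile, target tile) data.

    Per batch: one discriminator update on (real = target tile,
    fake = G(sim tile)), then one generator update.  NAdam for both networks;
    per-epoch validation losses are recorded in the checkpoint.  Fully
    deterministic for a given seed.
    """
    sims, exps = _as_pair_arrays(train_pairs)
    if len(sims) == 0:
        raise ValueError("training dataset is empty")
    vsims, vexps = _as_pair_arrays(val_pairs)
    if len(vsims) == 0:
        raise ValueError("validation dataset is empty")

    rng = np.random.default_rng(config.seed)
    gen = build_generator(config, rng)
    disc = build_discriminator(config, rng)
    opt_g = NAdam(gen.parameters(), lr=config.learning_rate)
    opt_d = NAdam(disc.parameters(), lr=config.learning_rate)

    n = len(sims)
    bs = max(1, min(config.batch_size, n))
    history_g: list[float] = []
    history_d: list[float] = []
    history_sl1: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            sim_b = sims[idx][:, None]  # (B, 1, D, H, W)
            exp_b = exps[idx][:, None]

            # --- discriminator step (generator output detached: the G
            # forward runs in inference mode, no graph is built through it)
            with ag.no_grad():
                fake = gen(Tensor(sim_b))
            d_real = disc(Tensor(exp_b))
            d_fake = disc(fake.detach())
            loss_d = _disc_loss_t(d_real, d_fake)
            if not np.isfinite(loss_d.data):
                raise RuntimeError(
                    f"discriminator loss diverged (non-finite) at epoch {epoch}"
                )
            loss_d.backward()
            opt_d.step()
            disc.zero_grad()
            gen.zero_grad()

            # --- generator step
            fake = gen(Tensor(sim_b))
            terms: list[Tensor] = []
            if config.use_smooth_l1:
                terms.append(ag.smooth_l1_loss(fake, Tensor(exp_b)))
            if config.alpha > 0.0:
                # ablation isolation: with alpha == 0 the discriminator is
                # never evaluated inside the generator update
                d_fake_g = disc(fake)
                terms.append(ag.mul(_adv_loss_t(d_fake_g), config.alpha))
            if not terms:
                raise ConfigError(
                    "generator loss is empty: use_smooth_l1=False and alpha=0"
                )
            loss_g = terms[0]
            for t in terms[1:]:
                loss_g = ag.add(loss_g, t)
            if not np.isfinite(loss_g.data):
                raise RuntimeError(
                    f"generator loss diverged (non-finite) at epoch {epoch}"
                )
            loss_g.backward()
            opt_g.step()
            gen.zero_grad()
            disc.zero_grad()  # discard discriminator grads from the G pass

        val_g, val_d, val_sl1 = _validate(gen, disc, vsims, vexps, config, bs)
        history_g.append(val_g)
        history_d.append(val_d)
        history_sl1.append(val_sl1)
        if log is not None:
            log(
                f"epoch={epoch + 1} lossG_val={val_g:.6f} lossD_val={val_d:.6f} "
                f"smoothL1_val={val_sl1:.6f}"
            )

    return Checkpoint(
        config=config,
        generator_state=gen.state_dict(),
        discriminator_state=disc.state_dict(),
        optimizer_g_state=opt_g.state_dict(),
        optimizer_d_state=opt_d.state_dict(),
        epoch=config.epochs,
        loss_history={
            "generator": history_g,
            "discriminator": history_d,
            "generator_smooth_l1": history_sl1,
        },
    )


def _validate(gen, disc, vsims, vexps, config, bs) -> tuple[float, float, float]:
    g_losses: list[float] = []
    d_losses: list[float] = []
    sl1_losses: list[float] = []
    with ag.no_grad():
        for lo in range(0, len(vsims), bs):
            sim_b = vsims[lo : lo + bs][:, None]
            exp_b = vexps[lo : lo + bs][:, None]
            fake = gen(Tensor(sim_b)).data
            d_real = disc(Tensor(exp_b)).data
            d_fake = disc(Tensor(fake)).data
            sl1_losses.append(smooth_l1(fake, exp_b))
            g_losses.append(
                generator_loss(fake, exp_b, d_fake, config.alpha, config.use_smooth_l1)
            )
            d_losses.append(discriminator_loss(d_real, d_fake))
    return float(np.mean(g_losses)), float(np.mean(d_losses)), float(np.mean(sl1_losses))


def validation_smooth_l1(checkpoint: Checkpoint, val_pairs) -> float:
    """SmoothL1 of the checkpointed generator over a validation set."""
    vsims, vexps = _as_pair_arrays(val_pairs)
    gen = build_generator(checkpoint.config)
    gen.load_state_dict(checkpoint.generator_state)
    out = apply_generator(gen, vsims, checkpoint.config.batch_size)
    return smooth_l1(out, vexps)


def apply_generator(gen: Generator, tiles: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Run the generator over a stack of tiles, returning a same-shape stack."""
    tiles = np.asarray(tiles, dtype=np.float32)
    outs = []
    with ag.no_grad():
        for lo in range(0, len(tiles), max(1, batch_size)):
            batch = tiles[lo : lo + max(1, batch_size)][:, None]
            outs.append(gen(Tensor(batch)).data[:, 0])
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def generate_map(
    model: AtomicModel,
    checkpoint: Checkpoint,
    sim_params: SimulationParams | None = None,
    voxel: float = 1.0,
    margin: float = 5.0,
) -> DensityMap:
    """Full inference: simulate, normalize, tile, translate, reassemble.

    The returned map shares the simulated map's grid; negative generator
    outputs are clamped to zero after reassembly.
    """
    sim_params = sim_params or SimulationParams()
    grid = grid_from_model(model, voxel=voxel, margin=margin)
    sim = minmax_normalize(simulate_map(model, grid, sim_params))
    return translate_map(sim, checkpoint)


def translate_map(sim: DensityMap, checkpoint: Checkpoint) -> DensityMap:
    """Run a normalized simulated map through the trained generator."""
    gen = build_generator(checkpoint.config)
    try:
        gen.load_state_dict(checkpoint.generator_state)
    except ValueError as exc:
        raise ConfigError(f"checkpoint incompatible with its config: {exc}") from exc
    pack = pad_and_tile(sim)
    processed = apply_generator(gen, pack.tiles, checkpoint.config.batch_size)
    out = reassemble(pack, processed)
    out.data = np.maximum(out.data, 0.0)
    return out
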