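"""GAN-based class balancing for the smear dataset.

A fully connected generator maps a uniform noise vector (length 100 by
default) through six dense layers whose widths end at side^2 (51,076 for
226x226 images), ReLU in the hidden layers and tanh at the output; a
six-layer dense discriminator with a final sigmoid scores authenticity.
Training alternates discriminator and generator updates on the minimax
value

    V(G, D) = E_x[log D(x)] + E_z[log(1 - D(G(z)))],

with the non-saturating surrogate -E_z[log D(G(z))] driving the generator
update (same optimum, healthier gradients). One GAN is trained per class;
``balance_classes`` then tops every class up to a common target count with
synthetic images.

Real images are mapped from [0, 1] to the generator's tanh range [-1, 1]
for discriminator input, and synthetic rasters are mapped back to [0, 1]
when they join the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import EPS, MLP, make_optimizer
from .preprocess import ImageSample

DEFAULT_GENERATOR_WIDTHS = [512, 1024, 2048, 4096, 8192, 51076]
DEFAULT_DISCRIMINATOR_WIDTHS = [4096, 2048, 1024, 512, 256, 1]


@dataclass
class GanConfig:
    """Architecture and training hyperparameters for one GAN."""

    side: int = 226
    noise_dim: int = 100
    generator_widths: list[int] = field(
        default_factory=lambda: list(DEFAULT_GENERATOR_WIDTHS)
    )
    discriminator_widths: list[int] = field(
        default_factory=lambda: list(DEFAULT_DISCRIMINATOR_WIDTHS)
    )
    learning_rate: float = 0.001
    optimizer: str = "adamax"
    batch_size: int = 12
    epochs: int = 100
    disc_steps_per_gen_step: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")
        if any(w < 1 for w in self.generator_widths + self.discriminator_widths):
            raise ValueError("all layer widths must be >= 1")
        if self.generator_widths[-1] != self.side**2:
            raise ValueError(
                f"last generator width {self.generator_widths[-1]} must equal "
                f"side^2 = {self.side**2}"
            )
        if self.discriminator_widths[-1] != 1:
            raise ValueError("discriminator must end in a single unit")

    @classmethod
    def for_side(cls, side: int, **kwargs) -> "GanConfig":
        """A config whose generator widths are scaled down to end at side^2,
        keeping the six-layer doubling profile."""
        widths = [max(16, side**2 // 2**k) for k in range(5, 0, -1)] + [side**2]
        disc = [max(32, side**2 // 2**k) for k in range(1, 6)] + [1]
        kwargs.setdefault("generator_widths", widths)
        kwargs.setdefault("discriminator_widths", disc)
        return cls(side=side, **kwargs)


@dataclass
class GanModels:
    """Trained generator/discriminator parameter sets plus loss history."""

    config: GanConfig
    generator_params: dict
    discriminator_params: dict
    training_history: list[dict] = field(default_factory=list)


def _generator_net(config: GanConfig) -> MLP:
    return MLP([config.noise_dim] + config.generator_widths, final_activation="tanh")


def _discriminator_net(config: GanConfig) -> MLP:
    # leaky ReLU hidden units: plain ReLU discriminators can go entirely
    # dead after a few optimizer steps at small widths, stalling training
    return MLP(
        [config.side**2] + config.discriminator_widths,
        final_activation="sigmoid",
        hidden_activation="lrelu",
    )


def init_gan(config: GanConfig, rng: np.random.Generator | None = None) -> GanModels:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return GanModels(
        config=config,
        generator_params=_generator_net(config).init_params(rng),
        discriminator_params=_discriminator_net(config).init_params(rng),
    )


def generator_forward(
    z: np.ndarray, params: dict, config: GanConfig
) -> np.ndarray:
    """Map noise vector(s) to side x side raster(s) in [-1, 1]."""
    z = np.asarray(z, dtype=float)
    single = z.ndim == 1
    if single:
        z = z[None, :]
    if z.shape[1] != config.noise_dim:
        raise ValueError(
            f"noise length {z.shape[1]} != configured noise_dim {config.noise_dim}"
        )
    if not np.all(np.isfinite(z)):
        raise ValueError("noise vector must be finite")
    flat = _generator_net(config).forward(z, params)
    out = flat.reshape(-1, config.side, config.side)
    return out[0] if single else out


def discriminator_forward(
    x: np.ndarray, params: dict, config: GanConfig
) -> np.ndarray:
    """Score raster(s) as genuine, in (0, 1)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None, :, :]
    if x.shape[1:] != (config.side, config.side):
        raise ValueError(
            f"raster shape {x.shape[1:]} != ({config.side}, {config.side})"
        )
    flat = x.reshape(x.shape[0], -1)
    p = _discriminator_net(config).forward(flat, params)[:, 0]
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(p[0]) if single else p


def gan_value(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """The minimax value V(G, D) = mean log D(x) + mean log(1 - D(G(z)))."""
    d_real = np.atleast_1d(np.asarray(d_real, dtype=float))
    d_fake = np.atleast_1d(np.asarray(d_fake, dtype=float))
    for p in (d_real, d_fake):
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
    d_real = np.clip(d_real, EPS, 1.0 - EPS)
    d_fake = np.clip(d_fake, EPS, 1.0 - EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def train_gan(
    real_images: list[np.ndarray] | np.ndarray, config: GanConfig
) -> GanModels:
    """Adversarial training on a stack of [0, 1] rasters.

    The discriminator minimizes binary cross-entropy on real-vs-generated
    batches; every ``disc_steps_per_gen_step`` discriminator updates the
    generator takes one non-saturating step. History records per-epoch mean
    discriminator loss, generator loss and the value V(G, D).
    """
    X = np.stack([np.asarray(im, dtype=float) for im in real_images])
    if X.shape[0] < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} images, got {X.shape[0]}"
        )
    if X.shape[1:] != (config.side, config.side):
        raise ValueError("image dimensions do not match config.side")
    X = X * 2.0 - 1.0  # match the generator's tanh range
    Xflat = X.reshape(X.shape[0], -1)

    rng = np.random.default_rng(config.seed)
    gnet = _generator_net(config)
    dnet = _discriminator_net(config)
    models = init_gan(config, rng)
    g_opt = make_optimizer(config.optimizer, config.learning_rate)
    d_opt = make_optimizer(config.optimizer, config.learning_rate)

    n = X.shape[0]
    bs = config.batch_size
    step = 0
    # fixed probe noise: lets the history track the generator's mean output
    z_probe = rng.uniform(-1.0, 1.0, size=(max(bs, 16), config.noise_dim))
    data_mean = float(Xflat.mean())
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses, values = [], [], []
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            real = Xflat[idx]

            # --- discriminator update ---
            z = rng.uniform(-1.0, 1.0, size=(bs, config.noise_dim))
            gcache: list = []
            fake = gnet.forward(z, models.generator_params, gcache)
            dcache_r: list = []
            p_real = np.clip(
                dnet.forward(real, models.discriminator_params, dcache_r)[:, 0],
                EPS, 1 - EPS,
            )
            dcache_f: list = []
            p_fake = np.clip(
                dnet.forward(fake, models.discriminator_params, dcache_f)[:, 0],
                EPS, 1 - EPS,
            )
            # BCE: -mean log p_real - mean log(1 - p_fake)
            d_loss = float(-np.mean(np.log(p_real)) - np.mean(np.log(1 - p_fake)))
            dout_r = (-1.0 / (p_real * bs))[:, None]
            dout_f = (1.0 / ((1 - p_fake) * bs))[:, None]
            _, grads_r = dnet.backward(dout_r, models.discriminator_params, dcache_r)
            _, grads_f = dnet.backward(dout_f, models.discriminator_params, dcache_f)
            grads = {k: grads_r[k] + grads_f[k] for k in grads_r}
            d_opt.step(models.discriminator_params, grads)
            d_losses.append(d_loss)
            values.append(gan_value(p_real, p_fake))
            step += 1

            # --- generator update (non-saturating) ---
            if step % config.disc_steps_per_gen_step == 0:
                z = rng.uniform(-1.0, 1.0, size=(bs, config.noise_dim))
                gcache = []
                fake = gnet.forward(z, models.generator_params, gcache)
                dcache: list = []
                p = np.clip(
                    dnet.forward(fake, models.discriminator_params, dcache)[:, 0],
                    EPS, 1 - EPS,
                )
                g_loss = float(-np.mean(np.log(p)))
                dout = (-1.0 / (p * bs))[:, None]
                dfake, _ = dnet.backward(dout, models.discriminator_params, dcache)
                _, g_grads = gnet.backward(dfake, models.generator_params, gcache)
                g_opt.step(models.generator_params, g_grads)
                g_losses.append(g_loss)

        gen_mean = float(gnet.forward(z_probe, models.generator_params).mean())
        models.training_history.append(
            {
                "epoch": epoch,
                "d_loss": float(np.mean(d_losses)) if d_losses else float("nan"),
                "g_loss": float(np.mean(g_losses)) if g_losses else float("nan"),
                "value": float(np.mean(values)) if values else float("nan"),
                "gen_mean": gen_mean,
                "data_mean": data_mean,
            }
        )
    return models


def sample_images(
    models: GanModels, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n synthetic rasters, rescaled from tanh range to [0, 1]."""
    z = rng.uniform(-1.0, 1.0, size=(n, models.config.noise_dim))
    out = generator_forward(z, models.generator_params, models.config)
    return (out + 1.0) / 2.0


def balance_classes(
    dataset: list[ImageSample],
    target_per_class: int,
    models: dict[str, GanModels],
    seed: int = 0,
) -> list[ImageSample]:
    """Top every class up to ``target_per_class`` images with GAN samples.

    Original samples are kept untouched; synthetic ones are flagged via a
    ``gan-<class>-<i>`` source id.
    """
    by_class: dict[str, list[ImageSample]] = {}
    for s in dataset:
        by_class.setdefault(s.label, []).append(s)
    max_count = max(len(v) for v in by_class.values())
    if target_per_class < max_count:
        raise ValueError(
            f"target_per_class={target_per_class} below existing class count "
            f"{max_count}"
        )
    rng = np.random.default_rng(seed)
    out = list(dataset)
    for label in sorted(by_class):
        deficit = target_per_class - len(by_class[label])
        if deficit == 0:
            continue
        if label not in models:
            raise ValueError(f"no trained GAN supplied for class {label!r}")
        imgs = sample_images(models[label], deficit, rng)
        for i in range(deficit):
            out.append(
                ImageSample(
                    pixels=imgs[i],
                    label=label,
                    source_id=f"gan-{label}-{i}",
                    meta={"synthetic": True},
                )
            )
    return out


def save_checkpoint(models: GanModels, path: str | Path):
    """Serialize all layer arrays plus the GanConfig as JSON metadata."""
    path = Path(path)
    arrays = {f"g_{k}": v for k, v in models.generator_params.items()}
    arrays.update({f"d_{k}": v for k, v in models.discriminator_params.items()})
    np.savez(path, **arrays)
    meta = {
        "config": asdict(models.config),
        "training_history": models.training_history,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_checkpoint(path: str | Path) -> GanModels:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    config = GanConfig(**meta["config"])
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        gen = {k[2:]: z[k] for k in z.files if k.startswith("g_")}
        dis = {k[2:]: z[k] for k in z.files if k.startswith("d_")}
    return GanModels(
        config=config,
        generator_params=gen,
        discriminator_params=dis,
        training_history=meta["training_history"],
    )
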