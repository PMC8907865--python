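"""The four networks of one slice model: encoder E, generator G and the
two discriminators Db (image realism) and Dz (latent prior).

E maps a slice to a latent code in [-1, 1]^latent_dim (tanh output, matching
the uniform latent prior); G maps the latent code concatenated with one-hot
age-bin and diagnosis conditions back to a [0, 1] slice (sigmoid output).
Db is a small convolutional classifier on slices, Dz a 3-layer MLP on
latent vectors; both end in a sigmoid probability.

Convolutions are stride-1 with 2x average pooling (encoder/Db) and 2x
nearest-neighbour upsampling (generator), which keeps the hand-written
gradients simple and avoids checkerboard artefacts.  Capacity scales with
``image_size`` so 16-32 px desk-scale experiments stay cheap.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autograd import Tensor, concat
from .nn import (Activation, AvgPool2, Conv2d, Dense, Flatten, Module,
                 Sequential, Upsample2)

__all__ = ["ModelConfig", "ModelSet", "build_models", "generate_sequence",
           "sample_latent_prior"]

N_DIAGNOSES = 4


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    image_size: int = 128
    latent_dim: int = 200
    n_age_bins: int = 10
    n_diagnoses: int = N_DIAGNOSES
    base_channels: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16 or self.image_size & (self.image_size - 1):
            raise ValueError("image_size must be a power of two >= 16")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.n_age_bins < 2:
            raise ValueError("need at least 2 age bins")

    @property
    def n_levels(self) -> int:
        """Number of pool/upsample levels between image_size and a 4x4 core."""
        return int(np.log2(self.image_size // 4))


class Encoder(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        layers: list[Module] = []
        c = 1
        for lv in range(cfg.n_levels):
            c_out = cfg.base_channels * 2 ** lv
            layers += [Conv2d(c, c_out, 3, rng), Activation("lrelu"), AvgPool2()]
            c = c_out
        layers.append(Flatten())
        self.body = Sequential(*layers)
        self.head = Dense(c * 16, cfg.latent_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.body(x)).tanh()


class Generator(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        c0 = cfg.base_channels * 2 ** (cfg.n_levels - 1)
        self.c0 = c0
        cond_dim = cfg.latent_dim + cfg.n_age_bins + cfg.n_diagnoses
        self.stem = Dense(cond_dim, c0 * 16, rng)
        layers: list[Module] = []
        c = c0
        for lv in reversed(range(cfg.n_levels)):
            c_out = cfg.base_channels * 2 ** max(lv - 1, 0)
            layers += [Upsample2(), Conv2d(c, c_out, 3, rng), Activation("lrelu")]
            c = c_out
        self.body = Sequential(*layers)
        self.out = Conv2d(c, 1, 3, rng)

    def forward(self, zc: Tensor) -> Tensor:
        """zc: (N, latent + A + n_diagnoses) conditioned latent batch."""
        h = self.stem(zc).leaky_relu(0.2).reshape(zc.shape[0], self.c0, 4, 4)
        return self.out(self.body(h)).sigmoid()


class BrainDiscriminator(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        layers: list[Module] = []
        c = 1
        for lv in range(cfg.n_levels):
            c_out = cfg.base_channels * 2 ** lv
            layers += [Conv2d(c, c_out, 3, rng), Activation("lrelu"), AvgPool2()]
            c = c_out
        layers.append(Flatten())
        self.body = Sequential(*layers)
        self.head = Dense(c * 16, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.body(x)).sigmoid()


class LatentDiscriminator(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator, hidden: int = 64):
        self.net = Sequential(
            Dense(cfg.latent_dim, hidden, rng), Activation("lrelu"),
            Dense(hidden, hidden, rng), Activation("lrelu"),
            Dense(hidden, 1, rng))

    def forward(self, z: Tensor) -> Tensor:
        return self.net(z).sigmoid()


@dataclasses.dataclass
class ModelSet:
    config: ModelConfig
    encoder: Encoder
    generator: Generator
    db: BrainDiscriminator
    dz: LatentDiscriminator

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for tag, net in self.named_nets():
            for k, v in net.state_dict().items():
                out[f"{tag}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for tag, net in self.named_nets():
            prefix = tag + "."
            net.load_state_dict({k[len(prefix):]: v for k, v in state.items()
                                 if k.startswith(prefix)})

    def named_nets(self):
        return [("E", self.encoder), ("G", self.generator),
                ("Db", self.db), ("Dz", self.dz)]


def build_models(config: ModelConfig) -> ModelSet:
    """Seeded construction of E, G, Db, Dz."""
    rng = np.random.default_rng(config.seed)
    return ModelSet(config,
                    Encoder(config, rng),
                    Generator(config, rng),
                    BrainDiscriminator(config, rng),
                    LatentDiscriminator(config, rng))


def condition(z: Tensor, a: int, d: int, cfg: ModelConfig) -> Tensor:
    """Concatenate one-hot age-bin and diagnosis codes to a latent batch."""
    n = z.shape[0]
    onehot = np.zeros((n, cfg.n_age_bins + cfg.n_diagnoses))
    onehot[:, a] = 1.0
    onehot[:, cfg.n_age_bins + d] = 1.0
    return concat([z, Tensor(onehot)], axis=1)


def generate_full_sequence(models: ModelSet, z: Tensor, d) -> Tensor:
    """Generate all A time points for a latent batch in one forward pass.

    ``d`` is a scalar diagnosis or per-sample array.  Returns a Tensor of
    shape (N, A, H, W): one row of A conditioned outputs per input.
    """
    cfg = models.config
    n = z.shape[0]
    d_arr = np.broadcast_to(np.asarray(d, dtype=int), (n,))
    blocks = []
    for i in range(cfg.n_age_bins):
        onehot = np.zeros((n, cfg.n_age_bins + cfg.n_diagnoses))
        onehot[:, i] = 1.0
        onehot[np.arange(n), cfg.n_age_bins + d_arr] = 1.0
        blocks.append(concat([z, Tensor(onehot)], axis=1))
    zc = concat(blocks, axis=0)               # (A*N, latent+A+4), i-major
    out = models.generator(zc)                # (A*N, 1, H, W)
    return out.reshape(cfg.n_age_bins, n, cfg.image_size,
                       cfg.image_size)        # indexed [i, sample]


def generate_sequence(models: ModelSet, x_slice: np.ndarray, d: int) -> np.ndarray:
    """A-length generated sequence for one input slice, shape (A, H, W).

    All outputs come from the same latent code E(x) and differ only in the
    age-bin condition.  Deterministic for fixed weights and input.
    """
    cfg = models.config
    if x_slice.shape != (cfg.image_size, cfg.image_size):
        raise ValueError(f"slice shape {x_slice.shape} != "
                         f"({cfg.image_size}, {cfg.image_size})")
    if d not in range(cfg.n_diagnoses):
        raise ValueError(f"diagnosis must be 0..{cfg.n_diagnoses - 1}")
    x = Tensor(x_slice[None, None])
    z = models.encoder(x)
    seq = generate_full_sequence(models, z, d)
    return seq.data[:, 0]


def sample_latent_prior(rng: np.random.Generator, n: int,
                        latent_dim: int) -> np.ndarray:
    """Uniform prior U on [-1, 1]^latent_dim."""
    return rng.uniform(-1.0, 1.0, size=(n, latent_dim))
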