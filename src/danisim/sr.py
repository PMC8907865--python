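"""Same-grid 3D super-resolution (restoration) stage.

The cross-slice Gaussian smoothing that keeps the slice models spatially
coherent also blurs anatomical detail.  This stage learns to undo that:
a small densely connected 3D convolutional network with a residual output
head is trained on (LR, HR) volume pairs where HR is a preprocessed
training scan and LR is the model's own reconstruction of that scan at its
true age (slice-smoothed, super-resolution disabled).  No upsampling is
involved — input and output share the grid.

The final convolution is zero-initialized, so the untrained network is the
identity map; training is patch-based to keep memory flat.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor, concat
from .nets import generate_full_sequence
from .nn import Adam, Conv3d, Module
from .prep import SliceStack
from .train import ProgressionModel, smooth_slices

__all__ = ["SRConfig", "SRPair", "SRNet", "make_pairs", "train_sr", "apply_sr"]


@dataclasses.dataclass(frozen=True)
class SRConfig:
    channels: int = 8
    n_dense_layers: int = 3
    kernel: int = 3
    epochs: int = 20
    patch_size: int = 8
    patches_per_pair: int = 8
    lr: float = 1e-3
    seed: int = 0


@dataclasses.dataclass
class SRPair:
    lr_volume: np.ndarray   # (T, H, W), in [0, 1]
    hr_volume: np.ndarray   # same shape

    def __post_init__(self):
        if self.lr_volume.shape != self.hr_volume.shape:
            raise ValueError("LR and HR volumes must share a shape")


class SRNet(Module):
    """Dense block of 3D convs; each layer sees all previous feature maps."""

    def __init__(self, config: SRConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.convs = []
        c_in = 1
        for _ in range(config.n_dense_layers):
            self.convs.append(Conv3d(c_in, config.channels, config.kernel, rng))
            c_in += config.channels
        self.final = Conv3d(c_in, 1, config.kernel, rng)
        self.final.weight.data[...] = 0.0   # residual head: identity at init
        self.final.bias.data[...] = 0.0

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 1, D, H, W) -> same shape, residual output."""
        feats = x
        for conv in self.convs:
            feats = concat([feats, conv(feats).leaky_relu(0.2)], axis=1)
        return x + self.final(feats)


def make_pairs(model: ProgressionModel,
               stacks: list[tuple[SliceStack, int]]) -> list[SRPair]:
    """LR/HR training pairs from the trained progression model.

    ``stacks`` holds (preprocessed scan, diagnosis) entries.  HR is the
    normalized input stack; LR is the model's reconstruction of the scan at
    its own age bin, Gaussian-smoothed across slices.  One pair per scan.
    """
    if not model.models:
        raise ValueError("progression model has no trained slice models")
    pairs = []
    for stack, d in stacks:
        a = model.binning.bin_index(stack.age)
        recon = np.empty_like(stack.slices)
        for pos, n in enumerate(stack.slice_indices):
            ms = model.models[int(n)]
            z = ms.encoder(Tensor(stack.slices[pos][None, None]))
            seq = generate_full_sequence(ms, z, 0 * np.array([d]) + d)
            recon[pos] = seq.data[a, 0]
        recon = smooth_slices(recon, model.train_config.smoothing_sigma,
                              model.train_config.smoothing_half_width)
        pairs.append(SRPair(lr_volume=recon, hr_volume=stack.slices.copy()))
    return pairs


def _sample_patches(pairs: list[SRPair], config: SRConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    p = config.patch_size
    lrs, hrs = [], []
    for pair in pairs:
        d, h, w = pair.lr_volume.shape
        pd_, ph, pw = min(p, d), min(p, h), min(p, w)
        for _ in range(config.patches_per_pair):
            z0 = rng.integers(0, d - pd_ + 1)
            y0 = rng.integers(0, h - ph + 1)
            x0 = rng.integers(0, w - pw + 1)
            sl = (slice(z0, z0 + pd_), slice(y0, y0 + ph), slice(x0, x0 + pw))
            lrs.append(pair.lr_volume[sl])
            hrs.append(pair.hr_volume[sl])
    return np.stack(lrs)[:, None], np.stack(hrs)[:, None]


def train_sr(pairs: list[SRPair],
             config: SRConfig = SRConfig()) -> tuple[SRNet, pd.DataFrame]:
    """Patch-based MSE training of the restoration net; returns net + loss log."""
    if not pairs:
        raise ValueError("no SR training pairs supplied")
    net = SRNet(config)
    opt = Adam(net.parameters(), lr=config.lr, beta1=0.9)
    rng = np.random.default_rng(config.seed)
    rows = []
    for epoch in range(config.epochs):
        lr_b, hr_b = _sample_patches(pairs, config, rng)
        out = net(Tensor(lr_b))
        diff = out - hr_b
        loss = (diff * diff).mean()
        net.zero_grad()
        loss.backward()
        opt.step()
        rows.append({"epoch": epoch, "mse": loss.item()})
    return net, pd.DataFrame(rows)


def apply_sr(net: SRNet, volume: np.ndarray) -> np.ndarray:
    """Restore one (T, H, W) volume; same shape, clipped to [0, 1]."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    out = net(Tensor(volume[None, None])).data[0, 0]
    return np.clip(out, 0.0, 1.0)


def save_sr(net: SRNet, path: str | Path) -> None:
    state = net.state_dict()
    cfg = json.dumps(dataclasses.asdict(net.config))
    np.savez(path, __config__=np.array([cfg]),
             **{f"p.{k}": v for k, v in state.items()})


def load_sr(path: str | Path) -> SRNet:
    with np.load(path, allow_pickle=False) as zf:
        cfg = json.loads(str(zf["__config__"][0]))
        net = SRNet(SRConfig(**cfg))
        net.load_state_dict({k[2:]: zf[k] for k in zf.files if k.startswith("p.")})
    return net
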