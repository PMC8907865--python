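"""Slice-wise adversarial training with PWF weighting and 3D consistency.

Each of the T axial slice positions gets its own model set (E, G, Db, Dz),
all started from a common initialization (a model pre-trained for a small
number of iterations on the central slices) and trained with the same
PWF-scheduled loss weights.  Per mini-batch the update order is: Db step,
Dz step, then a joint E+G step on the weighted total loss.  Discriminators
are trained on their plain cross-entropies; the PWF weights scale the
generator/encoder-side terms and the logged total.

Spatial coherence across the independently trained slice models is
maintained at inference by a Gaussian-weighted average over the +-2
nearest-neighbour slices (sigma = 1.5 slice units), renormalized at the
stack boundary.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor
from .losses import LossBundle, bce, loss_reg, loss_total, loss_vox
from .nets import (ModelConfig, ModelSet, build_models, generate_full_sequence,
                   sample_latent_prior)
from .nn import Adam
from .prep import AgeBinning, RegionSet
from .pwf import PWFParams, pwf_weights
from .regional import RegressorBank

__all__ = ["TrainConfig", "SliceDataset", "ProgressionModel",
           "TrainingDivergenceError", "common_init", "train_slice_model",
           "train_all", "smooth_slices"]


class TrainingDivergenceError(RuntimeError):
    """Raised when the total loss becomes non-finite; carries the last good state."""

    def __init__(self, msg: str, last_state: dict[str, np.ndarray]):
        super().__init__(msg)
        self.last_state = last_state


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 300
    batch_size: int = 100
    lr: float = 2e-4            # ADAM alpha
    beta1: float = 0.5          # ADAM beta1
    common_init_iters: int = 100
    smoothing_sigma: float = 1.5      # slice units
    smoothing_half_width: int = 2     # +- neighbour slices
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.smoothing_sigma <= 0:
            raise ValueError("smoothing sigma must be positive")
        if self.common_init_iters < 0:
            raise ValueError("common_init_iters must be >= 0")


@dataclasses.dataclass
class SliceDataset:
    """Training triples (X, theta, d) for one slice position."""
    x: np.ndarray      # (N, H, W) normalized slices
    ages: np.ndarray   # (N,) years
    dx: np.ndarray     # (N,) diagnosis codes 0-3

    def __post_init__(self):
        if not (len(self.x) == len(self.ages) == len(self.dx)):
            raise ValueError("x, ages and dx must have equal length")
        if len(self.x) == 0:
            raise ValueError("empty slice dataset")

    def __len__(self) -> int:
        return len(self.x)


def _slice_seed(seed: int, n: int) -> int:
    return int((seed * 1_000_003 + 7919 * (n + 1)) % (2 ** 31))


def _make_optimizers(models: ModelSet, cfg: TrainConfig) -> dict[str, Adam]:
    kw = dict(lr=cfg.lr, beta1=cfg.beta1)
    return {
        "eg": Adam(models.encoder.parameters() + models.generator.parameters(), **kw),
        "db": Adam(models.db.parameters(), **kw),
        "dz": Adam(models.dz.parameters(), **kw),
    }


def _zero_all(models: ModelSet) -> None:
    for _, net in models.named_nets():
        net.zero_grad()


def _train_step(models: ModelSet, opts: dict[str, Adam], x: np.ndarray,
                ages: np.ndarray, dx: np.ndarray, weights: dict[str, float],
                binning: AgeBinning, region_set: RegionSet | None,
                regressors, rng: np.random.Generator) -> LossBundle:
    """One mini-batch update (Db, Dz, then joint E+G); returns the loss bundle."""
    cfg = models.config
    nb = len(x)
    a_idx = np.array([binning.bin_index(t) for t in ages])
    x_t = Tensor(x[:, None])                      # (B, 1, H, W)

    # --- forward through E and G for all A time points -----------------------
    z = models.encoder(x_t)                       # (B, latent)
    seq = generate_full_sequence(models, z, dx)   # (A, B, H, W)
    own = seq.data[a_idx, np.arange(nb)]          # (B, H, W) at own age bin

    # --- discriminator updates on detached outputs ---------------------------
    real_p = models.db(x_t)
    fake_p = models.db(Tensor(own[:, None]))
    l_db = bce(real_p, 1.0) + bce(fake_p, 0.0)
    _zero_all(models)
    l_db.backward()
    opts["db"].step()

    prior = Tensor(sample_latent_prior(rng, nb, cfg.latent_dim))
    l_dz = bce(models.dz(prior), 1.0) + bce(models.dz(Tensor(z.data)), 0.0)
    _zero_all(models)
    l_dz.backward()
    opts["dz"].step()

    # --- joint E+G step on the weighted total --------------------------------
    mu = np.exp(-((ages[:, None] - binning.centers[None, :]) ** 2)
                / (2.0 * binning.sigmas[None, :] ** 2))       # (B, A)
    diff = seq - x[None]                                       # (A, B, H, W)
    per = (diff * diff).mean(axis=(2, 3))                      # (A, B)
    l_rec = (per * mu.T).sum(axis=0).mean()

    vox_terms = []
    reg_terms = []
    for b in range(nb):
        g_list = [seq[i, b] for i in range(cfg.n_age_bins)]
        vox_terms.append(loss_vox(g_list, int(a_idx[b])))
        if region_set is not None:
            reg_terms.append(loss_reg(g_list, int(a_idx[b]), int(dx[b]),
                                      region_set, regressors, binning.centers))
    l_vox = _mean_terms(vox_terms)
    l_reg = _mean_terms(reg_terms) if reg_terms else Tensor(0.0)

    g_term = bce(models.db(_seq_at_own(seq, a_idx)), 1.0)
    e_term = bce(models.dz(z), 1.0)

    objective = (weights["rec"] * l_rec + weights["vox"] * l_vox
                 + weights["reg"] * l_reg + weights["b"] * g_term
                 + weights["z"] * e_term)
    if not np.isfinite(objective.data):
        raise FloatingPointError("non-finite training objective")
    _zero_all(models)
    objective.backward()
    opts["eg"].step()
    _zero_all(models)

    return LossBundle(rec=_f(l_rec), vox=_f(l_vox), reg=_f(l_reg),
                      db=_f(l_db), dz=_f(l_dz))


def _seq_at_own(seq: Tensor, a_idx: np.ndarray) -> Tensor:
    """Differentiable gather of each sample's own-bin output, (B, 1, H, W)."""
    nb = len(a_idx)
    sel = seq[a_idx, np.arange(nb)]
    return sel.reshape(nb, 1, *sel.shape[1:])


def _mean_terms(terms: list) -> Tensor:
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


def _f(x) -> float:
    return x.item() if isinstance(x, Tensor) else float(x)


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def common_init(data: SliceDataset, binning: AgeBinning,
                model_config: ModelConfig, train_config: TrainConfig,
                pwf_params: PWFParams, region_set: RegionSet | None = None,
                regressors=None, iters: int | None = None) -> dict[str, np.ndarray]:
    """Shared initial weights: a short pre-training run on central-slice data.

    With ``iters == 0`` the seeded random initialization is returned
    unchanged.  The returned state dict initializes every slice model.
    """
    if len(data) == 0:
        raise ValueError("common_init needs a non-empty dataset")
    iters = train_config.common_init_iters if iters is None else iters
    models = build_models(model_config)
    if iters == 0:
        return models.state_dict()
    opts = _make_optimizers(models, train_config)
    rng = np.random.default_rng(_slice_seed(train_config.seed, -1))
    weights = pwf_weights(pwf_params, 0)
    done = 0
    while done < iters:
        for idx in _iterate_batches(len(data), train_config.batch_size, rng):
            if done >= iters:
                break
            _train_step(models, opts, data.x[idx], data.ages[idx], data.dx[idx],
                        weights, binning, region_set, regressors, rng)
            done += 1
    return models.state_dict()


def train_slice_model(n: int, data: SliceDataset,
                      shared_init: dict[str, np.ndarray] | None,
                      pwf_params: PWFParams, bank: RegressorBank | None,
                      region_set: RegionSet | None, binning: AgeBinning,
                      model_config: ModelConfig,
                      train_config: TrainConfig) -> tuple[ModelSet, pd.DataFrame]:
    """Train the slice-``n`` model; returns it with a per-epoch loss log."""
    models = build_models(model_config)
    if shared_init is not None:
        models.load_state_dict(shared_init)
    regressors = bank.for_slice(n) if bank is not None and region_set is not None \
        else None
    if region_set is not None and regressors is not None \
            and len(regressors) != region_set.n_regions:
        raise ValueError(f"slice {n}: regressor bank does not cover the region set")
    opts = _make_optimizers(models, train_config)
    rng = np.random.default_rng(_slice_seed(train_config.seed, n))
    rows = []
    last_state = models.state_dict()
    for epoch in range(train_config.epochs):
        weights = pwf_weights(pwf_params, epoch)
        bundles = []
        for idx in _iterate_batches(len(data), train_config.batch_size, rng):
            try:
                bundles.append(_train_step(
                    models, opts, data.x[idx], data.ages[idx], data.dx[idx],
                    weights, binning, region_set, regressors, rng))
            except FloatingPointError as err:
                raise TrainingDivergenceError(
                    f"slice {n}, epoch {epoch}: {err}", last_state) from err
        mean = LossBundle(*[float(np.mean([getattr(b, f) for b in bundles]))
                            for f in ("rec", "vox", "reg", "db", "dz")])
        rows.append({"epoch": epoch, "slice": n, "L_rec": mean.rec,
                     "L_vox": mean.vox, "L_reg": mean.reg, "L_Db": mean.db,
                     "L_Dz": mean.dz, "L_tot": loss_total(mean, weights),
                     **{f"w_{k}": v for k, v in weights.items()}})
        last_state = models.state_dict()
    return models, pd.DataFrame(rows)


@dataclasses.dataclass
class ProgressionModel:
    """T trained slice models plus everything needed to simulate."""
    model_config: ModelConfig
    train_config: TrainConfig
    pwf_params: PWFParams
    binning: AgeBinning
    models: dict[int, ModelSet]          # slice index -> trained nets
    logs: dict[int, pd.DataFrame]
    bank: RegressorBank | None = None
    region_sets: dict[int, RegionSet] | None = None

    @property
    def slice_indices(self) -> list[int]:
        return sorted(self.models)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for n, ms in self.models.items():
            sub = directory / f"slice_{n:03d}"
            sub.mkdir(exist_ok=True)
            np.savez(sub / "checkpoint.npz", **ms.state_dict())
            self.logs[n].to_csv(sub / "losses.csv", index=False)
        meta = {
            "model_config": dataclasses.asdict(self.model_config),
            "train_config": dataclasses.asdict(self.train_config),
            "pwf": {"shapes": self.pwf_params.shapes,
                    "directions": self.pwf_params.directions,
                    "rho": self.pwf_params.rho, "v": self.pwf_params.v},
            "binning": {"edges": self.binning.edges.tolist(),
                        "centers": self.binning.centers.tolist(),
                        "deltas": self.binning.deltas.tolist(),
                        "sigmas": self.binning.sigmas.tolist(),
                        "c": self.binning.c},
            "slices": self.slice_indices,
        }
        (directory / "meta.json").write_text(json.dumps(meta))
        if self.bank is not None:
            self.bank.save(directory / "lr_bank.json")

    @classmethod
    def load(cls, directory: str | Path) -> "ProgressionModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        mc = ModelConfig(**meta["model_config"])
        tc = TrainConfig(**meta["train_config"])
        pwf = PWFParams(shapes=meta["pwf"]["shapes"],
                        directions={k: int(v) for k, v in
                                    meta["pwf"]["directions"].items()},
                        rho=meta["pwf"]["rho"], v=meta["pwf"]["v"])
        b = meta["binning"]
        binning = AgeBinning(np.asarray(b["edges"]), np.asarray(b["centers"]),
                             np.asarray(b["deltas"]), np.asarray(b["sigmas"]),
                             b["c"])
        models, logs = {}, {}
        for n in meta["slices"]:
            sub = directory / f"slice_{n:03d}"
            ms = build_models(mc)
            with np.load(sub / "checkpoint.npz") as zf:
                ms.load_state_dict(dict(zf))
            models[n] = ms
            logs[n] = pd.read_csv(sub / "losses.csv")
        bank_path = directory / "lr_bank.json"
        bank = RegressorBank.load(bank_path) if bank_path.exists() else None
        return cls(mc, tc, pwf, binning, models, logs, bank=bank)


def train_all(slice_data: dict[int, SliceDataset],
              region_sets: dict[int, RegionSet] | None,
              bank: RegressorBank | None, binning: AgeBinning,
              model_config: ModelConfig, train_config: TrainConfig,
              pwf_params: PWFParams,
              shared_init: dict[str, np.ndarray] | None = None) -> ProgressionModel:
    """Train every slice model from a shared initialization.

    Slice models are independent given ``shared_init`` (they may be trained
    concurrently by any scheduler); this implementation runs them
    sequentially with per-slice seeds.
    """
    if not slice_data:
        raise ValueError("no slice datasets supplied")
    if shared_init is None and train_config.common_init_iters > 0:
        central = sorted(slice_data)[len(slice_data) // 2]
        rset = region_sets.get(central) if region_sets else None
        regs = bank.for_slice(central) if bank is not None and rset is not None else None
        shared_init = common_init(slice_data[central], binning, model_config,
                                  train_config, pwf_params, rset, regs)
    models, logs = {}, {}
    for n in sorted(slice_data):
        rset = region_sets.get(n) if region_sets else None
        ms, log = train_slice_model(n, slice_data[n], shared_init, pwf_params,
                                    bank, rset, binning, model_config,
                                    train_config)
        models[n] = ms
        logs[n] = log
    return ProgressionModel(model_config, train_config, pwf_params, binning,
                            models, logs, bank=bank, region_sets=region_sets)


def smoothing_weights(sigma: float = 1.5, half_width: int = 2) -> np.ndarray:
    """Unnormalized Gaussian neighbour weights w_k, k = -half_width..half_width."""
    k = np.arange(-half_width, half_width + 1)
    return np.exp(-(k ** 2) / (2.0 * sigma ** 2))


def smooth_slices(stack: np.ndarray, sigma: float = 1.5,
                  half_width: int = 2) -> np.ndarray:
    """Gaussian-weighted average over neighbouring slices of a (T, ...) stack.

    Weights are renormalized over the in-range neighbours at the stack
    boundary, so a constant stack is reproduced exactly.
    """
    stack = np.asarray(stack, dtype=np.float64)
    t = stack.shape[0]
    if t < 1:
        raise ValueError("empty slice stack")
    w = smoothing_weights(sigma, half_width)
    out = np.zeros_like(stack)
    for n in range(t):
        ks = [k for k in range(-half_width, half_width + 1) if 0 <= n + k < t]
        ws = np.array([w[k + half_width] for k in ks])
        ws = ws / ws.sum()
        for k, wk in zip(ks, ws):
            out[n] += wk * stack[n + k]
    return out
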