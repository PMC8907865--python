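"""Personalization and 4D sequence synthesis.

Starting from a single baseline scan, every slice model is fine-tuned for a
short number of iterations on that one scan (transfer learning with all
losses active at the final-epoch PWF weights; the super-resolution net is
frozen).  Simulation then encodes each slice once and generates the full
A-point age sequence, smooths across slices, applies super-resolution, and
inverts the per-slice normalization so the output lives in the input's
intensity range.  Intermediate ages are obtained by linear interpolation
between the two nearest bin-centre volumes.
"""

from __future__ import annotations

import copy
import dataclasses

import numpy as np

from .autograd import Tensor
from .nets import build_models, generate_full_sequence
from .nn import Adam
from .prep import normalize_slices
from .pwf import pwf_weights
from .sr import SRNet, apply_sr
from .train import (ProgressionModel, SliceDataset, _make_optimizers,
                    _train_step, smooth_slices)

__all__ = ["SimulationResult", "personalize", "simulate_sequence",
           "interpolate_age"]


@dataclasses.dataclass
class SimulationResult:
    subject_id: str
    baseline_age: float
    diagnosis: int
    volumes: list[np.ndarray]   # A volumes, input shape, de-normalized
    bin_ages: np.ndarray        # ascending bin centres m_i

    def __post_init__(self):
        if len(self.volumes) != len(self.bin_ages):
            raise ValueError("one volume per age bin required")
        if any(v.shape != self.volumes[0].shape for v in self.volumes):
            raise ValueError("simulated volumes must share a shape")
        if np.any(np.diff(self.bin_ages) <= 0):
            raise ValueError("bin ages must ascend")


def _clone(model: ProgressionModel) -> ProgressionModel:
    clone_models = {}
    for n, ms in model.models.items():
        fresh = build_models(model.model_config)
        fresh.load_state_dict(ms.state_dict())
        clone_models[n] = fresh
    return ProgressionModel(model.model_config, model.train_config,
                            model.pwf_params, model.binning, clone_models,
                            dict(model.logs), bank=model.bank,
                            region_sets=model.region_sets)


def personalize(model: ProgressionModel, baseline_volume: np.ndarray,
                age: float, d: int, iters: int = 50) -> ProgressionModel:
    """Fine-tune all slice-model parameters on one baseline scan.

    Runs ``iters`` extra training iterations per slice on the single input
    slice, with all losses active and the PWF weights fixed at their
    final-epoch values.  The input model is left untouched (a personalized
    copy is returned); the super-resolution stage holds no parameters here
    and is frozen by construction.  ``iters=0`` returns an identical copy.
    """
    if not model.models:
        raise ValueError("cannot personalize an untrained model")
    tuned = _clone(model)
    if iters == 0:
        return tuned
    t_final = model.train_config.epochs - 1
    weights = pwf_weights(model.pwf_params, t_final)
    stack = normalize_slices(baseline_volume, len(model.slice_indices))
    for pos, n in enumerate(tuned.slice_indices):
        ms = tuned.models[n]
        data = SliceDataset(x=stack.slices[pos][None],
                            ages=np.array([age]), dx=np.array([d]))
        opts = _make_optimizers(ms, model.train_config)
        rng = np.random.default_rng((model.train_config.seed + 104729 * (n + 1))
                                    % 2 ** 31)
        rset = model.region_sets.get(n) if model.region_sets else None
        regs = model.bank.for_slice(n) if model.bank is not None and rset is not None \
            else None
        for _ in range(iters):
            _train_step(ms, opts, data.x, data.ages, data.dx, weights,
                        model.binning, rset, regs, rng)
    return tuned


def simulate_sequence(model: ProgressionModel, baseline_volume: np.ndarray,
                      age: float, d: int, subject_id: str = "",
                      sr_net: SRNet | None = None) -> SimulationResult:
    """Synthesize the A-point image sequence from one baseline volume.

    Per slice: normalize, encode once, generate the A conditioned outputs;
    then smooth across slices, apply super-resolution (when supplied) and
    invert the stored normalization.  Axial slices not covered by the model
    keep their baseline content.
    """
    cfg = model.model_config
    t = len(model.slice_indices)
    stack = normalize_slices(baseline_volume, t)
    if stack.slices.shape[1:] != (cfg.image_size, cfg.image_size):
        raise ValueError(f"slice shape {stack.slices.shape[1:]} does not match "
                         f"model image size {cfg.image_size}")
    a_bins = cfg.n_age_bins
    raw = np.empty((a_bins, t) + stack.slices.shape[1:])
    for pos, n in enumerate(model.slice_indices):
        ms = model.models[n]
        z = ms.encoder(Tensor(stack.slices[pos][None, None]))
        seq = generate_full_sequence(ms, z, np.array([d]))
        raw[:, pos] = seq.data[:, 0]

    volumes = []
    for i in range(a_bins):
        smoothed = smooth_slices(raw[i], model.train_config.smoothing_sigma,
                                 model.train_config.smoothing_half_width)
        if sr_net is not None:
            smoothed = apply_sr(sr_net, smoothed)
        out = baseline_volume.astype(np.float64).copy()
        for pos, n in enumerate(stack.slice_indices):
            out[:, :, n] = stack.norm_records[pos].invert(smoothed[pos])
        volumes.append(out)
    return SimulationResult(subject_id, float(age), int(d), volumes,
                            np.asarray(model.binning.centers, dtype=float))


def interpolate_age(result: SimulationResult, age: float) -> np.ndarray:
    """Volume at an intermediate age by linear interpolation of the two
    bracketing bin-centre volumes: Y = (1-lam) Y_i + lam Y_{i+1}."""
    m = result.bin_ages
    if age < m[0] or age > m[-1]:
        raise ValueError(f"age {age} outside simulated range [{m[0]}, {m[-1]}]")
    j = int(np.searchsorted(m, age, side="right"))
    if j == len(m):           # exactly the last centre
        return result.volumes[-1].copy()
    if m[j - 1] == age:
        return result.volumes[j - 1].copy()
    lam = (age - m[j - 1]) / (m[j] - m[j - 1])
    return (1.0 - lam) * result.volumes[j - 1] + lam * result.volumes[j]
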