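"""The five training losses and their weighted total.

All losses operate on [0, 1]-normalized slices.  Every function accepts
either plain numpy arrays (returning floats, used by tests and logging) or
autograd :class:`~danisim.autograd.Tensor` inputs (returning a Tensor node,
used during training).  L2 distance means mean squared error over pixels,
so loss magnitudes are comparable across image sizes.

* reconstruction: membership-weighted MSE between the input slice and each
  generated time point, weighting nearer age bins more heavily;
* voxel monotonicity: the generated slice at the subject's own age bin must
  not exceed the element-wise minimum of earlier outputs nor fall below the
  element-wise maximum of later outputs (intensity is a proxy for tissue
  density and must not increase with age);
* regional progression: size-weighted squared deviation between the
  regional intensity ratios of the generated sequence and the ratios
  predicted by the per-region regressors;
* two adversarial cross-entropies (image realism via Db, latent prior
  matching via Dz), in the standard non-saturating GAN form.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autograd import Tensor, maximum, minimum
from .prep import RegionSet
from .regional import EPSILON, RegionalRegressor

__all__ = ["LossBundle", "loss_rec", "loss_vox", "loss_reg",
           "loss_adv_brain", "loss_adv_latent", "loss_total", "bce"]

_PROB_EPS = 1e-7


def _mse(a, b):
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        diff = a - b
        return (diff * diff).mean()
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.mean(diff * diff))


def _as_float(x) -> float:
    return x.item() if isinstance(x, Tensor) else float(x)


def loss_rec(x, g_seq, mu) -> "Tensor | float":
    """Membership-weighted reconstruction loss: sum_i mu_i * MSE(x, g_i).

    ``g_seq`` is the A-long generated sequence, ``mu`` the membership of
    the input's age in each of the A bins.
    """
    mu = np.asarray(mu, dtype=float)
    if len(g_seq) != len(mu):
        raise ValueError(f"sequence length {len(g_seq)} != membership count {len(mu)}")
    total = None
    for g_i, m in zip(g_seq, mu):
        term = _mse(x, g_i) * float(m)
        total = term if total is None else total + term
    return total


def loss_vox(g_seq, a: int) -> "Tensor | float":
    """Voxel-level monotone-intensity loss at (0-based) own-bin index ``a``.

    0.5 * [MSE(g_a, elementwise-min of earlier) + MSE(g_a, elementwise-max
    of later)]; a boundary bin keeps only the defined term at full weight.
    """
    n = len(g_seq)
    if not 0 <= a < n:
        raise IndexError(f"bin index {a} out of range 0..{n - 1}")
    terms = []
    if a > 0:
        lo = g_seq[0]
        for g in g_seq[1:a]:
            lo = minimum(lo, g) if isinstance(lo, Tensor) or isinstance(g, Tensor) \
                else np.minimum(lo, g)
        terms.append(_mse(g_seq[a], lo))
    if a < n - 1:
        hi = g_seq[a + 1]
        for g in g_seq[a + 2:]:
            hi = maximum(hi, g) if isinstance(hi, Tensor) or isinstance(g, Tensor) \
                else np.maximum(hi, g)
        terms.append(_mse(g_seq[a], hi))
    if not terms:
        return 0.0
    if len(terms) == 1:
        return terms[0]
    return (terms[0] + terms[1]) * 0.5


def loss_reg(g_seq, a: int, d: int, region_set: RegionSet,
             regressors: list[RegionalRegressor], bin_ages,
             eps: float = EPSILON) -> "Tensor | float":
    """Region-level progression loss against the regressor predictions.

    For each region q and each other time point o, compares the predicted
    ratio LR(m_min, m_max, d) with the generated later/earlier intensity
    ratio, squared and weighted by the region size s_q; normalized by
    R * (A - 1).
    """
    n_time = len(g_seq)
    bin_ages = np.asarray(bin_ages, dtype=float)
    if len(bin_ages) != n_time:
        raise ValueError("need one bin age per time point")
    if len(regressors) != region_set.n_regions:
        raise ValueError(f"regressor count {len(regressors)} != region count "
                         f"{region_set.n_regions}")
    if not 0 <= a < n_time:
        raise IndexError(f"bin index {a} out of range")
    sizes = region_set.sizes
    total = None
    for q, (mask, s_q) in enumerate(zip(region_set.masks, sizes)):
        lr = regressors[q]
        sums = []
        for g in g_seq:
            if isinstance(g, Tensor):
                sums.append((g * mask.astype(float)).sum() + eps)
            else:
                sums.append(float(np.asarray(g)[mask].sum()) + eps)
        for o in range(n_time):
            if o == a:
                continue
            if o < a:
                pred = lr.predict(bin_ages[o], bin_ages[a], d)
                ratio = sums[a] / sums[o]
            else:
                pred = lr.predict(bin_ages[a], bin_ages[o], d)
                ratio = sums[o] / sums[a]
            dev = pred - ratio
            term = dev * dev * float(s_q)
            total = term if total is None else total + term
    norm = 1.0 / (region_set.n_regions * (n_time - 1))
    return total * norm


def bce(probs, target: float) -> "Tensor | float":
    """Mean binary cross-entropy of probabilities against a constant target."""
    if isinstance(probs, Tensor):
        p = probs.clip(_PROB_EPS, 1.0 - _PROB_EPS)
        if target == 1.0:
            return -(p.log().mean())
        return -((1.0 - p).log().mean())
    p = np.clip(np.asarray(probs, dtype=float), _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-np.mean(np.log(p if target == 1.0 else 1.0 - p)))


def loss_adv_brain(db, real_batch, fake_batch):
    """Image-realism adversarial pair.

    Returns ``(discriminator loss, generator term)``: the discriminator is
    trained to score real slices 1 and generated slices 0; the generator
    term is the non-saturating BCE pushing fake scores towards 1.
    """
    if _batch_len(real_batch) == 0 or _batch_len(fake_batch) == 0:
        raise ValueError("adversarial losses need non-empty batches")
    d_loss = bce(db(real_batch), 1.0) + bce(db(fake_batch), 0.0)
    g_term = bce(db(fake_batch), 1.0)
    return d_loss, g_term


def loss_adv_latent(dz, z_prior_batch, z_encoded_batch):
    """Latent-prior adversarial pair: prior samples are 'real', encodings 'fake'."""
    if _batch_len(z_prior_batch) == 0 or _batch_len(z_encoded_batch) == 0:
        raise ValueError("adversarial losses need non-empty batches")
    d_loss = bce(dz(z_prior_batch), 1.0) + bce(dz(z_encoded_batch), 0.0)
    e_term = bce(dz(z_encoded_batch), 1.0)
    return d_loss, e_term


def _batch_len(batch) -> int:
    if isinstance(batch, Tensor):
        return batch.shape[0] if batch.ndim else 0
    return len(batch)


@dataclasses.dataclass(frozen=True)
class LossBundle:
    """The five loss components (adversarial terms as cross-entropies)."""
    rec: float
    vox: float
    reg: float
    db: float
    dz: float

    def total(self, weights: dict[str, float]) -> float:
        return loss_total(self, weights)


def loss_total(bundle: LossBundle, weights: dict[str, float]) -> float:
    """Weighted total w_reg*L_reg + w_vox*L_vox + w_b*L_Db + w_z*L_Dz + w_rec*L_rec."""
    for k in ("reg", "vox", "b", "z", "rec"):
        if weights[k] < 0:
            raise ValueError(f"weight {k} must be >= 0")
    return (weights["reg"] * _as_float(bundle.reg)
            + weights["vox"] * _as_float(bundle.vox)
            + weights["b"] * _as_float(bundle.db)
            + weights["z"] * _as_float(bundle.dz)
            + weights["rec"] * _as_float(bundle.rec))
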