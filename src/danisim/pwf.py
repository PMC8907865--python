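"""Profile weight functions (PWFs): dynamic per-loss training weights.

Training a stack of slice-wise adversarial models with five competing loss
terms is unstable if every term keeps a constant weight.  The PWF strategy
gives each loss term an epoch-dependent weight following a mean-reverting
exponential

    f_l(t) = rho^t * b_l + (1 - rho^t) * b_l * v^(d_l)

so f_l(0) = b_l and f_l(t) -> b_l * v^(d_l) as t -> inf.  The direction
d_l = +-1 decides whether a loss ramps up (+1) or decays (-1) by the factor
v; rho controls how fast the schedule converges.  The default shape and
direction parameters are the published grid-search optima: reconstruction
starts dominant (b_rec = 100, descending) while the adversarial and
biological-constraint terms ramp up.

The shape/direction parameters can be re-tuned by seeded random search on a
grid against a validation criterion (typically the total loss).
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd

__all__ = ["LOSS_KEYS", "PWFParams", "pwf_value", "pwf_weights",
           "pwf_schedule", "DEFAULT_GRID", "grid_search"]

LOSS_KEYS = ("reg", "vox", "b", "z", "rec")


@dataclasses.dataclass(frozen=True)
class PWFParams:
    """Shape b_l > 0 and direction d_l in {-1, +1} per loss, plus rho and v."""
    shapes: dict[str, float] = dataclasses.field(default_factory=lambda: {
        "reg": 1.25, "vox": 1.25, "b": 0.002, "z": 0.05, "rec": 100.0})
    directions: dict[str, int] = dataclasses.field(default_factory=lambda: {
        "reg": 1, "vox": 1, "b": 1, "z": 1, "rec": -1})
    rho: float = 0.99
    v: float = 10.0

    def __post_init__(self):
        if set(self.shapes) != set(LOSS_KEYS) or set(self.directions) != set(LOSS_KEYS):
            raise ValueError(f"shapes/directions must cover exactly {LOSS_KEYS}")
        if any(b <= 0 for b in self.shapes.values()):
            raise ValueError("shape parameters must be positive")
        if any(d not in (-1, 1) for d in self.directions.values()):
            raise ValueError("directions must be -1 or +1")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if self.v <= 0:
            raise ValueError("v must be positive")


def pwf_value(params: PWFParams, loss: str, t: int) -> float:
    """Weight of ``loss`` at epoch ``t`` (t >= 0)."""
    if loss not in LOSS_KEYS:
        raise KeyError(f"unknown loss key {loss!r}; expected one of {LOSS_KEYS}")
    if t < 0:
        raise ValueError("epoch t must be >= 0")
    b = params.shapes[loss]
    asymptote = b * params.v ** params.directions[loss]
    r = params.rho ** t
    return r * b + (1.0 - r) * asymptote


def pwf_weights(params: PWFParams, t: int) -> dict[str, float]:
    """All five weights at epoch ``t``."""
    return {k: pwf_value(params, k, t) for k in LOSS_KEYS}


def pwf_schedule(params: PWFParams, n_epochs: int) -> pd.DataFrame:
    """Per-epoch weight table, one row per epoch, columns w_<loss>."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    t = np.arange(n_epochs)
    r = params.rho ** t
    cols = {}
    for k in LOSS_KEYS:
        b = params.shapes[k]
        cols[f"w_{k}"] = r * b + (1.0 - r) * b * params.v ** params.directions[k]
    return pd.DataFrame(cols, index=pd.Index(t, name="epoch"))


def _steps(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(lo + i * step for i in range(n + 1))


#: Published random-search grid: shape ranges/steps per loss plus directions.
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "b_reg": _steps(1.0, 2.0, 0.25),
    "b_vox": _steps(1.0, 2.0, 0.25),
    "b_b": _steps(0.001, 0.004, 0.001),
    "b_z": _steps(0.05, 0.10, 0.01),
    "b_rec": _steps(75.0, 175.0, 25.0),
    "d_reg": (-1, 1),
    "d_vox": (-1, 1),
    "d_b": (-1, 1),
    "d_z": (-1, 1),
    "d_rec": (-1, 1),
}


def _params_from_point(point: dict[str, float], rho: float, v: float) -> PWFParams:
    """Grid point -> PWFParams; axes missing from the grid keep defaults."""
    defaults = PWFParams()
    return PWFParams(
        shapes={k: float(point.get(f"b_{k}", defaults.shapes[k])) for k in LOSS_KEYS},
        directions={k: int(point.get(f"d_{k}", defaults.directions[k]))
                    for k in LOSS_KEYS},
        rho=rho, v=v)


def grid_search(grid: dict[str, tuple[float, ...]] | None, n_draws: int,
                eval_fn, seed: int, rho: float = 0.99,
                v: float = 10.0) -> tuple[PWFParams, pd.DataFrame]:
    """Seeded random search over the Cartesian grid of PWF parameters.

    Draws ``n_draws`` distinct grid points uniformly without replacement
    (all of them if the grid is smaller), evaluates ``eval_fn(PWFParams)``
    (lower is better, e.g. a validation total loss) and returns the best
    parameters plus the full evaluation trace.
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    keys = sorted(grid)
    sizes = [len(grid[k]) for k in keys]
    if any(s == 0 for s in sizes):
        raise ValueError("grid axes must be non-empty")
    total = math.prod(sizes)
    rng = np.random.default_rng(seed)
    if n_draws >= total:
        flat_indices = np.arange(total)
    else:
        flat_indices = rng.choice(total, size=n_draws, replace=False)
    rows = []
    best: tuple[float, PWFParams] | None = None
    for flat in flat_indices:
        multi = np.unravel_index(int(flat), sizes)
        point = {k: grid[k][i] for k, i in zip(keys, multi)}
        params = _params_from_point(point, rho, v)
        score = float(eval_fn(params))
        rows.append({**point, "score": score})
        if best is None or score < best[0]:
            best = (score, params)
    assert best is not None
    return best[1], pd.DataFrame(rows)
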