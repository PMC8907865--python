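"""Per-region intensity-progression regressors.

Each region (slice n, mask q) gets a sigmoid-link regressor LR_{n,q}
predicting the regional intensity ratio between a baseline age ``o`` and a
follow-up age ``a`` given the diagnosis code ``d``:

    ratio(o, a, d) = sigmoid(beta0 + beta1*o + beta2*(a - o) + beta3*d)

fitted by least squares on logit-transformed ratios.  Ratios are the
epsilon-regularized sums of normalized slice intensity inside the mask,

    ratio = (sum(X_a * r) + eps) / (sum(X_o * r) + eps),   eps = 0.1,

and pairs where the regional intensity increased (ratio > 1) are removed
before fitting, since tissue density is assumed monotonically
non-increasing and such pairs represent noise.  At zero age gap the
prediction is pinned to exactly 1, and all predictions are clamped to
(0, 1].
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prep import RegionSet, SliceStack

__all__ = ["EPSILON", "RegionalRegressor", "RegressorBank",
           "extract_ratio_samples", "monotone_filter", "fit_regressor",
           "fit_bank"]

EPSILON = 0.1          # intensity-sum regularizer, shared with the region loss
MIN_SAMPLES = 4        # below this, fall back to the identity regressor
_RATIO_CLIP = (1e-4, 1.0 - 1e-4)


@dataclasses.dataclass
class RegionalRegressor:
    slice_index: int
    region: int
    beta: np.ndarray          # (intercept, baseline-age, age-gap, diagnosis)
    n_samples: int
    residual_rms: float
    identity: bool = False    # True when there was too little data to fit

    def predict(self, o: float, a: float, d: int) -> float:
        """Predicted intensity ratio in (0, 1]; exactly 1 at zero age gap."""
        if a < o:
            raise ValueError(f"follow-up age {a} precedes baseline {o}")
        if a == o or self.identity:
            return 1.0
        x = np.array([1.0, o, a - o, d])
        z = float(self.beta @ x)
        return float(min(1.0, 1.0 / (1.0 + np.exp(-z))))


def extract_ratio_samples(stacks_by_subject: dict[str, list[tuple[float, int, SliceStack]]],
                          region_set: RegionSet,
                          eps: float = EPSILON) -> pd.DataFrame:
    """Regional intensity ratios for every ordered scan pair of every subject.

    ``stacks_by_subject`` maps subject id to a list of (age, diagnosis,
    SliceStack) entries.  Returns a table with columns
    (subject, o, a, d, region, ratio); ``region`` indexes masks of
    ``region_set``.  Raises ``ValueError`` if no subject has >= 2 scans.
    """
    n = region_set.slice_index
    rows = []
    for sid, entries in stacks_by_subject.items():
        entries = sorted(entries, key=lambda e: e[0])
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                age_o, d, stack_o = entries[i]
                age_a, _, stack_a = entries[j]
                pos = list(stack_o.slice_indices).index(n) if n in stack_o.slice_indices else None
                if pos is None:
                    continue
                x_o = stack_o.slices[pos]
                x_a = stack_a.slices[pos]
                for q, mask in enumerate(region_set.masks):
                    ratio = (float(x_a[mask].sum()) + eps) / (float(x_o[mask].sum()) + eps)
                    rows.append((sid, age_o, age_a, d, q, ratio))
    if not rows:
        raise ValueError("no subject has two scans covering this slice: "
                         "cannot extract longitudinal ratio samples")
    return pd.DataFrame(rows, columns=["subject", "o", "a", "d", "region", "ratio"])


def monotone_filter(samples: pd.DataFrame) -> pd.DataFrame:
    """Drop rows where regional intensity increased (ratio > 1), keeping order."""
    return samples[samples["ratio"] <= 1.0].reset_index(drop=True)


def fit_regressor(samples: pd.DataFrame, slice_index: int,
                  region: int) -> RegionalRegressor:
    """Least-squares sigmoid-link fit of ratio against (1, o, a-o, d).

    With fewer than ``MIN_SAMPLES`` rows the identity regressor
    (prediction always 1) is returned with ``identity=True``.
    """
    if len(samples) < MIN_SAMPLES:
        return RegionalRegressor(slice_index, region, np.zeros(4), len(samples),
                                 0.0, identity=True)
    o = samples["o"].to_numpy(dtype=float)
    a = samples["a"].to_numpy(dtype=float)
    d = samples["d"].to_numpy(dtype=float)
    ratio = np.clip(samples["ratio"].to_numpy(dtype=float), *_RATIO_CLIP)
    y = np.log(ratio / (1.0 - ratio))
    design = np.column_stack([np.ones_like(o), o, a - o, d])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = 1.0 / (1.0 + np.exp(-(design @ beta)))
    rms = float(np.sqrt(np.mean((pred - ratio) ** 2)))
    return RegionalRegressor(slice_index, region, beta, len(samples), rms)


class RegressorBank:
    """Regressors keyed by (slice n, region q), serializable to JSON."""

    def __init__(self):
        self._bank: dict[tuple[int, int], RegionalRegressor] = {}

    def add(self, reg: RegionalRegressor) -> None:
        self._bank[(reg.slice_index, reg.region)] = reg

    def get(self, n: int, q: int) -> RegionalRegressor:
        try:
            return self._bank[(n, q)]
        except KeyError:
            raise KeyError(f"no regressor fitted for slice {n}, region {q}") from None

    def for_slice(self, n: int) -> list[RegionalRegressor]:
        regs = sorted((k[1], v) for k, v in self._bank.items() if k[0] == n)
        return [v for _, v in regs]

    def __len__(self) -> int:
        return len(self._bank)

    def save(self, path: str | Path) -> None:
        payload = [
            {"slice": r.slice_index, "region": r.region,
             "beta": list(map(float, r.beta)), "n_samples": r.n_samples,
             "residual_rms": r.residual_rms, "identity": r.identity}
            for r in self._bank.values()
        ]
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "RegressorBank":
        bank = cls()
        for entry in json.loads(Path(path).read_text()):
            bank.add(RegionalRegressor(
                entry["slice"], entry["region"], np.asarray(entry["beta"]),
                entry["n_samples"], entry["residual_rms"], entry["identity"]))
        return bank


def fit_bank(stacks_by_subject, region_sets: list[RegionSet],
             eps: float = EPSILON) -> RegressorBank:
    """Fit one regressor per (slice, region) over all region sets."""
    bank = RegressorBank()
    for rset in region_sets:
        samples = extract_ratio_samples(stacks_by_subject, rset, eps=eps)
        samples = monotone_filter(samples)
        for q in range(rset.n_regions):
            sub = samples[samples["region"] == q]
            bank.add(fit_regressor(sub, rset.slice_index, q))
    return bank
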