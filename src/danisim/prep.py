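"""Pre-processing: slice extraction and normalization, fuzzy age binning,
and atlas-region augmentation.

Volumes are assumed to be already co-registered and skull-free (the phantom
generator emits them that way; real-data users must register/strip
upstream).  Each of the T central axial slices is standardized to zero mean
and unit standard deviation, then affinely rescaled to [0, 1]; the per-slice
normalization record is kept so the mapping can be inverted after
simulation.  Working in [0, 1] keeps the monotone-intensity and
intensity-ratio losses well defined (sums of zero-mean signals can be
negative), while the standardization step still removes scanner gain and
offset.

Ages are grouped into A equal-width bins with a fuzzy Gaussian membership
mu_i(theta) = exp(-(theta - m_i)^2 / (2 sigma_i^2)) centred on the mean age
m_i of each bin, with width sigma_i = c * delta_i proportional to the
maximum age difference delta_i inside the bin.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.morphology import dilation, disk, erosion

__all__ = ["NormRecord", "SliceStack", "AgeBinning", "RegionSet",
           "normalize_slices", "build_age_bins", "membership", "memberships",
           "build_region_set", "central_slice_indices"]


@dataclasses.dataclass(frozen=True)
class NormRecord:
    """Invertible per-slice normalization: standardize then min-max to [0,1]."""
    mean: float
    sd: float
    zmin: float
    zmax: float

    def apply(self, raw: np.ndarray) -> np.ndarray:
        z = (raw - self.mean) / self.sd
        return (z - self.zmin) / (self.zmax - self.zmin)

    def invert(self, normalized: np.ndarray) -> np.ndarray:
        z = normalized * (self.zmax - self.zmin) + self.zmin
        return z * self.sd + self.mean


@dataclasses.dataclass
class SliceStack:
    subject_id: str
    age: float
    slices: np.ndarray              # (T, H, W), each slice in [0, 1]
    norm_records: list[NormRecord]  # one per slice
    slice_indices: np.ndarray       # original axial indices in the volume

    def invert(self) -> np.ndarray:
        """Reassemble the pre-normalization slices, shape (T, H, W)."""
        return np.stack([rec.invert(s) for s, rec in
                         zip(self.slices, self.norm_records)])


def central_slice_indices(depth: int, t: int) -> np.ndarray:
    """Indices of the ``t`` central axial slices of a depth-``depth`` volume."""
    if t > depth:
        raise ValueError(f"volume depth {depth} < requested slice count {t}")
    start = (depth - t) // 2
    return np.arange(start, start + t)


def normalize_slices(volume: np.ndarray, t: int, subject_id: str = "",
                     age: float = float("nan")) -> SliceStack:
    """Extract the ``t`` central axial slices (axis 2) and normalize each.

    Raises ``ValueError`` on a constant-intensity slice (sd == 0: the
    standardization is then undefined).
    """
    idx = central_slice_indices(volume.shape[2], t)
    slices, records = [], []
    for n in idx:
        raw = np.asarray(volume[:, :, n], dtype=np.float64)
        mean, sd = float(raw.mean()), float(raw.std())
        if sd == 0.0:
            raise ValueError(f"slice {n} has constant intensity; "
                             "normalization is degenerate")
        z = (raw - mean) / sd
        rec = NormRecord(mean, sd, float(z.min()), float(z.max()))
        slices.append((z - rec.zmin) / (rec.zmax - rec.zmin))
        records.append(rec)
    return SliceStack(subject_id, age, np.stack(slices), records, idx)


@dataclasses.dataclass(frozen=True)
class AgeBinning:
    """A equal-width age bins with fuzzy Gaussian memberships."""
    edges: np.ndarray    # length A+1, strictly increasing
    centers: np.ndarray  # m_i: mean age of samples in bin i (midpoint if empty)
    deltas: np.ndarray   # delta_i: max age difference inside bin i
    sigmas: np.ndarray   # sigma_i = c * delta_i
    c: float

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def bin_index(self, age: float) -> int:
        """0-based index of the bin containing ``age`` (clipped to range)."""
        i = int(np.searchsorted(self.edges, age, side="right")) - 1
        return int(np.clip(i, 0, self.n_bins - 1))


def build_age_bins(ages, a: int, c: float = 1.0) -> AgeBinning:
    """Equal-width binning of ``ages`` into ``a`` bins.

    m_i is the empirical mean age per bin (bin midpoint when empty);
    delta_i the max-min age inside the bin (bin width with < 2 samples);
    sigma_i = c * delta_i.
    """
    ages = np.asarray(ages, dtype=np.float64)
    if a < 2:
        raise ValueError("need at least 2 age bins")
    if len(ages) < a:
        raise ValueError(f"need >= {a} ages to build {a} bins")
    lo, hi = float(ages.min()), float(ages.max())
    if hi == lo:
        raise ValueError("all ages are equal: age range is degenerate")
    if c <= 0:
        raise ValueError("membership width factor c must be positive")
    edges = np.linspace(lo, hi, a + 1)
    width = edges[1] - edges[0]
    centers = np.empty(a)
    deltas = np.empty(a)
    for i in range(a):
        if i < a - 1:
            inside = ages[(ages >= edges[i]) & (ages < edges[i + 1])]
        else:
            inside = ages[(ages >= edges[i]) & (ages <= edges[i + 1])]
        centers[i] = inside.mean() if len(inside) else (edges[i] + edges[i + 1]) / 2
        deltas[i] = (inside.max() - inside.min()) if len(inside) >= 2 else width
        if deltas[i] == 0.0:
            deltas[i] = width
    return AgeBinning(edges, centers, deltas, c * deltas, c)


def membership(binning: AgeBinning, age: float, i: int) -> float:
    """Fuzzy Gaussian membership of ``age`` in bin ``i`` (0-based), in (0, 1]."""
    if not 0 <= i < binning.n_bins:
        raise IndexError(f"bin index {i} out of range 0..{binning.n_bins - 1}")
    sigma = binning.sigmas[i]
    if sigma == 0.0:
        raise ValueError(f"bin {i} has zero membership width")
    return float(np.exp(-((age - binning.centers[i]) ** 2) / (2.0 * sigma ** 2)))


def memberships(binning: AgeBinning, age: float) -> np.ndarray:
    """Membership of ``age`` in every bin, shape (A,)."""
    return np.exp(-((age - binning.centers) ** 2) / (2.0 * binning.sigmas ** 2))


@dataclasses.dataclass
class RegionSet:
    """Fixed (possibly overlapping) binary region masks for one slice."""
    slice_index: int
    masks: list[np.ndarray]   # each (H, W) boolean
    labels: list[str]         # provenance tag, e.g. "3", "3-ero1", "3-dil1"

    @property
    def sizes(self) -> np.ndarray:
        return np.array([int(m.sum()) for m in self.masks])

    @property
    def n_regions(self) -> int:
        return len(self.masks)


def build_region_set(atlas_slice: np.ndarray, n: int,
                     radii=(1,)) -> RegionSet:
    """Base atlas regions on slice ``n`` plus eroded/dilated variants.

    For each base label one eroded and one dilated variant per radius is
    added; variants that come out empty are discarded.  Raises
    ``ValueError`` if the atlas slice carries no labels.
    """
    labels = np.unique(atlas_slice)
    labels = labels[labels > 0]
    if len(labels) == 0:
        raise ValueError(f"atlas slice {n} has no labelled regions")
    masks: list[np.ndarray] = []
    tags: list[str] = []
    for lab in labels:
        base = atlas_slice == lab
        masks.append(base)
        tags.append(str(int(lab)))
        for r in radii:
            footprint = disk(r)
            ero = erosion(base, footprint)
            if ero.any():
                masks.append(ero)
                tags.append(f"{int(lab)}-ero{r}")
            dil = dilation(base, footprint)
            if dil.any():
                masks.append(dil)
                tags.append(f"{int(lab)}-dil{r}")
    return RegionSet(n, masks, tags)
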