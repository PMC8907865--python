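"""Synthetic longitudinal brain-phantom cohorts with known atrophy ground truth.

Each phantom is an ellipsoidal "brain" on a zero background whose per-region
mean intensity declines monotonically with age at a diagnosis-dependent
rate, following a logistic (sigmoid) decline curve

    g(theta) = 1 - w * kappa_d / (1 + exp(-(theta - tau) / s))

where ``kappa_d`` is the maximum fractional decline for diagnosis ``d``
(severity-ordered CN < SMC < MCI < AD), ``tau`` the inflection age, ``s``
the slope (years), and ``w`` a per-region severity weight: atrophy is
regionally heterogeneous, as in real neurodegeneration.  The regional
intensity ratio between two ages of the same subject is then
g(theta)/g(theta0), the quantity the regional progression regressors are
meant to recover.

Region 1 is a non-declining bright reference structure (severity 0, the
highest base intensity).  Because per-slice normalization is an increasing
affine map that pins the zero background to 0 and the brightest structure
to 1, a stable reference makes normalized regional ratios equal the
generative ratios — without it, slice-wise normalization would absorb any
decline shared uniformly by all regions.  A per-subject global intensity
scale (scanner-gain stand-in) is applied and is exactly removed by the
normalization.

Cohorts are fully determined by a :class:`SyntheticCohortSpec` (including
the seed) and can be written to / read from disk as NIfTI volumes plus CSV
manifests.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AtrophyParams", "SyntheticCohortSpec", "SubjectRecord", "PhantomCohort",
    "regional_decline", "generate_cohort", "write_cohort", "read_cohort",
    "DEFAULT_ATROPHY",
]

N_DIAGNOSES = 4


@dataclasses.dataclass(frozen=True)
class AtrophyParams:
    """Logistic decline parameters for one diagnosis class."""
    kappa: float        # max fractional decline, in [0, 1)
    tau: float = 75.0   # inflection age, years
    s: float = 5.0      # slope, years

    def __post_init__(self):
        if not 0.0 <= self.kappa < 1.0:
            raise ValueError(f"kappa must be in [0, 1), got {self.kappa}")
        if self.s <= 0:
            raise ValueError("slope s must be positive")


# Severity-ordered defaults: CN ages slowly, AD shows strong decline.
DEFAULT_ATROPHY: tuple[AtrophyParams, ...] = (
    AtrophyParams(kappa=0.05),
    AtrophyParams(kappa=0.12),
    AtrophyParams(kappa=0.22),
    AtrophyParams(kappa=0.35),
)


@dataclasses.dataclass(frozen=True)
class SyntheticCohortSpec:
    n_subjects: int = 20
    volume_shape: tuple[int, int, int] = (24, 24, 12)   # (H, W, depth); axial = axis 2
    n_regions_per_slice: int = 4
    age_range: tuple[float, float] = (63.0, 87.0)
    visits_per_subject: tuple[int, int] = (2, 5)
    visit_spacing: float = 1.0        # years between consecutive visits
    spacing_jitter: float = 0.2       # +- uniform jitter on the spacing, years
    diagnosis_probs: tuple[float, float, float, float] = (0.28, 0.04, 0.54, 0.14)
    atrophy_params: tuple[AtrophyParams, ...] = DEFAULT_ATROPHY
    severity_range: tuple[float, float] = (0.4, 1.0)   # per-region weights w_q, q >= 2
    gain_range: tuple[float, float] = (0.9, 1.1)       # per-subject global scale
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(dim < 4 for dim in self.volume_shape):
            raise ValueError(f"degenerate volume shape {self.volume_shape}: "
                             "every dimension must be >= 4")
        if abs(sum(self.diagnosis_probs) - 1.0) > 1e-9:
            raise ValueError("diagnosis_probs must sum to 1")
        if len(self.atrophy_params) != N_DIAGNOSES:
            raise ValueError("need one AtrophyParams per diagnosis code 0-3")
        kappas = [p.kappa for p in self.atrophy_params]
        if any(k2 < k1 for k1, k2 in zip(kappas, kappas[1:])):
            raise ValueError("kappa must be non-decreasing with diagnosis severity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.visits_per_subject[0] < 1 or self.visits_per_subject[0] > self.visits_per_subject[1]:
            raise ValueError("invalid visits_per_subject range")
        if self.spacing_jitter >= self.visit_spacing:
            raise ValueError("spacing_jitter must be smaller than visit_spacing "
                             "(visit ages must stay strictly increasing)")


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    diagnosis: int
    scans: list[tuple[float, np.ndarray]]  # (age in years, volume), ages increasing

    def __post_init__(self):
        if self.diagnosis not in range(N_DIAGNOSES):
            raise ValueError(f"diagnosis must be 0-3, got {self.diagnosis}")
        ages = [a for a, _ in self.scans]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise ValueError("scan ages must be strictly increasing")


@dataclasses.dataclass
class PhantomCohort:
    spec: SyntheticCohortSpec
    subjects: list[SubjectRecord]
    atlas: np.ndarray                 # integer labels, same shape as the volumes
    trajectories: pd.DataFrame        # subject_id, region_id, age, mean_intensity
    region_severity: np.ndarray | None = None   # w_q per region label (index 0 = label 1)

    def total_scans(self) -> int:
        return sum(len(s.scans) for s in self.subjects)


def _decline_curve(theta, params: AtrophyParams, severity: float = 1.0):
    return 1.0 - severity * params.kappa / (
        1.0 + np.exp(-(np.asarray(theta, dtype=float) - params.tau) / params.s))


def regional_decline(theta0: float, theta: float, d: int,
                     params: tuple[AtrophyParams, ...] = DEFAULT_ATROPHY,
                     severity: float = 1.0) -> float:
    """Ground-truth intensity ratio g(theta)/g(theta0) for diagnosis ``d``.

    ``severity`` is the per-region weight w (1 = full diagnosis-level
    decline, 0 = stable reference).  Equals 1 at ``theta == theta0`` and is
    non-increasing in ``theta``.
    """
    if theta < theta0:
        raise ValueError(f"follow-up age {theta} precedes baseline {theta0}")
    if d not in range(N_DIAGNOSES):
        raise ValueError(f"diagnosis must be 0-3, got {d}")
    p = params[d]
    return float(_decline_curve(theta, p, severity) / _decline_curve(theta0, p, severity))


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Foreground 'brain': axis-aligned ellipsoid with semi-axes 0.45*dim."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - (n - 1) / 2.0) / (0.45 * n)) ** 2 for g, n in zip(grids, shape))
    return r2 <= 1.0


def _sector_grid(n_regions: int) -> tuple[int, int]:
    rows = int(np.floor(np.sqrt(n_regions)))
    while n_regions % rows:
        rows -= 1
    return rows, n_regions // rows


def build_atlas(shape: tuple[int, int, int], n_regions_per_slice: int) -> np.ndarray:
    """Label volume tiling each axial slice into contiguous grid sectors.

    Sectors are intersected with the ellipsoidal foreground; background is 0.
    Labels 1..n_regions_per_slice repeat on every axial slice.
    """
    h, w, _ = shape
    rows, cols = _sector_grid(n_regions_per_slice)
    ri = np.minimum((np.arange(h) * rows) // h, rows - 1)
    ci = np.minimum((np.arange(w) * cols) // w, cols - 1)
    plane = (ri[:, None] * cols + ci[None, :] + 1).astype(np.int16)
    atlas = np.repeat(plane[:, :, None], shape[2], axis=2)
    atlas[~_ellipsoid_mask(shape)] = 0
    return atlas


def generate_cohort(spec: SyntheticCohortSpec) -> PhantomCohort:
    """Deterministically generate a longitudinal phantom cohort from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    atlas = build_atlas(spec.volume_shape, spec.n_regions_per_slice)
    fg = atlas > 0
    n_reg = spec.n_regions_per_slice
    region_ids = np.arange(1, n_reg + 1)
    # cohort-level region properties: region 1 = stable bright reference
    severity = np.empty(n_reg)
    severity[0] = 0.0
    severity[1:] = rng.uniform(*spec.severity_range, size=n_reg - 1)
    base = np.empty(n_reg)
    base[0] = 1.0
    base[1:] = rng.uniform(0.55, 0.85, size=n_reg - 1)

    subjects: list[SubjectRecord] = []
    traj_rows: list[tuple[str, int, float, float]] = []
    for si in range(spec.n_subjects):
        sid = f"sub-{si:04d}"
        d = int(rng.choice(N_DIAGNOSES, p=spec.diagnosis_probs))
        n_visits = int(rng.integers(spec.visits_per_subject[0],
                                    spec.visits_per_subject[1] + 1))
        lo, hi = spec.age_range
        baseline = float(rng.uniform(lo, hi - (n_visits - 1) * spec.visit_spacing))
        gaps = spec.visit_spacing + rng.uniform(-spec.spacing_jitter,
                                                spec.spacing_jitter,
                                                size=max(n_visits - 1, 0))
        ages = baseline + np.concatenate([[0.0], np.cumsum(gaps)])
        gain = float(rng.uniform(*spec.gain_range))   # scanner-gain stand-in
        params = spec.atrophy_params[d]
        scans = []
        for age in ages:
            vol = np.zeros(spec.volume_shape, dtype=np.float64)
            for q in region_ids:
                g = float(_decline_curve(age, params, severity[q - 1]))
                mean_int = gain * base[q - 1] * g
                vol[atlas == q] = mean_int
                traj_rows.append((sid, int(q), float(age), mean_int))
            if spec.noise_sd > 0:
                noise = rng.normal(0.0, spec.noise_sd, size=spec.volume_shape)
                vol[fg] += noise[fg]
            scans.append((float(age), vol))
        subjects.append(SubjectRecord(sid, d, scans))

    trajectories = pd.DataFrame(
        traj_rows, columns=["subject_id", "region_id", "age", "mean_intensity"])
    return PhantomCohort(spec, subjects, atlas, trajectories,
                         region_severity=severity)


def write_cohort(cohort: PhantomCohort, directory: str | Path) -> Path:
    """Write NIfTI scans + atlas, a scan manifest CSV and trajectories CSV.

    Returns the manifest path.  Raises ``FileNotFoundError`` if the parent
    of ``directory`` does not exist (``directory`` itself is created).
    """
    directory = Path(directory)
    if not directory.parent.exists():
        raise FileNotFoundError(f"no such directory: {directory.parent}")
    directory.mkdir(exist_ok=True)
    affine = np.eye(4)
    rows = []
    for sub in cohort.subjects:
        for vi, (age, vol) in enumerate(sub.scans):
            path = directory / f"{sub.subject_id}_visit{vi:02d}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.float64), affine), path)
            rows.append((sub.subject_id, age, sub.diagnosis, path.name))
    nib.save(nib.Nifti1Image(cohort.atlas.astype(np.int16), affine),
             directory / "atlas.nii.gz")
    manifest = pd.DataFrame(rows, columns=["subject_id", "age", "dx", "path"])
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    cohort.trajectories.to_csv(directory / "trajectories.csv", index=False)
    if cohort.region_severity is not None:
        pd.DataFrame({"region_id": np.arange(1, len(cohort.region_severity) + 1),
                      "severity": cohort.region_severity}
                     ).to_csv(directory / "region_severity.csv", index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path,
                spec: SyntheticCohortSpec | None = None) -> PhantomCohort:
    """Round-trip reader for :func:`write_cohort` output."""
    manifest_path = Path(manifest_path)
    directory = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    atlas = np.asarray(nib.load(directory / "atlas.nii.gz").dataobj).astype(np.int16)
    trajectories = pd.read_csv(directory / "trajectories.csv")
    subjects = []
    for sid, group in manifest.groupby("subject_id", sort=True):
        group = group.sort_values("age")
        scans = [(float(r.age),
                  np.asarray(nib.load(directory / r.path).dataobj, dtype=np.float64))
                 for r in group.itertuples()]
        subjects.append(SubjectRecord(str(sid), int(group["dx"].iloc[0]), scans))
    if spec is None:
        shape = subjects[0].scans[0][1].shape
        spec = SyntheticCohortSpec(n_subjects=len(subjects), volume_shape=shape,
                                   n_regions_per_slice=int(atlas.max()))
    severity = None
    sev_path = directory / "region_severity.csv"
    if sev_path.exists():
        severity = pd.read_csv(sev_path)["severity"].to_numpy()
    return PhantomCohort(spec, subjects, atlas, trajectories,
                         region_severity=severity)
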