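"""Shared fixtures: small phantom cohorts and a toy trained model.

Everything is generated programmatically and seeded; the session-scoped
trained model keeps the slow adversarial training to one run shared by the
super-resolution, personalization and simulation tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from danisim.nets import ModelConfig
from danisim.phantom import SyntheticCohortSpec, generate_cohort
from danisim.prep import build_age_bins, build_region_set, normalize_slices
from danisim.pwf import PWFParams
from danisim.regional import fit_bank
from danisim.train import SliceDataset, TrainConfig, train_all

TOY_T = 3
TOY_A = 3


@pytest.fixture(scope="session")
def tiny_cohort():
    spec = SyntheticCohortSpec(
        n_subjects=12, volume_shape=(16, 16, 7), n_regions_per_slice=4,
        visits_per_subject=(2, 3), noise_sd=0.0, seed=42,
        diagnosis_probs=(0.25, 0.25, 0.25, 0.25))
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_prepped(tiny_cohort):
    """Normalized stacks, binning, region sets and slice datasets."""
    cohort = tiny_cohort
    by_subject: dict[str, list] = {}
    flat = []
    for sub in cohort.subjects:
        for age, vol in sub.scans:
            stack = normalize_slices(vol, TOY_T, sub.subject_id, age)
            by_subject.setdefault(sub.subject_id, []).append(
                (age, sub.diagnosis, stack))
            flat.append((sub, age, stack))
    ages = [age for entries in by_subject.values() for age, _, _ in entries]
    binning = build_age_bins(ages, TOY_A)
    slice_indices = flat[0][2].slice_indices
    rsets = {int(n): build_region_set(cohort.atlas[:, :, int(n)], int(n),
                                      radii=[1])
             for n in slice_indices}
    bank = fit_bank(by_subject, [rsets[int(n)] for n in slice_indices])
    slice_data = {}
    for pos, n in enumerate(slice_indices):
        slice_data[int(n)] = SliceDataset(
            x=np.stack([st.slices[pos] for _, _, st in flat]),
            ages=np.array([age for _, age, _ in flat]),
            dx=np.array([sub.diagnosis for sub, _, _ in flat]))
    return {"cohort": cohort, "by_subject": by_subject, "binning": binning,
            "slice_indices": slice_indices, "region_sets": rsets,
            "bank": bank, "slice_data": slice_data, "flat": flat}


@pytest.fixture(scope="session")
def toy_model(tiny_prepped):
    """A small trained progression model shared across downstream tests."""
    mc = ModelConfig(image_size=16, latent_dim=12, n_age_bins=TOY_A,
                     base_channels=8, seed=7)
    tc = TrainConfig(epochs=4, batch_size=12, common_init_iters=5, seed=7)
    return train_all(tiny_prepped["slice_data"], tiny_prepped["region_sets"],
                     tiny_prepped["bank"], tiny_prepped["binning"], mc, tc,
                     PWFParams(rho=0.9))
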