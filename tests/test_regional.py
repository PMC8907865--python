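"""Regional ratio extraction, monotone filtering, and sigmoid-link fitting."""

import numpy as np
import pandas as pd
import pytest

from danisim.phantom import SyntheticCohortSpec, generate_cohort, regional_decline
from danisim.prep import RegionSet, SliceStack, build_region_set, normalize_slices
from danisim.regional import (EPSILON, RegressorBank, extract_ratio_samples,
                              fit_regressor, monotone_filter)


def _stack(slices, indices=(0,)):
    return SliceStack("s", 0.0, np.asarray(slices, dtype=float), [],
                      np.asarray(indices))


def _single_region(shape=(4, 4)):
    mask = np.ones(shape, dtype=bool)
    return RegionSet(0, [mask], ["1"])


class TestExtractRatios:
    def test_identical_scans_give_unit_ratio(self):
        s = np.random.default_rng(0).uniform(size=(1, 4, 4))
        data = {"p": [(70.0, 1, _stack(s)), (72.0, 1, _stack(s.copy()))]}
        samples = extract_ratio_samples(data, _single_region())
        assert samples["ratio"].to_numpy() == pytest.approx([1.0])

    def test_three_scans_give_three_ordered_pairs(self):
        rng = np.random.default_rng(1)
        data = {"p": [(70.0 + i, 0, _stack(rng.uniform(size=(1, 4, 4))))
                      for i in range(3)]}
        samples = extract_ratio_samples(data, _single_region())
        assert len(samples) == 3
        assert (samples["a"] > samples["o"]).all()

    def test_epsilon_regularized_hand_arithmetic(self):
        # region sums 50 then 40 with eps=0.1 -> 40.1 / 50.1
        early = np.full((1, 4, 4), 50.0 / 16)
        late = np.full((1, 4, 4), 40.0 / 16)
        data = {"p": [(70.0, 2, _stack(early)), (75.0, 2, _stack(late))]}
        samples = extract_ratio_samples(data, _single_region())
        assert samples["ratio"].iloc[0] == pytest.approx(40.1 / 50.1, abs=1e-12)
        assert EPSILON == 0.1

    def test_no_longitudinal_subjects_rejected(self):
        data = {"p": [(70.0, 0, _stack(np.ones((1, 4, 4))))]}
        with pytest.raises(ValueError, match="longitudinal"):
            extract_ratio_samples(data, _single_region())


class TestMonotoneFilter:
    def test_removes_increasing_ratios_preserving_order(self):
        df = pd.DataFrame({"ratio": [0.9, 1.1, 1.0, 0.8]})
        out = monotone_filter(df)
        assert out["ratio"].tolist() == [0.9, 1.0, 0.8]

    def test_all_compliant_is_noop(self):
        df = pd.DataFrame({"ratio": [0.5, 1.0, 0.7]})
        assert monotone_filter(df)["ratio"].tolist() == [0.5, 1.0, 0.7]

    def test_all_increasing_empties_table(self):
        df = pd.DataFrame({"ratio": [1.1, 1.5]})
        assert monotone_filter(df).empty

    def test_never_increases_sample_count(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"ratio": rng.uniform(0.5, 1.5, size=50)})
        assert len(monotone_filter(df)) <= len(df)


def _fit_on_phantom(n_subjects=60, seed=13):
    spec = SyntheticCohortSpec(n_subjects=n_subjects, volume_shape=(16, 16, 5),
                               visits_per_subject=(3, 3), noise_sd=0.0,
                               seed=seed,
                               diagnosis_probs=(0.25, 0.25, 0.25, 0.25))
    cohort = generate_cohort(spec)
    by_subject = {}
    for sub in cohort.subjects:
        for age, vol in sub.scans:
            st = normalize_slices(vol, 3, sub.subject_id, age)
            by_subject.setdefault(sub.subject_id, []).append(
                (age, sub.diagnosis, st))
    n = int(st.slice_indices[1])
    rset = build_region_set(cohort.atlas[:, :, n], n, radii=[])
    samples = monotone_filter(extract_ratio_samples(by_subject, rset))
    return cohort, spec, rset, samples, n


class TestFitRegressor:
    def test_recovers_generative_ratios_on_noiseless_phantom(self):
        cohort, spec, rset, samples, n = _fit_on_phantom()
        errs = []
        for q in range(rset.n_regions):
            sub = samples[samples["region"] == q]
            lr = fit_regressor(sub, n, q)
            w = cohort.region_severity[q]
            for row in sub.itertuples():
                truth = regional_decline(row.o, row.a, row.d,
                                         spec.atrophy_params, severity=w)
                errs.append(abs(lr.predict(row.o, row.a, row.d) - truth))
        assert np.mean(errs) <= 0.02

    def test_diagnosis_ordering_follows_generative_severity(self):
        cohort, spec, rset, samples, n = _fit_on_phantom()
        q = int(np.argmax(cohort.region_severity))
        lr = fit_regressor(samples[samples["region"] == q], n, q)
        o = float(samples["o"].median())
        a = o + 2.0
        assert lr.predict(o, a, 3) <= lr.predict(o, a, 0)

    def test_constant_unit_ratios_give_identity_predictor(self):
        df = pd.DataFrame({"o": [70, 71, 72, 73, 74.0],
                           "a": [72, 73, 74, 75, 76.0],
                           "d": [0, 1, 2, 3, 1], "ratio": [1.0] * 5})
        lr = fit_regressor(df, 0, 0)
        for o, a, d in [(70, 75, 0), (65, 80, 3)]:
            assert lr.predict(o, a, d) == pytest.approx(1.0, abs=1e-3)

    def test_insufficient_samples_fall_back_to_identity(self):
        df = pd.DataFrame({"o": [70.0], "a": [72.0], "d": [1],
                           "ratio": [0.8]})
        lr = fit_regressor(df, 0, 0)
        assert lr.identity
        assert lr.predict(60, 90, 3) == 1.0

    def test_zero_gap_pinned_to_one_and_interval_checked(self):
        _, _, rset, samples, n = _fit_on_phantom(n_subjects=20)
        lr = fit_regressor(samples[samples["region"] == 1], n, 1)
        assert lr.predict(70.0, 70.0, 2) == 1.0
        with pytest.raises(ValueError):
            lr.predict(75.0, 70.0, 2)

    def test_predictions_never_exceed_one(self):
        _, _, rset, samples, n = _fit_on_phantom(n_subjects=20)
        rng = np.random.default_rng(0)
        lr = fit_regressor(samples[samples["region"] == 2], n, 2)
        for _ in range(50):
            o = rng.uniform(60, 85)
            a = o + rng.uniform(0, 10)
            assert 0.0 < lr.predict(o, a, rng.integers(0, 4)) <= 1.0


class TestBank:
    def test_json_round_trip(self, tmp_path):
        _, _, rset, samples, n = _fit_on_phantom(n_subjects=20)
        bank = RegressorBank()
        for q in range(rset.n_regions):
            bank.add(fit_regressor(samples[samples["region"] == q], n, q))
        path = tmp_path / "bank.json"
        bank.save(path)
        loaded = RegressorBank.load(path)
        assert len(loaded) == len(bank)
        for q in range(rset.n_regions):
            a, b = bank.get(n, q), loaded.get(n, q)
            np.testing.assert_allclose(a.beta, b.beta)
            assert a.identity == b.identity

    def test_missing_regressor_raises(self):
        with pytest.raises(KeyError, match="no regressor"):
            RegressorBank().get(0, 0)
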