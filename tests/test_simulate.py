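"""Personalization, sequence synthesis, and age interpolation."""

import numpy as np
import pytest

from danisim.simulate import (SimulationResult, interpolate_age, personalize,
                              simulate_sequence)


def _result(vals=(0.0, 1.0, 2.0), ages=(65.0, 70.0, 75.0)):
    vols = [np.full((4, 4, 3), v) for v in vals]
    return SimulationResult("s", 65.0, 1, vols, np.asarray(ages))


class TestInterpolation:
    def test_bin_centre_returns_that_volume_exactly(self):
        res = _result()
        for i, age in enumerate(res.bin_ages):
            np.testing.assert_array_equal(interpolate_age(res, age),
                                          res.volumes[i])

    def test_midpoint_matches_elementwise_average(self):
        rng = np.random.default_rng(0)
        vols = [rng.uniform(size=(3, 3, 2)) for _ in range(2)]
        res = SimulationResult("s", 60.0, 0, vols, np.array([60.0, 70.0]))
        got = interpolate_age(res, 65.0)
        expected = np.empty_like(vols[0])
        for idx in np.ndindex(vols[0].shape):
            expected[idx] = 0.5 * (vols[0][idx] + vols[1][idx])
        np.testing.assert_allclose(got, expected)

    def test_linear_on_constant_volumes(self):
        res = _result(vals=(1.0, 3.0), ages=(60.0, 70.0))
        out = interpolate_age(res, 62.5)
        lam = 0.25
        np.testing.assert_allclose(out, np.full((4, 4, 3),
                                                (1 - lam) * 1.0 + lam * 3.0))

    def test_extrapolation_rejected(self):
        res = _result()
        with pytest.raises(ValueError, match="outside"):
            interpolate_age(res, 64.0)
        with pytest.raises(ValueError, match="outside"):
            interpolate_age(res, 76.0)

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError, match="ascend"):
            SimulationResult("s", 65.0, 0, [np.zeros((2, 2, 2))] * 2,
                             np.array([70.0, 65.0]))


class TestSimulateSequence:
    def test_sequence_length_and_shapes(self, toy_model, tiny_prepped):
        cohort = tiny_prepped["cohort"]
        sub = cohort.subjects[0]
        age, vol = sub.scans[0]
        res = simulate_sequence(toy_model, vol, age, sub.diagnosis,
                                subject_id=sub.subject_id)
        assert len(res.volumes) == toy_model.model_config.n_age_bins
        assert all(v.shape == vol.shape for v in res.volumes)
        np.testing.assert_allclose(res.bin_ages, toy_model.binning.centers)

    def test_deterministic_given_checkpoint(self, toy_model, tiny_prepped):
        sub = tiny_prepped["cohort"].subjects[1]
        age, vol = sub.scans[0]
        r1 = simulate_sequence(toy_model, vol, age, sub.diagnosis)
        r2 = simulate_sequence(toy_model, vol, age, sub.diagnosis)
        for v1, v2 in zip(r1.volumes, r2.volumes):
            np.testing.assert_array_equal(v1, v2)

    def test_outputs_live_in_input_intensity_range(self, toy_model, tiny_prepped):
        sub = tiny_prepped["cohort"].subjects[2]
        age, vol = sub.scans[0]
        res = simulate_sequence(toy_model, vol, age, sub.diagnosis)
        lo, hi = vol.min(), vol.max()
        span = hi - lo
        for v in res.volumes:
            assert v.min() >= lo - 1e-9 * span
            assert v.max() <= hi + 1e-9 * span

    def test_unmodelled_slices_keep_baseline_content(self, toy_model,
                                                     tiny_prepped):
        sub = tiny_prepped["cohort"].subjects[0]
        age, vol = sub.scans[0]
        res = simulate_sequence(toy_model, vol, age, sub.diagnosis)
        modelled = set(int(n) for n in toy_model.slice_indices)
        for n in range(vol.shape[2]):
            if n not in modelled:
                for v in res.volumes:
                    np.testing.assert_array_equal(v[:, :, n], vol[:, :, n])


class TestPersonalize:
    def test_zero_iterations_is_identity_copy(self, toy_model, tiny_prepped):
        sub = tiny_prepped["cohort"].subjects[0]
        age, vol = sub.scans[0]
        tuned = personalize(toy_model, vol, age, sub.diagnosis, iters=0)
        assert tuned is not toy_model
        for n in toy_model.slice_indices:
            s1 = toy_model.models[n].state_dict()
            s2 = tuned.models[n].state_dict()
            for k in s1:
                np.testing.assert_array_equal(s1[k], s2[k])

    def test_finetuning_improves_own_reconstruction(self, toy_model,
                                                    tiny_prepped):
        from danisim.nets import generate_sequence
        from danisim.prep import normalize_slices
        sub = tiny_prepped["cohort"].subjects[0]
        age, vol = sub.scans[0]
        tuned = personalize(toy_model, vol, age, sub.diagnosis, iters=50)
        t = len(toy_model.slice_indices)
        stack = normalize_slices(vol, t)
        a = toy_model.binning.bin_index(age)

        def recon_mse(model):
            total = 0.0
            for pos, n in enumerate(model.slice_indices):
                seq = generate_sequence(model.models[n], stack.slices[pos],
                                        sub.diagnosis)
                total += float(np.mean((seq[a] - stack.slices[pos]) ** 2))
            return total / t

        assert recon_mse(tuned) < recon_mse(toy_model)

    def test_original_model_untouched(self, toy_model, tiny_prepped):
        sub = tiny_prepped["cohort"].subjects[0]
        age, vol = sub.scans[0]
        before = {n: toy_model.models[n].state_dict()
                  for n in toy_model.slice_indices}
        personalize(toy_model, vol, age, sub.diagnosis, iters=2)
        for n, state in before.items():
            after = toy_model.models[n].state_dict()
            for k in state:
                np.testing.assert_array_equal(state[k], after[k])

    def test_sr_weights_frozen_through_personalization(self, toy_model,
                                                       tiny_prepped):
        from danisim.sr import SRConfig, SRNet
        net = SRNet(SRConfig(seed=5))
        digest_before = {k: v.copy() for k, v in net.state_dict().items()}
        sub = tiny_prepped["cohort"].subjects[0]
        age, vol = sub.scans[0]
        personalize(toy_model, vol, age, sub.diagnosis, iters=2)
        for k, v in net.state_dict().items():
            np.testing.assert_array_equal(v, digest_before[k])
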