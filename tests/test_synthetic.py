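"""The synthetic observer: determinism, decision model, planted encodings."""

import numpy as np
import pytest

from sir import synthetic as syn
from sir.core import DONT_KNOW, NUNS, VOLTAIRE
from sir.diagnostic import binarize_visibility, binary_mi_map


class TestSimulateTrials:
    def test_seed_determinism_bit_identical(self):
        a = syn.simulate_dataset(n_trials=120, seed=5, n_voxels=20)
        b = syn.simulate_dataset(n_trials=120, seed=5, n_voxels=20)
        assert np.array_equal(a.trials.masks, b.trials.masks)
        assert np.array_equal(a.trials.decisions, b.trials.decisions)
        assert np.array_equal(a.activity.data, b.activity.data)

    def test_dont_know_rate_near_target(self):
        truth = syn.default_ground_truth(n_voxels=20, seed=1)
        trials = syn.simulate_trials(truth, 2000, np.random.default_rng(1))
        dk = (trials.decisions == DONT_KNOW).mean()
        assert abs(dk - 0.25) < 0.05
        assert (trials.decisions == NUNS).any()
        assert (trials.decisions == VOLTAIRE).any()

    def test_unattainable_threshold_rejected_with_diagnostic(self):
        truth = syn.default_ground_truth(n_voxels=20, seed=2)
        truth.dont_know_threshold = 1e9
        with pytest.raises(ValueError, match="degenerate decision rule"):
            syn.simulate_trials(truth, 200, np.random.default_rng(0))
        trials = syn.simulate_trials(
            truth, 200, np.random.default_rng(0), allow_degenerate=True
        )
        assert (trials.decisions == DONT_KNOW).all()

    def test_noiseless_limit_follows_template_visibility(self):
        truth = syn.default_ground_truth(n_voxels=20, seed=3)
        truth.decision_noise_sd = 1e-9
        truth.dont_know_threshold = -1e9  # never abstain
        trials = syn.simulate_trials(
            truth, 300, np.random.default_rng(4), allow_degenerate=True
        )
        flat = trials.masks.reshape(300, -1).astype(float)
        coefs = flat @ truth.templates_flat().T
        z = (coefs - coefs.mean(0)) / coefs.std(0)
        ev_n = z[:, truth.percept_of_feature == NUNS].mean(axis=1)
        ev_v = z[:, truth.percept_of_feature == VOLTAIRE].mean(axis=1)
        # standardization of evidence preserves the argmax up to scale
        expect = np.where(
            ev_n / ev_n.std() > ev_v / ev_v.std(), NUNS, VOLTAIRE
        )
        assert (trials.decisions == expect).mean() > 0.99

    def test_too_few_trials_rejected(self):
        truth = syn.default_ground_truth(n_voxels=20, seed=0)
        with pytest.raises(ValueError, match="100 trials"):
            syn.simulate_trials(truth, 50, np.random.default_rng(0))


class TestSimulateActivity:
    def test_gradient_channel_is_temporal_derivative(self, small_dataset):
        data = small_dataset.activity.data
        dt = float(np.diff(small_dataset.activity.times_ms)[0])
        expected = np.gradient(data[..., 0], dt, axis=2)
        np.testing.assert_allclose(data[..., 1], expected, atol=1e-4)

    def test_non_encoding_voxels_are_pure_noise(self, small_dataset):
        truth = small_dataset.trials, small_dataset.truth
        encoded = {e.voxel for e in small_dataset.truth.encoding}
        silent = [v for v in range(small_dataset.truth.n_voxels) if v not in encoded]
        amp = small_dataset.activity.data[:, silent, :, 0]
        assert abs(amp.mean()) < 0.01
        assert amp.std() == pytest.approx(
            small_dataset.truth.activity_noise_sd, rel=0.05
        )

    def test_single_high_gain_voxel_dominates_mi(self, rng):
        from sir import features as feat

        truth = syn.default_ground_truth(n_voxels=20, seed=6)
        truth.encoding = [syn.EncodingEntry(7, 2, 100.0, 100.0, 10.0, True)]
        truth.activity_noise_sd = 0.05
        ds = syn.simulate_dataset(truth, n_trials=200, seed=6)
        basis = feat.BrainFeatureBasis(
            truth.templates_flat().copy(), truth.templates.shape[1:],
            truth.feature_labels(),
        )
        coefs = feat.feature_coefficients(ds.trials.masks, basis)
        rep = feat.representation_matrix(coefs, ds.activity, n_perm=0)
        f, v, t = np.unravel_index(np.argmax(rep.mi), rep.mi.shape)
        assert (f, v) == (2, 7)
        assert 100.0 <= rep.times_ms[t] < 200.0

    def test_invalid_encoding_rejected(self):
        truth = syn.default_ground_truth(n_voxels=10, seed=0)
        trials = syn.simulate_trials(truth, 120, np.random.default_rng(0))
        truth.encoding = [syn.EncodingEntry(50, 0, 100.0, 50.0, 1.0, True)]
        with pytest.raises(ValueError, match="out of range"):
            syn.simulate_activity(truth, trials, np.random.default_rng(0))
        truth.encoding = [syn.EncodingEntry(2, 0, 100.0, -5.0, 1.0, True)]
        with pytest.raises(ValueError, match="positive"):
            syn.simulate_activity(truth, trials, np.random.default_rng(0))


class TestGroundTruthStructure:
    def test_nondiagnostic_wavefront_durations_shrink_with_distance(self):
        truth = syn.default_ground_truth(n_voxels=200, seed=9)
        dist = np.linalg.norm(truth.coords, axis=1)
        nd = [e for e in truth.encoding if not e.diagnostic]
        d = np.array([dist[e.voxel] for e in nd])
        dur = np.array([e.duration_ms for e in nd])
        assert np.corrcoef(d, dur)[0, 1] < -0.99
        assert all(e.onset_ms + e.duration_ms <= truth.junction_ms + 1e-9 for e in nd)

    def test_diagnostic_wavefront_persists_past_junction(self):
        truth = syn.default_ground_truth(n_voxels=200, seed=9)
        diag = [e for e in truth.encoding if e.diagnostic]
        assert all(
            e.onset_ms + e.duration_ms > truth.junction_ms for e in diag
        )

    def test_more_trials_never_hurts_template_information(self):
        # mean MI over planted support pixels grows with trial count
        truth = syn.default_ground_truth(n_voxels=20, seed=13)
        support = truth.percept_support(NUNS)[:, :, 0].ravel()  # nuns live in band 0
        mis = []
        for n in (300, 900):
            trials = syn.simulate_trials(truth, n, np.random.default_rng(13))
            vis = binarize_visibility(trials.masks)
            sel = np.isin(trials.decisions, [NUNS, DONT_KNOW])
            y = (trials.decisions[sel] == NUNS).astype(int)
            flat = vis.bits[sel].reshape(sel.sum(), -1)
            band0 = flat.reshape(sel.sum(), -1, 5)[:, :, 0]
            mis.append(binary_mi_map(band0, y)[support].mean())
        assert mis[1] > 0.0
        # estimation noise shrinks and the planted signal stays, so the
        # support-pixel MI at 3x trials should not collapse
        assert mis[1] > 0.5 * mis[0]


class TestRecoveryReport:
    def test_missing_stage_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="no stage outputs"):
            syn.recovery_report(small_dataset, {})
        with pytest.raises(ValueError, match="nuns_vs_dk"):
            syn.recovery_report(small_dataset, {"diagnostic_maps": {}})

    def test_reports_metrics_for_present_stages(self, small_dataset, true_basis):
        report = syn.recovery_report(
            small_dataset, {"basis": true_basis, "junction_ms": 168.0}
        )
        assert report["feature_cosine_median"] == pytest.approx(1.0)
        assert report["junction_error_ms"] == pytest.approx(2.0)
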