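"""NMF brain features, coefficients, representation matrix, classification."""

import numpy as np
import pytest

from sir import features as feat
from sir import synthetic
from sir.core import DONT_KNOW, NUNS, VOLTAIRE, SourceActivity


def _prototype_stack(rng, k=4, n_cells=80, dim=500, noise=0.01):
    """Stack of nonnegative images mixing k disjoint-support prototypes."""
    protos = np.zeros((k, dim))
    block = dim // k
    for i in range(k):
        protos[i, i * block : (i + 1) * block] = rng.random(block) + 0.5
    load = rng.random((n_cells, k)) ** 2
    X = load @ protos + noise * rng.random((n_cells, dim))
    return feat.MIImageStack(X, [(0, t) for t in range(n_cells)], (dim,)), protos


class TestReducedMIImages:
    def test_noise_activity_gives_near_zero_images(self, rng):
        masks = rng.random((400, 8, 8, 2))
        act = rng.standard_normal((400, 3, 4))
        stack = feat.reduced_mi_images(masks, act)
        assert stack.images.shape == (12, 128)
        assert stack.images.mean() < 0.01

    def test_planted_cell_concentrates_on_template_support(self, rng):
        n, size = 600, 12
        masks = rng.random((n, size, size, 1))
        support = np.zeros((size, size), dtype=bool)
        support[3:6, 4:8] = True
        coef = masks[:, support, 0].sum(axis=1)
        act = rng.standard_normal((n, 2, 3)) * 0.2
        act[:, 1, 1] += coef
        stack = feat.reduced_mi_images(masks, act)
        img = stack.images[stack.cell_index.index((1, 1))]
        top = np.argsort(img)[-support.sum() :]
        frac_in = np.isin(top, np.flatnonzero(support.ravel())).mean()
        assert frac_in > 0.8

    def test_cell_count_is_components_times_times(self, rng):
        stack = feat.reduced_mi_images(
            rng.random((100, 4, 4, 1)), rng.standard_normal((100, 6, 5))
        )
        assert len(stack.cell_index) == 30

    def test_trial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            feat.reduced_mi_images(
                rng.random((100, 4, 4, 1)), rng.standard_normal((90, 2, 2))
            )


class TestNMFBasis:
    def test_recovers_disjoint_prototypes(self, rng):
        stack, protos = _prototype_stack(rng)
        basis = feat.nmf_basis(stack, 4, rng)
        _, cos = synthetic.match_features(basis.features, protos)
        assert (cos > 0.95).all()

    def test_threshold_zeroes_low_pixels_and_rows_unit_norm(self, rng):
        stack, _ = _prototype_stack(rng)
        basis = feat.nmf_basis(stack, 4, rng)
        for row in basis.features:
            nz = row[row > 0]
            assert np.linalg.norm(row) == pytest.approx(1.0, abs=1e-10)
            assert nz.min() >= 0.15 * row.max() - 1e-12

    def test_elbow_rule_matches_planted_rank(self, rng):
        stack, _ = _prototype_stack(rng, k=3, noise=0.001)
        k = feat.select_nmf_k(stack, k_max=6, min_improvement=0.05, rng=rng)
        assert k == 3

    def test_invalid_inputs_rejected(self, rng):
        stack, _ = _prototype_stack(rng)
        with pytest.raises(ValueError, match="k"):
            feat.nmf_basis(stack, 0, rng)
        zero = feat.MIImageStack(np.zeros((10, 20)), [], (20,))
        with pytest.raises(ValueError, match="all zero"):
            feat.nmf_basis(zero, 2, rng)


class TestFeatureCoefficients:
    def test_mask_equal_to_unit_feature_gives_mask_norm(self, rng):
        f = rng.random(32)
        f /= np.linalg.norm(f)
        basis = feat.BrainFeatureBasis(f[None, :], (32,))
        mask = 3.0 * f
        coefs = feat.feature_coefficients(mask[None, :], basis)
        assert coefs.coefs[0, 0] == pytest.approx(np.linalg.norm(mask), rel=1e-12)

    def test_zero_mask_gives_zero_coefficients(self):
        basis = feat.BrainFeatureBasis(np.random.default_rng(0).random((3, 50)), (50,))
        coefs = feat.feature_coefficients(np.zeros((2, 50)), basis)
        assert (coefs.coefs == 0).all()

    def test_matches_explicit_summation(self, rng):
        basis = feat.BrainFeatureBasis(rng.random((2, 4 * 4 * 2)), (4, 4, 2))
        masks = rng.random((5, 4, 4, 2))
        coefs = feat.feature_coefficients(masks, basis)
        for t in range(5):
            for f in range(2):
                ref = sum(
                    masks[t, i, j, b] * basis.features[f].reshape(4, 4, 2)[i, j, b]
                    for i in range(4)
                    for j in range(4)
                    for b in range(2)
                )
                assert coefs.coefs[t, f] == pytest.approx(ref, rel=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        basis = feat.BrainFeatureBasis(rng.random((2, 32)), (32,))
        with pytest.raises(ValueError, match="dimension"):
            feat.feature_coefficients(rng.random((5, 40)), basis)


def _toy_activity(rng, coef, n_voxels=6, n_times=10, gain=2.0, voxel=2, t=4):
    n = coef.shape[0]
    amp = rng.standard_normal((n, n_voxels, n_times))
    amp[:, voxel, t] += gain * (coef - coef.mean()) / coef.std()
    data = np.stack([amp, np.gradient(amp, axis=2)], axis=-1)
    coords = rng.random((n_voxels, 3))
    return SourceActivity(data.astype(np.float32), coords, 2.0 * np.arange(n_times))


class TestRepresentationMatrix:
    def test_planted_cell_is_matrix_maximum_and_significant(self, rng):
        coef = rng.random(400)
        act = _toy_activity(rng, coef)
        rep = feat.representation_matrix(
            feat.FeatureCoefficients(coef[:, None]), act, n_perm=100, rng=rng
        )
        k, v, t = np.unravel_index(np.argmax(rep.mi), rep.mi.shape)
        assert (v, t) == (2, 4)
        assert rep.significant[k, v, t]

    def test_invariant_to_positive_rescaling_of_coefficients(self, rng):
        coef = rng.random(300)
        act = _toy_activity(rng, coef)
        a = feat.representation_matrix(
            feat.FeatureCoefficients(coef[:, None]), act, n_perm=0
        )
        b = feat.representation_matrix(
            feat.FeatureCoefficients(np.exp(2 * coef)[:, None]), act, n_perm=0
        )
        np.testing.assert_allclose(a.mi, b.mi, atol=1e-12)

    def test_threshold_reproducible_under_fixed_seed(self, rng):
        coef = rng.random(300)
        act = _toy_activity(rng, coef)
        reps = [
            feat.representation_matrix(
                feat.FeatureCoefficients(coef[:, None]), act, n_perm=100,
                rng=np.random.default_rng(77),
            )
            for _ in range(2)
        ]
        assert reps[0].fwer_threshold == reps[1].fwer_threshold

    def test_trial_mismatch_rejected(self, rng):
        act = _toy_activity(rng, rng.random(100))
        with pytest.raises(ValueError, match="mismatch"):
            feat.representation_matrix(
                feat.FeatureCoefficients(rng.random((90, 1))), act, n_perm=0
            )


class TestClassifyFeatures:
    def _coefs_and_decisions(self, rng, n=2000):
        # feature 0 drives nuns, feature 1 drives voltaire, 2..5 independent
        C = rng.random((n, 6))
        ev_n = (C[:, 0] - C[:, 0].mean()) / C[:, 0].std()
        ev_v = (C[:, 1] - C[:, 1].mean()) / C[:, 1].std()
        d = np.where(
            np.maximum(ev_n, ev_v) < 0.3,
            DONT_KNOW,
            np.where(ev_n > ev_v, NUNS, VOLTAIRE),
        )
        return feat.FeatureCoefficients(C), d

    def test_planted_drivers_labeled_diagnostic(self, rng):
        coefs, d = self._coefs_and_decisions(rng)
        labels = feat.classify_features(coefs, d)
        assert labels[0] == "diagnostic_nuns"
        assert labels[1] == "diagnostic_voltaire"

    def test_independent_features_labeled_nondiagnostic(self, rng):
        coefs, d = self._coefs_and_decisions(rng)
        labels = feat.classify_features(coefs, d)
        assert "nondiagnostic" in labels[2:]
        assert "diagnostic_nuns" not in labels[2:]
        assert "diagnostic_voltaire" not in labels[2:]

    def test_identical_features_all_unclassified(self, rng):
        c = rng.random(1000)
        coefs = feat.FeatureCoefficients(np.tile(c[:, None], (1, 5)))
        d = rng.integers(0, 3, 1000)
        labels = feat.classify_features(coefs, d)
        assert labels == ["unclassified"] * 5

    def test_too_few_features_rejected(self, rng):
        coefs = feat.FeatureCoefficients(rng.random((500, 3)))
        with pytest.raises(ValueError, match="4 features"):
            feat.classify_features(coefs, rng.integers(0, 3, 500))

    def test_invariant_to_feature_reordering(self, rng):
        coefs, d = self._coefs_and_decisions(rng)
        labels = feat.classify_features(coefs, d)
        perm = [3, 0, 5, 1, 4, 2]
        permuted = feat.FeatureCoefficients(coefs.coefs[:, perm])
        labels_p = feat.classify_features(permuted, d)
        assert labels_p == [labels[i] for i in perm]


class TestKmeansBasis:
    def test_separated_clusters_recovered_exactly(self, rng):
        centers = np.eye(4)
        X = np.repeat(centers, 10, axis=0) + 0.01 * rng.random((40, 4))
        labels, cents = feat.kmeans_basis(X, k=4, n_restarts=10, rng=rng)
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat(np.arange(4), 10)
        assert adjusted_rand_score(truth, labels) == 1.0
        np.testing.assert_allclose(np.linalg.norm(cents, axis=1), 1.0, atol=1e-10)

    def test_duplicate_rows_share_cluster(self, rng):
        X = rng.random((12, 20))
        X[5] = X[2]
        labels, _ = feat.kmeans_basis(X, k=3, n_restarts=5, rng=rng)
        assert labels[5] == labels[2]

    def test_k_exceeding_rows_rejected(self, rng):
        with pytest.raises(ValueError, match="at least k"):
            feat.kmeans_basis(rng.random((5, 10)), k=8, n_restarts=2, rng=rng)

    def test_pooled_observer_basis_dimensionality_accepted(self, rng):
        # five observers' pooled features: 115 x 20480, k = 25
        X = rng.random((115, 20480))
        labels, cents = feat.kmeans_basis(X, k=25, n_restarts=2, rng=rng)
        assert labels.shape == (115,)
        assert cents.shape == (25, 20480)
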