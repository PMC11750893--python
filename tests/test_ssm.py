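"""PCA shape model: spectrum, deformation, and leave-one-out generalization."""

import warnings

import numpy as np
import pytest

from vcohort import Surface, deform, fit, generalization, modes_for_variance
from vcohort.registration import AlignedCohort, RigidTransform
from vcohort.ssm import project


def _toy_cohort(X, label="wall"):
    """Wrap a raw (N, 3m) matrix as an AlignedCohort for model fitting."""
    X = np.asarray(X, float)
    m = X.shape[1] // 3
    template = Surface("template", label, X.mean(axis=0).reshape(m, 3)
                       if m >= 4 else np.zeros((4, 3)))
    if m < 4:
        raise ValueError("toy cohorts need at least 4 points")
    ident = [RigidTransform.identity() for _ in range(len(X))]
    return AlignedCohort(template=template, X=X, transforms=ident,
                         label=label, patient_ids=[f"s{i}" for i in range(len(X))])


def _cohort_with_spectrum(lambdas, m, N, seed=0):
    """Rows whose sample covariance has exactly the requested eigenvalues."""
    rng = np.random.default_rng(seed)
    K = len(lambdas)
    # orthonormal factors orthogonal to the all-ones vector, so rows center
    A = rng.normal(size=(N, K))
    A -= A.mean(axis=0)
    U, _ = np.linalg.qr(A)
    V, _ = np.linalg.qr(rng.normal(size=(3 * m, K)))
    S = np.sqrt(np.asarray(lambdas) * (N - 1))
    X = (U[:, :K] * S) @ V.T
    return _toy_cohort(X + rng.normal(0, 0.0, size=X.shape))


class TestFit:
    def test_one_factor_cohort_has_single_mode(self, rng):
        m = 6
        v = rng.normal(size=3 * m)
        v /= np.linalg.norm(v)
        mean = rng.normal(size=3 * m)
        X = mean + np.outer([-2.0, -1.0, 0.0, 1.0, 2.0], v)
        model = fit(_toy_cohort(X))
        assert model.n_modes == 1
        assert abs(abs(model.modes[:, 0] @ v) - 1) < 1e-10

    def test_spectrum_matches_dense_eigendecomposition(self, rng):
        """SVD route equals a brute-force covariance eigensolve on a toy."""
        X = rng.normal(size=(5, 12))
        model = fit(_toy_cohort(X))
        cov = np.cov(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.variances, evals[:model.n_modes], atol=1e-8)

    def test_variance_fractions_sum_to_one(self, wall_model):
        assert abs(wall_model.variance_fractions.sum() - 1) < 1e-10
        assert np.all(np.diff(wall_model.variances) <= 1e-12)
        gram = wall_model.modes.T @ wall_model.modes
        assert np.allclose(gram, np.eye(wall_model.n_modes), atol=1e-8)

    def test_rank_zero_cohort_warns_with_zero_modes(self, rng):
        X = np.tile(rng.normal(size=12), (4, 1))
        with pytest.warns(UserWarning, match="no shape variability"):
            model = fit(_toy_cohort(X))
        assert model.n_modes == 0

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(8, 15))
        a = fit(_toy_cohort(X))
        b = fit(_toy_cohort(X[::-1]))
        assert np.allclose(a.variances, b.variances, atol=1e-10)

    def test_recovers_generative_subspace(self, rng):
        """Leading subspace within 5 degrees of a planted low-rank model."""
        N, m, K = 50, 10, 2
        V, _ = np.linalg.qr(rng.normal(size=(3 * m, K)))
        scores = rng.normal(size=(N, K)) * [8.0, 5.0]
        X = scores @ V.T + rng.normal(0, 0.3, size=(N, 3 * m))
        model = fit(_toy_cohort(X))
        # principal angles between fitted and generative subspaces
        s = np.linalg.svd(model.modes[:, :K].T @ V, compute_uv=False)
        angles = np.degrees(np.arccos(np.clip(s, -1, 1)))
        assert angles.max() < 5.0


class TestDeform:
    def test_zero_weights_give_mean_shape(self, wall_model):
        surf = deform(wall_model, np.zeros(wall_model.n_modes))
        assert np.allclose(surf.points.ravel(), wall_model.mean)

    def test_training_row_reconstructs_from_all_modes(self, aligned_wall,
                                                      wall_model):
        row = aligned_wall.X[3]
        scores = project(wall_model, row)
        weights = scores / wall_model.sigmas
        rebuilt = deform(wall_model, weights).points.ravel()
        rel = np.linalg.norm(rebuilt - row) / np.linalg.norm(row)
        assert rel < 1e-6

    def test_three_sigma_deformation_matches_direct_formula(self, rng):
        """+3 sigma on mode 1 equals mean + 3*sigma_1*phi_1, hand-computed."""
        X = rng.normal(size=(3, 12)) * 4
        model = fit(_toy_cohort(X))
        expected = (X.mean(axis=0)
                    + 3.0 * np.sqrt(model.variances[0]) * model.modes[:, 0])
        out = deform(model, [3.0])
        assert np.allclose(out.points.ravel(), expected, atol=1e-10)

    def test_too_many_weights_raise(self, wall_model):
        with pytest.raises(ValueError):
            deform(wall_model, np.zeros(wall_model.n_modes + 1))


class TestModesForVariance:
    def test_one_factor_model(self, rng):
        v = rng.normal(size=12)
        X = np.outer([-1.0, 0.0, 1.0], v)
        model = fit(_toy_cohort(X))
        assert modes_for_variance(model, 0.9) == 1

    def test_equal_eigenvalues_half_variance(self):
        cohort = _cohort_with_spectrum([2.0, 2.0, 2.0, 2.0], m=5, N=8)
        model = fit(cohort)
        assert modes_for_variance(model, 0.5) == 2

    def test_toy_spectrum_cumulative_sum(self):
        cohort = _cohort_with_spectrum([4.0, 3.0, 2.0, 1.0], m=5, N=8)
        model = fit(cohort)
        # cumulative fractions 0.4, 0.7, 0.9, 1.0
        assert modes_for_variance(model, 0.9) == 3
        assert modes_for_variance(model, 0.95) == 4
        assert modes_for_variance(model, 0.1) == 1

    def test_fraction_out_of_range(self, wall_model):
        with pytest.raises(ValueError):
            modes_for_variance(wall_model, 1.5)


def _loo_oracle(X, M):
    """Independent leave-one-out generalization via covariance eigensolve."""
    N, D = X.shape
    m = D // 3
    errs = []
    for i in range(N):
        rest = np.delete(X, i, axis=0)
        mean = rest.mean(axis=0)
        cov = np.cov(rest, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        keep = [j for j in order if evals[j] > 1e-12 * evals[order[0]]]
        Phi = evecs[:, keep[:M]]
        recon = mean + Phi @ (Phi.T @ (X[i] - mean))
        errs.append(np.sqrt(((X[i] - recon).reshape(m, 3) ** 2)
                            .sum(axis=1).mean()))
    return float(np.mean(errs))


class TestGeneralization:
    def test_identical_cohort_has_zero_error(self, rng):
        X = np.tile(rng.normal(size=15), (5, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = generalization(_toy_cohort(X), [1, 2])
        assert all(v < 1e-9 for v in report.generalization.values())

    def test_matches_independent_loo_loop(self, rng):
        X = rng.normal(size=(6, 15)) * 3
        report = generalization(_toy_cohort(X), [1, 2, 3, 4])
        for M, ge in report.generalization.items():
            assert ge == pytest.approx(_loo_oracle(X, M), abs=1e-9)

    def test_nonincreasing_in_mode_count(self, rng):
        v = rng.normal(size=18)
        t = rng.normal(size=10)[:, None]
        X = t * v + rng.normal(0, 0.2, size=(10, 18))
        report = generalization(_toy_cohort(X), [1, 2, 3, 4, 5])
        values = [report.generalization[M] for M in sorted(report.generalization)]
        assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))

    def test_excessive_modes_skipped_with_warning(self, rng):
        X = rng.normal(size=(5, 12))
        with pytest.warns(UserWarning, match="skipping"):
            report = generalization(_toy_cohort(X), [1, 2, 3, 4])
        assert report.skipped_modes == [4]
        assert sorted(report.generalization) == [1, 2, 3]
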