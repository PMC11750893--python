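"""PCA shape atlas: mean shape, orthonormal modes, deformation, quality.

The statistical shape model is a standard point-distribution model: the
corresponded coordinate vectors are mean-centered and decomposed by SVD
(equivalent to an eigendecomposition of the sample covariance with divisor
N - 1).  Mode signs are fixed so each mode's largest-magnitude entry is
positive — PCA signs are arbitrary, and fixing them makes results
reproducible across runs and platforms.

Model quality is summarized by compactness (cumulative explained variance)
and generalization: the mean leave-one-out reconstruction error

    GE(M) = (1/N) * sum_i || x_i - x_hat_i(M) ||

as a function of the number of retained modes M, where x_hat_i(M) is the
left-out shape rebuilt from a model fitted without it.  The norm is the
per-point RMS Euclidean distance in mm, so GE is independent of the
template resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .registration import AlignedCohort
from .surface import Surface

__all__ = ["ShapeModel", "QualityReport", "fit", "deform",
           "modes_for_variance", "generalization"]


@dataclass
class ShapeModel:
    """Mean shape + orthonormal deformation modes with per-mode variances."""

    label: str
    mean: np.ndarray            # (3m,) mm
    modes: np.ndarray           # (3m, K), orthonormal columns
    variances: np.ndarray       # (K,) eigenvalues, mm^2, non-increasing
    n_training: int
    faces: np.ndarray | None = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float).ravel()
        self.modes = np.asarray(self.modes, float)
        self.variances = np.asarray(self.variances, float)
        K = self.modes.shape[1] if self.modes.size else 0
        if K:
            gram = self.modes.T @ self.modes
            if not np.allclose(gram, np.eye(K), atol=1e-8):
                raise ValueError("modes must be orthonormal")
            if np.any(np.diff(self.variances) > 1e-12):
                raise ValueError("variances must be non-increasing")
        if K > max(self.n_training - 1, 0):
            raise ValueError("more modes than n_training - 1")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1] if self.modes.size else 0

    @property
    def n_points(self) -> int:
        return len(self.mean) // 3

    @property
    def sigmas(self) -> np.ndarray:
        return np.sqrt(self.variances)

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.variances.sum()
        return self.variances / total if total > 0 else self.variances

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_fractions)

    def mean_surface(self) -> Surface:
        return Surface("mean", self.label, self.mean.reshape(-1, 3),
                       faces=self.faces)

    def save(self, path: str) -> None:
        np.savez_compressed(
            path, mean=self.mean, modes=self.modes, variances=self.variances,
            label=self.label, n_training=self.n_training,
            faces=(self.faces if self.faces is not None
                   else np.zeros((0, 3), np.int64)))

    @classmethod
    def load(cls, path: str) -> "ShapeModel":
        d = np.load(path, allow_pickle=False)
        faces = d["faces"]
        return cls(label=str(d["label"]), mean=d["mean"], modes=d["modes"],
                   variances=d["variances"], n_training=int(d["n_training"]),
                   faces=faces if len(faces) else None)


@dataclass
class QualityReport:
    """Compactness and generalization summary of a fitted model."""

    cumulative_variance: np.ndarray
    modes_for_fraction: dict
    generalization: dict            # M -> GE(M), mm
    skipped_modes: list = field(default_factory=list)

    def __post_init__(self):
        cv = np.asarray(self.cumulative_variance, float)
        if np.any(np.diff(cv) < -1e-12):
            raise ValueError("cumulative variance must be non-decreasing")
        if cv.size and abs(cv[-1] - 1.0) > 1e-10:
            raise ValueError("cumulative variance must end at 1")


def _pca(X: np.ndarray):
    """Mean, orthonormal modes and variances (divisor N-1) via SVD."""
    X = np.asarray(X, float)
    N = len(X)
    mean = X.mean(axis=0)
    centered = X - mean
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    variances = s ** 2 / max(N - 1, 1)
    if variances.size == 0 or variances[0] <= 0:
        return mean, np.zeros((X.shape[1], 0)), np.zeros(0)
    keep = variances >= 1e-12 * variances[0]
    keep[min(N - 1, len(keep)):] = False
    modes = Vt[keep].T
    variances = variances[keep]
    # deterministic sign: largest-magnitude entry of each mode positive
    for j in range(modes.shape[1]):
        k = np.argmax(np.abs(modes[:, j]))
        if modes[k, j] < 0:
            modes[:, j] = -modes[:, j]
    return mean, modes, variances


def fit(cohort: AlignedCohort) -> ShapeModel:
    """Fit the PCA shape model to a corresponded cohort.

    A rank-0 cohort (all rows identical) yields a model with zero modes and
    a warning rather than an error.
    """
    if cohort.n_subjects < 3:
        raise ValueError("need at least 3 subjects to fit a shape model")
    mean, modes, variances = _pca(cohort.X)
    if modes.shape[1] == 0:
        warnings.warn("cohort has no shape variability; model has 0 modes",
                      stacklevel=2)
    return ShapeModel(label=cohort.label, mean=mean, modes=modes,
                      variances=variances, n_training=cohort.n_subjects,
                      faces=cohort.template.faces)


def _as_weight_array(weights, K: int) -> np.ndarray:
    w = getattr(weights, "weights", weights)
    w = np.asarray(w, float).ravel()
    if len(w) > K:
        raise ValueError(f"weight vector length {len(w)} exceeds {K} modes")
    out = np.zeros(K)
    out[:len(w)] = w
    return out


def deform(model: ShapeModel, weights) -> Surface:
    """Deform the mean shape along the modes by the given weights (sigma units).

    ``weights`` may be a plain vector or a :class:`~vcohort.cohort.ModeWeights`;
    entries beyond its length are zero.  The returned surface is
    mean + sum_j w_j * sigma_j * phi_j, with the template faces reused when
    available.
    """
    w = _as_weight_array(weights, model.n_modes)
    coords = model.mean + model.modes @ (w * model.sigmas)
    return Surface("virtual", model.label, coords.reshape(-1, 3),
                   faces=model.faces)


def project(model: ShapeModel, coords: np.ndarray) -> np.ndarray:
    """Mode scores (mm) of a corresponded coordinate vector or matrix."""
    arr = np.asarray(coords, float)
    flat = arr.reshape(-1, len(model.mean))
    return np.squeeze((flat - model.mean) @ model.modes)


def modes_for_variance(model: ShapeModel, fraction: float) -> int:
    """Smallest number of modes whose cumulative variance reaches ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if model.n_modes == 0:
        return 0
    cum = model.cumulative_variance
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def generalization(cohort: AlignedCohort, M_values) -> QualityReport:
    """Leave-one-out generalization GE(M) for each requested mode count.

    For every subject a model is fitted on the remaining N-1 rows, the
    left-out row is projected onto the first M modes and rebuilt, and the
    per-point RMS distance (mm) between original and reconstruction is
    recorded; GE(M) averages these over subjects.  Values of M exceeding
    N - 2 (the rank available inside a fold) are skipped with a warning.
    The same cohort alignment is reused across folds (no re-registration).
    """
    N = cohort.n_subjects
    if N < 4:
        raise ValueError("need at least 4 subjects for leave-one-out")
    M_values = sorted({int(M) for M in M_values})
    if any(M < 1 for M in M_values):
        raise ValueError("mode counts must be positive")
    valid = [M for M in M_values if M <= N - 2]
    skipped = [M for M in M_values if M > N - 2]
    if skipped:
        warnings.warn(f"skipping M values beyond N-2: {skipped}", stacklevel=2)

    m = cohort.template.n_points
    errors = np.zeros((N, len(valid)))
    for i in range(N):
        X_fold = np.delete(cohort.X, i, axis=0)
        mean, modes, _ = _pca(X_fold)
        resid = cohort.X[i] - mean
        scores = resid @ modes
        for j, M in enumerate(valid):
            Mj = min(M, modes.shape[1])
            recon = mean + modes[:, :Mj] @ scores[:Mj]
            diff = (cohort.X[i] - recon).reshape(m, 3)
            errors[i, j] = np.sqrt((diff ** 2).sum(axis=1).mean())

    full = fit(cohort)
    ge = {M: float(errors[:, j].mean()) for j, M in enumerate(valid)}
    fractions = {f: modes_for_variance(full, f) for f in (0.90, 0.95, 0.99)}
    return QualityReport(cumulative_variance=full.cumulative_variance,
                         modes_for_fraction=fractions, generalization=ge,
                         skipped_modes=skipped)
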