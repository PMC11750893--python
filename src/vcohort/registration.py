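"""Dense correspondence across a cohort of anatomical surfaces.

The correspondence chain is the classic point-distribution-model recipe:

1. rigid ICP (rotation + translation) of every subject onto a reference,
2. similarity ICP (adds isotropic scale) to tighten the match,
3. non-rigid registration: the template is warped onto each subject by
   iteratively moving template points toward their closest subject points,
   with the displacement field smoothed by a Gaussian kernel.  The warped
   template has the template's point count and ordering for every subject,
   which is what creates the dense correspondence PCA needs,
4. the mean shape is recomputed and steps 1-3 repeat against it until the
   mean no longer moves (reference-bias removal).

The ICP stopping rule follows the tolerance convention of the underlying
method: iteration halts when the mean point displacement induced by the
three most recent consecutive transform estimates falls below the tolerance
(0.01 mm for walls, relaxed to 0.2 mm for calcific plaques), with a hard cap
of 120 iterations.

Rows of the corresponded matrix are expressed in a canonical template frame
(mean shape centered at the origin, axes along its principal directions with
signs fixed by third moments).  This makes the cohort matrix invariant to a
common rigid motion applied to all inputs.  The similarity scale used during
matching is undone on each row, so subject size remains in the data and the
first PCA mode can capture it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError
from .surface import Surface

__all__ = [
    "RigidTransform", "AlignedCohort", "rigid_icp", "nonrigid_register",
    "align_cohort", "align_calcifications", "select_reference",
]


@dataclass
class RigidTransform:
    """Similarity transform ``p -> scale * R @ p + t`` (scale = 1 when rigid)."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant must be +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o inner`` (inner applied first)."""
        return RigidTransform(
            rotation=self.rotation @ inner.rotation,
            translation=self.scale * self.rotation @ inner.translation + self.translation,
            scale=self.scale * inner.scale,
            converged=self.converged and inner.converged,
        )

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation / self.scale,
                              1.0 / self.scale)


@dataclass
class AlignedCohort:
    """Corresponded shape matrix: one 3m-vector per subject, template frame."""

    template: Surface
    X: np.ndarray
    transforms: list
    label: str
    patient_ids: list
    iterations_to_mean_convergence: int = 1
    converged: bool = True
    reference_id: str | None = None
    axis_rotation_indices: list | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        m = self.template.n_points
        if self.X.ndim != 2 or self.X.shape[1] != 3 * m:
            raise ValueError("X rows must have length 3 * template point count")
        if len(self.patient_ids) != len(self.X):
            raise ValueError("one patient id per row required")

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    def row_points(self, i: int) -> np.ndarray:
        return self.X[i].reshape(-1, 3)

    def row_surface(self, i: int) -> Surface:
        return Surface(self.patient_ids[i], self.label, self.row_points(i),
                       faces=self.template.faces)

    def save(self, path: str) -> None:
        np.savez_compressed(
            path, X=self.X, template_points=self.template.points,
            template_faces=(self.template.faces if self.template.faces is not None
                            else np.zeros((0, 3), np.int64)),
            label=self.label, patient_ids=np.array(self.patient_ids),
            rotations=np.stack([t.rotation for t in self.transforms]),
            translations=np.stack([t.translation for t in self.transforms]),
            scales=np.array([t.scale for t in self.transforms]),
            iterations=self.iterations_to_mean_convergence,
            reference_id=str(self.reference_id))

    @classmethod
    def load(cls, path: str) -> "AlignedCohort":
        d = np.load(path, allow_pickle=False)
        faces = d["template_faces"]
        label = str(d["label"])
        template = Surface("template", label, d["template_points"],
                           faces=faces if len(faces) else None)
        transforms = [RigidTransform(r, t, s) for r, t, s in
                      zip(d["rotations"], d["translations"], d["scales"])]
        return cls(template=template, X=d["X"], transforms=transforms,
                   label=label, patient_ids=[str(p) for p in d["patient_ids"]],
                   iterations_to_mean_convergence=int(d["iterations"]),
                   reference_id=str(d["reference_id"]))


def _check_nondegenerate(points: np.ndarray, name: str) -> None:
    pts = np.asarray(points, float)
    if len(pts) < 4:
        raise GeometryError(f"{name}: need at least 4 points")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[2] <= max(1e-9, 1e-8 * s[0]):
        raise GeometryError(f"{name}: points are coplanar or collinear")


def _procrustes(src: np.ndarray, dst: np.ndarray, with_scale: bool):
    """Least-squares similarity fit dst ~= s R src + t (Kabsch/Umeyama)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    src_c, dst_c = src - mu_s, dst - mu_d
    cov = dst_c.T @ src_c / len(src)
    U, D, Vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(U @ Vt)) or 1.0
    S = np.diag([1.0, 1.0, sign])
    R = U @ S @ Vt
    if with_scale:
        var_src = (src_c ** 2).sum() / len(src)
        scale = float(np.trace(np.diag(D) @ S) / var_src)
    else:
        scale = 1.0
    t = mu_d - scale * R @ mu_s
    return RigidTransform(R, t, scale)


def rigid_icp(moving: Surface, fixed: Surface, tolerance_mm: float = 0.01,
              max_iter: int = 120, with_scale: bool = False) -> RigidTransform:
    """Iterative closest point alignment of ``moving`` onto ``fixed``.

    Returns the similarity transform minimizing the mean closest-point
    distance.  Stops when the mean displacement of the moving cloud between
    the three most recent consecutive transform estimates drops below
    ``tolerance_mm``, or after ``max_iter`` iterations (then the transform is
    returned with ``converged=False`` and a warning).

    ``with_scale=True`` additionally estimates an isotropic scale
    (similarity ICP, used to tighten alignment before non-rigid warping).
    """
    _check_nondegenerate(moving.points, "moving cloud")
    _check_nondegenerate(fixed.points, "fixed cloud")
    tree = cKDTree(fixed.points)
    src = moving.points
    T = RigidTransform.identity()
    current = src
    disp_history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, idx = tree.query(current)
        T_new = _procrustes(src, fixed.points[idx], with_scale)
        new_pts = T_new.apply(src)
        disp = float(np.linalg.norm(new_pts - current, axis=1).mean())
        disp_history.append(disp)
        T, current = T_new, new_pts
        if len(disp_history) >= 3 and np.mean(disp_history[-3:]) < tolerance_mm:
            converged = True
            break
    if not converged:
        warnings.warn(f"ICP did not converge within {max_iter} iterations "
                      f"(last mean displacement {disp_history[-1]:.4g} mm)",
                      stacklevel=2)
    T.converged = converged
    T.n_iter = it
    return T


class _GaussianSmoother:
    """Row-normalized Gaussian smoothing over fixed template points.

    Pairwise distances are cached so the bandwidth can change cheaply
    between iterations.  Dense for small clouds; k-nearest-neighbor
    truncated for large ones so memory stays linear in point count.
    """

    def __init__(self, points: np.ndarray, k: int = 64):
        m = len(points)
        if m <= 512:
            self._d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
            self._idx = None
        else:
            tree = cKDTree(points)
            dist, idx = tree.query(points, k=k)
            self._d2, self._idx = dist ** 2, idx

    def apply(self, field: np.ndarray, bandwidth: float) -> np.ndarray:
        w = np.exp(-self._d2 / (2.0 * bandwidth ** 2))
        w /= w.sum(axis=1, keepdims=True)
        if self._idx is None:
            return w @ field
        return np.einsum("ik,ikj->ij", w, field[self._idx])


def nonrigid_register(template: Surface, target: Surface,
                      smoothing_mm: float | None = None,
                      n_iter: int = 10, anneal: bool = True) -> Surface:
    """Warp the template onto the target with a smoothed closest-point flow.

    Each iteration moves every template point toward its closest target
    point, after smoothing the displacement field with a Gaussian kernel of
    bandwidth ``smoothing_mm`` (default: 5 % of the template bounding-box
    diagonal).  With ``anneal=True`` the bandwidth decays geometrically to
    the template's median point spacing over the iterations (coarse to
    fine), so the warp captures global shape first and local detail last;
    without annealing the bandwidth is fixed, and in the large-bandwidth
    limit the displacement field collapses to its own mean, i.e. a pure
    translation.  The output keeps the template's point count and ordering —
    this step is what creates dense correspondence.
    """
    if smoothing_mm is None:
        smoothing_mm = 0.05 * template.bounding_box_diagonal()
    if smoothing_mm <= 0:
        raise ValueError("smoothing_mm must be positive")
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    smoother = _GaussianSmoother(template.points)
    if anneal and n_iter > 1:
        tree_t = cKDTree(template.points)
        spacing = float(np.median(tree_t.query(template.points, k=2)[0][:, 1]))
        floor = max(min(spacing, smoothing_mm), 1e-6)
        bandwidths = np.geomspace(smoothing_mm, floor, n_iter)
    else:
        bandwidths = np.full(n_iter, smoothing_mm)
    tree = cKDTree(target.points)
    # soft correspondence: a Gaussian-weighted average of the k nearest
    # target points.  Hard closest-point assignments flip discretely at
    # Voronoi boundaries, which makes the warp unstable to tiny input
    # perturbations; the soft version varies smoothly.
    k_corr = min(4, len(target.points))
    current = template.points.copy()
    for h in bandwidths:
        dist, idx = tree.query(current, k=k_corr)
        dist = dist.reshape(len(current), k_corr)
        idx = idx.reshape(len(current), k_corr)
        # kernel width proportional to the nearest distance: an exact match
        # collapses to its target (zero displacement for identical clouds),
        # while near-ties are averaged smoothly
        sigma = np.maximum(0.5 * dist[:, :1], 1e-12)
        w = np.exp(-(dist ** 2 - dist[:, :1] ** 2) / (2 * sigma ** 2))
        w /= w.sum(axis=1, keepdims=True)
        soft_target = np.einsum("ik,ikj->ij", w, target.points[idx])
        disp = soft_target - current
        current = current + smoother.apply(disp, h)
    return template.with_points(current, faces=template.faces)


def _canonical_axes(points: np.ndarray):
    """Deterministic, rotation-equivariant frame for a near-tubular cloud.

    Plain PCA axes are unusable here: the transverse covariance of a tube is
    nearly degenerate, so eigenvectors (and third-moment signs) flip under
    tiny perturbations.  Instead the frame is built from stable functionals:

    * axis 1 — longest principal direction, signed so the wider end of the
      tube (larger transverse spread, e.g. the flared ascending aorta) lies
      on the positive side;
    * axis 2 — the bend direction of the centerline (transverse moment
      weighted by squared axial position), which has no sign ambiguity;
    * axis 3 — completes a right-handed basis.

    Falls back to moment-signed eigenvectors when the bend is negligible.
    """
    c = points.mean(axis=0)
    centered = points - c
    cov = centered.T @ centered / len(points)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    a = evecs[:, order[0]]
    p = centered @ a
    t = centered - p[:, None] * a
    r2 = (t ** 2).sum(axis=1)
    flare = float(np.mean((p - p.mean()) * (r2 - r2.mean())))
    if flare < 0:
        a = -a
        p = -p
    w = p ** 2 - np.mean(p ** 2)
    bend = (w[:, None] * t).mean(axis=0)
    bend -= (bend @ a) * a
    scale = float(np.sqrt(evals[order[0]]))
    if np.linalg.norm(bend) > 1e-8 * scale ** 3:
        b = bend / np.linalg.norm(bend)
    else:
        b = evecs[:, order[1]]
        if np.sum((centered @ b) ** 3) < 0:
            b = -b
    E = np.column_stack([a, b, np.cross(a, b)])
    return c, E


def _centroid_size(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(np.sqrt(((points - c) ** 2).sum(axis=1).mean()))


def _normalize_size(points: np.ndarray, target: float) -> np.ndarray:
    c = points.mean(axis=0)
    return (points - c) * (target / _centroid_size(points)) + c


def _register_one(subject: Surface, template: Surface, tolerance_mm: float,
                  max_iter: int, smoothing_mm, nonrigid_iter: int,
                  init: RigidTransform | None = None):
    """Rigid + similarity ICP, then warp template onto the aligned subject.

    Returns the warped template points (template scale) and the similarity
    transform mapping the subject into the template frame.  Keeping the
    warp at template scale makes the mean-shape iteration a stable fixed
    point; subject size is restored afterwards when the cohort matrix is
    assembled.

    ICP is a local optimizer, so the subject is first carried to the
    template by matching principal axes (signs fixed by third moments) —
    a global initialization that tolerates arbitrary input poses.
    """
    if init is not None:
        # warm start from a previous outer iteration's estimate
        T0 = RigidTransform(init.rotation, init.translation)
    else:
        c_s, E_s = _canonical_axes(subject.points)
        c_t, E_t = _canonical_axes(template.points)
        R0 = E_t @ E_s.T
        T0 = RigidTransform(R0, c_t - R0 @ c_s)
        # the transverse covariance of a near-tubular shape is close to
        # degenerate, so the azimuth of the moment-based init is
        # unreliable; pick the best of several rotations about the
        # template's long axis
        tree_t = cKDTree(template.points)
        best_cost, best_T0 = np.inf, T0
        for angle in np.linspace(0.0, 2 * np.pi, 12, endpoint=False):
            cand = _axis_rotation(E_t[:, 0], angle, c_t).compose(T0)
            cost = float(tree_t.query(cand.apply(subject.points))[0].mean())
            if cost < best_cost:
                best_cost, best_T0 = cost, cand
        T0 = best_T0
    stage0 = subject.with_points(T0.apply(subject.points))
    T1 = rigid_icp(stage0, template, tolerance_mm, max_iter, with_scale=False)
    T1 = T1.compose(T0)
    stage1 = subject.with_points(T1.apply(subject.points))
    T2 = rigid_icp(stage1, template, tolerance_mm, max_iter, with_scale=True)
    T = T2.compose(T1)
    aligned = subject.with_points(T.apply(subject.points))
    warped = nonrigid_register(template, aligned, smoothing_mm, nonrigid_iter)
    return warped.points, T


def align_cohort(surfaces, reference_id: str | None = None,
                 tolerance_mm: float = 0.01, max_mean_iter: int = 10,
                 mean_tol_mm: float = 0.05, max_iter: int = 120,
                 smoothing_mm: float | None = None,
                 nonrigid_iter: int = 10) -> AlignedCohort:
    """Build dense correspondence for a cohort of same-label surfaces.

    All subjects are aligned to a reference, the template is warped onto each
    subject, and the procedure is repeated against the recomputed mean shape
    until the mean moves less than ``mean_tol_mm`` on average (or
    ``max_mean_iter`` outer iterations).  Rows are reported in the canonical
    template frame; see the module docstring.
    """
    surfaces = list(surfaces)
    if len(surfaces) < 3:
        raise ValueError("need at least 3 surfaces to build a cohort")
    labels = {s.label for s in surfaces}
    if len(labels) != 1:
        raise ValueError(f"mixed labels in cohort: {sorted(labels)}")
    label = labels.pop()
    ids = [s.patient_id for s in surfaces]
    if reference_id is None:
        reference_id = select_reference(surfaces)
    if reference_id not in ids:
        raise ValueError(f"reference id {reference_id!r} not in cohort")
    template = surfaces[ids.index(reference_id)]

    # fixed template size (cohort-average centroid size): without this the
    # similarity-scale bias of closest-point matching compounds across outer
    # iterations and the mean shape drifts in scale (the usual generalized-
    # Procrustes normalization)
    target_size = float(np.mean([_centroid_size(s.points) for s in surfaces]))
    template = template.with_points(
        _normalize_size(template.points, target_size), faces=template.faces)
    # work in the reference's canonical frame from the start: the whole
    # iteration then sees (numerically) the same inputs regardless of the
    # pose the cohort arrived in, which makes the result equivariant under
    # a common rigid motion of all inputs
    c0, E0 = _canonical_axes(template.points)
    template = template.with_points((template.points - c0) @ E0,
                                    faces=template.faces)

    warps = transforms = None
    n_outer = 0
    converged = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # per-subject ICP caps
        prev_transforms = None
        for n_outer in range(1, max_mean_iter + 1):
            warps, transforms = [], []
            for j, s in enumerate(surfaces):
                init = prev_transforms[j] if prev_transforms else None
                w, T = _register_one(s, template, tolerance_mm, max_iter,
                                     smoothing_mm, nonrigid_iter, init=init)
                warps.append(w)
                transforms.append(T)
            prev_transforms = transforms
            mean_pts = _normalize_size(np.mean(warps, axis=0), target_size)
            # damped update: the raw mean can enter a period-2 limit cycle
            # (closest-point correspondences flip between two states)
            new_template = _normalize_size(
                0.5 * (template.points + mean_pts), target_size)
            shift = float(np.linalg.norm(new_template - template.points,
                                         axis=1).mean())
            template = template.with_points(new_template, faces=template.faces)
            if shift < mean_tol_mm:
                converged = True
                break
    if not converged:
        warnings.warn("mean shape did not stabilize within "
                      f"{max_mean_iter} outer iterations", stacklevel=2)

    # restore subject size (undo the similarity scale about the template
    # centroid) so the cohort matrix keeps size variation for PCA
    mean_pts = np.mean(warps, axis=0)
    c_t = template.centroid()
    rows = [(w - c_t) / T.scale + c_t for w, T in zip(warps, transforms)]
    mean_rows = np.mean(rows, axis=0)
    c, E = _canonical_axes(mean_rows)
    rows = [(r - c) @ E for r in rows]
    template = template.with_points((mean_rows - c) @ E, faces=template.faces)
    canon = RigidTransform(E.T, -E.T @ c)
    transforms = [canon.compose(T) for T in transforms]

    return AlignedCohort(template=template,
                         X=np.stack([r.ravel() for r in rows]),
                         transforms=transforms, label=label, patient_ids=ids,
                         iterations_to_mean_convergence=n_outer,
                         converged=converged, reference_id=reference_id)


def _axis_rotation(axis: np.ndarray, angle: float, center: np.ndarray) -> RigidTransform:
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(R, center - R @ center)


def align_calcifications(calc_surfaces, wall_cohort: AlignedCohort,
                         tolerance_mm: float = 0.2, axis_rotations: int = 3,
                         max_iter: int = 120, smoothing_mm: float | None = None,
                         nonrigid_iter: int = 10) -> AlignedCohort:
    """Corresponded calcification cohort, anchored to the wall alignment.

    Each subject's calcification cloud is first carried into the wall
    template frame by that subject's wall transform (scale undone, as for
    wall rows).  Because plaques sit on three leaflets, the residual
    leaflet-to-leaflet ambiguity is resolved by testing the
    ``axis_rotations`` rotations of 360/axis_rotations degrees about the
    root axis (the wall template's longest principal axis) and keeping the
    one that minimizes the mean plaque-to-template distance.  A plaque-only
    rigid + similarity ICP at the relaxed tolerance (default 0.2 mm) and the
    non-rigid template warp then produce the corresponded rows.
    """
    calc_surfaces = list(calc_surfaces)
    calc_ids = [s.patient_id for s in calc_surfaces]
    if sorted(calc_ids) != sorted(wall_cohort.patient_ids):
        raise ValueError("calcification subjects do not match the wall cohort")
    if any(s.label != "calcification" for s in calc_surfaces):
        raise ValueError("all surfaces must carry the 'calcification' label")
    order = [calc_ids.index(pid) for pid in wall_cohort.patient_ids]
    calc_surfaces = [calc_surfaces[i] for i in order]

    wall_c = wall_cohort.template.centroid()
    # canonical frame: first axis is the wall template's longest extent
    axis = np.array([1.0, 0.0, 0.0])
    _, E = _canonical_axes(wall_cohort.template.points)
    axis = E[:, 0]

    moved = []
    for surf, T in zip(calc_surfaces, wall_cohort.transforms):
        pts = (T.apply(surf.points) - wall_c) / T.scale + wall_c
        moved.append(surf.with_points(pts))

    ref_idx = (wall_cohort.patient_ids.index(wall_cohort.reference_id)
               if wall_cohort.reference_id in wall_cohort.patient_ids else 0)
    template = moved[ref_idx]
    tree = cKDTree(template.points)

    rows, transforms, chosen = [], [], []
    for surf, moved_surf, T_wall in zip(calc_surfaces, moved, wall_cohort.transforms):
        best_k, best_cost, best_pts, best_rot = 0, np.inf, moved_surf.points, None
        for k in range(axis_rotations):
            rot = _axis_rotation(axis, 2 * np.pi * k / axis_rotations, wall_c)
            pts = rot.apply(moved_surf.points)
            cost = float(tree.query(pts)[0].mean())
            if cost < best_cost:
                best_k, best_cost, best_pts, best_rot = k, cost, pts, rot
        chosen.append(best_k)
        rotated = moved_surf.with_points(best_pts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            warp, T_icp = _register_one(rotated, template, tolerance_mm,
                                        max_iter, smoothing_mm, nonrigid_iter)
        c_t = template.centroid()
        rows.append((warp - c_t) / T_icp.scale + c_t)  # keep plaque size
        # full transform: original calc -> template frame (without the final
        # row unscaling, which is a reporting convention, not a motion)
        unscale = RigidTransform(np.eye(3),
                                 wall_c - wall_c / T_wall.scale, 1.0 / T_wall.scale)
        transforms.append(T_icp.compose(best_rot.compose(unscale.compose(T_wall))))

    return AlignedCohort(template=template,
                         X=np.stack([r.ravel() for r in rows]),
                         transforms=transforms, label="calcification",
                         patient_ids=list(wall_cohort.patient_ids),
                         iterations_to_mean_convergence=1,
                         reference_id=wall_cohort.patient_ids[ref_idx],
                         axis_rotation_indices=chosen)


def select_reference(surfaces) -> str:
    """Pick the subject whose annulus diameter is closest to the cohort median.

    Falls back to the first subject for clouds too small to measure.
    """
    from .morphometrics import annulus_diameter

    diameters = []
    for s in surfaces:
        try:
            diameters.append(annulus_diameter(s))
        except Exception:
            diameters.append(np.nan)
    diameters = np.asarray(diameters)
    if np.isnan(diameters).all():
        return surfaces[0].patient_id
    median = np.nanmedian(diameters)
    idx = int(np.nanargmin(np.abs(diameters - median)))
    return surfaces[idx].patient_id
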