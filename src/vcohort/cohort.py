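"""Virtual patient synthesis by bounded random sampling of shape modes.

New anatomies are produced by deforming the mean shape along the modes that
retain 90 % of the shape variability, with per-mode weights drawn uniformly
from the discrete grid {-b, -b+step, ..., b} in sigma units (defaults
b = 2, step = 0.5).  Each deformed shape is annotated with an occurrence
probability and screened by an automated plausibility check (no folded or
self-intersecting surfaces); rejected draws are resampled.

On the occurrence probability: the deviation of a deformed shape from the
mean is measured in sigma units, and the reported probability is the
one-sided standardized upper-tail probability at the shape boundary b —
e.g. 30.85 % at 0.5 sigma and 2.28 % at 2 sigma, so a +/- 2 sigma cohort
leaves out under 2.28 % of shape variation per mode.  A chi-square variant
(squared Mahalanobis distance with k = 3 degrees of freedom) is exposed
separately as :func:`chi_square_shape_probability`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi2, norm

from .errors import GenerationError, GeometryError
from .ssm import ShapeModel, deform, modes_for_variance
from .surface import Surface

__all__ = ["ModeWeights", "VirtualShape", "VirtualPatient", "sample_weights",
           "shape_probability", "chi_square_shape_probability",
           "plausibility_check", "generate_cohort"]


@dataclass
class ModeWeights:
    """Per-mode deformation weights in sigma units, on a discrete grid."""

    weights: np.ndarray
    boundary: float
    step: float
    seed: int | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float).ravel()
        if self.boundary <= 0:
            raise ValueError("boundary must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if np.any(np.abs(self.weights) > self.boundary + 1e-9):
            raise ValueError("weights must lie within +/- boundary")
        ratio = self.weights / self.step
        if not np.allclose(ratio, np.round(ratio), atol=1e-9):
            raise ValueError("weights must be integer multiples of step")

    @property
    def max_deviation(self) -> float:
        return float(np.abs(self.weights).max()) if self.weights.size else 0.0


@dataclass
class VirtualShape:
    """A deformed surface with its weights, probability and plausibility."""

    surface: Surface
    weights: ModeWeights
    probability: float
    plausible: bool = False
    rejection_reason: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")
        if self.plausible and self.rejection_reason is not None:
            raise ValueError("a plausible shape cannot carry a rejection reason")


@dataclass
class VirtualPatient:
    patient_id: str
    wall: VirtualShape
    calcification: VirtualShape


def sample_weights(model: ShapeModel, n_modes: int, boundary: float = 2.0,
                   step: float = 0.5, seed: int | None = None) -> ModeWeights:
    """Draw one weight vector uniformly on the sigma grid.

    Each of the first ``n_modes`` weights is drawn independently and
    uniformly from {-b, -b+step, ..., 0, ..., b}; the remaining modes are
    implicitly zero.  Deterministic for a fixed seed.
    """
    if n_modes < 1 or n_modes > model.n_modes:
        raise ValueError(f"n_modes must be in [1, {model.n_modes}]")
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    if step <= 0 or step > boundary:
        raise ValueError("step must be positive and no larger than boundary")
    n_steps = boundary / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("step must divide boundary")
    n_steps = int(round(n_steps))
    levels = np.arange(-n_steps, n_steps + 1) * step
    rng = np.random.default_rng(seed)
    w = rng.choice(levels, size=n_modes)
    return ModeWeights(weights=w, boundary=boundary, step=step, seed=seed)


def shape_probability(deviation) -> float:
    """Occurrence probability of a shape at the given deviation (sigma units).

    This is the one-sided standardized upper-tail probability: 0.5 at zero
    deviation, 0.3085 at 0.5 sigma, 0.0228 at 2 sigma; strictly decreasing.
    """
    dev = np.asarray(deviation, float)
    if np.any(dev < 0):
        raise ValueError("deviation must be non-negative")
    out = norm.sf(dev)
    return float(out) if out.ndim == 0 else out


def chi_square_shape_probability(deviation) -> float:
    """Upper-tail of the squared Mahalanobis distance under chi-square(k=3)."""
    dev = np.asarray(deviation, float)
    if np.any(dev < 0):
        raise ValueError("deviation must be non-negative")
    out = chi2.sf(dev ** 2, df=3)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# plausibility screening


def _face_normals(points: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (points[faces[:, k]] for k in range(3))
    return np.cross(v1 - v0, v2 - v0)


def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray) -> bool:
    """Moller-style triangle/triangle intersection test for one pair."""

    def plane(tri):
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        return n, -n.dot(tri[0])

    n2, d2 = plane(t2)
    dist1 = t1 @ n2 + d2
    if np.all(dist1 > 1e-12) or np.all(dist1 < -1e-12):
        return False
    n1, d1 = plane(t1)
    dist2 = t2 @ n1 + d1
    if np.all(dist2 > 1e-12) or np.all(dist2 < -1e-12):
        return False
    direction = np.cross(n1, n2)
    if np.linalg.norm(direction) < 1e-12:
        return False  # coplanar pairs: treated as non-crossing
    axis = np.argmax(np.abs(direction))

    def interval(tri, dist):
        proj = tri[:, axis]
        pts = []
        for i in range(3):
            for j in range(i + 1, 3):
                if dist[i] * dist[j] < 0:
                    t = dist[i] / (dist[i] - dist[j])
                    pts.append(proj[i] + t * (proj[j] - proj[i]))
        on_plane = np.abs(dist) <= 1e-12
        pts.extend(proj[on_plane])
        if len(pts) < 2:
            return None
        return min(pts), max(pts)

    i1 = interval(t1, dist1)
    i2 = interval(t2, dist2)
    if i1 is None or i2 is None:
        return False
    return max(i1[0], i2[0]) < min(i1[1], i2[1]) - 1e-12


def _self_intersects(points: np.ndarray, faces: np.ndarray) -> bool:
    """BVH-flavored pairwise test: KD-tree pruning on triangle centroids."""
    tris = points[faces]
    centroids = tris.mean(axis=1)
    edge_max = max(np.linalg.norm(tris[:, i] - tris[:, j], axis=1).max()
                   for i, j in ((0, 1), (1, 2), (2, 0)))
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(r=1.01 * edge_max, output_type="ndarray")
    if len(pairs) == 0:
        return False
    share = np.array([len(set(faces[a]) & set(faces[b])) > 0 for a, b in pairs])
    for a, b in pairs[~share]:
        if _tri_tri_intersect(tris[a], tris[b]):
            return True
    return False


def plausibility_check(shape: VirtualShape, model: ShapeModel,
                       normal_agreement: float = 0.99,
                       spike_factor: float = 3.0) -> VirtualShape:
    """Screen a deformed shape for folded or self-intersecting geometry.

    With a triangulation, the shape fails if any two non-adjacent triangles
    intersect, or if fewer than ``normal_agreement`` of the face normals
    point the same way as the corresponding mean-shape normals.  Without
    faces, correspondence with the mean shape is used directly: local
    orientation is checked via neighbor cross products on the mean-shape
    k-nearest-neighbor graph, and single-vertex spikes are caught by
    comparing each point's displacement from the mean against the local
    average displacement (threshold: ``spike_factor`` times the local
    point spacing).
    """
    surf = shape.surface
    mean_pts = model.mean.reshape(-1, 3)
    if surf.n_points != len(mean_pts):
        raise ValueError("shape is not corresponded to the model's template")
    reason = None

    if surf.faces is not None and len(surf.faces):
        n_mean = _face_normals(mean_pts, surf.faces)
        n_def = _face_normals(surf.points, surf.faces)
        agree = np.einsum("ij,ij->i", n_mean, n_def) > 0
        if agree.mean() < normal_agreement:
            reason = (f"normal flip on {(~agree).sum()} of {len(agree)} faces")
        elif _self_intersects(surf.points, surf.faces):
            reason = "triangle self-intersection"
    else:
        if surf.n_points < 10:
            raise GeometryError("faceless plausibility check needs >= 10 points")
        k = min(8, surf.n_points - 1)
        tree = cKDTree(mean_pts)
        dist, nb = tree.query(mean_pts, k=k + 1)
        dist, nb = dist[:, 1:], nb[:, 1:]
        # orientation: the local normal estimated from neighbor cross
        # products (summed over consecutive neighbor pairs, fixed graph
        # from the mean shape) must keep its sign under the deformation
        def _local_normals(pts):
            edges = pts[nb] - pts[:, None, :]
            return np.cross(edges[:, :-1, :], edges[:, 1:, :]).sum(axis=1)

        if surf.label == "calcification":
            # plaques are volumetric clouds: local surface orientation is
            # undefined, so only the displacement-continuity test applies
            agree = np.ones(0, bool)
        else:
            c_mean = _local_normals(mean_pts)
            c_def = _local_normals(surf.points)
            norm_mean = np.linalg.norm(c_mean, axis=1)
            ok = norm_mean > 0.1 * np.median(norm_mean)  # ill-conditioned
            agree = np.einsum("ij,ij->i", c_mean[ok], c_def[ok]) > 0
        disp = surf.points - mean_pts
        local = disp[nb].mean(axis=1)
        resid = np.linalg.norm(disp - local, axis=1)
        spacing = np.median(dist, axis=1)
        spikes = resid > spike_factor * np.maximum(spacing, 1e-6)
        if agree.size and agree.mean() < normal_agreement:
            reason = (f"local orientation flip on {(~agree).sum()} of "
                      f"{agree.size} points")
        elif spikes.any():
            reason = f"displacement spike at {int(spikes.sum())} point(s)"

    return replace(shape, plausible=reason is None, rejection_reason=reason)


def _draw_shape(model: ShapeModel, n_modes: int, boundary: float, step: float,
                rng: np.random.Generator, max_attempts: int,
                patient_id: str) -> VirtualShape:
    last = None
    for _ in range(max_attempts):
        attempt_seed = int(rng.integers(2 ** 31))
        w = sample_weights(model, n_modes, boundary, step, seed=attempt_seed)
        surf = deform(model, w)
        surf = replace(surf, patient_id=patient_id)
        vs = VirtualShape(surface=surf, weights=w,
                          probability=shape_probability(w.max_deviation))
        vs = plausibility_check(vs, model)
        if vs.plausible:
            return vs
        last = vs
    raise GenerationError(
        f"no plausible shape after {max_attempts} attempts for {patient_id}; "
        f"last weights {np.array2string(last.weights.weights, precision=2)} "
        f"({last.rejection_reason})")


def generate_cohort(wall_model: ShapeModel, calc_model: ShapeModel,
                    n: int = 100, variance_fraction: float = 0.90,
                    boundary: float = 2.0, step: float = 0.5,
                    seed: int | None = None,
                    max_attempts_per_shape: int = 50) -> list:
    """Generate ``n`` plausibility-screened wall + calcification pairs.

    The number of sampled modes per model retains ``variance_fraction`` of
    the shape variability (90 % by default).  Wall and calcification weights
    are drawn independently from a shared seeded stream, so the whole cohort
    is reproducible from one seed; each shape's attempt seed is recorded on
    its :class:`ModeWeights`.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if wall_model.n_modes == 0 or calc_model.n_modes == 0:
        raise ValueError("both models must have at least one mode")
    nm_wall = modes_for_variance(wall_model, variance_fraction)
    nm_calc = modes_for_variance(calc_model, variance_fraction)
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        pid = f"virtual_{i:03d}"
        wall = _draw_shape(wall_model, nm_wall, boundary, step, rng,
                           max_attempts_per_shape, pid)
        calc = _draw_shape(calc_model, nm_calc, boundary, step, rng,
                           max_attempts_per_shape, pid)
        patients.append(VirtualPatient(pid, wall, calc))
    return patients


def cohort_manifest(patients) -> "pandas.DataFrame":
    """Tabular summary of a virtual cohort (one row per patient)."""
    import pandas as pd

    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id,
               "wall_probability": p.wall.probability,
               "calc_probability": p.calcification.probability,
               "plausible": p.wall.plausible and p.calcification.plausible}
        for j, w in enumerate(p.wall.weights.weights):
            row[f"wall_w{j + 1}"] = w
        for j, w in enumerate(p.calcification.weights.weights):
            row[f"calc_w{j + 1}"] = w
        rows.append(row)
    return pd.DataFrame(rows)
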