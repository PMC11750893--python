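"""Anatomical surface I/O, resampling, and grid-resolution convergence.

Surfaces are labeled 3D point clouds (optionally triangulated) in millimetres,
one per subject and structure (aortic-root wall or calcification).  STL carries
no unit information; coordinates are interpreted as mm, the CT convention.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import FormatError, GeometryError

WALL = "wall"
CALCIFICATION = "calcification"
_LABELS = (WALL, CALCIFICATION)


@dataclass
class Surface:
    """A labeled anatomical point cloud in mm, optionally triangulated.

    Parameters
    ----------
    patient_id : str
        Subject identifier.
    label : {"wall", "calcification"}
        Which structure the points describe.
    points : (m, 3) float array
        Vertex coordinates in mm; all finite, m >= 4.
    faces : (f, 3) int array, optional
        Triangle vertex indices; every index < m.
    source_path : str
        Where the surface was loaded from, if anywhere.
    """

    patient_id: str
    label: str
    points: np.ndarray
    faces: np.ndarray | None = None
    source_path: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (m, 3) array")
        if len(self.points) < 4:
            raise ValueError("a surface needs at least 4 points")
        if not np.isfinite(self.points).all():
            raise ValueError("all coordinates must be finite")
        if self.label not in _LABELS:
            raise ValueError(f"label must be one of {_LABELS}, got {self.label!r}")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)
            if self.faces.ndim != 2 or self.faces.shape[1] != 3:
                raise ValueError("faces must be an (f, 3) array")
            if len(self.faces) and self.faces.max() >= len(self.points):
                raise ValueError("face index out of range")
            if len(self.faces) and self.faces.min() < 0:
                raise ValueError("face indices must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def with_points(self, points: np.ndarray, faces: np.ndarray | None = None) -> "Surface":
        """Copy of this surface with replaced geometry."""
        return replace(self, points=np.asarray(points, float), faces=faces)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def bounding_box_diagonal(self) -> float:
        ext = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(ext))


@dataclass
class ResolutionReport:
    """Outcome of the grid-resolution convergence study.

    ``first_mode_fraction`` holds the mode-1 explained-variance fraction at
    each resampling level; convergence is declared at the first level whose
    relative change against the previous level drops below ``threshold``.
    """

    levels: list
    first_mode_fraction: list
    converged_level: int
    relative_changes: list
    threshold: float
    converged: bool = True

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly increasing")
        if any(c < 0 for c in self.relative_changes):
            raise ValueError("relative changes must be non-negative")


def read_surface(path: str, label: str) -> Surface:
    """Load an STL or PLY surface as a :class:`Surface`.

    The format is auto-detected by trimesh from the extension and magic
    bytes.  Duplicate vertices are merged when faces are present (binary STL
    stores each triangle's vertices independently).
    """
    if not os.path.exists(path):
        raise FormatError(f"no such surface file: {path}")
    if os.path.getsize(path) == 0:
        raise FormatError(f"empty surface file: {path}")
    try:
        mesh = trimesh.load(path, force=None)
    except Exception as exc:  # trimesh raises a zoo of types
        raise FormatError(f"could not parse surface file {path}: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise FormatError(f"no geometry in {path}")
        mesh = geoms[0]
    if isinstance(mesh, trimesh.points.PointCloud):
        points, faces = np.asarray(mesh.vertices, float), None
    elif isinstance(mesh, trimesh.Trimesh):
        mesh.merge_vertices()
        points = np.asarray(mesh.vertices, float)
        faces = np.asarray(mesh.faces, np.int64) if len(mesh.faces) else None
    else:
        raise FormatError(f"unsupported geometry type in {path}: {type(mesh).__name__}")
    if len(points) == 0:
        raise FormatError(f"no geometry in {path}")
    patient_id = os.path.splitext(os.path.basename(path))[0]
    try:
        return Surface(patient_id, label, points, faces, source_path=path)
    except ValueError as exc:
        raise FormatError(f"invalid geometry in {path}: {exc}") from exc


def write_surface(surface: Surface, path: str) -> None:
    """Write a surface as ASCII STL (faces required) or ASCII PLY.

    Both encodings keep full double precision, so read -> write -> read
    round-trips preserve coordinates to well below 1e-6 mm.  (Binary STL/PLY
    would truncate to float32.)
    """
    ext = os.path.splitext(path)[1].lower()
    if ext == ".stl":
        if surface.faces is None:
            raise ValueError("STL requires faces; use .ply for point clouds")
        mesh = trimesh.Trimesh(vertices=surface.points, faces=surface.faces, process=False)
        mesh.export(path, file_type="stl_ascii")
    elif ext == ".ply":
        _write_ascii_ply(surface, path)
    else:
        raise ValueError(f"unsupported surface format: {ext!r} (use .stl or .ply)")


def _write_ascii_ply(surface: Surface, path: str) -> None:
    # double-precision ASCII PLY; trimesh's exporter casts vertices to float32
    lines = ["ply", "format ascii 1.0", f"element vertex {surface.n_points}",
             "property double x", "property double y", "property double z"]
    if surface.faces is not None:
        lines += [f"element face {len(surface.faces)}",
                  "property list uchar int vertex_indices"]
    lines.append("end_header")
    lines += ["%.17g %.17g %.17g" % tuple(p) for p in surface.points]
    if surface.faces is not None:
        lines += ["3 %d %d %d" % tuple(f) for f in surface.faces]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def resample(surface: Surface, target_n: int, seed: int) -> Surface:
    """Uniform random subsample of the point cloud, without replacement.

    Faces are dropped: the subset is no longer a consistent triangulation.
    Deterministic for a fixed seed.
    """
    if target_n > surface.n_points:
        raise ValueError(
            f"target_n={target_n} exceeds point count {surface.n_points}")
    if target_n < 4:
        raise ValueError("target_n must be at least 4")
    rng = np.random.default_rng(seed)
    idx = rng.choice(surface.n_points, size=target_n, replace=False)
    out = replace(surface, points=surface.points[idx], faces=None)
    return out


# Paper-derived default resampling targets (points per structure).
DEFAULT_WALL_POINTS = 30_000
DEFAULT_CALC_POINTS = 50_000


def resolution_convergence(surfaces, levels, threshold: float = 0.05,
                           seed: int = 0, **align_kwargs) -> ResolutionReport:
    """Mode-1 variance fraction vs resampling level, with a 5 % stopping rule.

    For each level every surface is randomly resampled to that point count,
    the full correspondence + PCA pipeline is run, and the explained-variance
    fraction of the first shape mode is recorded.  The converged level is the
    first whose relative change against the previous level is below
    ``threshold``; if none converges the largest level is returned and
    ``converged`` is False (with a warning).
    """
    from .registration import align_cohort
    from .ssm import fit

    surfaces = list(surfaces)
    if len(surfaces) < 3:
        raise ValueError("need at least 3 surfaces")
    levels = [int(l) for l in levels]
    if len(levels) < 2:
        raise ValueError("need at least 2 resolution levels")
    if any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError("levels must be strictly increasing")

    fractions = []
    rng = np.random.default_rng(seed)
    for level in levels:
        sub = [resample(s, level, int(rng.integers(2 ** 31))) for s in surfaces]
        cohort = align_cohort(sub, reference_id=sub[0].patient_id, **align_kwargs)
        model = fit(cohort)
        fractions.append(float(model.variance_fractions[0]) if model.n_modes else 0.0)

    changes = []
    converged_level, converged = levels[-1], False
    for prev, cur, level in zip(fractions, fractions[1:], levels[1:]):
        denom = abs(prev) if prev else 1.0
        change = abs(cur - prev) / denom
        changes.append(change)
        if not converged and change < threshold:
            converged_level, converged = level, True
    if not converged:
        warnings.warn("first-mode fraction did not converge at any level; "
                      "using the largest level", stacklevel=2)
    return ResolutionReport(levels=levels, first_mode_fraction=fractions,
                            converged_level=converged_level,
                            relative_changes=changes, threshold=threshold,
                            converged=converged)
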