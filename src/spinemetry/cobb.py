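"""Analytic Cobb angle of a fitted spine centerline.

The clinical Cobb angle is measured between the endplates of the two
most tilted vertebrae of a curve.  The automated surrogate computed
here projects the fitted centerline into an anatomical plane and takes
the maximum angle between any two (rostral-to-caudal oriented) tangent
directions.  For a planar circular arc this equals the subtended angle,
i.e. the value an endplate-based measurement converges to.

Planes follow the package coordinate convention (x medio-lateral,
y dorso-ventral, z rostro-caudal): the *coronal* projection (normal y)
is where scoliosis is read, the *sagittal* projection (normal x) is
where kyphosis is read.  A custom unit normal may be given instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, UsageError, ValidationError
from .geometry import SpineCurve, evaluate_curve

__all__ = ["PLANE_NORMALS", "ProjectedCurve", "CobbMeasurement",
           "project_curve", "cobb_angle"]

PLANE_NORMALS = {
    "coronal": np.array([0.0, 1.0, 0.0]),
    "sagittal": np.array([1.0, 0.0, 0.0]),
}


@dataclass
class ProjectedCurve:
    """Centerline samples projected into a plane, with unit tangents."""

    plane: str
    normal: np.ndarray
    t_grid: np.ndarray  # parameters of the retained samples
    points: np.ndarray  # (n, 3) projected positions
    tangents: np.ndarray  # (n, 3) unit projected tangents, rostral->caudal


@dataclass
class CobbMeasurement:
    plane: str
    t_lower: float
    t_upper: float
    angle_deg: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValidationError("Cobb angle must lie in [0, 180) degrees")
        if self.t_lower >= self.t_upper:
            raise ValidationError("t_lower must be < t_upper")


def _resolve_plane(plane: str | np.ndarray) -> tuple[str, np.ndarray]:
    if isinstance(plane, str):
        if plane not in PLANE_NORMALS:
            raise UsageError(
                f"unknown plane {plane!r}; use 'coronal', 'sagittal' or a normal vector"
            )
        return plane, PLANE_NORMALS[plane]
    normal = np.asarray(plane, dtype=float)
    if normal.shape != (3,):
        raise UsageError("custom plane normal must be a 3-vector")
    norm = np.linalg.norm(normal)
    if norm < 1e-12:
        raise UsageError("plane normal must be non-zero")
    return "custom", normal / norm


def project_curve(
    curve: SpineCurve, plane: str | np.ndarray = "coronal", grid_size: int = 512
) -> ProjectedCurve:
    """Orthogonally project positions and tangents into a plane.

    Grid points whose projected tangent nearly vanishes (centerline
    locally orthogonal to the plane) are dropped; if more than half are
    dropped the curve is essentially orthogonal to the plane and a
    :class:`GeometryError` is raised.
    """
    name, normal = _resolve_plane(plane)
    t = np.linspace(0.0, 1.0, grid_size)
    pos, d1, _ = evaluate_curve(curve, t)
    proj_pos = pos - np.outer(pos @ normal, normal)
    proj_tan = d1 - np.outer(d1 @ normal, normal)
    norms = np.linalg.norm(proj_tan, axis=1)
    keep = norms >= 1e-9
    if keep.sum() < 0.5 * grid_size:
        raise GeometryError(
            "more than half of the tangents vanish after projection: "
            "curve is nearly orthogonal to the requested plane"
        )
    return ProjectedCurve(
        plane=name,
        normal=normal,
        t_grid=t[keep],
        points=proj_pos[keep],
        tangents=proj_tan[keep] / norms[keep, None],
    )


def cobb_angle(projected: ProjectedCurve) -> CobbMeasurement:
    """Maximum angle between oriented projected tangents.

    Tangents keep their rostral-to-caudal orientation, so the angle
    between a pair lies in [0, 180) and an S-shaped spine accumulates
    the divergence of its two opposed lobes.  Ties are broken by the
    lexicographically smallest (t_lower, t_upper) pair.
    """
    u = projected.tangents
    if u.shape[0] < 3:
        raise ValidationError("need >= 3 tangent samples for a Cobb angle")
    gram = u @ u.T
    # restrict to i < j; row-major argmin then picks the smallest (i, j)
    iu = np.triu_indices(u.shape[0], k=1)
    dots = gram[iu]
    k = int(np.argmin(dots))
    i, j = int(iu[0][k]), int(iu[1][k])
    angle = float(np.degrees(np.arccos(np.clip(dots[k], -1.0, 1.0))))
    angle = min(angle, np.nextafter(180.0, 0.0))
    return CobbMeasurement(
        plane=projected.plane,
        t_lower=float(projected.t_grid[i]),
        t_upper=float(projected.t_grid[j]),
        angle_deg=angle,
    )
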