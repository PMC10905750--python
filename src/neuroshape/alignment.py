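"""Canonical orientation and organ-relative location of cells and nuclei.

Rosette geometry dominates raw cell orientation: cells point at the
organ centre and tilt as they converge apically.  Alignment removes
this with three rotations.  Rotation 1 turns each cell about z by its
position angle so the radial direction maps onto +x.  Rotation 2
aligns the long axis of the xz-projection to z (for nuclei only when
the required turn is at most 45 deg; otherwise the axis goes to x).
Rotation 3 aligns the yz-projected long axis to z unless that would
take more than 45 deg, in which case the axis goes to y — preventing
horizontally lying shapes from being flipped upright.

"Long axis" means the dominant eigenvector of the projected
second-moment matrix of the surface coordinates, with the sign chosen
so the applied rotation is at most 90 deg in magnitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from .core import LabeledVolume, rotation_x, rotation_y, rotation_z, wrap_angle_deg

__all__ = [
    "NeuromastFrame",
    "LocationRecord",
    "AlignedShape",
    "compute_neuromast_frame",
    "rotation1_angle",
    "apply_rotation1",
    "align_shape",
    "location_record",
    "geometric_features",
]

_DEGENERATE_EIG_RATIO = 1.0 + 1e-6


@dataclass
class NeuromastFrame:
    """Organ centroid, radius and polarity of one neuromast."""

    centroid_um: np.ndarray  # (x, y, z)
    max_radius_r: float
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in ("parallel", "perpendicular"):
            raise ValueError("polarity must be 'parallel' or 'perpendicular'")


@dataclass(frozen=True)
class LocationRecord:
    """Normalized radial distance and (adjusted) angular location."""

    d: float
    o: float
    a: float


@dataclass
class AlignedShape:
    """A mesh in canonical pose plus the rotation angles that put it there.

    ``rotation_matrix`` is the net rotation applied to the centred
    vertices by rotations 2 and 3 (rotation 1 is applied upstream);
    its transpose recovers the original pose.
    """

    mesh: trimesh.Trimesh
    theta1: float
    theta2: float
    theta3: float
    object_class: str  # cell | nucleus
    voxel_count: int | None = None
    voxel_volume_um3: float | None = None
    rotation_matrix: np.ndarray | None = None
    flags: tuple[str, ...] = ()


def compute_neuromast_frame(
    cell_labels: LabeledVolume, polarity: str = "parallel"
) -> NeuromastFrame:
    """Organ centroid (union mask) and xy radius to the farthest cell."""
    centroids = cell_labels.centroids_um()
    if not centroids:
        raise ValueError("no cells in the label volume")
    mask = cell_labels.labels > 0
    zz, yy, xx = np.nonzero(mask)
    vz, vy, vx = cell_labels.voxel_size_um
    centroid = np.array([xx.mean() * vx, yy.mean() * vy, zz.mean() * vz])
    radii = [np.hypot(c[0] - centroid[0], c[1] - centroid[1])
             for c in centroids.values()]
    r = float(max(radii))
    if len(centroids) == 1:
        warnings.warn("single-cell organ: radius taken from that cell")
    if r <= 0:
        warnings.warn("all cell centroids coincide with the organ centroid")
    return NeuromastFrame(centroid, r, polarity)


def rotation1_angle(cell_centroid: np.ndarray, frame: NeuromastFrame) -> float:
    """Signed angle (deg) of the organ-to-cell xy vector from +x.

    Rotating the shape about z by the negative of this angle maps its
    radial direction onto +x.  A cell exactly at the organ centroid
    gets angle 0 with a warning.
    """
    dx = float(cell_centroid[0] - frame.centroid_um[0])
    dy = float(cell_centroid[1] - frame.centroid_um[1])
    if np.hypot(dx, dy) < 1e-12:
        warnings.warn("cell centroid coincides with the organ centroid in xy")
        return 0.0
    return wrap_angle_deg(np.degrees(np.arctan2(dy, dx)))


def apply_rotation1(mesh: trimesh.Trimesh, angle_deg: float,
                    about: np.ndarray | None = None) -> trimesh.Trimesh:
    """Rotate a mesh about the z axis by ``-angle_deg`` (radial -> +x)."""
    m = mesh.copy()
    c = m.center_mass if about is None else np.asarray(about, float)
    m.apply_translation(-c)
    m.apply_transform(_homog(rotation_z(-angle_deg)))
    return m


def _homog(r: np.ndarray) -> np.ndarray:
    t = np.eye(4)
    t[:3, :3] = r
    return t


def _projected_axis_angle(points: np.ndarray, plane: str) -> tuple[float, bool]:
    """Angle (deg) from the second plane-axis to the long axis.

    ``plane`` is ``"xz"`` or ``"yz"``; the angle is measured from z
    toward x (resp. y), in [-90, 90].  Returns (angle, degenerate).
    """
    cols = {"xz": (0, 2), "yz": (1, 2)}[plane]
    p = points[:, cols] - points[:, cols].mean(axis=0)
    cov = p.T @ p / len(p)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= evals[0] * _DEGENERATE_EIG_RATIO:
        return 0.0, True
    v = evecs[:, 1]  # (horizontal, z) components of the long axis
    ang = np.degrees(np.arctan2(v[0], v[1]))
    if ang > 90.0:
        ang -= 180.0
    elif ang <= -90.0:
        ang += 180.0
    return float(ang), False


def align_shape(shape: trimesh.Trimesh, object_class: str = "cell",
                theta1: float = 0.0) -> AlignedShape:
    """Apply rotations 2 and 3 to a rotation-1-aligned mesh.

    Cells: rotation 2 sends the xz long axis to z unconditionally.
    Nuclei: rotation 2 is capped at 45 deg — beyond that the axis goes
    to x instead.  Rotation 3 (both classes) sends the yz long axis to
    z, or to y when more than 45 deg would be needed.  Degenerate
    (isotropic) projections skip their rotation with a flag.
    """
    if object_class not in ("cell", "nucleus"):
        raise ValueError("object_class must be 'cell' or 'nucleus'")
    m = shape.copy()
    m.apply_translation(-m.center_mass)
    flags: list[str] = []

    ang2, degen2 = _projected_axis_angle(m.vertices, "xz")
    if degen2:
        theta2 = 0.0
        flags.append("rotation2_degenerate")
    elif object_class == "nucleus" and abs(ang2) > 45.0:
        theta2 = ang2 - np.sign(ang2) * 90.0  # long axis -> x
    else:
        theta2 = ang2  # long axis -> z
    if theta2 != 0.0:
        # R_y(phi) advances the xz axis angle by phi; undo the tilt
        m.apply_transform(_homog(rotation_y(-theta2)))

    ang3, degen3 = _projected_axis_angle(m.vertices, "yz")
    if degen3:
        theta3 = 0.0
        flags.append("rotation3_degenerate")
    elif abs(ang3) > 45.0:
        theta3 = ang3 - np.sign(ang3) * 90.0  # long axis -> y
    else:
        theta3 = ang3
    if theta3 != 0.0:
        # R_x(phi) retards the yz axis angle by phi
        m.apply_transform(_homog(rotation_x(theta3)))

    r_net = rotation_x(theta3) @ rotation_y(-theta2)
    return AlignedShape(m, float(theta1), float(theta2), float(theta3),
                        object_class, rotation_matrix=r_net,
                        flags=tuple(flags))


def location_record(
    cell_centroid: np.ndarray,
    frame: NeuromastFrame,
    perpendicular_offset_deg: float = -90.0,
) -> LocationRecord:
    """Normalized distance and original/adjusted angles of one cell.

    For perpendicular organs the angle is shifted by
    ``perpendicular_offset_deg`` (default -90, a 90-deg turn aligning
    the organ's poles with those of parallel organs) and wrapped back
    into (-180, 180].
    """
    if frame.max_radius_r <= 0:
        raise ValueError("frame radius must be positive")
    dx = float(cell_centroid[0] - frame.centroid_um[0])
    dy = float(cell_centroid[1] - frame.centroid_um[1])
    d = float(np.hypot(dx, dy) / frame.max_radius_r)
    o = rotation1_angle(cell_centroid, frame)
    if frame.polarity == "perpendicular":
        a = wrap_angle_deg(o + perpendicular_offset_deg)
    else:
        a = o
    return LocationRecord(d=d, o=o, a=float(a))


def geometric_features(
    aligned: AlignedShape, voxel_size_um: tuple[float, float, float] | None = None
) -> dict[str, float]:
    """Width/depth/height (x/y/z extents), volume and surface area.

    Extents and surface area come from the aligned mesh.  Volume is the
    voxel count times the voxel volume when the shape was digitized
    (``aligned.voxel_count`` set); otherwise the mesh volume.
    """
    m = aligned.mesh
    if len(m.vertices) == 0:
        raise ValueError("empty shape")
    lo, hi = m.bounds
    feats = {
        "width_um": float(hi[0] - lo[0]),
        "depth_um": float(hi[1] - lo[1]),
        "height_um": float(hi[2] - lo[2]),
        "surface_area_um2": float(m.area),
    }
    if aligned.voxel_count is not None:
        if aligned.voxel_volume_um3 is not None:
            vvox = aligned.voxel_volume_um3
        elif voxel_size_um is not None:
            vvox = float(np.prod(voxel_size_um))
        else:
            raise ValueError("voxel volume unknown for a digitized shape")
        feats["volume_um3"] = float(aligned.voxel_count * vvox)
    else:
        feats["volume_um3"] = float(m.volume)
    return feats
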