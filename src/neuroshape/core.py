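"""Shared containers and small numeric helpers.

Conventions used throughout the package:

* Voxel arrays are indexed ``(z, y, x)`` and carry a ``voxel_size_um``
  triple in the same order.
* Point coordinates handed to geometry code are ``(x, y, z)`` in
  micrometres.
* Angles are degrees in the half-open interval ``(-180, 180]``, measured
  with the ``atan2`` convention from the +x axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledVolume",
    "wrap_angle_deg",
    "points_from_mask",
    "rotation_z",
    "rotation_y",
    "rotation_x",
]


@dataclass
class LabeledVolume:
    """A 3D integer label image with voxel-size metadata.

    ``labels`` is a non-negative integer array indexed ``(z, y, x)``;
    background is 0.  ``voxel_size_um`` is the physical voxel spacing in
    micrometres, ``(z, y, x)``.
    """

    labels: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        vz, vy, vx = self.voxel_size_um
        if min(vz, vy, vx) <= 0:
            raise ValueError("voxel sizes must be positive")
        self.voxel_size_um = (float(vz), float(vy), float(vx))

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero label ids present in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]

    def centroid_um(self, label: int) -> np.ndarray:
        """Centroid of one object as ``(x, y, z)`` in micrometres."""
        zz, yy, xx = np.nonzero(self.labels == label)
        if zz.size == 0:
            raise KeyError(f"label {label} not present")
        vz, vy, vx = self.voxel_size_um
        return np.array([xx.mean() * vx, yy.mean() * vy, zz.mean() * vz])

    def centroids_um(self) -> dict[int, np.ndarray]:
        """Centroids of all objects, ``{label: (x, y, z) um}``."""
        from scipy import ndimage

        ids = self.ids
        if ids.size == 0:
            return {}
        coms = ndimage.center_of_mass(
            np.ones_like(self.labels, dtype=np.uint8), self.labels, ids
        )
        vz, vy, vx = self.voxel_size_um
        return {
            int(lab): np.array([c[2] * vx, c[1] * vy, c[0] * vz])
            for lab, c in zip(ids, coms)
        }


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) into the interval ``(-180, 180]``."""
    a = np.asarray(angle, dtype=float)
    w = ((-a + 180.0) % 360.0)
    w = 180.0 - w
    # modulo puts exactly -180 at the open end; move it to +180
    w = np.where(w <= -180.0, w + 360.0, w)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(w)
    return w


def points_from_mask(
    mask: np.ndarray, voxel_size_um: tuple[float, float, float]
) -> np.ndarray:
    """Voxel-centre coordinates of a binary mask as ``(n, 3)`` xyz um."""
    zz, yy, xx = np.nonzero(mask)
    vz, vy, vx = voxel_size_um
    return np.column_stack([xx * vx, yy * vy, zz * vz]).astype(float)


def _rot(c: float, s: float, axis: int) -> np.ndarray:
    m = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s if axis != 1 else s
    m[j, i] = s if axis != 1 else -s
    return m


def rotation_x(deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the x axis (xyz points)."""
    r = np.radians(deg)
    return _rot(np.cos(r), np.sin(r), 0)


def rotation_y(deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the y axis (xyz points)."""
    r = np.radians(deg)
    return _rot(np.cos(r), np.sin(r), 1)


def rotation_z(deg: float) -> np.ndarray:
    """Right-handed rotation matrix about the z axis (xyz points)."""
    r = np.radians(deg)
    return _rot(np.cos(r), np.sin(r), 2)
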