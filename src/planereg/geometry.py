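"""Plane parameterization and rigid-transform geometry.

A standard MPR plane is described by its center position ``A`` (mm, volume
coordinate system) and two orthonormal in-plane unit vectors ``e_u`` (row
direction) and ``e_v`` (column direction).  The plane normal ``e_w`` is always
derived as the cross product ``e_u x e_v`` and never stored, so orthonormality
cannot silently drift.

The volume coordinate system is right-handed, in millimeters, with the origin
at the geometric center of the volume and axes parallel to the voxel axes
(0-based voxel indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence
import warnings

import numpy as np

__all__ = [
    "StandardPlane",
    "PlaneTriplet",
    "RigidTransform",
    "VolumeGeometry",
    "PLANE_NAMES",
    "REGIONS",
    "plane_point",
    "plane_to_transform",
    "transform_to_plane",
    "apply_rigid_to_triplet",
    "normalize_translation",
    "denormalize_translation",
]

_UNIT_TOL = 1e-9
PLANE_NAMES = ("axial", "coronal", "semicoronal", "sagittal")
REGIONS = ("calcaneus", "ankle", "knee", "wrist")


def _as_vec3(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class StandardPlane:
    """One MPR plane: center + orthonormal in-plane frame, mm coordinates."""

    name: str
    center: np.ndarray
    e_u: np.ndarray
    e_v: np.ndarray

    def __post_init__(self):
        if self.name not in PLANE_NAMES:
            raise ValueError(f"unknown plane name {self.name!r}")
        object.__setattr__(self, "center", _as_vec3(self.center, "center"))
        object.__setattr__(self, "e_u", _as_vec3(self.e_u, "e_u"))
        object.__setattr__(self, "e_v", _as_vec3(self.e_v, "e_v"))
        if abs(np.linalg.norm(self.e_u) - 1.0) > 1e-6:
            raise ValueError("e_u is not a unit vector")
        if abs(np.linalg.norm(self.e_v) - 1.0) > 1e-6:
            raise ValueError("e_v is not a unit vector")
        if abs(float(self.e_u @ self.e_v)) > 1e-6:
            raise ValueError("e_u and e_v are not orthogonal")

    @property
    def e_w(self) -> np.ndarray:
        """Plane normal, derived as e_u x e_v."""
        return np.cross(self.e_u, self.e_v)

    def with_name(self, name: str) -> "StandardPlane":
        return replace(self, name=name)


@dataclass(frozen=True)
class PlaneTriplet:
    """Ordered [axial, (semi)coronal, sagittal] planes of one body region."""

    region: str
    planes: tuple

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        planes = tuple(self.planes)
        object.__setattr__(self, "planes", planes)
        if len(planes) != 3:
            raise ValueError("a triplet holds exactly 3 planes")
        expected_second = "semicoronal" if self.region == "calcaneus" else "coronal"
        names = tuple(p.name for p in planes)
        if names != ("axial", expected_second, "sagittal"):
            raise ValueError(
                f"plane order for region {self.region!r} must be "
                f"('axial', {expected_second!r}, 'sagittal'), got {names}"
            )

    @property
    def axial(self) -> StandardPlane:
        return self.planes[0]

    @property
    def coronal(self) -> StandardPlane:
        """Second plane: coronal, or semicoronal for the calcaneus."""
        return self.planes[1]

    @property
    def sagittal(self) -> StandardPlane:
        return self.planes[2]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform as a 4x4 homogeneous matrix."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row must be [0,0,0,1]")
        R = m[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has negative determinant (reflection)")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_rotation_translation(cls, R, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = np.asarray(R, dtype=float)
        m[:3, 3] = _as_vec3(t, "t")
        return cls(m)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation
        m = np.eye(4)
        m[:3, :3] = R.T
        m[:3, 3] = -R.T @ self.translation
        return RigidTransform(m)

    def apply_point(self, p) -> np.ndarray:
        return self.rotation @ _as_vec3(p, "p") + self.translation

    def apply_direction(self, d) -> np.ndarray:
        return self.rotation @ _as_vec3(d, "d")


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid geometry: shape (voxels) and isotropic-or-not spacing (mm)."""

    shape: tuple
    spacing: tuple

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("shape must be 3 positive integers")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing must be 3 positive reals")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths in mm."""
        return np.array(self.shape, dtype=float) * np.array(self.spacing)

    def voxel_to_mm(self, idx) -> np.ndarray:
        """0-based voxel index -> mm position (origin at volume center)."""
        idx = np.asarray(idx, dtype=float)
        half = (np.array(self.shape, dtype=float) - 1.0) / 2.0
        return (idx - half) * np.array(self.spacing)

    def mm_to_voxel(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        half = (np.array(self.shape, dtype=float) - 1.0) / 2.0
        return p / np.array(self.spacing) + half


def plane_point(plane: StandardPlane, lam: float, mu: float) -> np.ndarray:
    """Point on the plane: A + lam*e_u + mu*e_v."""
    return plane.center + lam * plane.e_u + mu * plane.e_v


def plane_to_transform(plane: StandardPlane) -> RigidTransform:
    """Homogeneous transform from plane coordinates to volume coordinates.

    Rotation columns are [e_u, e_v, e_w]; translation is the plane center, so
    the transform applied to (lam, mu, 0, 1) yields the plane point
    A + lam*e_u + mu*e_v.
    """
    R = np.column_stack([plane.e_u, plane.e_v, plane.e_w])
    return RigidTransform.from_rotation_translation(R, plane.center)


def transform_to_plane(T: RigidTransform, name: str) -> StandardPlane:
    """Inverse of :func:`plane_to_transform`; rejects reflections."""
    R = T.rotation
    if np.linalg.det(R) < 0:  # RigidTransform already rejects, belt-and-braces
        raise ValueError("transform contains a reflection")
    return StandardPlane(name=name, center=T.translation, e_u=R[:, 0], e_v=R[:, 1])


def apply_rigid_to_triplet(triplet: PlaneTriplet, M: RigidTransform) -> PlaneTriplet:
    """Map every plane of a triplet by a proper rigid transform."""
    planes = tuple(
        StandardPlane(
            name=p.name,
            center=M.apply_point(p.center),
            e_u=M.apply_direction(p.e_u),
            e_v=M.apply_direction(p.e_v),
        )
        for p in triplet.planes
    )
    return PlaneTriplet(region=triplet.region, planes=planes)


def normalize_translation(center, geom: VolumeGeometry) -> np.ndarray:
    """Map a mm center to half-extent units; [-1, 1] inside the volume.

    Values outside [-1, 1] are permitted (augmented planes may leave the
    field of view) but trigger a warning.
    """
    c = _as_vec3(center, "center")
    out = c / (geom.extent / 2.0)
    if np.any(np.abs(out) > 1.0 + 1e-12):
        warnings.warn("plane center lies outside the volume extent", stacklevel=2)
    return out


def denormalize_translation(v, geom: VolumeGeometry) -> np.ndarray:
    """Exact inverse of :func:`normalize_translation`."""
    return _as_vec3(v, "v") * (geom.extent / 2.0)
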