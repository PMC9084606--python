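"""Composed spatial/intensity augmentation and inference-time preprocessing.

Spatial augmentation composes subsampling/cropping, scaling, translation and
rotation into a single homogeneous matrix

    T_m = T_r @ T_s @ T_t @ T_R

so the volume is interpolated exactly once.  The matrix acts on physical
(mm, center-origin) coordinates: the output voxel at physical position p
samples the input volume at ``T_m @ F @ p``, where F is the optional
x-mirror.  Plane labels are pulled back through the inverse of that map so
the anatomical content of each plane is invariant; under mirroring the
normal is re-derived as ``e_u x e_v``, which simulates the left/right
handedness change of the anatomy.

Intensity normalization shifts HU by +1000, multiplies by a random
calibration factor f, clips to the shifted window [510, 2040], rescales to
[0, 1] and applies a logistic windowing ``w(x) = 1 / (1 + exp(g * (0.5 - x)))``
with gain ``g = log((1 - y) / y) / 0.4`` and ``y = 0.02`` on the unit range,
which compresses the uninformative air and metal tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import PlaneTriplet, StandardPlane, VolumeGeometry

__all__ = [
    "AugmentationConfig",
    "IntensityWindowConfig",
    "ComposedSpatialTransform",
    "AugmentationSample",
    "sample_augmentation",
    "resample_volume",
    "transform_labels",
    "intensity_normalize",
    "AIR_HU",
]

AIR_HU = -1000.0


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges and probabilities of the online training augmentation."""

    rotation_deg: float = 45.0
    scale_range: tuple = (0.95, 1.05)
    translation_mm: float = 12.0
    op_probability: float = 0.5
    mirror_probability: float = 0.5
    intensity_factor_range: tuple = (0.95, 1.05)
    crop_fraction: float = 1.0

    def __post_init__(self):
        for p in (self.op_probability, self.mirror_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class IntensityWindowConfig:
    """Clip window (HU, before the +1000 shift) and sigmoid parameters."""

    clip_range: tuple = (-490.0, 1040.0)
    offset: float = 1000.0
    y: float = 0.02

    @property
    def shifted_clip(self) -> tuple:
        lo, hi = self.clip_range
        return (lo + self.offset, hi + self.offset)

    @property
    def gain(self) -> float:
        return float(np.log((1.0 - self.y) / self.y) / 0.4)


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _homog(R=None, t=None) -> np.ndarray:
    m = np.eye(4)
    if R is not None:
        m[:3, :3] = R
    if t is not None:
        m[:3, 3] = t
    return m


@dataclass(frozen=True)
class ComposedSpatialTransform:
    """The four factors and their product T_m = T_r @ T_s @ T_t @ T_R."""

    T_r: np.ndarray
    T_s: np.ndarray
    T_t: np.ndarray
    T_R: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.T_r @ self.T_s @ self.T_t @ self.T_R

    @classmethod
    def identity(cls) -> "ComposedSpatialTransform":
        return cls(np.eye(4), np.eye(4), np.eye(4), np.eye(4))


@dataclass(frozen=True)
class AugmentationSample:
    """One drawn augmentation: spatial transform, mirror flag, intensity factor."""

    spatial: ComposedSpatialTransform
    mirror: bool
    intensity_factor: float

    @property
    def full_matrix(self) -> np.ndarray:
        """T_m @ F: the map from output physical coords to input sample coords."""
        F = np.diag([-1.0, 1.0, 1.0, 1.0]) if self.mirror else np.eye(4)
        return self.spatial.matrix @ F


def sample_augmentation(
    cfg: AugmentationConfig, rng: np.random.Generator
) -> AugmentationSample:
    """Draw one augmentation; each spatial op independently active with p=0.5.

    Rotation draws three Euler angles (intrinsic Z-Y-X, each uniform in the
    configured range); scaling draws one isotropic factor; translation draws
    one offset per axis.  The intensity factor is always drawn.
    """
    p = cfg.op_probability
    T_R = np.eye(4)
    if rng.random() < p:
        a, b, c = np.radians(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg, size=3))
        T_R = _homog(R=_rot_z(a) @ _rot_y(b) @ _rot_x(c))
    T_t = np.eye(4)
    if rng.random() < p:
        T_t = _homog(t=rng.uniform(-cfg.translation_mm, cfg.translation_mm, size=3))
    T_s = np.eye(4)
    if rng.random() < p:
        s = rng.uniform(*cfg.scale_range)
        T_s = _homog(R=np.diag([s, s, s]))
    T_r = _homog(R=np.diag([cfg.crop_fraction] * 3))
    mirror = bool(rng.random() < cfg.mirror_probability)
    f = float(rng.uniform(*cfg.intensity_factor_range))
    return AugmentationSample(
        spatial=ComposedSpatialTransform(T_r=T_r, T_s=T_s, T_t=T_t, T_R=T_R),
        mirror=mirror,
        intensity_factor=f,
    )


def _output_geometry(geom_in: VolumeGeometry, out_shape) -> VolumeGeometry:
    """Default output grid: same physical field of view, fewer voxels."""
    out_shape = tuple(int(s) for s in out_shape)
    spacing = tuple(
        e / n for e, n in zip(geom_in.extent, out_shape)
    )
    return VolumeGeometry(shape=out_shape, spacing=spacing)


def resample_volume(
    vol: np.ndarray,
    geom: VolumeGeometry,
    transform,
    out_shape,
    cval: float = AIR_HU,
) -> tuple:
    """One trilinear pass pulling the volume through the sampling map.

    Parameters
    ----------
    transform : ComposedSpatialTransform, AugmentationSample, or 4x4 array
        Map from output physical coordinates to input physical coordinates.
    out_shape : target voxel shape (network input resolution).

    Returns
    -------
    (resampled volume, output VolumeGeometry)
    """
    if isinstance(transform, AugmentationSample):
        M = transform.full_matrix
    elif isinstance(transform, ComposedSpatialTransform):
        M = transform.matrix
    else:
        M = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(M[:3, :3])) < 1e-12:
        raise ValueError("singular spatial transform cannot be resampled")

    geom_out = _output_geometry(geom, out_shape)
    A, b = M[:3, :3], M[:3, 3]
    D_in = np.array(geom.spacing)
    D_out = np.array(geom_out.spacing)
    h_in = (np.array(geom.shape, dtype=float) - 1.0) / 2.0
    h_out = (np.array(geom_out.shape, dtype=float) - 1.0) / 2.0
    # voxel_in = D_in^-1 (A D_out (voxel_out - h_out) + b) + h_in
    M_idx = (A * D_out[None, :]) / D_in[:, None]
    offset = (b - M_idx @ (h_out * D_in)) / D_in + h_in
    out = ndimage.affine_transform(
        np.asarray(vol, dtype=float),
        matrix=M_idx,
        offset=offset,
        output_shape=geom_out.shape,
        order=1,
        mode="constant",
        cval=cval,
    )
    return out, geom_out


def transform_labels(triplet: PlaneTriplet, transform, mirror: bool = False) -> PlaneTriplet:
    """Pull plane annotations back through the volume sampling map.

    The output-volume voxel at position p shows the input content at
    ``M @ p``, so a plane at input position x appears in the output at
    ``M^-1 @ x``: centers map through the inverse affine, directions through
    its (normalized) linear part, and the normal is re-derived as e_u x e_v —
    under mirroring this flips the frame handedness together with the anatomy.
    """
    if isinstance(transform, AugmentationSample):
        M = transform.full_matrix
        if mirror:
            raise ValueError("mirror flag is already part of AugmentationSample")
    elif isinstance(transform, ComposedSpatialTransform):
        M = transform.matrix
    else:
        M = np.asarray(transform, dtype=float)
    if mirror:
        M = M @ np.diag([-1.0, 1.0, 1.0, 1.0])
    N = np.linalg.inv(M)
    L, b = N[:3, :3], N[:3, 3]
    planes = []
    for p in triplet.planes:
        center = L @ p.center + b
        e_u = L @ p.e_u
        e_v = L @ p.e_v
        e_u = e_u / np.linalg.norm(e_u)
        e_v = e_v / np.linalg.norm(e_v)
        planes.append(StandardPlane(name=p.name, center=center, e_u=e_u, e_v=e_v))
    return PlaneTriplet(region=triplet.region, planes=tuple(planes))


def intensity_normalize(
    vol: np.ndarray,
    factor: float = 1.0,
    cfg: IntensityWindowConfig = IntensityWindowConfig(),
) -> np.ndarray:
    """HU volume -> (0, 1): shift, scale by f, clip, rescale, logistic window."""
    lo, hi = cfg.shifted_clip
    x = np.asarray(vol, dtype=float)
    c = (factor * (x + cfg.offset) - lo) / (hi - lo)
    c = np.clip(c, 0.0, 1.0)
    g = cfg.gain
    return 1.0 / (1.0 + np.exp(g * (0.5 - c)))
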