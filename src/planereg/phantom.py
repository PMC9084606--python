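"""Synthetic bone-like phantoms with analytically known standard planes.

Each phantom is a composite of analytic shapes in a canonical frame: a
cortical-bone shaft (cylinder along -z), a joint head (ellipsoid at the
origin), a soft-tissue envelope, and two high-density marker spheres offset
along +x and +y that break mirror and rotational symmetry, so the pose —
and hence left/right handedness — is unambiguous.  An optional metal sphere
emulates implants.  Shapes are rendered by signed-distance thresholding with
a one-voxel linear edge ramp; no meshes, so the ground-truth plane geometry
is exact: the ground-truth triplet is the canonical triplet mapped by the
sampled rigid pose.

Canonical standard planes (all centered at the joint-head center):

    axial      e_u = +x, e_v = +y  (normal +z)
    coronal    e_u = +x, e_v = +z  (normal -y)
    sagittal   e_u = +y, e_v = +z  (normal +x)

For the calcaneus the coronal plane is replaced by a semicoronal plane
tilted 30 deg about +x, which is oblique to the other two.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    PlaneTriplet,
    RigidTransform,
    StandardPlane,
    VolumeGeometry,
    apply_rigid_to_triplet,
)
from .preprocessing import AIR_HU, _rot_x, _rot_y, _rot_z

__all__ = [
    "PhantomSpec",
    "canonical_triplet",
    "sample_pose",
    "render_phantom",
    "generate_dataset",
    "SEMICORONAL_TILT_DEG",
]

SEMICORONAL_TILT_DEG = 30.0


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic volume; defaults give a 160 mm cube FOV."""

    shape: tuple = (128, 128, 128)
    spacing: tuple = (1.25, 1.25, 1.25)
    shaft_radius_mm: float = 12.0
    shaft_z_range_mm: tuple = (-70.0, -10.0)
    shaft_hu: float = 1200.0
    head_semiaxes_mm: tuple = (24.0, 18.0, 15.0)
    head_hu: float = 900.0
    marker_x_offset_mm: tuple = (30.0, 0.0, 5.0)
    marker_x_radius_mm: float = 10.0
    marker_x_hu: float = 1500.0
    marker_y_offset_mm: tuple = (0.0, 28.0, -5.0)
    marker_y_radius_mm: float = 8.0
    marker_y_hu: float = 1300.0
    soft_semiaxes_mm: tuple = (45.0, 40.0, 70.0)
    soft_hu: float = 50.0
    metal: bool = False
    metal_center_mm: tuple = (12.0, -10.0, 20.0)
    metal_radius_mm: float = 6.0
    metal_hu: float = 3000.0
    noise_sigma_hu: float = 20.0
    oblique: bool = False  # use the 30-deg semicoronal plane (calcaneus style)

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(shape=self.shape, spacing=self.spacing)


def canonical_triplet(region: str) -> PlaneTriplet:
    """Canonical standard planes of the phantom frame for one body region."""
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    ez = np.array([0.0, 0.0, 1.0])
    zero = np.zeros(3)
    axial = StandardPlane("axial", zero, ex, ey)
    sagittal = StandardPlane("sagittal", zero, ey, ez)
    if region == "calcaneus":
        Rx = _rot_x(np.radians(SEMICORONAL_TILT_DEG))
        second = StandardPlane("semicoronal", zero, ex, Rx @ ez)
    else:
        second = StandardPlane("coronal", zero, ex, ez)
    return PlaneTriplet(region=region, planes=(axial, second, sagittal))


def sample_pose(
    rng: np.random.Generator,
    max_angle_deg: float = 45.0,
    max_translation_mm: float = 12.0,
) -> RigidTransform:
    """Uniform Euler angles (intrinsic Z-Y-X) and per-axis translation."""
    a, b, c = np.radians(rng.uniform(-max_angle_deg, max_angle_deg, size=3))
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    R = _rot_z(a) @ _rot_y(b) @ _rot_x(c)
    return RigidTransform.from_rotation_translation(R, t)


def _sd_sphere(p, center, radius):
    return np.linalg.norm(p - np.asarray(center), axis=-1) - radius


def _sd_ellipsoid(p, semiaxes):
    # approximate SDF: radial excess scaled by the smallest semi-axis,
    # exact at the surface to first order — enough for 1-voxel smoothing
    a = np.asarray(semiaxes, dtype=float)
    r = np.linalg.norm(p / a, axis=-1)
    return (r - 1.0) * a.min()


def _sd_capped_cylinder(p, radius, z_range):
    radial = np.hypot(p[..., 0], p[..., 1]) - radius
    z0, z1 = z_range
    axial = np.maximum(z0 - p[..., 2], p[..., 2] - z1)
    return np.maximum(radial, axial)


def _composite(vol, occupancy, hu):
    return vol * (1.0 - occupancy) + hu * occupancy


def render_phantom(
    spec: PhantomSpec,
    pose: RigidTransform | None = None,
    rng: np.random.Generator | None = None,
    region: str | None = None,
):
    """Render one phantom volume and its exact ground-truth planes.

    Returns ``(volume HU, VolumeGeometry, PlaneTriplet)``.  The occupancy of
    each shape is evaluated analytically on the posed voxel grid; Gaussian HU
    noise is added after compositing (skipped when sigma is 0 or rng is None).
    """
    if pose is None:
        pose = RigidTransform.identity()
    geom = spec.geometry
    idx = np.indices(geom.shape, dtype=float)
    half = (np.array(geom.shape, dtype=float) - 1.0) / 2.0
    phys = np.stack(
        [(idx[k] - half[k]) * geom.spacing[k] for k in range(3)], axis=-1
    )
    inv = pose.inverse()
    m = phys @ inv.rotation.T + inv.translation  # material coordinates

    edge = float(min(geom.spacing))  # 1-voxel linear ramp

    def occ(sd):
        return np.clip(0.5 - sd / edge, 0.0, 1.0)

    vol = np.full(geom.shape, AIR_HU)
    vol = _composite(vol, occ(_sd_ellipsoid(m, spec.soft_semiaxes_mm)), spec.soft_hu)
    vol = _composite(
        vol,
        occ(_sd_capped_cylinder(m, spec.shaft_radius_mm, spec.shaft_z_range_mm)),
        spec.shaft_hu,
    )
    vol = _composite(vol, occ(_sd_ellipsoid(m, spec.head_semiaxes_mm)), spec.head_hu)
    vol = _composite(
        vol,
        occ(_sd_sphere(m, spec.marker_x_offset_mm, spec.marker_x_radius_mm)),
        spec.marker_x_hu,
    )
    vol = _composite(
        vol,
        occ(_sd_sphere(m, spec.marker_y_offset_mm, spec.marker_y_radius_mm)),
        spec.marker_y_hu,
    )
    if spec.metal:
        vol = _composite(
            vol,
            occ(_sd_sphere(m, spec.metal_center_mm, spec.metal_radius_mm)),
            spec.metal_hu,
        )
    if rng is not None and spec.noise_sigma_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)

    if region is None:
        region = "calcaneus" if spec.oblique else "ankle"
    triplet = apply_rigid_to_triplet(canonical_triplet(region), pose)
    return vol, geom, triplet


@dataclass
class PhantomSample:
    """One generated dataset entry."""

    volume: np.ndarray
    geometry: VolumeGeometry
    triplet: PlaneTriplet
    region: str
    patient_id: int
    fold: int
    pose: RigidTransform
    metal: bool = False


def generate_dataset(
    n: int,
    spec: PhantomSpec = PhantomSpec(),
    max_angle_deg: float = 45.0,
    max_translation_mm: float = 12.0,
    regions=("ankle",),
    seed: int = 0,
    n_folds: int = 5,
    metal_pairs: bool = False,
):
    """Generate ``n`` phantoms with uniformly sampled poses.

    Synthetic patient ids are assigned one per pose; with ``metal_pairs`` each
    patient contributes two volumes (with and without the metal sphere) that
    share the pose, emulating cadaver scans repeated with surface metal.  The
    fold assignment is by patient, so paired volumes never span folds.
    """
    if n < n_folds:
        raise ValueError("need at least one phantom per fold")
    rng = np.random.default_rng(seed)
    samples = []
    per = 2 if metal_pairs else 1
    n_patients = (n + per - 1) // per
    for pid in range(n_patients):
        region = regions[pid % len(regions)]
        pose = sample_pose(rng, max_angle_deg, max_translation_mm)
        fold = pid % n_folds
        for metal in ([False, True] if metal_pairs else [False]):
            if len(samples) >= n:
                break
            pspec = replace(spec, metal=metal, oblique=region == "calcaneus")
            vol, geom, triplet = render_phantom(pspec, pose, rng, region=region)
            samples.append(
                PhantomSample(
                    volume=vol,
                    geometry=geom,
                    triplet=triplet,
                    region=region,
                    patient_id=pid,
                    fold=fold,
                    pose=pose,
                    metal=metal,
                )
            )
    return samples
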