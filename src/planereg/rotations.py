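"""Bidirectional codecs between rotation matrices and bounded parameter vectors.

Four representations are supported as regression targets, all with components
in [-1, 1] for exact rotations:

``euler_sincos``
    Intrinsic Z-Y-X Euler angles, regressed as (sin, cos) pairs and decoded
    with atan2, which makes the encoding continuous and scale invariant.
``quaternion``
    Unit quaternion (w, x, y, z) with canonical nonnegative scalar part.
``six_d_xy`` / ``six_d_xz``
    Two rotation-matrix columns (x&y, or x&z — the latter carries the plane
    normal directly); decoding renormalizes via Gram-Schmidt and restores the
    missing column by cross product, so any non-degenerate 6-vector decodes to
    a proper rotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation as _R

from .geometry import (
    PlaneTriplet,
    StandardPlane,
    VolumeGeometry,
    denormalize_translation,
    normalize_translation,
)

__all__ = [
    "RotationCodec",
    "get_codec",
    "CODEC_KINDS",
    "encode_euler_sincos",
    "decode_euler_sincos",
    "encode_quaternion",
    "decode_quaternion",
    "encode_six_d",
    "decode_six_d",
    "build_parameter_vector",
    "parse_parameter_vector",
]

_DEGENERATE = 1e-8
CODEC_KINDS = ("euler_sincos", "quaternion", "six_d_xy", "six_d_xz")


def _check_rotation(R) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-6) or np.linalg.det(R) < 0:
        raise ValueError("not a proper rotation matrix")
    return R


def encode_euler_sincos(R) -> np.ndarray:
    """[sin a, cos a, sin b, cos b, sin g, cos g] for intrinsic Z-Y-X angles."""
    R = _check_rotation(R)
    angles = _R.from_matrix(R).as_euler("ZYX")
    return np.concatenate([np.array([np.sin(a), np.cos(a)]) for a in angles])


def decode_euler_sincos(v) -> np.ndarray:
    """Angles via atan2 per (sin, cos) pair; a (0, 0) pair decodes to 0."""
    v = np.asarray(v, dtype=float)
    if v.shape != (6,):
        raise ValueError("euler_sincos code must have 6 components")
    angles = []
    for s, c in v.reshape(3, 2):
        angles.append(0.0 if (s == 0.0 and c == 0.0) else np.arctan2(s, c))
    return _R.from_euler("ZYX", angles).as_matrix()


def encode_quaternion(R) -> np.ndarray:
    """Unit quaternion (w, x, y, z), scalar part canonically nonnegative."""
    R = _check_rotation(R)
    x, y, z, w = _R.from_matrix(R).as_quat()
    q = np.array([w, x, y, z])
    # canonical sign: scalar >= 0, tie broken by first nonzero component > 0
    for comp in q:
        if comp > 0:
            break
        if comp < 0:
            q = -q
            break
    return q


def decode_quaternion(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (4,):
        raise ValueError("quaternion code must have 4 components")
    n = np.linalg.norm(v)
    if n < _DEGENERATE:
        raise ValueError("near-zero quaternion does not define a rotation")
    w, x, y, z = v / n
    return _R.from_quat([x, y, z, w]).as_matrix()


def _gram_schmidt_pair(a, b):
    na = np.linalg.norm(a)
    if na < _DEGENERATE:
        raise ValueError("degenerate 6D code: first vector near zero")
    a = a / na
    nb = np.linalg.norm(b)
    if nb < _DEGENERATE:
        raise ValueError("degenerate 6D code: second vector near zero")
    if abs(float(a @ (b / nb))) > 1.0 - _DEGENERATE:
        raise ValueError("degenerate 6D code: vectors near parallel")
    b = b - (b @ a) * a
    return a, b / np.linalg.norm(b)


def encode_six_d(R, variant: str = "xy") -> np.ndarray:
    """Concatenate rotation columns: (1,2) for ``xy``, (1,3) for ``xz``."""
    R = _check_rotation(R)
    if variant == "xy":
        return np.concatenate([R[:, 0], R[:, 1]])
    if variant == "xz":
        return np.concatenate([R[:, 0], R[:, 2]])
    raise ValueError(f"unknown 6D variant {variant!r}")


def decode_six_d(v, variant: str = "xy") -> np.ndarray:
    """Gram-Schmidt the two regressed columns, restore the third by cross.

    xy: columns [a, b, a x b]; xz: first vector is the x column, second the
    normal (z column), and the y column is z x x so that det(R) = +1.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (6,):
        raise ValueError("6D code must have 6 components")
    a, b = _gram_schmidt_pair(v[:3], v[3:])
    if variant == "xy":
        return np.column_stack([a, b, np.cross(a, b)])
    if variant == "xz":
        return np.column_stack([a, np.cross(b, a), b])
    raise ValueError(f"unknown 6D variant {variant!r}")


@dataclass(frozen=True)
class RotationCodec:
    """One bounded rotation representation: kind, size, encode/decode pair."""

    kind: str
    n_params: int
    encode: Callable[[np.ndarray], np.ndarray]
    decode: Callable[[np.ndarray], np.ndarray]


_CODECS = {
    "euler_sincos": RotationCodec(
        "euler_sincos", 6, encode_euler_sincos, decode_euler_sincos
    ),
    "quaternion": RotationCodec("quaternion", 4, encode_quaternion, decode_quaternion),
    "six_d_xy": RotationCodec(
        "six_d_xy",
        6,
        lambda R: encode_six_d(R, "xy"),
        lambda v: decode_six_d(v, "xy"),
    ),
    "six_d_xz": RotationCodec(
        "six_d_xz",
        6,
        lambda R: encode_six_d(R, "xz"),
        lambda v: decode_six_d(v, "xz"),
    ),
}


def get_codec(kind: str) -> RotationCodec:
    try:
        return _CODECS[kind]
    except KeyError:
        raise ValueError(f"unknown codec {kind!r}; choose from {CODEC_KINDS}") from None


def parameter_vector_length(codec: RotationCodec) -> int:
    """3 planes x (3 normalized translations + rotation parameters)."""
    return 3 * (3 + codec.n_params)


def build_parameter_vector(
    triplet: PlaneTriplet, codec: RotationCodec, geom: VolumeGeometry
) -> np.ndarray:
    """Network regression target: per plane [normalized center, rotation code]."""
    parts = []
    for p in triplet.planes:
        R = np.column_stack([p.e_u, p.e_v, p.e_w])
        parts.append(normalize_translation(p.center, geom))
        parts.append(codec.encode(R))
    return np.concatenate(parts)


def parse_parameter_vector(
    v, region: str, codec: RotationCodec, geom: VolumeGeometry
) -> PlaneTriplet:
    """Inverse of :func:`build_parameter_vector` (up to codec round-trip)."""
    v = np.asarray(v, dtype=float)
    n = 3 + codec.n_params
    if v.shape != (3 * n,):
        raise ValueError(
            f"parameter vector for codec {codec.kind!r} must have length {3 * n}, "
            f"got {v.shape}"
        )
    names = ("axial", "semicoronal" if region == "calcaneus" else "coronal", "sagittal")
    planes = []
    for j, name in enumerate(names):
        chunk = v[j * n : (j + 1) * n]
        center = denormalize_translation(chunk[:3], geom)
        R = codec.decode(chunk[3:])
        planes.append(StandardPlane(name=name, center=center, e_u=R[:, 0], e_v=R[:, 1]))
    return PlaneTriplet(region=region, planes=tuple(planes))
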