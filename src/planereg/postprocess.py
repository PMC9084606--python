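"""Algorithmic consistency postprocessing of decoupled plane regressions.

The three planes are regressed independently, so their mutual geometry can be
slightly inconsistent.  The axial plane — typically the most accurately
regressed one — serves as the reference:

1. ``correct_inplane``: the in-plane rotation of the (semi)coronal and
   sagittal planes is corrected so that the trace of the axial plane on them
   runs at 0 deg, i.e. parallel to their row direction e_u.  Normals and
   centers are untouched.
2. ``orthogonalize_sagittal``: for regions whose standard planes are mutually
   orthogonal (everything except the calcaneus, whose semicoronal plane is
   oblique), the sagittal normal is replaced by the cross product of the axial
   and coronal normals, with the sign closest to the regressed normal.

Antiparallel traces are rotated all the way into alignment rather than by the
smaller angle to the axis, so 180-deg in-plane errors are corrected too.
"""

from __future__ import annotations

import warnings

import numpy as np

from .geometry import PlaneTriplet, StandardPlane

__all__ = ["correct_inplane", "orthogonalize_sagittal", "postprocess"]

_PARALLEL_TOL = 1e-8


def _rotate_frame_to(plane: StandardPlane, target_u: np.ndarray) -> StandardPlane:
    """In-plane rotation taking e_u onto target_u (unit, in the plane)."""
    e_w = plane.e_w
    new_u = target_u
    new_v = np.cross(e_w, new_u)
    return StandardPlane(name=plane.name, center=plane.center, e_u=new_u, e_v=new_v)


def correct_inplane(triplet: PlaneTriplet) -> PlaneTriplet:
    """Align each non-axial plane's row direction with its axial intersection."""
    axial = triplet.axial
    n_ax = axial.e_w
    out = [axial]
    for plane in triplet.planes[1:]:
        v = np.cross(n_ax, plane.e_w)
        norm = np.linalg.norm(v)
        if norm < _PARALLEL_TOL:
            warnings.warn(
                f"axial and {plane.name} normals are parallel; "
                "in-plane correction skipped",
                stacklevel=2,
            )
            out.append(plane)
            continue
        out.append(_rotate_frame_to(plane, v / norm))
    return PlaneTriplet(region=triplet.region, planes=tuple(out))


def orthogonalize_sagittal(triplet: PlaneTriplet) -> PlaneTriplet:
    """Force the sagittal normal orthogonal to axial and coronal normals.

    Applies only to regions with mutually orthogonal standard planes; for the
    calcaneus (oblique semicoronal) the triplet is returned unchanged.
    """
    if triplet.region == "calcaneus":
        return triplet
    axial, coronal, sagittal = triplet.planes
    n = np.cross(axial.e_w, coronal.e_w)
    norm = np.linalg.norm(n)
    if norm < _PARALLEL_TOL:
        warnings.warn(
            "axial and coronal normals are parallel; sagittal left unchanged",
            stacklevel=2,
        )
        return triplet
    n = n / norm
    if float(n @ sagittal.e_w) < 0:
        n = -n
    # rebuild the in-plane frame: project the old e_u onto the new plane
    u = sagittal.e_u - (sagittal.e_u @ n) * n
    u_norm = np.linalg.norm(u)
    if u_norm < _PARALLEL_TOL:
        raise ValueError("sagittal e_u is parallel to the orthogonalized normal")
    u = u / u_norm
    new_sag = StandardPlane(
        name=sagittal.name, center=sagittal.center, e_u=u, e_v=np.cross(n, u)
    )
    return PlaneTriplet(region=triplet.region, planes=(axial, coronal, new_sag))


def postprocess(triplet: PlaneTriplet) -> PlaneTriplet:
    """In-plane correction, then sagittal orthogonalization; idempotent."""
    return orthogonalize_sagittal(correct_inplane(triplet))
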