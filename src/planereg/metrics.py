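"""Plane-comparison errors and the weighted performance score.

For each plane the score combines three errors against the reference
annotation: d (mm), the absolute center offset along the reference normal;
eps_n (deg), the angle between predicted and reference normals; and eps_i
(deg), the in-plane rotation error, i.e. the mean unsigned angle between the
predicted row/column directions and the reference ones after projecting the
predictions onto the reference plane.  The per-volume score is

    p = mean over planes of (0.2 * d + 0.6 * eps_n + 0.2 * eps_i)

mixing mm and degrees by design; the normal carries the largest weight because
out-of-plane rotations are the hardest error to fix manually.  Flipped normals
score ~180 deg: plane flips are real failure modes and must stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PlaneTriplet, StandardPlane

__all__ = [
    "PlaneErrorReport",
    "translation_error",
    "normal_error",
    "inplane_error",
    "score",
    "aggregate_folds",
]

WEIGHT_D = 0.2
WEIGHT_NORMAL = 0.6
WEIGHT_INPLANE = 0.2


def translation_error(pred: StandardPlane, ref: StandardPlane) -> float:
    """|(A_pred - A_ref) . e_w_ref| in mm; in-plane shifts are invisible."""
    return float(abs((pred.center - ref.center) @ ref.e_w))


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    # atan2 of (cross, dot) is exact at 0 and 180 deg, unlike arccos
    return float(
        np.degrees(np.arctan2(np.linalg.norm(np.cross(a, b)), float(a @ b)))
    )


def normal_error(pred: StandardPlane, ref: StandardPlane) -> float:
    """Angle between the normals in degrees; a flipped normal scores ~180."""
    return _angle_deg(pred.e_w, ref.e_w)


def _projected_angle(d_pred, d_ref, n_ref) -> float:
    proj = d_pred - (d_pred @ n_ref) * n_ref
    norm = np.linalg.norm(proj)
    if norm < 1e-8:
        raise ValueError("predicted direction is parallel to the reference normal")
    return _angle_deg(proj / norm, d_ref)


def inplane_error(pred: StandardPlane, ref: StandardPlane) -> float:
    """Mean unsigned angle of e_u and e_v after projection onto the ref plane."""
    n = ref.e_w
    return 0.5 * (
        _projected_angle(pred.e_u, ref.e_u, n) + _projected_angle(pred.e_v, ref.e_v, n)
    )


@dataclass(frozen=True)
class PlaneErrorReport:
    """Per-plane errors (d mm, eps_n deg, eps_i deg) and the weighted score."""

    region: str
    plane_names: tuple
    d: np.ndarray
    eps_n: np.ndarray
    eps_i: np.ndarray

    @property
    def p(self) -> float:
        per_plane = (
            WEIGHT_D * self.d + WEIGHT_NORMAL * self.eps_n + WEIGHT_INPLANE * self.eps_i
        )
        return float(np.mean(per_plane))


def score(pred: PlaneTriplet, ref: PlaneTriplet) -> PlaneErrorReport:
    """Weighted plane-error report of a predicted triplet vs the annotation."""
    if pred.region != ref.region:
        raise ValueError(f"region mismatch: {pred.region!r} vs {ref.region!r}")
    d, en, ei = [], [], []
    for p, r in zip(pred.planes, ref.planes):
        d.append(translation_error(p, r))
        en.append(normal_error(p, r))
        ei.append(inplane_error(p, r))
    return PlaneErrorReport(
        region=ref.region,
        plane_names=tuple(p.name for p in ref.planes),
        d=np.array(d),
        eps_n=np.array(en),
        eps_i=np.array(ei),
    )


def aggregate_folds(reports_by_fold):
    """Mean +/- sample sd, across folds, of the per-fold median of each metric.

    Parameters
    ----------
    reports_by_fold : sequence of sequences of PlaneErrorReport
        One inner sequence per fold; each must be nonempty.

    Returns
    -------
    dict with keys 'd', 'eps_n', 'eps_i', 'p', each mapping to
    ``{'mean': float, 'sd': float, 'single_fold': bool}``.  With a single fold
    the sample sd is undefined and reported as 0.0 with the flag set.
    """
    folds = [list(f) for f in reports_by_fold]
    if not folds or any(len(f) == 0 for f in folds):
        raise ValueError("every fold must contain at least one report")

    def metric_values(rep, key):
        if key == "p":
            return rep.p
        return float(np.mean(getattr(rep, key)))

    out = {}
    single = len(folds) == 1
    for key in ("d", "eps_n", "eps_i", "p"):
        medians = [
            float(np.median([metric_values(r, key) for r in fold])) for fold in folds
        ]
        sd = 0.0 if single else float(np.std(medians, ddof=1))
        out[key] = {"mean": float(np.mean(medians)), "sd": sd, "single_fold": single}
    return out
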