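"""Readers and writers: NIfTI volumes, plane-annotation JSON, manifests.

The on-disk annotation schema (one JSON file per volume)::

    {
      "region": "ankle",
      "volume": {"shape": [i, j, k], "spacing_mm": [x, y, z]},
      "planes": [
        {"name": "axial", "center_mm": [...], "e_u": [...], "e_v": [...]},
        ...
      ]
    }

Numeric values are written with 17 significant digits so the geometry
round-trips bit-stably.  Volumes use the axis-aligned, center-origin
millimeter convention; NIfTI files with oblique direction cosines are
rejected loudly rather than silently re-interpreted.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .geometry import PlaneTriplet, StandardPlane, VolumeGeometry

__all__ = [
    "read_volume",
    "write_volume",
    "read_planes",
    "write_planes",
    "write_dataset",
]


def read_volume(path) -> tuple:
    """Load a NIfTI volume -> (HU array, VolumeGeometry)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D scalar volume, got ndim={data.ndim}")
    affine = img.affine
    direction = affine[:3, :3]
    spacing = np.linalg.norm(direction, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("volume header is missing valid voxel spacing")
    cosines = direction / spacing
    if not np.allclose(cosines, np.eye(3), atol=1e-6):
        raise ValueError(
            "oblique or permuted direction cosines are not supported: this "
            "package uses an axis-aligned, center-origin mm convention"
        )
    geom = VolumeGeometry(shape=data.shape, spacing=tuple(spacing))
    return data, geom


def write_volume(path, volume: np.ndarray, geom: VolumeGeometry) -> None:
    affine = np.diag([*geom.spacing, 1.0])
    # origin such that the volume center sits at physical 0
    affine[:3, 3] = -(np.array(geom.shape) - 1.0) / 2.0 * np.array(geom.spacing)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))


def _fmt(values) -> list:
    return [float(f"{v:.17g}") for v in np.asarray(values, dtype=float)]


def write_planes(path, triplet: PlaneTriplet, geom: VolumeGeometry) -> None:
    doc = {
        "region": triplet.region,
        "volume": {"shape": list(geom.shape), "spacing_mm": _fmt(geom.spacing)},
        "planes": [
            {
                "name": p.name,
                "center_mm": _fmt(p.center),
                "e_u": _fmt(p.e_u),
                "e_v": _fmt(p.e_v),
            }
            for p in triplet.planes
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_planes(path, reorthogonalize: bool = False) -> tuple:
    """Load and validate a plane-annotation file -> (PlaneTriplet, geometry).

    Orthonormality is re-checked on read (unit norms and e_u.e_v within 1e-6).
    With ``reorthogonalize`` the in-plane frame is Gram-Schmidt-corrected
    instead of rejected.
    """
    doc = json.loads(Path(path).read_text())
    for key in ("region", "volume", "planes"):
        if key not in doc:
            raise ValueError(f"annotation file is missing the {key!r} field")
    geom = VolumeGeometry(
        shape=tuple(doc["volume"]["shape"]),
        spacing=tuple(doc["volume"]["spacing_mm"]),
    )
    planes = []
    for entry in doc["planes"]:
        e_u = np.asarray(entry["e_u"], dtype=float)
        e_v = np.asarray(entry["e_v"], dtype=float)
        if reorthogonalize:
            e_u = e_u / np.linalg.norm(e_u)
            e_v = e_v - (e_v @ e_u) * e_u
            e_v = e_v / np.linalg.norm(e_v)
        planes.append(
            StandardPlane(
                name=entry["name"],
                center=np.asarray(entry["center_mm"], dtype=float),
                e_u=e_u,
                e_v=e_v,
            )
        )
    return PlaneTriplet(region=doc["region"], planes=tuple(planes)), geom


def write_dataset(samples, out_dir) -> Path:
    """Write phantom samples as NIfTI + JSON + a manifest CSV; returns the dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["index,region,patient_id,fold,metal,volume,planes"]
    for i, s in enumerate(samples):
        vol_name = f"phantom_{i:04d}.nii.gz"
        ann_name = f"phantom_{i:04d}.json"
        write_volume(out / vol_name, s.volume, s.geometry)
        write_planes(out / ann_name, s.triplet, s.geometry)
        rows.append(
            f"{i},{s.region},{s.patient_id},{s.fold},{int(s.metal)},{vol_name},{ann_name}"
        )
    (out / "manifest.csv").write_text("\n".join(rows) + "\n")
    return out
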