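"""Reading and writing pipeline artifacts.

Volumes (phantoms, attenuation maps, reconstructions) go to NIfTI via
nibabel with a YAML sidecar for non-image metadata; projection sets are a
NIfTI stack per energy window plus a geometry sidecar; cohorts and binned
tables are CSV; biokinetic models are YAML with infinity encoded as the
literal string ``inf``.
"""

from __future__ import annotations

import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetics import BiokineticModel, frame_to_records, records_to_frame
from .projector import AcquisitionGeometry, ProjectionSet
from .synthetic import DigitalPhantom

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_projections",
    "load_projections",
    "save_cohort_csv",
    "load_cohort_csv",
    "save_model_yaml",
    "load_model_yaml",
]


def _affine(voxel_size_cm: float) -> np.ndarray:
    # NIfTI spatial units are mm
    return np.diag([voxel_size_cm * 10.0] * 3 + [1.0])


def _save_nii(path, arr, voxel_size_cm):
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(voxel_size_cm)), str(path))


def save_phantom(phantom: DigitalPhantom, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v = phantom.voxel_size_cm
    _save_nii(out / "activity.nii.gz", phantom.activity_grid, v)
    _save_nii(out / "mu.nii.gz", phantom.mu_grid, v)
    masks = (
        phantom.left_kidney_mask.astype(np.uint8)
        + 2 * phantom.right_kidney_mask.astype(np.uint8)
        + 4 * phantom.body_mask.astype(np.uint8)
    )
    _save_nii(out / "masks.nii.gz", masks, v)
    meta = {
        "voxel_size_cm": v,
        "injected_activity_a0_mbq": phantom.injected_activity_a0_mbq,
        "injection_time_h": phantom.injection_time_h,
        "mask_encoding": "bit0: left kidney, bit1: right kidney, bit2: body",
    }
    (out / "phantom.yaml").write_text(yaml.safe_dump(meta))
    return out


def load_phantom(in_dir) -> DigitalPhantom:
    d = Path(in_dir)
    meta = yaml.safe_load((d / "phantom.yaml").read_text())
    act = np.asarray(nib.load(str(d / "activity.nii.gz")).get_fdata(), dtype=float)
    mu = np.asarray(nib.load(str(d / "mu.nii.gz")).get_fdata(), dtype=float)
    masks = np.asarray(nib.load(str(d / "masks.nii.gz")).get_fdata()).astype(np.uint8)
    return DigitalPhantom(
        activity_grid=act,
        mu_grid=mu,
        voxel_size_cm=float(meta["voxel_size_cm"]),
        left_kidney_mask=(masks & 1).astype(bool),
        right_kidney_mask=(masks & 2).astype(bool),
        body_mask=(masks & 4).astype(bool),
        injected_activity_a0_mbq=float(meta["injected_activity_a0_mbq"]),
        injection_time_h=float(meta.get("injection_time_h", 0.0)),
    )


def save_projections(proj: ProjectionSet, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for window, arr in proj.counts.items():
        _save_nii(out / f"counts_{window}.nii.gz", arr, proj.voxel_size_cm)
    if proj.scatter_expectation is not None:
        _save_nii(out / "scatter_expectation.nii.gz", proj.scatter_expectation,
                  proj.voxel_size_cm)
    g = proj.geometry
    meta = {
        "n_views": int(g.n_views),
        "arc_deg": float(g.arc_deg),
        "orbit_radius_cm": [float(r) for r in g.orbit_radii_cm],
        "seconds_per_view": float(g.seconds_per_view),
        "photopeak_window_kev": [float(v) for v in g.photopeak_window_kev],
        "scatter_window_kev": [float(v) for v in g.scatter_window_kev],
        "voxel_size_cm": float(proj.voxel_size_cm),
        "time_post_injection_h": float(proj.time_post_injection_h),
        "windows": sorted(proj.counts),
        "conventions": "0-based voxels; axial z; view 0 anterior; counterclockwise",
    }
    (out / "geometry.yaml").write_text(yaml.safe_dump(meta))
    return out


def load_projections(in_dir) -> ProjectionSet:
    d = Path(in_dir)
    meta = yaml.safe_load((d / "geometry.yaml").read_text())
    geom = AcquisitionGeometry(
        n_views=meta["n_views"],
        arc_deg=meta["arc_deg"],
        orbit_radius_cm=np.asarray(meta["orbit_radius_cm"], dtype=float),
        seconds_per_view=meta["seconds_per_view"],
        photopeak_window_kev=tuple(meta["photopeak_window_kev"]),
        scatter_window_kev=tuple(meta["scatter_window_kev"]),
    )
    counts = {
        w: np.asarray(nib.load(str(d / f"counts_{w}.nii.gz")).get_fdata(), dtype=float)
        for w in meta["windows"]
    }
    scatter_exp = None
    if (d / "scatter_expectation.nii.gz").exists():
        scatter_exp = np.asarray(
            nib.load(str(d / "scatter_expectation.nii.gz")).get_fdata(), dtype=float
        )
    return ProjectionSet(
        counts=counts,
        geometry=geom,
        voxel_size_cm=float(meta["voxel_size_cm"]),
        time_post_injection_h=float(meta["time_post_injection_h"]),
        scatter_expectation=scatter_exp,
    )


def save_cohort_csv(records, path) -> Path:
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    return path


def load_cohort_csv(path):
    return frame_to_records(pd.read_csv(path))


def save_model_yaml(model: BiokineticModel, path) -> Path:
    path = Path(path)
    doc = {
        "F_S": float(model.F_S),
        "components": [
            {"a": float(a), "T_h": "inf" if math.isinf(T) else float(T)}
            for a, T in model.components
        ],
    }
    if model.name:
        doc["name"] = model.name
    path.write_text(yaml.safe_dump(doc))
    return path


def load_model_yaml(path) -> BiokineticModel:
    doc = yaml.safe_load(Path(path).read_text())
    comps = tuple((float(c["a"]), float(c["T_h"])) for c in doc["components"])
    return BiokineticModel(F_S=float(doc["F_S"]), components=comps,
                           name=doc.get("name", ""))
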