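"""NIfTI / CSV / JSON round-trips for stacks, profiles and cohorts.

Phantom label volumes are stored as NIfTI-1 with the voxel spacing in the
header affine (labels: 0 background, 1 LV cavity, 2 LV myocardium, 3 RV) and
a JSON sidecar carrying the metadata NIfTI cannot (slice ordering, RV
insertion angle, label map, and the generating phantom spec when known).
Cohorts are plain CSV with a JSON ground-truth sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._types import LabelMaskStack, PhantomSpec, SegmentalWTProfile

__all__ = [
    "write_stack",
    "read_stack",
    "write_profiles",
    "read_profiles",
    "write_cohort",
]

WT_COLUMNS = [f"wt_{i:02d}" for i in range(1, 17)]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json")  # strips .nii.gz / .nii


def write_stack(stack: LabelMaskStack, path, spec: PhantomSpec | None = None) -> None:
    path = Path(path)
    sp, st = stack.in_plane_spacing, stack.slice_thickness
    # axes (slice, row, col) -> spatial (col, row, slice) for NIfTI x/y/z
    affine = np.diag([sp, sp, st, 1.0])
    img = nib.Nifti1Image(np.transpose(stack.label_volume, (2, 1, 0)).astype(np.int16), affine)
    img.header.set_zooms((sp, sp, st))
    nib.save(img, str(path))
    meta = {
        "base_to_apex": stack.base_to_apex,
        "rv_insertion_angle": stack.rv_insertion_angle,
        "label_map": stack.label_map,
    }
    if spec is not None:
        d = dataclasses.asdict(spec)
        d["sector_thickness"] = np.asarray(d["sector_thickness"]).tolist()
        meta["phantom_spec"] = d
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_stack(path) -> LabelMaskStack:
    path = Path(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return LabelMaskStack(
        label_volume=np.transpose(np.asarray(img.dataobj), (2, 1, 0)).astype(int),
        in_plane_spacing=float(zooms[0]),
        slice_thickness=float(zooms[2]),
        base_to_apex=meta.get("base_to_apex", True),
        rv_insertion_angle=meta.get("rv_insertion_angle"),
        label_map=meta.get("label_map", {"background": 0, "cavity": 1, "myocardium": 2, "rv": 3}),
    )


def write_profiles(profiles: list[SegmentalWTProfile], path) -> None:
    rows = [{"subject_id": p.subject_id, **dict(zip(WT_COLUMNS, p.wt))} for p in profiles]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path) -> list[SegmentalWTProfile]:
    df = pd.read_csv(path)
    return [
        SegmentalWTProfile(wt=row[WT_COLUMNS].to_numpy(float), subject_id=row["subject_id"])
        for _, row in df.iterrows()
    ]


def write_cohort(table: pd.DataFrame, truth, path) -> None:
    path = Path(path)
    table.to_csv(path, index=False)
    side = {
        "biomarker_coef": truth.biomarker_coef,
        "hazard": truth.hazard,
        "htn_intercept": truth.htn_intercept,
    }
    path.with_suffix(".truth.json").write_text(json.dumps(side, indent=2))
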