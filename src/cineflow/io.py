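"""Case container I/O.

A *case* is a directory holding a cine stack plus optional reference flow,
chamber masks and contours:

``frames.nii.gz``
    T x H x W intensity stack (NIfTI).
``flow_vx.nii.gz`` / ``flow_vy.nii.gz``
    in-plane velocity components, cm/s (optional).
``labels.nii.gz``
    labelled chamber mask, 0 background / 1..4 = LV, LA, RV, RA (optional).
``meta.json``
    sidecar with ps_x, ps_y (mm), frame_interval (s), heart_rate (bpm), n_phases.
``contours.csv``
    long-format polylines: phase, chamber, vertex_index, row, col (optional).

A single-file ``.npz`` container with keys ``frames, vx, vy, labels`` and the
metadata fields is also supported for compact fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    AcquisitionMeta,
    BloodPoolMask,
    CineSequence,
    ContourSet,
    FlowField,
    FormatError,
    ValidationError,
)

CaseTuple = Tuple[
    CineSequence, Optional[FlowField], Optional[BloodPoolMask], Optional[ContourSet]
]


def _save_nifti(arr: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(arr), affine=np.eye(4)), str(path))


def _load_nifti(path: Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def write_contours_csv(contours: ContourSet, path: Path) -> None:
    rows = []
    for phase in contours.phases():
        for chamber, poly in sorted(contours.polylines[phase].items()):
            for i, (r, c) in enumerate(poly):
                rows.append((phase, chamber, i, r, c))
    df = pd.DataFrame(rows, columns=["phase", "chamber", "vertex_index", "row", "col"])
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_contours_csv(path: Path) -> ContourSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"phase", "chamber", "vertex_index", "row", "col"}
    if not required.issubset(df.columns):
        raise FormatError(f"contours CSV missing columns {required - set(df.columns)}")
    cs = ContourSet()
    for (phase, chamber), grp in df.groupby(["phase", "chamber"]):
        grp = grp.sort_values("vertex_index")
        cs.add(int(phase), int(chamber), grp[["row", "col"]].to_numpy(dtype=np.float64))
    return cs


def write_case(
    path: str | Path,
    cine: CineSequence,
    flow: Optional[FlowField] = None,
    mask: Optional[BloodPoolMask] = None,
    contours: Optional[ContourSet] = None,
) -> Path:
    """Write a case directory; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _save_nifti(cine.frames, path / "frames.nii.gz")
    (path / "meta.json").write_text(json.dumps(cine.meta.to_dict(), indent=2))
    if flow is not None:
        if flow.shape != cine.shape:
            raise ValidationError(f"flow shape {flow.shape} != cine shape {cine.shape}")
        _save_nifti(flow.vx, path / "flow_vx.nii.gz")
        _save_nifti(flow.vy, path / "flow_vy.nii.gz")
    if mask is not None:
        if mask.shape != cine.shape:
            raise ValidationError(f"mask shape {mask.shape} != cine shape {cine.shape}")
        _save_nifti(mask.labels, path / "labels.nii.gz")
    if contours is not None:
        write_contours_csv(contours, path / "contours.csv")
    return path


def read_case(path: str | Path) -> CaseTuple:
    """Read a case directory (or ``.npz`` container) written by :func:`write_case`.

    Optional components absent on disk are returned as ``None``. Shapes of all
    present components are validated against the cine stack.
    """
    path = Path(path)
    if path.suffix == ".npz":
        return _read_case_npz(path)
    if not path.is_dir():
        raise FormatError(f"case path {path} does not exist or is not a directory")
    frames_p = path / "frames.nii.gz"
    meta_p = path / "meta.json"
    if not frames_p.exists():
        raise FormatError(f"case at {path} lacks mandatory 'frames' component")
    if not meta_p.exists():
        raise FormatError(f"case at {path} lacks mandatory 'meta.json'")
    meta = AcquisitionMeta.from_dict(json.loads(meta_p.read_text()))
    cine = CineSequence(frames=_load_nifti(frames_p), meta=meta)

    flow = None
    if (path / "flow_vx.nii.gz").exists():
        if not (path / "flow_vy.nii.gz").exists():
            raise FormatError("flow_vx present without flow_vy")
        flow = FlowField(
            vx=_load_nifti(path / "flow_vx.nii.gz"),
            vy=_load_nifti(path / "flow_vy.nii.gz"),
        )
        if flow.shape != cine.shape:
            raise ValidationError(f"flow shape {flow.shape} != cine shape {cine.shape}")

    mask = None
    if (path / "labels.nii.gz").exists():
        mask = BloodPoolMask(labels=_load_nifti(path / "labels.nii.gz"))
        if mask.shape != cine.shape:
            raise ValidationError(f"mask shape {mask.shape} != cine shape {cine.shape}")

    contours = None
    if (path / "contours.csv").exists():
        contours = read_contours_csv(path / "contours.csv")
    return cine, flow, mask, contours


def write_case_npz(
    path: str | Path,
    cine: CineSequence,
    flow: Optional[FlowField] = None,
    mask: Optional[BloodPoolMask] = None,
) -> Path:
    """Write a compact single-file container (compressed arrays + metadata)."""
    path = Path(path)
    payload = {"frames": cine.frames, **cine.meta.to_dict()}
    if flow is not None:
        payload["vx"], payload["vy"] = flow.vx, flow.vy
    if mask is not None:
        payload["labels"] = mask.labels
    np.savez_compressed(path, **payload)
    return path


def _read_case_npz(path: Path) -> CaseTuple:
    with np.load(path) as z:
        keys = set(z.files)
        if "frames" not in keys:
            raise FormatError(f"{path} lacks mandatory key 'frames'")
        meta_keys = {"ps_x", "ps_y", "frame_interval", "heart_rate", "n_phases"}
        if not meta_keys.issubset(keys):
            raise FormatError(f"{path} lacks metadata keys {meta_keys - keys}")
        meta = AcquisitionMeta.from_dict({k: z[k].item() for k in meta_keys})
        cine = CineSequence(frames=z["frames"], meta=meta)
        flow = None
        if "vx" in keys:
            if "vy" not in keys:
                raise FormatError("vx present without vy")
            flow = FlowField(vx=z["vx"], vy=z["vy"])
            if flow.shape != cine.shape:
                raise ValidationError(f"flow shape {flow.shape} != cine shape {cine.shape}")
        mask = None
        if "labels" in keys:
            mask = BloodPoolMask(labels=z["labels"])
            if mask.shape != cine.shape:
                raise ValidationError(f"mask shape {mask.shape} != cine shape {cine.shape}")
    return cine, flow, mask, None
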