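"""Readers and writers for the on-disk study dialects.

* contours — JSON, one file per session:
  ``{"session": {...}, "slices": [{"slice": s, "frame": f, "points": [[x, y], ...]}]}``
  with coordinates in mm;
* masks — NIfTI (``.nii.gz``), one 4-D volume per session, axes
  (x, y, slice, frame), affine encoding the in-plane and slice spacing;
* truth / measurements / metrics — plain CSV tables.

Configurations round-trip through YAML or JSON files that mirror the
``PhantomConfig`` field names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .geometry import MaskStack
from .phantom import PhantomConfig, PhantomTruth, Session

__all__ = [
    "write_contours_json",
    "read_contours_json",
    "write_masks_nifti",
    "read_masks_nifti",
    "write_truth",
    "load_config",
    "save_config",
    "config_digest",
]


def write_contours_json(session: Session, path: Union[str, Path]) -> None:
    payload = {
        "session": {
            "id": session.session_id,
            "reader": session.reader,
            "software": session.software,
            "repetition": session.repetition,
            "kind": session.kind,
            "duplicated": session.duplicated,
            "n_slices": session.n_slices,
            "n_frames": session.n_frames,
        },
        "slices": [
            {"slice": s, "frame": f, "points": session.contours[(s, f)].tolist()}
            for (s, f) in sorted(session.contours)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_contours_json(path: Union[str, Path]) -> Session:
    try:
        payload = json.loads(Path(path).read_text())
        meta = payload["session"]
        contours = {
            (int(entry["slice"]), int(entry["frame"])): np.asarray(entry["points"], float)
            for entry in payload["slices"]
        }
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise DataError(f"malformed contour file {path}: {exc}") from exc
    return Session(
        session_id=str(meta["id"]),
        reader=int(meta["reader"]),
        software=str(meta["software"]),
        repetition=int(meta["repetition"]),
        kind=str(meta.get("kind", "manual")),
        n_slices=int(meta["n_slices"]),
        n_frames=int(meta["n_frames"]),
        contours=contours,
        duplicated=bool(meta.get("duplicated", False)),
    )


def write_masks_nifti(
    session: Session, path: Union[str, Path]
) -> None:
    if session.masks is None:
        raise DataError(f"session {session.session_id} carries no masks")
    affine = np.diag([session.pixel_spacing, session.pixel_spacing, session.slice_spacing, 1.0])
    img = nib.Nifti1Image(session.masks.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_masks_nifti(path: Union[str, Path]) -> MaskStack:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise DataError(f"{path}: expected a 4-D (x, y, slice, frame) mask volume")
    affine = img.affine
    return MaskStack(
        data=data > 0,
        pixel_spacing=float(abs(affine[0, 0])),
        slice_spacing=float(abs(affine[2, 2])),
        meta={"path": str(path)},
    )


def write_truth(truth: PhantomTruth, outdir: Union[str, Path]) -> None:
    """Per-slice truth table (``truth.csv``) and the analytic clinical
    metrics (``truth_metrics.csv``)."""
    outdir = Path(outdir)
    n_slices, n_frames = truth.radius_mm.shape
    rows = [
        {
            "slice": s,
            "frame": f,
            "radius_mm": truth.radius_mm[s, f],
            "perimeter_cm": truth.perimeter_cm[s, f],
            "area_cm2": truth.area_cm2[s, f],
        }
        for s in range(n_slices)
        for f in range(n_frames)
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth.csv", index=False)
    metrics = dict(truth.metrics, ed_frame=truth.ed_frame, es_frame=truth.es_frame)
    pd.DataFrame([metrics]).to_csv(outdir / "truth_metrics.csv", index=False)


def save_config(config: PhantomConfig, path: Union[str, Path]) -> None:
    payload = dataclasses.asdict(config)
    payload["region_peak_strain"] = dict(payload["region_peak_strain"])
    payload["software_length_bias"] = dict(payload["software_length_bias"])
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, sort_keys=True, indent=2))


def load_config(path: Union[str, Path], **overrides) -> PhantomConfig:
    path = Path(path)
    try:
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(path.read_text()) or {}
        else:
            payload = json.loads(path.read_text())
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigurationError(f"config {path} must be a mapping of field names")
    payload.update(overrides)
    known = {f.name for f in dataclasses.fields(PhantomConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
    return PhantomConfig(**payload)


def config_digest(config: PhantomConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["region_peak_strain"] = dict(payload["region_peak_strain"])
    payload["software_length_bias"] = dict(payload["software_length_bias"])
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
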