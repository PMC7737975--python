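"""Clinical metrics from per-slice measurements.

Seven quantities summarise a session: end-diastolic and end-systolic
cavity volume (EDV, ESV, mL), left-ventricular ejection fraction
(LVEF, %), and the apical / mid-ventricular / basal / global
circumferential strains (ACS, MCS, BCS, GCS, %).

Volumes use composite midpoint integration: the per-slice cavity area is
multiplied by the effective slice spacing (slice thickness plus gap) and
summed over the stack.  ED is the frame of maximum total volume and ES
the frame of minimum total volume (earliest frame on ties).

Circumferential strain of a slice at frame n is the fractional change of
its endocardial perimeter relative to the ED frame,

    eps_n = (L_n - L_0) / L_0,

with L_0 the perimeter at the single, globally defined ED frame (ED is a
property of the summed volume curve, so one reference frame serves all
slices).  Regional strain curves are unweighted means of the slice
curves within each third of the stack (base / mid / apex); the global
curve averages all slices.  A reported "peak" strain is 100x the most
negative value of a curve; averaging slices into the regional curve
before taking the extremum is the default, with per-slice peaks averaged
afterwards available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "METRIC_NAMES",
    "VolumeCurve",
    "StrainMatrix",
    "ClinicalMetrics",
    "volume_curve",
    "lvef",
    "strain_matrix",
    "region_map",
    "regional_strain_curves",
    "peak_strain",
    "clinical_metrics",
]

#: Canonical metric order used in every table.
METRIC_NAMES = ("ACS", "MCS", "BCS", "GCS", "EDV", "ESV", "LVEF")

_REGIONS = ("base", "mid", "apex")


@dataclass(frozen=True)
class VolumeCurve:
    """Total cavity volume per frame (mL) with the ED/ES frame indices."""

    volume: np.ndarray
    ed_frame: int
    es_frame: int


@dataclass(frozen=True)
class StrainMatrix:
    """Dimensionless strain per (slice, frame) with its ED reference frame."""

    strain: np.ndarray
    ed_frame: int


@dataclass(frozen=True)
class ClinicalMetrics:
    """One session's seven clinical metrics (strains in %, volumes in mL)."""

    ACS: float
    MCS: float
    BCS: float
    GCS: float
    EDV: float
    ESV: float
    LVEF: float
    ed_frame: int
    es_frame: int

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _measurement_grid(measurements: pd.DataFrame, column: str) -> np.ndarray:
    """Pivot a measurement table to a dense (slice, frame) array."""
    pivot = measurements.pivot_table(
        index="slice", columns="frame", values=column, aggfunc="first"
    )
    n_slices = int(measurements["slice"].max()) + 1
    n_frames = int(measurements["frame"].max()) + 1
    if pivot.shape != (n_slices, n_frames) or pivot.isna().any().any():
        missing = [
            (s, f)
            for s in range(n_slices)
            for f in range(n_frames)
            if s not in pivot.index or f not in pivot.columns or pd.isna(pivot.loc[s, f])
        ]
        raise DataError(f"incomplete measurements: missing (slice, frame) {missing[:10]}")
    return pivot.sort_index().to_numpy()


def volume_curve(measurements: pd.DataFrame, slice_spacing_mm: float) -> VolumeCurve:
    """Composite midpoint volume per frame (mL).

    ``volume[f] = sum_slices area_cm2(s, f) * slice_spacing_cm``; ED/ES
    are the frames of maximum/minimum volume, earliest frame on ties.
    """
    if slice_spacing_mm <= 0:
        raise DataError("slice spacing must be positive")
    areas = _measurement_grid(measurements, "area_cm2")
    volume = areas.sum(axis=0) * (slice_spacing_mm / 10.0)
    ed = int(np.argmax(volume))
    es = int(np.argmin(volume))
    return VolumeCurve(volume=volume, ed_frame=ed, es_frame=es)


def lvef(edv: float, esv: float) -> float:
    """Ejection fraction in %, ``100 * (EDV - ESV) / EDV``."""
    if edv <= 0:
        raise DataError("EDV must be positive")
    if esv > edv:
        raise DataError("ESV exceeds EDV: ED/ES definition violated upstream")
    return 100.0 * (edv - esv) / edv


def strain_matrix(measurements: pd.DataFrame, ed_frame: int) -> StrainMatrix:
    """Per-slice circumferential strain relative to the ED perimeter."""
    perim = _measurement_grid(measurements, "perimeter_cm")
    if not 0 <= ed_frame < perim.shape[1]:
        raise DataError(f"ED frame {ed_frame} out of range")
    ref = perim[:, ed_frame]
    zero = np.nonzero(ref == 0.0)[0]
    if zero.size:
        raise DataError(f"zero ED perimeter at slice(s) {zero.tolist()}")
    return StrainMatrix(strain=(perim - ref[:, None]) / ref[:, None], ed_frame=ed_frame)


def region_map(n_slices: int) -> Dict[str, List[int]]:
    """Equal thirds of the stack: slices 0.. are basal, the last third apical."""
    if n_slices % 3 != 0:
        raise DataError("regional grouping needs a slice count divisible by 3")
    block = n_slices // 3
    return {r: list(range(i * block, (i + 1) * block)) for i, r in enumerate(_REGIONS)}


def regional_strain_curves(
    strains: StrainMatrix, regions: Mapping[str, Sequence[int]] | None = None
) -> Dict[str, np.ndarray]:
    """Per-region mean strain curves plus the all-slice ``"global"`` curve."""
    mat = strains.strain
    if regions is None:
        regions = region_map(mat.shape[0])
    curves: Dict[str, np.ndarray] = {}
    for region, slices in regions.items():
        if len(slices) == 0:
            raise DataError(f"region {region!r} contains no slices")
        curves[region] = mat[list(slices)].mean(axis=0)
    curves["global"] = mat.mean(axis=0)
    return curves


def peak_strain(curve: np.ndarray) -> float:
    """Peak (most negative) strain of a per-frame curve, in %."""
    return 100.0 * float(np.min(curve))


def clinical_metrics(
    measurements: pd.DataFrame,
    slice_spacing_mm: float,
    *,
    peak_mode: str = "curve_extremum",
) -> ClinicalMetrics:
    """All seven metrics of one session's measurement table.

    ``peak_mode="curve_extremum"`` (default) averages slice strains into
    regional curves first and takes each curve's extremum;
    ``"per_slice_peak"`` takes per-slice peaks and averages them.
    """
    vc = volume_curve(measurements, slice_spacing_mm)
    sm = strain_matrix(measurements, vc.ed_frame)
    regions = region_map(sm.strain.shape[0])
    if peak_mode == "curve_extremum":
        curves = regional_strain_curves(sm, regions)
        peaks = {r: peak_strain(c) for r, c in curves.items()}
    elif peak_mode == "per_slice_peak":
        slice_peaks = 100.0 * sm.strain.min(axis=1)
        peaks = {r: float(slice_peaks[list(s)].mean()) for r, s in regions.items()}
        peaks["global"] = float(slice_peaks.mean())
    else:
        raise DataError(f"unknown peak_mode {peak_mode!r}")
    edv = float(vc.volume[vc.ed_frame])
    esv = float(vc.volume[vc.es_frame])
    return ClinicalMetrics(
        ACS=peaks["apex"],
        MCS=peaks["mid"],
        BCS=peaks["base"],
        GCS=peaks["global"],
        EDV=edv,
        ESV=esv,
        LVEF=lvef(edv, esv),
        ed_frame=vc.ed_frame,
        es_frame=vc.es_frame,
    )
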