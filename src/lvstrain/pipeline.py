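"""End-to-end orchestration: phantom study -> measurements -> metrics ->
agreement reports, plus the replicated simulation experiments built on
that chain (length-bias recovery, bias cancellation in relative metrics).

The functions here are what the CLI subcommands and the analysis
scripts call; each takes and returns plain DataFrames so measured data
from the supported JSON/NIfTI dialects can enter the chain at any stage.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import metrics as clin
from .agreement import BlandAltmanResult, bland_altman, duplicate_single_run
from .errors import DataError
from .geometry import measure_session
from .phantom import PhantomConfig, Session, generate_study

__all__ = [
    "measure_study",
    "metrics_table",
    "bland_altman_lengths",
    "bland_altman_report",
    "length_bias_replicates",
    "standardized_shifts",
    "cancellation_ratio",
]

_SESSION_COLS = ["session_id", "reader", "software", "repetition", "kind", "duplicated"]


def measure_study(
    sessions: Iterable[Session],
    *,
    method: str = "auto",
    hull_convention: str = "centers",
    samples_per_segment: int = 200,
) -> pd.DataFrame:
    """Per-slice measurements of every session, with session metadata."""
    frames = []
    for session in sessions:
        meas = measure_session(
            session,
            method=method,
            hull_convention=hull_convention,
            samples_per_segment=samples_per_segment,
        )
        for col, value in zip(
            _SESSION_COLS,
            (
                session.session_id,
                session.reader,
                session.software,
                session.repetition,
                session.kind,
                session.duplicated,
            ),
        ):
            meas[col] = value
        frames.append(meas)
    if not frames:
        raise DataError("no sessions to measure")
    return pd.concat(frames, ignore_index=True)[
        _SESSION_COLS + ["slice", "frame", "method", "perimeter_cm", "area_cm2"]
    ]


def metrics_table(
    measurements: pd.DataFrame,
    slice_spacing_mm: float,
    *,
    peak_mode: str = "curve_extremum",
) -> pd.DataFrame:
    """One clinical-metrics row per session in a measurement table."""
    rows = []
    for session_id, group in measurements.groupby("session_id", sort=True):
        cm = clin.clinical_metrics(group, slice_spacing_mm, peak_mode=peak_mode)
        meta = group.iloc[0]
        row = {col: meta[col] for col in _SESSION_COLS}
        row.update(cm.as_dict())
        row["ed_frame"] = cm.ed_frame
        row["es_frame"] = cm.es_frame
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bland-Altman on raw contour lengths


def _paired_lengths(df_a: pd.DataFrame, df_b: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """Pair two groups' perimeter measurements element-wise.

    Pairing keys are (slice, frame, repetition) plus the reader whenever
    both groups have per-reader data; an automated (single-reader) group
    broadcasts across the manual group's readers.
    """
    keys = ["slice", "frame", "repetition"]
    if df_a["reader"].nunique() > 1 and df_b["reader"].nunique() > 1:
        keys.append("reader")
    merged = df_a.merge(df_b, on=keys, suffixes=("_a", "_b"))
    if merged.empty:
        raise DataError("no overlapping measurements to pair")
    return merged["perimeter_cm_a"].to_numpy(), merged["perimeter_cm_b"].to_numpy()


def bland_altman_lengths(
    measurements: pd.DataFrame,
    software_a: str,
    software_b: str,
    *,
    repetition: Optional[int] = None,
    loa_multiplier: float = 1.96,
) -> BlandAltmanResult:
    """Bland–Altman of contour lengths for the comparison "A vs B".

    Differences are A − B over (reader, repetition, slice, frame) pairs;
    restrict to one repetition with ``repetition=`` or pool both.
    """
    df = measurements
    df_a = df[df["software"] == software_a]
    df_b = df[df["software"] == software_b]
    if repetition is not None:
        df_a = df_a[df_a["repetition"] == repetition]
        df_b = df_b[df_b["repetition"] == repetition]
    if df_a.empty or df_b.empty:
        raise DataError(f"no measurements for {software_a!r} / {software_b!r}")
    x_b, y_a = _paired_lengths(df_b, df_a)
    return bland_altman(x_b, y_a, loa_multiplier=loa_multiplier)


def bland_altman_report(
    measurements: pd.DataFrame,
    pairings: Sequence[Tuple[str, str]],
    *,
    loa_multiplier: float = 1.96,
    split_repetitions: bool = True,
) -> pd.DataFrame:
    """One row per pairing (and repetition split, plus a pooled view)."""
    reps: List[Optional[int]] = [None]
    if split_repetitions:
        reps = sorted(measurements["repetition"].unique()) + [None]
    rows = []
    for software_a, software_b in pairings:
        for rep in reps:
            res = bland_altman_lengths(
                measurements, software_a, software_b,
                repetition=rep, loa_multiplier=loa_multiplier,
            )
            rows.append(
                {
                    "comparison": f"{software_a} vs {software_b}",
                    "repetition": "pooled" if rep is None else rep,
                    "bias_cm": res.bias,
                    "loa_low_cm": res.loa_low,
                    "loa_high_cm": res.loa_high,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def with_duplicated_automated(sessions: Sequence[Session]) -> List[Session]:
    """Expand every automated single run into two repetition entries."""
    out: List[Session] = []
    for s in sessions:
        if s.kind == "automated" and not s.duplicated:
            out.extend(duplicate_single_run(s))
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# replicated simulation experiments


def _replicate_seed(base_seed: int, replicate: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), int(replicate)]).generate_state(1)[0] % (2**31))


def length_bias_replicates(
    config: PhantomConfig,
    software_a: str,
    software_b: str,
    n_replicates: int,
    base_seed: int,
) -> np.ndarray:
    """Bland–Altman bias estimates (A vs B, cm) over replicated studies.

    Each replicate regenerates the manual sessions with a fresh derived
    seed, measures all contours through the spline chain and pools both
    repetitions into one Bland–Altman analysis.
    """
    import dataclasses

    biases = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=_replicate_seed(base_seed, r))
        sessions, _ = generate_study(cfg, render_masks=False)
        manual = [s for s in sessions if s.kind == "manual"]
        meas = measure_study(manual, method="spline")
        biases[r] = bland_altman_lengths(meas, software_a, software_b).bias
    return biases


def paired_metric_differences(
    metrics_df: pd.DataFrame, software_a: str, software_b: str
) -> pd.DataFrame:
    """Per-reader A − B difference of every metric (repetitions averaged)."""
    manual = metrics_df[metrics_df["kind"] == "manual"]
    out = {}
    for metric in clin.METRIC_NAMES:
        pivot = manual.pivot_table(index="reader", columns="software", values=metric)
        if software_a not in pivot or software_b not in pivot:
            raise DataError(f"missing software group for metric {metric}")
        out[metric] = pivot[software_a] - pivot[software_b]
    return pd.DataFrame(out)


def standardized_shifts(
    metrics_df: pd.DataFrame, software_a: str, software_b: str
) -> Dict[str, float]:
    """Paired standardized mean shift of each metric between two packages.

    Per reader, values are averaged over repetitions within each package;
    the shift is |mean difference| / SD of the per-reader differences
    (paired Cohen's d), so a systematic software effect scores high and
    pure reader variability scores near zero.
    """
    diffs = paired_metric_differences(metrics_df, software_a, software_b)
    shifts = {}
    for metric in clin.METRIC_NAMES:
        d = diffs[metric].to_numpy()
        sd = d.std(ddof=1)
        shifts[metric] = float("inf") if sd == 0 else abs(float(d.mean())) / float(sd)
    return shifts


def _shift_ratio(shifts: Dict[str, float]) -> float:
    absolute = min(shifts["EDV"], shifts["ESV"])
    relative = max(shifts["LVEF"], shifts["GCS"])
    if relative == 0.0:
        return float("inf")
    return absolute / relative


def cancellation_ratio(
    metrics_df: pd.DataFrame, software_a: str, software_b: str
) -> float:
    """How much more a length bias moves absolute than relative metrics.

    Ratio of the smaller of the EDV/ESV standardized shifts to the larger
    of the LVEF/GCS ones; systematic contour-length offsets shift the
    volumes but cancel in the size-normalised metrics, so the ratio is
    large when the cancellation mechanism operates.
    """
    return _shift_ratio(standardized_shifts(metrics_df, software_a, software_b))


def cancellation_replicates(
    config: PhantomConfig,
    software_a: str,
    software_b: str,
    n_replicates: int,
    base_seed: int,
) -> Tuple[Dict[str, float], float]:
    """Standardized shifts and their absolute/relative ratio, pooled over
    replicated studies.

    Per-reader paired differences are pooled across replicates before
    standardizing, which stabilises the Cohen's-d estimates (7 readers
    give a noisy SD on their own).  Returns ``(shifts, ratio)``.
    """
    import dataclasses

    pools: List[pd.DataFrame] = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=_replicate_seed(base_seed, r))
        sessions, _ = generate_study(cfg, render_masks=False)
        manual = [s for s in sessions if s.kind == "manual"]
        meas = measure_study(manual, method="spline")
        mt = metrics_table(meas, cfg.slice_spacing)
        pools.append(paired_metric_differences(mt, software_a, software_b))
    diffs = pd.concat(pools, ignore_index=True)
    shifts = {}
    for metric in clin.METRIC_NAMES:
        d = diffs[metric].to_numpy()
        sd = d.std(ddof=1)
        shifts[metric] = float("inf") if sd == 0 else abs(float(d.mean())) / float(sd)
    return shifts, _shift_ratio(shifts)
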