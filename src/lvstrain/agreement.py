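"""Agreement statistics for multi-reader, multi-software metric tables.

Three layers mirror how contouring reproducibility studies are reported:

* group summaries — per (metric, software, repetition): mean, sample SD,
  SD as a percentage of the mean, and a t-based 95% CI over readers;
* paired comparisons — paired t-tests between repetitions of one
  package (repeatability) and between packages at a fixed repetition
  (reproducibility), with a Bonferroni-corrected significance threshold;
* Bland–Altman analysis of raw contour lengths — mean bias and 95%
  limits of agreement (bias ± 1.96 SD of the paired differences).

Sign conventions (fixed here because every downstream number inherits
them): intra-software differences are repetition 1 − repetition 2;
inter-software differences are first-listed software − second-listed;
``bland_altman(x, y)`` reports ``mean(y − x)`` so that "A vs B" with
``y`` = A's lengths gives a negative bias when A measures shorter
("bias towards A").

An automated package run once is handled by the duplication rule: its
single session is treated as both repetitions (assumed 100% repeatable)
and flagged as duplicated wherever it appears.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .metrics import METRIC_NAMES
from .phantom import Session

__all__ = [
    "SummaryRow",
    "PairedComparison",
    "BlandAltmanResult",
    "group_summary",
    "sd_percent_of_mean",
    "paired_comparison",
    "bonferroni_threshold",
    "format_threshold",
    "bland_altman",
    "duplicate_single_run",
    "build_tables",
]


@dataclass(frozen=True)
class SummaryRow:
    mean: float
    sd: float
    sd_pct: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class PairedComparison:
    """Paired difference of one metric between two matched groups.

    ``mean_difference`` is first group − second group and, by pairing,
    equals the difference of the group means exactly.  ``p`` is the
    two-sided paired t-test p-value; it is NaN (``degenerate=True``)
    when the differences have zero variance.
    """

    mean_of_attempts: float
    mean_difference: float
    sd_difference: float
    sd_pct: float
    p: float
    n: int
    degenerate: bool = False


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    points: pd.DataFrame
    n: int


def sd_percent_of_mean(mean: float, sd: float) -> float:
    """SD as a percentage of the absolute mean, ``100 * sd / |mean|``."""
    if mean == 0.0:
        return float("inf") if sd > 0 else 0.0
    return 100.0 * sd / abs(mean)


def group_summary(values: Sequence[float], confidence: float = 0.95) -> SummaryRow:
    """Mean, sample SD, SD%, and t-based CI of one group of readers."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DataError("a group summary needs at least 2 values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = stats.t.ppf(0.5 + confidence / 2.0, x.size - 1) * sd / np.sqrt(x.size)
    return SummaryRow(
        mean=mean,
        sd=sd,
        sd_pct=sd_percent_of_mean(mean, sd),
        ci_low=mean - half,
        ci_high=mean + half,
        n=int(x.size),
    )


def paired_comparison(a: Sequence[float], b: Sequence[float]) -> PairedComparison:
    """Two-sided paired t comparison of reader-matched value vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired groups must have the same length and reader order")
    if a.size < 2:
        raise DataError("a paired comparison needs at least 2 readers")
    d = a - b
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    attempts = float(((a + b) / 2.0).mean())
    if sd_d == 0.0:
        return PairedComparison(
            mean_of_attempts=attempts,
            mean_difference=mean_d,
            sd_difference=0.0,
            sd_pct=sd_percent_of_mean(attempts, 0.0),
            p=float("nan"),
            n=int(a.size),
            degenerate=True,
        )
    t = mean_d / (sd_d / np.sqrt(a.size))
    p = 2.0 * stats.t.sf(abs(t), a.size - 1)
    return PairedComparison(
        mean_of_attempts=attempts,
        mean_difference=mean_d,
        sd_difference=sd_d,
        sd_pct=sd_percent_of_mean(attempts, sd_d),
        p=float(p),
        n=int(a.size),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected per-test significance level, ``alpha / m``."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ConfigurationError("the comparison count m must be >= 1")
    return alpha / m


def format_threshold(threshold: float) -> float:
    """Reporting convention: the corrected level rounded to 3 decimals."""
    return round(threshold, 3)


def bland_altman(
    x: Sequence[float], y: Sequence[float], loa_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland–Altman agreement of paired measurements.

    Differences are ``y − x``; for a comparison labelled "A vs B" pass
    ``x`` = B's values and ``y`` = A's values so a negative bias reads
    "towards A".  Limits of agreement are ``bias ± loa_multiplier * SD``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("Bland-Altman inputs must be paired element-wise")
    if x.size < 2:
        raise DataError("Bland-Altman needs at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    spread = loa_multiplier * float(d.std(ddof=1))
    points = pd.DataFrame({"mean": (x + y) / 2.0, "difference": d})
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - spread,
        loa_high=bias + spread,
        points=points,
        n=int(x.size),
    )


def duplicate_single_run(session: Session) -> Tuple[Session, Session]:
    """Treat a single automated run as both test repetitions.

    Returns two sessions sharing the original's measurements, labelled
    repetition 1 and 2 and flagged ``duplicated`` so reports can surface
    the 100%-repeatability assumption.  Refuses sessions that already
    belong to a multi-repetition series.
    """
    if session.duplicated:
        raise DataError("session is already a duplicated repetition entry")
    if session.repetition != 1:
        raise DataError("only a single-repetition (repetition 1) session can be duplicated")
    out = []
    for rep in (1, 2):
        out.append(
            dataclasses.replace(
                session,
                session_id=f"{session.session_id}-t{rep}",
                repetition=rep,
                duplicated=True,
            )
        )
    return tuple(out)


# ---------------------------------------------------------------------------
# table assembly


def _comparison_to_row(metric: str, label: str, comp: PairedComparison, threshold: float):
    return {
        "metric": metric,
        "comparison": label,
        "mean_of_attempts": comp.mean_of_attempts,
        "mean_difference": comp.mean_difference,
        "sd_difference": comp.sd_difference,
        "sd_pct": comp.sd_pct,
        "p": comp.p,
        "n": comp.n,
        "significant": bool(comp.p <= threshold) if np.isfinite(comp.p) else False,
    }


def build_tables(
    metrics_table: pd.DataFrame,
    *,
    software_order: Optional[List[str]] = None,
    alpha: float = 0.05,
    bonferroni_m: Optional[int] = None,
    metric_names: Sequence[str] = METRIC_NAMES,
) -> Tuple[pd.DataFrame, pd.DataFrame, float]:
    """Summary and paired-comparison reports for a manual-session table.

    ``metrics_table`` must hold one row per (reader, software,
    repetition) with one column per metric.  Returns the summary table
    (one row per metric × software × repetition), the comparison table
    (per metric: repetition 1 vs 2 within each software, and software A
    vs B at each repetition) and the Bonferroni threshold used for the
    significance flags.  ``bonferroni_m`` defaults to the number of
    metrics.
    """
    required = {"reader", "software", "repetition", *metric_names}
    missing_cols = required - set(metrics_table.columns)
    if missing_cols:
        raise DataError(f"metrics table lacks columns {sorted(missing_cols)}")
    df = metrics_table.copy()
    if software_order is None:
        software_order = list(dict.fromkeys(df["software"]))
    if len(software_order) < 2:
        raise DataError("paired comparisons need at least 2 software groups")
    repetitions = sorted(df["repetition"].unique())
    if len(repetitions) < 2:
        raise DataError("paired comparisons need 2 repetitions per software")

    groups: Dict[Tuple[str, int], pd.DataFrame] = {}
    for software in software_order:
        for rep in repetitions:
            grp = df[(df["software"] == software) & (df["repetition"] == rep)]
            if grp.empty:
                raise DataError(f"missing group: software {software!r} repetition {rep}")
            groups[(software, rep)] = grp.sort_values("reader").set_index("reader")
    reader_sets = {key: tuple(grp.index) for key, grp in groups.items()}
    if len(set(reader_sets.values())) != 1:
        raise DataError(f"groups have mismatched reader sets: {reader_sets}")

    m = bonferroni_m if bonferroni_m is not None else len(metric_names)
    threshold = bonferroni_threshold(alpha, m)

    summary_rows = []
    for metric in metric_names:
        for (software, rep), grp in groups.items():
            s = group_summary(grp[metric].to_numpy())
            summary_rows.append(
                {
                    "metric": metric,
                    "software": software,
                    "repetition": rep,
                    "mean": s.mean,
                    "sd": s.sd,
                    "sd_pct": s.sd_pct,
                    "ci_low": s.ci_low,
                    "ci_high": s.ci_high,
                    "n": s.n,
                }
            )

    comp_rows = []
    rep1, rep2 = repetitions[0], repetitions[1]
    for metric in metric_names:
        for software in software_order:
            comp = paired_comparison(
                groups[(software, rep1)][metric].to_numpy(),
                groups[(software, rep2)][metric].to_numpy(),
            )
            comp_rows.append(
                _comparison_to_row(metric, f"{software}: T{rep1} vs T{rep2}", comp, threshold)
            )
        sw_a, sw_b = software_order[0], software_order[1]
        for rep in (rep1, rep2):
            comp = paired_comparison(
                groups[(sw_a, rep)][metric].to_numpy(),
                groups[(sw_b, rep)][metric].to_numpy(),
            )
            comp_rows.append(
                _comparison_to_row(metric, f"T{rep}: {sw_a} vs {sw_b}", comp, threshold)
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(comp_rows), threshold
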