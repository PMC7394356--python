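"""Time-course trend screen: per-protein linear regression of log2 fold
changes against treatment time.

For every protein observed at the baseline and at all treatment time points,
each biological replicate's NSAF at time t is divided by the same replicate's
baseline NSAF, giving log2 fold-change points (with 3 time points and 3
replicates, nine points per protein).  An ordinary least-squares line with a
free intercept is fitted through them; proteins whose slope differs from zero
at p < 0.05 are classified as having an increasing or decreasing expression
profile.  (The equivalent published criterion |log2 p| > 4.32 is the same
threshold: |log2 0.05| = 4.32.)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import NSAFMatrix, SpectralCountMatrix, ValidationError
from .quantify import QuantConfig, combine_technical_replicates, compute_nsaf, filter_min_average_count

logger = logging.getLogger(__name__)

TREND_INCREASING = "increasing"
TREND_DECREASING = "decreasing"
TREND_NONE = "none"

# residual sum of squares below this (relative to the response scale) is
# treated as an exact fit, with the degenerate p conventions below
_EXACT_FIT_RTOL = 1e-12


@dataclass(frozen=True)
class TrendConfig:
    """Settings for the trend screen.

    alpha
        Significance level for the slope test (default 0.05, applied
        strictly: p must be *below* alpha).
    baseline_condition
        Condition used as the fold-change denominator (time 0).
    timepoints
        Ordered (condition, time_h) pairs for the treatment time points;
        must not include the baseline.
    """

    baseline_condition: str
    timepoints: tuple[tuple[str, float], ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        conds = [c for c, _ in self.timepoints]
        if self.baseline_condition in conds:
            raise ValidationError("baseline condition must not be a timepoint")
        if len(set(conds)) != len(conds):
            raise ValidationError("duplicate timepoint condition")

    @classmethod
    def from_runs(cls, runs, alpha: float = 0.05) -> "TrendConfig":
        """Infer baseline (smallest time_h) and timepoints from descriptors."""
        times: dict[str, float] = {}
        for r in runs:
            if r.time_h is not None:
                times[r.condition] = r.time_h
        if len(times) < 3:
            raise ValidationError(
                "need a timed baseline and at least 2 timepoints to infer a design"
            )
        ordered = sorted(times.items(), key=lambda kv: kv[1])
        baseline = ordered[0][0]
        return cls(
            baseline_condition=baseline,
            timepoints=tuple((c, t) for c, t in ordered[1:]),
            alpha=alpha,
        )


@dataclass(frozen=True)
class TrendRecord:
    """Per-protein time-series result: OLS slope of log2 fold change per hour."""

    protein: str
    slope: float
    intercept: float
    p_value: float
    trend: str
    n_points: int
    degenerate: bool = False


@dataclass
class TrendResult:
    """Trend records plus the per-point table and stage counts."""

    records: list[TrendRecord]
    points: pd.DataFrame  # columns: protein, time_h, bio_rep, log2_fc
    stages: dict[str, int]

    def __iter__(self) -> Iterator[TrendRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def with_trend(self, trend: str) -> list[TrendRecord]:
        return [r for r in self.records if r.trend == trend]


def common_proteins(nsaf: NSAFMatrix, cfg: TrendConfig) -> set[str]:
    """Proteins detected (nonzero NSAF in >= 1 biological replicate) in the
    baseline and in every timepoint condition."""
    conditions = [cfg.baseline_condition] + [c for c, _ in cfg.timepoints]
    common: set[str] | None = None
    for cond in conditions:
        cols = nsaf.run_ids(cond)  # raises on missing condition
        present = set(nsaf.nsaf.index[(nsaf.nsaf[cols] > 0).any(axis=1)])
        common = present if common is None else common & present
    return common or set()


def _points_by_replicate(
    nsaf: NSAFMatrix, protein: str, cfg: TrendConfig
) -> list[tuple[int, float, float]]:
    """(bio_rep, time_h, log2_fc) points, replicate-paired to the baseline.

    A replicate whose baseline NSAF is zero contributes no points; a zero
    NSAF at a single timepoint drops only that point.  Drops are logged.
    """
    base_runs = {r.bio_rep: r.run_id for r in nsaf.runs_for(cfg.baseline_condition)}
    points: list[tuple[int, float, float]] = []
    for rep, base_id in sorted(base_runs.items()):
        base = float(nsaf.nsaf.at[protein, base_id])
        if base <= 0:
            logger.debug(
                "protein %s: baseline NSAF 0 in bio_rep %d; replicate dropped",
                protein,
                rep,
            )
            continue
        for cond, time_h in cfg.timepoints:
            run_ids = {r.bio_rep: r.run_id for r in nsaf.runs_for(cond)}
            if rep not in run_ids:
                continue
            value = float(nsaf.nsaf.at[protein, run_ids[rep]])
            if value <= 0:
                logger.debug(
                    "protein %s: zero NSAF at %s (bio_rep %d); point dropped",
                    protein,
                    cond,
                    rep,
                )
                continue
            points.append((rep, time_h, math.log2(value / base)))
    return points


def log2_fc_points(
    nsaf: NSAFMatrix, protein: str, cfg: TrendConfig
) -> list[tuple[float, float]]:
    """Per-replicate (time_h, log2 fold change vs baseline) points.

    With 3 timepoints and 3 biological replicates all nonzero, returns
    exactly nine points.  The baseline itself is not included as a point.
    """
    return [(t, y) for _, t, y in _points_by_replicate(nsaf, protein, cfg)]


def fit_trend(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Ordinary least squares with intercept; returns (slope, intercept, p).

    p is the two-sided t-test of slope != 0 on n-2 degrees of freedom.
    Exact fits have no residual variance: p = 0 for a nonzero slope and
    p = 1 for a flat exact fit, by convention.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValidationError("need at least 3 points to fit a trend")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValidationError("need at least 2 distinct time values")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    scale = max(float(y @ y), 1.0)
    if ss_res <= _EXACT_FIT_RTOL * scale:
        return slope, intercept, (1.0 if slope == 0 else 0.0)
    return slope, intercept, float(res.pvalue)


def classify_trend(slope: float, p: float, cfg: TrendConfig) -> str:
    """Significant positive slope -> increasing; negative -> decreasing.

    The comparison is strict (p must be below alpha), so p exactly equal to
    alpha is not significant.
    """
    if p < cfg.alpha:
        if slope > 0:
            return TREND_INCREASING
        if slope < 0:
            return TREND_DECREASING
    return TREND_NONE


def run_trend_screen(
    m: SpectralCountMatrix,
    tcfg: TrendConfig,
    qcfg: QuantConfig | None = None,
) -> TrendResult:
    """Run the full time-course screen.

    Pipeline: pool technical replicates -> average-count filter -> NSAF ->
    common-protein gate -> replicate-paired log2 fold-change points -> OLS ->
    classification.  Proteins with too few usable points (fewer than 3, or a
    single distinct time) are dropped with a logged reason.
    """
    qcfg = qcfg or QuantConfig()
    if len(tcfg.timepoints) < 2:
        raise ValidationError("trend screen needs at least 2 timepoints")
    conditions = [tcfg.baseline_condition] + [c for c, _ in tcfg.timepoints]
    sub = m.subset_conditions(conditions)
    mc = combine_technical_replicates(sub)
    if len(mc.runs_for(tcfg.baseline_condition)) < 2:
        raise ValidationError("trend screen needs at least 2 biological replicates")
    stages = {"loaded": mc.n_proteins}
    quant = filter_min_average_count(mc, qcfg)
    stages["after_min_avg_count"] = quant.n_proteins
    nsaf = compute_nsaf(quant)
    common = common_proteins(nsaf, tcfg)
    stages["common_across_timepoints"] = len(common)

    records: list[TrendRecord] = []
    point_rows: list[dict] = []
    dropped = 0
    for protein in quant.proteins:
        if protein not in common:
            continue
        pts = _points_by_replicate(nsaf, protein, tcfg)
        for rep, t, y in pts:
            point_rows.append(
                {"protein": protein, "time_h": t, "bio_rep": rep, "log2_fc": y}
            )
        xy = [(t, y) for _, t, y in pts]
        try:
            slope, intercept, p = fit_trend(xy)
        except ValidationError as exc:
            logger.info("protein %s dropped from trend fit: %s", protein, exc)
            dropped += 1
            continue
        records.append(
            TrendRecord(
                protein=protein,
                slope=slope,
                intercept=intercept,
                p_value=p,
                trend=classify_trend(slope, p, tcfg),
                n_points=len(xy),
                degenerate=(p in (0.0, 1.0) and len(xy) > 2),
            )
        )
    stages["fitted"] = len(records)
    stages["dropped_insufficient_points"] = dropped
    stages["increasing"] = sum(r.trend == TREND_INCREASING for r in records)
    stages["decreasing"] = sum(r.trend == TREND_DECREASING for r in records)
    points = pd.DataFrame(point_rows, columns=["protein", "time_h", "bio_rep", "log2_fc"])
    return TrendResult(records=records, points=points, stages=stages)
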