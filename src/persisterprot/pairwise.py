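"""Before/after differential-expression screen on NSAF values.

For each protein quantified in both conditions, a two-sample t-test compares
the per-biological-replicate NSAF values; Benjamini–Hochberg correction
controls the false-discovery rate (default 10%), and only proteins whose
group-mean fold change exceeds +/-1.5-fold are called differentially
expressed.  Proteins absent from every baseline replicate but observed after
treatment with a total spectral count above a threshold (default > 5) are
reported separately as *newly detected* — presumed upregulated, with no
p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import SpectralCountMatrix, ValidationError
from .quantify import (
    QuantConfig,
    combine_technical_replicates,
    compute_nsaf,
    presence_by_bio_rep,
)

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NOT_SIGNIFICANT = "not_significant"
STATUS_NEWLY_DETECTED = "newly_detected"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class PairwiseConfig:
    """Settings for the pairwise screen.

    fdr_alpha
        Benjamini–Hochberg FDR level (default 0.10).
    fc_threshold
        Fold-change gate; calls require fold change >= fc_threshold or
        <= 1/fc_threshold (default 1.5).
    newly_detected_min_psm
        Newly-detected proteins must have a total combined spectral count in
        the test condition strictly greater than this (default 5).
    test_variant
        ``"welch"`` (unequal variances, Satterthwaite df) or ``"pooled"``.
    """

    fdr_alpha: float = 0.10
    fc_threshold: float = 1.5
    newly_detected_min_psm: int = 5
    test_variant: str = "welch"

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha < 1):
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValidationError("fc_threshold must be > 1")
        if self.newly_detected_min_psm < 0:
            raise ValidationError("newly_detected_min_psm must be >= 0")
        if self.test_variant not in {"welch", "pooled"}:
            raise ValidationError("test_variant must be 'welch' or 'pooled'")


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-protein pairwise result (test condition B relative to reference A)."""

    protein: str
    mean_nsaf_A: float
    mean_nsaf_B: float
    fold_change: float
    log2_fc: float
    p_value: float
    q_value: float
    status: str
    degenerate: bool = False


def two_sample_t(
    valuesA: Sequence[float], valuesB: Sequence[float], variant: str = "welch"
) -> tuple[float, float]:
    """Two-sided two-sample t-test; returns (t, p).

    ``variant="welch"`` uses unequal variances with Satterthwaite degrees of
    freedom; ``"pooled"`` is the classic equal-variance Student test.
    Degenerate inputs follow fixed conventions: both groups constant and
    equal -> (0, 1); both constant and unequal -> (+/-inf, 0).
    """
    a = np.asarray(valuesA, dtype=float)
    b = np.asarray(valuesB, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if variant not in {"welch", "pooled"}:
        raise ValidationError("variant must be 'welch' or 'pooled'")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, b.mean() - a.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(
    p_values: Sequence[float], alpha: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns ``(q_values, reject)`` in the input order.  q_i is the smallest
    FDR level at which hypothesis i would be rejected
    (min over ranks >= rank(i) of m * p / rank, capped at 1); the reject set
    is the largest k with p_(k) <= k * alpha / m and all smaller ranks.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def fold_change(nsafA: Sequence[float], nsafB: Sequence[float]) -> float:
    """Ratio of group-mean NSAFs, test (B) over reference (A)."""
    mean_a = float(np.mean(nsafA))
    mean_b = float(np.mean(nsafB))
    if mean_a <= 0:
        raise ValidationError(
            "fold change undefined for zero reference mean; route to the "
            "newly-detected rule or exclude"
        )
    return mean_b / mean_a


def detect_newly_present(
    m: SpectralCountMatrix,
    condA: str,
    condB: str,
    cfg: PairwiseConfig | None = None,
) -> set[str]:
    """Proteins absent from every biological replicate of ``condA`` whose
    total combined spectral count in ``condB`` strictly exceeds the
    newly-detected threshold."""
    cfg = cfg or PairwiseConfig()
    mc = combine_technical_replicates(m)
    zero_in_a = mc.counts[mc.run_ids(condA)].sum(axis=1) == 0
    total_b = mc.counts[mc.run_ids(condB)].sum(axis=1)
    mask = zero_in_a & (total_b > cfg.newly_detected_min_psm)
    return set(mc.counts.index[mask])


def classify_differential(
    record: DifferentialRecord, cfg: PairwiseConfig | None = None
) -> str:
    """Apply the significance + fold-change gate to a tested record.

    up: BH-significant and fold change >= threshold; down: BH-significant
    and fold change <= 1/threshold; otherwise not significant (the paper-
    style 1.44-fold case stays uncalled even at small q).
    """
    cfg = cfg or PairwiseConfig()
    if not (record.q_value <= cfg.fdr_alpha):
        return STATUS_NOT_SIGNIFICANT
    if record.fold_change >= cfg.fc_threshold:
        return STATUS_UP
    if record.fold_change <= 1.0 / cfg.fc_threshold:
        return STATUS_DOWN
    return STATUS_NOT_SIGNIFICANT


@dataclass
class PairwiseResult:
    """Records plus stage-by-stage protein counts for the run manifest."""

    records: list[DifferentialRecord]
    stages: dict[str, int]

    def __iter__(self) -> Iterator[DifferentialRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def with_status(self, status: str) -> list[DifferentialRecord]:
        return [r for r in self.records if r.status == status]


def _vector_ttest(
    a: np.ndarray, b: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t-tests with the same degenerate conventions as
    :func:`two_sample_t`."""
    with warnings.catch_warnings():
        # near-constant rows trip scipy's precision warning; those rows are
        # overwritten with the explicit degenerate conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    both_const = (va == 0) & (vb == 0)
    if both_const.any():
        equal = both_const & (a.mean(axis=1) == b.mean(axis=1))
        unequal = both_const & ~equal
        t[equal], p[equal] = 0.0, 1.0
        t[unequal] = np.copysign(np.inf, (b.mean(axis=1) - a.mean(axis=1))[unequal])
        p[unequal] = 0.0
    return t, p


def run_pairwise_screen(
    m: SpectralCountMatrix,
    condA: str,
    condB: str,
    qcfg: QuantConfig | None = None,
    pcfg: PairwiseConfig | None = None,
) -> PairwiseResult:
    """Run the full pairwise screen of condition B against reference A.

    Pipeline: pool technical replicates -> newly-detected rule -> average-
    count and presence filters -> NSAF -> per-protein t-test -> BH across
    tested proteins -> fold-change gate.  Every input protein appears in
    exactly one of {tested, newly_detected, excluded}.
    """
    qcfg = qcfg or QuantConfig()
    pcfg = pcfg or PairwiseConfig()
    sub = m.subset_conditions([condA, condB])
    mc = combine_technical_replicates(sub)
    for cond in (condA, condB):
        if len(mc.runs_for(cond)) < 2:
            raise ValidationError(
                f"condition {cond!r} has fewer than 2 usable biological replicates"
            )
    stages = {"loaded": mc.n_proteins}

    newly = detect_newly_present(mc, condA, condB, pcfg)

    means = mc.counts.mean(axis=1)
    pass_avg = means >= qcfg.min_avg_count
    stages["after_min_avg_count"] = int(pass_avg.sum())
    pres_a = presence_by_bio_rep(mc, condA)
    pres_b = presence_by_bio_rep(mc, condB)
    pass_presence = (pres_a >= qcfg.min_bio_reps_present) & (
        pres_b >= qcfg.min_bio_reps_present
    )
    tested_mask = pass_avg & pass_presence & ~mc.counts.index.isin(sorted(newly))
    tested = list(mc.counts.index[tested_mask])
    stages["tested"] = len(tested)
    stages["newly_detected"] = len(newly)
    stages["excluded"] = mc.n_proteins - len(tested) - len(newly)

    records: list[DifferentialRecord] = []
    nan = float("nan")
    if tested:
        quant = mc.subset_proteins(mc.counts.index[pass_avg])
        nsaf = compute_nsaf(quant)
        cols_a = nsaf.run_ids(condA)
        cols_b = nsaf.run_ids(condB)
        a = nsaf.nsaf.loc[tested, cols_a].to_numpy(dtype=float)
        b = nsaf.nsaf.loc[tested, cols_b].to_numpy(dtype=float)
        _, p = _vector_ttest(a, b, pcfg.test_variant)
        q, _ = benjamini_hochberg(p, pcfg.fdr_alpha)
        mean_a = a.mean(axis=1)
        mean_b = b.mean(axis=1)
        fc = mean_b / mean_a
        degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
        for i, protein in enumerate(tested):
            rec = DifferentialRecord(
                protein=protein,
                mean_nsaf_A=float(mean_a[i]),
                mean_nsaf_B=float(mean_b[i]),
                fold_change=float(fc[i]),
                log2_fc=float(np.log2(fc[i])) if fc[i] > 0 else -math.inf,
                p_value=float(p[i]),
                q_value=float(q[i]),
                status=STATUS_NOT_SIGNIFICANT,
                degenerate=bool(degenerate[i]),
            )
            records.append(replace(rec, status=classify_differential(rec, pcfg)))

    for protein in sorted(newly):
        records.append(
            DifferentialRecord(
                protein=protein,
                mean_nsaf_A=0.0,
                mean_nsaf_B=nan,
                fold_change=nan,
                log2_fc=nan,
                p_value=nan,
                q_value=nan,
                status=STATUS_NEWLY_DETECTED,
            )
        )
    tested_set = set(tested)
    excluded_ids = [
        pid for pid in mc.counts.index if pid not in tested_set and pid not in newly
    ]
    for protein in excluded_ids:
        records.append(
            DifferentialRecord(
                protein=protein,
                mean_nsaf_A=nan,
                mean_nsaf_B=nan,
                fold_change=nan,
                log2_fc=nan,
                p_value=nan,
                q_value=nan,
                status=STATUS_EXCLUDED,
            )
        )
    stages["up"] = sum(r.status == STATUS_UP for r in records)
    stages["down"] = sum(r.status == STATUS_DOWN for r in records)
    return PairwiseResult(records=records, stages=stages)
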