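"""Quantification: technical-replicate pooling, count filters, and NSAF.

The quantification gates mirror standard spectral-counting practice: the two
technical replicates of each biological replicate are pooled by summing PSM
counts, only proteins with an average spectral count of at least 3 across all
runs are quantified, and (for the pairwise screen) a protein must be
identified in at least two of the three biological replicates of a condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    NSAFMatrix,
    RunDescriptor,
    SpectralCountMatrix,
    ValidationError,
)


@dataclass(frozen=True)
class QuantConfig:
    """Quantification-filter settings.

    min_avg_count
        Minimum mean combined spectral count across all runs for a protein to
        be quantified (default 3).
    min_bio_reps_present
        Minimum number of biological replicates of a condition in which a
        protein must be detected (default 2).
    bio_reps_total
        Number of biological replicates per condition in the design
        (default 3).
    """

    min_avg_count: float = 3.0
    min_bio_reps_present: int = 2
    bio_reps_total: int = 3

    def __post_init__(self) -> None:
        if self.min_avg_count < 0:
            raise ValidationError("min_avg_count must be >= 0")
        if not (1 <= self.min_bio_reps_present <= self.bio_reps_total):
            raise ValidationError(
                "min_bio_reps_present must lie in [1, bio_reps_total]"
            )


def combine_technical_replicates(m: SpectralCountMatrix) -> SpectralCountMatrix:
    """Pool technical replicates by summing PSM counts per protein.

    Returns one run per (condition, bio_rep); a biological replicate with a
    single technical run passes through unchanged.  Combined runs are given
    the run id ``"<condition>:b<bio_rep>"`` and tech_rep 1.
    """
    groups: dict[tuple[str, int], list[RunDescriptor]] = {}
    for r in m.runs:
        groups.setdefault((r.condition, r.bio_rep), []).append(r)
    if all(len(g) == 1 for g in groups.values()):
        return m
    new_runs: list[RunDescriptor] = []
    columns: dict[str, pd.Series] = {}
    for (condition, bio_rep), members in groups.items():
        run_id = f"{condition}:b{bio_rep}"
        new_runs.append(
            RunDescriptor(
                run_id=run_id,
                condition=condition,
                bio_rep=bio_rep,
                tech_rep=1,
                time_h=members[0].time_h,
            )
        )
        columns[run_id] = m.counts[[r.run_id for r in members]].sum(axis=1)
    counts = pd.DataFrame(columns, index=m.counts.index)
    return SpectralCountMatrix(counts, new_runs, m.lengths)


def filter_min_average_count(
    m: SpectralCountMatrix, cfg: QuantConfig | None = None
) -> SpectralCountMatrix:
    """Retain proteins whose mean count across all runs is >= the threshold.

    The boundary is inclusive: a protein averaging exactly ``min_avg_count``
    is retained.
    """
    cfg = cfg or QuantConfig()
    if len(m.runs) == 0:
        raise ValidationError("cannot average counts over zero runs")
    means = m.counts.mean(axis=1)
    keep = means[means >= cfg.min_avg_count].index
    return m.subset_proteins(keep)


def presence_by_bio_rep(m: SpectralCountMatrix, condition: str) -> pd.Series:
    """Number of biological replicates of ``condition`` in which each protein
    is detected (any technical replicate with count > 0)."""
    runs = m.runs_for(condition)
    by_rep: dict[int, list[str]] = {}
    for r in runs:
        by_rep.setdefault(r.bio_rep, []).append(r.run_id)
    present = pd.Series(0, index=m.counts.index, dtype=np.int64)
    for run_ids in by_rep.values():
        present += (m.counts[run_ids].sum(axis=1) > 0).astype(np.int64)
    return present


def compute_nsaf(m: SpectralCountMatrix) -> NSAFMatrix:
    """Compute per-run normalized spectral abundance factors.

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j), per run, over the proteins
    present in the matrix.  Zero counts stay exactly zero and every run
    column sums to 1.  A run with no detected protein has no defined
    normalization and raises.
    """
    if m.lengths is None:
        raise ValidationError("protein lengths are required to compute NSAF")
    sa = m.counts.div(m.lengths, axis=0)
    denom = sa.sum(axis=0)
    dead = denom[denom == 0].index.tolist()
    if dead:
        raise ValidationError(f"run(s) with all-zero counts: {dead}")
    nsaf = sa.div(denom, axis=1)
    return NSAFMatrix(nsaf, list(m.runs))
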