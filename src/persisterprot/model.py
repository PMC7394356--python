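"""Shared data model for spectral-counting experiments.

The pipeline's raw input is a protein-by-run matrix of peptide-spectrum-match
(PSM) counts plus per-run metadata (condition, biological/technical replicate,
treatment time) and per-protein lengths in amino acids.  Abundances are
expressed as the normalized spectral abundance factor (NSAF): per run,
``(SpC_i / L_i) / sum_j (SpC_j / L_j)`` over all identified proteins, so each
run's NSAF column sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class PipelineError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(PipelineError):
    """Input violates a documented invariant."""


class ParseError(PipelineError):
    """A file could not be parsed; the message names the offending cell."""


@dataclass(frozen=True)
class RunDescriptor:
    """Metadata for one mass-spectrometry run.

    Parameters
    ----------
    run_id : str
        Opaque unique identifier, typically the raw-file stem.
    condition : str
        Experimental condition label (e.g. ``"pre"``, ``"amp_5h"``).
    bio_rep : int
        Biological replicate index, 1-based.
    tech_rep : int
        Technical replicate index, 1-based.  Technical replicates of the
        same biological replicate are pooled before quantification.
    time_h : float or None
        Treatment time in hours for time-course designs; must be identical
        for all runs sharing a condition.
    """

    run_id: str
    condition: str
    bio_rep: int
    tech_rep: int = 1
    time_h: float | None = None

    def __post_init__(self) -> None:
        if self.bio_rep < 1:
            raise ValidationError(f"run {self.run_id!r}: bio_rep must be >= 1")
        if self.tech_rep < 1:
            raise ValidationError(f"run {self.run_id!r}: tech_rep must be >= 1")
        if self.time_h is not None and self.time_h < 0:
            raise ValidationError(f"run {self.run_id!r}: time_h must be >= 0")

    @property
    def replicate_key(self) -> tuple[str, int, int]:
        return (self.condition, self.bio_rep, self.tech_rep)


def validate_runs(runs: Sequence[RunDescriptor]) -> None:
    """Check run-level invariants: unique ids, unique (condition, bio_rep,
    tech_rep) triples, and a single time_h per condition."""
    ids = [r.run_id for r in runs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate run_id(s): {dupes}")
    keys = [r.replicate_key for r in runs]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(
            f"duplicate (condition, bio_rep, tech_rep) triple(s): {dupes}"
        )
    times: dict[str, float | None] = {}
    for r in runs:
        if r.condition in times:
            if times[r.condition] != r.time_h:
                raise ValidationError(
                    f"condition {r.condition!r} has inconsistent time_h: "
                    f"{times[r.condition]} vs {r.time_h}"
                )
        else:
            times[r.condition] = r.time_h


@dataclass
class SpectralCountMatrix:
    """Protein-by-run PSM counts with run metadata and protein lengths.

    ``counts`` is a pandas DataFrame indexed by protein id with one column
    per run (column order matches ``runs``).  ``lengths`` maps protein id to
    length in amino acids and may be None until attached.
    """

    counts: pd.DataFrame
    runs: list[RunDescriptor]
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        validate_runs(self.runs)
        run_ids = [r.run_id for r in self.runs]
        if list(self.counts.columns) != run_ids:
            raise ValidationError(
                "count-matrix columns do not match run descriptors: "
                f"{list(self.counts.columns)} vs {run_ids}"
            )
        if self.counts.index.has_duplicates:
            dupes = sorted(self.counts.index[self.counts.index.duplicated()])
            raise ValidationError(f"duplicate protein id(s): {dupes}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(np.mod(values, 1) == 0):
                    raise ValidationError("spectral counts must be integers")
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if (values < 0).any():
                raise ValidationError("spectral counts must be >= 0")
        if self.lengths is not None:
            self.lengths = self.lengths.astype(np.int64)
            missing = self.counts.index.difference(self.lengths.index)
            if len(missing):
                raise ValidationError(
                    f"proteins without a length entry: {sorted(missing)}"
                )
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths < 1).any():
                bad = sorted(self.lengths.index[self.lengths < 1])
                raise ValidationError(f"non-positive protein length(s): {bad}")

    # -- convenience accessors -------------------------------------------------

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_proteins(self) -> int:
        return self.counts.shape[0]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for r in self.runs:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    def runs_for(self, condition: str) -> list[RunDescriptor]:
        out = [r for r in self.runs if r.condition == condition]
        if not out:
            raise ValidationError(f"unknown condition: {condition!r}")
        return out

    def run_ids(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return [r.run_id for r in self.runs]
        return [r.run_id for r in self.runs_for(condition)]

    def subset_proteins(self, proteins: Iterable[str]) -> "SpectralCountMatrix":
        keep = [p for p in self.proteins if p in set(proteins)]
        lengths = self.lengths.loc[keep] if self.lengths is not None else None
        return SpectralCountMatrix(self.counts.loc[keep], list(self.runs), lengths)

    def subset_conditions(self, conditions: Sequence[str]) -> "SpectralCountMatrix":
        wanted = set(conditions)
        unknown = wanted - set(self.conditions)
        if unknown:
            raise ValidationError(f"unknown condition(s): {sorted(unknown)}")
        runs = [r for r in self.runs if r.condition in wanted]
        ids = [r.run_id for r in runs]
        return SpectralCountMatrix(self.counts[ids], runs, self.lengths)

    def with_lengths(self, lengths: Mapping[str, int] | pd.Series) -> "SpectralCountMatrix":
        series = pd.Series(dict(lengths)) if not isinstance(lengths, pd.Series) else lengths
        missing = self.counts.index.difference(series.index)
        if len(missing):
            raise ValidationError(
                f"length source is missing protein(s): {sorted(missing)}"
            )
        return replace(self, lengths=series.reindex(self.counts.index))

    def with_runs(self, runs: Sequence[RunDescriptor]) -> "SpectralCountMatrix":
        """Attach run metadata (e.g. from a design table) by run_id."""
        by_id = {r.run_id: r for r in runs}
        missing = [c for c in self.counts.columns if c not in by_id]
        if missing:
            raise ValidationError(
                f"design table is missing run(s) present in the count table: {missing}"
            )
        ordered = [by_id[c] for c in self.counts.columns]
        return SpectralCountMatrix(self.counts, ordered, self.lengths)


@dataclass
class NSAFMatrix:
    """Per-run normalized spectral abundance factors.

    Each run column sums to 1 over the proteins detected in that run; NSAF is
    exactly 0 where the source count is 0.
    """

    nsaf: pd.DataFrame
    runs: list[RunDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_runs(self.runs)
        run_ids = [r.run_id for r in self.runs]
        if list(self.nsaf.columns) != run_ids:
            raise ValidationError("NSAF columns do not match run descriptors")
        values = self.nsaf.to_numpy()
        if values.size:
            if (values < 0).any() or (values > 1).any():
                raise ValidationError("NSAF values must lie in [0, 1]")
            sums = values.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = [run_ids[i] for i in np.nonzero(np.abs(sums - 1.0) > 1e-9)[0]]
                raise ValidationError(f"NSAF columns do not sum to 1: {bad}")

    @property
    def proteins(self) -> list[str]:
        return list(self.nsaf.index)

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for r in self.runs:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    def runs_for(self, condition: str) -> list[RunDescriptor]:
        out = [r for r in self.runs if r.condition == condition]
        if not out:
            raise ValidationError(f"unknown condition: {condition!r}")
        return out

    def run_ids(self, condition: str | None = None) -> list[str]:
        if condition is None:
            return [r.run_id for r in self.runs]
        return [r.run_id for r in self.runs_for(condition)]
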