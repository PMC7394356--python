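"""Synthetic spectral-count experiments with known ground truth.

The generator emulates a shotgun-proteomics spectral-counting study of the
kind the pipeline targets: 3 biological x 2 technical replicates per
condition, run-level depth variation, protein lengths drawn log-normally,
overdispersed (negative-binomial) PSM counts, detection dropout, injected
condition fold changes, injected log-linear temporal trends, and proteins
structurally absent before treatment but present after (to exercise the
newly-detected rule).

Sampling model
--------------
Each protein gets a relative abundance ``a_i`` (log-normal) and a length
``L_i``; its sampling weight is ``a_i * L_i`` because longer proteins yield
proportionally more spectra — NSAF divides the count by length precisely to
undo this, so the generator makes that purpose testable.  For run r in
condition c the expected count is

    mu_ir = depth_r * (a_i * L_i * e_ic) / sum_j (a_j * L_j * e_jc)

where ``e_ic`` is the protein's class effect (condition fold change,
``2^(slope * time_h)`` for trends, 0 in the baseline for newly-detected
proteins) and ``depth_r`` is the run's realized total depth.  Counts are
negative-binomial with variance ``mu + dispersion * mu^2`` (Poisson when
dispersion is 0); dropout then forces a fraction of cells to zero.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import write_count_table, write_design_table, write_lengths_table
from .model import RunDescriptor, SpectralCountMatrix, ValidationError

CLASS_NULL = "null"
CLASS_DE_UP = "de_up"
CLASS_DE_DOWN = "de_down"
CLASS_TREND_UP = "trend_up"
CLASS_TREND_DOWN = "trend_down"
CLASS_NEWLY_DETECTED = "newly_detected"

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class SimParams:
    """Generator settings.  Defaults describe the study design the pipeline
    targets: a two-condition (before / 5 h ampicillin) comparison with three
    biological and two technical replicates, ~20k PSMs per run, and 10% of
    proteins carrying a 4-fold condition effect (split evenly up/down).

    conditions
        Ordered (label, time_h) pairs; the first is the baseline/reference.
    depth_mean
        Expected total PSMs per run; depth_cv is the run-to-run log-normal
        coefficient of variation.
    dispersion
        Negative-binomial overdispersion (variance = mu + dispersion*mu^2);
        0 gives Poisson counts.
    frac_de / de_fold
        Fraction of proteins with a condition effect and its fold change
        (applied up for half of them, down for the other half) in every
        non-baseline condition.
    frac_trend_up / frac_trend_down / trend_slope
        Fractions with temporal log-linear trends of +/- trend_slope
        log2-units per hour (requires timed conditions).
    frac_newly_detected
        Fraction structurally absent (weight 0) in the baseline condition.
    dropout_rate
        Per-(protein, run) probability of forcing an observed zero.
    """

    n_proteins: int = 1000
    n_bio_reps: int = 3
    n_tech_reps: int = 2
    conditions: tuple[tuple[str, float | None], ...] = (("pre", 0.0), ("amp_5h", 5.0))
    depth_mean: float = 20000.0
    depth_cv: float = 0.1
    dispersion: float = 0.2
    length_log_mean: float = 5.6
    length_log_sd: float = 0.45
    abundance_log_sd: float = 1.2
    frac_de: float = 0.10
    de_fold: float = 4.0
    frac_trend_up: float = 0.0
    frac_trend_down: float = 0.0
    trend_slope: float = 0.4
    frac_newly_detected: float = 0.0
    dropout_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if self.depth_mean <= 0:
            raise ValidationError("depth_mean must be > 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        fracs = (
            self.frac_de,
            self.frac_trend_up,
            self.frac_trend_down,
            self.frac_newly_detected,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValidationError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValidationError("class fractions must jointly be <= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if len(self.conditions) < 2:
            raise ValidationError("need at least 2 conditions")
        labels = [c for c, _ in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValidationError("condition labels must be unique")
        timed = [t for _, t in self.conditions[1:] if t is not None]
        if (self.frac_trend_up > 0 or self.frac_trend_down > 0) and not timed:
            raise ValidationError(
                "temporal trends require timed non-baseline conditions"
            )

    @property
    def baseline(self) -> str:
        return self.conditions[0][0]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth labels emitted with each synthetic experiment.

    ``table`` has one row per protein: protein, label, true_fold_change
    (for de classes), true_slope (log2/h, for trend classes).
    """

    table: pd.DataFrame

    def proteins_of(self, label: str) -> set[str]:
        return set(self.table.protein[self.table.label == label])

    def label_of(self) -> pd.Series:
        return self.table.set_index("protein")["label"]


def _run_descriptors(params: SimParams) -> list[RunDescriptor]:
    runs = []
    for cond, time_h in params.conditions:
        for b in range(1, params.n_bio_reps + 1):
            for t in range(1, params.n_tech_reps + 1):
                runs.append(
                    RunDescriptor(
                        run_id=f"{cond}_b{b}_t{t}",
                        condition=cond,
                        bio_rep=b,
                        tech_rep=t,
                        time_h=time_h,
                    )
                )
    return runs


@lru_cache(maxsize=8)
def _model(params: SimParams):
    """Deterministic experiment structure: lengths, abundances, class labels,
    per-condition effect multipliers, per-run depths."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(params.seed)))
    n = params.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    lengths = np.maximum(
        30, np.round(rng.lognormal(params.length_log_mean, params.length_log_sd, n))
    ).astype(np.int64)
    abundance = rng.lognormal(0.0, params.abundance_log_sd, n)

    labels = np.array([CLASS_NULL] * n, dtype=object)
    perm = rng.permutation(n)
    n_de = int(math.floor(params.frac_de * n))
    n_tu = int(math.floor(params.frac_trend_up * n))
    n_td = int(math.floor(params.frac_trend_down * n))
    n_nd = int(math.floor(params.frac_newly_detected * n))
    cursor = 0
    de_idx = perm[cursor : cursor + n_de]
    cursor += n_de
    labels[de_idx[: n_de // 2 + n_de % 2]] = CLASS_DE_UP
    labels[de_idx[n_de // 2 + n_de % 2 :]] = CLASS_DE_DOWN
    labels[perm[cursor : cursor + n_tu]] = CLASS_TREND_UP
    cursor += n_tu
    labels[perm[cursor : cursor + n_td]] = CLASS_TREND_DOWN
    cursor += n_td
    labels[perm[cursor : cursor + n_nd]] = CLASS_NEWLY_DETECTED
    cursor += n_nd

    # per-condition effect multiplier for every protein
    effects = {}
    for ci, (cond, time_h) in enumerate(params.conditions):
        e = np.ones(n)
        is_baseline = ci == 0
        if not is_baseline:
            e[labels == CLASS_DE_UP] = params.de_fold
            e[labels == CLASS_DE_DOWN] = 1.0 / params.de_fold
        if time_h is not None:
            e[labels == CLASS_TREND_UP] = 2.0 ** (params.trend_slope * time_h)
            e[labels == CLASS_TREND_DOWN] = 2.0 ** (-params.trend_slope * time_h)
        if is_baseline:
            e[labels == CLASS_NEWLY_DETECTED] = 0.0
        effects[cond] = e

    runs = _run_descriptors(params)
    if params.depth_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.depth_cv**2))
        factors = rng.lognormal(-0.5 * sigma**2, sigma, len(runs))
    else:
        factors = np.ones(len(runs))
    depths = {r.run_id: params.depth_mean * factors[i] for i, r in enumerate(runs)}

    weights = abundance * lengths
    mu = {}
    for r in runs:
        w = weights * effects[r.condition]
        mu[r.run_id] = depths[r.run_id] * w / w.sum()
    return proteins, lengths, abundance, labels, runs, mu


def expected_counts(params: SimParams, protein: str, run_id: str) -> float:
    """Mean of the sampling distribution for one (protein, run) cell,
    including the dropout thinning factor.  The Monte-Carlo mean of
    :func:`generate_experiment` counts over many noise seeds converges to
    this value."""
    proteins, _, _, _, runs, mu = _model(params)
    if protein not in proteins:
        raise ValidationError(f"unknown protein {protein!r}")
    run_ids = [r.run_id for r in runs]
    if run_id not in run_ids:
        raise ValidationError(f"unknown run {run_id!r}")
    i = proteins.index(protein)
    return float(mu[run_id][i] * (1.0 - params.dropout_rate))


def relative_abundances(params: SimParams) -> pd.Series:
    """True per-protein relative molar abundances (baseline condition),
    normalized to sum to 1.  NSAF estimates exactly this quantity, so the
    two should rank-correlate increasingly well as run depth grows."""
    proteins, _, abundance, _, _, _ = _model(params)
    series = pd.Series(abundance, index=proteins, name="abundance")
    return series / series.sum()


def generate_experiment(
    params: SimParams, noise_seed: int | None = None
) -> tuple[SpectralCountMatrix, SyntheticTruth]:
    """Draw a synthetic experiment; fully reproducible from ``params.seed``.

    ``noise_seed`` optionally re-draws only the count noise (and dropout)
    while keeping the experiment structure — lengths, abundances, class
    assignment, run depths — fixed; by default it derives from
    ``params.seed`` so identical params give identical matrices.
    """
    proteins, lengths, _, labels, runs, mu = _model(params)
    if noise_seed is None:
        noise_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([params.seed, 1]))
        )
    else:
        noise_rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence([noise_seed, 1]))
        )
    columns = {}
    for r in runs:
        m = mu[r.run_id]
        if params.dispersion == 0:
            counts = noise_rng.poisson(m)
        else:
            size = 1.0 / params.dispersion
            p = size / (size + m)
            counts = noise_rng.negative_binomial(size, p)
        if params.dropout_rate > 0:
            counts = np.where(
                noise_rng.random(len(m)) < params.dropout_rate, 0, counts
            )
        columns[r.run_id] = counts.astype(np.int64)
    counts_df = pd.DataFrame(columns, index=pd.Index(proteins, name="protein"))
    matrix = SpectralCountMatrix(
        counts_df, runs, pd.Series(lengths, index=proteins, name="length")
    )
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "protein": proteins,
                "label": labels,
                "true_fold_change": [
                    params.de_fold
                    if l == CLASS_DE_UP
                    else (1.0 / params.de_fold if l == CLASS_DE_DOWN else np.nan)
                    for l in labels
                ],
                "true_slope": [
                    params.trend_slope
                    if l == CLASS_TREND_UP
                    else (-params.trend_slope if l == CLASS_TREND_DOWN else np.nan)
                    for l in labels
                ],
            }
        )
    )
    return matrix, truth


def write_fixture(
    matrix: SpectralCountMatrix,
    truth: SyntheticTruth,
    directory: str | os.PathLike,
    params: SimParams | None = None,
) -> dict[str, str]:
    """Write counts.tsv, lengths.tsv, design.tsv, truth.tsv (and params.json
    when params are given) into ``directory``; the files are directly
    consumable by :func:`persisterprot.io.load_experiment`."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": os.path.join(directory, "counts.tsv"),
        "lengths": os.path.join(directory, "lengths.tsv"),
        "design": os.path.join(directory, "design.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    write_count_table(matrix, paths["counts"])
    write_lengths_table(matrix.lengths, paths["lengths"])
    write_design_table(matrix.runs, paths["design"])
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    if params is not None:
        paths["params"] = os.path.join(directory, "params.json")
        payload = dataclasses.asdict(params)
        payload["conditions"] = [list(c) for c in params.conditions]
        payload["rng_algorithm"] = RNG_ALGORITHM
        with open(paths["params"], "w") as fh:
            json.dump(payload, fh, indent=2)
    return paths
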