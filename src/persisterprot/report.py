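"""Reporting utilities and reproducible end-to-end runs.

Provides the per-condition identification ("Venn") counts, volcano-style
tables for plotting, a run manifest recording input digests, configuration
and stage-by-stage protein counts, and a config-file driver that produces
byte-identical outputs to the equivalent flag invocation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .model import SpectralCountMatrix, ValidationError
from .pairwise import PairwiseConfig, run_pairwise_screen
from .quantify import QuantConfig, combine_technical_replicates
from .simulate import SimParams, generate_experiment, write_fixture
from .trend import TrendConfig, run_trend_screen

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class VennCounts:
    """Identified-protein sets per condition and exact region counts.

    A protein counts as identified in a condition when it has a nonzero
    count in at least one biological replicate.  ``exclusive_regions`` maps
    each condition subset to the number of proteins identified in exactly
    those conditions (the numbers printed inside a Venn diagram);
    ``intersections`` maps each subset to the plain intersection size.
    """

    sets: dict[str, frozenset[str]]
    per_condition: dict[str, int] = field(init=False)
    exclusive_regions: dict[frozenset[str], int] = field(init=False)
    intersections: dict[frozenset[str], int] = field(init=False)

    def __post_init__(self) -> None:
        conds = list(self.sets)
        self.per_condition = {c: len(s) for c, s in self.sets.items()}
        self.exclusive_regions = {}
        self.intersections = {}
        universe = set().union(*self.sets.values()) if self.sets else set()
        for k in range(1, len(conds) + 1):
            for subset in combinations(conds, k):
                inside = set(universe)
                for c in subset:
                    inside &= self.sets[c]
                self.intersections[frozenset(subset)] = len(inside)
                exclusive = set(inside)
                for c in conds:
                    if c not in subset:
                        exclusive -= self.sets[c]
                self.exclusive_regions[frozenset(subset)] = len(exclusive)

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "conditions": "&".join(sorted(sub)),
                "intersection": self.intersections[sub],
                "exclusive": self.exclusive_regions[sub],
            }
            for sub in sorted(self.exclusive_regions, key=lambda s: (len(s), sorted(s)))
        ]
        return pd.DataFrame(rows, columns=["conditions", "intersection", "exclusive"])


def venn_counts(
    m: SpectralCountMatrix, conditions: Sequence[str] | None = None
) -> VennCounts:
    """Per-condition identified-protein counts and all intersection counts."""
    conditions = list(conditions) if conditions is not None else m.conditions
    if len(conditions) < 2:
        raise ValidationError("venn counts need at least 2 conditions")
    mc = combine_technical_replicates(m)
    sets = {}
    for cond in conditions:
        cols = mc.run_ids(cond)
        sets[cond] = frozenset(mc.counts.index[(mc.counts[cols] > 0).any(axis=1)])
    return VennCounts(sets=sets)


def volcano_table(records: Sequence) -> pd.DataFrame:
    """Volcano coordinates for pairwise or trend records.

    x is log2 fold change (pairwise) or slope (trend); y is -log10 p.
    Rows without a p-value (newly detected / excluded) or with a degenerate
    p = 0 (infinite y) are flagged rather than dropped.
    """
    rows = []
    for r in records:
        is_trend = hasattr(r, "slope")
        x = r.slope if is_trend else r.log2_fc
        p = r.p_value
        label = r.trend if is_trend else r.status
        if p is None or (isinstance(p, float) and np.isnan(p)):
            y, flagged = np.nan, True
        elif p == 0:
            y, flagged = np.inf, True
        else:
            y, flagged = -np.log10(p), bool(getattr(r, "degenerate", False))
        rows.append(
            {"protein": r.protein, "x": x, "y": y, "label": label, "flagged": flagged}
        )
    return pd.DataFrame(rows, columns=["protein", "x", "y", "label", "flagged"])


@dataclass
class RunManifest:
    """Reproducibility record emitted with every pipeline run."""

    mode: str
    inputs: dict[str, str]
    config: dict
    stages: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__
    seed: int | None = None
    status: str = "ok"
    timestamp: str = ""

    def write(self, path: str | os.PathLike) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Config-driven execution (shared by the CLI and run_from_config)
# ---------------------------------------------------------------------------

_COMMON_KEYS = {"mode", "out_dir", "counts", "lengths", "design"}
_MODE_KEYS = {
    "pairwise": _COMMON_KEYS
    | {
        "ref",
        "test",
        "fdr",
        "fc",
        "new_psm_min",
        "test_variant",
        "min_avg_count",
        "min_present",
        "n_bio_reps",
    },
    "trend": _COMMON_KEYS
    | {"baseline", "timepoints", "alpha", "min_avg_count", "min_present", "n_bio_reps"},
    "simulate": {"mode", "out_dir", "params", "seed"},
    "venn": _COMMON_KEYS | {"conditions"},
}


class _StrictLoader(yaml.SafeLoader):
    """YAML loader that rejects duplicate mapping keys."""


def _no_duplicates(loader: _StrictLoader, node: yaml.nodes.MappingNode, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ValidationError(f"duplicate config key: {key!r}")
        seen.add(key)
    return loader.construct_mapping(node, deep=deep)  # type: ignore[call-arg]


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def _parse_timepoints(spec: str) -> tuple[tuple[str, float], ...]:
    """Parse ``COND:H,COND:H,...`` into (condition, time_h) pairs."""
    out = []
    for part in str(spec).split(","):
        cond, _, hours = part.strip().partition(":")
        if not hours:
            raise ValidationError(f"malformed timepoint {part!r}; expected COND:H")
        out.append((cond, float(hours)))
    return tuple(out)


def run_pipeline(mode: str, options: Mapping, out_dir: str | os.PathLike) -> RunManifest:
    """Execute one pipeline mode and write its outputs plus manifest.json.

    Result tables carry no timestamps, so repeated runs on identical inputs
    are byte-identical; wall-clock time lives only in the manifest.
    """
    if mode not in _MODE_KEYS:
        raise ValidationError(f"unknown mode {mode!r}")
    unknown = set(options) - _MODE_KEYS[mode]
    if unknown:
        raise ValidationError(f"unknown config key(s) for {mode}: {sorted(unknown)}")
    os.makedirs(out_dir, exist_ok=True)
    opts = dict(options)
    manifest = RunManifest(mode=mode, inputs={}, config=dict(opts), stages={})
    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    try:
        if mode == "simulate":
            params_spec = opts.get("params", {}) or {}
            if isinstance(params_spec, (str, os.PathLike)):
                manifest.inputs["params"] = _sha256(params_spec)
                with open(params_spec) as fh:
                    params_spec = json.load(fh)
            if "conditions" in params_spec:
                params_spec["conditions"] = tuple(
                    (c, None if t is None else float(t))
                    for c, t in params_spec["conditions"]
                )
            params_spec.pop("rng_algorithm", None)
            if "seed" in opts:
                params_spec["seed"] = int(opts["seed"])
            params = SimParams(**params_spec)
            manifest.seed = params.seed
            matrix, truth = generate_experiment(params)
            paths = write_fixture(matrix, truth, out_dir, params)
            manifest.outputs = {k: _sha256(v) for k, v in paths.items()}
            manifest.stages = {
                "proteins": matrix.n_proteins,
                "runs": len(matrix.runs),
            }
        else:
            for key in ("counts", "lengths", "design"):
                if key not in opts:
                    raise ValidationError(f"mode {mode!r} requires the {key!r} key")
                manifest.inputs[key] = _sha256(opts[key])
            m = pio.load_experiment(opts["counts"], opts["lengths"], opts["design"])
            if mode == "pairwise":
                for key in ("ref", "test"):
                    if key not in opts:
                        raise ValidationError(f"pairwise requires the {key!r} key")
                qcfg = QuantConfig(
                    min_avg_count=float(opts.get("min_avg_count", 3)),
                    min_bio_reps_present=int(opts.get("min_present", 2)),
                    bio_reps_total=int(opts.get("n_bio_reps", 3)),
                )
                pcfg = PairwiseConfig(
                    fdr_alpha=float(opts.get("fdr", 0.10)),
                    fc_threshold=float(opts.get("fc", 1.5)),
                    newly_detected_min_psm=int(opts.get("new_psm_min", 5)),
                    test_variant=str(opts.get("test_variant", "welch")),
                )
                result = run_pairwise_screen(m, opts["ref"], opts["test"], qcfg, pcfg)
                out = os.path.join(out_dir, "pairwise_results.tsv")
                pio.write_records_table(result.records, out)
                manifest.outputs["results"] = _sha256(out)
                manifest.stages = result.stages
            elif mode == "trend":
                for key in ("baseline", "timepoints"):
                    if key not in opts:
                        raise ValidationError(f"trend requires the {key!r} key")
                qcfg = QuantConfig(
                    min_avg_count=float(opts.get("min_avg_count", 3)),
                    min_bio_reps_present=int(opts.get("min_present", 2)),
                    bio_reps_total=int(opts.get("n_bio_reps", 3)),
                )
                tcfg = TrendConfig(
                    baseline_condition=str(opts["baseline"]),
                    timepoints=_parse_timepoints(opts["timepoints"]),
                    alpha=float(opts.get("alpha", 0.05)),
                )
                result = run_trend_screen(m, tcfg, qcfg)
                out = os.path.join(out_dir, "trend_results.tsv")
                pio.write_records_table(result.records, out)
                points_out = os.path.join(out_dir, "trend_points.tsv")
                result.points.to_csv(points_out, sep="\t", index=False, float_format="%.6g")
                manifest.outputs["results"] = _sha256(out)
                manifest.outputs["points"] = _sha256(points_out)
                manifest.stages = result.stages
            elif mode == "venn":
                conds = opts.get("conditions")
                conds = [c.strip() for c in str(conds).split(",")] if conds else None
                vc = venn_counts(m, conds)
                out = os.path.join(out_dir, "venn_counts.tsv")
                vc.to_table().to_csv(out, sep="\t", index=False)
                manifest.outputs["venn"] = _sha256(out)
                manifest.stages = {"proteins": m.n_proteins, **vc.per_condition}
        for stage, count in manifest.stages.items():
            logger.info("stage %s: %d proteins", stage, count)
    except Exception:
        manifest.status = "error"
        raise
    finally:
        manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest


def run_from_config(config_path: str | os.PathLike, out_dir: str | os.PathLike | None = None) -> RunManifest:
    """Execute a run described by a flat YAML/key-value config file.

    The config mirrors the CLI flag names; results are byte-identical to the
    equivalent flag invocation.  Unknown or duplicate keys raise.
    """
    with open(config_path) as fh:
        cfg = yaml.load(fh, Loader=_StrictLoader)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{config_path}: config must be a key-value mapping")
    if "mode" not in cfg:
        raise ValidationError(f"{config_path}: missing required key 'mode'")
    mode = str(cfg.pop("mode"))
    out = out_dir or cfg.pop("out_dir", None)
    cfg.pop("out_dir", None)
    if out is None:
        raise ValidationError(f"{config_path}: missing required key 'out_dir'")
    return run_pipeline(mode, cfg, out)
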