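"""Batch driver: run every (array, cochlea, strategy) combination and
aggregate the grade distributions into the per-array and per-cochlea pivot
tables used to compare the insertion scenarios.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .errors import InvalidConfigError
from .optimize import OptimizationConfig, optimize_insertion
from .strategies import (
    ManAOSConfig,
    plan_autoAOS,
    plan_manAOS,
    simulate,
    state_outlines,
)
from .trauma import StepCostField

__all__ = ["RunConfig", "BatchResult", "run_batch"]

log = logging.getLogger("cisim.batch")

STRATEGIES = ("autoAOS", "manAOS", "optIns")
GRADE_COLS = ["grade_0", "grade_I", "grade_II", "grade_III", "grade_IV"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run; unknown keys are rejected."""

    fixture_dir: str = "fixtures"
    output_dir: str = "results"
    arrays: tuple[str, ...] = ("RE01", "RE06", "RE07", "RE08")
    cochleae: tuple[str, ...] = ("CS", "CM", "CL")
    strategies: tuple[str, ...] = STRATEGIES
    seed: int = 0
    log_level: str = "INFO"
    write_traces: bool = True
    optimizer: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.strategies) == 0:
            raise InvalidConfigError("strategy list must not be empty")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise InvalidConfigError(f"unknown strategies: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("arrays", "cochleae", "strategies"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class BatchResult:
    """Per-combination summaries plus the two pivot layouts."""

    records: list[dict]
    config: RunConfig

    @property
    def n_cells(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def pivot_by_array(self) -> pd.DataFrame:
        """Rows = arrays; grade shares averaged over cochleae, per strategy."""
        df = self.to_frame()
        return df.groupby(["array", "strategy"])[GRADE_COLS + ["mean_grade"]].mean()

    def pivot_by_cochlea(self) -> pd.DataFrame:
        """Rows = cochleae; grade shares averaged over arrays, per strategy."""
        df = self.to_frame()
        return df.groupby(["cochlea", "strategy"])[GRADE_COLS + ["mean_grade"]].mean()


def _load_fixture(path: Path, reader):
    if not path.exists():
        raise FileNotFoundError(f"missing fixture file: {path}")
    return reader(path)


def run_batch(config: RunConfig) -> BatchResult:
    """Execute all (array, cochlea, strategy) combinations on the packaged
    fixture files, writing traces, summaries and pivot tables."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fdir = Path(config.fixture_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    log.info(
        "batch start: seed=%d config_hash=%s cisim=%s",
        config.seed,
        config.config_hash(),
        __version__,
    )

    profiles = {
        a: _load_fixture(fdir / f"profile_{a}.csv", cio.read_profile)
        for a in config.arrays
    }
    cochleae = {
        c: _load_fixture(fdir / f"cochlea_{c}.csv", cio.read_contour)
        for c in config.cochleae
    }

    opt_cfg = OptimizationConfig(**{"seed": config.seed, **config.optimizer})
    records: list[dict] = []
    for a, profile in profiles.items():
        outls = state_outlines(profile)
        for c, contour in cochleae.items():
            w0 = max(opt_cfg.weights[0], 1e-12)
            field_ = StepCostField(
                contour,
                depth_weight=opt_cfg.weights[1] / w0,
                count_weight=opt_cfg.weights[2] / w0,
            )
            plans = {}
            if "autoAOS" in config.strategies:
                plans["autoAOS"] = plan_autoAOS(profile, contour)
            if "manAOS" in config.strategies:
                plans["manAOS"] = plan_manAOS(
                    profile,
                    contour,
                    config=ManAOSConfig(rate_cap_deg=opt_cfg.rate_caps[2]),
                    cost_field=field_,
                    outlines=outls,
                )
            if "optIns" in config.strategies:
                res = optimize_insertion(
                    profile, contour, opt_cfg, outlines=outls, cost_field=field_
                )
                plans["optIns"] = res.plan
            for strat, plan in plans.items():
                trace = simulate(plan, profile, contour, outlines=outls)
                hist = trace.histogram
                rec = {
                    "array": a,
                    "cochlea": c,
                    "strategy": strat,
                    **{GRADE_COLS[i]: float(hist[i]) for i in range(5)},
                    "mean_grade": trace.mean_grade,
                    "total_overlap_cost": trace.total_cost,
                    "n_steps": len(trace.steps),
                }
                records.append(rec)
                log.info(
                    "%s/%s %s: histogram=%s", a, c, strat, np.round(hist, 3).tolist()
                )
                if config.write_traces:
                    cio.write_trace(trace, outdir / f"trace_{a}_{c}_{strat}.csv")
                    cio.write_plan(plan, outdir / f"plan_{a}_{c}_{strat}.csv")

    result = BatchResult(records=records, config=config)
    df = result.to_frame()
    df.to_csv(outdir / "summary.csv", index=False)
    result.pivot_by_array().to_csv(outdir / "pivot_by_array.csv")
    result.pivot_by_cochlea().to_csv(outdir / "pivot_by_cochlea.csv")
    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_cells": result.n_cells,
        "records": records,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return result
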