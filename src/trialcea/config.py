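"""Run configuration, config hashing, and structured logging.

Every analysis is driven by an :class:`AnalysisConfig`; all result files are
stamped with the config hash and seed so a run can be reproduced from files
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "AnalysisConfig",
    "config_hash",
    "get_run_logger",
    "ANALYSIS_MODES",
]

ANALYSIS_MODES = ("base_case", "complete_case", "multiple_imputation", "population_cost")

#: months at which assessments are collected
DEFAULT_WAVES = (0, 3, 6, 9, 12)
#: follow-up waves entering totals (baseline is covariate only)
FOLLOWUP_WAVES = (3, 6, 9, 12)
#: length of one assessment interval, years
WAVE_YEARS = 0.25


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one economic-evaluation run.

    Parameters
    ----------
    bootstrap_B : number of bootstrap iterations (trial default 1000).
    alpha : two-sided significance level for all intervals.
    wtp_grid : willingness-to-pay grid (AUD per effect unit) for CEACs.
    wtp_headline : the headline threshold (AUD 50,000 per QALY).
    seed : master seed; every random stream derives from it.
    covariates : baseline adjustment set (baseline outcome, sex, national
        origin), fixed a priori.
    analysis_mode : one of ``base_case``, ``complete_case``,
        ``multiple_imputation``, ``population_cost``.
    zero_cost_policy : how GLMs with positive-support families treat
        nonpositive totals: ``"shift"`` (add half the smallest positive
        observed total) or ``"gaussian"`` (fall back to gaussian identity).
    pmm_donors : donor pool size for predictive-mean-matching imputation.
    mice_cycles : chained-equation cycles per imputation.
    """

    bootstrap_B: int = 1000
    alpha: float = 0.05
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in range(0, 100_001, 1000))
    wtp_headline: float = 50_000.0
    seed: int = 0
    covariates: tuple[str, ...] = ("baseline", "sex", "country")
    analysis_mode: str = "base_case"
    zero_cost_policy: str = "shift"
    pmm_donors: int = 5
    mice_cycles: int = 10

    def __post_init__(self) -> None:
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        grid = tuple(float(x) for x in self.wtp_grid)
        if list(grid) != sorted(grid):
            raise ValueError("wtp_grid must be sorted ascending")
        if self.wtp_headline not in grid:
            raise ValueError("wtp_headline must be a point of wtp_grid")
        if self.analysis_mode not in ANALYSIS_MODES:
            raise ValueError(f"unknown analysis_mode {self.analysis_mode!r}")
        if self.zero_cost_policy not in ("shift", "gaussian"):
            raise ValueError("zero_cost_policy must be 'shift' or 'gaussian'")
        object.__setattr__(self, "wtp_grid", grid)

    def with_(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["wtp_grid"] = list(d["wtp_grid"])
        d["covariates"] = list(d["covariates"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "wtp_grid" in d:
            d["wtp_grid"] = tuple(float(x) for x in d["wtp_grid"])
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d.get("analysis", d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"analysis": self.to_dict()}, fh, sort_keys=True)

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Named random stream derived from the master seed."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serializable configuration object."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def get_run_logger(run_id: str, seed: int, cfg_hash: str) -> logging.LoggerAdapter:
    """Logger whose records carry run id, seed, and config hash."""
    logger = logging.getLogger(f"trialcea.run.{run_id}")
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s [run=%(run_id)s seed=%(seed)s cfg=%(cfg)s] %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logging.LoggerAdapter(logger, {"run_id": run_id, "seed": seed, "cfg": cfg_hash})
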