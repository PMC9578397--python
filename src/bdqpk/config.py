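"""Run configuration: YAML-backed settings for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "load_config"]


def _check_keys(name: str, data: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Validated configuration for the command-line pipeline.

    seed            : base random seed for every stochastic stage
    output_dir      : where tables/figures/logs are written
    estimation      : fit settings (maxiter, extra_starts, compute_se)
    scm_candidates  : candidate list for stepwise covariate modeling; each
                      entry has parameter, covariate, kind (and optionally
                      form, reference)
    bootstrap       : n_resamples
    vpc             : n_sim, bins
    dose_simulation : ggt_levels, genotypes, dose, tau
    """

    seed: int = 20201001
    output_dir: str = "results"
    estimation: dict = field(default_factory=dict)
    scm_candidates: list = field(default_factory=list)
    bootstrap: dict = field(default_factory=lambda: {"n_resamples": 1000})
    vpc: dict = field(default_factory=lambda: {"n_sim": 1000, "bins": 8})
    dose_simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_keys("estimation", self.estimation, {"maxiter", "extra_starts", "compute_se"})
        _check_keys("bootstrap", self.bootstrap, {"n_resamples"})
        _check_keys("vpc", self.vpc, {"n_sim", "bins"})
        _check_keys(
            "dose_simulation", self.dose_simulation, {"ggt_levels", "genotypes", "dose", "tau"}
        )
        for i, cand in enumerate(self.scm_candidates):
            _check_keys(
                f"scm_candidates[{i}]", cand,
                {"parameter", "covariate", "kind", "form", "reference"},
            )
            for key in ("parameter", "covariate", "kind"):
                if key not in cand:
                    raise ValueError(f"scm_candidates[{i}] is missing {key!r}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {f.name for f in fields(RunConfig)}
    _check_keys("config", raw, allowed)
    return RunConfig(**raw)
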