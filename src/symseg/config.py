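"""Run configuration: YAML-backed, flag-overridable parameter bundle.

A config file is a flat YAML mapping whose keys are the dataclass fields
below. Unknown keys are rejected (typos must not silently fall back to
defaults). The effective configuration of a run can be written back out and
reloaded to reproduce the run exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .evolution import EvolutionParams
from .exceptions import InputError, ParameterError
from .symmetry import HarrisParams


@dataclass(frozen=True)
class RunConfig:
    # evolution / energy weights
    mu: float = 0.2
    lam: float = 2.0
    alpha: float = -2.0
    eta: float = 1.0
    epsilon: float = 1.5
    dt: float = 1.0
    sigma: float = 1.0
    radius: float | None = None
    max_iters: int = 600
    change_tol: float = 1e-4
    mode: str = "lsm-sec"
    edge_gain: float = 4.0
    sct_literal: bool = False
    axis_refresh_every: int = 0
    checkpoint_every: int = 10
    # tip detection
    window_sigma: float = 2.0
    sensitivity: float = 0.05
    response_threshold: float = 0.1
    search_halfwidth_k: float | None = None
    y_band: float = 0.4
    # I/O & behaviour
    edge_source: str = "gradient"  # "gradient" or "file:<path>"
    axis: str = "auto"  # "auto" or "A,B,C"
    largest_component: bool = False
    verbosity: int = 1

    def evolution_params(self) -> EvolutionParams:
        return EvolutionParams(
            mu=self.mu, lam=self.lam, alpha=self.alpha, eta=self.eta,
            epsilon=self.epsilon, dt=self.dt, sigma=self.sigma,
            radius=self.radius, max_iters=self.max_iters,
            change_tol=self.change_tol, mode=self.mode,
            edge_gain=self.edge_gain, sct_literal=self.sct_literal,
            axis_refresh_every=self.axis_refresh_every,
            checkpoint_every=self.checkpoint_every,
        )

    def harris_params(self) -> HarrisParams:
        return HarrisParams(
            window_sigma=self.window_sigma, sensitivity=self.sensitivity,
            response_threshold=self.response_threshold,
            search_halfwidth_k=self.search_halfwidth_k, y_band=self.y_band,
        )

    def with_overrides(self, **kwargs) -> "RunConfig":
        """Return a copy with the non-None overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file, rejecting unknown keys."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise InputError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a flat mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path) -> None:
    """Write the effective configuration; reloading reproduces the run."""
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
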