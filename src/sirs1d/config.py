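"""Run configuration: flat key=value files, validation, manifests.

A run is fully determined by a :class:`RunConfig` plus the master seed;
the config is serialised verbatim into the output manifest so any table
can be regenerated byte-identically from manifest + seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Union

from .model import SIRSParams

__all__ = ["RunConfig", "ConfigError", "load_config", "validate_config", "write_manifest"]

logger = logging.getLogger(__name__)

SELECTORS = ("simulate", "scan", "exponents", "dtco", "qsd", "fss", "spacetime")


class ConfigError(ValueError):
    """A configuration value violates its contract; the message names the field."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment.

    Grids are plain lists; ``init`` is an initial-condition recipe
    ("single", "full", "staggered" or an initial density).
    """

    experiment: str = "simulate"
    N: int = 10_000
    k: int = 3
    lam: float = 0.1
    tau_I: int = 7
    tau_R: int = 9
    max_steps: int = 10_000
    seed: int = 0
    init: Union[str, float] = 0.1
    reps: int = 100
    discard: int = 10_000
    window: int = 1_000
    steps: int = 1_000  #: rows for space-time recording
    cell_window: int = 100  #: observation cell for occupancy histograms
    lam_grid: list[float] = field(default_factory=list)
    rho0_grid: list[float] = field(default_factory=list)
    n_grid: list[int] = field(default_factory=list)
    out: str = "results"

    def params(self, **over) -> SIRSParams:
        kw = dict(
            N=self.N, lam=self.lam, k=self.k,
            tau_I=self.tau_I, tau_R=self.tau_R,
            max_steps=self.max_steps, seed=self.seed,
        )
        kw.update(over)
        return SIRSParams(**kw)


_LIST_FIELDS = {"lam_grid", "rho0_grid", "n_grid"}
_INT_FIELDS = {"N", "k", "tau_I", "tau_R", "max_steps", "seed", "reps",
               "discard", "window", "steps", "cell_window"}
_FLOAT_FIELDS = {"lam"}


def _parse_value(key: str, raw: str):
    if key in _LIST_FIELDS:
        items = [tok for tok in raw.replace(",", " ").split() if tok]
        return [int(t) for t in items] if key == "n_grid" else [float(t) for t in items]
    if key in _INT_FIELDS:
        return int(raw)
    if key in _FLOAT_FIELDS:
        return float(raw)
    if key == "init":
        try:
            return float(raw)
        except ValueError:
            return raw
    return raw


def load_config(path: Union[str, Path]) -> RunConfig:
    """Read a flat ``key = value`` config file (``#`` starts a comment)."""
    known = {f.name for f in fields(RunConfig)}
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in known:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = _parse_value(key, raw)
    return RunConfig(**values)


def validate_config(cfg: RunConfig) -> RunConfig:
    """Check every bound, naming the offending field; inject nothing new.

    Model defaults (``k=3``, ``tau_I=7``, ``tau_R=9``) are already the
    dataclass defaults, so an empty config is a valid full default.  The
    regime ``tau_R <= tau_I`` is accepted — the simulator supports it —
    but noted in the log because the two-threshold analysis assumes
    ``tau_R > tau_I``.
    """
    if cfg.experiment not in SELECTORS:
        raise ConfigError(
            f"experiment: unknown selector {cfg.experiment!r}; choose from {SELECTORS}"
        )
    if not 0.0 <= cfg.lam <= 1.0:
        raise ConfigError(f"lam: must be in [0, 1], got {cfg.lam}")
    for name in ("N", "k", "tau_I", "tau_R", "reps"):
        if getattr(cfg, name) < 1:
            raise ConfigError(f"{name}: must be >= 1, got {getattr(cfg, name)}")
    if cfg.N > 1 and 2 * cfg.k >= cfg.N:
        raise ConfigError(f"k: neighbourhood must satisfy 2k < N (k={cfg.k}, N={cfg.N})")
    for name in ("max_steps", "discard", "window", "steps", "cell_window", "seed"):
        if getattr(cfg, name) < 0:
            raise ConfigError(f"{name}: must be >= 0, got {getattr(cfg, name)}")
    if isinstance(cfg.init, str):
        if cfg.init not in ("single", "full", "staggered"):
            raise ConfigError(
                f"init: must be 'single', 'full', 'staggered' or a density, got {cfg.init!r}"
            )
    elif not 0.0 <= float(cfg.init) <= 1.0:
        raise ConfigError(f"init: density must be in [0, 1], got {cfg.init}")
    for lam in cfg.lam_grid:
        if not 0.0 <= lam <= 1.0:
            raise ConfigError(f"lam_grid: entries must be in [0, 1], got {lam}")
    for rho0 in cfg.rho0_grid:
        if not 0.0 <= rho0 <= 1.0:
            raise ConfigError(f"rho0_grid: entries must be in [0, 1], got {rho0}")
    for n in cfg.n_grid:
        if n < 1 or 2 * cfg.k >= n:
            raise ConfigError(f"n_grid: entries must satisfy 2k < N, got {n}")
    if cfg.tau_R <= cfg.tau_I:
        logger.warning(
            "tau_R=%d <= tau_I=%d: single-threshold regime; the two-threshold "
            "analysis assumes tau_R > tau_I", cfg.tau_R, cfg.tau_I,
        )
    return cfg


def write_manifest(cfg: RunConfig, path: Union[str, Path], extra: Optional[dict] = None) -> Path:
    """Serialise the config (plus derived values) as a flat manifest."""
    from . import __version__

    path = Path(path)
    lines = [f"sirs1d_version = {__version__}"]
    for f in fields(RunConfig):
        v = getattr(cfg, f.name)
        if isinstance(v, list):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name} = {v}")
    for k, v in (extra or {}).items():
        lines.append(f"{k} = {v}")
    path.write_text("\n".join(lines) + "\n")
    return path
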