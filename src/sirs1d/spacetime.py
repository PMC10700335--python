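"""Space-time diagrams of the automaton and their plain-text export.

A space-time record is the full compartment grid of one run: one row
per time step (time increases downward), one column per lattice site.
Two dependency-free text formats are supported:

* symbol matrix — rows of whitespace-separated ``S``/``I``/``R`` tokens,
  preceded by a header comment carrying the run parameters;
* plain PGM (P2) — one pixel per site and step on a 3-level gray scale
  with infected darkest (I -> 0, R -> 1, S -> 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .ensemble import InitSpec, make_initial_state
from .model import COMPARTMENT_SYMBOLS, SIRSParams, run_until_absorbed

__all__ = ["SpaceTimeRecord", "record_spacetime", "export_grid", "parse_grid"]

_SYMBOL_TO_CODE = {sym: code for code, sym in enumerate(COMPARTMENT_SYMBOLS)}
_PGM_GRAY = {0: 2, 1: 0, 2: 1}  # S light, I dark, R mid


@dataclass
class SpaceTimeRecord:
    """Compartment grid of one run; row 0 is the initial configuration."""

    matrix: np.ndarray  # (steps+1, N) int8 over {S, I, R}
    params: Optional[SIRSParams] = None
    init: Optional[InitSpec] = None

    @property
    def steps(self) -> int:
        return self.matrix.shape[0] - 1

    @property
    def N(self) -> int:
        return self.matrix.shape[1]


def record_spacetime(
    params: SIRSParams,
    init: InitSpec,
    steps: int,
    rng: Optional[np.random.Generator] = None,
) -> SpaceTimeRecord:
    """Simulate up to ``steps`` updates and keep the whole grid.

    The dynamics is the one of :func:`~sirs1d.model.run_until_absorbed`
    with the same random stream, so a recorded run and a plain run from
    the same seed agree step for step.  Recording stops early once the
    lattice is all-susceptible (every later row would repeat it).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if rng is None:
        rng = params.rng()
    # run_until_absorbed consumes the rng identically; cap at `steps`
    p = SIRSParams(
        N=params.N, lam=params.lam, k=params.k,
        tau_I=params.tau_I, tau_R=params.tau_R,
        max_steps=steps, seed=params.seed,
    )
    state = make_initial_state(p, init, rng)
    traj = run_until_absorbed(state, p, rng, record_spacetime=True)
    return SpaceTimeRecord(matrix=traj.spacetime, params=p, init=init)


def _header(rec: SpaceTimeRecord) -> str:
    if rec.params is None:
        return "# sirs1d spacetime"
    p = rec.params
    return (
        f"# sirs1d spacetime N={p.N} k={p.k} lam={p.lam!r} "
        f"tau_I={p.tau_I} tau_R={p.tau_R} max_steps={p.max_steps} seed={p.seed}"
    )


def export_grid(
    rec: SpaceTimeRecord, path: Union[str, Path], format: str = "text"
) -> Path:
    """Write the record as a symbol matrix (``"text"``) or plain PGM.

    The text format round-trips through :func:`parse_grid`; the PGM is
    a ready-to-view image with time increasing downward.
    """
    path = Path(path)
    if format == "text":
        lines = [_header(rec)]
        for row in rec.matrix:
            lines.append(" ".join(COMPARTMENT_SYMBOLS[c] for c in row))
        path.write_text("\n".join(lines) + "\n")
    elif format == "pgm":
        rows, cols = rec.matrix.shape
        lines = ["P2", f"# {_header(rec)[2:]}", f"{cols} {rows}", "2"]
        gray = np.vectorize(_PGM_GRAY.__getitem__)(rec.matrix)
        for row in gray:
            lines.append(" ".join(str(int(g)) for g in row))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'text' or 'pgm'")
    return path


def _parse_params(header: str) -> Optional[SIRSParams]:
    fields = {}
    for tok in header.lstrip("# ").split():
        if "=" in tok:
            key, val = tok.split("=", 1)
            fields[key] = val
    try:
        return SIRSParams(
            N=int(fields["N"]),
            lam=float(fields["lam"]),
            k=int(fields["k"]),
            tau_I=int(fields["tau_I"]),
            tau_R=int(fields["tau_R"]),
            max_steps=int(fields.get("max_steps", 10_000)),
            seed=None if fields.get("seed") in (None, "None") else int(fields["seed"]),
        )
    except (KeyError, ValueError):
        return None


def parse_grid(path: Union[str, Path]) -> SpaceTimeRecord:
    """Read a symbol-matrix export back into a :class:`SpaceTimeRecord`."""
    lines = Path(path).read_text().splitlines()
    params = None
    rows = []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if params is None:
                params = _parse_params(line)
            continue
        try:
            rows.append([_SYMBOL_TO_CODE[tok] for tok in line.split()])
        except KeyError as exc:
            raise ValueError(f"unknown compartment symbol {exc.args[0]!r}") from exc
    if not rows:
        raise ValueError(f"no grid rows found in {path}")
    matrix = np.asarray(rows, dtype=np.int8)
    if matrix.ndim != 2:
        raise ValueError("grid rows have unequal lengths")
    return SpaceTimeRecord(matrix=matrix, params=params)
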