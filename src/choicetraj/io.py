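"""Panel CSV round-tripping and run configuration.

The canonical on-disk panel is a wide CSV: one row per participant with the
five baseline choice dimensions followed by per-outcome occasion columns
named ``<outcome>_t<years>``.  Empty cells are missing values (never zero).
Lines starting with ``#`` are metadata headers (package version, seed,
config hash) and are ignored when reading.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import COVARIATE_NAMES, CohortPanel


def write_panel(panel: CohortPanel, path, *, seed: int | None = None,
                config_hash: str | None = None) -> None:
    """Write a panel as wide CSV with a metadata header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# choicetraj {__version__}")
        if seed is not None:
            fh.write(f" seed={seed}")
        if config_hash is not None:
            fh.write(f" config={config_hash}")
        fh.write(f" centered={int(panel.centered)}\n")
        writer = csv.writer(fh)
        header = ["participant_id", *panel.covariate_names]
        for name in panel.outcomes:
            header += [f"{name}_t{t:g}" for t in panel.times[name]]
        writer.writerow(header)
        for i in range(panel.n):
            row: list[str] = [str(i), *(repr(float(v)) for v in panel.covariates[i])]
            for name in panel.outcomes:
                for v in panel.outcomes[name][i]:
                    row.append("" if np.isnan(v) else repr(float(v)))
            writer.writerow(row)


def read_panel(path) -> CohortPanel:
    """Read a wide panel CSV; empty cells become NaN (missing)."""
    path = Path(path)
    centered = False
    with path.open() as fh:
        lines = fh.readlines()
    data_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            if "centered=1" in line:
                centered = True
            continue
        if line.strip():
            data_lines.append((lineno, line))
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    header_lineno, header_line = data_lines[0]
    header = next(csv.reader([header_line]))
    if header[:1] != ["participant_id"]:
        raise ValueError(f"{path}:{header_lineno}: first column must be participant_id")
    cov_names = [c for c in header[1:] if c in COVARIATE_NAMES]
    outcome_cols: dict[str, list[tuple[int, float]]] = {}
    for idx, col in enumerate(header):
        if col == "participant_id" or col in COVARIATE_NAMES:
            continue
        name, _, t = col.rpartition("_t")
        if not name:
            raise ValueError(f"{path}:{header_lineno}: unrecognized column {col!r}")
        outcome_cols.setdefault(name, []).append((idx, float(t)))
    cov_idx = [header.index(c) for c in cov_names]
    covariates, rows = [], []
    for lineno, line in data_lines[1:]:
        cells = next(csv.reader([line]))
        if len(cells) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
        try:
            covariates.append([float(cells[j]) for j in cov_idx])
            rows.append(cells)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    outcomes, times = {}, {}
    for name, cols in outcome_cols.items():
        mat = np.full((len(rows), len(cols)), np.nan)
        for i, cells in enumerate(rows):
            for j, (idx, _) in enumerate(cols):
                cell = cells[idx].strip()
                if cell:
                    mat[i, j] = float(cell)
        outcomes[name] = mat
        times[name] = np.array([t for _, t in cols], dtype=float)
    return CohortPanel(covariates=np.asarray(covariates, dtype=float),
                       covariate_names=tuple(cov_names), outcomes=outcomes,
                       times=times, centered=centered)


def panel_to_long(panel: CohortPanel):
    """Long-format DataFrame (participant_id, outcome, time, value)."""
    import pandas as pd

    records = []
    for name, y in panel.outcomes.items():
        t = panel.times[name]
        for i in range(panel.n):
            for j, tj in enumerate(t):
                if not np.isnan(y[i, j]):
                    records.append((i, name, float(tj), float(y[i, j])))
    return pd.DataFrame(records,
                        columns=["participant_id", "outcome", "time", "value"])


@dataclass
class RunConfig:
    """End-to-end pipeline settings."""

    seed: int = 0
    n_participants: int = 198
    outdir: str = "choicetraj_output"
    attrition_mechanism: str = "MCAR_dropout"
    simulate_sessions: bool = True    # estimate covariates from adaptive tasks
    session_trials: int | None = None  # None = battery defaults (30/40)
    trajectory_step: float = 0.1      # years, for exported trajectories
    verbosity: int = 1

    def validate(self) -> None:
        if self.n_participants < 10:
            raise ValueError("n_participants must be at least 10")
        if self.attrition_mechanism not in ("MCAR_dropout", "MAR_dropout"):
            raise ValueError("unknown attrition mechanism")

    def config_hash(self) -> str:
        # exclude fields that do not affect the computed results
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("outdir", "verbosity")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**raw)
    config.validate()
    return config
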