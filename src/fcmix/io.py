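"""CSV readers/writers and run configuration.

Tables are comma-separated UTF-8 with a header row; affinities accept
scientific notation.  The measurement table is stored with a ``pair``
column (``"IgG1/IgG2"``), expanded on read into ``subclass1``/``subclass2``
used throughout the package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fcmix.binding import AffinityMatrix, ReceptorPool

__all__ = [
    "RunConfig",
    "load_config",
    "read_measurements",
    "write_measurements",
    "read_affinity_table",
    "read_expression_table",
    "read_cell_profiles",
    "read_depletion_records",
    "write_run_log",
]

_MEASUREMENT_COLS = ["day", "receptor", "valency", "pair", "frac1", "replicate", "rfu"]


@dataclass(frozen=True)
class RunConfig:
    """Validated key-value run configuration (YAML).

    ``seed`` is mandatory: every stochastic stage derives its randomness
    from it.  Unknown keys are rejected rather than silently ignored.
    """

    seed: int
    regime: str = "fit_affinity"
    chains: int = 2
    draws: int = 500
    warmup: int = 500
    l0: float = 1e-9
    f_valencies: tuple[float, float] = (4.0, 33.0)
    composition_series: tuple[float, ...] = (1.0, 0.9, 2.0 / 3.0, 1.0 / 3.0, 0.1, 0.0)
    ka_mode_clip: float = 1e4
    ka_iqr_clip: float = 1e5
    replicates: int = 3
    noise_cv: float = 0.2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML config, rejecting unknown keys; ``seed`` is required."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    for key in ("f_valencies", "composition_series"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_measurements(
    path: str | Path, known_receptors: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Read and validate a replicate-level measurement table.

    Splits ``pair`` into ``subclass1``/``subclass2``, rejects nonpositive
    RFU (with the offending row index) and unknown receptor labels, and
    warns when any day's geometric mean is away from 1 (un-normalized
    input).
    """
    df = pd.read_csv(path)
    _require(df, _MEASUREMENT_COLS, "measurement table")
    bad = df.index[df["rfu"] <= 0]
    if len(bad):
        raise ValueError(f"nonpositive rfu at rows {list(bad[:5])}")
    if known_receptors is not None:
        unknown = set(df["receptor"]) - set(known_receptors)
        if unknown:
            raise ValueError(f"unknown receptor labels: {sorted(unknown)}")
    parts = df["pair"].str.split("/", expand=True)
    if parts.shape[1] != 2 or parts.isna().any().any():
        raise ValueError('pair column must be formatted "IgG1/IgG2"')
    df["subclass1"] = parts[0]
    df["subclass2"] = parts[1]
    gm = df.groupby("day")["rfu"].apply(lambda v: float(np.exp(np.mean(np.log(v)))))
    off = gm[np.abs(gm - 1.0) > 1e-6]
    if len(off):
        warnings.warn(
            f"per-day geometric means deviate from 1.0 (e.g. {off.iloc[0]:.4f}); "
            "input appears un-normalized",
            UserWarning,
        )
    return df


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table, collapsing subclasses into ``pair``."""
    out = table.copy()
    if "pair" not in out.columns:
        out["pair"] = out["subclass1"] + "/" + out["subclass2"]
    out[_MEASUREMENT_COLS].to_csv(path, index=False)


def read_affinity_table(path: str | Path) -> pd.DataFrame:
    """Documented-affinity table: ligand, receptor, ka, ka_se (M^-1)."""
    df = pd.read_csv(path)
    _require(df, ["ligand", "receptor", "ka", "ka_se"], "affinity table")
    if (df["ka"] < 0).any() or (df["ka_se"] < 0).any():
        raise ValueError("affinities and standard errors must be nonnegative")
    return df


def affinity_matrix_from_table(df: pd.DataFrame) -> AffinityMatrix:
    """Pivot a tidy affinity table into an :class:`AffinityMatrix`."""
    piv = df.pivot(index="ligand", columns="receptor", values="ka")
    if piv.isna().any().any():
        raise ValueError("affinity table has missing (ligand, receptor) entries")
    return AffinityMatrix(tuple(piv.index), tuple(piv.columns), piv.to_numpy())


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Per-line expression replicates: receptor, replicate, rtot."""
    df = pd.read_csv(path)
    _require(df, ["receptor", "rtot"], "expression table")
    if (df["rtot"] <= 0).any():
        raise ValueError("expression replicates must be positive")
    return df


def read_cell_profiles(
    path: str | Path, receptor_order: tuple[str, ...]
) -> dict[str, ReceptorPool]:
    """Cell-type receptor abundances: cell, receptor, rtot -> pools."""
    df = pd.read_csv(path)
    _require(df, ["cell", "receptor", "rtot"], "cell profile table")
    pools = {}
    for cell, grp in df.groupby("cell", sort=False):
        m = dict(zip(grp["receptor"], grp["rtot"]))
        missing = set(receptor_order) - set(m)
        if missing:
            raise ValueError(f"cell {cell!r} lacks receptors {sorted(missing)}")
        pools[str(cell)] = ReceptorPool(str(cell), np.array([m[r] for r in receptor_order]))
    return pools


def read_depletion_records(path: str | Path) -> pd.DataFrame:
    """Depletion records: treatment, experiment, y in [0, 1]."""
    df = pd.read_csv(path)
    _require(df, ["treatment", "experiment", "y"], "depletion table")
    if ((df["y"] < 0) | (df["y"] > 1)).any():
        raise ValueError("depletion fractions must lie in [0, 1]")
    return df


def write_run_log(path: str | Path, config: dict, seed: int, stage: str) -> None:
    """Append a plain-text record of a stage run (config hash + seed)."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(path, "a") as fh:
        fh.write(f"stage={stage} seed={seed} config_sha256={digest} config={json.dumps(config, sort_keys=True, default=str)}\n")
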