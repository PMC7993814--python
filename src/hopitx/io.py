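"""Data ingestion and run configuration.

Datasets travel as delimited text with a header: one ordinal
self-assessment column, ``J`` vignette columns, covariate columns.
Ordinal labels may be arbitrary strings ("none" ... "extreme") mapped
to 1..K through an ordered category map in the configuration.  Rows
with missing values in any mapped column are dropped (complete-case
rule) with a logged count; unmapped columns are ignored entirely.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import SurveyDataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Column mappings and numerical settings for a model run."""

    outcome: str = "y"
    vignette_columns: list = field(default_factory=list)
    x_columns: list = field(default_factory=list)
    z_columns: list | None = None  # default: intercept + x_columns
    category_order: list | None = None  # ordered labels -> 1..K; None: integers
    variant: str = "extended_hopit"
    draws: tuple = (200, 1000, 101)
    gtol: float = 1e-5
    maxiter: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.draws = tuple(cfg.draws)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["draws"] = list(self.draws)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _map_ordinal(series: pd.Series, order: list | None, colname: str) -> np.ndarray:
    if order is None:
        vals = pd.to_numeric(series, errors="coerce")
        if vals.isna().any():
            bad = series[vals.isna()].iloc[0]
            raise ValueError(
                f"column {colname!r}: unmapped non-numeric label {bad!r} "
                "(provide category_order)"
            )
        return vals.to_numpy(dtype=np.int64)
    lookup = {lab: k + 1 for k, lab in enumerate(order)}
    out = series.map(lookup)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise ValueError(f"column {colname!r}: label {bad!r} not in category_order")
    return out.to_numpy(dtype=np.int64)


def read_dataset(path, config: RunConfig) -> SurveyDataset:
    """Read and validate a delimited survey file into a SurveyDataset.

    Accepts wide vignette columns (one per vignette) listed in
    ``config.vignette_columns``.  Listwise deletion applies to mapped
    columns only.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    mapped = [config.outcome, *config.vignette_columns, *config.x_columns]
    if config.z_columns:
        mapped += [c for c in config.z_columns if c not in mapped]
    missing_cols = [c for c in mapped if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing column(s) in {path.name}: {missing_cols}")
    n0 = len(df)
    df = df.dropna(subset=mapped)
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d row(s) with missing mapped values", dropped)
    if not len(df):
        raise ValueError("no rows survive the complete-case filter")

    y = _map_ordinal(df[config.outcome], config.category_order, config.outcome)
    V = (
        np.column_stack(
            [
                _map_ordinal(df[c], config.category_order, c)
                for c in config.vignette_columns
            ]
        )
        if config.vignette_columns
        else np.empty((len(df), 0), dtype=np.int64)
    )
    X = df[config.x_columns].to_numpy(dtype=float)
    if config.z_columns:
        Z = df[config.z_columns].to_numpy(dtype=float)
    else:
        Z = np.hstack([np.ones((len(df), 1)), X])
    K = (
        len(config.category_order)
        if config.category_order
        else int(max(y.max(), V.max() if V.size else 0))
    )
    return SurveyDataset(y=y, V=V, X=X, Z=Z, K=K)


def read_long_vignettes(path, config: RunConfig, id_col="respondent",
                        vignette_col="vignette_id", rating_col="rating") -> pd.DataFrame:
    """Pivot a long-format vignette table (respondent, vignette_id, rating) wide."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    wide = df.pivot(index=id_col, columns=vignette_col, values=rating_col)
    wide.columns = [f"V{c}" for c in wide.columns]
    return wide.reset_index()


def write_dataset(sim, path) -> None:
    """Write a simulated dataset as delimited text: y, V1..VJ, x1..xp."""
    data = sim.dataset if hasattr(sim, "dataset") else sim
    cols = {"y": data.y}
    for j in range(data.J):
        cols[f"V{j + 1}"] = data.V[:, j]
    for c in range(data.p):
        cols[f"x{c + 1}"] = data.X[:, c]
    pd.DataFrame(cols).to_csv(path, index=False)


def default_sim_config_for(path_or_df) -> RunConfig:
    """RunConfig matching :func:`write_dataset`'s column layout."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, nrows=1)
    )
    vcols = sorted(
        (c for c in df.columns if c.startswith("V") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    return RunConfig(outcome="y", vignette_columns=vcols, x_columns=xcols)
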