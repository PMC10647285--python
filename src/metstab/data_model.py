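"""Containers, I/O and validation for multi-environment yield trials.

A trial is a long-format table with one row per (environment, genotype,
replicate) observation of grain yield (g/plot).  Replicates are nested in
environments.  All downstream analyses (AMMI, BLUP/WAASB, GGE, indices)
operate either on the replicate-level table or on the genotype x environment
matrix of cell means produced here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "IntegrityError",
    "BalanceError",
    "MetTrial",
    "CellMeans",
    "BalanceReport",
    "DEFAULT_COLUMNS",
    "load_trial",
    "write_trial",
    "check_balance",
    "cell_means",
    "write_cell_means",
    "write_balance_report",
]


class SchemaError(ValueError):
    """Input table is missing required columns or has unparseable values."""


class IntegrityError(ValueError):
    """Record-level invariant violated (duplicate keys, too few levels...)."""


class BalanceError(ValueError):
    """Operation requires a balanced trial (equal replication in every cell)."""


#: default CSV header names for the long format, overridable via column_map
DEFAULT_COLUMNS: dict[str, str] = {"env": "ENV", "gen": "GEN", "rep": "REP", "yield": "Y"}

_SOWING_LEVELS = frozenset({"normal", "late"})


@dataclass
class MetTrial:
    """Replicate-level yield records plus optional environment metadata.

    ``data`` has columns ``env``, ``gen``, ``rep`` (labels) and ``yield``
    (g/plot, non-negative).  ``env_meta``, if given, has one row per
    environment with columns ``env``, ``location``, ``year``, ``sowing``
    (``normal``/``late``) and is used only to pair environments for the
    heat-susceptibility index.
    """

    data: pd.DataFrame
    env_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = ["env", "gen", "rep", "yield"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise SchemaError(f"trial table missing columns: {missing}")
        df = self.data.loc[:, required].copy()
        for c in ("env", "gen", "rep"):
            df[c] = df[c].astype(str)
        y = pd.to_numeric(df["yield"], errors="coerce")
        if y.isna().any():
            raise SchemaError("yield column contains non-numeric or missing values")
        if (y < 0).any():
            raise ValueError("yield values must be non-negative (g/plot)")
        df["yield"] = y.astype(float)
        if len(df) == 0:
            raise IntegrityError("empty trial: no records")
        dup = df.duplicated(subset=["env", "gen", "rep"])
        if dup.any():
            keys = df.loc[dup, ["env", "gen", "rep"]].head(5).to_records(index=False)
            raise IntegrityError(f"duplicate (env, gen, rep) keys, e.g. {list(keys)}")
        if df["gen"].nunique() < 2:
            raise IntegrityError("need at least 2 genotypes")
        if df["env"].nunique() < 2:
            raise IntegrityError("need at least 2 environments")
        self.data = df.reset_index(drop=True)
        if self.env_meta is not None:
            meta = self.env_meta.copy()
            need = ["env", "location", "year", "sowing"]
            lost = [c for c in need if c not in meta.columns]
            if lost:
                raise SchemaError(f"env_meta missing columns: {lost}")
            meta["env"] = meta["env"].astype(str)
            bad = set(meta["sowing"]) - _SOWING_LEVELS
            if bad:
                raise SchemaError(f"env_meta sowing must be 'normal'/'late', got {sorted(bad)}")
            if meta["env"].duplicated().any():
                raise IntegrityError("env_meta has duplicate environment rows")
            self.env_meta = meta.reset_index(drop=True)

    # -- label order is sorted-lexicographic everywhere; ties in downstream
    #    rankings are broken in this order.
    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["gen"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.data["env"].unique())

    @property
    def n_genotypes(self) -> int:
        return self.data["gen"].nunique()

    @property
    def n_environments(self) -> int:
        return self.data["env"].nunique()

    @property
    def is_balanced(self) -> bool:
        return check_balance(self).is_balanced

    @property
    def rep_count(self) -> int:
        """Common replicate count; raises if the trial is unbalanced."""
        rep = check_balance(self)
        if not rep.is_balanced:
            raise BalanceError("trial is unbalanced; no common replicate count")
        return int(rep.rep_counts.to_numpy()[0, 0])


@dataclass
class CellMeans:
    """Genotype x environment matrix of replicate-mean yields."""

    matrix: np.ndarray  # shape (g, e)
    genotypes: list[str]
    environments: list[str]
    rep_count: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.genotypes), len(self.environments)):
            raise ValueError("matrix shape does not match label counts")

    @classmethod
    def from_matrix(cls, matrix, genotypes=None, environments=None, rep_count=1) -> "CellMeans":
        matrix = np.asarray(matrix, dtype=float)
        g, e = matrix.shape
        genotypes = list(genotypes) if genotypes is not None else [f"G{i+1:02d}" for i in range(g)]
        environments = list(environments) if environments is not None else [f"E{j+1:02d}" for j in range(e)]
        return cls(matrix, genotypes, environments, rep_count)

    @property
    def grand_mean(self) -> float:
        return float(self.matrix.mean())

    @property
    def genotype_means(self) -> pd.Series:
        return pd.Series(self.matrix.mean(axis=1), index=self.genotypes, name="mean")

    @property
    def env_means(self) -> pd.Series:
        return pd.Series(self.matrix.mean(axis=0), index=self.environments, name="mean")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.genotypes, columns=self.environments)


@dataclass
class BalanceReport:
    is_balanced: bool
    missing_cells: list[tuple[str, str]]
    rep_counts: pd.DataFrame  # gen x env integer counts

    def to_frame(self) -> pd.DataFrame:
        return self.rep_counts


def load_trial(
    path: str | Path | io.IOBase,
    column_map: Mapping[str, str] | None = None,
    meta_path: str | Path | None = None,
) -> MetTrial:
    """Read a long-format CSV into a validated :class:`MetTrial`.

    ``column_map`` maps the internal names (``env``, ``gen``, ``rep``,
    ``yield``) to the file's header names; defaults to
    ``ENV, GEN, REP, Y``.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise SchemaError(f"input file missing columns {missing}; present: {list(raw.columns)}")
    df = raw.rename(columns={v: k for k, v in cmap.items()})
    meta = pd.read_csv(meta_path) if meta_path is not None else None
    return MetTrial(df[["env", "gen", "rep", "yield"]], env_meta=meta)


def write_trial(trial: MetTrial, path: str | Path, column_map: Mapping[str, str] | None = None) -> None:
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    trial.data.rename(columns=cmap).to_csv(path, index=False)


def check_balance(trial: MetTrial) -> BalanceReport:
    """Per-cell replicate counts, missing (env, gen) cells, and balance flag."""
    counts = (
        trial.data.groupby(["gen", "env"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=trial.genotypes, columns=trial.environments, fill_value=0)
    )
    arr = counts.to_numpy()
    missing = [
        (trial.environments[j], trial.genotypes[i])
        for i, j in zip(*np.nonzero(arr == 0))
    ]
    balanced = (arr > 0).all() and arr.min() == arr.max()
    return BalanceReport(bool(balanced), missing, counts)


def cell_means(trial: MetTrial) -> CellMeans:
    """Average over replicates within each (genotype, environment) cell.

    Requires a balanced trial; unbalanced data are rejected rather than
    imputed because the exact ANOVA df partition downstream presumes balance.
    """
    report = check_balance(trial)
    if not report.is_balanced:
        raise BalanceError(
            f"trial is unbalanced ({len(report.missing_cells)} missing cells, "
            f"rep counts {int(report.rep_counts.to_numpy().min())}"
            f"..{int(report.rep_counts.to_numpy().max())})"
        )
    piv = (
        trial.data.groupby(["gen", "env"], sort=True)["yield"]
        .mean()
        .unstack()
        .reindex(index=trial.genotypes, columns=trial.environments)
    )
    r = int(report.rep_counts.to_numpy()[0, 0])
    return CellMeans(piv.to_numpy(), trial.genotypes, trial.environments, rep_count=r)


def write_cell_means(cm: CellMeans, path: str | Path) -> None:
    cm.to_frame().rename_axis("GEN").to_csv(path)


def write_balance_report(report: BalanceReport, path: str | Path) -> None:
    report.rep_counts.rename_axis("GEN").to_csv(path)
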