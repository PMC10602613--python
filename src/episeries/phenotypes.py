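"""Reading, validating and summarizing per-fruit phenotype tables.

The canonical layout is one row per fruit with seven columns::

    trial_id  clv3_allele  wus  cle9  plant_id  fruit_id  locule_count

``locule_count`` is a positive integer (tomato fruits have at least two
locules, but counts of 1 are tolerated).  Tables produced by the simulator in
continuous mode carry a ``log_phenotype`` column instead of ``locule_count``;
all downstream analysis operates on the natural log of the phenotype, so both
layouts are accepted interchangeably.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataValueError, DuplicateKeyError, SchemaError
from .genotypes import CLE9_STATES, WUS_STATES, Genotype

#: required columns, in canonical order (phenotype column appended separately)
KEY_COLUMNS = ("trial_id", "clv3_allele", "wus", "cle9", "plant_id", "fruit_id")
COUNT_COLUMN = "locule_count"
LOG_COLUMN = "log_phenotype"

_FRUIT_KEY = ("trial_id", "clv3_allele", "wus", "cle9", "plant_id", "fruit_id")


@dataclass(frozen=True)
class Violation:
    """One validation failure; ``row`` is the 0-based row index (or None)."""

    kind: str
    message: str
    row: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (row {self.row})" if self.row is not None else ""
        return f"{self.kind}{loc}: {self.message}"


@dataclass(frozen=True)
class GenotypeSummary:
    """Per-genotype replication and log-scale phenotype summary.

    ``mean_log`` is the mean natural-log locule count, the "mean log locule
    number" axis of the effect plots; ``se_log = sd_log / sqrt(n_fruits)``.
    With a single fruit the SE is undefined and flagged NaN.
    ``mean_count`` is the arithmetic mean of raw counts (NaN for continuous
    tables).
    """

    genotype_id: str
    n_plants: int
    n_fruits: int
    mean_log: float
    sd_log: float
    se_log: float
    mean_count: float

    @property
    def genotype(self) -> Genotype:
        return Genotype.from_id(self.genotype_id)


class PhenotypeTable:
    """A validated-on-construction wrapper around the per-fruit DataFrame."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if COUNT_COLUMN not in df.columns and LOG_COLUMN not in df.columns:
            raise SchemaError(
                f"need a phenotype column: {COUNT_COLUMN!r} or {LOG_COLUMN!r}"
            )
        self.df = df.reset_index(drop=True)

    # -- basic properties -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_counts(self) -> bool:
        return COUNT_COLUMN in self.df.columns

    def genotype_ids(self) -> pd.Series:
        d = self.df
        return d["clv3_allele"].astype(str) + "|" + d["wus"].astype(str) + "|" + d["cle9"].astype(str)

    @property
    def n_genotypes(self) -> int:
        return int(self.genotype_ids().nunique())

    def log_values(self) -> np.ndarray:
        """Natural-log phenotype per fruit (log of count, or the raw log column)."""
        if self.has_counts:
            return np.log(self.df[COUNT_COLUMN].to_numpy(dtype=float))
        return self.df[LOG_COLUMN].to_numpy(dtype=float)

    def trials(self) -> list[str]:
        return sorted(self.df["trial_id"].astype(str).unique())

    def split_by_trial(self) -> dict[str, "PhenotypeTable"]:
        return {
            str(t): PhenotypeTable(g.copy())
            for t, g in self.df.groupby("trial_id", sort=True)
        }

    # -- serialization -----------------------------------------------------
    def write(self, path: str | Path, format: str = "tsv") -> None:
        sep = {"tsv": "\t", "csv": ","}[format]
        self.df.to_csv(path, sep=sep, index=False)

    # -- validation ---------------------------------------------------------
    def validate(self) -> list[Violation]:
        return validate_table(self)

    def summarize(self, per_trial: bool = False) -> list[GenotypeSummary]:
        return summarize(self, per_trial=per_trial)


def read_phenotype_table(
    path: str | Path,
    format: str = "tsv",
    column_map: Mapping[str, str] | None = None,
) -> PhenotypeTable:
    """Read a per-fruit phenotype table from TSV or CSV.

    Parameters
    ----------
    path : file path
    format : ``"tsv"`` or ``"csv"``
    column_map : optional mapping from the file's header names to the
        canonical names, for tables exported with different headers.

    Raises
    ------
    SchemaError
        Missing required column (named in the message).
    DataValueError
        Non-integer or non-positive locule count (row number in the message).
    DuplicateKeyError
        Duplicated (trial, genotype, plant, fruit) key.
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {format!r}")
    sep = "\t" if format == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))

    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    has_counts = COUNT_COLUMN in df.columns
    if not has_counts and LOG_COLUMN not in df.columns:
        raise SchemaError(f"missing phenotype column {COUNT_COLUMN!r} (or {LOG_COLUMN!r})")

    if has_counts:
        counts = np.empty(len(df), dtype=np.int64)
        for i, raw in enumerate(df[COUNT_COLUMN].tolist()):
            try:
                val = int(raw)
                if str(raw).strip() != str(val):  # reject "4.5", "4.0", " 4x"
                    raise ValueError
            except (TypeError, ValueError):
                raise DataValueError(
                    f"row {i + 1}: locule_count {raw!r} is not an integer"
                ) from None
            if val <= 0:
                raise DataValueError(f"row {i + 1}: locule_count must be >= 1, got {val}")
            counts[i] = val
        df[COUNT_COLUMN] = counts
    else:
        df[LOG_COLUMN] = pd.to_numeric(df[LOG_COLUMN])

    dup = df.duplicated(subset=list(_FRUIT_KEY))
    if dup.any():
        first = int(np.flatnonzero(dup.to_numpy())[0])
        raise DuplicateKeyError(
            f"row {first + 1}: duplicated (trial, genotype, plant, fruit) key"
        )

    # validate enum states eagerly so the table is well-typed from the start
    for col, allowed in (("wus", WUS_STATES), ("cle9", CLE9_STATES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataValueError(
                f"row {first + 1}: {col}={df[col].iloc[first]!r} not in {allowed}"
            )
    return PhenotypeTable(df)


def validate_table(table: PhenotypeTable) -> list[Violation]:
    """Check type invariants; returns violations instead of raising."""
    out: list[Violation] = []
    df = table.df
    if table.has_counts:
        counts = pd.to_numeric(df[COUNT_COLUMN], errors="coerce")
        bad = counts.isna() | (counts < 1) | (counts != counts.round())
        for i in np.flatnonzero(bad.to_numpy()):
            out.append(
                Violation("value", f"locule_count={df[COUNT_COLUMN].iloc[i]!r} invalid", int(i))
            )
    dup = df.duplicated(subset=list(_FRUIT_KEY))
    for i in np.flatnonzero(dup.to_numpy()):
        out.append(Violation("duplicate", "duplicated (trial, genotype, plant, fruit) key", int(i)))
    for col, allowed in (("wus", WUS_STATES), ("cle9", CLE9_STATES)):
        bad = ~df[col].isin(allowed)
        for i in np.flatnonzero(bad.to_numpy()):
            out.append(Violation("value", f"{col}={df[col].iloc[i]!r} not in {allowed}", int(i)))
    empty = df["clv3_allele"].astype(str).str.len() == 0
    for i in np.flatnonzero(empty.to_numpy()):
        out.append(Violation("value", "empty clv3_allele label", int(i)))
    return out


def summarize(table: PhenotypeTable, per_trial: bool = False) -> list[GenotypeSummary]:
    """One :class:`GenotypeSummary` per distinct genotype.

    Trials are pooled by default; with ``per_trial=True`` the genotype id is
    suffixed ``@trial``.
    """
    df = table.df.copy()
    df["_gid"] = table.genotype_ids()
    df["_y"] = table.log_values()
    keys = ["_gid", "trial_id"] if per_trial else ["_gid"]
    out: list[GenotypeSummary] = []
    for key, g in df.groupby(keys, sort=True):
        gid = key[0] if per_trial else (key[0] if isinstance(key, tuple) else key)
        label = f"{gid}@{key[1]}" if per_trial else gid
        y = g["_y"].to_numpy()
        n = len(y)
        mean_log = float(y.mean())
        sd_log = float(y.std(ddof=1)) if n > 1 else float("nan")
        se_log = sd_log / math.sqrt(n) if n > 1 else float("nan")
        mean_count = float(g[COUNT_COLUMN].mean()) if table.has_counts else float("nan")
        out.append(
            GenotypeSummary(
                genotype_id=label,
                n_plants=int(g["plant_id"].nunique()),
                n_fruits=n,
                mean_log=mean_log,
                sd_log=sd_log,
                se_log=se_log,
                mean_count=mean_count,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[GenotypeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def write_summaries(
    summaries: Iterable[GenotypeSummary], tsv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Emit summaries as a TSV table and/or a JSON report keyed by genotype id."""
    summaries = list(summaries)
    if tsv_path is not None:
        summaries_to_frame(summaries).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            s.genotype_id: {
                k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in s.__dict__.items()
                if k != "genotype_id"
            }
            for s in summaries
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))
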