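"""Subject-level expression tables.

Long (tidy) format: one row per (subject, gene, region) measurement, with the
subject nested in an (age, treatment) cell. Values are expression levels in
arbitrary optical-density units. A wide-format (region-per-column) importer is
provided as a convenience converter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateMeasurement,
    InsufficientSubjects,
    IoFailure,
    MissingColumn,
    NonNumericValue,
    UnknownRegion,
)
from .registry import RegionRegistry

logger = logging.getLogger(__name__)

COLUMNS = ["subject_id", "age", "treatment", "gene", "region", "value"]

GENES = ("cfos", "arc")
AGES = ("adolescent", "adult")
TREATMENTS = ("saline", "D2", "D1Gs", "D1Gq", "D1Gs+D2", "D1Gq+D2")


@dataclass(frozen=True, order=True)
class GroupKey:
    """One analysis cell: a gene measured in one (age, treatment) group."""

    gene: str
    age: str
    treatment: str

    def label(self) -> str:
        """Filesystem-safe group label."""
        treat = self.treatment.replace("+", "-")
        return f"{self.gene}_{self.age}_{treat}"


def full_factorial_groups(
    genes=GENES, ages=AGES, treatments=TREATMENTS
) -> list[GroupKey]:
    """All gene x age x treatment cells (2 x 2 x 6 = 24 by default)."""
    return [
        GroupKey(g, a, t)
        for g, a, t in itertools.product(genes, ages, treatments)
    ]


class ExpressionTable:
    """Validated long-format expression table.

    Wraps a pandas DataFrame with columns
    ``subject_id, age, treatment, gene, region, value``. Region ids are
    canonicalized against the registry at construction; duplicates and
    non-numeric values are rejected.
    """

    def __init__(self, df: pd.DataFrame, registry: RegionRegistry):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise MissingColumn(f"missing columns: {missing}")
        df = df[COLUMNS].copy()
        for col in COLUMNS[:-1]:
            df[col] = df[col].astype(str)

        def _to_float(v):
            # exact round-trip parsing (pd.to_numeric's fast path is lossy)
            try:
                f = float(v)
            except (TypeError, ValueError):
                return None
            return f if np.isfinite(f) else None

        values = df["value"].map(_to_float)
        bad = df.index[values.isna()]
        if len(bad):
            rows = df.loc[bad[:5]].to_dict("records")
            raise NonNumericValue(f"non-numeric expression values in rows: {rows}")
        df["value"] = values.astype(float)

        unknown = sorted(set(df["region"]) - {r.lower() for r in registry.ids} - set(registry.ids))
        unknown = [u for u in unknown if u not in registry]
        if unknown:
            raise UnknownRegion(f"unknown regions: {unknown}")
        df["region"] = df["region"].map(registry.resolve)

        dup = df.duplicated(subset=["subject_id", "gene", "region"], keep=False)
        if dup.any():
            rows = df.loc[dup].head(5).to_dict("records")
            raise DuplicateMeasurement(
                f"duplicate (subject, gene, region) measurements: {rows}"
            )

        self.df = df.sort_values(
            ["gene", "age", "treatment", "subject_id", "region"]
        ).reset_index(drop=True)
        self.registry = registry

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionTable) and self.df.equals(other.df)

    def __len__(self) -> int:
        return len(self.df)

    def groups(self) -> list[GroupKey]:
        """Distinct (gene, age, treatment) cells present, sorted."""
        cells = self.df[["gene", "age", "treatment"]].drop_duplicates()
        return sorted(GroupKey(r.gene, r.age, r.treatment) for r in cells.itertuples())

    def subject_counts(self) -> dict[GroupKey, int]:
        out: dict[GroupKey, int] = {}
        for key, sub in self.df.groupby(["gene", "age", "treatment"]):
            out[GroupKey(*key)] = sub["subject_id"].nunique()
        return out

    def group_matrix(
        self, group: GroupKey, allow_missing: bool = False
    ) -> pd.DataFrame:
        """Subjects x regions value matrix for one group.

        Subjects with any missing region are dropped listwise when
        ``allow_missing`` is set (and logged); otherwise an incomplete panel
        raises. Columns follow registry order.
        """
        sub = self.df[
            (self.df["gene"] == group.gene)
            & (self.df["age"] == group.age)
            & (self.df["treatment"] == group.treatment)
        ]
        if sub.empty:
            raise InsufficientSubjects(f"no rows for group {group}")
        wide = sub.pivot(index="subject_id", columns="region", values="value")
        wide = wide.reindex(columns=self.registry.ids)
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        if incomplete:
            if not allow_missing:
                raise InsufficientSubjects(
                    f"subjects {incomplete} in group {group} have missing "
                    "regions; pass allow_missing=True to drop them"
                )
            logger.warning(
                "group %s: dropping %d subject(s) with missing regions: %s",
                group, len(incomplete), incomplete,
            )
            wide = wide.drop(index=incomplete)
        return wide.sort_index()


def load_expression(path: str | Path, registry: RegionRegistry) -> ExpressionTable:
    """Load a TSV/CSV expression table (delimiter inferred from extension)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    return ExpressionTable(df, registry)


def write_expression(table: ExpressionTable, path: str | Path) -> Path:
    """Write a table as TSV with deterministic row sort and column order."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = table.df.copy()
        df["value"] = df["value"].map(lambda v: format(v, ".17g"))
        df.to_csv(path, sep=sep, index=False, lineterminator="\n")
    except OSError as exc:
        raise IoFailure(f"cannot write {path}: {exc}") from exc
    return path


def from_wide(
    wide: pd.DataFrame, group: GroupKey, registry: RegionRegistry
) -> ExpressionTable:
    """Convert a subjects x regions matrix for one group to a long table."""
    long = wide.reset_index(names="subject_id").melt(
        id_vars="subject_id", var_name="region", value_name="value"
    )
    long["gene"] = group.gene
    long["age"] = group.age
    long["treatment"] = group.treatment
    return ExpressionTable(long, registry)


def concat_tables(tables: list[ExpressionTable]) -> ExpressionTable:
    if not tables:
        raise ValueError("no tables to concatenate")
    registry = tables[0].registry
    df = pd.concat([t.df for t in tables], ignore_index=True)
    return ExpressionTable(df, registry)
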