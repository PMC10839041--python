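"""Data model and text I/O for abundance tables, study designs and phenotypes.

The package works downstream of read processing: its inputs are samples x taxa
relative-abundance (or count) tables at a single taxonomic level, a sample ->
group design with exactly three ordered roles (control diet, disease diet,
treated disease diet), and per-sample numeric phenotype tables.

Abundances are stored internally as proportions on [0, 1]; percent formatting
happens only when reports are written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "StudyDesign",
    "read_abundance",
    "write_abundance",
    "read_design",
    "read_phenotypes",
    "to_relative",
    "subset_groups",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class AbundanceTable:
    """A samples x taxa nonnegative matrix at one taxonomic level.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are taxa. No missing entries allowed.
    mode : {"counts", "relative"}
        ``relative`` rows must sum to 1 within 1e-9.
    level : str, optional
        Taxonomic-level label (e.g. ``"phylum"``, ``"genus"``).

    Taxa absent from a sample are explicit zeros, never NaN: the
    abundance-based dissimilarities below depend on that convention.
    """

    data: pd.DataFrame
    mode: str = "relative"
    level: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        values = df.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
            )
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
            if bad.any():
                sid = df.index[np.argmax(bad)]
                raise ValueError(
                    f"relative rows must sum to 1: sample {sid!r} sums to "
                    f"{sums[np.argmax(bad)]:.12g}"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class StudyDesign:
    """Ordered three-group assignment: (control, disease, treatment).

    ``group_order`` fixes the roles: the first label is the control diet,
    the second the disease diet, the third the treated disease diet.
    """

    assignments: pd.Series
    group_order: tuple = ("ND", "WD", "WD-T070")

    def __post_init__(self) -> None:
        if len(self.group_order) != 3:
            raise ValueError("group_order must name exactly three groups")
        if self.assignments.index.has_duplicates:
            raise ValueError("duplicate sample ids in design")
        present = set(self.assignments.unique())
        expected = set(self.group_order)
        if present != expected:
            raise ValueError(
                f"design groups {sorted(map(str, present))} do not match "
                f"group_order {list(self.group_order)}"
            )
        for g in self.group_order:
            if (self.assignments == g).sum() == 0:
                raise ValueError(f"group {g!r} is empty")

    @property
    def sample_ids(self) -> list:
        return list(self.assignments.index)

    def groups_of(self, sample_ids) -> np.ndarray:
        """Group label for each of the given samples, in order."""
        missing = [s for s in sample_ids if s not in self.assignments.index]
        if missing:
            raise KeyError(f"samples missing from design: {missing}")
        return self.assignments.loc[list(sample_ids)].to_numpy()

    def group_sizes(self) -> dict:
        return {g: int((self.assignments == g).sum()) for g in self.group_order}


def read_abundance(path, mode: str = "relative", level: str | None = None) -> AbundanceTable:
    """Read a tab-separated abundance table (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return AbundanceTable(data=df, mode=mode, level=level)


def write_abundance(table: AbundanceTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_design(path, group_order: tuple = ("ND", "WD", "WD-T070")) -> StudyDesign:
    """Read a two-column ``sample_id<TAB>group`` design table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError("design table must have exactly two columns: sample_id, group")
    ser = df.iloc[:, 0].astype(str)
    ser.index = ser.index.astype(str)
    return StudyDesign(assignments=ser, group_order=group_order)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a per-sample phenotype table; missing values stay NaN (flagged)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric phenotype columns: {non_numeric}")
    return df


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each row by its total. Idempotent on relative tables."""
    if table.mode == "relative":
        return table
    totals = table.values.sum(axis=1)
    if (totals == 0).any():
        sid = table.data.index[int(np.argmax(totals == 0))]
        raise ValueError(f"sample {sid!r} has zero total count")
    data = table.data.div(totals, axis=0)
    return AbundanceTable(data=data, mode="relative", level=table.level)


def subset_groups(table: AbundanceTable, design: StudyDesign, groups) -> tuple:
    """Restrict a table+design to the named groups, preserving sample order.

    Returns a ``(AbundanceTable, pandas.Series)`` pair; the series maps the
    retained samples to their group labels (a full three-group StudyDesign is
    not reconstructed because a subset usually drops a role).
    """
    groups = list(groups)
    unknown = [g for g in groups if g not in design.group_order]
    if unknown:
        raise KeyError(f"unknown group labels: {unknown}")
    labels = design.groups_of(table.sample_ids)
    keep = np.isin(labels, groups)
    sub = AbundanceTable(data=table.data.loc[keep], mode=table.mode, level=table.level)
    assignments = design.assignments.loc[sub.sample_ids]
    return sub, assignments
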