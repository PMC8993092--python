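"""Tabular readers/writers (TSV, UTF-8, '.' decimal) and the small-RNA
class composition report."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .de import CountMatrix

__all__ = [
    "BIOTYPE_VOCABULARY",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_biotypes",
    "composition_report",
]

BIOTYPE_VOCABULARY = ("miRNA", "lncRNA", "tRNA", "snoRNA", "snRNA", "other")


def read_count_matrix(path) -> CountMatrix:
    """Read a count TSV (first column = miRNA ID, header = sample IDs)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dupes = pd.Index(samples)[pd.Index(samples).duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate sample columns in {path}: {dupes[:5]}")
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate miRNA identifiers in {path}: {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample columns in {path}: {dup[:5]}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as err:
            raise ValueError(f"non-numeric values in column {col!r} of {path}") from err
    if (df.to_numpy() < 0).any():
        bad = df.columns[(df < 0).any(axis=0)].tolist()
        raise ValueError(f"negative counts in columns {bad} of {path}")
    return CountMatrix(df)


def write_count_matrix(counts: CountMatrix, path) -> None:
    out = counts.counts.copy()
    out.index.name = "mirna_id"
    out.to_csv(Path(path), sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id rows in sample sheet")
    if "disease" not in df.columns:
        df["disease"] = "disease"
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(Path(path), sep="\t", index=False)


def read_biotypes(path) -> pd.Series:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"feature_id", "class"} <= set(df.columns):
        raise ValueError("biotype table needs feature_id and class columns")
    bad = set(df["class"]) - set(BIOTYPE_VOCABULARY)
    if bad:
        raise ValueError(f"unknown biotype classes: {sorted(bad)}")
    return df.set_index("feature_id")["class"]


def composition_report(
    counts: CountMatrix,
    biotypes: pd.Series,
    grouping: pd.Series | None = None,
) -> pd.DataFrame:
    """Percentage of total counts per small-RNA class, per sample group.

    ``biotypes`` maps feature IDs to class labels; unannotated features are
    assigned 'other'. ``grouping`` maps sample IDs to group labels (e.g. the
    disease); None pools all samples into one group. Percentages sum to 100
    within each group.
    """
    classes = biotypes.reindex(counts.mirnas).fillna("other")
    bad = set(classes) - set(BIOTYPE_VOCABULARY)
    if bad:
        raise ValueError(f"unknown biotype classes: {sorted(bad)}")
    if grouping is None:
        grouping = pd.Series("all", index=counts.samples)
    else:
        grouping = pd.Series(grouping).reindex(counts.samples)
        if grouping.isna().any():
            raise ValueError("grouping missing for some samples")

    per_class = counts.counts.groupby(classes.to_numpy()).sum()
    per_group = per_class.T.groupby(grouping.to_numpy()).sum().T  # class x group
    totals = per_group.sum(axis=0)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"groups with zero total counts: {empty}")
    pct = per_group / totals * 100.0
    pct.index.name = "class"
    pct.columns.name = "group"
    return pct
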