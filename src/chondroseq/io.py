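"""Readers and writers for the package's tabular formats.

Primary dialect is TSV throughout: count matrices (first column
``gene_id``, one column per sample), sample sheets, DE tables, truth
tables. Gene sets are read from one-id-per-line text files (``#``
comments and blank lines ignored) or Broad-convention GMT (tab-separated
name, description, members). Reports are JSON with a schema version.
"""

from __future__ import annotations

import json
import pathlib
import warnings

import numpy as np
import pandas as pd

from .geneset import GeneSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_de_table",
    "write_de_table",
    "read_gene_list",
    "read_gmt",
    "read_gene_sets",
]

DE_COLUMNS = ["gene_id", "base_mean", "lfc", "se", "wald", "p", "padj", "significant"]


def read_counts(path) -> pd.DataFrame:
    """Read and validate a gene x sample count matrix from TSV.

    Every cell must be a nonnegative integer; violations are reported
    with the offending gene and sample. Duplicate gene or sample ids and
    empty files are errors. CRLF and LF line endings are equivalent.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty count matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: a count matrix needs at least 2 samples")
    values = df.to_numpy()
    numeric = pd.to_numeric(values.ravel(), errors="coerce").reshape(values.shape)
    bad = ~np.isfinite(numeric) | (numeric != np.floor(numeric)) | (numeric < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: cell ({df.index[i]!r}, {df.columns[j]!r}) = "
            f"{values[i, j]!r} is not a nonnegative integer"
        )
    out = pd.DataFrame(numeric.astype(np.int64), index=df.index, columns=df.columns)
    out.index.name = "gene_id"
    return out


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_de_table(table: pd.DataFrame, path) -> None:
    table[DE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing columns {missing}")
    return df


def read_gene_list(path) -> GeneSet:
    """One gene id per line; '#' comments and blank lines ignored."""
    path = pathlib.Path(path)
    members = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            members.append(line)
    if not members:
        raise ValueError(f"{path}: no gene ids after parsing")
    return GeneSet(name=path.stem, members=tuple(members), provenance=str(path))


def read_gmt(path) -> list[GeneSet]:
    """Broad-convention GMT: name <tab> description <tab> member ids."""
    path = pathlib.Path(path)
    sets = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT rows need name, description and >= 1 member"
            )
        name, description, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(
            name=name, members=tuple(members),
            provenance=f"{path} ({description})" if description else str(path),
        ))
    if not sets:
        raise ValueError(f"{path}: no gene sets after parsing")
    return sets


def read_gene_sets(path) -> list[GeneSet]:
    """Dispatch on extension: .gmt files may carry several sets."""
    if str(path).lower().endswith(".gmt"):
        return read_gmt(path)
    return [read_gene_list(path)]


def write_json_report(obj: dict, path) -> None:
    obj = {"schema_version": 1, **obj}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    warnings.warn(f"JSON-serialising {type(o)} via str()", stacklevel=2)
    return str(o)
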