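"""Delimited-text I/O for screen plate tables, count matrices and colony counts.

All outputs are plain TSV/CSV with an optional leading ``#``-comment header
that records the run's config hash and seed, so that every file is traceable
to the run that produced it and round-trips through the readers unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

PLATE_META_COLUMNS = ["plate", "well", "target", "role"]
ROLES = {"library", "nt", "positive"}


def config_hash(config: Mapping) -> str:
    """Short stable hash of a JSON-serializable config mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _meta_header(meta: Mapping | None) -> str:
    if not meta:
        return ""
    fields = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# reprophen {fields}\n"


def write_table(df: pd.DataFrame, path: str | Path, meta: Mapping | None = None,
                index: bool = False) -> Path:
    """Write a DataFrame as TSV with an optional ``#`` metadata header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns of a plate table."""
    return [c for c in table.columns if c not in PLATE_META_COLUMNS
            and c not in ("replicate",)]


def validate_plate_table(table: pd.DataFrame) -> None:
    """Check the plate-table schema; raise ``ValueError`` naming the problem."""
    missing = [c for c in PLATE_META_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"plate table missing columns: {missing}")
    feats = feature_columns(table)
    if not feats:
        raise ValueError("plate table has no feature columns")
    for plate, sub in table.groupby("plate"):
        if sub["well"].duplicated().any():
            dup = sub.loc[sub["well"].duplicated(), "well"].iloc[0]
            raise ValueError(f"duplicate well {dup!r} on plate {plate!r}")
    bad_roles = set(table["role"].unique()) - ROLES
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}")
    non_numeric = [c for c in feats
                   if not pd.api.types.is_numeric_dtype(table[c])]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")


def write_screen(tables: Mapping[tuple[int, int], pd.DataFrame],
                 outdir: str | Path, meta: Mapping | None = None) -> list[Path]:
    """Write one TSV per (plate, replicate) under ``outdir``."""
    outdir = Path(outdir)
    paths = []
    for (plate, rep), df in sorted(tables.items()):
        paths.append(write_table(df, outdir / f"plate{plate}_rep{rep}.tsv", meta))
    return paths


def read_screen(indir: str | Path) -> dict[tuple[int, int], pd.DataFrame]:
    """Read all ``plate*_rep*.tsv`` tables from a directory."""
    indir = Path(indir)
    tables: dict[tuple[int, int], pd.DataFrame] = {}
    for path in sorted(indir.glob("plate*_rep*.tsv")):
        stem = path.stem  # e.g. plate3_rep2
        plate = int(stem.split("_")[0].removeprefix("plate"))
        rep = int(stem.split("_")[1].removeprefix("rep"))
        df = read_table(path)
        validate_plate_table(df)
        tables[(plate, rep)] = df
    if not tables:
        raise ValueError(f"no plate tables found in {indir}")
    return tables


def write_counts(counts: pd.DataFrame, samples: pd.DataFrame,
                 outdir: str | Path, meta: Mapping | None = None) -> tuple[Path, Path]:
    """Write a gene-by-sample count matrix plus its sample sheet."""
    outdir = Path(outdir)
    p1 = write_table(counts.rename_axis("gene"), outdir / "counts.tsv",
                     meta, index=True)
    p2 = write_table(samples, outdir / "samples.tsv", meta)
    return p1, p2


def read_counts(counts_path: str | Path,
                samples_path: str | Path | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a count matrix (TSV gene-by-sample, or MatrixMarket triplet).

    For ``.mtx`` input, row/column names are read from sidecar files
    ``<stem>.genes.txt`` and ``<stem>.samples.txt``.
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        from scipy.io import mmread
        mat = mmread(counts_path).toarray()
        genes = Path(counts_path.with_suffix("")).with_suffix(".genes.txt")
        cols = Path(counts_path.with_suffix("")).with_suffix(".samples.txt")
        gene_names = genes.read_text().split()
        col_names = cols.read_text().split()
        counts = pd.DataFrame(mat, index=gene_names, columns=col_names)
    else:
        counts = read_table(counts_path, index_col=0)
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids in count matrix")
    samples = read_table(samples_path) if samples_path is not None else None
    return counts, samples


def write_colony_counts(table: pd.DataFrame, path: str | Path,
                        meta: Mapping | None = None) -> Path:
    return write_table(table, path, meta)


def read_colony_counts(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in ("condition", "replicate", "count") if c not in df.columns]
    if missing:
        raise ValueError(f"colony table missing columns: {missing}")
    if (df["count"] < 0).any():
        raise ValueError("negative colony counts")
    return df
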