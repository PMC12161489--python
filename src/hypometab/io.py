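"""Reading and writing the delimited-text formats the pipeline touches.

Expression matrices, clinical tables and metabolite panels travel as
TSV/CSV (delimiter sniffed from the file extension); gene-set collections
travel as GMT.  Every reader validates on ingestion and either raises or
logs — samples are never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("hypometab")

#: missing-value spellings accepted on input; "NA" is always emitted.
NA_TOKENS = ["NA", "NaN", "nan", ""]
NA_OUT = "NA"

_TIME_COLS = ("time_os", "time_dss", "time_rfs")
_EVENT_COLS = ("event_os", "event_dss", "event_rfs")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes x samples, with unique string ids."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        all_na = df.columns[df.isna().all(axis=0)]
        if len(all_na):
            raise FormatError(f"samples with no data: {list(all_na)[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> (description, member gene symbols)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        if not self.sets:
            raise FormatError("no gene sets")
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            seen: set[str] = set()
            deduped = [g for g in genes if not (g in seen or seen.add(g))]
            if len(deduped) != len(genes):
                logger.warning(
                    "gene set %s: removed %d duplicate symbols",
                    name, len(genes) - len(deduped),
                )
                self.sets[name] = (self.sets[name][0], deduped)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: survival endpoints + covariates.

    Columns are a subset of: time_os/dss/rfs (months, nonnegative),
    event_os/dss/rfs (0/1/NA), grade, stage (ordinal or NA), pam50.
    """

    table: pd.DataFrame  # index: sample ids

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids in clinical table")
        for col in _TIME_COLS:
            if col in df.columns:
                t = pd.to_numeric(df[col], errors="coerce")
                if (t.dropna() < 0).any():
                    bad = df.index[t < 0][0]
                    raise FormatError(f"negative {col} for sample {bad!r}")
                df[col] = t
        for col in _EVENT_COLS:
            if col in df.columns:
                e = pd.to_numeric(df[col], errors="coerce")
                ok = e.dropna().isin([0, 1])
                if not ok.all():
                    bad = df.index[e.notna() & ~e.isin([0, 1])][0]
                    raise FormatError(
                        f"{col} outside {{0,1}} for sample {bad!r}"
                    )
                df[col] = e

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def endpoint(self, name: str) -> tuple[pd.Series, pd.Series]:
        """Return (time, event) for endpoint 'os', 'dss' or 'rfs',
        restricted to samples with both fields present."""
        tcol, ecol = f"time_{name}", f"event_{name}"
        if tcol not in self.table.columns or ecol not in self.table.columns:
            raise KeyError(f"endpoint {name!r} not present in clinical table")
        sub = self.table[[tcol, ecol]].dropna()
        return sub[tcol], sub[ecol].astype(int)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_frame(path: str | Path) -> pd.DataFrame:
    """Delimited text -> DataFrame of strings, first column as index."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))
    names = [h.strip() for h in header[1:]]
    dups = {n for n in names if names.count(n) > 1}
    if dups:
        # pandas would silently mangle repeated header names
        raise FormatError(f"{path}: duplicate column ids {sorted(dups)[:5]}")
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str,
        keep_default_na=False,
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return df


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Convert a string frame to floats; name the offending cell on failure."""
    out = df.mask(df.isin(NA_TOKENS))
    try:
        return out.astype(float)
    except ValueError:
        for col in out.columns:
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = coerced.isna() & out[col].notna()
            if bad.any():
                row = out.index[bad][0]
                raise FormatError(
                    f"{path}: non-numeric value {out.loc[row, col]!r} "
                    f"at row {row!r}, column {col!r}"
                ) from None
        raise


def read_expression(
    path: str | Path, orientation: str = "genes_rows"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV/CSV.

    ``orientation`` states explicitly whether rows are genes or samples —
    auto-detection is deliberately not attempted.  Duplicate gene rows are
    collapsed by their mean (count logged); duplicate sample ids are an
    error.
    """
    if orientation not in ("genes_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_frame(path), path)
    if orientation == "samples_rows":
        df = df.T
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups[:5]}")
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.warning(
            "%s: collapsed %d duplicate gene rows by mean", path, n_dup
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected name, description and "
                    f"at least one gene, got {len(fields)} fields"
                )
            name, desc, genes = fields[0], fields[1], [
                g.strip() for g in fields[2:] if g.strip()
            ]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = (desc, genes)
    if not sets:
        raise FormatError(f"{path}: no gene sets")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in collection:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    df = _read_frame(path)
    return ClinicalTable(df.mask(df.isin(NA_TOKENS)))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a numeric features x samples table (deregulation, metabolites)."""
    return _to_numeric(_read_frame(path), path)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a mixed-type output table back (scores, types, fingerprints),
    with pandas' usual dtype inference and "NA" as missing."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     na_values=NA_TOKENS, keep_default_na=False)
    df.index = df.index.astype(str).str.strip()
    return df


def write_table(obj, path: str | Path, index_label: str | None = None) -> None:
    """Write a DataFrame (or container exposing one) as delimited text.

    Floats are written with pandas' shortest-round-trip representation, so
    write-then-read is the identity up to 1e-12; NA is emitted as "NA".
    """
    if isinstance(obj, ExpressionMatrix):
        df, index_label = obj.values, index_label or "gene_id"
    elif isinstance(obj, ClinicalTable):
        df, index_label = obj.table, index_label or "sample_id"
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:  # containers with a .table DataFrame (ScoreTable, assignments, ...)
        df = obj.table
        index_label = index_label or "sample_id"
    df.to_csv(path, sep=_sep_for(path), na_rep=NA_OUT,
              index_label=index_label or df.index.name or "id")
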