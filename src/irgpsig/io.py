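"""Reading and harmonizing expression matrices, clinical tables, and gene lists.

Conventions used throughout the package:

* An *expression matrix* is a :class:`pandas.DataFrame` with genes in rows
  (unique index of gene identifiers) and samples in columns (unique column
  labels).  Values are numeric; units are arbitrary but consistent within a
  sample — the downstream pair indicators only use within-sample orderings.
* A *clinical table* is a :class:`pandas.DataFrame` indexed by sample id with
  at least ``time`` (survival time in **years**) and ``event`` (1 = death,
  0 = censored) columns, plus optional covariates (``age`` in years;
  ``gender``, ``grade``, ``stage`` categorical).
* A *gene list* is an ordered list of unique gene symbols.

Gene identifiers are matched case-sensitively by exact string; no alias
resolution is attempted.  Missing values are rejected at read time rather
than imputed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "read_clinical",
    "read_gene_list",
    "collapse_duplicates",
    "restrict_to_gene_list",
    "align_cohort",
]

#: factors converting a declared time unit to years
_TIME_UNIT_TO_YEARS = {"days": 1.0 / 365.25, "months": 1.0 / 12.0, "years": 1.0}


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def read_expression(
    path: str | Path,
    format: str | None = None,
    orientation: str = "genes_in_rows",
) -> pd.DataFrame:
    """Read a delimited expression file into canonical genes × samples form.

    Parameters
    ----------
    path:
        TSV/CSV file whose first column holds row identifiers and whose
        header holds column identifiers.
    format:
        ``"tsv"`` or ``"csv"``; inferred from the file suffix when omitted.
    orientation:
        ``"genes_in_rows"`` (canonical) or ``"samples_in_rows"`` (the file
        is transposed and will be flipped into canonical orientation).

    Raises
    ------
    ValueError
        On duplicate identifiers or any cell that does not parse as a
        finite number (the offending row/column is named).
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, format)
    # pandas silently renames duplicate header entries; check the raw header
    raw_header = pd.read_csv(path, sep=sep, header=None, nrows=1,
                             dtype=str).iloc[0, 1:]
    if raw_header.duplicated().any():
        dup = raw_header[raw_header.duplicated()].iloc[0]
        what = "sample" if orientation == "genes_in_rows" else "gene"
        raise ValueError(
            f"duplicate {what} identifier {dup!r} in {path.name}; collapse "
            "explicitly with collapse_duplicates"
        )
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    if orientation == "samples_in_rows":
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(
            f"duplicate gene identifier {dup!r} in {path.name}; collapse probes "
            "explicitly with collapse_duplicates"
        )
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(
            f"duplicate sample identifier {dup!r} in {path.name}; collapse records "
            "explicitly with collapse_duplicates"
        )
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing expression value {df.iat[i, j]!r} at "
            f"gene {df.index[i]!r}, sample {df.columns[j]!r} in {path.name}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = "gene"
    return numeric


def read_clinical(
    path: str | Path,
    format: str | None = None,
    time_unit: str = "years",
) -> pd.DataFrame:
    """Read a clinical table and convert survival times to years.

    The file must contain ``sample_id``, ``time`` and ``event`` columns;
    any further columns are carried along as covariates.
    """
    path = Path(path)
    if time_unit not in _TIME_UNIT_TO_YEARS:
        raise ValueError(f"unknown time unit {time_unit!r}; expected one of "
                         f"{sorted(_TIME_UNIT_TO_YEARS)}")
    df = pd.read_csv(path, sep=_sep_for(path, format))
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical file {path.name} lacks required column {col!r}")
    df = df.set_index(df["sample_id"].astype(str)).drop(columns="sample_id")
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample_id {dup!r} in {path.name}")
    df["time"] = pd.to_numeric(df["time"]) * _TIME_UNIT_TO_YEARS[time_unit]
    df["event"] = pd.to_numeric(df["event"])
    if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
        bad = df.index[~(df["time"] > 0)][0]
        raise ValueError(f"non-positive or missing survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.index[~df["event"].isin([0, 1])][0]
        raise ValueError(f"event flag for sample {bad!r} is not 0/1")
    df["event"] = df["event"].astype(int)
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list (one symbol per line, ``#`` comments)."""
    symbols: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            symbols[sym] = None
    if not symbols:
        raise ValueError(f"gene list {Path(path).name} is empty")
    return list(symbols)


def _collapse_axis(df: pd.DataFrame, mapping: Mapping[str, str] | None,
                   axis: int, what: str) -> pd.DataFrame:
    if mapping is None:
        return df
    ids = df.index if axis == 0 else df.columns
    missing = [i for i in ids if i not in mapping]
    if missing:
        raise ValueError(f"{what} {missing[0]!r} has no entry in its mapping")
    targets = [mapping[i] for i in ids]
    order = list(dict.fromkeys(targets))
    if axis == 0:
        out = df.set_axis(targets, axis=0).groupby(level=0, sort=False).mean()
        out = out.loc[order]
        out.index.name = df.index.name
    else:
        out = df.T.set_axis(targets, axis=0).groupby(level=0, sort=False).mean().T
        out = out.loc[:, order]
    return out


def collapse_duplicates(
    m: pd.DataFrame,
    gene_map: Mapping[str, str] | None = None,
    sample_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Average multi-probe genes and multi-record patients.

    ``gene_map`` maps each probe (row id) to a gene; probes sharing a gene
    are averaged per sample.  ``sample_map`` maps each record (column id) to
    a patient; records sharing a patient are averaged per gene.  ``None``
    means identity (no collapsing on that axis).  Output identifiers keep
    first-occurrence order.
    """
    out = _collapse_axis(m, gene_map, axis=0, what="probe")
    out = _collapse_axis(out, sample_map, axis=1, what="record")
    return out


def restrict_to_gene_list(m: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Keep only rows whose gene id is in ``genes``, preserving matrix order."""
    wanted = set(genes)
    keep = [g for g in m.index if g in wanted]
    if not keep:
        raise ValueError("no genes of the expression matrix appear in the gene list")
    return m.loc[keep]


def align_cohort(
    m: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict expression and clinical data to their shared samples.

    Both outputs carry the shared samples in the expression matrix's column
    order, so downstream per-sample arrays line up positionally.
    """
    shared = [s for s in m.columns if s in set(clinical.index)]
    if not shared:
        raise ValueError("expression and clinical tables share no samples")
    return m.loc[:, shared], clinical.loc[shared]
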