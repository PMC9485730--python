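"""Readers/writers for the tabular formats the pipeline touches.

Gene-level expression lives in an :class:`ExpressionMatrix` (genes x samples,
log2 scale); survival and clinical covariates in a :class:`ClinicalTable`;
gene sets for over-representation in a :class:`GeneSetCollection`.

Conventions
-----------
* All files are UTF-8, tab-separated, '.' decimal.
* Gene symbols are case-normalized to uppercase on read.
* Duplicate gene symbols are collapsed to the row with maximal mean
  expression (the usual array convention when probes map to one symbol).
* Expression values are assumed already log2-transformed; pass
  ``log2_transform=True`` to apply log2(x+1) on read.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

# Controlled vocabularies (clinical staging / grading)
T_STAGES = ("T1", "T2", "T3", "T4")
N_STAGES = ("N0", "N1", "N2", "N3")
TNM_STAGES = ("Stage I", "Stage II", "Stage III")
GRADES = ("Poorly", "Moderately", "Well")

CLINICAL_COLUMNS = (
    "os_time",
    "os_event",
    "sex",
    "age",
    "tobacco",
    "alcohol",
    "t_stage",
    "n_stage",
    "tnm_stage",
    "grade",
)


@dataclass
class ExpressionMatrix:
    """log2 expression, genes x samples.

    ``values`` is a DataFrame indexed by unique gene symbols with unique
    sample-ID columns; ``metadata`` is a free key-value store.
    """

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups}")
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dups}")
        if not all(np.issubdtype(dt, np.number) for dt in self.values.dtypes):
            raise ValidationError("expression values must be numeric")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], dict(self.metadata))

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], dict(self.metadata))


@dataclass
class ClinicalTable:
    """Per-sample survival outcome plus clinical covariates.

    ``data`` is indexed by sample ID. ``os_time`` (months, > 0) and
    ``os_event`` (0/1) are mandatory; covariates may be missing (NaN) but,
    when present, staging/grade fields must come from the controlled
    vocabularies (T1-T4, N0-N3, Stage I-III, Poorly/Moderately/Well).
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise ValidationError(f"missing mandatory column {col!r}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample IDs in clinical table")
        if df["os_time"].isna().any() or (df["os_time"] <= 0).any():
            bad = df.index[df["os_time"].isna() | (df["os_time"] <= 0)].tolist()
            raise ValidationError(f"os_time must be > 0; offending samples: {bad}")
        ev = df["os_event"]
        if ev.isna().any() or not ev.isin([0, 1]).all():
            bad = df.index[~ev.isin([0, 1])].tolist()
            raise ValidationError(f"os_event must be 0/1; offending samples: {bad}")
        for col, vocab in (
            ("t_stage", T_STAGES),
            ("n_stage", N_STAGES),
            ("tnm_stage", TNM_STAGES),
            ("grade", GRADES),
        ):
            if col in df.columns:
                vals = df[col].dropna()
                bad = vals[~vals.isin(vocab)]
                if len(bad):
                    raise ValidationError(
                        f"{col} values outside {vocab}: {sorted(set(bad))}"
                    )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(m.upper() for m in members))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name) -> list[str]:
        return self.sets[name]


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene symbols, keeping the row with maximal mean.

    Order-independent: ties broken by the symbol's first occurrence after a
    stable sort on (-mean), so permuting the input rows cannot change the
    surviving values.
    """
    if not df.index.duplicated().any():
        return df
    means = df.mean(axis=1).to_numpy()
    keep: dict[str, int] = {}
    best: dict[str, float] = {}
    for i, (sym, m) in enumerate(zip(df.index, means)):
        if sym not in best or m > best[sym]:
            best[sym] = m
            keep[sym] = i
    order = dict.fromkeys(df.index)  # first-occurrence order of symbols
    rows = [keep[sym] for sym in order]
    out = df.iloc[rows]
    return out


def _check_unique_header(path) -> None:
    """pandas mangles duplicate column names on read, so inspect the raw
    header line first."""
    if hasattr(path, "readline"):
        pos = path.tell()
        line = path.readline()
        path.seek(pos)
    else:
        with open(path, encoding="utf-8") as fh:
            line = fh.readline()
    cols = line.rstrip("\n").split("\t")[1:]
    dups = sorted({c for c in cols if cols.count(c) > 1})
    if dups:
        raise FormatError(f"{path}: duplicate sample IDs {dups}")


def read_expression_tsv(path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene symbol, header = sample IDs)."""
    _check_unique_header(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, header=0)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression table")
    if raw.columns.duplicated().any():
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample IDs {dups}")
    cols = {}
    for j, col in enumerate(raw.columns):
        try:
            cols[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError):
            for i, v in enumerate(raw[col]):
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"{path}: non-numeric value {v!r} at gene "
                        f"{raw.index[i]!r} (row {i + 2}), sample {col!r} "
                        f"(column {j + 2})"
                    ) from None
            raise
    df = pd.DataFrame(cols, index=raw.index.astype(str).str.upper())
    df = _collapse_duplicates(df)
    if log2_transform:
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, {"source": str(path)})


def write_expression_tsv(em: ExpressionMatrix, path) -> None:
    em.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_series_matrix(path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read the GEO series-matrix dialect: !-prefixed headers and an
    expression table delimited by !series_matrix_table_begin/end.

    Returns the expression matrix plus a sample-annotation frame built from
    the ``!Sample_*`` header lines (one row per annotation line, columns =
    samples, quoting stripped).
    """
    header_lines: list[list[str]] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = saw_end = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table, saw_begin = True, True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table, saw_end = False, True
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                fields = [f.strip('"') for f in line.split("\t")]
                header_lines.append(fields)
    if not (saw_begin and saw_end):
        raise FormatError(
            f"{path}: missing !series_matrix_table_begin/end delimiters"
        )
    if not table_lines:
        raise FormatError(f"{path}: empty series-matrix table")
    buf = io.StringIO("\n".join(table_lines).replace('"', ""))
    em = read_expression_tsv(buf)
    em.metadata["source"] = str(path)
    ann_rows = {}
    counts: dict[str, int] = {}
    for fields in header_lines:
        key = fields[0].lstrip("!")
        counts[key] = counts.get(key, 0) + 1
        name = key if counts[key] == 1 else f"{key}.{counts[key]}"
        ann_rows[name] = fields[1:]
    annotations = pd.DataFrame.from_dict(ann_rows, orient="index")
    if not annotations.empty:
        annotations.columns = em.samples[: annotations.shape[1]]
    return em, annotations


_HEADER_WORDS = {"SYMBOL", "GENE", "GENE_SYMBOL", "GENES", "ID"}


def read_symbol_list(path) -> set[str]:
    """Read a one-symbol-per-line list (ImmPort-style); dedup, uppercase."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    symbols = [ln.upper() for ln in lines if ln]
    if symbols and symbols[0] in _HEADER_WORDS:
        symbols = symbols[1:]
    out = set(symbols)
    if not out:
        raise FormatError(f"{path}: no gene symbols found")
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields (< 3)"
                )
            name, desc, *members = fields
            sets[name] = [m for m in members if m]
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def _to_number(v, col, sample):
    try:
        return float(v)
    except (ValueError, TypeError):
        raise ParseError(f"non-numeric {col} {v!r} for sample {sample!r}") from None


def read_clinical_tsv(path) -> ClinicalTable:
    """Read a clinical TSV with mandatory os_time/os_event and optional
    vocabulary-checked covariates."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: empty clinical table")
    for col in ("os_time", "os_event"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing mandatory column {col!r}")
    out = pd.DataFrame(index=df.index.astype(str))
    out["os_time"] = [
        _to_number(v, "os_time", s) for s, v in zip(df.index, df["os_time"])
    ]
    events = []
    for s, v in zip(df.index, df["os_event"]):
        x = _to_number(v, "os_event", s)
        if x not in (0.0, 1.0):
            raise ValidationError(f"{path}: os_event {v!r} for sample {s!r} not 0/1")
        events.append(int(x))
    out["os_event"] = events
    for col in CLINICAL_COLUMNS[2:]:
        if col in df.columns:
            if col == "age":
                out[col] = [
                    math.nan if pd.isna(v) else _to_number(v, "age", s)
                    for s, v in zip(df.index, df[col])
                ]
            else:
                out[col] = df[col].where(~df[col].isna(), other=np.nan)
    return ClinicalTable(out)


def write_clinical_tsv(ct: ClinicalTable, path) -> None:
    ct.data.to_csv(path, sep="\t", index_label="sample", float_format="%.6g")
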