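"""Readers, writers and validated domain types for every external format.

The pipeline exchanges four kinds of files:

* expression matrices — TSV, genes as rows, samples as columns, values on a
  ``log2(normalized expression + 1)`` scale;
* gene sets — standard GMT (``name<TAB>description<TAB>gene...``);
* sample metadata — TSV with a fixed header covering anatomical region,
  diagnostic label, survival, and control/treated pairing;
* qPCR Ct tables — CSV with one row per (subject, condition, gene, replicate).

All readers validate on load and fail loudly with file/line context; nothing
is silently dropped. Gene symbols are matched case-sensitively and exactly —
no alias resolution is attempted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "GliosigWarning",
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_ct_csv",
    "write_ct_csv",
]

#: Anatomical region vocabulary (anatomically dissected glioblastoma
#: compartments): leading edge, infiltrating tumor, cellular tumor,
#: microvascular proliferation, pseudopalisading cells around necrosis.
REGIONS = ("LE", "IT", "CT", "MVP", "PAN")

METADATA_COLUMNS = (
    "sample_id",
    "region",
    "diagnostic_label",
    "survival_time",
    "event",
    "subject_id",
    "condition",
)

CT_COLUMNS = ("subject_id", "condition", "gene", "ct", "replicate")

_NA_TOKENS = {"", "NA", "nan", "NaN"}


class GliosigWarning(UserWarning):
    """Base warning category for non-fatal data issues."""


class FormatError(ValueError):
    """A file violated its format contract; message carries file/line context."""


def _is_na(token: object) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and math.isnan(token):
        return True
    return str(token).strip() in _NA_TOKENS


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """A validated gene-by-sample expression matrix on the log2 scale.

    Parameters
    ----------
    data:
        DataFrame with gene symbols as the index and sample identifiers as
        columns. Values must be finite floats; duplicate gene or sample ids
        are rejected; the matrix must be at least 2 x 2.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        if data.shape[0] < 2 or data.shape[1] < 2:
            raise FormatError(
                f"expression matrix must be at least 2 genes x 2 samples, got {data.shape}"
            )
        values = data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite value at gene {data.index[bad[0]]!r}, "
                f"sample {data.columns[bad[1]]!r}"
            )
        self.data = data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)])

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def read_expression_tsv(path: str | Path, log2_transform: bool = False) -> ExpressionMatrix:
    """Read a genes-as-rows TSV expression matrix.

    The first column holds gene symbols; the header row holds sample ids.
    With ``log2_transform=True`` raw values ``x`` are replaced by
    ``log2(x + 1)`` on load (for count-scale inputs).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing cell at gene {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if log2_transform:
        numeric = np.log2(numeric + 1.0)
    try:
        return ExpressionMatrix(numeric)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(Path(path), sep="\t", index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene symbols."""

    name: str
    description: str = ""
    genes: frozenset[str] = field(default_factory=frozenset)
    empty_allowed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes and not self.empty_allowed:
            raise FormatError(f"gene set {self.name!r} is empty")
        if not self.genes and self.empty_allowed:
            warnings.warn(f"gene set {self.name!r} is empty", GliosigWarning, stacklevel=2)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(sorted(self.genes))

    def intersect(self, other: "GeneSet | Iterable[str]") -> frozenset[str]:
        other_genes = other.genes if isinstance(other, GeneSet) else frozenset(other)
        return self.genes & other_genes


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one gene set per line, name TAB description TAB genes."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            raw_genes = [g for g in fields[2:] if g.strip()]
            unique = frozenset(raw_genes)
            if len(unique) < len(raw_genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} collapsed",
                    GliosigWarning,
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, description=description, genes=unique,
                                empty_allowed=True))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for gs in gene_sets:
            fields = [gs.name, gs.description, *sorted(gs.genes)]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def _validate_metadata(df: pd.DataFrame, context: str = "metadata") -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{context}: missing columns {missing}")
    df = df.loc[:, list(METADATA_COLUMNS)].copy()
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{context}: duplicate sample ids: {dupes[:5]}")

    for i, row in df.iterrows():
        line = f"{context}: sample {row['sample_id']!r}"
        if not _is_na(row["region"]) and row["region"] not in REGIONS:
            raise FormatError(
                f"{line}: unknown region {row['region']!r}; expected one of {REGIONS} or NA"
            )
        if not _is_na(row["diagnostic_label"]) and row["diagnostic_label"] not in (
            "case",
            "control",
        ):
            raise FormatError(
                f"{line}: diagnostic_label must be case/control/NA, got {row['diagnostic_label']!r}"
            )
        if not _is_na(row["condition"]) and row["condition"] not in ("control", "treated"):
            raise FormatError(
                f"{line}: condition must be control/treated/NA, got {row['condition']!r}"
            )
        if not _is_na(row["event"]):
            ev = float(row["event"])
            if ev not in (0.0, 1.0):
                raise FormatError(f"{line}: event must be 0, 1 or NA, got {row['event']!r}")
            if ev == 1.0 and _is_na(row["survival_time"]):
                raise FormatError(f"{line}: event=1 requires survival_time")
        if not _is_na(row["survival_time"]) and float(row["survival_time"]) < 0:
            raise FormatError(f"{line}: survival_time must be >= 0")

    out = df.copy()
    out["region"] = [None if _is_na(v) else str(v) for v in df["region"]]
    out["diagnostic_label"] = [None if _is_na(v) else str(v) for v in df["diagnostic_label"]]
    out["condition"] = [None if _is_na(v) else str(v) for v in df["condition"]]
    out["survival_time"] = [
        np.nan if _is_na(v) else float(v) for v in df["survival_time"]
    ]
    out["event"] = [np.nan if _is_na(v) else float(v) for v in df["event"]]
    out["sample_id"] = df["sample_id"].astype(str)
    out["subject_id"] = [None if _is_na(v) else str(v) for v in df["subject_id"]]
    return out.reset_index(drop=True)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample metadata TSV.

    Returns a DataFrame with the fixed columns ``sample_id, region,
    diagnostic_label, survival_time, event, subject_id, condition``; missing
    values (empty cell or ``NA``) become None/NaN.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return _validate_metadata(df, context=str(path))


def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.loc[:, list(METADATA_COLUMNS)].copy()

    def fmt(v: object) -> str:
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return "NA"
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    out = out.map(fmt)
    out.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def _validate_ct(df: pd.DataFrame, context: str = "ct table") -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{context}: missing columns {missing}")
    df = df.loc[:, list(CT_COLUMNS)].copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if df["ct"].isna().any() or not np.isfinite(df["ct"]).all():
        bad = df.index[~np.isfinite(df["ct"].fillna(np.nan))][0]
        raise FormatError(f"{context}: non-numeric or non-finite ct at row {bad + 2}")
    if (df["ct"] <= 0).any():
        bad = df.index[df["ct"] <= 0][0]
        raise FormatError(f"{context}: ct must be > 0 at row {bad + 2}")
    bad_cond = ~df["condition"].isin(["control", "treated"])
    if bad_cond.any():
        bad = df.index[bad_cond][0]
        raise FormatError(
            f"{context}: condition must be control/treated at row {bad + 2}, "
            f"got {df.loc[bad, 'condition']!r}"
        )
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    if df["replicate"].isna().any():
        bad = df.index[df["replicate"].isna()][0]
        raise FormatError(f"{context}: non-integer replicate at row {bad + 2}")
    df["replicate"] = df["replicate"].astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    return df.reset_index(drop=True)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table CSV with columns subject_id, condition, gene, ct, replicate."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return _validate_ct(df, context=str(path))


def write_ct_csv(ct: pd.DataFrame, path: str | Path) -> None:
    ct.loc[:, list(CT_COLUMNS)].to_csv(Path(path), index=False, float_format="%.10g")
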