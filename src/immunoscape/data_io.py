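"""Readers, writers and validated domain types for all external formats.

Expression matrices are genes x samples TSV (or MatrixMarket triplets with
sidecar gene/sample lists), gene sets are standard GMT, clinical tables are
TSV.  Everything is tab-separated UTF-8 with "." as the decimal point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


class ParseError(ValueError):
    """A file does not conform to its format."""


class SchemaError(ValueError):
    """A table is missing required columns."""


#: Anatomic primary-site -> side mapping; rectum counts as left.
DEFAULT_SIDE_MAP: Mapping[str, str] = {
    "cecum": "right",
    "ascending colon": "right",
    "hepatic flexure": "right",
    "transverse colon": "right",
    "splenic flexure": "left",
    "descending colon": "left",
    "sigmoid colon": "left",
    "rectum": "left",
    "right": "right",
    "left": "left",
    "unknown": "unknown",
}

SIDE_LEVELS = ("left", "right", "unknown")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples normalized expression; non-negative, finite, unique ids."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 1:
            raise ValidationError(
                f"expression matrix needs >= 2 genes and >= 1 sample, got {df.shape}"
            )
        arr = df.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression at gene {df.index[gi]!r}, sample {df.columns[si]!r}"
            )
        if (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression {arr[gi, si]} at gene {df.index[gi]!r}, "
                f"sample {df.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; member order preserved, members unique within a set."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(
                f"gene sets not found: {missing}; available: {sorted(self.sets)}"
            )
        return GeneSetCollection(
            {n: list(self.sets[n]) for n in names},
            {n: self.descriptions.get(n, "") for n in names},
        )


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical covariates: OS days, event, tumor side, optional flags."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.table
        for col in ("os_days", "event", "side"):
            if col not in df.columns:
                raise SchemaError(f"clinical table missing required column {col!r}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if (df["os_days"] < 0).any():
            bad = df.index[df["os_days"] < 0].tolist()
            raise ValidationError(f"negative os_days for samples {bad}")
        bad_event = ~df["event"].isin([0, 1])
        if bad_event.any():
            raise ValidationError(
                f"event must be 0 or 1; offending samples {df.index[bad_event].tolist()}"
            )
        bad_side = ~df["side"].isin(SIDE_LEVELS)
        if bad_side.any():
            raise ValidationError(
                f"side must be one of {SIDE_LEVELS}; offending samples "
                f"{df.index[bad_side].tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV or MatrixMarket.

    TSV: header row of sample ids, first column of gene symbols.  MTX: the
    triplet file must sit next to ``<stem>.genes.txt`` and
    ``<stem>.samples.txt`` line lists.  Duplicate gene rows are collapsed by
    per-sample maximum with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
            raise ParseError(f"malformed expression TSV {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise ParseError(f"{path}: no sample columns found (header malformed?)")
        non_numeric = df.columns[
            [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
        ].tolist()
        if non_numeric:
            raise ParseError(f"{path}: non-numeric values in columns {non_numeric}")
    elif format == "mtx":
        from scipy.io import mmread

        genes = Path(str(path).replace(".mtx", ".genes.txt"))
        samples = Path(str(path).replace(".mtx", ".samples.txt"))
        if not genes.exists() or not samples.exists():
            raise ParseError(f"{path}: sidecar {genes.name} / {samples.name} not found")
        raw = mmread(str(path))
        mat = np.asarray(raw.todense() if hasattr(raw, "todense") else raw, dtype=float)
        gene_ids = genes.read_text().split()
        sample_ids = samples.read_text().split()
        if mat.shape != (len(gene_ids), len(sample_ids)):
            raise ParseError(
                f"{path}: matrix shape {mat.shape} does not match sidecar lengths "
                f"({len(gene_ids)}, {len(sample_ids)})"
            )
        df = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
    else:
        raise ValueError(f"unknown expression format {format!r}")

    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        warnings.warn(
            f"collapsing duplicate gene rows by per-sample maximum: {dups}",
            stacklevel=2,
        )
        df = df.groupby(level=0, sort=False).max()
    return ExpressionMatrix(df.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line as ``name<TAB>description<TAB>genes...``.

    Duplicate members within a set are dropped (first occurrence kept) with a
    warning; lines with fewer than three fields raise :class:`ParseError`
    naming the line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and at least "
                    f"one member ({len(fields)} fields found)"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            seen: set[str] = set()
            unique: list[str] = []
            for m in members:
                if m in seen:
                    continue
                seen.add(m)
                unique.append(m)
            if len(unique) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: dropped duplicate members in set {name!r}",
                    stacklevel=2,
                )
            sets[name] = unique
            descriptions[name] = desc
    if not sets:
        raise ParseError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical(
    path: str | Path,
    side_map: Mapping[str, str] | None = None,
) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, os_days, event, side.

    ``side`` values are passed through ``side_map`` (default: anatomic sites,
    rectum -> left); unmapped labels become ``unknown`` with a warning.  Extra
    columns (mutation flags, stage, ...) are carried along untouched.
    """
    side_map = dict(DEFAULT_SIDE_MAP if side_map is None else side_map)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"malformed clinical TSV {path}: {exc}") from exc
    required = ["sample_id", "os_days", "event", "side"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")

    os_days = pd.to_numeric(df["os_days"], errors="coerce")
    if os_days.isna().any() or (os_days != os_days.round()).any():
        bad = df.loc[os_days.isna() | (os_days != os_days.round()), "sample_id"].tolist()
        raise ValidationError(f"{path}: non-integer os_days for samples {bad}")
    df["os_days"] = os_days.astype(int)

    mapped = df["side"].astype(str).str.strip().str.lower().map(side_map)
    unknown = mapped.isna()
    if unknown.any():
        labels = sorted(df.loc[unknown, "side"].astype(str).unique())
        warnings.warn(
            f"unrecognized side labels mapped to 'unknown': {labels}", stacklevel=2
        )
        mapped = mapped.fillna("unknown")
    df["side"] = mapped

    return ClinicalTable(df.set_index("sample_id"))


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


def intersect_samples(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to their shared samples, preserving expression order."""
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise ValidationError("expression and clinical tables share no samples")
    return (
        expr.subset_samples(shared),
        ClinicalTable(clinical.table.loc[shared]),
    )
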