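"""Quantification-table data model and TSV I/O.

A :class:`QuantTable` holds a proteins x replicate-columns abundance matrix
together with per-protein metadata (gene symbol, species) and per-column
design metadata (condition, biological sample, technical replicate).
Columns are named ``<condition>_s<sample>_r<replicate>`` with condition
``A`` (angiogenic core) or ``I`` (invasive rim), e.g. ``I_s2_r3``.

Abundances are strictly positive where present; missingness is explicit
(empty cell or ``NA`` on disk, NaN in memory).  Zeros are rejected rather
than silently treated as missing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("A", "I")
META_COLUMNS = ("protein_id", "gene_symbol", "species")
SPECIES = ("human", "mouse")

_COLUMN_RE = re.compile(r"^([AI])_s(\d+)_r(\d+)$")


class QuantTableError(ValueError):
    """Malformed quantification table."""


@dataclass(frozen=True, order=True)
class ColumnKey:
    """Design coordinates of one replicate column."""

    condition: str
    sample: int
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise QuantTableError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.condition}_s{self.sample}_r{self.replicate}"

    @classmethod
    def parse(cls, label: str) -> "ColumnKey":
        m = _COLUMN_RE.match(label)
        if m is None:
            raise QuantTableError(
                f"malformed column header {label!r}: expected "
                "'<A|I>_s<sample>_r<replicate>'"
            )
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


class QuantTable:
    """Proteins x replicate-columns abundance matrix with metadata.

    Parameters
    ----------
    meta:
        DataFrame indexed by unique protein accession with columns
        ``gene_symbol`` and ``species``.
    values:
        Float DataFrame with the same index and one column per
        :class:`ColumnKey` label; NaN marks a missing quantification.
    """

    def __init__(self, meta: pd.DataFrame, values: pd.DataFrame):
        if list(meta.columns) != ["gene_symbol", "species"]:
            raise QuantTableError("meta must have columns gene_symbol, species")
        if meta.index.has_duplicates:
            dup = meta.index[meta.index.duplicated()].unique().tolist()
            raise QuantTableError(f"duplicate protein_id: {dup}")
        if not meta.index.equals(values.index):
            raise QuantTableError("meta and values must share the protein index")
        labels = list(values.columns)
        if len(set(labels)) != len(labels):
            dup = sorted({c for c in labels if labels.count(c) > 1})
            raise QuantTableError(f"duplicate column header: {dup}")
        keys = [ColumnKey.parse(c) for c in labels]
        bad_species = set(meta["species"]) - set(SPECIES)
        if bad_species:
            raise QuantTableError(f"unknown species tag: {sorted(bad_species)}")
        vals = values.astype(float)
        with np.errstate(invalid="ignore"):
            nonpos = (vals.to_numpy() <= 0) & ~np.isnan(vals.to_numpy())
        if nonpos.any():
            r, c = np.argwhere(nonpos)[0]
            raise QuantTableError(
                f"non-positive abundance {vals.iat[r, c]} at protein "
                f"{vals.index[r]!r}, column {labels[c]!r} (encode missing as "
                "empty/NA, not 0)"
            )
        self.meta = meta
        self.values = vals
        self.column_keys = keys

    # -- introspection -------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    def columns_for(self, condition: str, sample: int | None = None) -> list[str]:
        """Labels of the columns of one condition (optionally one sample)."""
        return [
            k.label
            for k in self.column_keys
            if k.condition == condition and (sample is None or k.sample == sample)
        ]

    @property
    def samples(self) -> list[int]:
        return sorted({k.sample for k in self.column_keys})

    def presence_counts(self, condition: str) -> pd.Series:
        """Per-protein count of non-missing cells in one condition."""
        return self.values[self.columns_for(condition)].notna().sum(axis=1)

    # -- derivation ----------------------------------------------------

    def subset_proteins(self, ids: Sequence[str] | pd.Index) -> "QuantTable":
        ids = pd.Index(ids)
        return QuantTable(self.meta.loc[ids], self.values.loc[ids])

    def subset_species(self, species: str) -> "QuantTable":
        if species == "both":
            return self
        if species not in SPECIES:
            raise QuantTableError(f"unknown species {species!r}")
        mask = self.meta["species"] == species
        return QuantTable(self.meta[mask], self.values[mask])

    def with_values(self, values: pd.DataFrame) -> "QuantTable":
        return QuantTable(self.meta, values)

    def to_frame(self) -> pd.DataFrame:
        """Single DataFrame view: metadata columns then value columns."""
        out = self.meta.reset_index().rename(columns={"index": "protein_id"})
        if out.columns[0] != "protein_id":
            out = out.rename(columns={out.columns[0]: "protein_id"})
        return pd.concat(
            [out, self.values.reset_index(drop=True)], axis=1
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantTable):
            return NotImplemented
        return self.meta.equals(other.meta) and self.values.equals(other.values)


def read_quant_table(path: str | Path) -> QuantTable:
    """Read a quantification TSV into a validated :class:`QuantTable`.

    Layout: header row; columns ``protein_id``, ``gene_symbol``,
    ``species`` followed by replicate columns named per the
    ``<condition>_s<sample>_r<replicate>`` convention.  Empty cells and the
    literal ``NA`` parse as missing.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in META_COLUMNS},
        na_values=["NA"],
        keep_default_na=False,
    )
    missing_meta = [c for c in META_COLUMNS if c not in raw.columns]
    if missing_meta:
        raise QuantTableError(f"missing metadata columns: {missing_meta}")
    # pandas mangles duplicate headers to 'X.1'; detect them on the raw header
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise QuantTableError(f"duplicate column header: {dups}")
    value_cols = [c for c in raw.columns if c not in META_COLUMNS]
    values = raw[value_cols].replace("", np.nan).apply(pd.to_numeric)
    meta = raw[list(META_COLUMNS)].set_index("protein_id")
    values.index = meta.index
    return QuantTable(meta, values)


def _format_float(x: object) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return f"{x:.6g}"
    return str(x)


def write_table(obj: "QuantTable | pd.DataFrame", path: str | Path) -> None:
    """Write a pipeline table as deterministic TSV.

    Reals are rendered with 6 significant digits and missing values as
    ``NA``; identical inputs always produce identical bytes.
    """
    if isinstance(obj, QuantTable):
        frame = obj.to_frame()
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    path = Path(path)
    lines = ["\t".join(map(str, frame.columns))]
    for row in frame.itertuples(index=False):
        lines.append("\t".join(_format_float(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
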