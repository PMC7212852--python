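"""Shared fixtures: tiny handwritten quantification tables and builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from invadome.quant import ColumnKey, QuantTable


def full_grid_labels(samples: int = 3, replicates: int = 3) -> list[str]:
    """All 18 column labels of the standard 2 x samples x replicates design."""
    return [
        ColumnKey(cond, s, r).label
        for cond in ("A", "I")
        for s in range(1, samples + 1)
        for r in range(1, replicates + 1)
    ]


def make_table(
    rows: dict[str, list[float | None]],
    columns: list[str] | None = None,
    species: str | dict[str, str] = "human",
) -> QuantTable:
    """Build a QuantTable from {protein_id: values}; None marks missing."""
    columns = columns or full_grid_labels()
    ids = list(rows)
    values = pd.DataFrame(
        [[np.nan if v is None else float(v) for v in row] for row in rows.values()],
        index=pd.Index(ids, name="protein_id"),
        columns=columns,
    )
    if isinstance(species, str):
        species = {pid: species for pid in ids}
    meta = pd.DataFrame(
        {"gene_symbol": [f"G_{pid}" for pid in ids], "species": [species[p] for p in ids]},
        index=values.index,
    )
    return QuantTable(meta, values)


@pytest.fixture
def grid_labels() -> list[str]:
    return full_grid_labels()


@pytest.fixture
def tiny_table() -> QuantTable:
    """Two clean proteins on the full 18-column grid."""
    base = {
        "P1": [100.0 + i for i in range(18)],
        "P2": [50.0 + 2 * i for i in range(18)],
    }
    return make_table(base)
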