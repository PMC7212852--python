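"""Over-representation analysis against GMT gene-set collections.

Given the thresholded differential subset (|log2FC| > 1 among significant
proteins), each gene set is tested for overlap enrichment with the
hypergeometric upper tail: the probability of drawing at least the
observed overlap when sampling the query from the universe.  P-values are
BH-corrected across all tested sets; sets with adjusted p below the cutoff
(default 0.05) are called enriched.  The ``ratio`` column — overlap
divided by query size — is the dot-size statistic of the usual enrichment
dot plot.

The universe should be the detected proteome of the species analyzed, not
the whole genome: only detectable proteins could ever have entered the
query, and a genome-wide background would overstate every enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import pandas as pd
from scipy import stats

from invadome.diffexpr import bh_adjust


class GmtError(ValueError):
    """Malformed gene-set file."""


@dataclass
class GeneSetCollection:
    """Named gene-symbol sets (GMT semantics: id, description, members)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with a universe, dropping emptied sets."""
        uni = set(universe)
        sets = {name: s & uni for name, s in self.sets.items()}
        sets = {name: s for name, s in sets.items() if s}
        return GeneSetCollection(
            sets, {name: self.descriptions[name] for name in sets}
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    Duplicate member symbols within a set are deduplicated; a set with no
    members is skipped with a warning; a set name listed twice is an error.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise GmtError(f"line {lineno}: expected name, description, members...")
        name, desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise GmtError(f"gene set {name!r} listed twice")
        if not members:
            warnings.warn(f"gene set {name!r} has no members; skipped")
            continue
        sets[name] = set(members)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        members = sorted(collection.sets[name])
        lines.append("\t".join([name, collection.descriptions[name], *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_tail(overlap: int, universe: int, set_size: int, query: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, query)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def ora_test(
    query: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    Query symbols outside the universe are dropped (their count is
    reported in the ``n_query_dropped`` DataFrame attribute); gene sets
    are restricted to the universe before testing.  Rows are sorted by
    adjusted p then set id for byte-stable output.
    """
    uni = sorted(set(universe))
    uni_set = set(uni)
    q = sorted(set(query))
    dropped = [g for g in q if g not in uni_set]
    q_in = [g for g in q if g in uni_set]
    if not q_in:
        raise ValueError("query is empty after restriction to the universe")
    restricted = collection.restrict(uni_set)
    rows = []
    for name in sorted(restricted.sets):
        members = restricted.sets[name]
        overlap = len(members & set(q_in))
        p = hypergeom_tail(overlap, len(uni), len(members), len(q_in))
        rows.append(
            (
                name,
                restricted.descriptions[name],
                overlap,
                len(q_in),
                len(members),
                len(uni),
                overlap / len(q_in),
                p,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "set_name",
            "overlap_count",
            "query_size",
            "set_size",
            "universe_size",
            "ratio",
            "p_value",
        ],
    )
    out["padj"] = bh_adjust(out["p_value"].to_numpy())
    out["enriched"] = out["padj"] < padj_threshold
    out = out.sort_values(["padj", "set_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_query_dropped"] = len(dropped)
    return out
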