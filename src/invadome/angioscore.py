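"""Literature-keyword angiogenesis scoring (AngioScore).

For each gene, the AngioScore is the percentage of its assigned
publication abstracts that contain at least one angiogenesis keyword.
Matching is case-insensitive, whole-word/whole-phrase (no stemming), so a
lexicon entry ``angiogenesis`` does not match ``hemangiogenesisx``.  The
lexicon ships as an editable one-keyword-per-line text file; absolute
scores depend on both the lexicon and the corpus snapshot, so only
relative core-vs-invasive comparisons are meaningful.

The group comparison takes the top-N hits of each area (ranked by
|log2FC| among significant proteins), averages their scores, reports the
core/invasive ratio, and tests the difference with a two-sample t-test.
Genes without any publication are flagged and excluded from the group
statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Default angiogenesis lexicon; editable via the corpus directory's
#: ``lexicon.txt``.
DEFAULT_LEXICON = (
    "angiogenesis",
    "angiogenic",
    "neovascularization",
    "neovascularisation",
    "tumor vasculature",
    "tumour vasculature",
    "vascular endothelial growth factor",
    "endothelial proliferation",
    "vessel sprouting",
)


class CorpusError(ValueError):
    """Malformed publication corpus."""


@dataclass
class PublicationCorpus:
    """Per-gene abstract lists plus the keyword lexicon."""

    abstracts: dict[str, list[str]]
    lexicon: list[str]

    def __post_init__(self) -> None:
        if not self.lexicon:
            raise CorpusError("lexicon must be non-empty")

    def genes(self) -> list[str]:
        return sorted(self.abstracts)


class GeneScore(NamedTuple):
    n_publications: int
    n_matching: int
    angioscore: float  # percent; NaN when no publications


def _compile_lexicon(lexicon: Iterable[str]) -> list[re.Pattern]:
    patterns = []
    for kw in dict.fromkeys(k.strip().lower() for k in lexicon if k.strip()):
        patterns.append(re.compile(r"\b" + re.escape(kw) + r"\b", re.IGNORECASE))
    if not patterns:
        raise CorpusError("lexicon must be non-empty")
    return patterns


def score_gene(abstracts: Sequence[str], lexicon: Sequence[str]) -> GeneScore:
    """Fraction (as percent) of abstracts containing any lexicon keyword."""
    patterns = _compile_lexicon(lexicon)
    n = len(abstracts)
    matches = sum(
        1 for text in abstracts if any(p.search(text) for p in patterns)
    )
    score = 100.0 * matches / n if n else float("nan")
    return GeneScore(n, matches, score)


def score_corpus(corpus: PublicationCorpus) -> pd.DataFrame:
    """Score every gene in the corpus; genes with no abstracts are flagged."""
    rows = []
    for gene in corpus.genes():
        s = score_gene(corpus.abstracts[gene], corpus.lexicon)
        rows.append((gene, s.n_publications, s.n_matching, s.angioscore))
    out = pd.DataFrame(
        rows, columns=["gene", "n_publications", "n_matching", "angioscore"]
    )
    out["no_publications"] = out["n_publications"] == 0
    return out


def compare_groups(
    scores: pd.DataFrame,
    core_hits: Sequence[str],
    invasive_hits: Sequence[str],
    top_n: int = 30,
    top_listing: int = 20,
) -> dict:
    """Core-vs-invasive AngioScore comparison on the top hits of each area.

    Parameters
    ----------
    scores:
        Output of :func:`score_corpus` (or equivalent table with columns
        ``gene`` and ``angioscore``).
    core_hits, invasive_hits:
        Ranked gene lists (best hit first, e.g. by |log2FC| among
        significant proteins); the first ``top_n`` scored genes of each
        are compared.
    top_n:
        Group size for the mean/ratio/t-test comparison.
    top_listing:
        Length of the highest-AngioScore listing emitted per area.

    Returns a dict with per-group means, the core/invasive ratio, the
    two-sample t statistic and p-value, the per-group score tables, and
    the top listings.
    """
    if top_n > len(core_hits) or top_n > len(invasive_hits):
        raise ValueError(
            f"top_n={top_n} exceeds a ranked hit list "
            f"({len(core_hits)} core / {len(invasive_hits)} invasive)"
        )
    lookup = scores.set_index("gene")

    def group_scores(ranked: Sequence[str]) -> pd.DataFrame:
        sel = [g for g in ranked[:top_n] if g in lookup.index]
        grp = lookup.loc[sel].reset_index()
        return grp[~grp["no_publications"]] if "no_publications" in grp else grp

    core = group_scores(core_hits)
    invasive = group_scores(invasive_hits)
    if len(core) < 2 or len(invasive) < 2:
        raise ValueError("each group needs at least two scored genes for a t-test")
    mean_core = float(core["angioscore"].mean())
    mean_invasive = float(invasive["angioscore"].mean())
    t, p = stats.ttest_ind(core["angioscore"], invasive["angioscore"])
    ratio = mean_core / mean_invasive if mean_invasive > 0 else float("inf")
    listing = {
        area: tbl.sort_values(["angioscore", "gene"], ascending=[False, True])
        .head(top_listing)
        .reset_index(drop=True)
        for area, tbl in (("core", core), ("invasive", invasive))
    }
    return {
        "mean_core": mean_core,
        "mean_invasive": mean_invasive,
        "ratio_core_over_invasive": ratio,
        "t_statistic": float(t),
        "p_value": float(p),
        "core_scores": core,
        "invasive_scores": invasive,
        "top_listing": listing,
    }


def read_corpus(directory: str | Path) -> PublicationCorpus:
    """Load a corpus directory: ``lexicon.txt`` plus one ``<GENE>.txt`` per
    gene with blank-line-separated abstract records."""
    directory = Path(directory)
    lex_path = directory / "lexicon.txt"
    if not lex_path.exists():
        raise CorpusError(f"missing lexicon file {lex_path}")
    lexicon = [l.strip() for l in lex_path.read_text().splitlines() if l.strip()]
    abstracts: dict[str, list[str]] = {}
    for path in sorted(directory.glob("*.txt")):
        if path.name == "lexicon.txt":
            continue
        gene = path.stem
        records = [
            " ".join(block.split())
            for block in path.read_text().split("\n\n")
            if block.strip()
        ]
        abstracts[gene] = records
    return PublicationCorpus(abstracts, lexicon)


def write_corpus(corpus: PublicationCorpus, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "lexicon.txt").write_text("\n".join(corpus.lexicon) + "\n")
    for gene in corpus.genes():
        (directory / f"{gene}.txt").write_text(
            "\n\n".join(corpus.abstracts[gene]) + "\n"
        )
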