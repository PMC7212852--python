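"""Synthetic dual-species quantification tables with planted ground truth.

The generator emulates the structure of a two-area xenograft LFQ study so
every downstream stage is testable offline:

* two conditions (core ``A`` / invasive ``I``) x 3 biological samples x 3
  technical replicates (9 columns per condition);
* ~750 human (tumor) and ~520 mouse (stroma) proteins;
* log-normal base abundances with additive log-space biological-sample
  effects and multiplicative technical noise whose CV follows a
  bulk-plus-heavy-tail mixture (the tail crossing the 0.8
  reproducibility gate);
* a planted differentially expressed fraction with |log2FC| up to ~6,
  applied to condition I;
* logistic abundance-dependent dropout (low-abundance cells vanish more),
  the reason presence filters exist;
* a synthetic publication corpus whose core-area genes mention
  angiogenesis keywords at an elevated rate.

What it does not emulate: peptide-level effects, shared-peptide protein
inference, batch effects beyond the sample term, or real missingness
mechanisms other than abundance-dependent dropout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from invadome.angioscore import DEFAULT_LEXICON, PublicationCorpus
from invadome.config import SimConfig
from invadome.quant import ColumnKey, QuantTable


@dataclass
class GroundTruth:
    """Planted per-protein truth of one simulated table.

    Columns of ``table``: protein_id, gene_symbol, species,
    base_log2_abundance, true_log2fc, is_de, true_cv, high_cv (whether the
    protein was drawn from the heavy CV tail).
    """

    table: pd.DataFrame

    @property
    def de_ids(self) -> list[str]:
        return list(self.table.loc[self.table["is_de"], "protein_id"])

    @property
    def null_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["is_de"], "protein_id"])


def _protein_ids(species: str, n: int) -> tuple[list[str], list[str]]:
    prefix = "HUM" if species == "human" else "MOU"
    gene_prefix = "GH" if species == "human" else "Gm"
    ids = [f"{prefix}{i:05d}" for i in range(n)]
    genes = [f"{gene_prefix}{i:05d}" for i in range(n)]
    return ids, genes


def simulate_quant(config: SimConfig) -> tuple[QuantTable, GroundTruth]:
    """Draw one quantification table plus its ground truth.

    The abundance of protein p in column (condition c, sample s,
    replicate r) is, in log2 space, ``base_p + sample-effect_{p,s} +
    log2fc_p * [c == I]`` plus multiplicative technical noise with the
    protein's CV; cells are then removed by the logistic dropout curve.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    species = ["human"] * config.n_human + ["mouse"] * config.n_mouse
    n = len(species)
    ids_h, genes_h = _protein_ids("human", config.n_human)
    ids_m, genes_m = _protein_ids("mouse", config.n_mouse)
    protein_ids = ids_h + ids_m
    gene_symbols = genes_h + genes_m

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    is_de = rng.random(n) < config.de_fraction
    lo, hi = config.log2fc_range
    magnitude = rng.uniform(lo, hi, size=n)
    sign = np.where(rng.random(n) < config.invasive_up_fraction, 1.0, -1.0)
    log2fc = np.where(is_de, sign * magnitude, 0.0)
    high_cv = rng.random(n) < config.cv_tail_fraction
    true_cv = np.where(high_cv, config.cv_tail, config.cv_bulk)
    # multiplicative log-normal technical noise with CV c has
    # log-sd sigma = sqrt(ln(1 + c^2))
    sigma_tech = np.sqrt(np.log1p(true_cv**2))

    keys = [
        ColumnKey(cond, s, r)
        for cond in ("A", "I")
        for s in range(1, config.samples + 1)
        for r in range(1, config.replicates + 1)
    ]
    sample_effect = rng.normal(
        0.0, config.sample_sd_log2, size=(n, config.samples)
    )

    values = np.empty((n, len(keys)))
    for j, key in enumerate(keys):
        mean_log2 = base + sample_effect[:, key.sample - 1]
        if key.condition == "I":
            mean_log2 = mean_log2 + log2fc
        noise = rng.normal(0.0, 1.0, size=n)
        # center the log-normal so its linear-space mean is 2**mean_log2
        values[:, j] = np.exp2(mean_log2) * np.exp(
            sigma_tech * noise - sigma_tech**2 / 2
        )

    if config.dropout:
        log2_vals = np.log2(values)
        p_missing = 1.0 / (
            1.0
            + np.exp(
                config.dropout_steepness * (log2_vals - config.dropout_midpoint)
            )
        )
        mask = rng.random(values.shape) < p_missing
        values = np.where(mask, np.nan, values)

    meta = pd.DataFrame(
        {"gene_symbol": gene_symbols, "species": species},
        index=pd.Index(protein_ids, name="protein_id"),
    )
    frame = pd.DataFrame(
        values, index=meta.index, columns=[k.label for k in keys]
    )
    truth = GroundTruth(
        pd.DataFrame(
            {
                "protein_id": protein_ids,
                "gene_symbol": gene_symbols,
                "species": species,
                "base_log2_abundance": base,
                "true_log2fc": log2fc,
                "is_de": is_de,
                "true_cv": true_cv,
                "high_cv": high_cv,
            }
        )
    )
    return QuantTable(meta, frame), truth


_FILLER_SENTENCES = (
    "We characterized protein expression in tumor tissue sections.",
    "Mass spectrometry identified differential protein abundance patterns.",
    "The gene was profiled across patient cohorts with clinical follow-up.",
    "Knockdown experiments revealed altered cell migration in vitro.",
    "Expression correlated with histological grade in the studied samples.",
)


def simulate_corpus(
    genes: list[str],
    core_genes: list[str],
    invasive_genes: list[str],
    rate_core: float = 0.3,
    rate_other: float = 0.2,
    pubs_per_gene: int = 200,
    seed: int = 0,
    lexicon: tuple[str, ...] = DEFAULT_LEXICON,
) -> PublicationCorpus:
    """Synthetic per-gene abstract corpus with planted keyword rates.

    Every gene receives ``pubs_per_gene`` abstracts; an abstract of a gene
    in ``core_genes`` mentions an angiogenesis keyword with probability
    ``rate_core``, any other gene's abstracts with probability
    ``rate_other``.  Core and invasive gene lists must not overlap.
    """
    if not 0 <= rate_core <= 1 or not 0 <= rate_other <= 1:
        raise ValueError("keyword rates must lie in [0, 1]")
    if pubs_per_gene < 0:
        raise ValueError("pubs_per_gene must be >= 0")
    overlap = set(core_genes) & set(invasive_genes)
    if overlap:
        raise ValueError(f"core and invasive gene lists overlap: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    core = set(core_genes)
    abstracts: dict[str, list[str]] = {}
    for gene in genes:
        rate = rate_core if gene in core else rate_other
        texts = []
        for _ in range(pubs_per_gene):
            filler = _FILLER_SENTENCES[rng.integers(0, len(_FILLER_SENTENCES))]
            text = f"Study of {gene}. {filler}"
            if rng.random() < rate:
                kw = lexicon[rng.integers(0, len(lexicon))]
                text += f" The role of {gene} in {kw} was examined."
            texts.append(text)
        abstracts[gene] = texts
    return PublicationCorpus(abstracts, list(lexicon))
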