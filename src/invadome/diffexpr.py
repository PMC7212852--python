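"""Normalization, imputation and differential expression.

Differential abundance between the invasive rim (condition ``I``) and the
angiogenic core (``A``) is assessed per protein by Welch's unequal-variance
t-test on the observed replicate vectors, with Benjamini-Hochberg FDR
control across proteins.  Effect size is ``log2FC = log2(mu_I / mu_A)``
with means taken over present values, so a positive log2FC means
invasive-up.

Median-ratio normalization rescales each column so that its median ratio
to the per-protein median reference profile is one, removing per-column
loading differences.  Low-quantile imputation (per-column 1st percentile)
exists only to feed clustering and heatmaps, which need complete matrices;
the t-test always runs on observed values, because imputing before testing
fabricates degrees of freedom.

Hit tiers are nested by construction for human data: ``significant``
(padj < 0.01), ``enrichment_hit`` (also |log2FC| > 1, the subset submitted
to over-representation analysis) and ``clustermap_hit`` (also |log2FC|
above the species threshold, 2 for human and 5 for mouse).
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from invadome.config import PipelineConfig
from invadome.quant import QuantTable


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def median_ratio_normalize(table: QuantTable) -> tuple[QuantTable, pd.Series]:
    """Scale columns to unit median ratio against the median reference profile.

    The reference profile is the per-protein median across all columns
    (over present values).  Each column is multiplied by the inverse of
    the median of its ratios to the reference, so that afterwards every
    column's median ratio to the reference equals one.  Returns the
    normalized table and the per-column scale factors applied.
    """
    vals = table.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reference = vals.median(axis=1, skipna=True)
    scales = {}
    for col in vals.columns:
        ratios = vals[col] / reference
        ratios = ratios.dropna()
        if ratios.empty:
            raise ValueError(
                f"column {col!r} shares no quantified protein with the reference"
            )
        scales[col] = 1.0 / float(ratios.median())
    scale = pd.Series(scales, name="scale")
    normalized = vals * scale
    return table.with_values(normalized), scale


def impute_missing(
    table: QuantTable, quantile: float = 0.01
) -> tuple[QuantTable, pd.DataFrame]:
    """Replace missing cells by a per-column low quantile (default 1st pct).

    Missing-at-low-abundance is the dominant mechanism in label-free
    proteomics, so absent values are imputed near each column's detection
    floor.  Returns the complete table and a boolean flag frame marking
    imputed cells.  Used only for clustering/visualization, never for the
    t-test.
    """
    vals = table.values.copy()
    flags = vals.isna()
    for col in vals.columns:
        present = vals[col].dropna()
        if present.empty:
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        floor = float(np.quantile(present.to_numpy(), quantile))
        vals[col] = vals[col].fillna(floor)
    return table.with_values(vals), flags


def missing_value_variant_hook(de: pd.DataFrame) -> pd.DataFrame:
    """Hook for an upstream missing-value inference variant; currently a no-op.

    Acquisition software sometimes applies an alternative inference rule
    for proteins showing at least a 1.5-fold change at adjusted p < 0.05.
    The rule's exact definition is not specified well enough to implement
    faithfully, so this hook documents the extension point and returns its
    input unchanged.
    """
    return de


def welch_t_test(a, b) -> WelchResult:
    """Welch's unequal-variance t-test, two-sided.

    Computes the t statistic, Welch-Satterthwaite degrees of freedom and
    the two-sided p-value from Student's t distribution.  Requires at
    least two present values per group; otherwise returns NaNs (the
    protein is excluded from FDR correction downstream).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return WelchResult(float("nan"), float("nan"), float("nan"))
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        # identical constant groups: no evidence either way
        return WelchResult(0.0, float(na + nb - 2), 1.0)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the correction and returned as NaN;
    defined entries are adjusted with monotonicity enforcement, capped at
    one, and restored to input order.
    """
    p = np.asarray(p, dtype=float)
    defined = ~np.isnan(p)
    if ((p[defined] < 0) | (p[defined] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if defined.sum():
        out[defined] = multipletests(p[defined], method="fdr_bh")[1]
    return out


def log_fold_change(mean_i: float, mean_a: float) -> float:
    """log2 of the invasive/core mean ratio; NaN if either mean is not positive."""
    if not (mean_i > 0 and mean_a > 0):
        return float("nan")
    return float(np.log2(mean_i / mean_a))


def differential_expression(table: QuantTable) -> pd.DataFrame:
    """Per-protein Welch test (I vs A) with BH correction and log2FC.

    Means and tests use observed values only.  Returns a DataFrame with
    columns protein_id, gene_symbol, species, n_A, n_I, mean_A, mean_I,
    log2fc, t, df, p, padj.
    """
    A = table.values[table.columns_for("A")].to_numpy(dtype=float)
    I = table.values[table.columns_for("I")].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n_a = (~np.isnan(A)).sum(axis=1)
        n_i = (~np.isnan(I)).sum(axis=1)
        mean_a = np.nanmean(np.where(n_a[:, None] > 0, A, np.nan), axis=1)
        mean_i = np.nanmean(np.where(n_i[:, None] > 0, I, np.nan), axis=1)
        var_a = np.nanvar(A, axis=1, ddof=1)
        var_i = np.nanvar(I, axis=1, ddof=1)
    # vectorized Welch: same formulas as welch_t_test
    testable = (n_a >= 2) & (n_i >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = var_i / n_i + var_a / n_a
        t = (mean_i - mean_a) / np.sqrt(se2)
        df = se2**2 / (
            (var_i / n_i) ** 2 / np.maximum(n_i - 1, 1)
            + (var_a / n_a) ** 2 / np.maximum(n_a - 1, 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
        # identical constant groups: no evidence either way
        degenerate = testable & (se2 == 0)
        t = np.where(degenerate, 0.0, t)
        df = np.where(degenerate, n_a + n_i - 2, df)
        p = np.where(degenerate, 1.0, p)
        t = np.where(testable, t, np.nan)
        df = np.where(testable, df, np.nan)
        p = np.where(testable, p, np.nan)
        log2fc = np.where(
            (mean_i > 0) & (mean_a > 0), np.log2(mean_i / mean_a), np.nan
        )
    de = pd.DataFrame(
        {
            "protein_id": table.meta.index,
            "gene_symbol": table.meta["gene_symbol"].to_numpy(),
            "species": table.meta["species"].to_numpy(),
            "n_A": n_a,
            "n_I": n_i,
            "mean_A": mean_a,
            "mean_I": mean_i,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
        }
    ).reset_index(drop=True)
    de["padj"] = bh_adjust(de["p"].to_numpy())
    return de


def flag_hits(de: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Attach the nested significance tiers and direction calls.

    Adds boolean columns ``significant`` (padj gate), ``enrichment_hit``
    (plus |log2FC| > 1) and ``clustermap_hit`` (plus the species |log2FC|
    threshold), and a ``direction`` column (invasive-up / core-up).
    """
    out = de.copy()
    padj_ok = out["padj"] < config.padj_threshold
    abs_lfc = out["log2fc"].abs()
    cm_thresh = out["species"].map(
        {
            "human": config.logfc_clustermap_human,
            "mouse": config.logfc_clustermap_mouse,
        }
    )
    out["significant"] = (padj_ok & out["log2fc"].notna()).fillna(False)
    out["enrichment_hit"] = out["significant"] & (abs_lfc > config.logfc_enrichment)
    out["clustermap_hit"] = out["significant"] & (abs_lfc > cm_thresh)
    out["direction"] = np.where(out["log2fc"] > 0, "invasive-up", "core-up")
    return out


def hit_summary(flagged: pd.DataFrame) -> pd.DataFrame:
    """Per-species, per-direction counts of each hit tier."""
    rows = []
    for species, grp in flagged.groupby("species"):
        for direction in ("invasive-up", "core-up"):
            sub = grp[grp["direction"] == direction]
            rows.append(
                (
                    species,
                    direction,
                    int(sub["significant"].sum()),
                    int(sub["enrichment_hit"].sum()),
                    int(sub["clustermap_hit"].sum()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["species", "direction", "significant", "enrichment_hit", "clustermap_hit"],
    )
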