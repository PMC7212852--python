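"""Technical-reproducibility filtering and presence-based aggregation.

The first gate of the pipeline: per (protein, condition, biological
sample), the coefficient of variation (CV = sd / mean) of the technical
triplicate measures quantification dispersion.  A protein survives only if
every defined CV is below the threshold (default 0.8) in both conditions.
The second gate keeps proteins quantified in at least 6 of the 9 columns of
each condition, and flags the "common" subset present in every column.

CV uses the sample standard deviation (n-1 denominator), the standard
choice for a three-point dispersion estimate; pass ``ddof=0`` for the
population form.  A triplet with fewer than two present values contributes
no CV and does not veto retention — absence is the presence filter's job,
not the CV filter's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from invadome.quant import CONDITIONS, QuantTable


@dataclass
class CVReport:
    """Per-(protein, condition, sample) CVs plus the retention verdict.

    Attributes
    ----------
    per_sample:
        Long-format DataFrame with columns ``protein_id``, ``condition``,
        ``sample``, ``n_present``, ``cv`` (NaN when fewer than two values
        are present).
    retained:
        Boolean Series per protein.
    threshold:
        The CV cutoff applied.
    """

    per_sample: pd.DataFrame
    retained: pd.Series
    threshold: float

    def histogram(self, bin_width: float = 0.05) -> pd.DataFrame:
        """Binned CV counts per (condition, sample), ready for plotting.

        Returns columns ``condition``, ``sample``, ``bin_left``, ``count``.
        """
        rows = []
        defined = self.per_sample.dropna(subset=["cv"])
        for (cond, sample), grp in defined.groupby(["condition", "sample"]):
            nbins = max(1, math.ceil((grp["cv"].max() + 1e-12) / bin_width))
            edges = np.arange(nbins + 1) * bin_width
            counts, _ = np.histogram(grp["cv"], bins=edges)
            for left, c in zip(edges[:-1], counts):
                rows.append((cond, sample, round(float(left), 10), int(c)))
        return pd.DataFrame(
            rows, columns=["condition", "sample", "bin_left", "count"]
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.per_sample.copy()
        out["retained"] = out["protein_id"].map(self.retained).astype(bool)
        return out


def coefficient_of_variation(values, ddof: int = 1) -> float:
    """CV = sd / mean of a vector of positive abundances.

    Returns NaN (undefined) for fewer than two values; callers propagate
    the NaN rather than treating it as a failure.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        return float("nan")
    return float(np.std(arr, ddof=ddof) / np.mean(arr))


def cv_filter(
    table: QuantTable, threshold: float = 0.8, ddof: int = 1
) -> tuple[QuantTable, CVReport]:
    """Drop proteins whose technical triplicates are irreproducible.

    CV is computed per (protein, condition, sample) over that sample's
    technical replicates; a protein is retained iff every defined CV is
    strictly below ``threshold`` in both conditions.
    """
    if threshold <= 0:
        raise ValueError(f"cv threshold must be > 0, got {threshold}")
    records = []
    max_cv = pd.Series(0.0, index=table.meta.index)
    any_bad = pd.Series(False, index=table.meta.index)
    for cond in CONDITIONS:
        for sample in table.samples:
            cols = table.columns_for(cond, sample)
            if not cols:
                continue
            block = table.values[cols].to_numpy()
            n_present = np.sum(~np.isnan(block), axis=1)
            with warnings.catch_warnings(), np.errstate(invalid="ignore"):
                warnings.simplefilter("ignore", RuntimeWarning)
                cv = np.nanstd(block, axis=1, ddof=ddof) / np.nanmean(block, axis=1)
            cv = np.where(n_present >= 2, cv, np.nan)
            any_bad |= pd.Series(cv >= threshold, index=table.meta.index).fillna(False)
            for pid, npres, c in zip(table.meta.index, n_present, cv):
                records.append((pid, cond, sample, int(npres), c))
    retained = ~any_bad
    report = CVReport(
        per_sample=pd.DataFrame(
            records, columns=["protein_id", "condition", "sample", "n_present", "cv"]
        ),
        retained=retained,
        threshold=threshold,
    )
    kept = table.subset_proteins(table.meta.index[retained])
    return kept, report


def aggregate(
    table: QuantTable, presence_min: int = 6, presence_total: int = 9
) -> tuple[QuantTable, pd.Series]:
    """Apply the per-condition presence rule and flag the common subset.

    A protein is kept iff it is quantified in at least ``presence_min`` of
    the ``presence_total`` columns of *each* condition.  The returned
    Series flags, per kept protein, membership in the "common" subset
    (present in every column of both conditions).
    """
    if presence_min > presence_total:
        raise ValueError("presence_min exceeds presence_total")
    for cond in CONDITIONS:
        ncols = len(table.columns_for(cond))
        if ncols != presence_total:
            raise ValueError(
                f"condition {cond} has {ncols} columns but presence_total="
                f"{presence_total}"
            )
    counts = {c: table.presence_counts(c) for c in CONDITIONS}
    keep = (counts["A"] >= presence_min) & (counts["I"] >= presence_min)
    kept = table.subset_proteins(table.meta.index[keep])
    common = (counts["A"][keep] == presence_total) & (
        counts["I"][keep] == presence_total
    )
    common.name = "common"
    return kept, common
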