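"""Genetic risk score computation, standardization and quantile binning.

The raw score of sample *j* is the weighted sum of effect-allele dosages,
``raw_j = sum_i w_i * d_ij``. Scores are standardized within the cohort
to zero mean and unit sample standard deviation (n-1 denominator), and
optionally divided into quantile-interval bins with the lowest interval
as the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import DosageMatrix, VariantWeight

__all__ = ["ScoreVector", "QuantileBins", "compute_grs", "standardize", "quantile_bins"]


@dataclass
class ScoreVector:
    """Per-sample raw and standardized score values.

    ``n_variants_used`` counts variants contributing an observed (non
    mean-imputed) dosage for each sample.
    """

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray | None = None
    n_variants_used: np.ndarray | None = None
    n_imputed_entries: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"sample_id": self.sample_ids, "raw": self.raw})
        if self.standardized is not None:
            out["standardized"] = self.standardized
        if self.n_variants_used is not None:
            out["n_variants_used"] = self.n_variants_used
        return out

    def write_tsv(self, path: str | Path, bins: "QuantileBins | None" = None) -> None:
        out = self.to_frame()
        if bins is not None:
            out["bin"] = bins.bin_label
        out.to_csv(path, sep="\t", index=False)


@dataclass
class QuantileBins:
    """Quantile-interval assignment of a score (default: quartiles Q1..Q4)."""

    bin_edges: np.ndarray
    bin_label: list[str]
    reference_bin: str = "Q1"
    labels: list[str] = field(default_factory=list)


def compute_grs(
    weights: Sequence[VariantWeight],
    matrix: DosageMatrix,
    *,
    impute_missing: bool = True,
) -> ScoreVector:
    """Weighted dosage sum over harmonized variants.

    ``matrix`` columns must already be aligned to effect alleles and
    correspond 1:1, in order, to ``weights``. Missing dosages are filled
    with the per-variant mean dosage (2 x the effect-allele frequency)
    before summation so every sample receives a score; the number of
    imputed entries is recorded and ``n_variants_used`` reflects observed
    contributions only.
    """
    if [w.variant_id for w in weights] != matrix.variant_ids:
        raise ValueError(
            "weights and matrix columns must match 1:1 in order; "
            "run harmonize_alleles first"
        )
    d = matrix.dosages.to_numpy(dtype=float)
    w = np.array([vw.effect_weight for vw in weights], dtype=float)
    observed = ~np.isnan(d)
    n_imputed = int(observed.size - observed.sum())
    if n_imputed:
        if not impute_missing:
            raise ValueError(f"{n_imputed} missing dosage entries and impute_missing=False")
        col_mean = np.nanmean(d, axis=0)
        if np.isnan(col_mean).any():
            raise ValueError("variant with all dosages missing cannot be mean-imputed")
        d = np.where(observed, d, col_mean[np.newaxis, :])
    raw = d @ w
    return ScoreVector(
        sample_ids=matrix.sample_ids,
        raw=raw,
        n_variants_used=observed.sum(axis=1),
        n_imputed_entries=n_imputed,
    )


def standardize(scores: ScoreVector) -> ScoreVector:
    """Return a copy with ``standardized = (raw - mean) / sd`` filled.

    The sample standard deviation (n-1 denominator) is computed within
    the supplied cohort; cross-cohort pooling is deliberately not done,
    since per-SD effect sizes are reported per cohort.
    """
    raw = np.asarray(scores.raw, dtype=float)
    if raw.size < 2:
        raise ValueError("standardization needs at least 2 samples")
    sd = raw.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate score: zero variance across the cohort")
    return ScoreVector(
        sample_ids=scores.sample_ids,
        raw=raw,
        standardized=(raw - raw.mean()) / sd,
        n_variants_used=scores.n_variants_used,
        n_imputed_entries=scores.n_imputed_entries,
    )


def quantile_bins(scores: ScoreVector, n_bins: int = 4) -> QuantileBins:
    """Assign samples to quantile intervals of the score.

    Edges are the empirical quantiles at k/n_bins, k = 0..n_bins, so
    ``n_bins`` intervals are bounded by ``n_bins + 1`` quantile edges.
    Intervals are left-open/right-closed except the lowest, which includes
    its left edge; a value equal to an internal edge therefore falls in
    the lower bin. The lowest interval (Q1) is the reference group.
    """
    vals = np.asarray(
        scores.standardized if scores.standardized is not None else scores.raw, dtype=float
    )
    if np.unique(vals).size < n_bins:
        raise ValueError(f"need at least {n_bins} distinct score values for {n_bins} bins")
    edges = np.quantile(vals, np.linspace(0, 1, n_bins + 1))
    idx = np.searchsorted(edges[1:-1], vals, side="left")
    labels = [f"Q{k + 1}" for k in range(n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        empty = labels[int(np.argmin(counts))]
        raise ValueError(
            f"quantile bin {empty} is empty (heavy ties); use fewer bins"
        )
    return QuantileBins(
        bin_edges=edges,
        bin_label=[labels[i] for i in idx],
        reference_bin=labels[0],
        labels=labels,
    )
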