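"""Expression containers, normalization and the co-expression pre-filter.

The primitive unit of the pipeline is a transcript x sample matrix of raw
fragment counts together with per-transcript effective lengths.  Two
normalizations are provided:

* FPKM (fragments per kilobase of transcript per million mapped fragments),
  the length- and depth-normalized scale on which presence/absence and the
  co-expression network are defined;
* median-of-ratios size factors, the depth-only normalization consumed by the
  negative-binomial empirical-Bayes engine, which models raw counts.

``filter_null_fraction`` implements the network pre-filter that discards
transcripts with more than 50% zero values across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNT = "count"
FPKM = "fpkm"


@dataclass
class ExpressionMatrix:
    """Transcript x sample expression values with a unit tag.

    Parameters
    ----------
    values:
        DataFrame, rows indexed by transcript id, columns by sample id.
        All values must be non-negative.
    lengths:
        Per-transcript effective lengths in nucleotides, aligned with
        ``values.index``.  Optional for matrices that never pass through
        FPKM normalization (toy fixtures).
    unit:
        ``"count"`` or ``"fpkm"``.
    """

    values: pd.DataFrame
    lengths: Optional[pd.Series] = None
    unit: str = COUNT

    def __post_init__(self) -> None:
        if self.unit not in (COUNT, FPKM):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            raise ValueError("duplicated transcript ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicated sample ids")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if self.lengths.isna().any():
                missing = self.lengths.index[self.lengths.isna()][0]
                raise ValueError(f"missing length for transcript {missing!r}")
            if (self.lengths <= 0).any():
                raise ValueError("transcript lengths must be positive")

    @property
    def n_transcripts(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.lengths, self.unit)

    def subset_transcripts(self, transcripts) -> "ExpressionMatrix":
        idx = self.values.index.intersection(pd.Index(transcripts))
        lengths = self.lengths.loc[idx] if self.lengths is not None else None
        return ExpressionMatrix(self.values.loc[idx], lengths, self.unit)


def fpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to FPKM.

    FPKM_gj = X_gj * 1e9 / (L_g * N_j) with X the fragment count, L the
    transcript length in nt and N the sample's total mapped fragments.
    """
    if counts.unit != COUNT:
        raise ValueError("fpkm() expects a count matrix")
    if counts.lengths is None:
        raise ValueError("fpkm() requires transcript lengths")
    col_sums = counts.values.sum(axis=0)
    if (col_sums <= 0).any():
        bad = col_sums.index[col_sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    vals = counts.values * 1e9
    vals = vals.div(counts.lengths, axis=0).div(col_sums, axis=1)
    return ExpressionMatrix(vals, counts.lengths, FPKM)


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each transcript positive in every sample, compute the ratio of each
    sample's count to the transcript's geometric mean across samples; a
    sample's factor is the median of those ratios.  Falls back to column-sum
    ratios (with a warning) when no transcript is positive everywhere.
    """
    if counts.unit != COUNT:
        raise ValueError("size_factors() expects a count matrix")
    x = counts.values.to_numpy(dtype=float)
    if x.shape[1] == 1:
        return pd.Series([1.0], index=counts.values.columns)
    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        sub = x[all_pos]
        log_geo = np.log(sub).mean(axis=1, keepdims=True)
        ratios = sub / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no transcript positive in all samples; size factors fall back "
            "to column-sum ratios"
        )
        totals = x.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.values.columns)


def filter_null_fraction(
    matrix: ExpressionMatrix, max_null_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop transcripts whose fraction of zero values exceeds the threshold.

    The inequality is strict: a transcript with exactly ``max_null_fraction``
    zeros is retained.  Row order is otherwise preserved.
    """
    if matrix.n_transcripts == 0:
        raise ValueError("empty expression matrix")
    zero_frac = (matrix.values == 0).sum(axis=1) / matrix.n_samples
    keep = zero_frac <= max_null_fraction
    lengths = matrix.lengths[keep] if matrix.lengths is not None else None
    return ExpressionMatrix(matrix.values[keep], lengths, matrix.unit)
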