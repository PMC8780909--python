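"""Spike-in-restricted median-of-ratios size factors.

Exogenous spike-in RNA (the Drosophila S2 role in 4SU-TT-seq) is added in a
fixed amount per sample, so spike-in counts identify each library's depth
regardless of condition or assay.  Size factors are the DESeq2-style
median-of-ratios statistic computed on the spike-in subset only: for each
spike-in gene a geometric-mean reference across samples, for each sample the
median of count/reference ratios over spike-in genes.  Spike-ins with a zero
count in any sample are dropped from the reference (the standard
median-of-ratios convention).  Because the spike-in is itself 4SU-labeled it
is present in both the nascent and the total libraries, so one factor set
covers both assays — exactly what the nascent/total ratio needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counttable import CountTable
from .errors import NormalizationError, ValidationError


def estimate_size_factors(table: CountTable) -> pd.Series:
    """Per-sample size factors from spike-in genes only.

    Returns a positive Series indexed by sample_id.  Raises
    :class:`NormalizationError` when no spike-in gene has positive counts in
    every sample, naming the samples with zeros.
    """
    sub = table.counts.loc[table.spikein.to_numpy()]
    if sub.empty:
        raise NormalizationError("count table contains no spike-in genes")
    all_positive = (sub > 0).all(axis=1)
    if not all_positive.any():
        offenders = sorted(sub.columns[(sub <= 0).any(axis=0)])
        raise NormalizationError(
            "no spike-in gene has positive counts in every sample; "
            f"samples with zero spike-in counts: {offenders}"
        )
    ref = sub.loc[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geomean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors.name = "size_factor"
    return factors


def normalize(table: CountTable, factors: pd.Series) -> CountTable:
    """Divide each sample's counts by its size factor (real-valued result)."""
    factors = factors.reindex(table.counts.columns)
    if factors.isna().any():
        raise ValidationError("size factors missing for some samples")
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    return CountTable(
        counts=table.counts / factors,
        samples=table.samples,
        spikein=table.spikein,
    )


def write_size_factors(factors: pd.Series, path) -> None:
    factors.rename_axis("sample_id").to_csv(path, sep="\t")


def read_size_factors(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="sample_id")["size_factor"]
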