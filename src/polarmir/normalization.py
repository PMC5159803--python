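"""Between-sample normalization and detection filtering for count matrices.

Normalization uses the median-of-ratios estimator: every sample is scaled by
the median, over features with a positive geometric mean, of the ratio of
its count to that feature's geometric mean across samples.  This makes
samples comparable without being driven by a handful of highly expressed
features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios size-factor normalization.

    Operates on feature x sample count DataFrames (the genomics
    convention: rows are features, columns are samples).

    Attributes
    ----------
    size_factors_ : pandas.Series
        Per-sample positive scale factor, indexed by sample id.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "MedianOfRatiosNormalizer":
        counts = _as_frame(X)
        if counts.shape[1] < 2:
            raise ValueError("need at least 2 samples to estimate size factors")
        values = counts.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        positive = (values > 0).all(axis=1)
        if not positive.any():
            raise ValueError(
                "no feature has positive counts in every sample; "
                "filter low-coverage samples or features before normalizing"
            )
        logv = np.log(values[positive])
        geomean = np.exp(logv.mean(axis=1))
        factors = np.median(values[positive] / geomean[:, None], axis=0)
        self.n_features_in_ = counts.shape[0]
        self.size_factors_ = pd.Series(factors, index=counts.columns, name="size_factor")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        counts = _as_frame(X)
        missing = [c for c in counts.columns if c not in self.size_factors_.index]
        if missing:
            raise ValueError(f"samples without fitted size factors: {missing}")
        return counts / self.size_factors_[counts.columns]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample column)."""
    return MedianOfRatiosNormalizer().fit(counts).size_factors_


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Return (normalized matrix, size factors)."""
    norm = MedianOfRatiosNormalizer().fit(counts)
    return norm.transform(counts), norm.size_factors_


def detection_filter(normalized: pd.DataFrame, min_max_count: float = 0.0) -> pd.DataFrame:
    """Keep features whose maximum normalized count strictly exceeds a floor.

    ``min_max_count=0`` keeps features detected in at least one sample
    (the gene rule); ``min_max_count=10`` applies the miRNA rule of a
    maximum normalized count over 10 reads.  The comparison is strict: a
    feature whose maximum is exactly the threshold is removed.
    Idempotent: filtering twice equals filtering once.
    """
    if min_max_count < 0:
        raise ValueError("min_max_count must be >= 0")
    keep = normalized.max(axis=1) > min_max_count
    dropped = int((~keep).sum())
    if dropped:
        log.info("detection_filter removed %d features at max-count threshold %g", dropped, min_max_count)
    return normalized.loc[keep]
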