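"""Per-sample size-factor estimation.

Sequencing depth differs across samples, so counts are scaled by a
per-sample size factor before any cross-sample comparison. Three
estimators are provided:

``total_count``
    s_i proportional to the sample's total read count.
``median_ratio``
    median-of-ratios to per-gene geometric means (DESeq-style); genes with
    a zero count in any sample are excluded (their geometric mean is 0).
``upper_quartile``
    s_i proportional to the 75th percentile of the sample's gene counts
    (linear-interpolation quantile).

All three divide by the sum over training samples, so training size
factors are positive and sum to 1. A test sample's factor reuses the
training denominator (and, for median_ratio, the training geometric
means), so a test sample identical to training sample i gets s* = s_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CountMatrix, TestSample, ValidationError

METHODS = ("total_count", "median_ratio", "upper_quartile")
DEFAULT_METHOD = "total_count"


@dataclass
class SizeFactors:
    """Training size factors plus the statistics needed for test samples.

    Attributes
    ----------
    s
        Per-sample positive factors summing to 1.
    method
        One of ``total_count``, ``median_ratio``, ``upper_quartile``.
    denominator
        The normalizing sum: grand total count, sum of raw median ratios,
        or sum of upper quartiles, depending on the method.
    geo_means
        Per-gene geometric means of training counts (median_ratio only;
        0 marks genes excluded from the median).
    """

    s: np.ndarray
    method: str
    denominator: float
    geo_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0):
            raise ValidationError("size factors must be strictly positive")

    @property
    def n(self) -> int:
        return self.s.size


def estimate_size_factors(train: CountMatrix, method: str = DEFAULT_METHOD) -> SizeFactors:
    """Dispatch to the requested estimator."""
    if method == "total_count":
        return size_factors_total_count(train)
    if method == "median_ratio":
        return size_factors_median_ratio(train)
    if method == "upper_quartile":
        return size_factors_upper_quartile(train)
    raise ValueError(f"unknown size-factor method {method!r}; choose from {METHODS}")


def size_factor_test(test: TestSample, sf: SizeFactors) -> float:
    """Size factor s* for a test sample, on the training scale."""
    x = np.asarray(test.counts, dtype=float)
    if sf.method == "total_count":
        total = x.sum()
        if total <= 0:
            raise ValidationError("all-zero test sample: total-count size factor undefined")
        return float(total / sf.denominator)
    if sf.method == "median_ratio":
        assert sf.geo_means is not None
        usable = sf.geo_means > 0
        m_star = float(np.median(x[usable] / sf.geo_means[usable]))
        if m_star <= 0:
            raise ValidationError(
                "test sample has zero median ratio; filter low-count genes first"
            )
        return float(m_star / sf.denominator)
    if sf.method == "upper_quartile":
        q_star = float(np.percentile(x, 75))
        if q_star <= 0:
            raise ValidationError(
                "test sample upper quartile is 0; filter low-count genes first"
            )
        return float(q_star / sf.denominator)
    raise ValueError(f"unknown size-factor method {sf.method!r}")


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def size_factors_total_count(train: CountMatrix) -> SizeFactors:
    """s_i = (sample i total) / (grand total)."""
    totals = train.counts.sum(axis=0).astype(float)
    if np.any(totals <= 0):
        bad = train.sample_ids[int(np.argmin(totals))]
        raise ValidationError(f"sample {bad!r} has zero total count; size factor undefined")
    grand = float(totals.sum())
    return SizeFactors(s=totals / grand, method="total_count", denominator=grand)


def size_factors_median_ratio(train: CountMatrix) -> SizeFactors:
    """Median-of-ratios to gene geometric means, normalized to sum to 1.

    m_i = median over genes with all-positive counts of X_ig / geomean_g;
    s_i = m_i / sum_i m_i.
    """
    X = train.counts.astype(float)
    usable = np.all(X > 0, axis=1)
    if not usable.any():
        raise ValidationError(
            "no gene has strictly positive counts in every sample; "
            "median-ratio size factors need at least one such gene "
            "(filter genes or use total_count)"
        )
    geo = np.zeros(train.n_genes)
    geo[usable] = np.exp(np.mean(np.log(X[usable]), axis=1))
    m = np.median(X[usable] / geo[usable, None], axis=0)
    m_sum = float(m.sum())
    return SizeFactors(s=m / m_sum, method="median_ratio", denominator=m_sum, geo_means=geo)


def size_factors_upper_quartile(train: CountMatrix) -> SizeFactors:
    """s_i proportional to the sample's 75th-percentile gene count."""
    q = np.percentile(train.counts, 75, axis=0).astype(float)
    if np.any(q <= 0):
        bad = train.sample_ids[int(np.argmin(q))]
        raise ValidationError(
            f"sample {bad!r} has upper quartile 0; filter low-count genes first"
        )
    q_sum = float(q.sum())
    return SizeFactors(s=q / q_sum, method="upper_quartile", denominator=q_sum)
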