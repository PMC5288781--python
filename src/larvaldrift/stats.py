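"""Biogeographic statistics: nested-model LRT and richness-substrate correlation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class NestedModelComparison:
    neg_lnl_null: float
    neg_lnl_alt: float
    df: int
    statistic: float
    p_value: float
    inverted: bool  # True when the "alternative" fits worse than the null


@dataclass
class RichnessCorrelation:
    labels: list
    r: float
    df: int
    p_value: float
    n: int


def nested_lrt(neg_lnl_null: float, neg_lnl_alt: float, df: int = 1) -> NestedModelComparison:
    """Likelihood-ratio test between nested models given -lnL values.

    D = 2 (-lnL_null - -lnL_alt); the p-value is the chi-square upper tail at
    the given degrees of freedom, evaluated in full double precision (no
    underflow to zero above ~1e-300).  A negative D (inverted input) is
    flagged and reported with p = 1.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    D = 2.0 * (neg_lnl_null - neg_lnl_alt)
    if D < 0:
        return NestedModelComparison(
            neg_lnl_null=neg_lnl_null,
            neg_lnl_alt=neg_lnl_alt,
            df=df,
            statistic=float(D),
            p_value=1.0,
            inverted=True,
        )
    p = float(sps.chi2.sf(D, df))
    return NestedModelComparison(
        neg_lnl_null=neg_lnl_null,
        neg_lnl_alt=neg_lnl_alt,
        df=df,
        statistic=float(D),
        p_value=p,
        inverted=False,
    )


def richness_correlation(counts, measure, labels=None) -> RichnessCorrelation:
    """Pearson correlation between species richness and a substrate measure.

    The two-sided p-value comes from t = r sqrt(df / (1 - r^2)) with
    df = n - 2, the standard test for a Pearson correlation.
    """
    counts = np.asarray(counts, dtype=float)
    measure = np.asarray(measure, dtype=float)
    if counts.shape != measure.shape or counts.ndim != 1:
        raise ValueError("counts and measure must be matched 1-d vectors")
    n = len(counts)
    if n < 3:
        raise ValueError("need at least 3 islands")
    if np.std(counts) == 0 or np.std(measure) == 0:
        raise ValueError("zero variance in counts or measure")
    res = sps.pearsonr(counts, measure)
    return RichnessCorrelation(
        labels=list(labels) if labels is not None else list(range(n)),
        r=float(res.statistic),
        df=n - 2,
        p_value=float(res.pvalue),
        n=n,
    )
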