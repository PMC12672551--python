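"""Method-comparison statistics: Pearson correlation and Bland–Altman.

These are the two tools used to compare simulated (CFD) endpoints against
echo-style estimates across a cohort: the product-moment correlation
coefficient, and the Bland–Altman summary of paired differences
(mean difference, standard deviation of the differences, and the
mean ± 1.96·SD limits of agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = ["AgreementStats", "pearson_r", "bland_altman"]

#: Multiplier defining the limits of agreement (95% under normality).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Bland–Altman summary for paired measurements of one quantity.

    Differences are taken as ``x - y`` (method A minus method B), so a
    positive ``mean_diff`` means method A reads higher on average.
    """

    mean_diff: float
    sdd: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.mean_diff <= self.loa_high):
            raise ValueError("limits of agreement must bracket mean_diff")


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two paired samples.

    Raises
    ------
    ValueError
        If the samples differ in length, have fewer than 3 pairs, or either
        has zero variance (the coefficient is undefined there; it is never
        silently reported as 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r requires two 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r is undefined for zero-variance input")
    return float(_sps.pearsonr(x, y).statistic)


def bland_altman(x, y) -> AgreementStats:
    """Bland–Altman agreement between paired methods ``x`` and ``y``.

    Uses the sample (n−1) standard deviation of the differences and fixed
    1.96 multiplier for the limits of agreement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("bland_altman requires two 1-d arrays of equal length")
    if x.size < 2:
        raise ValueError("bland_altman requires at least 2 pairs")
    d = x - y
    mean_diff = float(np.mean(d))
    sdd = float(np.std(d, ddof=1))
    return AgreementStats(
        mean_diff=mean_diff,
        sdd=sdd,
        loa_low=mean_diff - LOA_MULTIPLIER * sdd,
        loa_high=mean_diff + LOA_MULTIPLIER * sdd,
        n=int(d.size),
    )
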