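"""Circular and non-parametric statistics used by the trajectory pipeline.

The Rayleigh test assumes a unimodal alternative; orbiting produces an
axial (bimodal, 180-degree-symmetric) bearing distribution, so bearings
are angle-doubled first when that alternative is expected. Rank tests are
thin wrappers around scipy with the normal-approximation z reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError


def double_angles(angles_deg) -> np.ndarray:
    """Map each angle a -> (2a) mod 360.

    Collapses an axial (bimodal) distribution into a unimodal one: a and
    a + 180 map to the same doubled angle. Inputs are normalised into
    [0, 360) first.
    """
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    return np.mod(2.0 * a, 360.0)


@dataclass
class CircTestResult:
    """Rayleigh test outcome: z = n * r_bar**2."""

    z: float
    r_bar: float
    n: int
    p: float
    doubled: bool


def rayleigh_test(angles_deg, double: bool = False) -> CircTestResult:
    """Rayleigh z-test for non-uniformity of a circular sample (degrees).

    r_bar is the mean resultant length, z = n * r_bar**2, and the p-value
    uses the standard large-sample approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - n z)) - (1 + 2n)).
    """
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    n = a.size
    if n < 2:
        raise InsufficientDataError("Rayleigh test needs n >= 2 angles")
    if double:
        a = double_angles(a)
    rad = np.deg2rad(a)
    r_bar = float(np.hypot(np.cos(rad).mean(), np.sin(rad).mean()))
    z = n * r_bar ** 2
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n ** 2 - n * z))
                 - (1.0 + 2.0 * n))
    return CircTestResult(z=float(z), r_bar=r_bar, n=int(n),
                          p=min(p, 1.0), doubled=bool(double))


class Chi2Result(NamedTuple):
    statistic: float
    p: float
    defined: bool


def chi_square_2x2(table) -> Chi2Result:
    """Pearson chi-square (df = 1, no continuity correction) on a 2x2
    contingency table. A zero row/column marginal makes the statistic
    undefined; ``defined`` is then False and the numbers are nan."""
    T = np.asarray(table, dtype=float)
    if T.shape != (2, 2) or np.any(T < 0):
        raise ConfigurationError("table must be 2x2 with non-negative counts")
    if T.sum() == 0:
        raise ConfigurationError("table total must be > 0")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        return Chi2Result(math.nan, math.nan, False)
    stat, p, _, _ = stats.chi2_contingency(T, correction=False)
    return Chi2Result(float(stat), float(p), True)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ConfigurationError("number of tests m must be >= 1")
    return alpha / m


def wilcoxon_signed_rank(x, mu: float = 0.0) -> tuple:
    """One-sample Wilcoxon signed-rank test of location against ``mu``.

    Returns (|z|, p) from the normal approximation (tie-corrected,
    zero-differences dropped), matching the z-style reporting common in
    behavioural work.
    """
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0.0]
    if d.size == 0:
        raise InsufficientDataError("no non-zero differences")
    res = stats.wilcoxon(d, correction=False, method="approx")
    z = float(stats.norm.isf(res.pvalue / 2.0))
    return z, float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple:
    """Two-sample Wilcoxon rank-sum test; returns (z, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    res = stats.ranksums(x, y)
    return float(res.statistic), float(res.pvalue)
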