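"""Self-contained statistics used across the pipeline.

The Kolmogorov-Smirnov statistic and the Cochran-Armitage trend test are
implemented directly (they are checked against independent oracles in the
test suite); tail probabilities come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as sps

from .models import MISSING


@dataclass(frozen=True)
class KSResult:
    d: float
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0 + 1e-12):
            raise ValueError(f"D out of range: {self.d}")


@dataclass(frozen=True)
class TrendTable:
    """Case/control counts by genotype dosage (0, 1, 2 copies)."""

    r0: int
    r1: int
    r2: int
    s0: int
    s1: int
    s2: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.case_counts + self.control_counts):
            raise ValueError("negative counts")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def case_counts(self) -> tuple[int, int, int]:
        return (self.r0, self.r1, self.r2)

    @property
    def control_counts(self) -> tuple[int, int, int]:
        return (self.s0, self.s1, self.s2)

    @property
    def n_cases(self) -> int:
        return self.r0 + self.r1 + self.r2

    @property
    def n_controls(self) -> int:
        return self.s0 + self.s1 + self.s2

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    table: tuple[int, int, int, int]  # (a, b, c, d)
    continuity_corrected: bool = False


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample KS: D is the exact sup of |ECDF_x - ECDF_y| over the pooled
    sample points; p is asymptotic with effective n = |x||y| / (|x|+|y|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), pooled, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), pooled, side="right") / y.size
    d = float(np.abs(cdf_x - cdf_y).max())
    en = x.size * y.size / (x.size + y.size)
    p = float(np.clip(special.kolmogorov(math.sqrt(en) * d), 0.0, 1.0))
    return KSResult(d=min(d, 1.0), p=p)


_TREND_WEIGHTS = (0.0, 1.0, 2.0)


def cochran_armitage_trend(
    table: TrendTable, weights: Sequence[float] = _TREND_WEIGHTS
) -> tuple[float, float]:
    """Cochran-Armitage trend chi-square (1 df) and its two-sided p-value.

    Degenerate margins (no cases, no controls, or a single nonzero dosage
    column) give (0.0, 1.0).
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(table.case_counts, dtype=float)
    s = np.asarray(table.control_counts, dtype=float)
    big_r, big_s = r.sum(), s.sum()
    n = big_r + big_s
    cols = r + s
    if big_r == 0 or big_s == 0 or (cols > 0).sum() < 2:
        return 0.0, 1.0
    t = float(np.dot(w, r * big_s - s * big_r))
    var = (big_r * big_s / n) * (
        float(np.dot(w**2, cols * (n - cols)))
        - 2.0 * float(sum(w[i] * w[j] * cols[i] * cols[j]
                          for i in range(len(w)) for j in range(i + 1, len(w))))
    )
    if var <= 0:
        return 0.0, 1.0
    stat = t * t / var
    p = float(sps.chi2.sf(stat, df=1))
    return stat, p


def bonferroni_adjust(p: float, m: int) -> float:
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    return min(1.0, m * p)


def carrier_odds_ratio(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Odds ratio of the 2x2 (cases carrier a / non-carrier b, controls
    carrier c / non-carrier d), with a 95% CI from the log-OR normal
    approximation.  Zero cells trigger a Haldane-Anscombe 0.5 correction,
    flagged in the result."""
    if a + b == 0 or c + d == 0:
        raise ValueError("empty case or control row")
    cells = [a, b, c, d]
    corrected = any(x == 0 for x in cells)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = (float(x) for x in cells)
    or_value = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = sps.norm.ppf(0.975)
    return OddsRatioResult(
        or_value=or_value,
        ci_low=or_value * math.exp(-z * se),
        ci_high=or_value * math.exp(z * se),
        table=(a, b, c, d),
        continuity_corrected=corrected,
    )


def minor_allele_frequency(dosages: Sequence[int]) -> float:
    arr = np.asarray(dosages)
    ok = arr != MISSING
    if not ok.any():
        raise ValueError("all genotypes missing")
    f = float(arr[ok].sum()) / (2.0 * int(ok.sum()))
    return min(f, 1.0 - f)
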