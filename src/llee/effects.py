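"""Effect-size preprocessing: risk ratios from 2x2 tables, OR-to-RR conversion.

Published intervention studies report effects in mixed currencies.  Two
utilities put them on a relative-risk footing before calibration:

* :func:`rr_from_2x2` - the risk ratio from raw arm counts, with a Katz
  log-normal confidence interval and a Pearson chi-squared p-value (no
  continuity correction by default, matching the convention of quoting a
  plain chi-squared test alongside the RR).
* :func:`or_to_rr` - the Zhang-Yu correction converting an odds ratio to a
  risk ratio given the control-arm baseline risk:
  RR = OR / (1 - p0 + p0 * OR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = ["TwoByTwo", "RiskRatioResult", "UndefinedRiskError", "rr_from_2x2", "or_to_rr"]


class UndefinedRiskError(ValueError):
    """The control arm has zero events; the risk ratio is undefined."""


@dataclass(frozen=True)
class TwoByTwo:
    """Arm-level counts: a/n1 events in intervention, c/n0 in control."""

    a: int
    n1: int
    c: int
    n0: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n0 <= 0:
            raise ValueError("denominators n1 and n0 must be positive")
        if not 0 <= self.a <= self.n1:
            raise ValueError(f"a must be in [0, n1], got a={self.a}, n1={self.n1}")
        if not 0 <= self.c <= self.n0:
            raise ValueError(f"c must be in [0, n0], got c={self.c}, n0={self.n0}")


@dataclass(frozen=True)
class RiskRatioResult:
    """Risk ratio with Katz CI and chi-squared p; ``ci_defined`` is False
    when a zero cell makes the log-RR variance undefined (rr = 0 case)."""

    rr: float
    ci_low: float
    ci_high: float
    p_chi2: float
    ci_defined: bool = True


def _pearson_chi2_p(a: int, n1: int, c: int, n0: int, continuity: bool) -> float:
    b, d = n1 - a, n0 - c
    n = n1 + n0
    margins = (a + c, b + d)
    if 0 in margins:
        # all subjects share one outcome: no association to test
        return 1.0
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff * diff / (n1 * n0 * margins[0] * margins[1])
    return float(stats.chi2.sf(stat, df=1))


def rr_from_2x2(
    t: TwoByTwo, alpha: float = 0.05, continuity: bool = False
) -> RiskRatioResult:
    """Risk ratio (a/n1)/(c/n0) with Katz log CI and chi-squared p-value.

    The CI is exp(ln RR +/- z * sqrt(1/a - 1/n1 + 1/c - 1/n0)).  With zero
    events in the intervention arm the RR is 0 and the CI is flagged
    undefined rather than raising; zero control-arm events raise
    :class:`UndefinedRiskError`.
    """
    if t.c == 0:
        raise UndefinedRiskError("control arm has zero events; RR undefined")
    p = _pearson_chi2_p(t.a, t.n1, t.c, t.n0, continuity)
    rr = (t.a / t.n1) / (t.c / t.n0)
    if t.a == 0:
        return RiskRatioResult(0.0, math.nan, math.nan, p, ci_defined=False)
    var_terms = 1.0 / t.a - 1.0 / t.n1 + 1.0 / t.c - 1.0 / t.n0
    if var_terms <= 0:
        # both arms at 100% risk: RR exactly 1 with a degenerate interval
        return RiskRatioResult(rr, rr, rr, p, ci_defined=True)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = math.sqrt(var_terms)
    return RiskRatioResult(
        rr=rr,
        ci_low=rr * math.exp(-z * se),
        ci_high=rr * math.exp(z * se),
        p_chi2=p,
    )


def or_to_rr(or_value: float, p0: float) -> float:
    """Convert an odds ratio to a risk ratio at control-arm risk ``p0``.

    RR = OR / (1 - p0 + p0 * OR).  At p0 = 0 (rare outcome) RR = OR; as p0
    grows the RR is pulled toward 1.  Undefined at p0 = 1.
    """
    if or_value <= 0:
        raise ValueError(f"or_value must be > 0, got {or_value}")
    if not 0.0 <= p0 < 1.0:
        raise ValueError(f"p0 must be in [0, 1), got {p0}")
    return or_value / (1.0 - p0 + p0 * or_value)
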