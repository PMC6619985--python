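"""Sample-size planning for detecting an individual nurse effect.

The question: how many patient-shift encounters must a nurse accumulate so a
one-sample, one-tailed proportion test can distinguish the nurse's event
proportion from the unit norm?  The default formulation is the
normal-approximation score test, which uses the null variance for the
critical value and the alternative variance for the power:

    n = ceil( ( (z_{1-a} sqrt(p0 q0) + z_{1-b} sqrt(pa qa)) / (pa - p0) )^2 )

An exact-binomial mode is provided for verification: it enumerates the
critical value of the exact one-tailed test at each n and finds the smallest
n whose exact power reaches the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import PowerError


@dataclass(frozen=True)
class PowerSpec:
    """One-sample proportion test specification (one-tailed)."""

    p_null: float = 0.05705
    p_alt: float = 0.000001
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        for name in ("p_null", "p_alt", "alpha", "power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise PowerError(f"{name} must lie in (0, 1), got {v}")
        if self.p_null == self.p_alt:
            raise PowerError("p_null == p_alt: required n is infinite")


def min_encounters_per_nurse(spec: PowerSpec, method: str = "score") -> int:
    """Smallest integer n achieving the target power.

    method="score" uses the closed-form normal approximation above;
    method="exact" searches exact-binomial power over n.
    """
    if method == "score":
        z_a = stats.norm.ppf(1.0 - spec.alpha)
        z_b = stats.norm.ppf(spec.power)
        num = z_a * math.sqrt(spec.p_null * (1 - spec.p_null)) + z_b * math.sqrt(
            spec.p_alt * (1 - spec.p_alt)
        )
        n = math.ceil((num / (spec.p_alt - spec.p_null)) ** 2)
        return max(n, 1)
    if method == "exact":
        for n in range(1, 100000):
            if exact_power(spec, n) >= spec.power:
                return n
        raise PowerError("exact search exceeded n = 100000")
    raise PowerError(f"unknown method {method!r}")


def achieved_power(spec: PowerSpec, n: int) -> float:
    """Normal-approximation power of the one-tailed score test at sample size n."""
    if n < 1:
        raise PowerError("n must be >= 1")
    z_a = stats.norm.ppf(1.0 - spec.alpha)
    s0 = math.sqrt(spec.p_null * (1 - spec.p_null))
    sa = math.sqrt(spec.p_alt * (1 - spec.p_alt))
    if sa == 0.0:
        sa = 1e-12
    z = (abs(spec.p_alt - spec.p_null) * math.sqrt(n) - z_a * s0) / sa
    return float(stats.norm.cdf(z))


def exact_power(spec: PowerSpec, n: int) -> float:
    """Exact-binomial power of the one-tailed test (alternative below null).

    The critical value c is the largest event count with
    P(X <= c | p_null) <= alpha; power is P(X <= c | p_alt).
    """
    if n < 1:
        raise PowerError("n must be >= 1")
    p0, pa = spec.p_null, spec.p_alt
    if pa > p0:
        # mirror so the alternative is always the lower tail
        p0, pa = 1 - p0, 1 - pa
    cdf_null = stats.binom.cdf(range(n + 1), n, p0)
    c = -1
    for k in range(n + 1):
        if cdf_null[k] <= spec.alpha:
            c = k
        else:
            break
    if c < 0:
        return 0.0
    return float(stats.binom.cdf(c, n, pa))
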