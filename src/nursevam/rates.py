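"""Distributional diagnostics of nurse rates and the avoidable-case projection.

Moments use the sample (n-1) variance; kurtosis is on the Pearson scale
(normal = 3).  Normality is tested with the Kolmogorov-Smirnov statistic
under the Lilliefors correction by default (mean and SD are estimated from
the sample); a plain-KS variant is available.  Quartile 1 holds the LOWEST
rates.  The avoidable-case projection multiplies the lowest quartile's mean
shortfall below the sample median (per 100 encounters) by the per-nurse
encounter load and the number of low-quartile nurses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError
from .results import TestResult


def _as_rates(rates) -> tuple[np.ndarray, np.ndarray]:
    """Accept a NurseRateTable DataFrame or a plain vector; return
    (rates, nurse_ids)."""
    if isinstance(rates, pd.DataFrame):
        return rates["rate_per_100"].to_numpy(float), rates["nurse_id"].to_numpy()
    arr = np.asarray(rates, dtype=float)
    return arr, np.arange(len(arr))


def event_rate_percent(n_events: int, n_patients: int) -> float:
    """Observed event percentage: 100 * events / patients."""
    if n_patients <= 0:
        raise InsufficientDataError("n_patients must be positive")
    return 100.0 * n_events / n_patients


@dataclass
class DistributionSummary:
    mean: float
    median: float
    sd: float
    min: float
    max: float
    skewness: float
    kurtosis: float  # Pearson scale, normal = 3
    ks: TestResult | None
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        d = {
            k: float(getattr(self, k))
            for k in ("mean", "median", "sd", "min", "max", "skewness", "kurtosis")
        }
        d["n"] = self.n
        d["degenerate"] = self.degenerate
        d["ks"] = self.ks.to_dict() if self.ks is not None else None
        return d


def summarize_distribution(rates, ks_method: str = "lilliefors") -> DistributionSummary:
    """Moments plus a normality test for a vector of nurse rates."""
    x, _ = _as_rates(rates)
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 nurses for distribution moments")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return DistributionSummary(
            mean=float(x.mean()), median=float(np.median(x)), sd=0.0,
            min=float(x.min()), max=float(x.max()),
            skewness=0.0, kurtosis=0.0, ks=None, n=len(x), degenerate=True,
        )
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=False, bias=False))
    if ks_method == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(x, dist="norm")
    elif ks_method == "ks":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    else:
        raise ValueError(f"unknown ks_method {ks_method!r}")
    ks = TestResult(statistic=float(stat), p_value=float(np.clip(p, 0, 1)), kind="ks")
    return DistributionSummary(
        mean=float(x.mean()), median=float(np.median(x)), sd=sd,
        min=float(x.min()), max=float(x.max()),
        skewness=skew, kurtosis=kurt, ks=ks, n=len(x),
    )


@dataclass
class QuartileAssignment:
    assignments: pd.DataFrame  # nurse_id, quartile (1..4; 1 = lowest rates)
    cutpoints: tuple[float, float, float]

    def quartile_of(self) -> pd.Series:
        return self.assignments.set_index("nurse_id")["quartile"]

    def sizes(self) -> list[int]:
        return [int((self.assignments["quartile"] == q).sum()) for q in (1, 2, 3, 4)]


def assign_quartiles(rates) -> QuartileAssignment:
    """Rank-based quartiles of the rate distribution, quartile 1 lowest.

    Group sizes differ by at most one (any remainder goes to quartiles 1 and
    3 first, matching the published 24/23/24/23 pattern for n = 94).  Ties are
    broken by nurse_id order, deterministically; a tie spanning a cutpoint is
    logged as a warning.  A fully tied vector degenerates to quartile 1.
    """
    x, ids = _as_rates(rates)
    n = len(x)
    if n < 4:
        raise InsufficientDataError("need at least 4 nurses for quartiles")
    cutpoints = tuple(float(c) for c in np.quantile(x, [0.25, 0.5, 0.75]))
    if np.all(x == x[0]):
        warnings.warn("all rates tied; assigning every nurse to quartile 1")
        out = pd.DataFrame({"nurse_id": ids, "quartile": 1})
        return QuartileAssignment(out, cutpoints)

    order = np.lexsort((np.asarray(ids).astype(str), x))
    base, rem = divmod(n, 4)
    sizes = [base] * 4
    for q in (0, 2, 1, 3)[:rem]:
        sizes[q] += 1
    quart = np.empty(n, dtype=int)
    pos = 0
    for q, sz in enumerate(sizes, start=1):
        quart[order[pos : pos + sz]] = q
        pos += sz
    # warn when the value at a group boundary is shared across groups
    for q in (1, 2, 3):
        lo = x[order[sum(sizes[:q]) - 1]]
        hi = x[order[sum(sizes[:q])]]
        if lo == hi:
            warnings.warn(f"tied rates span the quartile {q}/{q + 1} boundary ({lo})")
    out = pd.DataFrame({"nurse_id": ids, "quartile": quart})
    return QuartileAssignment(out, cutpoints)


@dataclass
class AvoidableCasesEstimate:
    deficit_per_100: float  # mean below-median deviation of quartile-1 nurses (negative)
    shifts_per_nurse: float
    n_low_nurses: int
    avoidable_cases: int
    observed_cases: int
    relative_reduction_pct: float

    def to_dict(self) -> dict:
        return {
            "deficit_per_100": self.deficit_per_100,
            "shifts_per_nurse": self.shifts_per_nurse,
            "n_low_nurses": self.n_low_nurses,
            "avoidable_cases": self.avoidable_cases,
            "observed_cases": self.observed_cases,
            "relative_reduction_pct": self.relative_reduction_pct,
        }


def avoidable_cases_from_deficit(
    deficit_per_100: float,
    shifts_per_nurse: float,
    n_low_nurses: int,
    observed_cases: int,
) -> AvoidableCasesEstimate:
    """Counterfactual cases avoided by raising low-quartile nurses to the
    median: |deficit|/100 x shifts/nurse x nurses, rounded to whole cases."""
    if observed_cases <= 0:
        raise InsufficientDataError("observed_cases must be positive")
    avoidable = int(round(abs(deficit_per_100) / 100.0 * shifts_per_nurse * n_low_nurses))
    return AvoidableCasesEstimate(
        deficit_per_100=float(deficit_per_100),
        shifts_per_nurse=float(shifts_per_nurse),
        n_low_nurses=int(n_low_nurses),
        avoidable_cases=avoidable,
        observed_cases=int(observed_cases),
        relative_reduction_pct=100.0 * avoidable / observed_cases,
    )


def project_avoidable_cases(
    rates,
    quartiles: QuartileAssignment,
    shifts_per_nurse: float,
    observed_cases: int,
) -> AvoidableCasesEstimate:
    """Deficit = mean(quartile-1 rates) - median(all rates), then the
    arithmetic of :func:`avoidable_cases_from_deficit`."""
    x, ids = _as_rates(rates)
    q = quartiles.quartile_of().reindex(ids).to_numpy()
    low = x[q == 1]
    if len(low) == 0:
        raise InsufficientDataError("quartile 1 is empty")
    deficit = float(low.mean() - np.median(x))
    return avoidable_cases_from_deficit(deficit, shifts_per_nurse, len(low), observed_cases)


def plot_rate_distribution(rates, path) -> None:
    """Histogram with a normal overlay plus the empirical CDF."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, _ = _as_rates(rates)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].hist(x, bins=min(20, max(5, len(x) // 5)), density=True,
                 color="#5b8db8", edgecolor="white")
    mu, sd = x.mean(), np.std(x, ddof=1)
    if sd > 0:
        grid = np.linspace(x.min() - sd, x.max() + sd, 200)
        axes[0].plot(grid, stats.norm.pdf(grid, mu, sd), "k--", lw=1)
    axes[0].set_xlabel("CAABU-free rate per 100 patient-shifts")
    axes[0].set_ylabel("density")
    xs = np.sort(x)
    axes[1].step(xs, np.arange(1, len(xs) + 1) / len(xs), where="post", color="#5b8db8")
    axes[1].set_xlabel("CAABU-free rate per 100 patient-shifts")
    axes[1].set_ylabel("empirical CDF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
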