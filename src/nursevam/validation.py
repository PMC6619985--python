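"""Cross-sample validation of nurse rate estimates.

Four analyses, mirroring a split-sample design with an estimation half
("2015") and a validation half ("2016"):

* randomness-of-assignment balance tests: were last year's nurse rates
  associated with this year's assigned-patient characteristics?
* a weighted Pearson correlation between the two halves' rate estimates,
  weighted by each nurse's total encounter count;
* k-medians clustering (Canberra distance) of nurses in the 2-D space of
  (estimation rate, validation rate);
* a quartile-to-quartile transition matrix estimated by a weighted saturated
  multinomial logistic regression, with delta-method 95% CIs and one-tailed
  tests of each cell against the 0.25 random-chance probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .cohort import AssembledCohort
from .exceptions import ValidationError
from .rates import QuartileAssignment
from .results import TestResult

# ------------------------------------------------------------------ balance


@dataclass
class BalanceReport:
    tests: dict[str, TestResult]
    random_assignment_supported: bool
    n_high: int
    n_low: int

    def to_dict(self) -> dict:
        return {
            "tests": {k: t.to_dict() for k, t in self.tests.items()},
            "random_assignment_supported": self.random_assignment_supported,
            "n_high": self.n_high,
            "n_low": self.n_low,
        }


def _two_group_t(high: np.ndarray, low: np.ndarray) -> TestResult:
    if len(high) < 2 or len(low) < 2:
        return TestResult(statistic=np.nan, p_value=np.nan, kind="t")
    if np.var(high) == 0 and np.var(low) == 0:
        # identical pools: no evidence against balance by construction
        equal = float(np.mean(high)) == float(np.mean(low))
        return TestResult(statistic=0.0, p_value=1.0 if equal else 0.0, kind="t",
                          df=len(high) + len(low) - 2)
    t, p = stats.ttest_ind(high, low, equal_var=False)
    df = len(high) + len(low) - 2
    return TestResult(statistic=float(t), p_value=float(p), kind="t", df=df)


def _lumped_chi2(cat: pd.Series, group: np.ndarray, min_expected: float = 5.0) -> TestResult:
    tab = pd.crosstab(cat, group)
    if tab.shape[1] < 2:
        return TestResult(statistic=np.nan, p_value=np.nan, kind="chi2")
    # lump categories whose smallest expected count is below threshold
    expected_min = tab.sum(axis=1) * tab.sum(axis=0).min() / tab.to_numpy().sum()
    rare = expected_min < min_expected
    if rare.any() and (~rare).sum() >= 1:
        lumped = tab.loc[~rare].copy()
        lumped.loc["(other)"] = tab.loc[rare].sum()
        tab = lumped
    if tab.shape[0] < 2:
        return TestResult(statistic=0.0, p_value=1.0, kind="chi2", df=1)
    chi2, p, df, _ = stats.chi2_contingency(tab.to_numpy())
    return TestResult(statistic=float(chi2), p_value=float(p), kind="chi2", df=df)


def assignment_balance_tests(
    rates_est: pd.DataFrame,
    cohort_val: AssembledCohort,
    alpha: float = 0.05,
) -> BalanceReport:
    """Test whether estimation-half nurse rates predict validation-half
    patient characteristics (the random-assignment null).

    Nurses are split at the median of their estimation rates, and each
    validation-half patient is classified high/low by the mean estimation rate
    of their attending nurses (averaged over the patient's encounters).  The
    two patient groups — each patient counted once, so groups are made of
    independent units — are compared with Welch t-tests for continuous/binary
    covariates and chi-square tests (rare categories lumped) for MDC and
    insurance.
    """
    enc = cohort_val.encounters
    rate_map = rates_est.set_index("nurse_id")["rate_per_100"]
    common = sorted(set(rate_map.index) & {n for t in enc["nurse_ids"] for n in t})
    if not common:
        raise ValidationError("no overlapping nurses between estimation rates and validation cohort")
    rate_map = rate_map.loc[common]
    med = float(np.median(rate_map.to_numpy()))
    high_set = {n for n, r in rate_map.items() if r > med}
    low_set = {n for n, r in rate_map.items() if r <= med}

    pat = enc.drop_duplicates("patient_id").set_index("patient_id")
    pat_rates = (
        pd.DataFrame(
            [
                (pid, np.mean([rate_map[n] for n in tup if n in rate_map.index]))
                for tup, pid in zip(enc["nurse_ids"], enc["patient_id"])
                if any(n in rate_map.index for n in tup)
            ],
            columns=["patient_id", "rate"],
        )
        .groupby("patient_id")["rate"]
        .mean()
    )
    group = pat_rates > med
    pat2 = pat.loc[pat.index.intersection(group.index)]
    grp = group.loc[pat2.index].to_numpy()

    tests: dict[str, TestResult] = {}
    for covname in ("age", "male", "surgical", "prior_admission_30d"):
        v = pat2[covname].to_numpy(float)
        tests[covname] = _two_group_t(v[grp], v[~grp])
    grp_label = np.where(grp, "high", "low")
    tests["mdc"] = _lumped_chi2(pat2["mdc"], grp_label)
    tests["insurance"] = _lumped_chi2(pat2["insurance"], grp_label)

    ok = all(
        np.isnan(t.p_value) or t.p_value > alpha for t in tests.values()
    )
    return BalanceReport(
        tests=tests,
        random_assignment_supported=ok,
        n_high=len(high_set),
        n_low=len(low_set),
    )


# -------------------------------------------------------------- correlation


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    weights_used: bool
    n_pairs: int

    def to_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "p_value": self.p_value,
            "weights_used": self.weights_used,
            "n_pairs": self.n_pairs,
        }


def weighted_rate_correlation(
    rates_a: pd.DataFrame, rates_b: pd.DataFrame
) -> CorrelationResult:
    """Weighted Pearson correlation between two rate tables over common
    nurses, weighted by summed encounter counts across both samples; the
    zero-correlation t-test uses effective-n degrees of freedom."""
    a = rates_a.set_index("nurse_id")
    b = rates_b.set_index("nurse_id")
    common = sorted(set(a.index) & set(b.index))
    if len(common) < 3:
        raise ValidationError("need at least 3 common nurses for a correlation")
    x = a.loc[common, "rate_per_100"].to_numpy(float)
    y = b.loc[common, "rate_per_100"].to_numpy(float)
    w = (
        a.loc[common, "n_encounters"].to_numpy(float)
        + b.loc[common, "n_encounters"].to_numpy(float)
    )
    if np.all(w == 0):
        raise ValidationError("all weights are zero")
    w = w / w.sum()
    mx, my = float(w @ x), float(w @ y)
    vx = float(w @ (x - mx) ** 2)
    vy = float(w @ (y - my) ** 2)
    tol = 1e-12 * max(1.0, mx * mx, my * my)
    if vx <= tol or vy <= tol:
        raise ValidationError("zero-variance rate vector: correlation undefined")
    cov = float(w @ ((x - mx) * (y - my)))
    r = cov / np.sqrt(vx * vy)
    r = float(np.clip(r, -1.0, 1.0))
    n_eff = 1.0 / float(np.sum(w**2))
    df = max(n_eff - 2.0, 1.0)
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(coefficient=r, p_value=p, weights_used=True, n_pairs=len(common))


# ---------------------------------------------------------------- k-medians


@dataclass
class ClusterAssignment:
    assignments: pd.DataFrame  # nurse_id, cluster (1..k)
    medians: np.ndarray  # k x 2
    n_iterations_run: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def objective(self) -> float:
        return self.objective_history[-1]


def _canberra_cost(points: np.ndarray, median: np.ndarray) -> float:
    return float(cdist(points, median[None, :], metric="canberra").sum())


def cluster_nurses(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
    k: int = 4,
    init: QuartileAssignment | None = None,
    max_iter: int = 10000,
    seed: int = 0,
) -> ClusterAssignment:
    """k-medians in (estimation rate, validation rate) space under the
    Canberra distance d(x, y) = sum_i |x_i - y_i| / (|x_i| + |y_i|).

    Initial groups come from the estimation-half quartiles (quartile q ->
    cluster q) when ``init`` is given, else from a seeded random partition.
    Medians update component-wise; an update that would increase a cluster's
    cost is rejected, so the objective is nonincreasing.  An emptied cluster
    is re-seeded at the point farthest from its assigned median.
    """
    a = rates_a.set_index("nurse_id")["rate_per_100"]
    b = rates_b.set_index("nurse_id")["rate_per_100"]
    common = sorted(set(a.index) & set(b.index))
    if len(common) < k:
        raise ValidationError(f"need at least k={k} common nurses")
    pts = np.column_stack([a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)])
    n = len(common)
    rng = np.random.default_rng([int(seed), 23])
    if init is not None:
        qmap = init.quartile_of()
        labels = np.array([int(qmap.get(nid, 0)) - 1 for nid in common])
        labels[labels < 0] = rng.integers(0, k, size=int((labels < 0).sum()))
        labels = np.clip(labels, 0, k - 1)
    else:
        labels = rng.integers(0, k, size=n)

    medians = np.zeros((k, 2))
    for c in range(k):
        sel = pts[labels == c]
        medians[c] = np.median(sel, axis=0) if len(sel) else pts[rng.integers(n)]

    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        D = cdist(pts, medians, metric="canberra")
        new_labels = D.argmin(axis=1)
        # re-seed emptied clusters at the farthest point
        for c in range(k):
            if not np.any(new_labels == c):
                far = int(D[np.arange(n), new_labels].argmax())
                warnings.warn(f"cluster {c + 1} emptied; re-seeding at farthest point")
                medians[c] = pts[far]
                D = cdist(pts, medians, metric="canberra")
                new_labels = D.argmin(axis=1)
        obj = float(D[np.arange(n), new_labels].sum())
        history.append(obj)
        changed = not np.array_equal(new_labels, labels)
        labels = new_labels
        # safeguarded component-wise median update
        moved = False
        for c in range(k):
            sel = pts[labels == c]
            cand = np.median(sel, axis=0)
            if _canberra_cost(sel, cand) <= _canberra_cost(sel, medians[c]):
                if not np.allclose(cand, medians[c]):
                    moved = True
                medians[c] = cand
        if not changed and not moved:
            break

    out = pd.DataFrame({"nurse_id": common, "cluster": labels + 1})
    return ClusterAssignment(out, medians, n_iter, history)


# ------------------------------------------------------------- transitions


@dataclass
class TransitionMatrix:
    probs: pd.DataFrame  # 4x4, rows = period-1 quartile, cols = period-2 quartile
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    tests_vs_quarter: pd.DataFrame  # one-tailed p-values for p > 0.25
    statistics: pd.DataFrame  # signed chi-square statistics
    weights: pd.Series
    counts: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Table-2-style layout: 'prob (lo, hi)' strings."""
        rows = {}
        for q1 in self.probs.index:
            rows[q1] = {
                q2: f"{self.probs.loc[q1, q2]:.3f} "
                f"({self.ci_low.loc[q1, q2]:.3f}, {self.ci_high.loc[q1, q2]:.3f})"
                for q2 in self.probs.columns
            }
        return pd.DataFrame(rows).T


def _fit_weighted_mnlogit(
    X: np.ndarray, ycat: np.ndarray, w: np.ndarray, n_classes: int,
    maxiter: int = 300, tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton fit of a weighted multinomial logit (class 0 is reference).

    Returns (theta [kx * (n_classes-1)], covariance from the inverse Hessian,
    pseudo-inverted when the design is saturated with empty cells).
    """
    n, kx = X.shape
    m = n_classes - 1
    theta = np.zeros(kx * m)
    Y = np.zeros((n, m))
    for j in range(1, n_classes):
        Y[:, j - 1] = ycat == j

    def probs(th):
        Z = X @ th.reshape(m, kx).T  # n x m
        Z = np.column_stack([np.zeros(n), Z])
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        P = E / E.sum(axis=1, keepdims=True)
        return P  # n x n_classes

    ll_old = -np.inf
    H = np.eye(kx * m)
    for _ in range(maxiter):
        P = probs(theta)
        ll = float(np.sum(w * np.log(np.clip(P[np.arange(n), ycat], 1e-300, None))))
        grad = np.zeros(kx * m)
        H = np.zeros((kx * m, kx * m))
        for j in range(m):
            grad[j * kx : (j + 1) * kx] = X.T @ (w * (Y[:, j] - P[:, j + 1]))
            for l in range(m):
                wjl = w * (
                    P[:, j + 1] * ((j == l) - P[:, l + 1])
                )
                H[j * kx : (j + 1) * kx, l * kx : (l + 1) * kx] = (X * wjl[:, None]).T @ X
        if np.max(np.abs(grad)) < 1e-10:
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(kx * m), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(H) @ grad
        step = np.clip(step, -10, 10)
        theta = theta + step
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0) and np.max(np.abs(grad)) < 1e-8:
            break
        ll_old = ll
    cov = np.linalg.pinv(H)
    return theta, cov


def transition_matrix(
    quart_a: QuartileAssignment,
    quart_b: QuartileAssignment,
    weights: pd.Series,
) -> TransitionMatrix:
    """Quartile-to-quartile transition probabilities with 95% CIs and
    one-tailed tests against the 0.25 random-chance value.

    Estimated by a nurse-level weighted multinomial logistic regression of the
    period-2 quartile on period-1 quartile indicators (saturated), followed by
    predictive margins per period-1 quartile.  Weights are per-nurse encounter
    counts, normalized to sum to the number of nurses so that CI widths are on
    the nurse scale.  The test against 0.25 is a one-sample proportion score
    test with a direction-signed chi-square statistic.
    """
    qa = quart_a.quartile_of()
    qb = quart_b.quartile_of()
    common = sorted(set(qa.index) & set(qb.index))
    if len(common) < 4:
        raise ValidationError("need at least 4 common nurses")
    qa = qa.loc[common].to_numpy()
    qb = qb.loc[common].to_numpy()
    w = weights.reindex(common).to_numpy(float)
    if np.any(~np.isfinite(w)) or np.all(w <= 0):
        raise ValidationError("invalid weights")
    for q in (1, 2, 3, 4):
        if not np.any(qa == q):
            raise ValidationError(f"period-1 quartile {q} is empty: row undefined")
    w = w * len(common) / w.sum()

    X = np.column_stack([np.ones(len(common))] + [(qa == q).astype(float) for q in (2, 3, 4)])
    ycat = qb - 1
    theta, cov = _fit_weighted_mnlogit(X, ycat, w, n_classes=4)

    kx, m = 4, 3
    Th = theta.reshape(m, kx)
    labels = [f"Q{q}" for q in (1, 2, 3, 4)]
    P = np.zeros((4, 4))
    CL = np.zeros((4, 4))
    CH = np.zeros((4, 4))
    PV = np.ones((4, 4))
    ST = np.zeros((4, 4))
    z975 = stats.norm.ppf(0.975)
    for qi, q in enumerate((1, 2, 3, 4)):
        x = np.zeros(kx)
        x[0] = 1.0
        if q > 1:
            x[q - 1] = 1.0
        z = np.concatenate([[0.0], Th @ x])
        z = z - z.max()
        e = np.exp(z)
        p = e / e.sum()
        P[qi] = p
        # delta method: dp_c/dtheta_{j} = p_c (1{c=j} - p_j) x
        Grad = np.zeros((4, kx * m))
        for c in range(4):
            for j in range(1, 4):
                Grad[c, (j - 1) * kx : j * kx] = p[c] * ((c == j) - p[j]) * x
        var = np.clip(np.einsum("ck,kl,cl->c", Grad, cov, Grad), 0.0, None)
        se = np.sqrt(var)
        CL[qi] = p - z975 * se
        CH[qi] = p + z975 * se
        row_w = w[qa == q]
        n_eff = float(row_w.sum() ** 2 / np.sum(row_w**2))
        se0 = np.sqrt(0.25 * 0.75 / n_eff)
        zstat = (p - 0.25) / se0
        ST[qi] = np.sign(zstat) * zstat**2
        PV[qi] = stats.norm.sf(zstat)  # one-tailed: alternative p > 0.25

    counts = pd.crosstab(pd.Series(qa, name="q1"), pd.Series(qb, name="q2")).reindex(
        index=(1, 2, 3, 4), columns=(1, 2, 3, 4), fill_value=0
    )
    mk = lambda A: pd.DataFrame(A, index=labels, columns=labels)
    return TransitionMatrix(
        probs=mk(P), ci_low=mk(CL), ci_high=mk(CH),
        tests_vs_quarter=mk(PV), statistics=mk(ST),
        weights=pd.Series(w, index=common), counts=counts,
    )


def plot_cross_validation(
    rates_a: pd.DataFrame,
    rates_b: pd.DataFrame,
    clusters: ClusterAssignment,
    path,
) -> None:
    """Scatter of estimation vs validation rates, sized by encounters,
    colored by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = rates_a.set_index("nurse_id")
    b = rates_b.set_index("nurse_id")
    lab = clusters.assignments.set_index("nurse_id")["cluster"]
    common = lab.index
    x = a.loc[common, "rate_per_100"]
    y = b.loc[common, "rate_per_100"]
    size = a.loc[common, "n_encounters"] + b.loc[common, "n_encounters"]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    sc = ax.scatter(x, y, s=10 + 90 * size / size.max(), c=lab, cmap="viridis", alpha=0.8)
    ax.set_xlabel("CAABU-free rate per 100, estimation half")
    ax.set_ylabel("CAABU-free rate per 100, validation half")
    handles, _ = sc.legend_elements()
    ax.legend(handles, [f"cluster {c}" for c in sorted(lab.unique())], loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
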