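"""Fixed-effects logistic value-added model (VAM) for nurse-level outcomes.

The model is a logistic regression of the encounter-level CAABU-free
indicator on a block of nurse indicator variables (one per roster nurse,
minus a random reference) plus patient covariates, shift controls, and a
unit fixed effect:

    logit P(Y_i = 1) = alpha + sum_j beta_j N_ij + x_i' gamma

Inference uses a clustered sandwich covariance (patients by default; a
row-level "encounter" option degenerates to the HC1 heteroskedasticity-robust
estimator).  Because several nurses in this setting have all-CAABU-free
encounter histories, the plain MLE is separated; the default fit applies a
small ridge (1e-4 * n_obs) to the NURSE coefficients only, which keeps every
nurse in the rate table.  ``penalty=0`` reproduces conventional behavior by
dropping perfectly-predicting nurse columns before maximizing.

Per-nurse CAABU-free rates are predictive margins: the sample-average
predicted probability with nurse j's indicator forced to 1 and (by default)
every other nurse indicator forced to 0, covariates at observed values,
scaled to a rate per 100 encounters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import VamDesign
from .exceptions import FitError, SeparationError
from .results import TestResult

DEFAULT_PENALTY_SCALE = 1e-4  # ridge per nurse coefficient = scale * n_obs
MAX_ITER = 200
TOL = 1e-8


def _cr2_meat(X, resid, w, groups, G, Hinv):
    """Bell-McCaffrey (CR2) bias-reduced meat for a weighted-GLM sandwich.

    Per cluster g, scores are adjusted by the inverse symmetric square root
    of I - H_gg computed on the W^{1/2}-scaled design, which removes the
    downward leverage bias of the plain cluster sandwich; with singleton
    clusters this reduces to HC2.  Near-zero eigenvalues (absorbed clusters)
    are pseudo-inverted.
    """
    k = X.shape[1]
    sw = np.sqrt(w)
    order = np.argsort(groups, kind="stable")
    Xo, ro, swo, go = X[order], resid[order], sw[order], groups[order]
    bounds = np.flatnonzero(np.r_[True, go[1:] != go[:-1], True])
    meat = np.zeros((k, k))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        Xg = Xo[b0:b1]
        Ug = Xg * swo[b0:b1, None]
        Bg = -Ug @ Hinv @ Ug.T
        Bg[np.diag_indices_from(Bg)] += 1.0
        vals, vecs = np.linalg.eigh((Bg + Bg.T) / 2.0)
        inv_sqrt = np.where(vals > 1e-10, 1.0 / np.sqrt(np.clip(vals, 1e-10, None)), 0.0)
        Ag = (vecs * inv_sqrt) @ vecs.T
        eg = ro[b0:b1] / np.where(swo[b0:b1] > 0, swo[b0:b1], 1.0)
        sg = Ug.T @ (Ag @ eg)
        meat += np.outer(sg, sg)
    return meat


def _penalized_loglik(y, eta, beta, P):
    # numerically safe Bernoulli log-likelihood minus quadratic ridge
    ll = np.sum(y * eta - np.logaddexp(0.0, eta))
    return ll - 0.5 * float(beta @ (P @ beta))


def _nurse_ridge_matrix(k, nurse_ix, lam, n_nurses_total):
    """Centered ridge on the nurse block.

    Penalizes each nurse effect's deviation from the block mean (with a
    weak lam/J pull of the mean itself toward zero, which identifies the
    block against the intercept): lam * [sum_j (e_j - e_bar)^2 + J e_bar^2 / J].
    A plain diagonal ridge would shrink everyone toward an arbitrary
    reference; the centered form treats all nurses symmetrically.
    """
    P = np.zeros((k, k))
    if lam == 0.0 or len(nurse_ix) == 0:
        return P
    m = len(nurse_ix)
    J = n_nurses_total
    block = lam * (np.eye(m) - (1.0 - 1.0 / J) * np.ones((m, m)) / J)
    P[np.ix_(nurse_ix, nurse_ix)] = block
    return P


class CaabuVam:
    """Value-added logistic model over a :class:`~nursevam.cohort.VamDesign`."""

    def __init__(self, design: VamDesign):
        if not design.nurse_cols:
            raise FitError("design has no nurse columns")
        if len(np.unique(design.y)) < 2:
            raise FitError("outcome is constant; the model is not estimable")
        self.design = design

    @classmethod
    def from_cohort(cls, cohort, ref_seed: int = 0) -> "CaabuVam":
        from .cohort import build_design_matrix

        return cls(build_design_matrix(cohort, ref_seed=ref_seed))

    def fit(
        self,
        penalty: float | None = None,
        cluster_level: str = "patient",
        cov_method: str = "cr2",
        maxiter: int = MAX_ITER,
        tol: float = TOL,
    ) -> "CaabuVamResults":
        """Maximize the (optionally nurse-ridge-penalized) likelihood.

        penalty: ridge strength applied to each nurse coefficient; ``None``
        selects the default ``1e-4 * n_obs``; ``0`` is plain ML with
        perfectly-predicting nurse columns dropped first.

        cov_method: "cr2" (default) is the bias-reduced Bell-McCaffrey
        cluster covariance, which keeps Wald tests near nominal size when
        events are sparse within clusters; "cr1" is the conventional
        Stata-style sandwich with the G/(G-1) x (N-1)/(N-K) factor.
        """
        if cluster_level not in ("patient", "encounter"):
            raise FitError(f"unknown cluster_level {cluster_level!r}")
        design = self.design
        X_df = design.X
        y = design.y.astype(float)
        n = len(y)
        lam = DEFAULT_PENALTY_SCALE * n if penalty is None else float(penalty)
        if lam < 0:
            raise FitError("penalty must be >= 0")

        nurse_cols = list(design.nurse_cols)
        dropped_separated: list[str] = []
        # Perfectly-predicting indicator columns make the MLE diverge along
        # that axis.  Nurse columns are kept when the ridge is on (keeping
        # every nurse in the rate table is the point of the ridge); covariate
        # indicators are always dropped, i.e. merged with their reference
        # category, as conventional packages do.
        nurse_set = set(nurse_cols)
        for c in X_df.columns:
            if c == "const" or (lam > 0.0 and c in nurse_set):
                continue
            v = X_df[c].to_numpy()
            if set(np.unique(v)) <= {0.0, 1.0}:
                on, off = v == 1.0, v == 0.0
                # either side of a binary split being outcome-constant sends
                # the MLE along that axis to infinity
                if (on.any() and y[on].min() == y[on].max()) or (
                    off.any() and y[off].min() == y[off].max()
                ):
                    dropped_separated.append(c)
        if dropped_separated:
            warnings.warn(
                f"dropped {len(dropped_separated)} perfectly-predicting "
                f"indicator columns (separation): {dropped_separated[:6]}"
            )
            X_df = X_df.drop(columns=dropped_separated)
            nurse_cols = [c for c in nurse_cols if c not in dropped_separated]
            if not nurse_cols:
                raise SeparationError(
                    "all nurse columns perfectly predict the outcome; "
                    "refit with penalty > 0"
                )

        ref_col = f"nurse:{design.ref_nurse}"
        if lam > 0.0 and design.ref_nurse_indicator is not None and ref_col not in X_df.columns:
            # penalized fits carry the FULL nurse block: with multi-nurse
            # encounters the reference-dropped design spans a genuinely
            # different model per reference choice; the centered ridge over
            # all nurses is reference-invariant
            X_df = X_df.copy()
            X_df[ref_col] = np.asarray(design.ref_nurse_indicator, dtype=float)
            nurse_cols = nurse_cols + [ref_col]

        cols = list(X_df.columns)
        X = X_df.to_numpy(dtype=float)
        k = X.shape[1]
        nurse_ix = [cols.index(c) for c in nurse_cols]
        n_nurses_total = len(design.nurse_cols) + 1  # roster incl. reference
        P = _nurse_ridge_matrix(k, nurse_ix, lam, n_nurses_total)

        beta = np.zeros(k)
        p_bar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[cols.index("const")] = np.log(p_bar / (1 - p_bar))
        eta = X @ beta
        ll = _penalized_loglik(y, eta, beta, P)
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            p = expit(eta)
            w = np.clip(p * (1 - p), 1e-12, None)
            grad = X.T @ (y - p) - P @ beta
            H = (X * w[:, None]).T @ X + P
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # step-halving line search on the penalized log-likelihood
            t = 1.0
            for _ in range(40):
                beta_new = beta + t * step
                eta_new = X @ beta_new
                ll_new = _penalized_loglik(y, eta_new, beta_new, P)
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            beta, eta = beta_new, eta_new
            if abs(ll_new - ll) < tol * (abs(ll) + 1.0) and np.max(np.abs(grad)) < 1e-5 * n:
                ll = ll_new
                converged = True
                break
            ll = ll_new
        if not converged:
            if lam == 0.0 and np.max(np.abs(beta)) > 25:
                raise SeparationError(
                    "MLE diverging (|coef| > 25): likely separation; refit with penalty > 0",
                    details={"max_abs_coef": float(np.max(np.abs(beta))), "n_iter": n_iter},
                )
            raise FitError(
                f"no convergence after {n_iter} iterations",
                details={"last_ll": float(ll), "max_grad": float(np.max(np.abs(grad)))},
            )

        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X + P
        Hinv = np.linalg.pinv(H)

        resid = y - p
        if cluster_level == "patient":
            groups = pd.factorize(design.cluster_patient)[0]
        else:
            groups = np.arange(n)
        G = int(groups.max()) + 1
        if cov_method == "cr1":
            S = np.zeros((G, k))
            np.add.at(S, groups, X * resid[:, None])
            meat = S.T @ S
            dof_c = (G / max(G - 1, 1)) * ((n - 1) / max(n - k, 1))
        elif cov_method == "cr2":
            meat = _cr2_meat(X, resid, w, groups, G, Hinv)
            dof_c = 1.0
        else:
            raise FitError(f"unknown cov_method {cov_method!r}")
        V = dof_c * Hinv @ meat @ Hinv
        V = (V + V.T) / 2.0

        llf = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return CaabuVamResults(
            model=self,
            params=pd.Series(beta, index=cols),
            cov=pd.DataFrame(V, index=cols, columns=cols),
            nurse_cols=nurse_cols,
            dropped_separated=dropped_separated,
            llf=llf,
            nobs=n,
            converged=converged,
            n_iter=n_iter,
            penalty=lam,
            cluster_level=cluster_level,
            cov_method=cov_method,
            n_clusters=G,
            fittedvalues=pd.Series(p, index=X_df.index),
        )


@dataclass
class CaabuVamResults:
    """Fitted VAM: coefficients, clustered covariance, margins, tests."""

    model: CaabuVam
    params: pd.Series
    cov: pd.DataFrame
    nurse_cols: list[str]
    dropped_separated: list[str]
    llf: float
    nobs: int
    converged: bool
    n_iter: int
    penalty: float
    cluster_level: str
    cov_method: str
    n_clusters: int
    fittedvalues: pd.Series

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.clip(np.diag(self.cov.to_numpy()), 0.0, None)),
            index=self.params.index,
        )

    @property
    def design(self) -> VamDesign:
        return self.model.design

    # ---------------------------------------------------------------- margins
    def nurse_margins(self, mode: str = "zero") -> pd.DataFrame:
        """Per-nurse adjusted CAABU-free rates per 100 encounters.

        mode="zero" (default): profile nurse j with every OTHER nurse
        indicator set to 0 — a pure single-nurse counterfactual.
        mode="observed": leave the other nurse indicators at observed values.
        The reference nurse's margin uses an all-zero nurse block.  Standard
        errors are delta-method under the clustered covariance.
        """
        if mode not in ("zero", "observed"):
            raise ValueError(f"unknown margin mode {mode!r}")
        design = self.design
        cols = list(self.params.index)
        X = design.X.reindex(columns=cols).to_numpy(dtype=float)
        beta = self.params.to_numpy()
        V = self.cov.to_numpy()
        nurse_ix = np.array([cols.index(c) for c in self.nurse_cols], dtype=int)
        cov_ix = np.array([i for i in range(len(cols)) if i not in set(nurse_ix)], dtype=int)

        if mode == "zero":
            base_eta = X[:, cov_ix] @ beta[cov_ix]
        else:
            base_eta = X @ beta  # adjusted per-nurse below

        roster = sorted(design.nurse_link_counts.index)
        records = []
        for nurse in roster:
            col = f"nurse:{nurse}"
            if col in self.dropped_separated:
                # penalty=0 drops separated nurses from the model: their rate
                # is the observed (degenerate) one, with no SE
                records.append((nurse, np.nan, np.nan))
                continue
            if col in cols:
                j_ix = cols.index(col)
                b_j = beta[j_ix]
            else:
                # reference nurse of an unpenalized fit: implicit zero
                j_ix = None
                b_j = 0.0
            if mode == "zero":
                eta_j = base_eta + b_j
            elif j_ix is None:
                # reference nurse contributes 0 to eta; observed values kept
                eta_j = base_eta
            else:
                eta_j = base_eta + b_j * (1.0 - X[:, j_ix])
            p_j = expit(eta_j)
            m = p_j.mean()
            wgt = p_j * (1 - p_j)
            g = np.zeros(len(cols))
            if mode == "zero":
                g[cov_ix] = (X[:, cov_ix] * wgt[:, None]).mean(axis=0)
                if j_ix is not None:
                    g[j_ix] = wgt.mean()
            else:
                Xj = X.copy()
                if j_ix is not None:
                    Xj[:, j_ix] = 1.0
                g = (Xj * wgt[:, None]).mean(axis=0)
            se = float(np.sqrt(max(g @ V @ g, 0.0)))
            records.append((nurse, 100.0 * m, 100.0 * se))

        out = pd.DataFrame(records, columns=["nurse_id", "rate_per_100", "std_err"])
        out["n_encounters"] = out["nurse_id"].map(design.nurse_link_counts).astype(int)
        out["unit"] = out["nurse_id"].map(design.nurse_units)
        return out

    # ------------------------------------------------------------------ tests
    def joint_nurse_test(self) -> TestResult:
        """Wald chi-square test of no nurse-level differences.

        For unpenalized fits (reference column absent) this is the classical
        test that all nurse coefficients are zero.  Penalized fits carry the
        full nurse block, so the equivalent null — every nurse equals the
        reference — is tested through difference contrasts, keeping
        df = roster size - 1 either way.
        """
        ix = [list(self.params.index).index(c) for c in self.nurse_cols]
        b = self.params.to_numpy()[ix]
        V = self.cov.to_numpy()[np.ix_(ix, ix)]
        ref_col = f"nurse:{self.design.ref_nurse}"
        if ref_col in self.nurse_cols:
            r = self.nurse_cols.index(ref_col)
            m = len(self.nurse_cols)
            C = np.delete(np.eye(m), r, axis=0)
            C[:, r] = -1.0
            b = C @ b
            V = C @ V @ C.T
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:
            warnings.warn("singular nurse covariance block; using pseudo-inverse")
            stat = float(b @ np.linalg.pinv(V) @ b)
        if not np.isfinite(stat) or stat < 0:
            warnings.warn("ill-conditioned nurse covariance block; using pseudo-inverse")
            stat = float(b @ np.linalg.pinv(V) @ b)
        df = len(b)
        return TestResult(
            statistic=stat, p_value=float(stats.chi2.sf(stat, df)), kind="wald_joint", df=df
        )

    def summary(self) -> str:
        """Plain-text model summary (covariates in full, nurse block digested)."""
        lines = [
            "Value-added logistic model (CAABU-free outcome)",
            "=" * 58,
            f"n obs: {self.nobs}    clusters ({self.cluster_level}): {self.n_clusters}",
            f"log-likelihood: {self.llf:.2f}    ridge on nurse block: {self.penalty:.4g}",
            f"converged: {self.converged} in {self.n_iter} iterations",
            "-" * 58,
            f"{'term':<34}{'coef':>9}{'se':>8}{'p':>7}",
        ]
        bse = self.bse
        for name in self.params.index:
            if name.startswith("nurse:"):
                continue
            b, s = self.params[name], bse[name]
            p = 2 * stats.norm.sf(abs(b / s)) if s > 0 else np.nan
            lines.append(f"{name:<34}{b:>9.4f}{s:>8.4f}{p:>7.3f}")
        jt = self.joint_nurse_test()
        lines.append("-" * 58)
        lines.append(
            f"nurse block: {len(self.nurse_cols)} indicators "
            f"(ref {self.design.ref_nurse}); joint Wald chi2({jt.df}) = "
            f"{jt.statistic:.2f}, p = {jt.p_value:.3g}"
        )
        if self.dropped_separated:
            lines.append(f"dropped for separation: {len(self.dropped_separated)}")
        return "\n".join(lines)

    def coefficient_table(self) -> pd.DataFrame:
        """Long-form coefficient table (CSV-friendly, S2/S3-style layout)."""
        bse = self.bse
        rows = [
            {"term": t, "coef": float(self.params[t]), "se": float(bse[t])}
            for t in self.params.index
        ]
        ref_col = f"nurse:{self.design.ref_nurse}"
        if ref_col not in self.params.index:
            rows.append({"term": ref_col + " [ref]", "coef": np.nan, "se": np.nan})
        for c in self.dropped_separated:
            rows.append({"term": c + " [omitted]", "coef": np.nan, "se": np.nan})
        return pd.DataFrame(rows)


def fit_vam(
    design: VamDesign,
    cluster_level: str = "patient",
    penalty: float | None = None,
    cov_method: str = "cr2",
) -> CaabuVamResults:
    """Functional wrapper over ``CaabuVam(design).fit(...)``."""
    return CaabuVam(design).fit(
        penalty=penalty, cluster_level=cluster_level, cov_method=cov_method
    )


@dataclass
class AucComparison:
    auc_restricted: float
    auc_full: float
    test: TestResult
    n_boot: int


def _restricted_design(design: VamDesign) -> pd.DataFrame:
    return design.X[design.covariate_cols]


def _drop_separated_indicators(X_df: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
    """Drop 0/1 columns that perfectly predict the outcome on their support
    (merged with the reference category), keeping the plain MLE finite."""
    drop = []
    for c in X_df.columns:
        if c == "const":
            continue
        v = X_df[c].to_numpy()
        if set(np.unique(v)) <= {0.0, 1.0}:
            on, off = v == 1.0, v == 0.0
            if (on.any() and y[on].min() == y[on].max()) or (
                off.any() and y[off].min() == y[off].max()
            ):
                drop.append(c)
    return X_df.drop(columns=drop) if drop else X_df


def auc_comparison(
    design: VamDesign,
    cluster_level: str = "patient",
    penalty: float = 0.0,
    n_boot: int = 999,
    seed: int = 0,
) -> AucComparison:
    """In-sample AUC of the covariate-only model vs the model with the nurse
    block, with a patient-cluster bootstrap one-sided p-value for the gain.

    Both models are plain maximum likelihood (separated indicator columns
    dropped under the same rule) so the full model nests the restricted one;
    AUCs use the Mann-Whitney formulation.  The bootstrap resamples patients
    with replacement and recomputes both AUCs from the fitted scores (scores
    are not refit), testing whether the observed in-sample improvement is
    distinguishable from zero under cluster resampling.  ``penalty`` > 0
    ridges the full model's nurse block instead of dropping separated nurses;
    in-sample nesting of the AUCs is then no longer guaranteed.
    """
    from sklearn.metrics import roc_auc_score

    full = CaabuVam(design).fit(penalty=penalty, cluster_level=cluster_level)
    y = design.y
    X_r = _drop_separated_indicators(_restricted_design(design), y)
    restricted = _plain_logit(X_r.to_numpy(float), y.astype(float))

    p_full = full.fittedvalues.to_numpy()
    p_restr = expit(X_r.to_numpy(float) @ restricted)
    if len(np.unique(y)) < 2 or np.allclose(p_full, p_full[0]) or np.allclose(p_restr, p_restr[0]):
        raise FitError("constant outcome or predictions: AUC undefined")
    auc_f = float(roc_auc_score(y, p_full))
    auc_r = float(roc_auc_score(y, p_restr))
    delta = auc_f - auc_r

    rng = np.random.default_rng([int(seed), 11])
    patients, inverse = np.unique(design.cluster_patient, return_inverse=True)
    rows_by_patient = [np.flatnonzero(inverse == g) for g in range(len(patients))]
    n_le = 0
    n_used = 0
    for _ in range(n_boot):
        take = rng.integers(0, len(patients), size=len(patients))
        rows = np.concatenate([rows_by_patient[g] for g in take])
        yb = y[rows]
        if yb.min() == yb.max():
            continue
        d_star = roc_auc_score(yb, p_full[rows]) - roc_auc_score(yb, p_restr[rows])
        n_used += 1
        if d_star <= 0:
            n_le += 1
    p_one = (n_le + 1) / (n_used + 1) if n_used else np.nan
    test = TestResult(
        statistic=delta, p_value=float(p_one), kind="auc_delta", df=None,
        extra={"n_boot_used": n_used},
    )
    return AucComparison(auc_restricted=auc_r, auc_full=auc_f, test=test, n_boot=n_boot)


def _plain_logit(X: np.ndarray, y: np.ndarray, maxiter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Small unpenalized Newton logistic used for the restricted AUC model."""
    beta = np.zeros(X.shape[1])
    p_bar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = np.log(p_bar / (1 - p_bar))
    ll = -np.inf
    for _ in range(maxiter):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        grad = X.T @ (y - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            beta_new = beta + t * step
            ll_new = float(np.sum(y * (X @ beta_new) - np.logaddexp(0.0, X @ beta_new)))
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta_new
        if abs(ll_new - ll) < tol * (abs(ll_new) + 1.0):
            break
        ll = ll_new
    return beta
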