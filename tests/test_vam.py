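import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from nursevam import CaabuVam, fit_vam
from nursevam.cohort import VamDesign, build_design_matrix
from nursevam.exceptions import FitError, SeparationError
from nursevam.vam import CaabuVamResults, auc_comparison


def make_design(X: pd.DataFrame, y, nurse_cols, ref_nurse="REF", clusters=None):
    roster = sorted({c.split(":", 1)[1] for c in nurse_cols} | {ref_nurse})
    counts = pd.Series({n: 10 for n in roster})
    units = pd.Series({n: "medical" for n in roster})
    return VamDesign(
        X=X.astype(float),
        y=np.asarray(y, dtype=int),
        nurse_cols=list(nurse_cols),
        ref_nurse=ref_nurse,
        cluster_patient=np.asarray(
            clusters if clusters is not None else np.arange(len(y))
        ),
        nurse_link_counts=counts,
        nurse_units=units,
        dropped_columns=[],
    )


def two_by_two_design(a=30, b=10, c=20, d=40):
    """Exposed (nurse A): a successes, b failures; unexposed: c successes,
    d failures."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    X = pd.DataFrame({"const": 1.0, "nurse:A": x})
    return make_design(X, y, ["nurse:A"]), np.log((a / b) / (c / d))


class TestFit:
    def test_two_by_two_closed_form(self):
        """The 2x2 logistic MLE equals the log odds-ratio of the table."""
        design, log_or = two_by_two_design()
        res = CaabuVam(design).fit(penalty=0, cluster_level="encounter")
        assert res.converged
        assert res.params["nurse:A"] == pytest.approx(log_or, abs=1e-8)
        assert res.params["const"] == pytest.approx(np.log(20 / 40), abs=1e-8)

    def test_penalty_continuity(self):
        design, _ = two_by_two_design()
        r0 = CaabuVam(design).fit(penalty=0, cluster_level="encounter")
        r1 = CaabuVam(design).fit(penalty=1e-10, cluster_level="encounter")
        assert np.allclose(r0.params, r1.params, atol=1e-4)

    def test_statsmodels_crosscheck_unpenalized(self, rng):
        """Dual-route check: coefficients and clustered sandwich SEs match
        statsmodels Logit with cov_type='cluster' on simulated data."""
        import statsmodels.api as sm

        n = 600
        x1 = rng.normal(size=n)
        nurse = (rng.random(n) < 0.4).astype(float)
        eta = 0.5 + 0.8 * x1 - 0.6 * nurse
        y = (rng.random(n) < expit(eta)).astype(int)
        clusters = rng.integers(0, 120, size=n)
        X = pd.DataFrame({"const": 1.0, "x1": x1, "nurse:A": nurse})
        design = make_design(X, y, ["nurse:A"], clusters=clusters)
        mine = CaabuVam(design).fit(penalty=0, cov_method="cr1")
        smr = sm.Logit(y, X).fit(
            disp=0, cov_type="cluster", cov_kwds={"groups": clusters}
        )
        assert np.allclose(mine.params, smr.params, atol=1e-7)
        assert np.allclose(mine.bse, smr.bse, atol=1e-7)

    def test_separation_dropped_at_penalty_zero(self):
        y = np.r_[np.ones(20), np.zeros(5), np.ones(15)]
        nurse = np.r_[np.ones(20), np.zeros(20)]  # nurse A: all CAABU-free
        X = pd.DataFrame({"const": 1.0, "nurse:A": nurse})
        design = make_design(X, y, ["nurse:A"])
        with pytest.raises(SeparationError):
            CaabuVam(design).fit(penalty=0, cluster_level="encounter")
        res = CaabuVam(design).fit(penalty=1.0, cluster_level="encounter")
        assert res.converged and np.isfinite(res.params["nurse:A"])

    def test_constant_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(10), "nurse:A": np.r_[np.ones(5), np.zeros(5)]})
        with pytest.raises(FitError):
            CaabuVam(make_design(X, np.ones(10), ["nurse:A"]))

    def test_fit_vam_wrapper(self, small_run):
        design = build_design_matrix(small_run["est"], ref_seed=0)
        res = fit_vam(design)
        assert res.converged
        assert res.cov.shape[0] == len(res.params)
        v = res.cov.to_numpy()
        assert np.allclose(v, v.T)
        assert (np.linalg.eigvalsh(v) > -1e-8).all()


class TestMargins:
    def brute_force_margins(self, res, design, mode="zero"):
        """Independent scripted oracle: per-encounter prediction averaging
        with explicit loops."""
        cols = list(res.params.index)
        X = design.X[cols].to_numpy()
        beta = res.params.to_numpy()
        out = {}
        for nurse in sorted(design.nurse_link_counts.index):
            col = f"nurse:{nurse}"
            total = 0.0
            for i in range(len(X)):
                row = X[i].copy()
                for c in res.nurse_cols:
                    row[cols.index(c)] = 0.0 if mode == "zero" else row[cols.index(c)]
                if mode == "zero":
                    for c in res.nurse_cols:
                        row[cols.index(c)] = 0.0
                if col in cols:
                    row[cols.index(col)] = 1.0
                total += 1.0 / (1.0 + np.exp(-(row @ beta)))
            out[nurse] = 100.0 * total / len(X)
        return out

    def test_margins_equal_brute_force_on_toy_design(self, rng):
        n = 10
        X = pd.DataFrame(
            {
                "const": 1.0,
                "age": rng.normal(60, 10, n).round(1),
                "nurse:A": [1, 1, 0, 0, 0, 1, 0, 0, 1, 0],
                "nurse:B": [0, 0, 1, 1, 0, 0, 1, 0, 0, 1],
            }
        )
        y = [1, 1, 0, 1, 1, 1, 0, 1, 1, 1]
        design = make_design(X, y, ["nurse:A", "nurse:B"])
        res = CaabuVam(design).fit(penalty=0.5, cluster_level="encounter")
        got = res.nurse_margins(mode="zero").set_index("nurse_id")["rate_per_100"]
        want = self.brute_force_margins(res, design, mode="zero")
        for nurse, val in want.items():
            assert got[nurse] == pytest.approx(val, abs=1e-10)

    def test_all_zero_nurse_coefficients_give_identical_rates(self):
        X = pd.DataFrame(
            {
                "const": np.ones(8),
                "age": np.r_[np.full(4, 55.0), np.full(4, 70.0)],
                "nurse:A": [1, 0, 0, 0, 1, 0, 0, 0],
                "nurse:B": [0, 1, 1, 0, 0, 1, 1, 0],
            }
        )
        y = [1, 0, 1, 1, 1, 0, 1, 1]
        design = make_design(X, y, ["nurse:A", "nurse:B"])
        res = CaabuVam(design).fit(penalty=1e-8, cluster_level="encounter")
        forced = res.params.copy()
        forced["nurse:A"] = 0.0
        forced["nurse:B"] = 0.0
        res_zero = CaabuVamResults(
            model=res.model, params=forced, cov=res.cov, nurse_cols=res.nurse_cols,
            dropped_separated=[], llf=res.llf, nobs=res.nobs, converged=True,
            n_iter=res.n_iter, penalty=res.penalty, cluster_level=res.cluster_level,
            cov_method=res.cov_method, n_clusters=res.n_clusters,
            fittedvalues=res.fittedvalues,
        )
        rates = res_zero.nurse_margins(mode="zero")["rate_per_100"]
        assert rates.nunique() == 1
        expected = 100 * expit(
            design.X[["const", "age"]].to_numpy() @ forced[["const", "age"]].to_numpy()
        ).mean()
        assert rates.iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_saturating_coefficient_drives_rate_to_100(self):
        X = pd.DataFrame({"const": np.ones(6), "nurse:A": [1, 0, 1, 0, 1, 0]})
        design = make_design(X, [1, 0, 1, 1, 0, 1], ["nurse:A"])
        res = CaabuVam(design).fit(penalty=1.0, cluster_level="encounter")
        forced = res.params.copy()
        forced["nurse:A"] = 20.0
        res2 = CaabuVamResults(
            model=res.model, params=forced, cov=res.cov, nurse_cols=res.nurse_cols,
            dropped_separated=[], llf=res.llf, nobs=res.nobs, converged=True,
            n_iter=res.n_iter, penalty=res.penalty, cluster_level=res.cluster_level,
            cov_method=res.cov_method, n_clusters=res.n_clusters,
            fittedvalues=res.fittedvalues,
        )
        rate = res2.nurse_margins().set_index("nurse_id").loc["A", "rate_per_100"]
        assert rate == pytest.approx(100.0, abs=1e-4)

    def test_rates_strictly_inside_bounds_with_penalty(self, small_run):
        res = CaabuVam.from_cohort(small_run["est"], ref_seed=0).fit()
        r = res.nurse_margins()["rate_per_100"]
        assert ((r > 0) & (r < 100)).all()

    def test_relabeling_nurses_permutes_rates(self, small_run):
        est = small_run["est"]
        res = CaabuVam.from_cohort(est, ref_seed=0).fit()
        base = res.nurse_margins().set_index("nurse_id")["rate_per_100"]

        relabeled = est.encounters.copy()
        mapping = {n: f"Z{i:03d}" for i, n in enumerate(sorted(est.nurse_roster))}
        relabeled["nurse_ids"] = [
            tuple(sorted(mapping[n] for n in tup)) for tup in relabeled["nurse_ids"]
        ]
        from nursevam import AssembledCohort

        cohort2 = AssembledCohort(
            relabeled, tuple(sorted(mapping.values())), est.exclusion_log
        )
        res2 = CaabuVam.from_cohort(cohort2, ref_seed=0).fit()
        back = res2.nurse_margins().set_index("nurse_id")["rate_per_100"]
        # identical ordering of sorted rosters -> same reference index -> equal
        for n, n2 in mapping.items():
            assert back[n2] == pytest.approx(base[n], abs=1e-8)

    def test_reference_nurse_choice_barely_moves_rates(self, small_run):
        est = small_run["est"]
        r1 = CaabuVam.from_cohort(est, ref_seed=0).fit().nurse_margins()
        r2 = CaabuVam.from_cohort(est, ref_seed=1).fit().nurse_margins()
        a = r1.set_index("nurse_id")["rate_per_100"]
        b = r2.set_index("nurse_id")["rate_per_100"]
        assert (a - b).abs().max() < 0.1


class TestJointTest:
    def test_null_point_gives_zero_statistic(self):
        X = pd.DataFrame({"const": np.ones(4), "nurse:A": [1, 0, 1, 0]})
        design = make_design(X, [1, 0, 0, 1], ["nurse:A"])
        res = CaabuVam(design).fit(penalty=1.0, cluster_level="encounter")
        forced = res.params.copy()
        forced["nurse:A"] = 0.0
        res2 = CaabuVamResults(
            model=res.model, params=forced, cov=res.cov, nurse_cols=res.nurse_cols,
            dropped_separated=[], llf=res.llf, nobs=res.nobs, converged=True,
            n_iter=res.n_iter, penalty=res.penalty, cluster_level=res.cluster_level,
            cov_method=res.cov_method, n_clusters=res.n_clusters,
            fittedvalues=res.fittedvalues,
        )
        t = res2.joint_nurse_test()
        assert t.statistic == pytest.approx(0.0)
        assert t.p_value == pytest.approx(1.0)

    def test_two_nurse_hand_quadratic_form(self):
        """b' V^-1 b for b=(0.5,-0.3), V=[[.04,.01],[.01,.09]] equals
        8.3142857... (hand matrix arithmetic)."""
        X = pd.DataFrame(
            {"const": np.ones(6), "nurse:A": [1, 0, 0, 1, 0, 0], "nurse:B": [0, 1, 0, 0, 1, 0]}
        )
        design = make_design(X, [1, 0, 1, 0, 1, 1], ["nurse:A", "nurse:B"])
        res = CaabuVam(design).fit(penalty=1.0, cluster_level="encounter")
        params = res.params.copy()
        params["nurse:A"], params["nurse:B"] = 0.5, -0.3
        cov = res.cov.copy()
        cov.loc["nurse:A", "nurse:A"] = 0.04
        cov.loc["nurse:B", "nurse:B"] = 0.09
        cov.loc["nurse:A", "nurse:B"] = cov.loc["nurse:B", "nurse:A"] = 0.01
        res2 = CaabuVamResults(
            model=res.model, params=params, cov=cov, nurse_cols=res.nurse_cols,
            dropped_separated=[], llf=res.llf, nobs=res.nobs, converged=True,
            n_iter=res.n_iter, penalty=res.penalty, cluster_level=res.cluster_level,
            cov_method=res.cov_method, n_clusters=res.n_clusters,
            fittedvalues=res.fittedvalues,
        )
        t = res2.joint_nurse_test()
        assert t.statistic == pytest.approx(8.314285714285715, abs=1e-9)
        assert t.df == 2
        assert t.p_value == pytest.approx(stats.chi2.sf(8.314285714285715, 2))

    def test_strong_effects_detected(self, study_run):
        res = CaabuVam.from_cohort(study_run["est"], ref_seed=0).fit()
        assert res.joint_nurse_test().p_value < 0.001


class TestAuc:
    def test_nesting_full_at_least_restricted(self, rng):
        """The model with the nurse block can never have lower in-sample AUC
        than the covariate-only model (nesting), across simulated fits."""
        from nursevam import SimulationConfig, apply_exclusions, label_outcomes, simulate_extract

        for seed in range(6):
            cfg = SimulationConfig(
                seed=200 + seed,
                n_nurses_per_unit={"medical": 4, "neurological": 4},
                n_beds_per_unit={"medical": 4, "neurological": 4},
                n_days=150,
            )
            ex, _ = simulate_extract(cfg)
            cohort = apply_exclusions(
                label_outcomes(ex), ex.event_table, float_nurses=ex.float_nurses
            )
            design = build_design_matrix(cohort, ref_seed=seed)
            cmp = auc_comparison(design, n_boot=19, seed=seed)
            assert cmp.auc_full >= cmp.auc_restricted - 1e-9
            assert 0.0 <= cmp.test.p_value <= 1.0

    def test_perfect_predictor_auc_one(self):
        x = np.r_[np.ones(12), np.zeros(12)]
        y = x.astype(int)  # nurse indicator perfectly ranks the outcome
        X = pd.DataFrame({"const": 1.0, "nurse:A": x})
        design = make_design(X, y, ["nurse:A"])
        res = CaabuVam(design).fit(penalty=1.0, cluster_level="encounter")
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, res.fittedvalues) == 1.0

    def test_null_discrimination_near_half(self, rng):
        n = 4000
        X = pd.DataFrame(
            {"const": np.ones(n), "x": rng.normal(size=n), "nurse:A": (rng.random(n) < 0.5) * 1.0}
        )
        y = (rng.random(n) < 0.5).astype(int)  # independent of everything
        design = make_design(X, y, ["nurse:A"])
        cmp = auc_comparison(design, n_boot=19, seed=0, penalty=1e-3)
        assert abs(cmp.auc_full - 0.5) < 0.02
        assert abs(cmp.auc_restricted - 0.5) < 0.02


def test_summary_renders(small_run):
    res = CaabuVam.from_cohort(small_run["est"], ref_seed=0).fit()
    text = res.summary()
    assert "joint Wald" in text and "nurse block" in text
    tbl = res.coefficient_table()
    assert (tbl["term"] == f"nurse:{res.design.ref_nurse}").any()
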