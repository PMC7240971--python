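"""Random-intercept models, BY adjustment, and the association analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from metaboref import (
    CohortConfig,
    MetaboliteSpec,
    bmi_association,
    by_adjust,
    cluster_correlation_profiles,
    fit_random_intercept,
    interval_trends,
    lab_correlations,
    simulate_cohort,
    tanner_contrasts,
)
from metaboref.associations import CorrelationMatrix


def clustered_null(rng, ns=300, nv=2, icc=0.4):
    subj = np.repeat(np.arange(ns), nv)
    u = rng.normal(size=ns)
    y = np.sqrt(icc) * u[subj] + np.sqrt(1 - icc) * rng.normal(size=ns * nv)
    x = rng.normal(size=ns * nv)
    return y, pd.DataFrame({"x": x}), subj


class TestRandomIntercept:
    def test_matches_ols_without_group_variance(self):
        # large balanced design so the REML variance ratio pins to ~zero
        rng = np.random.default_rng(0)
        ns = 8000
        subj = np.repeat(np.arange(ns), 2)
        x = rng.normal(size=2 * ns)
        y = 0.3 * x + rng.normal(size=2 * ns)
        fit = fit_random_intercept(y, pd.DataFrame({"x": x}), subj)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        X = np.column_stack([np.ones(2 * ns), xs])
        beta = np.linalg.solve(X.T @ X, X.T @ ys)  # normal-equations oracle
        assert fit.coefficients["x"] == pytest.approx(beta[1], abs=1e-4)

    def test_agrees_with_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        y, X, subj = clustered_null(rng)
        fit = fit_random_intercept(y, X, subj)
        ys = (y - y.mean()) / y.std(ddof=1)
        xs = (X["x"] - X["x"].mean()) / X["x"].std(ddof=1)
        res = sm.MixedLM(ys, np.column_stack([np.ones(len(ys)), xs]), groups=subj).fit(
            reml=True
        )
        assert fit.coefficients["x"] == pytest.approx(res.params[1], abs=1e-3)
        assert fit.se["x"] == pytest.approx(res.bse[1], abs=1e-3)
        assert fit.pvalues["x"] == pytest.approx(res.pvalues[1], abs=2e-3)
        assert fit.re_var == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), abs=5e-3)

    def test_perfect_fit_falls_back(self, rng):
        x = rng.normal(size=100)
        subj = np.repeat(np.arange(50), 2)
        fit = fit_random_intercept(x.copy(), pd.DataFrame({"x": x}), subj)
        assert fit.method == "ols"
        assert fit.coefficients["x"] == pytest.approx(1.0, abs=1e-10)
        assert fit.resid_var == pytest.approx(0.0, abs=1e-12)

    def test_single_group_falls_back_with_warning(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        fit = fit_random_intercept(y, pd.DataFrame({"x": x}), np.zeros(40))
        assert fit.method == "ols" and "single group" in fit.warning

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear.*('a'|'b')"):
            fit_random_intercept(rng.normal(size=60), X, np.repeat(np.arange(30), 2))

    def test_estimates_variance_components(self, rng):
        est = []
        for _ in range(30):
            y, X, subj = clustered_null(rng, ns=500)
            fit = fit_random_intercept(y, X, subj)
            est.append(fit.re_var / (fit.re_var + fit.resid_var))
        assert np.mean(est) == pytest.approx(0.4, abs=0.05)


class TestByAdjust:
    def test_worked_triple_collapses_to_0055(self):
        adj = by_adjust([0.01, 0.02, 0.03])
        # c(3) = 11/6; all three monotonize to 0.01 * 3 * (11/6) = 0.055
        assert np.allclose(adj, 0.055, atol=1e-12)

    def test_single_p_unchanged(self):
        assert by_adjust([0.031])[0] == pytest.approx(0.031, abs=1e-15)

    def test_cap_at_one(self):
        assert np.all(by_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                by_adjust(bad)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=30))
    def test_order_invariance_and_monotonicity(self, ps):
        p = np.array(ps)
        adj = by_adjust(p)
        assert np.all(adj >= p - 1e-15)  # adjusted never below raw
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(by_adjust(p[perm]), adj[perm])


class TestIntervalTrends:
    @staticmethod
    def _frame(rng, ns, slope_fn, age_lo=1.0, age_hi=13.0):
        subj = np.repeat(np.arange(ns), 2)
        age = rng.uniform(age_lo, age_hi, size=2 * ns)
        u = rng.normal(size=ns)
        sds = slope_fn(age) + np.sqrt(0.4) * u[subj] + np.sqrt(0.6) * rng.normal(size=2 * ns)
        return pd.DataFrame(
            {
                "subject_id": subj,
                "sex": np.where(subj % 2 == 0, "F", "M"),
                "age_years": age,
                "X": sds,
            }
        )

    def test_boundary_age_joins_right_interval(self):
        df = pd.DataFrame(
            {
                "subject_id": np.arange(80),
                "sex": ["F", "M"] * 40,
                "age_years": np.full(80, 5.0),  # exactly at the cut
                "X": np.random.default_rng(0).normal(size=80),
            }
        )
        out = interval_trends(df, "X", cuts=(5.0,))
        left = out[out.covariate == "age[0.25,5.0)"]
        right = out[out.covariate == "age[5.0,18.0)"]
        assert (left.n_obs == 0).all()
        assert right.n_obs.sum() == 80

    def test_detects_rise_only_where_injected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = self._frame(rng, 800, lambda a: 0.1 * np.clip(a - 5.0, 0, None))
            out = interval_trends(df, "X", cuts=(5.0,))
            out = out[out.estimable]
            sig = out[out.significant]
            flat_sig = (sig.covariate == "age[0.25,5.0)").any()
            rise_sig = (
                out[(out.covariate == "age[5.0,18.0)")].significant.all()
            )
            hits += rise_sig and not flat_sig
        assert hits >= 45  # >= 90% of seeds

    def test_null_type_one_error_calibrated(self):
        raw_sig = total = 0
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            df = self._frame(rng, 400, lambda a: 0.0)
            out = interval_trends(df, "X", cuts=(7.0,))
            est = out[out.estimable]
            raw_sig += (est.p_raw < 0.05).sum()
            total += len(est)
        frac = raw_sig / total
        band = 3 * np.sqrt(0.05 * 0.95 / total)
        assert abs(frac - 0.05) <= band

    def test_sparse_interval_reported_not_estimable(self, rng):
        df = self._frame(rng, 100, lambda a: 0.0, age_lo=1.0, age_hi=4.9)
        out = interval_trends(df, "X", cuts=(5.0,))
        empty = out[out.covariate == "age[5.0,18.0)"]
        assert (~empty.estimable).all() and not empty.empty


class TestBmiAssociation:
    @staticmethod
    def _cohort(seed, slopes, n=1000):
        spec = [MetaboliteSpec("X", 4, "BCCG", 100.0)]
        cfg = CohortConfig(
            n_subjects=n, metabolites=spec, lab_markers=[],
            bmi_slopes={"X": slopes}, seed=seed,
        )
        data = simulate_cohort(cfg)
        tab = data.table
        tab["X_sds"] = np.where(
            tab.sex == "F",
            data.truth.true_sds("X", "F", tab.age_years, tab.X),
            data.truth.true_sds("X", "M", tab.age_years, tab.X),
        )
        return tab

    def test_common_slope_reported_pooled_and_recovered(self):
        tab = self._cohort(1, (0.2, 0.2))
        out = bmi_association(tab, "X_sds")
        assert list(out.stratum) == ["pooled"]
        assert out.estimate.iloc[0] == pytest.approx(0.2, abs=0.05)

    def test_opposite_slopes_trigger_per_sex_reporting(self):
        hits = 0
        for seed in range(25):
            tab = self._cohort(100 + seed, (-0.1, 0.3))
            out = bmi_association(tab, "X_sds")
            if set(out.stratum) == {"F", "M"}:
                est = out.set_index("stratum")["estimate"]
                hits += est["M"] > est["F"]
        assert hits >= 23  # per-sex reporting plus correct ordering >= 90%

    def test_constant_bmi_rejected(self, rng):
        df = pd.DataFrame(
            {
                "subject_id": np.arange(60),
                "sex": ["F", "M"] * 30,
                "bmi_sds": 0.0,
                "X_sds": rng.normal(size=60),
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            bmi_association(df, "X_sds")

    def test_missing_sex_rejected(self, rng):
        df = pd.DataFrame(
            {
                "subject_id": np.arange(60),
                "sex": ["F", None] * 30,
                "bmi_sds": rng.normal(size=60),
                "X_sds": rng.normal(size=60),
            }
        )
        with pytest.raises(ValueError, match="sex codes"):
            bmi_association(df, "X_sds")


class TestTannerContrasts:
    @staticmethod
    def _frame(rng, ns, effect_fn):
        sex = np.where(np.arange(ns) % 2 == 0, "F", "M")
        stage = rng.integers(1, 6, size=ns)
        y = effect_fn(sex, stage) + rng.normal(size=ns)
        return pd.DataFrame(
            {"subject_id": np.arange(ns), "sex": sex, "tanner_stage": stage, "X": y}
        )

    def test_reference_stage_not_contrasted(self, rng):
        out = tanner_contrasts(self._frame(rng, 300, lambda s, t: 0.0), "X")
        assert not out.covariate.str.endswith("_1").any()
        assert set(out.covariate) == {"tanner_2", "tanner_3", "tanner_4", "tanner_5"}

    def test_null_permutation_mostly_non_significant(self):
        sig = total = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            out = tanner_contrasts(self._frame(rng, 300, lambda s, t: 0.0), "X")
            est = out[out.estimable]
            sig += est.significant.sum()
            total += len(est)
        assert 1 - sig / total >= 0.95

    def test_female_early_stage_effect_localized(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(500 + seed)
            eff = lambda s, t: 0.5 * ((s == "F") & np.isin(t, (2, 3)))
            out = tanner_contrasts(self._frame(rng, 2000, eff), "X")
            f = out[(out.stratum == "F") & out.covariate.isin(["tanner_2", "tanner_3"])]
            m = out[(out.stratum == "M") & out.covariate.isin(["tanner_2", "tanner_3"])]
            hits += f.significant.all() and not m.significant.any()
        assert hits >= 45

    def test_unobserved_stage_not_estimable(self, rng):
        df = self._frame(rng, 200, lambda s, t: 0.0)
        df = df[df.tanner_stage != 4]
        out = tanner_contrasts(df, "X")
        assert (~out[out.covariate == "tanner_4"].estimable).all()


class TestLabCorrelations:
    def test_independent_marker_near_zero(self, rng):
        ns = 1500
        subj = np.repeat(np.arange(ns), 2)
        u = rng.normal(size=ns)
        met = pd.DataFrame(
            {f"m{i}": np.sqrt(0.4) * u[subj] + np.sqrt(0.6) * rng.normal(size=2 * ns)
             for i in range(5)}
        )
        mk = pd.DataFrame({"lab": rng.normal(size=2 * ns)})
        cm = lab_correlations(met, mk, subj, mode="absolute")
        assert np.abs(cm.estimates["lab"]).mean() < 0.03

    def test_exact_linear_marker_gives_unit_cell(self, rng):
        ns = 400
        subj = np.repeat(np.arange(ns), 2)
        x = rng.normal(size=2 * ns)
        met = pd.DataFrame({"m": x})
        mk = pd.DataFrame({"lab": 3.0 * x + 1.0})
        cm = lab_correlations(met, mk, subj)
        assert cm.estimates.loc["m", "lab"] == pytest.approx(1.0, abs=1e-6)

    def test_targeted_rho_recovered_and_age_confounding_attenuates(self):
        specs = [MetaboliteSpec(f"M{i}", 4, "BCCG", 50.0) for i in range(4)]
        specs.append(MetaboliteSpec("T2", 2, "BCCG", 80.0))
        from metaboref import LabMarkerSpec

        markers = [
            LabMarkerSpec("target", 10.0, 2.0, {f"M{i}": 0.45 for i in range(4)}),
            LabMarkerSpec("aged", 5.0, 1.0, {"T2": 0.3}, age_coef=0.6),
        ]
        cfg = CohortConfig(
            n_subjects=1700, metabolites=specs, lab_markers=markers, seed=21
        )
        data = simulate_cohort(cfg)
        tab = data.table
        sds_df = pd.DataFrame(
            {
                m.name: np.where(
                    tab.sex == "F",
                    data.truth.true_sds(m.name, "F", tab.age_years, tab[m.name]),
                    data.truth.true_sds(m.name, "M", tab.age_years, tab[m.name]),
                )
                for m in specs
            }
        )
        groups = tab.subject_id.to_numpy()
        cm_sds = lab_correlations(sds_df, tab[["target", "aged"]], groups, mode="sds")
        for i in range(4):
            assert cm_sds.estimates.loc[f"M{i}", "target"] == pytest.approx(0.45, abs=0.07)
        cm_abs = lab_correlations(
            tab[[m.name for m in specs]], tab[["target", "aged"]], groups, mode="absolute"
        )
        # the age-trending metabolite picks up the marker's age component in
        # absolute mode; SDS mode removes the age signal
        assert (
            cm_abs.estimates.loc["T2", "aged"]
            > cm_sds.estimates.loc["T2", "aged"] + 0.05
        )

    def test_zero_variance_marker_reported_missing(self, rng):
        met = pd.DataFrame({"m": rng.normal(size=100)})
        mk = pd.DataFrame({"flat": np.ones(100), "ok": rng.normal(size=100)})
        cm = lab_correlations(met, mk, np.arange(100) // 2)
        assert cm.missing_markers == ["flat"]
        assert np.isnan(cm.estimates.loc["m", "flat"])


class TestClustering:
    @staticmethod
    def _planted(noise=0.01):
        rng = np.random.default_rng(3)
        rows = {}
        for i in range(5):
            rows[f"a{i}"] = [0.5, 0.5, 0.0, 0.0] + rng.normal(0, noise, 4)
        for i in range(5):
            rows[f"b{i}"] = [0.0, 0.0, 0.5, 0.5] + rng.normal(0, noise, 4)
        est = pd.DataFrame(rows).T
        est.columns = ["w", "x", "y", "z"]
        ones = pd.DataFrame(1.0, index=est.index, columns=est.columns)
        return CorrelationMatrix(estimates=est, p_raw=ones, p_adj=ones, mode="sds")

    def test_planted_partition_recovered(self):
        cm = self._planted()
        labels = cluster_correlation_profiles(cm, k=2)
        a = set(labels[[f"a{i}" for i in range(5)]])
        b = set(labels[[f"b{i}" for i in range(5)]])
        assert len(a) == 1 and len(b) == 1 and a != b

    def test_k1_single_cluster(self):
        labels = cluster_correlation_profiles(self._planted(), k=1)
        assert set(labels) == {0}

    def test_permutation_invariance_up_to_renaming(self):
        cm = self._planted()
        labels = cluster_correlation_profiles(cm, k=2)
        perm = np.random.default_rng(1).permutation(len(cm.estimates))
        cm2 = CorrelationMatrix(
            estimates=cm.estimates.iloc[perm], p_raw=cm.p_raw.iloc[perm],
            p_adj=cm.p_adj.iloc[perm], mode="sds",
        )
        labels2 = cluster_correlation_profiles(cm2, k=2)
        # same partition: co-membership matrices agree
        for i in cm.estimates.index:
            for j in cm.estimates.index:
                assert (labels[i] == labels[j]) == (labels2[i] == labels2[j])

    def test_k_bounds(self):
        with pytest.raises(ValueError, match="k must"):
            cluster_correlation_profiles(self._planted(), k=11)
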