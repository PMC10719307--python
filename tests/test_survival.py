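import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mallostasis import (
    FitConfig,
    back_project,
    composite_score,
    concordance_index,
    drift_risk_correlation,
    fit,
    fit_hazard_coefficients,
    mallostatic_scenario,
    simulate_cohort,
    standardize,
    stratify_by_quartile,
    to_start_stop,
)
from mallostasis.survival import RiskTable


def _brute_force_c(scores, times, events):
    conc = comp = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                comp += 1
                if scores[i] < scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    conc += 0.5
    return conc / comp


class TestStartStop:
    def test_interval_construction(self, toy_cohort):
        z = toy_cohort.data[["id", "age"]].copy()
        z["z1"] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        records = to_start_stop(toy_cohort, z)
        a = records[records["id"] == "a"]
        # visits 65, 68, 71; death at 73 -> intervals (65,68,0) (68,71,0) (71,73,1)
        assert list(a["start"]) == [65.0, 68.0, 71.0]
        assert list(a["stop"]) == [68.0, 71.0, 73.0]
        assert list(a["event"]) == [0, 0, 1]
        # covariate held constant from the interval's starting visit
        assert list(a["z1"]) == [0.1, 0.2, 0.3]

    def test_censored_at_last_visit_contributes_no_final_record(self):
        from mallostasis import LongitudinalCohort

        data = pd.DataFrame({"id": ["x"], "age": [70.0], "b": [0.0]})
        events = pd.DataFrame(
            {"event_age": [70.0], "event_status": [0]}, index=pd.Index(["x"], name="id")
        )
        c = LongitudinalCohort(data, ["b"], [], events)
        z = data[["id", "age"]].copy()
        z["z1"] = [0.0]
        records = to_start_stop(c, z)
        assert len(records) == 0
        assert records.attrs["n_no_followup"] == 1

    def test_censored_after_followup_all_zero_events(self, toy_cohort):
        z = toy_cohort.data[["id", "age"]].copy()
        z["z1"] = 0.0
        records = to_start_stop(toy_cohort, z)
        b = records[records["id"] == "b"]
        assert len(b) == 2
        assert (b["event"] == 0).all()


class TestConcordance:
    def test_perfect_ranking(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        times = np.array([1.0, 2.0, 3.0, 4.0])  # low score dies first
        events = np.ones(4, int)
        assert concordance_index(scores, times, events) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        scores = rng.standard_normal(n)
        times = rng.exponential(10.0, n)
        events = np.ones(n, int)
        assert abs(concordance_index(scores, times, events) - 0.5) < 0.03

    def test_hand_enumerated_with_censoring(self):
        scores = np.array([0.5, 1.5, 1.0, 2.0])
        times = np.array([2.0, 4.0, 3.0, 5.0])
        events = np.array([1, 0, 1, 1])
        got = concordance_index(scores, times, events)
        assert got == _brute_force_c(scores, times, events)

    def test_matches_brute_force_and_lifelines_on_cohort(self, scenario_bundle):
        from lifelines.utils import concordance_index as ll_c

        b = scenario_bundle
        base = b.latent_z.groupby("id").head(1).head(200)
        ev = b.cohort.events.loc[base["id"]]
        s = base["z1"].to_numpy()
        t = ev["event_age"].to_numpy()
        e = ev["event_status"].to_numpy(int)
        mine = concordance_index(s, t, e)
        assert mine == pytest.approx(_brute_force_c(s, t, e))
        assert mine == pytest.approx(ll_c(t, s, e))

    def test_no_comparable_pairs_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [5.0, 6.0], [0, 0])


class TestHazardCoefficients:
    def test_null_link_coefficients_within_noise(self):
        cfg = mallostatic_scenario(4, 400, seed=61)
        cfg.hazard_coefficients = np.zeros(4)
        cfg.missing_rate = 0.0
        bundle = simulate_cohort(cfg)
        cohort, _ = standardize(bundle.cohort)
        fr = fit(cohort, FitConfig(model_form="full"))
        records = to_start_stop(fr.completed_cohort, fr.natural_z())
        risk = fit_hazard_coefficients(records, mu_age=fr.params.mu_age)
        t = risk.table
        assert (np.abs(t["beta"]) < 3 * t["beta_se"]).all()

    def test_strong_link_sign_recovered(self, full_fit):
        records = to_start_stop(full_fit.completed_cohort, full_fit.natural_z())
        risk = fit_hazard_coefficients(records, mu_age=full_fit.params.mu_age)
        t = risk.table
        lead = t.iloc[np.argmax(np.abs(t["beta"]))]
        # the strongest risk variable is one of the constructed drifters and
        # its C-index points the same way as its Cox coefficient
        assert lead["natural_variable"] in ("z1", "z2")
        # C-index and Cox coefficient point the same way: beta > 0 means high
        # values risky, which is C < 0.5 under the baseline-score convention
        assert np.sign(0.5 - lead["c_index"]) == np.sign(lead["beta"])

    def test_collinear_covariate_flagged(self, full_fit):
        records = to_start_stop(full_fit.completed_cohort, full_fit.natural_z())
        records["z1"] = records["age"]  # duplicate the adjustment covariate
        risk = fit_hazard_coefficients(records)
        assert bool(risk.table.loc[risk.table["natural_variable"] == "z1", "flagged"].iloc[0])


class TestDriftRisk:
    def _table(self, mu_age, c_index, beta):
        return RiskTable(
            pd.DataFrame(
                {
                    "natural_variable": [f"z{j + 1}" for j in range(len(mu_age))],
                    "c_index": c_index,
                    "beta": beta,
                    "beta_se": 0.1,
                    "mu_age": mu_age,
                    "flagged": False,
                }
            )
        )

    def test_fisher_exact_hypergeometric_value(self):
        # perfect 3-3 split: two-sided hypergeometric p = 2/20 = 0.1
        mu_age = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        c = np.array([0.4, 0.4, 0.4, 0.6, 0.6, 0.6])  # C<0.5 => high risky
        beta = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        res = drift_risk_correlation(self._table(mu_age, c, beta))
        assert np.array_equal(res.fisher_table, [[3, 0], [0, 3]])
        assert res.fisher_p == pytest.approx(0.1)
        # oracle: exhaustive hypergeometric enumeration
        assert res.fisher_p == pytest.approx(
            sum(stats.hypergeom(6, 3, 3).pmf(k) for k in (0, 3))
        )

    def test_proportional_construction_perfect_correlation(self):
        mu_age = np.array([0.05, -0.02, 0.01, -0.04])
        beta = 30.0 * mu_age
        c = 0.5 - 0.5 * np.tanh(beta)
        res = drift_risk_correlation(self._table(mu_age, c, beta))
        assert res.corr_beta == pytest.approx(1.0)
        assert res.n_agree == 4

    def test_degenerate_when_all_drifts_one_sign(self):
        mu_age = np.array([0.05, 0.02, 0.01])
        res = drift_risk_correlation(self._table(mu_age, [0.4, 0.45, 0.48], mu_age))
        assert res.degenerate

    def test_needs_three_variables(self):
        with pytest.raises(ValueError):
            drift_risk_correlation(self._table([0.1, 0.2], [0.4, 0.6], [1.0, -1.0]))


class TestCompositeScore:
    def test_zero_and_orthogonal(self):
        mu_age = np.array([0.1, -0.2])
        assert composite_score(mu_age, np.zeros(2)) == 0.0
        z_perp = np.array([2.0, 1.0])  # orthogonal to (0.1, -0.2)
        assert composite_score(mu_age, z_perp) == pytest.approx(0.0)

    def test_dot_product(self):
        assert composite_score(np.array([0.1, -0.2]), np.array([1.0, 1.0])) == pytest.approx(-0.1)

    def test_invariant_under_consistent_permutation(self):
        rng = np.random.default_rng(1)
        mu_age = rng.standard_normal(5)
        z = rng.standard_normal(5)
        perm = rng.permutation(5)
        assert composite_score(mu_age, z) == pytest.approx(
            composite_score(mu_age[perm], z[perm])
        )


class TestQuartiles:
    def test_eight_distinct_scores_split_in_twos(self):
        scores = pd.Series(np.arange(8.0), index=[f"i{k}" for k in range(8)])
        times = np.arange(1.0, 9.0)
        events = np.ones(8, int)
        assign, fitters, _ = stratify_by_quartile(scores, times, events)
        assert assign["quartile"].value_counts().sort_index().tolist() == [2, 2, 2, 2]

    def test_strong_link_orders_survival(self, full_fit, scenario_bundle):
        z = full_fit.natural_z()
        base = z.groupby("id").head(1).set_index("id")
        mu_age = full_fit.params.mu_age
        zcols = [c for c in base.columns if c.startswith("z")]
        scores = pd.Series(base[zcols].to_numpy() @ mu_age, index=base.index)
        ev = scenario_bundle.cohort.events.loc[scores.index]
        assign, fitters, test = stratify_by_quartile(
            scores, ev["event_age"].to_numpy(), ev["event_status"].to_numpy()
        )
        assert test.p_value < 0.05
        # death fraction ordered across extreme quartiles
        d = assign.join(ev)
        frac = d.groupby("quartile")["event_status"].mean()
        assert abs(frac[4] - frac[1]) > 0.1

    def test_null_link_no_separation(self):
        rng = np.random.default_rng(4)
        n = 400
        scores = pd.Series(rng.standard_normal(n), index=[f"i{k:04d}" for k in range(n)])
        times = rng.exponential(10.0, n)
        events = (rng.random(n) < 0.7).astype(int)
        _, _, test = stratify_by_quartile(scores, times, events)
        assert test.p_value > 0.01

    def test_too_few_individuals(self):
        with pytest.raises(ValueError):
            stratify_by_quartile(pd.Series([1.0] * 7), np.ones(7), np.ones(7, int))


class TestBackProject:
    def test_zero_mean_gives_zero_vector(self, full_fit):
        from mallostasis import AnalyticState

        st = AnalyticState(lam=-0.1, mu0=0.0, mu_age=0.0, z0_mean=0.0, z0_var=0.0, sigma2=0.0)
        out = back_project(full_fit, 0, [70.0, 80.0], state=st)
        assert np.allclose(out.to_numpy(), 0.0)

    def test_steady_state_contribution_linear_in_age(self, full_fit):
        ages = np.array([70.0, 75.0, 80.0])
        out = back_project(full_fit, 0, ages).to_numpy()
        # each biomarker's contribution is linear with slope P[k,0]*mu_age[0]
        slopes = (out[:, 1] - out[:, 0]) / 5.0
        expected = full_fit.basis.P[:, 0] * full_fit.params.mu_age[0]
        assert np.allclose(slopes, expected, atol=1e-10)
        assert np.allclose(out[:, 2] - out[:, 1], out[:, 1] - out[:, 0], atol=1e-10)

    def test_index_out_of_range(self, full_fit):
        with pytest.raises(IndexError):
            back_project(full_fit, 99, [70.0])

    def test_single_loading_confines_contribution(self, full_fit):
        import dataclasses

        # a basis column with one nonzero entry confines the contribution
        basis = dataclasses.replace(full_fit.basis, P=np.eye(5), eigenvalues=full_fit.basis.eigenvalues)
        fr = dataclasses.replace(full_fit, basis=basis)
        out = back_project(fr, 1, [70.0, 80.0]).to_numpy()
        assert (np.count_nonzero(out, axis=0) == 1).all()
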