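"""Propensity-score model, greedy caliper matching, quintile strata and
inverse-probability weights."""

import numpy as np
import pytest
from scipy.special import expit, logit

from pshazard.datagen import (OutcomeModel, TreatmentModel,
                              calibrate_treatment_intercept, simulate_cohort)
from pshazard.psmethods import (fit_propensity_model, greedy_caliper_match,
                                iptw_weights, quintile_strata)


class TestPropensityModel:

    def test_null_slopes_recovered(self):
        """Treatment independent of X: all slopes within 4 Wald SEs of 0."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10 ** 5, 10))
        z = (rng.random(10 ** 5) < 0.3).astype(int)
        ps = fit_propensity_model(X, z)
        se = np.sqrt(np.diag(ps.coef_cov))
        assert np.all(np.abs(ps.coef[1:]) < 4 * se[1:])

    def test_self_consistency_unit_slope(self):
        """Covariate equal to the true logit: slope ~1, intercept ~0."""
        rng = np.random.default_rng(2)
        n = 10 ** 6
        p = rng.uniform(0.05, 0.95, n)
        X = np.zeros((n, 10))
        X[:, 0] = logit(p)
        z = (rng.random(n) < p).astype(int)
        ps = fit_propensity_model(X, z, columns=(0,))
        assert ps.coef[1] == pytest.approx(1.0, abs=0.02)

    def test_row_duplication_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((500, 10))
        z = (rng.random(500) < expit(X[:, 3])).astype(int)
        f1 = fit_propensity_model(X, z)
        f2 = fit_propensity_model(np.vstack([X, X]), np.r_[z, z])
        assert np.allclose(f1.coef, f2.coef, atol=1e-7)

    def test_logit_consistency(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((300, 10))
        z = (rng.random(300) < 0.4).astype(int)
        ps = fit_propensity_model(X, z)
        assert np.allclose(logit(ps.ps), ps.logit_ps, atol=1e-8)
        assert np.all((ps.ps > 0) & (ps.ps < 1))

    def test_one_class_raises(self):
        X = np.random.default_rng(5).standard_normal((50, 10))
        with pytest.raises(ValueError):
            fit_propensity_model(X, np.ones(50, int))

    def test_perfect_separation_raises(self):
        X = np.zeros((40, 10))
        X[:, 3] = np.r_[np.ones(20), -np.ones(20)]
        z = np.r_[np.ones(20, int), np.zeros(20, int)]
        with pytest.raises(RuntimeError):
            fit_propensity_model(X, z)


class TestGreedyCaliperMatch:

    @staticmethod
    def _match_toy(t_logits, u_logits, caliper, order="data"):
        lp = np.r_[t_logits, u_logits]
        z = np.r_[np.ones(len(t_logits), int), np.zeros(len(u_logits), int)]
        sd = np.std(lp, ddof=1)
        return greedy_caliper_match(lp, z, caliper / sd, rng=0, order=order,
                                    sd_method="overall")

    def test_single_pair_within_caliper(self):
        m = self._match_toy([0.0], [0.05], caliper=0.1)
        assert m.n_pairs == 1 and m.n_unmatched_treated == 0

    def test_single_treated_outside_caliper(self):
        m = self._match_toy([0.0], [0.5], caliper=0.1)
        assert m.n_pairs == 0 and m.n_unmatched_treated == 1

    @pytest.mark.parametrize("t_order", [[0.0, 0.2], [0.2, 0.0]])
    def test_toy_greedy_order_invariant_here(self, t_order):
        """Both processing orders give pairs (0.0, 0.01) and (0.2, 0.19)."""
        m = self._match_toy(t_order, [0.01, 0.19, 0.5], caliper=0.1)
        lp = np.r_[t_order, [0.01, 0.19, 0.5]]
        got = {(round(lp[t], 2), round(lp[u], 2)) for t, u in m.pairs}
        assert got == {(0.0, 0.01), (0.2, 0.19)}

    def test_pair_invariants_random(self):
        """Each subject in at most one pair, arms correct, distances
        within the caliper."""
        rng = np.random.default_rng(6)
        for seed in range(5):
            n = 400
            lp = rng.standard_normal(n)
            z = (rng.random(n) < 0.3).astype(int)
            m = greedy_caliper_match(lp, z, 0.2, rng=seed)
            flat = m.pairs.reshape(-1)
            assert len(np.unique(flat)) == flat.shape[0]
            assert np.all(z[m.pairs[:, 0]] == 1)
            assert np.all(z[m.pairs[:, 1]] == 0)
            d = np.abs(lp[m.pairs[:, 0]] - lp[m.pairs[:, 1]])
            assert np.all(d <= m.caliper + 1e-12)
            assert m.n_pairs + m.n_unmatched_treated == z.sum()

    def test_infinite_caliper_equal_groups_matches_all(self):
        rng = np.random.default_rng(7)
        lp = rng.standard_normal(100)
        z = np.r_[np.ones(50, int), np.zeros(50, int)]
        m = greedy_caliper_match(lp, z, 1e9, rng=0)
        assert m.n_pairs == 50

    def test_nearest_neighbor_tie_break_lower_index(self):
        # untreated at -0.1 and +0.1 are equidistant from the treated at 0
        lp = np.array([0.0, 0.1, -0.1])
        z = np.array([1, 0, 0])
        m = greedy_caliper_match(lp, z, 10.0, rng=0, sd_method="overall")
        assert m.pairs.tolist() == [[0, 1]]

    def test_no_untreated_warns_empty(self):
        with pytest.warns(UserWarning):
            m = greedy_caliper_match(np.array([0.0, 0.1]), np.array([1, 1]),
                                     0.2, rng=0)
        assert m.n_pairs == 0 and m.n_unmatched_treated == 2

    def test_matched_sample_balances_confounders(self):
        """Mean |standardized difference| of X4..X10 below 0.1 in matched
        samples, averaged over 50 simulated cohorts."""
        a0 = calibrate_treatment_intercept(0.25)
        tm, om = TreatmentModel(a0), OutcomeModel(0.8)
        rng = np.random.default_rng(8)
        sds = []
        for _ in range(50):
            cohort = simulate_cohort(2000, tm, om, rng)
            ps = fit_propensity_model(cohort.X, cohort.z)
            m = greedy_caliper_match(ps.logit_ps, cohort.z, 0.2, rng)
            xt = cohort.X[m.pairs[:, 0]][:, 3:]
            xu = cohort.X[m.pairs[:, 1]][:, 3:]
            pooled = np.sqrt((xt.var(axis=0, ddof=1) + xu.var(axis=0, ddof=1)) / 2)
            sds.append(np.abs(xt.mean(axis=0) - xu.mean(axis=0)) / pooled)
        assert np.mean(sds) < 0.1


class TestQuintileStrata:

    def test_exact_quintiles_of_ten(self):
        s = quintile_strata(np.arange(0.1, 1.05, 0.1))
        assert np.bincount(s.labels, minlength=6)[1:].tolist() == [2, 2, 2, 2, 2]

    def test_labels_monotone_in_ps(self):
        rng = np.random.default_rng(9)
        ps = rng.random(1000)
        s = quintile_strata(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(s.labels[order]) >= 0)
        assert set(np.unique(s.labels)) == {1, 2, 3, 4, 5}

    def test_equal_sizes_with_distinct_values(self):
        rng = np.random.default_rng(10)
        ps = rng.permutation(np.linspace(0.001, 0.999, 10_000))
        s = quintile_strata(ps)
        assert np.bincount(s.labels)[1:].tolist() == [2000] * 5

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            quintile_strata(np.array([0.1, 0.2, 0.3, 0.4]))


class TestIPTWWeights:

    def test_formula_substitution(self):
        ps = np.array([0.5, 0.25, 0.9])
        z = np.array([1, 0, 1])
        ate = iptw_weights(ps, z, "ATE").weights
        att = iptw_weights(ps, z, "ATT").weights
        assert ate[0] == pytest.approx(2.0)
        assert ate[1] == pytest.approx(4.0 / 3.0)
        assert att[1] == pytest.approx(1.0 / 3.0)
        assert att[0] == 1.0 and att[2] == 1.0

    def test_ate_weights_at_least_one(self):
        rng = np.random.default_rng(11)
        ps = rng.uniform(0.01, 0.99, 500)
        z = (rng.random(500) < ps).astype(int)
        assert np.all(iptw_weights(ps, z, "ATE").weights >= 1.0)

    def test_degenerate_ps_rejected(self):
        with pytest.raises(ValueError):
            iptw_weights(np.array([0.0, 0.5]), np.array([0, 1]), "ATE")
        with pytest.raises(ValueError):
            iptw_weights(np.array([1.0, 0.5]), np.array([1, 0]), "ATT")

    def test_att_weight_mass_matches_treated_count(self):
        """Sum of ATT weights over untreated estimates the treated count."""
        a0 = calibrate_treatment_intercept(0.25)
        tm, om = TreatmentModel(a0), OutcomeModel(0.0)
        rng = np.random.default_rng(12)
        diffs = []
        for _ in range(30):
            cohort = simulate_cohort(2000, tm, om, rng)
            ps = fit_propensity_model(cohort.X, cohort.z)
            w = iptw_weights(ps.ps, cohort.z, "ATT").weights
            diffs.append(w[cohort.z == 0].sum() - cohort.n_treated)
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(len(diffs))
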