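import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dfcvar.group_stats import (
    DegenerateTestError,
    delta_variability,
    posthoc_tests,
    remission_ratio,
    rm_ancova_interaction,
    spearman_partial,
    variability_fc_coupling,
)


class TestRemissionRatio:
    def test_quarter_improvement(self):
        assert remission_ratio(20, 15) == pytest.approx(0.25)

    def test_no_change_is_zero(self):
        assert remission_ratio(18, 18) == 0.0

    def test_group_mean_consistency(self):
        # typical treated-group negative-subscale means: 23.56 -> 18.07
        assert remission_ratio(23.56, 18.07) == pytest.approx(0.2330, abs=5e-5)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            remission_ratio(0.0, 5.0)

    def test_scale_invariance(self, rng):
        a, b = 24.0, 17.0
        for c in (0.5, 2.0, 13.0):
            assert remission_ratio(c * a, c * b) == pytest.approx(remission_ratio(a, b))


class TestDeltaVariability:
    def test_halving_gives_minus_half(self):
        assert delta_variability(0.2, 0.1) == pytest.approx(-0.5)

    def test_no_change_is_zero(self):
        assert delta_variability(0.37, 0.37) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            delta_variability(0.0, 0.1)

    def test_scale_invariance(self):
        assert delta_variability(0.4, 0.3) == pytest.approx(delta_variability(4.0, 3.0))


def _long_frame(deltas_by_group, rng=None, covariates=False):
    """Build a two-timepoint long table with given per-subject change scores."""
    rows = []
    idx = 0
    for group, deltas in deltas_by_group.items():
        for d in deltas:
            sid = f"s{idx:03d}"
            idx += 1
            base = 1.0 if rng is None else float(rng.standard_normal())
            cov = {}
            if covariates:
                cov = {
                    "age_years": float(rng.uniform(20, 60)),
                    "sex": "M" if rng.random() < 0.5 else "F",
                    "illness_duration_months": float(rng.uniform(5, 40)),
                    "education_years": float(rng.uniform(6, 18)),
                    "cpz_equiv_mg_per_day": float(rng.uniform(100, 500)),
                }
            for tp, val in (("t1", base), ("t2", base + d)):
                rows.append(
                    {"subject_id": sid, "group": group, "timepoint": tp, "outcome": val, **cov}
                )
    return pd.DataFrame(rows)


class TestRmAncovaInteraction:
    def test_matches_two_sample_t_on_change_scores(self, rng):
        # covariate-free oracle: the interaction F equals the squared
        # two-sample t comparing the groups' change scores
        d_tsz = rng.standard_normal(8) - 0.8
        d_dsz = rng.standard_normal(8)
        data = _long_frame({"TSZ": d_tsz, "DSZ": d_dsz}, rng)
        res = rm_ancova_interaction(data, use_covariates=False)
        t, p = stats.ttest_ind(d_dsz, d_tsz)
        assert res.f_value == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        assert res.df == (1, 14)

    def test_planted_group_difference_detected(self, rng):
        d_tsz = -1.0 + 0.3 * rng.standard_normal(20)
        d_dsz = 0.3 * rng.standard_normal(20)
        data = _long_frame({"TSZ": d_tsz, "DSZ": d_dsz}, rng, covariates=True)
        res = rm_ancova_interaction(data)
        assert res.p_value < 0.005

    def test_missing_timepoint_rejected(self, rng):
        data = _long_frame({"TSZ": [0.1, 0.2], "DSZ": [0.0, 0.1]}, rng)
        data = data.drop(data.index[-1])
        with pytest.raises(ValueError, match="both t1 and t2"):
            rm_ancova_interaction(data, use_covariates=False)

    def test_collinear_covariates_rejected(self, rng):
        data = _long_frame(
            {"TSZ": rng.standard_normal(5), "DSZ": rng.standard_normal(5)},
            rng,
            covariates=True,
        )
        data["education_years"] = data["age_years"]  # exact collinearity
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            rm_ancova_interaction(data)

    def test_subject_order_invariance(self, rng):
        data = _long_frame(
            {"TSZ": rng.standard_normal(6) - 0.5, "DSZ": rng.standard_normal(6)},
            rng,
            covariates=True,
        )
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = rm_ancova_interaction(data)
        b = rm_ancova_interaction(shuffled)
        assert a.f_value == pytest.approx(b.f_value, rel=1e-10)


class TestPosthoc:
    def test_identical_timepoints_give_zero_t(self):
        data = _long_frame({"TSZ": [0.0] * 4, "DSZ": [0.0] * 4})
        res = posthoc_tests(data)
        for r in res.paired_by_group.values():
            assert r.t_value == 0.0
            assert r.p_value == 1.0

    def test_three_pair_hand_example(self):
        # t1 = (5, 6, 7), t2 = (4, 5, 5): d = (1, 1, 2), mean 4/3,
        # sd = 1/sqrt(3), se = 1/3 -> t = 4 exactly, reported for t1 vs t2
        rows = []
        for i, (a, b) in enumerate(zip([5, 6, 7], [4, 5, 5])):
            rows.append({"subject_id": f"s{i}", "group": "TSZ", "timepoint": "t1", "outcome": a})
            rows.append({"subject_id": f"s{i}", "group": "TSZ", "timepoint": "t2", "outcome": b})
        res = posthoc_tests(pd.DataFrame(rows))
        assert res.paired_by_group["TSZ"].t_value == pytest.approx(4.0)

    def test_decrease_gives_positive_t(self, rng):
        t1 = 1.0 + 0.05 * rng.standard_normal(10)
        data = _long_frame({"TSZ": -0.5 + 0.05 * rng.standard_normal(10)}, rng)
        res = posthoc_tests(data)
        assert res.paired_by_group["TSZ"].t_value > 0
        assert res.paired_by_group["TSZ"].p_value < 0.005

    def test_reference_comparison_included(self, rng):
        data = _long_frame(
            {"TSZ": rng.standard_normal(5), "DSZ": rng.standard_normal(5)}, rng
        )
        ref = pd.DataFrame({"outcome": rng.standard_normal(8) + 3.0})
        res = posthoc_tests(data, reference=ref)
        assert set(res.vs_reference) == {"TSZ_t1", "TSZ_t2", "DSZ_t1", "DSZ_t2"}
        assert res.vs_reference["TSZ_t1"].p_value < 0.05  # reference is shifted


class TestSpearmanPartial:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.standard_normal(30)
        rho, p = spearman_partial(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_matches_scipy_without_covariates(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        rho, _ = spearman_partial(x, y)
        expected = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(expected, abs=1e-10)

    def test_partial_recovers_confounded_sign(self, rng):
        # y depends negatively on x directly but both load positively on z,
        # so the naive correlation is positive while the partial is negative
        n = 300
        z = rng.standard_normal(n)
        x = z + 0.6 * rng.standard_normal(n)
        y = -0.5 * x + 1.5 * z + 0.3 * rng.standard_normal(n)
        naive, _ = spearman_partial(x, y)
        partial, p = spearman_partial(x, y, covariates=z[:, None])
        assert naive > 0
        assert partial < 0
        assert p < 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_partial(np.ones(10), np.arange(10.0))

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            _, p = spearman_partial(x, y)
            rejections += p < 0.05
        assert 0.02 < rejections / n_rep < 0.09


class TestCoupling:
    def test_exact_negative_affine_relation(self, rng):
        R = 6
        var = np.abs(rng.standard_normal((R, R)))
        var = (var + var.T) / 2
        np.fill_diagonal(var, 0)
        fc = -2.0 * var + 0.9
        r, p = variability_fc_coupling(var, fc)
        assert r == pytest.approx(-1.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            variability_fc_coupling(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_shuffled_pairs_decorrelate(self, rng):
        R = 10
        iu = np.triu_indices(R, 1)
        var = np.zeros((R, R))
        base = np.sort(rng.uniform(0, 1, iu[0].size))
        var[iu] = base
        var += var.T
        fc = np.zeros((R, R))
        fc[iu] = 1.0 - base  # perfectly anti-ordered
        fc += fc.T
        rs = []
        for _ in range(50):
            shuffled = np.zeros((R, R))
            shuffled[iu] = rng.permutation(base)
            shuffled += shuffled.T
            r, _ = variability_fc_coupling(shuffled, fc)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.2
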