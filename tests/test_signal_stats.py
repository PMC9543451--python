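"""Propensity scores, caliper matching, OR estimation, BH, classification."""

import numpy as np
import pandas as pd
import pytest

from dikidetect.signal_stats import (
    MatchedCohort,
    SeparationError,
    adjust_bh,
    analyze_drug,
    classify_signal,
    estimate_or,
    fit_propensity,
    match_1to4,
    standardized_mean_differences,
)


def make_members(exposed, outcome, age=None, sex=None, admit=None, dx=None):
    n = len(exposed)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "record_id": [f"R{i}" for i in range(n)],
        "exposed": np.asarray(exposed, dtype=bool),
        "outcome": np.asarray(outcome, dtype=bool),
        "age": age if age is not None else rng.uniform(1, 17, n),
        "sex": sex if sex is not None else np.where(rng.random(n) < 0.5, "male", "female"),
        "admission_time": admit if admit is not None else
        pd.to_datetime("2015-06-01") + pd.to_timedelta(rng.uniform(0, 1000, n), unit="D"),
        "main_diagnosis": dx if dx is not None else rng.choice(["J15.9", "A09.0"], n),
        "first_exposure_time": pd.NaT,
    })


def members_from_counts(a, b, c, d):
    """Expand a 2x2 table (exp/event, exp/no, unexp/event, unexp/no)."""
    exposed = np.r_[np.ones(a + b), np.zeros(c + d)].astype(bool)
    outcome = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(bool)
    return make_members(exposed, outcome)


class TestPropensity:
    def test_scores_recover_true_probabilities(self):
        rng = np.random.default_rng(12)
        n = 10_000
        age = rng.uniform(0.5, 17.5, n)
        sexm = rng.random(n) < 0.5
        logit = -2.2 + 0.12 * (age - 9.0) + 0.4 * sexm
        p = 1 / (1 + np.exp(-logit))
        exposed = rng.random(n) < p
        m = make_members(exposed, np.zeros(n, bool), age=age,
                         sex=np.where(sexm, "male", "female"))
        scores = fit_propensity(m)
        assert np.all((scores > 0) & (scores < 1))
        assert np.sqrt(np.mean((scores - p) ** 2)) < 0.02  # Monte-Carlo tolerance

    def test_identical_covariates_give_prevalence_scores(self):
        n = 400
        m = make_members(np.r_[np.ones(100), np.zeros(300)], np.zeros(n, bool),
                         age=np.full(n, 5.0), sex=["male"] * n,
                         admit=pd.to_datetime(["2015-01-01T00:00"] * n),
                         dx=["J15.9"] * n)
        scores = fit_propensity(m)
        assert np.allclose(scores, 0.25, atol=1e-6)

    def test_separating_covariate_is_named(self):
        n = 200
        age = np.r_[np.full(100, 15.0), np.full(100, 3.0)]
        exposed = np.r_[np.ones(100), np.zeros(100)].astype(bool)
        m = make_members(exposed, np.zeros(n, bool), age=age)
        with pytest.raises(SeparationError, match="age"):
            fit_propensity(m)

    def test_single_group_is_an_error(self):
        m = make_members(np.ones(10, bool), np.zeros(10, bool))
        with pytest.raises(ValueError):
            fit_propensity(m)


class TestMatching:
    def test_forced_complete_match(self):
        scores = np.array([0.50, 0.45, 0.48, 0.52, 0.55])
        exposed = np.array([True, False, False, False, False])
        mc = match_1to4(scores, exposed, caliper=0.1, seed=0)
        assert len(mc.pairs) == 4
        assert set(mc.pairs["unexposed_index"]) == {1, 2, 3, 4}

    def test_caliper_excludes_distant_candidates(self):
        scores = np.array([0.50, 0.70, 0.29])
        exposed = np.array([True, False, False])
        mc = match_1to4(scores, exposed, caliper=0.1, seed=0)
        assert len(mc.pairs) == 0
        assert list(mc.dropped_exposed) == [0]

    def test_without_replacement_and_ratio_bound(self):
        rng = np.random.default_rng(2)
        scores = rng.random(60)
        exposed = np.zeros(60, bool)
        exposed[:10] = True
        mc = match_1to4(scores, exposed, caliper=0.2, seed=3)
        used = mc.pairs["unexposed_index"].to_numpy()
        assert len(used) == len(set(used))               # no reuse
        assert len(used) <= 4 * exposed.sum()
        dist = np.abs(scores[mc.pairs["exposed_index"]] - scores[used])
        assert (dist <= 0.2 + 1e-12).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        scores = rng.random(200)
        exposed = rng.random(200) < 0.2
        a = match_1to4(scores, exposed, seed=11)
        b = match_1to4(scores, exposed, seed=11)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_greedy_oracle(self, trial):
        """Small instances: linked-list matcher equals a naive greedy that
        rescans the full pool at every step."""
        rng = np.random.default_rng(100 + trial)
        n_exp = int(rng.integers(1, 7))
        n_une = int(rng.integers(1, 31))
        scores = np.round(rng.random(n_exp + n_une), 3)
        exposed = np.zeros(n_exp + n_une, bool)
        exposed[:n_exp] = True
        caliper = 0.15
        mc = match_1to4(scores, exposed, caliper=caliper, ratio=4, seed=trial)

        exp_idx = np.flatnonzero(exposed)
        une_idx = np.flatnonzero(~exposed)
        order = np.random.default_rng(trial).permutation(n_exp)
        avail = {int(i) for i in une_idx}
        expected_pairs = []
        for oi in order:
            e = exp_idx[oi]
            got = []
            for _ in range(4):
                cands = sorted(avail, key=lambda u: (abs(scores[u] - scores[e]),
                                                     scores[u]))
                if not cands or abs(scores[cands[0]] - scores[e]) > caliper:
                    break
                got.append(cands[0])
                avail.remove(cands[0])
            expected_pairs.extend((e, u) for u in got)
        got_pairs = list(map(tuple, mc.pairs[["exposed_index", "unexposed_index"]].to_numpy()))
        assert sorted(got_pairs) == sorted(expected_pairs)


class TestOddsRatio:
    def test_unadjusted_equals_cross_product_on_reference_counts(self):
        m = members_from_counts(571, 2363, 1558, 10178)
        row = estimate_or(m, adjusted=False)
        expected = (571 * 10178) / (2363 * 1558)
        assert row.or_estimate == pytest.approx(expected, rel=1e-6)
        assert row.or_estimate == pytest.approx(1.579, abs=5e-4)
        assert row.ci_lo < row.or_estimate < row.ci_hi

    def test_null_effect_gives_or_one(self):
        m = members_from_counts(50, 450, 200, 1800)
        row = estimate_or(m, adjusted=False)
        assert row.or_estimate == pytest.approx(1.0, rel=1e-6)
        assert row.ci_lo < 1.0 < row.ci_hi
        assert row.signal == "negative"

    def test_zero_cell_uses_haldane_correction(self, caplog):
        m = members_from_counts(0, 100, 30, 270)
        with caplog.at_level("WARNING"):
            row = estimate_or(m, adjusted=False)
        expected = (0.5 * 270.5) / (100.5 * 30.5)
        assert row.or_estimate == pytest.approx(expected, rel=1e-9)
        assert "Haldane" in caplog.text

    def test_adjusted_model_recovers_known_or_across_replicates(self):
        """Injected conditional OR 1.6: the 95% CI covers truth in >=90% of
        seeded replicates."""
        true_log_or = np.log(1.6)
        rng = np.random.default_rng(77)
        n_exp, n_une = 5000, 20000
        covered = 0
        reps = 100
        for _ in range(reps):
            exposed = np.r_[np.ones(n_exp), np.zeros(n_une)].astype(bool)
            eta = -2.3 + true_log_or * exposed
            outcome = rng.random(n_exp + n_une) < 1 / (1 + np.exp(-eta))
            m = make_members(exposed, outcome)
            row = estimate_or(m, adjusted=False)
            covered += row.ci_lo <= 1.6 <= row.ci_hi
        assert covered >= 0.90 * reps

    def test_type_one_error_control_under_null(self):
        """200 null replicates at 2,000 exposed: CI covers 1 in 95% +/- 4%,
        and the positive-signal rate stays at or below ~5%."""
        rng = np.random.default_rng(88)
        n_exp, n_une = 2000, 8000
        covered = 0
        positive = 0
        reps = 200
        for _ in range(reps):
            exposed = np.r_[np.ones(n_exp), np.zeros(n_une)].astype(bool)
            outcome = rng.random(n_exp + n_une) < 0.10
            m = make_members(exposed, outcome)
            row = estimate_or(m, adjusted=False)
            covered += row.ci_lo <= 1.0 <= row.ci_hi
            positive += row.signal == "positive"
        assert 0.91 <= covered / reps <= 0.99
        assert positive / reps <= 0.07

    def test_constant_outcome_is_an_error(self):
        m = members_from_counts(0, 100, 0, 400)
        with pytest.raises(ValueError):
            estimate_or(m, adjusted=False)


class TestBenjaminiHochberg:
    @staticmethod
    def bh_oracle(p):
        """Textbook step-up: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, m * p[idx] / rank)
            q[idx] = running
        return q

    def test_single_p_is_identity(self):
        assert adjust_bh([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(9)
        np.testing.assert_allclose(adjust_bh(p), self.bh_oracle(p), atol=1e-12)

    def test_order_invariance_and_bounds(self):
        rng = np.random.default_rng(9)
        p = rng.random(12)
        perm = rng.permutation(12)
        q = adjust_bh(p)
        np.testing.assert_allclose(q[perm], adjust_bh(p[perm]), atol=1e-12)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adjust_bh([])
        with pytest.raises(ValueError):
            adjust_bh([0.2, 1.4])


class TestClassification:
    @pytest.mark.parametrize("orv,ci,expected", [
        (1.61, (1.43, 1.80), "positive"),
        (1.06, (0.89, 1.27), "negative"),
        (1.20, (1.00, 1.44), "negative"),   # strict: lower bound exactly 1
    ])
    def test_signal_rule(self, orv, ci, expected):
        assert classify_signal(orv, ci) == expected

    def test_inconsistent_ci_rejected(self):
        with pytest.raises(ValueError):
            classify_signal(2.0, (2.5, 3.0))


def test_analyze_drug_balances_covariates():
    """Matching pulls the age SMD toward zero when exposure depends on age."""
    rng = np.random.default_rng(21)
    n = 6000
    age = rng.uniform(0.5, 17.5, n)
    p = 1 / (1 + np.exp(-(-2.0 + 0.18 * (age - 9.0))))
    exposed = rng.random(n) < p
    outcome = rng.random(n) < 0.10
    m = make_members(exposed, outcome, age=age)
    res = analyze_drug(m, "X", adjusted=False, seed=5)
    assert abs(res.smd_post["age"]) < abs(res.smd_pre["age"])
    assert abs(res.smd_post["age"]) < 0.1
    n_match = len(res.matched.pairs)
    assert n_match <= 4 * len(res.matched.matched_exposed)
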