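import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from promcat import (
    BankSpec,
    Item,
    ItemBank,
    ResponsePattern,
    ThetaGrid,
    eap_estimate,
    generate_bank,
    pattern_log_likelihood,
    simulate_response,
)
from promcat.estimation import AbilityEstimate


def fine_grid_eap(pattern, bank, n_points=10_001, bound=4.5):
    """Independent oracle: EAP posterior mean/SD by direct numerical
    integration on a dense grid, with the GRM likelihood written out from
    the logistic form."""
    theta = np.linspace(-bound, bound, n_points)
    log_post = norm.logpdf(theta)
    for item_id, category in pattern.entries:
        item = bank[item_id]
        b = np.array(item.thresholds)
        pstar = np.vstack(
            [
                np.ones_like(theta),
                1.0 / (1.0 + np.exp(-item.discrimination * (theta[None, :] - b[:, None]))),
                np.zeros_like(theta),
            ]
        )
        log_post += np.log(pstar[category] - pstar[category + 1])
    post = np.exp(log_post - log_post.max())
    post /= post.sum()
    mean = float(theta @ post)
    sd = float(np.sqrt((theta - mean) ** 2 @ post))
    return mean, sd


class TestPatternLogLikelihood:
    def test_empty_pattern_is_zero(self, small_bank):
        assert pattern_log_likelihood(ResponsePattern(), small_bank, 0.7) == 0.0

    def test_single_item_is_log_category_probability(self, small_bank):
        from promcat import category_probabilities

        pattern = ResponsePattern((("poly", 2),))
        expected = np.log(category_probabilities(small_bank["poly"], 0.3)[2])
        assert pattern_log_likelihood(pattern, small_bank, 0.3) == pytest.approx(
            expected
        )

    def test_three_items_sum(self, small_bank):
        parts = [("dich", 1), ("poly", 0), ("third", 2)]
        total = pattern_log_likelihood(
            ResponsePattern(tuple(parts)), small_bank, -0.4
        )
        by_hand = sum(
            pattern_log_likelihood(ResponsePattern((p,)), small_bank, -0.4)
            for p in parts
        )
        assert total == pytest.approx(by_hand)

    def test_unknown_item_rejected(self, small_bank):
        with pytest.raises(KeyError, match="ghost"):
            pattern_log_likelihood(
                ResponsePattern((("ghost", 0),)), small_bank, 0.0
            )

    def test_invalid_category_rejected(self, small_bank):
        with pytest.raises(ValueError, match="category"):
            pattern_log_likelihood(ResponsePattern((("dich", 5),)), small_bank, 0.0)


class TestEapEstimate:
    def test_empty_pattern_returns_prior_exactly(self, small_bank, grid):
        est = eap_estimate(ResponsePattern(), small_bank, grid)
        assert (est.theta, est.sem, est.n_responses) == (0.0, 1.0, 0)

    def test_single_item_symmetry(self, grid):
        item = Item("i", "q", ("0", "1"), 1.3, (0.0,))
        bank = ItemBank((item,))
        up = eap_estimate(ResponsePattern((("i", 1),)), bank, grid)
        down = eap_estimate(ResponsePattern((("i", 0),)), bank, grid)
        assert up.theta == pytest.approx(-down.theta, abs=1e-12)
        assert up.sem == pytest.approx(down.sem, abs=1e-12)
        assert up.theta > 0

    def test_matches_fine_grid_oracle_on_random_patterns(self, grid):
        """200 random 5-item patterns: theta and SEM agree with 10,001-point
        direct integration to 1e-4."""
        bank = generate_bank(BankSpec(n_items=40, n_categories=4, seed=11))
        rng = np.random.default_rng(321)
        for _ in range(200):
            ids = rng.choice(bank.item_ids, size=5, replace=False)
            pattern = ResponsePattern(
                tuple(
                    (i, int(rng.integers(bank[i].n_categories))) for i in ids
                )
            )
            est = eap_estimate(pattern, bank, grid)
            theta_ref, sem_ref = fine_grid_eap(pattern, bank)
            assert est.theta == pytest.approx(theta_ref, abs=1e-4)
            assert est.sem == pytest.approx(sem_ref, abs=1e-4)

    def test_extreme_long_pattern_does_not_underflow(self, grid):
        bank = generate_bank(BankSpec(n_items=80, n_categories=4, seed=5))
        pattern = ResponsePattern(tuple((i, 0) for i in bank.item_ids))
        est = eap_estimate(pattern, bank, grid)
        assert np.isfinite(est.theta) and est.sem > 0

    def test_sem_never_exceeds_prior_sd(self, grid):
        bank = generate_bank(BankSpec(n_items=30, n_categories=4, seed=9))
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(1, 15))
            ids = rng.choice(bank.item_ids, size=n, replace=False)
            pattern = ResponsePattern(
                tuple((i, int(rng.integers(bank[i].n_categories))) for i in ids)
            )
            assert eap_estimate(pattern, bank, grid).sem <= 1.0 + 1e-9

    def test_mean_sem_decreases_as_items_accumulate(self, grid):
        bank = generate_bank(BankSpec(n_items=20, n_categories=4, seed=13))
        rng = np.random.default_rng(99)
        sems = np.zeros(10)
        for _ in range(30):
            theta = rng.normal()
            ids = rng.permutation(bank.item_ids)[:10]
            pattern = ResponsePattern()
            for step, item_id in enumerate(ids):
                cat = simulate_response(bank[item_id], theta, rng)
                pattern = pattern.with_response(item_id, cat)
                sems[step] += eap_estimate(pattern, bank, grid).sem
        assert np.all(np.diff(sems) < 0)

    def test_shrinkage_toward_prior_mean(self, grid):
        """EAP lies between the prior mean (0) and the ML estimate whenever
        the ML solution is interior and away from the prior mean. (When ML
        is ~0 the ordering is meaningless: posterior skew, not shrinkage,
        sets the sign of a near-zero EAP.)"""
        bank = generate_bank(BankSpec(n_items=15, n_categories=4, seed=21))
        rng = np.random.default_rng(4)
        checked = 0
        for _ in range(40):
            ids = rng.choice(bank.item_ids, size=6, replace=False)
            pattern = ResponsePattern(
                tuple((i, int(rng.integers(bank[i].n_categories))) for i in ids)
            )
            res = minimize_scalar(
                lambda t: -pattern_log_likelihood(pattern, bank, t),
                bounds=(-4.4, 4.4),
                method="bounded",
            )
            ml = res.x
            if abs(ml) > 4.2 or abs(ml) < 0.1:
                continue
            eap = eap_estimate(pattern, bank, grid).theta
            assert 0 <= eap / ml <= 1 + 1e-6
            checked += 1
        assert checked >= 10

    def test_consistency_slope_and_rmse_shrinks_with_bank_size(self, grid):
        """Full-bank EAP over simulees theta~N(0,1): calibration slope in
        (0.8, 1.0] and RMSE smaller for the larger bank."""
        rng = np.random.default_rng(2718)
        rmse = {}
        for n_items in (10, 40):
            bank = generate_bank(
                BankSpec(n_items=n_items, n_categories=4, seed=31)
            )
            thetas = rng.normal(size=150)
            est = np.empty_like(thetas)
            for i, theta in enumerate(thetas):
                pattern = ResponsePattern(
                    tuple(
                        (it.item_id, simulate_response(it, theta, rng))
                        for it in bank
                    )
                )
                est[i] = eap_estimate(pattern, bank, grid).theta
            slope = np.polyfit(thetas, est, 1)[0]
            rmse[n_items] = np.sqrt(np.mean((est - thetas) ** 2))
            assert 0.8 < slope <= 1.0, f"slope {slope} at {n_items} items"
        assert rmse[40] < rmse[10]


class TestAbilityEstimate:
    def test_nonpositive_sem_rejected(self):
        with pytest.raises(ValueError):
            AbilityEstimate(theta=0.0, sem=0.0, n_responses=1)

    def test_repeated_item_in_pattern_rejected(self):
        with pytest.raises(ValueError, match="repeats"):
            ResponsePattern((("a", 0), ("a", 1)))
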