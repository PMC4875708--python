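import numpy as np
import pytest

from gpdcat.cat_engine import (
    BankExhaustedError,
    CatConfig,
    PriorSpec,
    estimate_bme,
    estimate_eap,
    estimate_mle,
    run_cat_session,
    select_fpkl,
    select_uwfi,
)
from gpdcat.grm import item_information
from gpdcat.item_bank import ItemIrtParams
from gpdcat.synthetic_data import generate_response_matrix


def _pattern(bank, theta, n_items=8, seed=0):
    """A reproducible mixed response pattern on the first items."""
    resp = generate_response_matrix(bank, np.array([theta]), seed=seed)[0]
    items = bank.irt_items[:n_items]
    return list(resp[:n_items]), items


def _grid_argmax(fun, lo=-6.0, hi=6.0, n=120_001):
    grid = np.linspace(lo, hi, n)
    return grid[int(np.argmax(fun(grid)))]


def _loglik_fn(responses, items):
    def ll(thetas):
        thetas = np.atleast_1d(thetas)
        out = np.zeros_like(thetas, dtype=float)
        from gpdcat.grm import category_probs

        for th_i, th in enumerate(thetas):
            s = 0.0
            for r, it in zip(responses, items):
                s += np.log(max(category_probs(it, th)[r], 1e-300))
            out[th_i] = s
        return out

    return ll


class TestMle:
    def test_matches_grid_search(self, bank):
        responses, items = _pattern(bank, 0.8, seed=1)
        est = estimate_mle(responses, items)
        expected = _grid_argmax(_loglik_fn(responses, items))
        assert est.converged
        assert est.theta == pytest.approx(expected, abs=1e-4)
        info = sum(item_information(it, est.theta) for it in items)
        assert est.sem == pytest.approx(1 / np.sqrt(info))

    def test_symmetric_dichotomous_midpoint(self):
        # two mirror-image 2-category responses put the MLE at t/alpha
        it = ItemIrtParams("d", 2, 1.5, (0.6,))
        est = estimate_mle([0, 1], [it, it])
        assert est.theta == pytest.approx(0.6 / 1.5, abs=1e-4)

    def test_all_extreme_pattern_hits_bound(self, bank):
        items = bank.irt_items[:5]
        top = [it.n_categories - 1 for it in items]
        est = estimate_mle(top, items)
        assert est.theta == 6.0 and not est.converged
        est = estimate_mle([0] * 5, items)
        assert est.theta == -6.0 and not est.converged

    def test_requires_a_response(self, bank):
        with pytest.raises(ValueError):
            estimate_mle([], [])


class TestBme:
    def test_prior_mode_with_no_items(self):
        est = estimate_bme([], [], PriorSpec(kind="normal_standard"))
        assert est.theta == 0.0 and est.sem == pytest.approx(1.0)

    def test_uniform_prior_equals_bounded_mle(self, bank):
        responses, items = _pattern(bank, -0.5, seed=2)
        mle = estimate_mle(responses, items)
        bme = estimate_bme(responses, items, PriorSpec(kind="uniform"))
        assert bme.theta == pytest.approx(mle.theta, abs=1e-9)
        assert bme.sem == pytest.approx(mle.sem, abs=1e-9)

    def test_normal_prior_shrinks_toward_zero(self, bank):
        for theta, seed in [(1.6, 3), (-1.8, 4), (0.9, 5)]:
            responses, items = _pattern(bank, theta, seed=seed)
            mle = estimate_mle(responses, items)
            bme = estimate_bme(responses, items,
                               PriorSpec(kind="normal_standard"))
            assert abs(bme.theta) <= abs(mle.theta) + 1e-9

    def test_normal_mode_matches_grid_posterior(self, bank):
        responses, items = _pattern(bank, 1.1, seed=6)
        ll = _loglik_fn(responses, items)
        expected = _grid_argmax(lambda th: ll(th) - 0.5 * th**2)
        est = estimate_bme(responses, items,
                           PriorSpec(kind="normal_standard"))
        assert est.theta == pytest.approx(expected, abs=1e-4)

    def test_rejects_missing_prior(self, bank):
        responses, items = _pattern(bank, 0.0)
        with pytest.raises(ValueError):
            estimate_bme(responses, items, PriorSpec(kind="none"))


class TestEap:
    def test_prior_moments_with_no_items(self):
        est = estimate_eap([], [], PriorSpec(kind="normal_standard"))
        assert est.theta == pytest.approx(0.0, abs=1e-12)
        assert est.sem == pytest.approx(1.0, abs=1e-3)

    def test_agrees_with_fine_quadrature(self, bank):
        responses, items = _pattern(bank, 0.4, seed=7)
        coarse = estimate_eap(responses, items,
                              PriorSpec(kind="normal_standard"))
        fine = estimate_eap(responses, items,
                            PriorSpec(kind="normal_standard"),
                            quadrature=(611, -6.0, 6.0))
        assert coarse.theta == pytest.approx(fine.theta, abs=1e-3)
        assert coarse.sem == pytest.approx(fine.sem, abs=1e-3)

    def test_posterior_sd_shrinks_with_more_items(self, bank):
        theta = 0.2
        resp = generate_response_matrix(
            bank, np.array([theta]), seed=8
        )[0]
        prior = PriorSpec(kind="normal_standard")
        sds = []
        for n_items in (3, 10, 30, 52):
            est = estimate_eap(list(resp[:n_items]),
                               bank.irt_items[:n_items], prior)
            sds.append(est.sem)
        assert all(a >= b - 1e-9 for a, b in zip(sds, sds[1:]))


class TestSelection:
    def test_singleton_candidate(self, bank):
        it = bank.irt_items[7]
        assert select_uwfi([it], 0.3) == it.item_id
        assert select_fpkl([it], 0.3) == it.item_id

    def test_uwfi_matches_exhaustive_ranking(self, bank):
        theta = 1.5
        info = [item_information(it, theta) for it in bank.irt_items]
        expected = bank.irt_items[int(np.argmax(info))].item_id
        assert select_uwfi(bank.irt_items, theta) == expected

    def test_fpkl_matches_exhaustive_ranking(self, bank):
        import math

        from gpdcat.grm import category_probs

        theta, delta = 0.0, 0.1
        best, best_val = None, -1.0
        for it in bank.irt_items:
            hi = category_probs(it, theta + delta)
            lo = category_probs(it, theta - delta)
            val = sum(
                (h - l) * math.log(h / l)
                for h, l in zip(hi, lo) if h > 1e-12 and l > 1e-12
            )
            if val > best_val:
                best, best_val = it.item_id, val
        assert select_fpkl(bank.irt_items, theta, delta) == best

    def test_fpkl_small_delta_converges_to_information_ranking(self, bank):
        theta = 0.7
        assert select_fpkl(bank.irt_items, theta, delta=1e-4) == \
            select_uwfi(bank.irt_items, theta)

    def test_tie_breaks_to_lower_index(self, bank):
        it = bank.irt_items[0]
        twin = ItemIrtParams("twin", it.n_categories, it.alpha, it.t)
        assert select_uwfi([it, twin], 0.0) == it.item_id
        assert select_fpkl([it, twin], 0.0) == it.item_id

    def test_empty_candidates(self):
        with pytest.raises((BankExhaustedError, ValueError)):
            select_uwfi([], 0.0)

    def test_fpkl_requires_positive_delta(self, bank):
        with pytest.raises(ValueError):
            select_fpkl(bank.irt_items, 0.0, delta=0.0)


class TestConfig:
    def test_mle_rejects_prior(self):
        with pytest.raises(ValueError):
            CatConfig(estimator="MLE",
                      prior=PriorSpec(kind="normal_standard"))

    def test_bayesian_estimators_require_prior(self):
        with pytest.raises(ValueError):
            CatConfig(estimator="EAP", prior=PriorSpec(kind="none"))


class TestSession:
    def test_invariants(self, admin_bank):
        cfg = CatConfig(estimator="MLE", selector="UW-FI",
                        prior=PriorSpec.none(), sem_threshold=0.4)
        for seed, theta in [(0, -1.2), (1, 0.0), (2, 2.5)]:
            rec = run_cat_session(theta, admin_bank, cfg, seed=seed)
            assert 3 <= rec.n_administered <= 52
            assert len(set(rec.administered)) == rec.n_administered
            assert set(rec.administered) <= set(admin_bank.item_ids)
            if rec.termination_reason == "sem_met":
                assert rec.final_estimate.sem <= cfg.sem_threshold
            assert -1 <= rec.theta_start <= 1

    def test_unreachable_threshold_exhausts_bank(self, admin_bank):
        cfg = CatConfig(estimator="MLE", selector="UW-FI",
                        prior=PriorSpec.none(), sem_threshold=0.0)
        rec = run_cat_session(0.5, admin_bank, cfg, seed=3)
        assert rec.n_administered == 52
        assert rec.termination_reason == "bank_exhausted"

    def test_deterministic_under_seed(self, admin_bank):
        cfg = CatConfig(estimator="EAP", selector="FP-KL",
                        prior=PriorSpec(kind="normal_standard"),
                        sem_threshold=0.4)
        a = run_cat_session(0.7, admin_bank, cfg, seed=11)
        b = run_cat_session(0.7, admin_bank, cfg, seed=11)
        assert a.administered == b.administered
        assert a.responses == b.responses
        assert a.final_estimate == b.final_estimate

    def test_mle_and_uniform_bme_share_trajectories(self, admin_bank):
        mle_cfg = CatConfig(estimator="MLE", selector="UW-FI",
                            prior=PriorSpec.none(), sem_threshold=0.4)
        bme_cfg = CatConfig(estimator="BME", selector="UW-FI",
                            prior=PriorSpec(kind="uniform"),
                            sem_threshold=0.4)
        for seed, theta in [(5, -0.8), (6, 0.3), (7, 1.9)]:
            a = run_cat_session(theta, admin_bank, mle_cfg, seed=seed)
            b = run_cat_session(theta, admin_bank, bme_cfg, seed=seed)
            assert a.administered == b.administered
            assert a.responses == b.responses
            assert a.final_estimate.theta == pytest.approx(
                b.final_estimate.theta, abs=1e-9
            )

    def test_fixed_start_scoring_selects_at_theta0(self, admin_bank):
        # with fixed start scoring the three starters are the top-3
        # information ranking at theta0
        cfg = CatConfig(estimator="MLE", selector="UW-FI",
                        prior=PriorSpec.none(), sem_threshold=0.4,
                        start_scoring="fixed")
        rec = run_cat_session(0.0, admin_bank, cfg, seed=13)
        info = [item_information(it, rec.theta_start)
                for it in admin_bank.irt_items]
        expected = {admin_bank.item_ids[i]
                    for i in np.argsort(info)[-3:]}
        assert set(rec.administered[:3]) == expected
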