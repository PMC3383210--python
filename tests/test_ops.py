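import numpy as np
import pytest
from dataclasses import replace

from opspls.dataio import DescriptorTable
from opspls.ops import (
    OPSConfig,
    informative_vector,
    ops_search,
    run_all_vectors,
)
from opspls.preprocess import autoscale
from opspls.synthetic import SyntheticSpec, generate
from opspls.validation import loo_cv


def _autoscaled(rng, n=20, m=6):
    X = rng.normal(size=(n, m))
    Xs, _ = autoscale(X)
    return Xs


class TestInformativeVector:
    def test_response_copy_dominates_all_kinds(self, rng):
        Xs = _autoscaled(rng)
        y = Xs[:, 3] * 2.0 + 1.0
        yc = y - y.mean()
        for kind in ("correlation", "regression", "product"):
            scores = informative_vector(Xs, yc, kind, pilot_lv=3)
            assert np.argmax(np.abs(scores)) == 3

    def test_product_is_elementwise_product(self, rng):
        Xs = _autoscaled(rng)
        yc = rng.normal(size=20)
        yc -= yc.mean()
        corr = informative_vector(Xs, yc, "correlation", pilot_lv=3)
        reg = informative_vector(Xs, yc, "regression", pilot_lv=3)
        prod = informative_vector(Xs, yc, "product", pilot_lv=3)
        assert np.allclose(prod, corr * reg, atol=1e-12)

    def test_correlation_scores_bounded(self, rng):
        Xs = _autoscaled(rng, n=30, m=10)
        yc = rng.normal(size=30)
        scores = informative_vector(Xs, yc - yc.mean(), "correlation")
        assert np.all(np.abs(scores) <= 1 + 1e-12)

    def test_unknown_kind_rejected(self, rng):
        with pytest.raises(ValueError):
            informative_vector(_autoscaled(rng), rng.normal(size=20), "bogus")


def _planted_search_spec(seed):
    # response is an exact 3-descriptor signal plus small noise; decoys are
    # weakly correlated relatives
    return SyntheticSpec(
        n=31, m=40, k_true=3, beta=(2.0, -1.0, 1.0), noise_sd=0.2,
        n_factors=3, factor_rho=0.0, unique_sd=0.0,
        n_decoys=15, decoy_rho=0.25, decoy_rho_jitter=0.05,
        noise_block_size=10, noise_block_rho=0.5, seed=seed,
    )


class TestOPSSearch:
    def test_column_equal_to_response_is_found(self, rng):
        X = rng.normal(size=(20, 8))
        y = X[:, 5].copy()
        cfg = OPSConfig(window=1, lv_range=(1,))
        res = ops_search(X, y, cfg, kind="correlation")
        assert res.best_names == ["x5"]
        assert res.best_q2 >= 0.999

    def test_planted_signal_recovered_across_seeds(self):
        """The three planted descriptors end up in the best subset."""
        cfg = OPSConfig(window=3, lv_range=(1, 2, 3), max_subset=10)
        hits = 0
        for seed in range(50):
            ds = generate(_planted_search_spec(seed))
            res = ops_search(ds.descriptors, ds.y, cfg, kind="product")
            if set(ds.true_names) <= set(res.best_names):
                hits += 1
        assert hits >= 45  # >= 90% of 50 seeds

    def test_q2_and_sev_criteria_select_the_same_model(self, rng):
        X = rng.normal(size=(25, 12))
        y = X[:, 0] - X[:, 4] + rng.normal(0, 0.5, 25)
        res_q2 = ops_search(X, y, OPSConfig(criterion="q2", lv_range=(1, 2, 3)))
        res_sev = ops_search(X, y, OPSConfig(criterion="sev", lv_range=(1, 2, 3)))
        assert res_q2.best_names == res_sev.best_names
        assert res_q2.best_lv == res_sev.best_lv

    def test_sev_is_monotone_in_press_at_fixed_n(self, rng):
        X = rng.normal(size=(20, 8))
        y = rng.normal(size=20)
        res = ops_search(X, y, OPSConfig(lv_range=(1, 2)))
        trials = sorted(res.trials, key=lambda t: t.q2)
        sevs = [t.sev for t in trials]
        assert np.all(np.diff(sevs) <= 1e-12)  # higher q2 <=> lower sev

    def test_full_subset_q2_independent_of_ranking(self, rng):
        """At subset size m every kind fits the same model."""
        X = rng.normal(size=(18, 6))
        y = rng.normal(size=18)
        cfg = OPSConfig(window=6, max_subset=6, lv_range=(2,))
        q2s = {
            kind: ops_search(X, y, cfg, kind=kind).trials[-1].q2
            for kind in ("correlation", "regression", "product")
        }
        vals = list(q2s.values())
        assert vals[0] == pytest.approx(vals[1], abs=1e-12)
        assert vals[0] == pytest.approx(vals[2], abs=1e-12)

    def test_best_trial_reproducible_from_reported_subset(self, rng):
        X = rng.normal(size=(22, 10))
        y = X[:, 1] + rng.normal(0, 0.5, 22)
        res = ops_search(X, y, OPSConfig(lv_range=(1, 2, 3)))
        names = [f"x{j}" for j in range(10)]
        idx = [names.index(n) for n in res.best_names]
        cv = loo_cv(X[:, idx], y, res.best_lv)
        assert cv.q2 == pytest.approx(res.best_q2, abs=1e-10)

    def test_infeasible_config_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            ops_search(X, y, OPSConfig(window=5, max_subset=4))
        with pytest.raises(ValueError):
            ops_search(X, y, OPSConfig(lv_range=(9,)))


class TestRunAllVectors:
    def test_overall_best_dominates_each_kind(self, rng):
        ds = generate(_planted_search_spec(7))
        res = run_all_vectors(ds.descriptors, ds.y, OPSConfig(lv_range=(1, 2, 3), max_subset=10))
        assert res.best.best_q2 >= max(r.best_q2 for r in res.per_kind.values()) - 1e-12
        assert set(res.per_kind) == {"correlation", "regression", "product"}

    def test_no_ranking_freedom_when_window_is_everything(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        cfg = OPSConfig(window=4, max_subset=4, lv_range=(2,))
        res = run_all_vectors(X, y, cfg)
        q2s = [r.best_q2 for r in res.per_kind.values()]
        assert max(q2s) - min(q2s) <= 1e-12

    def test_deterministic(self):
        ds = generate(_planted_search_spec(3))
        cfg = OPSConfig(lv_range=(1, 2), max_subset=8)
        a = run_all_vectors(ds.descriptors, ds.y, cfg)
        b = run_all_vectors(ds.descriptors, ds.y, cfg)
        assert a.best.best_names == b.best.best_names
        assert a.best.best_q2 == b.best.best_q2
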