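import math

import numpy as np
import pytest
from scipy import special

from opspls.dataio import load_model_stats
from opspls.pls import fit_pls
from opspls.synthetic import SyntheticSpec, generate
from opspls.validation import (
    fit_statistics,
    lno_cv,
    loo_cv,
    ssy,
    y_randomization,
)


def _strong_signal_dataset(seed=0):
    """31 compounds, clear 3-descriptor signal: a stable reference model."""
    spec = SyntheticSpec(
        n=31, m=6, k_true=6, beta=(1.2, 1.1, 1.1, 1.0, 1.0, 0.9),
        noise_sd=2.0, n_factors=3, factor_rho=0.5, unique_sd=1.0,
        n_decoys=0, noise_block_size=1, noise_block_rho=0.0, seed=seed,
    )
    return generate(spec)


class TestSSy:
    def test_reference_response_sums(self, table1, table2):
        assert ssy(table1.pic50) == pytest.approx(9.491, abs=2e-3)
        training = table1.drop(table2.ids)
        assert ssy(training.pic50) == pytest.approx(8.026, abs=2e-3)

    def test_constant_vector(self):
        assert ssy(np.full(5, 3.3)) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            ssy(np.array([1.0]))


class TestFitStatistics:
    def test_definitional_invariants(self, rng):
        y = rng.normal(size=20)
        fitted = y + rng.normal(0, 0.3, 20)
        s = fit_statistics(y, fitted, p=3)
        assert s.r2 == pytest.approx(1 - s.rss / s.ssy, abs=1e-10)
        assert s.sec == pytest.approx(math.sqrt(s.rss / (s.n - s.p - 1)), abs=1e-12)
        assert s.f_value == pytest.approx(
            (s.r2 / s.p) / ((1 - s.r2) / (s.n - s.p - 1)), abs=1e-9
        )

    def test_perfect_fit_flags_overflow(self, rng):
        y = rng.normal(size=10)
        s = fit_statistics(y, y.copy(), p=2)
        assert s.r2 == 1.0 and s.sec == 0.0
        assert math.isinf(s.f_value) and s.f_overflow

    @pytest.mark.parametrize("n,p,expected", [(31, 3, 2.960), (26, 3, 3.049)])
    def test_critical_f_values(self, rng, n, p, expected):
        y = rng.normal(size=n)
        fitted = y + rng.normal(0, 0.2, n)
        s = fit_statistics(y, fitted, p=p, alpha=0.05)
        assert s.f_crit == pytest.approx(expected, abs=1e-3)
        # independent quantile route
        assert s.f_crit == pytest.approx(special.fdtri(p, n - p - 1, 0.95), abs=1e-10)

    def test_needs_spare_degrees_of_freedom(self, rng):
        with pytest.raises(ValueError):
            fit_statistics(rng.normal(size=4), rng.normal(size=4), p=3)


class TestLeaveOneOut:
    @pytest.mark.parametrize("refit_scaling", [True, False])
    def test_matches_naive_full_refit_loop(self, rng, refit_scaling):
        X = rng.normal(size=(15, 5))
        y = rng.normal(size=15)
        A = 3
        press = 0.0
        for i in range(15):
            mask = np.ones(15, bool)
            mask[i] = False
            if refit_scaling:
                model = fit_pls(X[mask], y[mask], A)
                pred = model.predict(X[i : i + 1])[0]
            else:
                mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
                from opspls.pls import _nipals_pls1

                ym = y[mask].mean()
                _, _, _, _, b = _nipals_pls1(
                    (X[mask] - mu) / sd, y[mask] - ym, A
                )
                pred = ((X[i] - mu) / sd) @ b + ym
            press += (y[i] - pred) ** 2
        cv = loo_cv(X, y, A, refit_scaling=refit_scaling)
        assert cv.press == pytest.approx(press, abs=1e-10)
        assert cv.q2 == pytest.approx(1 - press / ssy(y), abs=1e-12)
        assert cv.sev == pytest.approx(math.sqrt(press / 15), abs=1e-12)

    def test_perfect_linear_response(self, rng):
        X = rng.normal(size=(12, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        cv = loo_cv(X, y, 3)
        assert cv.q2 == pytest.approx(1.0, abs=1e-6)

    def test_summary_arithmetic_of_reference_block(self):
        # Q2 and SEV follow from the printed PRESS/SSy of the full model
        press, total, n = 3.621, 9.491, 31
        assert 1 - press / total == pytest.approx(0.618, abs=1e-3)
        assert math.sqrt(press / n) == pytest.approx(0.342, abs=1e-3)


class TestLeaveNOut:
    def test_n1_equals_loo_exactly(self):
        ds = _strong_signal_dataset(4)
        X = ds.descriptors.values
        loo = loo_cv(X, ds.y, 3)
        lno = lno_cv(X, ds.y, 3, n_max=1, replicates=3, seed=99)
        assert np.all(lno.q2[1] == loo.q2)

    def test_stable_model_stays_close_to_loo(self):
        ds = _strong_signal_dataset(1)
        X = ds.descriptors.values
        loo = loo_cv(X, ds.y, 3)
        lno = lno_cv(X, ds.y, 3, n_max=7, replicates=6, seed=7)
        for N in lno.n_values:
            assert abs(lno.mean[N] - loo.q2) <= 0.1
            assert lno.sd[N] <= 0.1

    def test_destroyed_signal_gives_negative_q2(self, rng):
        ds = _strong_signal_dataset(2)
        X = ds.descriptors.values
        y_perm = ds.y[rng.permutation(len(ds.y))]
        lno = lno_cv(X, y_perm, 3, n_max=5, replicates=6, seed=11)
        assert np.mean([lno.mean[N] for N in lno.n_values]) < 0

    def test_reproducible_for_fixed_seed(self):
        ds = _strong_signal_dataset(5)
        X = ds.descriptors.values
        a = lno_cv(X, ds.y, 3, n_max=4, replicates=3, seed=42)
        b = lno_cv(X, ds.y, 3, n_max=4, replicates=3, seed=42)
        for N in a.n_values:
            assert np.all(a.q2[N] == b.q2[N])

    def test_infeasible_block_size(self):
        ds = _strong_signal_dataset(6)
        with pytest.raises(ValueError):
            lno_cv(ds.descriptors.values, ds.y, 3, n_max=30)


class TestYRandomization:
    def test_structure_and_flags(self):
        ds = _strong_signal_dataset(3)
        res = y_randomization(ds.descriptors.values, ds.y, 3, n_scrambles=10, seed=1)
        assert res.n_scrambles == 10
        assert np.all((res.abs_r >= 0) & (res.abs_r <= 1))
        assert res.pass_r2 == (res.intercept_r2 < 0.3)
        assert res.pass_q2 == (res.intercept_q2 < 0.05)

    def test_planted_signal_passes_intercept_rules(self):
        ds = _strong_signal_dataset(8)
        res = y_randomization(ds.descriptors.values, ds.y, 3, n_scrambles=10, seed=2)
        assert res.intercept_r2 < 0.3
        assert res.intercept_q2 < 0.05

    def test_scrambled_models_are_poor(self):
        ds = _strong_signal_dataset(9)
        res = y_randomization(ds.descriptors.values, ds.y, 3, n_scrambles=10, seed=3)
        assert res.original_q2 > 0.5
        assert np.max(res.q2) < res.original_q2

    def test_anchor_point_controls_intercept(self, rng):
        # with flat scrambled quality the anchored line pivots on the original
        ds = _strong_signal_dataset(10)
        with_anchor = y_randomization(
            ds.descriptors.values, ds.y, 3, n_scrambles=5, seed=4, include_original=True
        )
        without = y_randomization(
            ds.descriptors.values, ds.y, 3, n_scrambles=5, seed=4, include_original=False
        )
        assert with_anchor.abs_r == pytest.approx(without.abs_r)
        assert with_anchor.intercept_r2 != without.intercept_r2

    def test_too_few_scrambles(self):
        ds = _strong_signal_dataset(11)
        with pytest.raises(ValueError):
            y_randomization(ds.descriptors.values, ds.y, 3, n_scrambles=1)


class TestConsistencyChain:
    """Printed statistic blocks are algebraically self-consistent."""

    @pytest.mark.parametrize("fixture", ["eq1_stats", "eq2_stats"])
    def test_printed_block_reproduces_derived_statistics(self, fixture):
        blk = load_model_stats(fixture)
        n, p = blk["n"], blk["p"]
        rss = (1 - blk["r2"]) * blk["ssy"]
        assert math.sqrt(rss / (n - p - 1)) == pytest.approx(blk["sec"], abs=1e-3)
        f = (blk["r2"] / p) / ((1 - blk["r2"]) / (n - p - 1))
        assert f == pytest.approx(blk["f_value"], abs=0.1)
        assert 1 - blk["press"] / blk["ssy"] == pytest.approx(blk["q2_loo"], abs=1e-3)
        assert math.sqrt(blk["press"] / n) == pytest.approx(blk["sev"], abs=1e-3)
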