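import numpy as np
import pytest

from opspls import (
    OPSConfig,
    correlation_prefilter,
    load_activity_table,
    load_observed_predicted,
    loo_cv,
    remove_degenerate_columns,
    run_all_vectors,
)
from opspls.synthetic import paperlike


@pytest.fixture(scope="session")
def table1():
    return load_activity_table("table1")


@pytest.fixture(scope="session")
def table2():
    return load_observed_predicted("table2")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def run_paperlike_pipeline(seed: int):
    """Prefilter -> OPS -> PLS(3) LOO on one study-regime dataset.

    Scan design: LV 1..3 (the planted latent rank), window 6 (the planted
    model size), subsets up to 30 descriptors.
    """
    ds = paperlike(seed)
    cleaned, _ = remove_degenerate_columns(ds.descriptors)
    filtered, _ = correlation_prefilter(cleaned, ds.y, 0.3)
    result = run_all_vectors(
        filtered, ds.y,
        OPSConfig(lv_range=(1, 2, 3), window=6, max_subset=min(30, filtered.m)),
    )
    selected = result.best.best_names
    cv = loo_cv(filtered.select(selected), ds.y, min(3, len(selected)))
    n_recovered = len(set(selected) & set(ds.true_names))
    return cv.q2, n_recovered


@pytest.fixture(scope="session")
def paperlike_experiment():
    """Q2 and planted-descriptor recovery of the full pipeline, 50 seeds."""
    results = [run_paperlike_pipeline(seed) for seed in range(50)]
    q2 = np.array([r[0] for r in results])
    recovered = np.array([r[1] for r in results])
    return q2, recovered
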