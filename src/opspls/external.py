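"""Train/test splitting and external predictivity metrics.

External validation asks whether the model predicts compounds it has never
seen.  The split can be given explicitly (``fixed_split``) or derived with a
hierarchical-clustering heuristic that keeps the test set spread over both
the activity range and the descriptor space.  Predictive power is measured
by R²pred and SEP, complemented by the Golbraikh–Tropsha battery on the
through-origin regressions between observed and predicted activity:
k, k' ∈ [0.85, 1.15] and |R²₀ - R'²₀| < 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage

from .dataio import DescriptorTable

__all__ = [
    "SplitSpec",
    "ExternalValidationReport",
    "fixed_split",
    "hca_split",
    "external_metrics",
]

K_RANGE = (0.85, 1.15)
R2_DIFF_LIMIT = 0.3
R2PRED_LIMIT = 0.5


@dataclass
class SplitSpec:
    """A train/test partition of the compound ids."""

    train_ids: list[str]
    test_ids: list[str]
    method: str

    def __post_init__(self):
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValueError(f"train/test overlap: {sorted(train & test)}")
        if not self.test_ids:
            raise ValueError("test set is empty")
        if not self.train_ids:
            raise ValueError("training set is empty")


def fixed_split(all_ids: Sequence[str], test_ids: Sequence[str]) -> SplitSpec:
    """Split by an explicit test-id list (order of ``all_ids`` preserved)."""
    test = list(test_ids)
    missing = set(test) - set(all_ids)
    if missing:
        raise KeyError(f"test ids not in data set: {sorted(missing)}")
    train = [i for i in all_ids if i not in set(test)]
    return SplitSpec(train_ids=train, test_ids=test, method="fixed-list")


def hca_split(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    n_test: int,
    linkage: str = "complete",
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> SplitSpec:
    """Representative test set via hierarchical clustering on autoscaled X.

    The compounds are clustered (Euclidean distance, configurable linkage)
    and one test compound is drawn per activity-quantile stratum, preferring
    an as-yet-unused cluster, and never the compounds with the global
    minimum or maximum activity (those anchor the training range).
    """
    if isinstance(X, DescriptorTable):
        from .preprocess import autoscale

        values, _ = autoscale(X)
        ids = list(X.ids) if ids is None else list(ids)
    else:
        values = np.asarray(X, dtype=float)
        ids = [f"c{i}" for i in range(values.shape[0])] if ids is None else list(ids)
    y = np.asarray(y, dtype=float)
    n = y.size
    if not 1 <= n_test < n / 2:
        raise ValueError(f"n_test must be in 1..{(n - 1) // 2}")

    Z = scipy_linkage(values, method=linkage, metric="euclidean")
    clusters = fcluster(Z, t=n_test, criterion="maxclust")
    rng = np.random.default_rng(seed)

    forbidden = {int(np.argmin(y)), int(np.argmax(y))}
    order = np.argsort(y, kind="stable")
    strata = np.array_split(order, n_test)

    chosen: list[int] = []
    used_clusters: set[int] = set()
    for stratum in strata:
        pool = [i for i in stratum if i not in forbidden and i not in chosen]
        if not pool:
            continue
        fresh = [i for i in pool if clusters[i] not in used_clusters]
        candidates = fresh if fresh else pool
        pick = int(rng.choice(candidates))
        chosen.append(pick)
        used_clusters.add(int(clusters[pick]))
    # top up from the global pool if some stratum was exhausted
    if len(chosen) < n_test:
        rest = [i for i in range(n) if i not in forbidden and i not in chosen]
        extra = rng.choice(rest, size=n_test - len(chosen), replace=False)
        chosen.extend(int(i) for i in extra)

    test = [ids[i] for i in sorted(chosen)]
    train = [ids[i] for i in range(n) if ids[i] not in set(test)]
    return SplitSpec(train_ids=train, test_ids=test, method="hca-representative")


@dataclass
class ExternalValidationReport:
    """R²pred, SEP and the Golbraikh–Tropsha statistics with pass flags."""

    n_test: int
    press_test: float
    sep: float
    r2pred: float
    k: float | None = None
    kprime: float | None = None
    r2_0: float | None = None
    rprime2_0: float | None = None
    abs_diff: float | None = None
    pass_r2pred: bool = False
    pass_k: bool | None = None
    pass_kprime: bool | None = None
    pass_diff: bool | None = None

    @property
    def all_pass(self) -> bool:
        flags = [self.pass_r2pred, self.pass_k, self.pass_kprime, self.pass_diff]
        return all(f for f in flags if f is not None) and None not in flags


def external_metrics(
    obs: np.ndarray,
    pred: np.ndarray,
    y_train_mean: float,
    include_gt: bool = True,
) -> ExternalValidationReport:
    """External predictivity metrics from observed/predicted test activities.

    R²pred = 1 - PRESS / Σ(obs - ȳ_train)², with the *training-set* mean in
    the denominator; SEP = sqrt(PRESS / n).  With ``include_gt`` the
    through-origin slopes k = Σ(obs·pred)/Σpred² and k' = Σ(obs·pred)/Σobs²,
    and the corresponding through-origin determination coefficients R²₀
    (observed against k·pred) and R'²₀ (predicted against k'·obs), are added
    with their pass flags.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    n = obs.size
    if n < 2:
        raise ValueError("need at least two test compounds")

    press = float(((obs - pred) ** 2).sum())
    denom = float(((obs - y_train_mean) ** 2).sum())
    if denom == 0:
        raise ValueError("degenerate R2pred denominator: test observations all equal the training mean")
    sep = math.sqrt(press / n)
    r2pred = 1.0 - press / denom
    report = ExternalValidationReport(
        n_test=n, press_test=press, sep=sep, r2pred=r2pred,
        pass_r2pred=r2pred > R2PRED_LIMIT,
    )
    if not include_gt:
        return report

    sum_op = float(obs @ pred)
    sum_pp = float(pred @ pred)
    sum_oo = float(obs @ obs)
    if sum_pp == 0:
        raise ValueError("degenerate slope k: predicted values are all zero")
    if sum_oo == 0:
        raise ValueError("degenerate slope k': observed values are all zero")
    k = sum_op / sum_pp
    kprime = sum_op / sum_oo

    var_obs = float(((obs - obs.mean()) ** 2).sum())
    var_pred = float(((pred - pred.mean()) ** 2).sum())
    if var_obs == 0:
        raise ValueError("degenerate R2_0: observed test activities have zero variance")
    if var_pred == 0:
        raise ValueError("degenerate R'2_0: predicted test activities have zero variance")
    r2_0 = 1.0 - float(((obs - k * pred) ** 2).sum()) / var_obs
    rprime2_0 = 1.0 - float(((pred - kprime * obs) ** 2).sum()) / var_pred
    abs_diff = abs(r2_0 - rprime2_0)

    report.k = k
    report.kprime = kprime
    report.r2_0 = r2_0
    report.rprime2_0 = rprime2_0
    report.abs_diff = abs_diff
    report.pass_k = K_RANGE[0] <= k <= K_RANGE[1]
    report.pass_kprime = K_RANGE[0] <= kprime <= K_RANGE[1]
    report.pass_diff = abs_diff < R2_DIFF_LIMIT
    return report
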