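"""Internal model statistics and the robustness / chance-correlation battery.

Covers the calibration statistics (R², SEC, F against its critical value),
leave-one-out cross-validation (PRESS, Q², SEV), leave-N-out with randomized
row order, and the y-randomization test with the intercept criteria of the
Eriksson approach (R²-line intercept < 0.3, Q²-line intercept < 0.05).

Conventions used throughout:

* Q² = 1 - PRESS / SSy, where SSy = Σ(y - ȳ)² of the full (unpermuted)
  training response.  Q² can be negative; that simply means the model
  predicts worse than the training mean.
* SEC = sqrt(RSS / (n - p - 1)) with p the number of latent variables;
  SEV = sqrt(PRESS / n).
* Cross-validation re-autoscales inside each fold by default
  (``refit_scaling=True``); the fixed-scaling variant scales once on the
  full data, mimicking tools that preprocess before CV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import stats

from .dataio import DescriptorTable
from .pls import _nipals_pls1

__all__ = [
    "FitStats",
    "CVStats",
    "LNOResult",
    "YRandomizationResult",
    "ssy",
    "fit_statistics",
    "loo_cv",
    "lno_cv",
    "y_randomization",
]


def _values(X: Union[DescriptorTable, np.ndarray]) -> np.ndarray:
    return X.values if isinstance(X, DescriptorTable) else np.asarray(X, dtype=float)


def ssy(y: np.ndarray) -> float:
    """Total sum of squares of the response about its mean, Σ(yᵢ - ȳ)²."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two response values")
    d = y - y.mean()
    return float(d @ d)


@dataclass
class FitStats:
    """Calibration statistics of a fitted model."""

    r2: float
    sec: float
    rss: float
    ssy: float
    f_value: float
    f_crit: float
    f_overflow: bool
    n: int
    p: int
    alpha: float


def fit_statistics(y: np.ndarray, fitted: np.ndarray, p: int, alpha: float = 0.05) -> FitStats:
    """R², SEC, RSS and the F-ratio with its critical value.

    ``p`` is the model dimensionality (number of latent variables); the F
    test uses (p, n - p - 1) degrees of freedom.  A perfect fit is reported
    with ``f_value = inf`` and the overflow flag set.
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if y.shape != fitted.shape:
        raise ValueError("y and fitted lengths differ")
    n = y.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    total = ssy(y)
    resid = y - fitted
    rss = float(resid @ resid)
    r2 = 1.0 - rss / total
    sec = math.sqrt(rss / (n - p - 1))
    if rss == 0.0 or r2 >= 1.0:
        f_value, overflow = math.inf, True
    else:
        f_value = (r2 / p) / ((1.0 - r2) / (n - p - 1))
        overflow = False
    f_crit = float(stats.f.ppf(1.0 - alpha, p, n - p - 1))
    return FitStats(
        r2=r2, sec=sec, rss=rss, ssy=total,
        f_value=f_value, f_crit=f_crit, f_overflow=overflow,
        n=n, p=p, alpha=alpha,
    )


@dataclass
class CVStats:
    """Cross-validation statistics: PRESS, Q² = 1 - PRESS/SSy, SEV."""

    press: float
    q2: float
    sev: float
    ssy: float
    n: int
    predictions: np.ndarray | None = None


def _cv_predictions(
    X: np.ndarray, y: np.ndarray, n_components: int,
    blocks: list[np.ndarray], refit_scaling: bool,
) -> np.ndarray:
    """Out-of-block predictions for an arbitrary disjoint block partition."""
    n = y.size
    pred = np.empty(n)
    if not refit_scaling:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise ValueError("zero-variance column under fixed scaling")
    for block in blocks:
        mask = np.ones(n, dtype=bool)
        mask[block] = False
        Xtr, ytr = X[mask], y[mask]
        if n_components > min(Xtr.shape[0] - 1, Xtr.shape[1]):
            raise ValueError("n_components infeasible inside a CV fold")
        if refit_scaling:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("zero-variance column inside a CV fold")
        ym = ytr.mean()
        _, _, _, _, b = _nipals_pls1((Xtr - mu) / sd, ytr - ym, n_components)
        pred[block] = ((X[block] - mu) / sd) @ b + ym
    return pred


def loo_cv(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    n_components: int,
    refit_scaling: bool = True,
) -> CVStats:
    """Leave-one-out cross-validation of a PLS1 model.

    Each compound is predicted by a model fitted on the remaining n - 1;
    PRESS accumulates the squared prediction errors.
    """
    Xv = _values(X)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("leave-one-out needs at least three compounds")
    blocks = [np.array([i]) for i in range(n)]
    pred = _cv_predictions(Xv, y, n_components, blocks, refit_scaling)
    press = float(((y - pred) ** 2).sum())
    total = ssy(y)
    return CVStats(
        press=press, q2=1.0 - press / total, sev=math.sqrt(press / n),
        ssy=total, n=n, predictions=pred,
    )


@dataclass
class LNOResult:
    """Leave-N-out Q² per block size, replicated over random row orders."""

    n_values: list[int]
    q2: dict[int, np.ndarray]        # N -> replicate Q² values
    mean: dict[int, float]
    sd: dict[int, float]
    replicates: int
    seed: int

    @property
    def overall_mean(self) -> float:
        return float(np.mean([self.mean[N] for N in self.n_values]))


def lno_cv(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    n_components: int,
    n_max: int = 7,
    replicates: int = 6,
    seed: int = 0,
    refit_scaling: bool = True,
) -> LNOResult:
    """Leave-N-out cross-validation for N = 1..n_max with randomized rows.

    Per replicate the rows of X and y are jointly permuted, the data is cut
    into consecutive blocks of size N (last block possibly smaller), each
    block is left out once, and Q² = 1 - PRESS/SSy uses the SSy of the full
    unpermuted response.  A robust model keeps mean Q²(N) close to the
    leave-one-out value with small spread.
    """
    Xv = _values(X)
    y = np.asarray(y, dtype=float)
    n = y.size
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 1 <= n_max <= n - 2:
        raise ValueError(f"n_max must be in 1..{n - 2}")
    rng = np.random.default_rng(seed)
    total = ssy(y)
    q2: dict[int, np.ndarray] = {}
    for N in range(1, n_max + 1):
        vals = np.empty(replicates)
        for r in range(replicates):
            perm = rng.permutation(n)
            blocks = [perm[i:i + N] for i in range(0, n, N)]
            pred = _cv_predictions(Xv, y, n_components, blocks, refit_scaling)
            press = float(((y - pred) ** 2).sum())
            vals[r] = 1.0 - press / total
        q2[N] = vals
    return LNOResult(
        n_values=list(range(1, n_max + 1)),
        q2=q2,
        mean={N: float(v.mean()) for N, v in q2.items()},
        sd={N: float(v.std(ddof=1)) if replicates > 1 else 0.0 for N, v in q2.items()},
        replicates=replicates,
        seed=seed,
    )


@dataclass
class YRandomizationResult:
    """Chance-correlation test: model quality after scrambling the response."""

    abs_r: np.ndarray          # |r(y_scrambled, y)| per scramble
    r2: np.ndarray
    q2: np.ndarray
    original_r2: float
    original_q2: float
    intercept_r2: float
    intercept_q2: float
    pass_r2: bool              # intercept_r2 < 0.3
    pass_q2: bool              # intercept_q2 < 0.05
    include_original: bool
    seed: int
    n_scrambles: int = field(init=False)

    def __post_init__(self):
        self.n_scrambles = len(self.abs_r)


def _line_intercept(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def y_randomization(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    n_components: int,
    n_scrambles: int = 10,
    seed: int = 0,
    refit_scaling: bool = True,
    include_original: bool = True,
) -> YRandomizationResult:
    """Scramble y, refit on the fixed descriptor set, test the intercepts.

    For each scramble the model is refitted (same descriptors, same number
    of latent variables) and R², Q²(LOO) and |r| between the scrambled and
    original response are recorded.  Two least-squares lines are then fitted
    through the (|r|, R²) and (|r|, Q²) points — anchored, by default, by
    the original model at |r| = 1 — and their intercepts must stay below
    0.3 and 0.05 respectively.  Identity permutations are not resampled, so
    the null stays exact.
    """
    Xv = _values(X)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n_scrambles < 2:
        raise ValueError("need at least two scrambles")
    if n < 3:
        raise ValueError("too few compounds to permute meaningfully")
    rng = np.random.default_rng(seed)
    sy = y.std(ddof=1)
    if sy <= 0:
        raise ValueError("zero-variance response")

    from .pls import fit_pls  # local import avoids a cycle at module load

    original = fit_pls(Xv, y, n_components)
    orig_stats = fit_statistics(y, original.fitted, n_components)
    orig_cv = loo_cv(Xv, y, n_components, refit_scaling=refit_scaling)

    abs_r = np.empty(n_scrambles)
    r2 = np.empty(n_scrambles)
    q2 = np.empty(n_scrambles)
    for s in range(n_scrambles):
        yp = y[rng.permutation(n)]
        abs_r[s] = abs(float(np.corrcoef(yp, y)[0, 1]))
        model = fit_pls(Xv, yp, n_components)
        r2[s] = fit_statistics(yp, model.fitted, n_components).r2
        q2[s] = loo_cv(Xv, yp, n_components, refit_scaling=refit_scaling).q2

    if include_original:
        xs = np.append(abs_r, 1.0)
        r2_pts = np.append(r2, orig_stats.r2)
        q2_pts = np.append(q2, orig_cv.q2)
    else:
        xs, r2_pts, q2_pts = abs_r, r2, q2
    intercept_r2 = _line_intercept(xs, r2_pts)
    intercept_q2 = _line_intercept(xs, q2_pts)
    return YRandomizationResult(
        abs_r=abs_r, r2=r2, q2=q2,
        original_r2=orig_stats.r2, original_q2=orig_cv.q2,
        intercept_r2=intercept_r2, intercept_q2=intercept_q2,
        pass_r2=intercept_r2 < 0.3, pass_q2=intercept_q2 < 0.05,
        include_original=include_original, seed=seed,
    )
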