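"""NIPALS PLS1 regression on autoscaled descriptors.

Partial least squares projects the descriptor matrix onto a small number of
orthogonal latent variables chosen to maximise covariance with the response.
For a single response (PLS1) the NIPALS weight vector of each component is
obtained directly as the normalised X'y of the deflated matrix, so the fit
is fully deterministic — no iteration, no random initialisation.

Descriptors are autoscaled internally; the response is mean-centred (unit
variance scaling of y is optional and leaves predictions unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .dataio import DescriptorTable
from .preprocess import ScalingParams, autoscale

__all__ = [
    "PLSModel",
    "CoefficientReport",
    "fit_pls",
    "predict",
    "standardized_coefficients",
    "explained_variance",
    "wold_report",
]


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core PLS1 decomposition of a centred/scaled X and centred y.

    Returns (W, P, q, T, b) with b the regression vector in the scaled
    coordinates: yc_hat = Xc @ b.
    """
    n, m = Xc.shape
    W = np.empty((m, n_components))
    P = np.empty((m, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    X = Xc.copy()
    y = yc.copy()
    y_norm = float(np.linalg.norm(yc)) or 1.0
    for a in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * y_norm:
            raise ValueError(
                f"X'y vanished at component {a + 1}: requested {n_components} "
                "components exceed the informative rank"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-24:
            raise ValueError(f"degenerate score at component {a + 1}")
        p = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, p)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p, qa, t
    # b = W (P'W)^{-1} q  maps the (scaled) X directly onto centred y
    b = W @ np.linalg.solve(P.T @ W, q)
    return W, P, q, T, b


@dataclass
class PLSModel:
    """A fitted PLS1 model with its scaling, loadings and coefficients."""

    n_components: int
    names: list[str]
    weights: np.ndarray        # m x A
    x_loadings: np.ndarray     # m x A
    y_loadings: np.ndarray     # A
    scores: np.ndarray         # n x A (training)
    x_scaling: ScalingParams
    y_mean: float
    y_sd: float                # sample sd of training y (always stored)
    y_scaled: bool             # whether y was divided by y_sd during fitting
    coef_scaled: np.ndarray    # regression vector in scaled coordinates
    coef_raw: np.ndarray       # per-descriptor coefficients in original units
    intercept: float
    explained_x_variance: np.ndarray  # per-LV % of scaled-X sum of squares
    y: np.ndarray              # training response
    fitted: np.ndarray         # training fitted values

    @property
    def coef_std(self) -> np.ndarray:
        """Standardized coefficients (autoscaled x AND autoscaled y)."""
        return self.coef_scaled if self.y_scaled else self.coef_scaled / self.y_sd

    def transform(self, X: Union[DescriptorTable, np.ndarray]) -> np.ndarray:
        """Latent-variable scores for new compounds (original-unit input)."""
        Xs = self.x_scaling.transform(self._values(X))
        R = self.weights @ np.linalg.solve(self.x_loadings.T @ self.weights,
                                           np.eye(self.n_components))
        return Xs @ R

    def predict(self, X: Union[DescriptorTable, np.ndarray]) -> np.ndarray:
        return predict(self, X)

    def _values(self, X: Union[DescriptorTable, np.ndarray]) -> np.ndarray:
        if isinstance(X, DescriptorTable):
            if X.names != self.names:
                raise ValueError("descriptor columns do not match the training set")
            return X.values
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[1] != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} descriptor columns, got {arr.shape[1]}"
            )
        return arr


@dataclass
class CoefficientReport:
    """Standardized coefficients with the half-maximum significance rule.

    A descriptor counts as significant when |b_std| is at least half the
    largest |b_std| in the model (Wold's rule of thumb).
    """

    names: list[str]
    b_std: np.ndarray
    threshold: float
    significant: np.ndarray

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "coefficients": {
                n: {"b_std": float(b), "significant": bool(s)}
                for n, b, s in zip(self.names, self.b_std, self.significant)
            },
        }


def fit_pls(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    n_components: int,
    scale_y: bool = False,
    names: Sequence[str] | None = None,
) -> PLSModel:
    """Fit a NIPALS PLS1 model on original-unit descriptors.

    ``X`` is autoscaled internally and ``y`` mean-centred (divided by its
    sample sd as well when ``scale_y``).  ``n_components`` must not exceed
    min(n - 1, m).
    """
    if isinstance(X, DescriptorTable):
        values, col_names = X.values, X.names
    else:
        values = np.asarray(X, dtype=float)
        col_names = list(names) if names is not None else [f"x{j}" for j in range(values.shape[1])]
    y = np.asarray(y, dtype=float)
    n, m = values.shape
    if y.shape != (n,):
        raise ValueError("y length does not match X rows")
    if not 1 <= n_components <= min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} infeasible for n={n}, m={m} "
            f"(must be in 1..{min(n - 1, m)})"
        )
    y_sd = float(y.std(ddof=1))
    if y_sd <= 0:
        raise ValueError("zero-variance response")
    Xs, scaling = autoscale(values)
    scaling.names = list(col_names)
    y_mean = float(y.mean())
    yc = (y - y_mean) / (y_sd if scale_y else 1.0)

    W, P, q, T, b = _nipals_pls1(Xs, yc, n_components)

    ssx = float((Xs * Xs).sum())
    tt = (T * T).sum(axis=0)
    pp = (P * P).sum(axis=0)
    explained = 100.0 * tt * pp / ssx

    y_scale_used = y_sd if scale_y else 1.0
    coef_raw = b * y_scale_used / scaling.sd
    intercept = y_mean - float(scaling.mean @ coef_raw)
    fitted = values @ coef_raw + intercept

    return PLSModel(
        n_components=n_components,
        names=list(col_names),
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        x_scaling=scaling,
        y_mean=y_mean,
        y_sd=y_sd,
        y_scaled=scale_y,
        coef_scaled=b,
        coef_raw=coef_raw,
        intercept=intercept,
        explained_x_variance=explained,
        y=y.copy(),
        fitted=fitted,
    )


def predict(model: PLSModel, X: Union[DescriptorTable, np.ndarray]) -> np.ndarray:
    """Predict activities for new compounds given in original units."""
    values = model._values(X)
    return values @ model.coef_raw + model.intercept


def explained_variance(model: PLSModel) -> np.ndarray:
    """Percent of the autoscaled-X sum of squares captured by each LV."""
    return model.explained_x_variance.copy()


def wold_report(b_std: np.ndarray, names: Sequence[str]) -> CoefficientReport:
    """Apply the half-maximum significance rule to standardized coefficients."""
    b_std = np.asarray(b_std, dtype=float)
    threshold = 0.5 * float(np.max(np.abs(b_std)))
    return CoefficientReport(
        names=list(names),
        b_std=b_std,
        threshold=threshold,
        significant=np.abs(b_std) >= threshold,
    )


def standardized_coefficients(model: PLSModel) -> CoefficientReport:
    """Standardized coefficients of a fitted model with significance flags.

    b_std_j = b_raw_j * sd(x_j) / sd(y); the significance threshold is half
    the largest absolute standardized coefficient.
    """
    return wold_report(model.coef_std, model.names)
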