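"""Outlier diagnostics in latent-variable space: leverages and residuals.

The Williams-plot pair of statistics: the leverage of each compound in the
score space, h_i = 1/n + t_i'(T'T)^{-1} t_i, and its internally studentized
residual r_i = e_i / (s * sqrt(1 - h_i)) with s the standard error of
calibration.  A compound is flagged as high-leverage above the cutoff
h* = 3(A + 1)/n (the usual Williams-plot convention) and as a response
outlier when |r_i| exceeds a threshold in sigma units (default 2.5).

Flags never remove compounds; what to do with a flagged compound is the
modeller's call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .pls import PLSModel

__all__ = [
    "OutlierDiagnostics",
    "leverages",
    "studentized_residuals",
    "outlier_report",
]


def leverages(model: PLSModel) -> np.ndarray:
    """Per-compound leverage h_i = 1/n + t_i'(T'T)^{-1} t_i.

    The leverages of a fitted model sum to A + 1 (score trace identity).
    """
    T = model.scores
    n = T.shape[0]
    G = T.T @ T
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular score cross-product; cannot compute leverages") from exc
    return 1.0 / n + np.einsum("ij,jk,ik->i", T, Ginv, T)


def studentized_residuals(
    y: np.ndarray, fitted: np.ndarray, h: np.ndarray, p: int
) -> np.ndarray:
    """Internally studentized residuals r_i = e_i / (s * sqrt(1 - h_i)).

    ``s`` is the standard error of calibration sqrt(RSS / (n - p - 1)).
    """
    y = np.asarray(y, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    h = np.asarray(h, dtype=float)
    n = y.size
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    if np.any(h >= 1) or np.any(h <= 0):
        raise ValueError("leverages must lie strictly in (0, 1)")
    resid = y - fitted
    s = math.sqrt(float(resid @ resid) / (n - p - 1))
    if s == 0:
        return np.zeros_like(resid)
    return resid / (s * np.sqrt(1.0 - h))


@dataclass
class OutlierDiagnostics:
    """Leverage/residual diagnostics for every training compound."""

    ids: list[str] | None
    leverage: np.ndarray
    r_student: np.ndarray
    leverage_cutoff: float
    residual_threshold: float
    high_leverage: np.ndarray
    high_residual: np.ndarray

    @property
    def outlier_free(self) -> bool:
        return not bool(self.high_residual.any())


def outlier_report(
    model: PLSModel,
    y: np.ndarray | None = None,
    residual_threshold: float = 2.5,
    leverage_rule: Union[float, Callable[[int, int], float], None] = None,
    ids: list[str] | None = None,
) -> OutlierDiagnostics:
    """Combined leverage + studentized-residual report for a fitted model.

    ``leverage_rule`` may be a number (used as h* directly), a callable
    ``(A, n) -> h*``, or None for the default 3(A + 1)/n.
    """
    y = model.y if y is None else np.asarray(y, dtype=float)
    h = leverages(model)
    n = h.size
    A = model.n_components
    if leverage_rule is None:
        h_star = 3.0 * (A + 1) / n
    elif callable(leverage_rule):
        h_star = float(leverage_rule(A, n))
    else:
        h_star = float(leverage_rule)
    r = studentized_residuals(y, model.fitted, h, A)
    return OutlierDiagnostics(
        ids=ids,
        leverage=h,
        r_student=r,
        leverage_cutoff=h_star,
        residual_threshold=residual_threshold,
        high_leverage=h > h_star,
        high_residual=np.abs(r) > residual_threshold,
    )
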