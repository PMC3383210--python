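"""Descriptor-matrix cleaning, autoscaling and the activity-correlation filter.

Preprocessing follows the standard chemometric sequence: drop degenerate
columns (missing values, invariant or quasi-invariant descriptors), then
autoscale (column-wise mean-centre and scale to unit sample variance), and
optionally discard descriptors whose absolute Pearson correlation with the
response falls below a threshold before variable selection proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .dataio import DescriptorTable

__all__ = [
    "ScalingParams",
    "FilterReport",
    "autoscale",
    "remove_degenerate_columns",
    "correlation_prefilter",
    "pearson_columns",
]


@dataclass
class ScalingParams:
    """Per-column mean and sample standard deviation (n-1 denominator)."""

    mean: np.ndarray
    sd: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean/sd shape mismatch")
        if np.any(self.sd <= 0):
            bad = np.nonzero(self.sd <= 0)[0]
            name = self.names[bad[0]] if self.names else f"column {bad[0]}"
            raise ValueError(f"non-positive standard deviation for {name}")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.sd + self.mean


@dataclass
class FilterReport:
    """Which columns a cleaning/filter step kept and why the rest were dropped."""

    kept: list[str]
    removed_missing: list[str] = field(default_factory=list)
    removed_invariant: list[str] = field(default_factory=list)
    removed_quasi_invariant: list[str] = field(default_factory=list)
    removed_low_correlation: list[str] = field(default_factory=list)
    abs_r: dict[str, float] = field(default_factory=dict)
    threshold: float | None = None

    @property
    def removed(self) -> list[str]:
        return (
            self.removed_missing
            + self.removed_invariant
            + self.removed_quasi_invariant
            + self.removed_low_correlation
        )


def _as_matrix(X: Union[DescriptorTable, np.ndarray]):
    if isinstance(X, DescriptorTable):
        return X.values, X.names, X.ids
    arr = np.asarray(X, dtype=float)
    return arr, [f"x{j}" for j in range(arr.shape[1])], None


def autoscale(X: Union[DescriptorTable, np.ndarray]) -> tuple[np.ndarray, ScalingParams]:
    """Mean-centre each column and scale it to unit sample variance.

    Returns the scaled matrix and the :class:`ScalingParams` needed to apply
    the identical transform to new compounds (or to invert it).  Raises if
    any column has zero variance, naming the column.
    """
    values, names, _ = _as_matrix(X)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    zero = np.nonzero(sd <= 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance column: {names[zero[0]]!r}")
    params = ScalingParams(mean=mean, sd=sd, names=list(names))
    return (values - mean) / sd, params


def remove_degenerate_columns(
    X: DescriptorTable, quasi_invariant_fraction: float = 0.95
) -> tuple[DescriptorTable, FilterReport]:
    """Drop descriptors with missing values, zero variance, or a dominant mode.

    A column is quasi-invariant when its most frequent value occurs in more
    than ``quasi_invariant_fraction`` of the compounds.
    """
    if not 0 < quasi_invariant_fraction <= 1:
        raise ValueError("quasi_invariant_fraction must be in (0, 1]")
    n = X.n
    keep, missing, invariant, quasi = [], [], [], []
    for j, name in enumerate(X.names):
        col = X.values[:, j]
        if np.any(~np.isfinite(col)):
            missing.append(name)
            continue
        if np.ptp(col) == 0:
            invariant.append(name)
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / n > quasi_invariant_fraction:
            quasi.append(name)
            continue
        keep.append(name)
    if not keep:
        raise ValueError("no descriptors remain after degeneracy filtering")
    report = FilterReport(
        kept=keep,
        removed_missing=missing,
        removed_invariant=invariant,
        removed_quasi_invariant=quasi,
    )
    return X.select(keep), report


def pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``X`` with ``y``.

    Zero-variance columns get r = 0 (they carry no linear association).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    if sy == 0:
        raise ValueError("zero-variance response")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    return r


def correlation_prefilter(
    X: DescriptorTable, y: np.ndarray, min_abs_r: float = 0.3
) -> tuple[DescriptorTable, FilterReport]:
    """Keep descriptors with |Pearson r| >= ``min_abs_r`` against the response.

    The boundary is inclusive: a descriptor at exactly the threshold is kept
    (only correlations strictly lower are eliminated).  The report carries
    |r| for every input descriptor.
    """
    if not 0 <= min_abs_r <= 1:
        raise ValueError("min_abs_r must be in [0, 1]")
    y = np.asarray(y, dtype=float)
    r = pearson_columns(X.values, y)
    abs_r = np.abs(r)
    kept = [name for name, a in zip(X.names, abs_r) if a >= min_abs_r]
    removed = [name for name, a in zip(X.names, abs_r) if a < min_abs_r]
    if not kept:
        raise ValueError("no descriptors remain after the correlation filter")
    report = FilterReport(
        kept=kept,
        removed_low_correlation=removed,
        abs_r={name: float(a) for name, a in zip(X.names, abs_r)},
        threshold=min_abs_r,
    )
    return X.select(kept), report
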