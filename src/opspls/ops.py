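"""Ordered predictors selection (OPS) over PLS1 models.

OPS ranks the descriptors by an *informative vector* — the correlation
vector, the PLS regression vector, or their element-wise product — reorders
the matrix so the most informative columns come first, and then scans nested
column subsets of increasing size, fitting a PLS model and scoring it by
leave-one-out Q² (or equivalently SEV) at each candidate number of latent
variables.  The best-scoring (subset, LV count) pair is returned together
with the full trial table.

Ties are broken towards parsimony: smaller subset, then fewer latent
variables, then lexicographic descriptor names — which also makes the search
fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .dataio import DescriptorTable
from .pls import _nipals_pls1
from .preprocess import pearson_columns
from .validation import loo_cv

__all__ = [
    "OPSConfig",
    "Trial",
    "OPSResult",
    "AllVectorsResult",
    "informative_vector",
    "ops_search",
    "run_all_vectors",
    "VECTOR_KINDS",
]

VECTOR_KINDS = ("correlation", "regression", "product")


@dataclass
class OPSConfig:
    """Hyperparameters of the OPS scan.

    window
        Initial subset size; defaults to the largest candidate LV count.
    increment
        Step between successive subset sizes.
    max_subset
        Largest subset size tried; defaults to min(m, 30).
    lv_range
        Candidate latent-variable counts; defaults to 1..min(8, n - 2).
    criterion
        "q2" (maximise leave-one-out Q²) or "sev" (minimise SEV) — monotone
        transforms of PRESS at fixed n, hence equivalent rankings.
    refit_scaling
        Re-autoscale within each leave-one-out fold (leakage-safe default).
    """

    window: int | None = None
    increment: int = 1
    max_subset: int | None = None
    lv_range: tuple[int, ...] | None = None
    criterion: str = "q2"
    refit_scaling: bool = True

    def resolved(self, n: int, m: int) -> "OPSConfig":
        lv = self.lv_range or tuple(range(1, min(8, n - 2) + 1))
        lv = tuple(sorted(set(int(a) for a in lv)))
        if not lv or lv[0] < 1 or lv[-1] > n - 2:
            raise ValueError(f"lv_range {lv} infeasible for n={n}")
        window = self.window if self.window is not None else lv[-1]
        max_subset = self.max_subset if self.max_subset is not None else min(m, 30)
        if not 1 <= window <= max_subset <= m:
            raise ValueError(
                f"need 1 <= window ({window}) <= max_subset ({max_subset}) <= m ({m})"
            )
        if self.increment < 1:
            raise ValueError("increment must be >= 1")
        if self.criterion not in ("q2", "sev"):
            raise ValueError("criterion must be 'q2' or 'sev'")
        return OPSConfig(window, self.increment, max_subset, lv, self.criterion,
                         self.refit_scaling)


@dataclass
class Trial:
    size: int
    n_lv: int
    q2: float
    sev: float


@dataclass
class OPSResult:
    """Outcome of one OPS scan with a single informative vector."""

    vector_kind: str
    ranking: list[str]               # all descriptors, most informative first
    trials: list[Trial]
    best_names: list[str]
    best_lv: int
    best_q2: float
    best_sev: float
    criterion: str

    @property
    def best_score(self) -> float:
        return self.best_q2 if self.criterion == "q2" else self.best_sev


@dataclass
class AllVectorsResult:
    """Best OPS result across the three informative vectors."""

    best: OPSResult
    per_kind: dict[str, OPSResult] = field(default_factory=dict)


def informative_vector(
    Xs: np.ndarray, yc: np.ndarray, kind: str, pilot_lv: int | None = None
) -> np.ndarray:
    """Descriptor importance scores on autoscaled X and centred y.

    correlation
        Pearson r of each column with y.
    regression
        Standardized regression vector of a pilot PLS fit with ``pilot_lv``
        components (default: min(8, n - 2) capped by m).
    product
        Element-wise product of the two.
    """
    Xs = np.asarray(Xs, dtype=float)
    yc = np.asarray(yc, dtype=float)
    if kind not in VECTOR_KINDS:
        raise ValueError(f"unknown informative vector kind {kind!r}")
    if kind == "correlation":
        return pearson_columns(Xs, yc)
    n, m = Xs.shape
    a = pilot_lv if pilot_lv is not None else min(8, n - 2, m)
    a = min(a, n - 1, m)
    _, _, _, _, b = _nipals_pls1(Xs, yc - yc.mean(), a)
    sy = yc.std(ddof=1)
    reg = b / sy if sy > 0 else b
    if kind == "regression":
        return reg
    return pearson_columns(Xs, yc) * reg


def _rank_names(X: DescriptorTable, y: np.ndarray, kind: str, pilot_lv: int) -> list[str]:
    from .preprocess import autoscale

    Xs, _ = autoscale(X)
    scores = informative_vector(Xs, y - y.mean(), kind, pilot_lv=pilot_lv)
    # stable sort on (-|score|, name) for deterministic ties
    order = sorted(range(X.m), key=lambda j: (-abs(scores[j]), X.names[j]))
    return [X.names[j] for j in order]


def _better(a: tuple, b: tuple, criterion: str) -> bool:
    """True if trial key ``a`` beats ``b``; keys are (score, size, lv, names)."""
    sa, za, la, na = a
    sb, zb, lb, nb = b
    if sa != sb:
        return sa > sb if criterion == "q2" else sa < sb
    return (za, la, na) < (zb, lb, nb)


def ops_search(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    config: OPSConfig | None = None,
    kind: str = "product",
) -> OPSResult:
    """Run the OPS scan with one informative vector.

    Descriptors are ranked by |score|, then nested subsets of size window,
    window + increment, ... <= max_subset are evaluated by leave-one-out Q²
    at every feasible LV count.
    """
    if not isinstance(X, DescriptorTable):
        arr = np.asarray(X, dtype=float)
        X = DescriptorTable([f"c{i}" for i in range(arr.shape[0])],
                            [f"x{j}" for j in range(arr.shape[1])], arr)
    y = np.asarray(y, dtype=float)
    cfg = (config or OPSConfig()).resolved(X.n, X.m)
    ranking = _rank_names(X, y, kind, pilot_lv=max(cfg.lv_range))

    trials: list[Trial] = []
    best_key = None
    best = None
    for size in range(cfg.window, cfg.max_subset + 1, cfg.increment):
        names = ranking[:size]
        sub = X.select(names).values
        for lv in cfg.lv_range:
            if lv > min(size, X.n - 2):
                continue
            cv = loo_cv(sub, y, lv, refit_scaling=cfg.refit_scaling)
            trials.append(Trial(size=size, n_lv=lv, q2=cv.q2, sev=cv.sev))
            score = cv.q2 if cfg.criterion == "q2" else cv.sev
            key = (score, size, lv, tuple(sorted(names)))
            if best_key is None or _better(key, best_key, cfg.criterion):
                best_key = key
                best = (names, lv, cv.q2, cv.sev)
    if best is None:
        raise ValueError("no feasible (subset size, LV) combination")
    names, lv, q2, sev = best
    return OPSResult(
        vector_kind=kind, ranking=ranking, trials=trials,
        best_names=list(names), best_lv=lv, best_q2=q2, best_sev=sev,
        criterion=cfg.criterion,
    )


def run_all_vectors(
    X: Union[DescriptorTable, np.ndarray],
    y: np.ndarray,
    config: OPSConfig | None = None,
) -> AllVectorsResult:
    """Run the OPS scan with all three informative vectors; keep the best."""
    cfg = config or OPSConfig()
    per_kind = {kind: ops_search(X, y, cfg, kind=kind) for kind in VECTOR_KINDS}
    criterion = cfg.criterion
    best = None
    best_key = None
    for kind in VECTOR_KINDS:
        res = per_kind[kind]
        score = res.best_q2 if criterion == "q2" else res.best_sev
        key = (score, len(res.best_names), res.best_lv, tuple(sorted(res.best_names)))
        if best_key is None or _better(key, best_key, criterion):
            best_key, best = key, res
    return AllVectorsResult(best=best, per_kind=per_kind)
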