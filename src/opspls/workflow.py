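"""End-to-end pipeline runner and the packaged-table reproduction report.

``run_pipeline`` chains the whole analysis — cleaning, autoscaling, the
|r| prefilter, OPS variable selection, the PLS fit, the internal validation
battery (R²/SEC/F, LOO, LNO, y-randomization), a train/test split, external
validation and outlier diagnostics — and returns one JSON-serializable
report with every statistic and its pass/fail against the usual QSAR
thresholds (R² > 0.6, Q² > 0.5, R²pred > 0.5, slopes in [0.85, 1.15]).

``reproduce_paper`` recomputes, from the packaged reference tables alone,
every statistic that is recomputable at desk scale (external-validation
metrics from the observed/predicted table; SEC, F, Q², SEV and critical-F
consistency of both printed statistic blocks; the activity conversions) and
compares each to its printed value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import yaml

from . import dataio, diagnostics, external, ops, preprocess, validation
from .pls import fit_pls, standardized_coefficients, wold_report
from .synthetic import paperlike

__all__ = ["PipelineConfig", "run_pipeline", "reproduce_paper"]

R2_LIMIT = 0.6
Q2_LIMIT = 0.5


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; all seeds explicit."""

    activity: Optional[str] = None       # CSV path or fixture name
    descriptors: Optional[str] = None    # CSV path
    synthetic_seed: Optional[int] = None  # use the paperlike generator instead
    quasi_invariant_fraction: float = 0.95
    min_abs_r: float = 0.3
    ops_window: Optional[int] = None
    ops_increment: int = 1
    ops_max_subset: Optional[int] = None
    ops_lv_range: Optional[list[int]] = None
    ops_criterion: str = "q2"
    n_components: Optional[int] = None   # None -> LV count chosen by OPS
    lno_n_max: int = 7
    lno_replicates: int = 6
    n_scrambles: int = 10
    n_test: int = 5
    test_ids: Optional[list[str]] = None
    hca_linkage: str = "complete"
    seed: int = 0
    permute_y: bool = False              # negative control: destroy the signal

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def ops_config(self) -> ops.OPSConfig:
        return ops.OPSConfig(
            window=self.ops_window,
            increment=self.ops_increment,
            max_subset=self.ops_max_subset,
            lv_range=tuple(self.ops_lv_range) if self.ops_lv_range else None,
            criterion=self.ops_criterion,
        )


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis and return a machine-readable report."""
    # ---- data -----------------------------------------------------------
    if config.synthetic_seed is not None:
        ds = _stage("data", paperlike, config.synthetic_seed)
        X, y, ids = ds.descriptors, ds.y, ds.descriptors.ids
    else:
        if config.activity is None or config.descriptors is None:
            raise ValueError("need activity + descriptors paths, or synthetic_seed")
        act = _stage("data", dataio.load_activity_table, config.activity)
        X = _stage("data", dataio.load_descriptor_table, config.descriptors)
        X = X.rows(act.ids)  # align rows to the activity table
        y, ids = act.pic50, act.ids

    rng = np.random.default_rng(config.seed)
    if config.permute_y:
        y = y[rng.permutation(len(y))]

    # ---- cleaning and prefilter ----------------------------------------
    X_clean, clean_report = _stage(
        "clean", preprocess.remove_degenerate_columns, X, config.quasi_invariant_fraction
    )
    X_filt, corr_report = _stage(
        "prefilter", preprocess.correlation_prefilter, X_clean, y, config.min_abs_r
    )

    # ---- OPS variable selection ----------------------------------------
    all_vec = _stage("ops", ops.run_all_vectors, X_filt, y, config.ops_config())
    best = all_vec.best
    selected = best.best_names
    n_lv = config.n_components or best.best_lv

    # ---- final model and internal validation ---------------------------
    X_sel = X_filt.select(selected)
    model = _stage("fit", fit_pls, X_sel, y, n_lv)
    fit_stats = _stage("fit", validation.fit_statistics, y, model.fitted, n_lv)
    coef_report = standardized_coefficients(model)
    cv = _stage("loo", validation.loo_cv, X_sel, y, n_lv)
    lno = _stage(
        "lno", validation.lno_cv, X_sel, y, n_lv,
        n_max=config.lno_n_max, replicates=config.lno_replicates, seed=config.seed,
    )
    yrand = _stage(
        "y-randomization", validation.y_randomization, X_sel, y, n_lv,
        n_scrambles=config.n_scrambles, seed=config.seed,
    )

    # ---- split, refit, external validation -----------------------------
    if config.test_ids:
        split = _stage("split", external.fixed_split, ids, config.test_ids)
    else:
        split = _stage(
            "split", external.hca_split, X_filt, y,
            config.n_test, config.hca_linkage, config.seed,
        )
    pos = {cid: k for k, cid in enumerate(ids)}
    tr = [pos[i] for i in split.train_ids]
    te = [pos[i] for i in split.test_ids]
    model_tr = _stage("refit", fit_pls, X_sel.values[tr], y[tr], n_lv,
                      names=selected)
    fit_tr = validation.fit_statistics(y[tr], model_tr.fitted, n_lv)
    cv_tr = validation.loo_cv(X_sel.values[tr], y[tr], n_lv)
    pred_te = model_tr.predict(X_sel.values[te])
    ext = _stage("external", external.external_metrics, y[te], pred_te,
                 float(np.mean(y[tr])))

    # ---- diagnostics ----------------------------------------------------
    diag = _stage("diagnostics", diagnostics.outlier_report, model, y, ids=ids)

    report = {
        "data": {"n": len(ids), "m_raw": X.m, "ids": ids,
                 "source": "synthetic" if config.synthetic_seed is not None else "files",
                 "permuted_y": config.permute_y},
        "prefilter": {
            "m_after_cleaning": len(clean_report.kept),
            "m_after_correlation_filter": len(corr_report.kept),
            "threshold": corr_report.threshold,
            "removed_degenerate": clean_report.removed,
        },
        "selection": {
            "vector_kind": best.vector_kind,
            "descriptors": selected,
            "n_lv": n_lv,
            "best_q2": best.best_q2,
            "best_sev": best.best_sev,
            "per_kind_best_q2": {k: r.best_q2 for k, r in all_vec.per_kind.items()},
        },
        "model": {
            "coefficients_raw": dict(zip(selected, model.coef_raw.tolist())),
            "intercept": model.intercept,
            "standardized_coefficients": dict(zip(selected, model.coef_std.tolist())),
            "wold_threshold": coef_report.threshold,
            "significant": dict(zip(selected, coef_report.significant.tolist())),
            "explained_x_variance": model.explained_x_variance.tolist(),
            "cumulative_x_variance": float(model.explained_x_variance.sum()),
        },
        "calibration": {
            "r2": fit_stats.r2, "sec": fit_stats.sec, "f_value": fit_stats.f_value,
            "f_crit": fit_stats.f_crit, "ssy": fit_stats.ssy, "n": fit_stats.n,
            "p": fit_stats.p,
        },
        "cross_validation": {
            "q2_loo": cv.q2, "sev": cv.sev, "press": cv.press, "ssy": cv.ssy,
        },
        "lno": {
            "n_values": lno.n_values,
            "mean": {str(k): v for k, v in lno.mean.items()},
            "sd": {str(k): v for k, v in lno.sd.items()},
            "overall_mean": lno.overall_mean,
            "replicates": lno.replicates,
        },
        "y_randomization": {
            "n_scrambles": yrand.n_scrambles,
            "intercept_r2": yrand.intercept_r2,
            "intercept_q2": yrand.intercept_q2,
            "max_scrambled_r2": float(yrand.r2.max()),
            "max_scrambled_q2": float(yrand.q2.max()),
        },
        "split": {"method": split.method, "train_ids": split.train_ids,
                  "test_ids": split.test_ids},
        "training_model": {"r2": fit_tr.r2, "sec": fit_tr.sec,
                           "q2_loo": cv_tr.q2, "sev": cv_tr.sev,
                           "press": cv_tr.press, "ssy": cv_tr.ssy},
        "external": {
            "r2pred": ext.r2pred, "sep": ext.sep, "press_test": ext.press_test,
            "k": ext.k, "kprime": ext.kprime,
            "r2_0": ext.r2_0, "rprime2_0": ext.rprime2_0, "abs_diff": ext.abs_diff,
        },
        "diagnostics": {
            "leverage_cutoff": diag.leverage_cutoff,
            "residual_threshold": diag.residual_threshold,
            "n_high_leverage": int(diag.high_leverage.sum()),
            "n_high_residual": int(diag.high_residual.sum()),
            "high_leverage_ids": [i for i, f in zip(ids, diag.high_leverage) if f],
            "high_residual_ids": [i for i, f in zip(ids, diag.high_residual) if f],
        },
        "flags": {
            "r2_above_0.6": fit_stats.r2 > R2_LIMIT,
            "q2_above_0.5": cv.q2 > Q2_LIMIT,
            "press_below_ssy": cv.press < cv.ssy,
            "f_above_critical": fit_stats.f_value > fit_stats.f_crit,
            "yrand_intercepts_ok": yrand.pass_r2 and yrand.pass_q2,
            "r2pred_above_0.5": ext.pass_r2pred,
            "k_in_range": ext.pass_k,
            "kprime_in_range": ext.pass_kprime,
            "r2_0_diff_below_0.3": ext.pass_diff,
            "outlier_free": diag.outlier_free,
        },
        "seeds": {"pipeline": config.seed, "synthetic": config.synthetic_seed},
    }
    return report


# ---------------------------------------------------------------------------
# reproduction of the packaged reference values
# ---------------------------------------------------------------------------

def _target(name, computed, reference, tol):
    return {
        "name": name,
        "computed": float(computed),
        "reference": float(reference),
        "tolerance": float(tol),
        "ok": bool(abs(computed - reference) <= tol),
    }


def reproduce_paper(test_ids: Optional[list[str]] = None) -> dict[str, Any]:
    """Recompute every desk-scale statistic from the packaged tables.

    ``test_ids`` overrides the external test set used for the training-mean
    and SSy(26) computations (default: the ids of the observed/predicted
    table).  Returns a dict with the target list and an ``all_ok`` flag.
    """
    act = dataio.load_activity_table("table1")
    obs_pred = dataio.load_observed_predicted("table2")
    eq1 = dataio.load_model_stats("eq1_stats")
    eq2 = dataio.load_model_stats("eq2_stats")
    test_ids = list(test_ids) if test_ids else [str(i) for i in eq2["test_ids"]]

    train = act.drop([i for i in test_ids if i in act.ids])
    y_train_mean = float(train.pic50.mean())
    targets: list[dict] = []

    # activity conversion: every printed pIC50 agrees with 9 - log10(IC50/nM)
    dev = max(
        abs(r.pic50 - dataio.ic50_to_pic50(r.ic50_nM)) for r in act.records
    )
    targets.append(_target("pic50_conversion_max_abs_dev", dev, 0.0, 5e-4))

    # response sums of squares
    targets.append(_target("ssy_full", validation.ssy(act.pic50), eq1["ssy"], 2e-3))
    targets.append(_target("ssy_training", validation.ssy(train.pic50), eq2["ssy"], 2e-3))

    # external validation from the observed/predicted table
    ext = external.external_metrics(obs_pred.observed, obs_pred.predicted, y_train_mean)
    ref = eq2["external"]
    targets.append(_target("r2pred", ext.r2pred, ref["r2_pred"], 2e-3))
    targets.append(_target("sep", ext.sep, ref["sep"], 2e-3))
    targets.append(_target("k", ext.k, ref["k"], 2e-3))
    targets.append(_target("kprime", ext.kprime, ref["k_prime"], 2e-3))
    targets.append(_target("abs_r2_diff", ext.abs_diff, ref["abs_r2_diff"], 2e-3))

    # algebraic consistency of both printed statistic blocks
    for label, blk in (("eq1", eq1), ("eq2", eq2)):
        n, p, r2, ssy_, press = blk["n"], blk["p"], blk["r2"], blk["ssy"], blk["press"]
        rss = (1.0 - r2) * ssy_
        sec = np.sqrt(rss / (n - p - 1))
        f_value = (r2 / p) / ((1.0 - r2) / (n - p - 1))
        q2 = 1.0 - press / ssy_
        sev = np.sqrt(press / n)
        from scipy import stats as sps

        f_crit = sps.f.ppf(1 - blk["alpha"], p, n - p - 1)
        targets.append(_target(f"{label}_sec", sec, blk["sec"], 1e-3))
        targets.append(_target(f"{label}_f_value", f_value, blk["f_value"], 0.1))
        targets.append(_target(f"{label}_q2", q2, blk["q2_loo"], 1e-3))
        targets.append(_target(f"{label}_sev", sev, blk["sev"], 1e-3))
        targets.append(_target(f"{label}_f_crit", f_crit, blk["f_crit"], 1e-3))

    # half-maximum coefficient-significance threshold of the full model
    b_std = np.array(list(eq1["standardized_coefficients"].values()))
    rep = wold_report(b_std, list(eq1["standardized_coefficients"]))
    targets.append(_target("wold_threshold", rep.threshold, eq1["wold_threshold"], 1e-3))

    return {
        "test_ids": test_ids,
        "y_train_mean": y_train_mean,
        "targets": targets,
        "all_ok": all(t["ok"] for t in targets),
    }
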