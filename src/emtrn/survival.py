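"""Prognostic screening of biclique modules.

Per module, a joint multi-gene Cox proportional-hazards model is fitted on a
random half of the tumor samples (Breslow tie handling, Newton iterations);
the linear risk score sum_i beta_i * x_i is dichotomized at the training
median (ties go to the low-risk group) and the high/low groups are compared
with the two-group log-rank test in both the training and the held-out half.
A module is retained when the log-rank p-value is <= the cut in BOTH halves,
with no correction across modules (the screen reports raw p-values).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from sksurv.linear_model import CoxPHSurvivalAnalysis

from .bicliques import BicliqueModule
from .errors import ParameterError

MAX_ABS_COEF = 50.0  # beyond this the partial likelihood is considered monotone


@dataclass
class RiskModel:
    """Fitted risk model and train/test screening result for one module."""

    module_id: str
    genes: list[str]
    coefficients: np.ndarray
    cutoff: float
    chi2_train: float
    p_train: float
    chi2_test: float
    p_test: float
    retained: bool
    flags: list[str] = field(default_factory=list)


def split_samples(samples: list[str], seed: int) -> pd.Series:
    """Random half split: first ceil(n/2) of a uniform permutation train."""
    if len(samples) < 4:
        raise ParameterError(f"need >= 4 samples to split, got {len(samples)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    n_train = math.ceil(len(samples) / 2)
    labels = np.empty(len(samples), dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train:]] = "test"
    return pd.Series(labels, index=samples, name="partition")


def fit_cox(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    standardize: bool = False,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> np.ndarray:
    """Joint Cox PH fit of module genes (rows of ``expression``) on samples.

    ``survival`` carries sample_id/time/event for the training samples.
    Raises ParameterError on degenerate covariates, monotone likelihood or
    non-convergence.
    """
    surv = survival.set_index("sample_id").loc[expression.columns]
    if not surv["event"].any():
        raise ParameterError("no events in the training set")
    X = expression.to_numpy(dtype=float).T
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(expression.index[sd == 0])
        raise ParameterError(f"constant covariate(s): {bad[:3]}")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    y = np.empty(len(surv), dtype=[("event", bool), ("time", float)])
    y["event"] = surv["event"].to_numpy(dtype=bool)
    y["time"] = surv["time"].to_numpy(dtype=float)
    model = CoxPHSurvivalAnalysis(ties="breslow", tol=tol, n_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            model.fit(X, y)
        except Exception as exc:  # singular Hessian, no convergence, ...
            raise ParameterError(f"Cox fit failed: {exc}") from exc
    coef = np.asarray(model.coef_, dtype=float)
    if not np.all(np.isfinite(coef)) or np.abs(coef).max() > MAX_ABS_COEF:
        raise ParameterError("monotone partial likelihood: no finite MLE")
    if standardize:
        coef = coef / sd
    return coef


def risk_scores_and_split(
    coefficients: np.ndarray,
    expression: pd.DataFrame,
    partition: pd.Series,
) -> pd.DataFrame:
    """Linear risk scores with the training-median cutoff applied everywhere.

    Returns a per-sample frame with columns score, risk_group, partition;
    samples exactly at the cutoff go to the low-risk group.
    """
    scores = pd.Series(
        expression.to_numpy(dtype=float).T @ np.asarray(coefficients, dtype=float),
        index=expression.columns,
        name="score",
    )
    train = partition.index[partition == "train"]
    cutoff = float(scores.loc[train].median())
    out = scores.to_frame()
    out["risk_group"] = np.where(scores > cutoff, "high", "low")
    out["partition"] = partition.reindex(out.index)
    out.attrs["cutoff"] = cutoff
    return out


def logrank_test(groups: pd.Series, survival: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square and p-value.

    ``groups`` maps sample_id -> 'high'/'low'. With no events in either
    group the test is undefined and (nan, 1.0) is returned.
    """
    surv = survival.set_index("sample_id").loc[groups.index]
    high = groups == "high"
    if high.all() or (~high).all():
        raise ParameterError("both risk groups must be non-empty")
    if not surv["event"].any():
        warnings.warn("no events; log-rank undefined, p = 1")
        return float("nan"), 1.0
    res = _lifelines_logrank(
        surv.loc[high.values, "time"], surv.loc[~high.values, "time"],
        event_observed_A=surv.loc[high.values, "event"].astype(int),
        event_observed_B=surv.loc[~high.values, "event"].astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def screen_prognostic_modules(
    modules: list[BicliqueModule],
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    survival: pd.DataFrame,
    seed: int,
    p_cut: float = 0.05,
    standardize: bool = False,
) -> list[RiskModel]:
    """Train/test survival screen of every module.

    One random half split of the tumor samples is drawn once (from ``seed``)
    and shared by all modules, mirroring a single randomized cohort split.
    Modules whose Cox fit fails are reported with a flag and not retained.
    """
    samples = [s for s in survival["sample_id"] if s in lnc_expr.columns]
    partition = split_samples(samples, seed)
    train_ids = list(partition.index[partition == "train"])
    results: list[RiskModel] = []
    expr_all = pd.concat([lnc_expr, mrna_expr])
    surv = survival.loc[survival["sample_id"].isin(samples)]
    for module in modules:
        genes = sorted(module.lncrnas) + sorted(module.mrnas)
        present = [g for g in genes if g in expr_all.index]
        if len(present) < len(genes):
            results.append(RiskModel(module.module_id, genes, np.array([]), np.nan,
                                     np.nan, np.nan, np.nan, np.nan, False,
                                     ["missing expression"]))
            continue
        E = expr_all.loc[present, samples]
        try:
            coef = fit_cox(E[train_ids], surv, standardize=standardize)
        except ParameterError as exc:
            results.append(RiskModel(module.module_id, present, np.array([]), np.nan,
                                     np.nan, np.nan, np.nan, np.nan, False, [str(exc)]))
            continue
        scored = risk_scores_and_split(coef, E, partition)
        flags: list[str] = []
        stats_by_part = {}
        for part in ("train", "test"):
            sub = scored.loc[scored["partition"] == part]
            if sub["risk_group"].nunique() < 2:
                stats_by_part[part] = (float("nan"), 1.0)
                flags.append(f"single risk group in {part}")
                continue
            stats_by_part[part] = logrank_test(sub["risk_group"], surv)
        (chi2_tr, p_tr), (chi2_te, p_te) = stats_by_part["train"], stats_by_part["test"]
        retained = bool(p_tr <= p_cut and p_te <= p_cut)
        results.append(RiskModel(module.module_id, present, coef,
                                 scored.attrs["cutoff"], chi2_tr, p_tr,
                                 chi2_te, p_te, retained, flags))
    return results


def risk_models_table(models: list[RiskModel]) -> pd.DataFrame:
    rows = [
        (m.module_id, ",".join(m.genes),
         ",".join(f"{c:.6g}" for c in m.coefficients),
         m.cutoff, m.chi2_train, m.p_train, m.chi2_test, m.p_test,
         int(m.retained), ";".join(m.flags))
        for m in models
    ]
    return pd.DataFrame(rows, columns=[
        "module_id", "genes", "coefficients", "cutoff",
        "chi2_train", "p_train", "chi2_test", "p_test", "retained", "flags",
    ])
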